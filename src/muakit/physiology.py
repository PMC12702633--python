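"""From fitted weights to tissue physiology.

Fitted weights multiply normalized component spectra, so they carry no
concentration scale of their own.  Anchoring the water content of lung
tissue at a known volume fraction (80% is a good estimate) lets the
remaining weights be rescaled onto the leftover volume: each non-water
chromophore receives a share of ``100 - water_fraction`` proportional to
its weight.

The fitted hemoglobin concentration then supports a back-calculation of
the blood volume concentration (BVC).  Whole blood decomposes into
hemoglobin, red-cell membranes, other cells, and plasma; with a known
hematocrit, the hemoglobin fraction of whole blood follows, and the
tissue's hemoglobin content scales up to a whole-blood volume.  The
plasma part of that volume is water, so it can be split off the
tissue's total water content to give the non-plasma ("bloodless")
water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mua import EnsembleStats
from .spectra import Spectrum
from .synthlib import ComponentLibrary
from .unmix import full_reconstruction

__all__ = [
    "BLOOD_PRESETS",
    "BloodModel",
    "ConcentrationTable",
    "BloodVolumeBreakdown",
    "weights_to_concentrations",
    "concentration_sd",
    "ensemble_concentrations",
    "hb_fraction_of_blood",
    "whole_blood_composition",
    "blood_volume_chain",
    "rounded_blood_volume_chain",
]


@dataclass(frozen=True)
class ConcentrationTable:
    """Per-component tissue concentrations (% of tissue volume).

    Water is pinned at the anchor fraction; the non-water concentrations
    sum to the remainder exactly.
    """

    concentrations: dict[str, float]
    water_fraction: float
    sds: dict[str, float] | None = None

    def __getitem__(self, name: str) -> float:
        return self.concentrations[name]

    @property
    def total(self) -> float:
        return float(sum(self.concentrations.values()))


def weights_to_concentrations(
    weights: dict[str, float], water_fraction: float = 80.0
) -> ConcentrationTable:
    """Rescale fitted weights onto a volume-percent scale.

    Water is fixed at ``water_fraction``; each non-water component gets
    ``p_i / sum(non-water p_j) * (100 - water_fraction)``.  Water's own
    weight does not enter the rescaling.
    """
    if "water" not in weights:
        raise ValueError("weights must include 'water'")
    if not 0 < water_fraction < 100:
        raise ValueError("water_fraction must lie in (0, 100)")
    others = {k: v for k, v in weights.items() if k != "water"}
    if not others:
        raise ValueError("need at least one non-water component")
    if any(v < 0 for v in others.values()):
        bad = {k: v for k, v in others.items() if v < 0}
        raise ValueError(f"negative weights: {bad}")
    total = sum(others.values())
    if total == 0:
        raise ValueError("all non-water weights are zero; rescaling is degenerate")
    remainder = 100.0 - water_fraction
    conc = {"water": water_fraction}
    conc.update({k: v / total * remainder for k, v in others.items()})
    return ConcentrationTable(concentrations=conc, water_fraction=water_fraction)


def concentration_sd(
    mean_mu_a: Spectrum,
    sd_mu_a: Spectrum,
    library: ComponentLibrary,
    water_fraction: float = 80.0,
    fit_window: np.ndarray | None = None,
) -> dict[str, float]:
    """Propagate the spectral ensemble SD to concentration SDs.

    The mean spectrum and the mean-plus-SD spectrum are each run through
    the full two-step reconstruction and converted to concentrations;
    the per-component absolute difference is the concentration SD.  The
    water anchor is fixed, so its SD is zero by construction.
    """
    if np.any(sd_mu_a.values < 0):
        raise ValueError("sd spectrum must be nonnegative")
    base = full_reconstruction(mean_mu_a, library, fit_window)
    shifted_spectrum = mean_mu_a.with_values(mean_mu_a.values + sd_mu_a.values)
    shifted = full_reconstruction(shifted_spectrum, library, fit_window)
    conc0 = weights_to_concentrations(base.weights, water_fraction)
    conc1 = weights_to_concentrations(shifted.weights, water_fraction)
    return {
        name: abs(conc1[name] - conc0[name]) for name in conc0.concentrations
    }


def ensemble_concentrations(
    stats: EnsembleStats,
    library: ComponentLibrary,
    water_fraction: float = 80.0,
    fit_window: np.ndarray | None = None,
) -> ConcentrationTable:
    """Concentrations (with SDs) from ensemble mean/SD spectra."""
    fit = full_reconstruction(stats.mean, library, fit_window)
    table = weights_to_concentrations(fit.weights, water_fraction)
    sds = concentration_sd(stats.mean, stats.sd, library, water_fraction, fit_window)
    return ConcentrationTable(
        concentrations=table.concentrations,
        water_fraction=water_fraction,
        sds=sds,
    )


@dataclass(frozen=True)
class BloodModel:
    """Volumetric composition of whole blood, all in percent.

    ``hematocrit`` is the cellular fraction of blood volume (RBCs +
    WBCs + platelets); ``other_cells`` the WBC + platelet part of it;
    ``hb_fraction_of_rbc`` the hemoglobin share of RBC volume.  Plasma
    is the complement of the hematocrit by construction.
    """

    hematocrit: float
    other_cells: float = 1.0
    hb_fraction_of_rbc: float = 95.0
    plasma_protein_fraction: float = 7.0
    albumin_fraction_of_plasma_protein: float = 55.0

    def __post_init__(self) -> None:
        for name in (
            "hematocrit",
            "other_cells",
            "hb_fraction_of_rbc",
            "plasma_protein_fraction",
            "albumin_fraction_of_plasma_protein",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {value}")

    @property
    def plasma_fraction(self) -> float:
        return 100.0 - self.hematocrit

    @property
    def rbc_fraction(self) -> float:
        return self.hematocrit - self.other_cells


#: Named presets: ``rabbit42`` is the mid-range adult-rabbit hematocrit
#: (33–50% span) used for the blood-volume chain; ``textbook45`` the
#: textbook human composition used for the whole-blood breakdown.
BLOOD_PRESETS = {
    "rabbit42": BloodModel(hematocrit=42.0),
    "textbook45": BloodModel(hematocrit=45.0),
}


def hb_fraction_of_blood(model: BloodModel) -> float:
    """Hemoglobin share of whole-blood volume, percent (unrounded).

    ``(hematocrit - other_cells) * hb_fraction_of_rbc / 100``; e.g.
    38.95% for the rabbit42 preset, conventionally rounded to 39%.
    """
    if model.hematocrit <= model.other_cells:
        raise ValueError(
            "hematocrit must exceed the WBC+platelet fraction "
            f"({model.hematocrit} <= {model.other_cells})"
        )
    return model.rbc_fraction * model.hb_fraction_of_rbc / 100.0


def whole_blood_composition(model: BloodModel) -> dict[str, float]:
    """Volumetric breakdown of whole blood, percent.

    ``hemoglobin + rbc_membranes + other_cells + plasma`` sums to 100;
    ``albumin`` (a sub-part of plasma) is reported alongside.
    """
    hb = model.rbc_fraction * model.hb_fraction_of_rbc / 100.0
    membranes = model.rbc_fraction - hb
    albumin = (
        model.plasma_fraction
        * model.plasma_protein_fraction
        * model.albumin_fraction_of_plasma_protein
        / 10_000.0
    )
    return {
        "hemoglobin": hb,
        "rbc_membranes": membranes,
        "other_cells": model.other_cells,
        "plasma": model.plasma_fraction,
        "albumin": albumin,
    }


@dataclass(frozen=True)
class BloodVolumeBreakdown:
    """Blood-volume back-calculation results, % of tissue volume.

    Identities: ``bvc = hb_in_tissue + non_hb_blood_in_tissue`` and
    ``plasma_in_tissue = non_hb_blood_in_tissue - cellular_non_hb_in_tissue``.
    """

    hb_fraction_of_blood: float
    hb_in_tissue: float
    non_hb_blood_in_tissue: float
    bvc: float
    cellular_non_hb_in_tissue: float
    plasma_in_tissue: float
    non_plasma_water: float
    water_fraction: float


def blood_volume_chain(
    hb_in_tissue: float,
    model: BloodModel,
    water_fraction: float = 80.0,
    *,
    round_hb_fraction: bool = True,
) -> BloodVolumeBreakdown:
    """Back-calculate the blood volume concentration from hemoglobin.

    With hemoglobin occupying ``f_hb`` percent of whole blood, a tissue
    hemoglobin content ``hb_in_tissue`` implies a non-hemoglobin blood
    volume of ``hb_in_tissue * (100 - f_hb) / f_hb``; their sum is the
    BVC.  The non-hemoglobin part splits into the cellular remainder
    (RBC membranes + other cells) and plasma; subtracting the plasma
    from the tissue's total water gives the non-plasma water.

    ``round_hb_fraction`` applies the convention of carrying ``f_hb``
    as a whole-number percentage (e.g. 39 rather than 38.95) through
    the chain; disable it for a fully unrounded computation.  All
    returned fields are otherwise full precision — see
    :func:`rounded_blood_volume_chain` for one-decimal presentation.
    """
    if hb_in_tissue < 0:
        raise ValueError("hb_in_tissue must be nonnegative")
    f_hb = hb_fraction_of_blood(model)
    if round_hb_fraction:
        f_hb = float(round(f_hb))
    if hb_in_tissue == 0:
        return BloodVolumeBreakdown(
            hb_fraction_of_blood=f_hb,
            hb_in_tissue=0.0,
            non_hb_blood_in_tissue=0.0,
            bvc=0.0,
            cellular_non_hb_in_tissue=0.0,
            plasma_in_tissue=0.0,
            non_plasma_water=water_fraction,
            water_fraction=water_fraction,
        )
    non_hb = hb_in_tissue * (100.0 - f_hb) / f_hb
    # Cellular share of the non-hemoglobin blood volume: RBC membranes
    # plus the other cells, relative to everything that is not hemoglobin.
    hb_blood = hb_fraction_of_blood(model)
    cellular_pct_of_blood = (model.rbc_fraction - hb_blood) + model.other_cells
    cellular = non_hb * cellular_pct_of_blood / (100.0 - f_hb)
    plasma = non_hb - cellular
    if plasma > water_fraction:
        raise ValueError(
            f"implied plasma volume ({plasma:.1f}%) exceeds the tissue water "
            f"fraction ({water_fraction}%); model and anchor are inconsistent"
        )
    return BloodVolumeBreakdown(
        hb_fraction_of_blood=f_hb,
        hb_in_tissue=hb_in_tissue,
        non_hb_blood_in_tissue=non_hb,
        bvc=hb_in_tissue + non_hb,
        cellular_non_hb_in_tissue=cellular,
        plasma_in_tissue=plasma,
        non_plasma_water=water_fraction - plasma,
        water_fraction=water_fraction,
    )


def rounded_blood_volume_chain(
    hb_in_tissue: float,
    model: BloodModel,
    water_fraction: float = 80.0,
) -> BloodVolumeBreakdown:
    """The blood-volume chain carried out on printed one-decimal values.

    Reproduces the figures of a hand calculation in which every
    intermediate is written down at one decimal and reused: the
    hemoglobin fraction of blood and the cellular percentages are
    carried as whole numbers, and the non-hemoglobin blood volume is
    truncated (not rounded) to one decimal before being chained, which
    keeps the downstream sums consistent with the written intermediate.
    """
    f_hb = float(round(hb_fraction_of_blood(model)))
    membranes = float(round(model.rbc_fraction - hb_fraction_of_blood(model)))
    cellular_pct_of_blood = membranes + float(round(model.other_cells))
    non_hb = math.floor(hb_in_tissue * (100.0 - f_hb) / f_hb * 10.0) / 10.0
    bvc = round(hb_in_tissue + non_hb, 1)
    cellular = round(non_hb * cellular_pct_of_blood / (100.0 - f_hb), 1)
    plasma = round(non_hb - cellular, 1)
    if plasma > water_fraction:
        raise ValueError(
            f"implied plasma volume ({plasma:.1f}%) exceeds the tissue water "
            f"fraction ({water_fraction}%); model and anchor are inconsistent"
        )
    return BloodVolumeBreakdown(
        hb_fraction_of_blood=f_hb,
        hb_in_tissue=hb_in_tissue,
        non_hb_blood_in_tissue=non_hb,
        bvc=bvc,
        cellular_non_hb_in_tissue=cellular,
        plasma_in_tissue=plasma,
        non_plasma_water=round(water_fraction - plasma, 1),
        water_fraction=water_fraction,
    )
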