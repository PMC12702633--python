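"""Absorption fold-ratios at named chromophore bands.

The fold-ratio of a chromophore — the absorption value at its band peak
divided by the baseline value at the same wavelength — is a content
proxy.  Before baseline removal the divisor is the fitted pigment
baseline curve; after removal it is the scalar flat floor of the
corrected spectrum.  Peaks are searched within a window around each
nominal centre, because band maxima drift by a few nm between tissues
(the protein band, nominally 230 nm, sits at 235 nm in lung).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baseline import BaselineFit
from .spectra import Spectrum, SpectraError

__all__ = [
    "DEFAULT_BANDS",
    "DivisionUndefinedError",
    "BandDefinition",
    "BandRatio",
    "FoldRatioReport",
    "locate_peak",
    "fold_ratios",
]


class DivisionUndefinedError(ValueError):
    """Baseline value at a band peak is not positive."""


@dataclass(frozen=True)
class BandDefinition:
    """A chromophore band: nominal centre and peak-search half-width, nm."""

    name: str
    nominal_center: float
    search_halfwidth: float = 15.0

    def __post_init__(self) -> None:
        if self.search_halfwidth <= 0:
            raise ValueError("search_halfwidth must be positive")


#: The major lung chromophore bands.
DEFAULT_BANDS = (
    BandDefinition("proteins", 235.0),
    BandDefinition("dna", 261.0),
    BandDefinition("hbo_soret", 412.0),
    BandDefinition("hbo_q540", 540.0),
    BandDefinition("hbo_q570", 570.0),
    BandDefinition("water", 974.0),
)


@dataclass(frozen=True)
class BandRatio:
    name: str
    peak_wavelength: float
    peak_mu_a: float
    baseline_value: float
    fold_ratio: float


@dataclass(frozen=True)
class FoldRatioReport:
    """Per-band fold-ratios in one mode: original or baseline_removed."""

    entries: tuple[BandRatio, ...]
    mode: str

    def __getitem__(self, name: str) -> BandRatio:
        for entry in self.entries:
            if entry.name == name:
                return entry
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "band": e.name,
                    "peak_nm": e.peak_wavelength,
                    "peak_mu_a": e.peak_mu_a,
                    "baseline_value": e.baseline_value,
                    "fold_ratio": e.fold_ratio,
                }
                for e in self.entries
            ]
        )


def locate_peak(spectrum: Spectrum, band: BandDefinition) -> float:
    """Wavelength of the maximum within the band's search window.

    Ties are broken toward the nominal centre, then toward shorter
    wavelength.
    """
    grid = spectrum.grid
    lo = band.nominal_center - band.search_halfwidth
    hi = band.nominal_center + band.search_halfwidth
    if lo < grid.start - 1e-9 or hi > grid.stop + 1e-9:
        raise SpectraError(
            f"search window [{lo}, {hi}] nm for band {band.name!r} "
            f"falls outside the grid [{grid.start}, {grid.stop}] nm"
        )
    mask = grid.mask(lo, hi)
    lam = grid.values[mask]
    vals = spectrum.values[mask]
    peak = vals.max()
    candidates = lam[vals == peak]
    order = np.lexsort((candidates, np.abs(candidates - band.nominal_center)))
    return float(candidates[order[0]])


def fold_ratios(
    spectrum: Spectrum,
    baseline_source: BaselineFit | float,
    bands=DEFAULT_BANDS,
) -> FoldRatioReport:
    """Fold-ratios of ``spectrum`` at each band.

    Parameters
    ----------
    spectrum : Spectrum
        Original mu_a (with a :class:`BaselineFit` source) or the
        baseline-removed spectrum (with a scalar floor).
    baseline_source : BaselineFit or float
        A fit makes the divisor the baseline curve at each located peak
        (mode ``original``); a positive scalar makes it a horizontal
        floor (mode ``baseline_removed``).
    """
    if isinstance(baseline_source, BaselineFit):
        mode = "original"

        def divisor(lam: float) -> float:
            return baseline_source.baseline.value_at(lam)

    else:
        mode = "baseline_removed"
        floor = float(baseline_source)

        def divisor(lam: float) -> float:
            return floor

    entries = []
    for band in bands:
        lam_peak = locate_peak(spectrum, band)
        peak = spectrum.value_at(lam_peak)
        base = divisor(lam_peak)
        if base <= 0:
            raise DivisionUndefinedError(
                f"baseline value {base:.6g} cm^-1 at {lam_peak:.0f} nm "
                f"(band {band.name!r}) is not positive"
            )
        entries.append(
            BandRatio(
                name=band.name,
                peak_wavelength=lam_peak,
                peak_mu_a=peak,
                baseline_value=base,
                fold_ratio=peak / base,
            )
        )
    return FoldRatioReport(entries=tuple(entries), mode=mode)
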