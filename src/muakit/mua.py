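"""Direct calculation of the absorption coefficient from measurements.

In the photon-diffusion (direct-calculation) regime the broadband
absorption coefficient of a thin tissue sample follows from its total
transmittance and total reflectance:

.. math:: \\mu_a(\\lambda) = \\frac{1 - (T_t(\\lambda) + R_t(\\lambda))}{d}

with *d* the sample thickness in cm, so that mu_a emerges in cm^-1.
The relation treats every photon that neither crosses the sample nor
returns from it as absorbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import GridMismatchError, Spectrum

__all__ = [
    "NonphysicalMeasurementError",
    "MeasurementPair",
    "EnsembleStats",
    "mu_a_from_measurement",
    "mu_a_ensemble",
    "ensemble_stats",
]

#: T_t + R_t may exceed 1 by at most this much (floating-point dust)
#: before the measurement is rejected as nonphysical.
SUM_TOLERANCE = 1e-9


class NonphysicalMeasurementError(ValueError):
    """T_t + R_t exceeds 1: the absorbed fraction would be negative."""

    def __init__(self, wavelengths: np.ndarray):
        self.wavelengths = np.asarray(wavelengths)
        shown = ", ".join(f"{w:.6g}" for w in self.wavelengths[:8])
        more = "" if self.wavelengths.size <= 8 else f" (+{self.wavelengths.size - 8} more)"
        super().__init__(f"T_t + R_t > 1 at wavelengths [nm]: {shown}{more}")


@dataclass(frozen=True)
class MeasurementPair:
    """One sample's T_t/R_t spectra and its thickness in cm."""

    sample_id: str
    transmittance: Spectrum
    reflectance: Spectrum
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.transmittance.grid != self.reflectance.grid:
            raise GridMismatchError(
                f"{self.sample_id}: T_t and R_t are on different grids"
            )
        for name, spec in (("T_t", self.transmittance), ("R_t", self.reflectance)):
            if spec.unit != "fraction":
                raise ValueError(f"{self.sample_id}: {name} must have unit 'fraction'")
        if self.thickness_cm <= 0:
            raise ValueError(f"{self.sample_id}: thickness must be positive")


def mu_a_from_measurement(
    pair: MeasurementPair, *, allow_nonphysical: bool = False
) -> Spectrum:
    """Absorption coefficient spectrum of one measurement pair, cm^-1.

    Sums marginally above 1 (within ``SUM_TOLERANCE``) are clamped to 1;
    larger violations raise :class:`NonphysicalMeasurementError` naming
    the offending wavelengths.

    Parameters
    ----------
    allow_nonphysical : bool
        For noisy ensembles, keep the raw sum instead of raising, so
        zero-mean measurement noise stays zero-mean on mu_a (individual
        values may then dip slightly below zero).  Default False.
    """
    total = pair.transmittance.values + pair.reflectance.values
    if not allow_nonphysical:
        bad = total > 1.0 + SUM_TOLERANCE
        if np.any(bad):
            raise NonphysicalMeasurementError(pair.transmittance.wavelengths[bad])
        total = np.minimum(total, 1.0)
    values = (1.0 - total) / pair.thickness_cm
    return Spectrum(pair.transmittance.grid, values, "cm^-1")


def mu_a_ensemble(pairs, *, allow_nonphysical: bool = False) -> "EnsembleStats":
    """Per-sample direct calculation followed by ensemble statistics."""
    spectra = [mu_a_from_measurement(p, allow_nonphysical=allow_nonphysical) for p in pairs]
    return ensemble_stats(spectra)


@dataclass(frozen=True)
class EnsembleStats:
    """Pointwise mean and sample SD of an ensemble of spectra."""

    mean: Spectrum
    sd: Spectrum
    n: int


def ensemble_stats(spectra) -> EnsembleStats:
    """Pointwise mean and sample standard deviation (n-1 denominator).

    With a single spectrum the SD is identically zero.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    grid = spectra[0].grid
    if any(s.grid != grid for s in spectra):
        raise GridMismatchError("ensemble spectra are not on a common grid")
    unit = spectra[0].unit
    stack = np.vstack([s.values for s in spectra])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros(grid.n_points)
    return EnsembleStats(
        mean=Spectrum(grid, mean, unit),
        sd=Spectrum(grid, sd, unit),
        n=len(spectra),
    )
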