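"""Wavelength grids and spectra.

These are the carrier types for everything downstream: absorption
coefficient spectra :math:`\\mu_a(\\lambda)` in cm\\ :sup:`-1`, measured
total transmittance/reflectance fractions, and normalized component
spectra.  The canonical acquisition grid is 200–1000 nm at a 1 nm step
(801 samples); all fitting happens on a single shared grid.

Normalization follows the shift-then-scale convention used for component
libraries in tissue spectroscopy: displace the spectrum so its minimum is
zero, then divide by the resulting maximum, mapping it onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CANONICAL_START",
    "CANONICAL_STOP",
    "CANONICAL_STEP",
    "UNITS",
    "SpectraError",
    "ExtrapolationError",
    "DegenerateSpectrumError",
    "GridMismatchError",
    "WavelengthGrid",
    "Spectrum",
    "resample",
    "normalize_spectrum",
]

CANONICAL_START = 200.0
CANONICAL_STOP = 1000.0
CANONICAL_STEP = 1.0

#: Allowed physical units for :class:`Spectrum` values.
UNITS = ("cm^-1", "fraction", "normalized")


class SpectraError(ValueError):
    """Base class for spectrum-domain errors."""


class ExtrapolationError(SpectraError):
    """Target grid extends beyond the source grid; no silent extrapolation."""


class DegenerateSpectrumError(SpectraError):
    """Constant spectrum cannot be normalized onto [0, 1]."""


class GridMismatchError(SpectraError):
    """Operation requires spectra on a common wavelength grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, strictly increasing wavelength grid in nanometres.

    Parameters
    ----------
    start, stop : float
        Inclusive endpoints, nm.
    step : float
        Grid spacing, nm.  ``(stop - start) / step`` must be integral.
    """

    start: float = CANONICAL_START
    stop: float = CANONICAL_STOP
    step: float = CANONICAL_STEP

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise SpectraError(f"step must be positive, got {self.step}")
        if self.stop <= self.start:
            raise SpectraError(
                f"stop ({self.stop}) must exceed start ({self.start})"
            )
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise SpectraError(
                "grid span is not an integral number of steps: "
                f"({self.start}, {self.stop}, {self.step})"
            )

    @classmethod
    def canonical(cls) -> "WavelengthGrid":
        """The 200–1000 nm, 1 nm acquisition grid (801 points)."""
        return cls(CANONICAL_START, CANONICAL_STOP, CANONICAL_STEP)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "WavelengthGrid":
        """Infer a uniform grid from explicit wavelengths.

        Raises
        ------
        SpectraError
            If the wavelengths are not strictly increasing with uniform
            spacing.
        """
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise SpectraError("need at least two wavelengths to infer a grid")
        diffs = np.diff(values)
        if np.any(diffs <= 0):
            raise SpectraError("wavelengths are not strictly increasing")
        step = float(np.median(diffs))
        if not np.allclose(diffs, step, rtol=1e-6, atol=1e-9 * max(1.0, step)):
            raise SpectraError("wavelength spacing is not uniform")
        return cls(float(values[0]), float(values[-1]), step)

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    def index_of(self, wavelength: float) -> int:
        """Index of an exact grid wavelength (raises if off-grid)."""
        pos = (wavelength - self.start) / self.step
        idx = int(round(pos))
        if abs(pos - idx) > 1e-6 or not 0 <= idx < self.n_points:
            raise SpectraError(f"{wavelength} nm is not on the grid {self}")
        return idx

    def mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points with ``lo <= λ <= hi`` (inclusive)."""
        lam = self.values
        return (lam >= lo - 1e-9) & (lam <= hi + 1e-9)


@dataclass(frozen=True, eq=False)
class Spectrum:
    """Values on a :class:`WavelengthGrid`.

    Parameters
    ----------
    grid : WavelengthGrid
    values : array-like
        One finite value per grid point.
    unit : {"cm^-1", "fraction", "normalized"}
        ``fraction`` constrains values to [0, 1] (dimensionless measured
        fractions); ``normalized`` marks spectra mapped onto [0, 1] by
        :func:`normalize_spectrum`; ``cm^-1`` carries absorption
        coefficients and differences thereof (may be negative after
        baseline subtraction).
    """

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)
    unit: str = "cm^-1"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.grid.n_points:
            raise SpectraError(
                f"expected {self.grid.n_points} values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise SpectraError("spectrum contains non-finite values")
        if self.unit not in UNITS:
            raise SpectraError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.unit == "fraction":
            if values.min() < -1e-9 or values.max() > 1 + 1e-9:
                raise SpectraError(
                    "fraction-valued spectrum outside [0, 1]: "
                    f"range [{values.min()}, {values.max()}]"
                )
            # Tolerate floating-point dust at the boundaries.
            object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    def value_at(self, wavelength: float) -> float:
        return float(self.values[self.grid.index_of(wavelength)])

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, unit or self.unit)


def resample(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Extrapolation is an error: every target wavelength must lie inside the
    source range.  The unit is preserved.
    """
    if target == spectrum.grid:
        return Spectrum(target, spectrum.values.copy(), spectrum.unit)
    if target.start < spectrum.grid.start - 1e-9 or target.stop > spectrum.grid.stop + 1e-9:
        raise ExtrapolationError(
            f"target grid [{target.start}, {target.stop}] nm extends beyond "
            f"source [{spectrum.grid.start}, {spectrum.grid.stop}] nm"
        )
    values = np.interp(target.values, spectrum.grid.values, spectrum.values)
    return Spectrum(target, values, spectrum.unit)


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Shift-then-scale a spectrum onto [0, 1].

    The spectrum is displaced so its minimum equals zero and then divided
    by its maximum, so the output has min 0 and max 1 and preserves the
    rank order of values.

    Raises
    ------
    DegenerateSpectrumError
        For a constant spectrum (zero peak-to-peak range).
    """
    lo = float(spectrum.values.min())
    span = float(spectrum.values.max()) - lo
    if span == 0.0:
        raise DegenerateSpectrumError("constant spectrum cannot be normalized")
    return Spectrum(spectrum.grid, (spectrum.values - lo) / span, "normalized")
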