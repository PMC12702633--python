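"""Pigment baseline reconstruction and removal.

Aging tissue accumulates melanin and lipofuscin, whose broadband,
wavelength-decreasing absorption forms a baseline under the chromophore
bands:

.. math:: \\mu_{a\\text{-baseline}}(\\lambda)
          = p_{Mel}\\,\\mu_{a\\text{-Mel}}(\\lambda)
          + p_{Lip}\\,\\mu_{a\\text{-Lip}}(\\lambda)

The two pigment weights are fitted by nonnegative least squares over a
band-free window — wavelengths where no chromophore band contributes, so
only the pigments constrain the fit — and the baseline is then evaluated
and subtracted on the full grid.  Negative residuals after subtraction
are kept, not clipped, so the residual floor between bands stays honest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectra import GridMismatchError, Spectrum, WavelengthGrid
from .synthlib import ComponentLibrary

__all__ = [
    "DEFAULT_EXCLUDED_CENTERS",
    "DEFAULT_EXCLUSION_HALFWIDTH",
    "DEFAULT_SHORT_CUTOFF",
    "DEFAULT_LONG_CUTOFF",
    "UnderdeterminedFitError",
    "BaselineFit",
    "default_fit_window",
    "fit_baseline",
    "subtract_baseline",
    "flat_floor",
]

#: Chromophore band centres excluded from the pigment fit window (nm):
#: proteins 235, DNA 261, HbO 275 / Soret 412 / Q-bands 540 and 570.
DEFAULT_EXCLUDED_CENTERS = (235.0, 261.0, 275.0, 412.0, 540.0, 570.0)
DEFAULT_EXCLUSION_HALFWIDTH = 35.0
#: Below 300 nm the deep-UV protein/DNA structure overlaps irreducibly
#: with the pigment curves, so the window starts here.
DEFAULT_SHORT_CUTOFF = 300.0
#: Above 900 nm the water band dominates; excluded from the window.
DEFAULT_LONG_CUTOFF = 900.0


class UnderdeterminedFitError(ValueError):
    """Fit window has fewer points than pigment parameters."""


@dataclass(frozen=True)
class BaselineFit:
    """Fitted pigment weights and the reconstructed baseline.

    ``baseline`` is exactly ``p_mel * mel + p_lip * lip`` on the full
    grid; ``residual_rms`` is the root-mean-square misfit over the fit
    window only.
    """

    p_mel: float
    p_lip: float
    baseline: Spectrum
    fit_window: np.ndarray
    residual_rms: float


def default_fit_window(
    grid: WavelengthGrid,
    *,
    excluded_centers=DEFAULT_EXCLUDED_CENTERS,
    exclusion_halfwidth: float = DEFAULT_EXCLUSION_HALFWIDTH,
    short_cutoff: float = DEFAULT_SHORT_CUTOFF,
    long_cutoff: float = DEFAULT_LONG_CUTOFF,
) -> np.ndarray:
    """Band-free wavelengths used to constrain the pigment fit."""
    lam = grid.values
    keep = (lam >= short_cutoff) & (lam <= long_cutoff)
    for center in excluded_centers:
        keep &= np.abs(lam - center) > exclusion_halfwidth
    return lam[keep]


def _window_indices(grid: WavelengthGrid, fit_window: np.ndarray) -> np.ndarray:
    return np.array([grid.index_of(w) for w in np.asarray(fit_window, dtype=float)])


def fit_baseline(
    mu_a: Spectrum,
    library: ComponentLibrary,
    fit_window: np.ndarray | None = None,
) -> BaselineFit:
    """Nonnegative least-squares fit of the two pigment weights.

    Parameters
    ----------
    mu_a : Spectrum
        Absorption coefficient spectrum, cm^-1, on the library grid.
    library : ComponentLibrary
        Must contain ``melanin`` and ``lipofuscin``.
    fit_window : array of wavelengths, optional
        Grid wavelengths constraining the fit; defaults to
        :func:`default_fit_window`.
    """
    if mu_a.grid != library.grid:
        raise GridMismatchError("mu_a and library are on different grids")
    if fit_window is None:
        fit_window = default_fit_window(mu_a.grid)
    idx = _window_indices(mu_a.grid, fit_window)
    if idx.size < 2:
        raise UnderdeterminedFitError(
            f"fit window has {idx.size} point(s); need at least 2"
        )
    mel = library["melanin"].values
    lip = library["lipofuscin"].values
    design = np.column_stack([mel[idx], lip[idx]])
    weights, _ = nnls(design, mu_a.values[idx])
    p_mel, p_lip = (float(w) for w in weights)
    baseline = Spectrum(mu_a.grid, p_mel * mel + p_lip * lip, "cm^-1")
    residual = mu_a.values[idx] - baseline.values[idx]
    return BaselineFit(
        p_mel=p_mel,
        p_lip=p_lip,
        baseline=baseline,
        fit_window=np.asarray(fit_window, dtype=float),
        residual_rms=float(np.sqrt(np.mean(residual**2))),
    )


def subtract_baseline(mu_a: Spectrum, fit: BaselineFit) -> Spectrum:
    """Pointwise ``mu_a - baseline``; small negatives are kept."""
    if mu_a.grid != fit.baseline.grid:
        raise GridMismatchError("mu_a and baseline are on different grids")
    return Spectrum(mu_a.grid, mu_a.values - fit.baseline.values, "cm^-1")


def flat_floor(corrected: Spectrum, lo: float = 800.0, hi: float = 850.0) -> float:
    """Minimum of the baseline-removed spectrum over [lo, hi] nm.

    After pigment removal the spectrum flattens between the chromophore
    bands; its minimum over a band-free near-infrared window serves as
    the scalar floor for corrected fold-ratios.
    """
    if lo >= hi:
        raise ValueError(f"empty window: lo={lo} >= hi={hi}")
    mask = corrected.grid.mask(lo, hi)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] nm contains no grid points")
    return float(corrected.values[mask].min())
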