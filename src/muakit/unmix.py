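"""Weighted-component reconstruction of the absorption spectrum.

The tissue absorption spectrum is modeled as a weighted sum of
normalized component spectra,

.. math:: \\mu_a(\\lambda) = \\sum_i p_i\\,\\mu_{ai}(\\lambda),

and the weights are recovered in two steps: the pigment baseline
(melanin + lipofuscin) is fitted first over band-free wavelengths and
subtracted; the remaining spectrum is then fitted on the full grid with
the structural components (water, DNA, HbO, proteins) by nonnegative
least squares.  A joint six-component fit is available for comparison
but the two-step path is the reference procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .baseline import BaselineFit, fit_baseline, subtract_baseline
from .spectra import GridMismatchError, Spectrum
from .synthlib import ComponentLibrary, PIGMENTS, STRUCTURAL_COMPONENTS

__all__ = [
    "CollinearityWarning",
    "UnmixResult",
    "reconstruct",
    "fit_components",
    "full_reconstruction",
]


class CollinearityWarning(UserWarning):
    """Design matrix is rank deficient; weights are not uniquely determined."""


@dataclass(frozen=True)
class UnmixResult:
    """Fitted weights, reconstructed spectrum, residual diagnostics."""

    weights: dict[str, float]
    reconstructed: Spectrum
    residual_rms: float
    residual_max: float
    method: str
    baseline_fit: BaselineFit | None = None


def reconstruct(library: ComponentLibrary, weights: dict[str, float]) -> Spectrum:
    """Pointwise weighted sum of component spectra, cm^-1."""
    total = np.zeros(library.grid.n_points)
    for name, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for {name!r}: {w}")
        total += w * library[name].values
    return Spectrum(library.grid, total, "cm^-1")


def _residuals(observed: Spectrum, reconstructed: Spectrum) -> tuple[float, float]:
    diff = observed.values - reconstructed.values
    return float(np.sqrt(np.mean(diff**2))), float(np.abs(diff).max())


def _nnls_fit(
    target: Spectrum, library: ComponentLibrary, names: tuple[str, ...]
) -> dict[str, float]:
    design = library.design_matrix(names)
    if np.linalg.matrix_rank(design) < len(names):
        warnings.warn(
            f"component design matrix for {names} is rank deficient; "
            "fitted weights are a deterministic but non-unique solution",
            CollinearityWarning,
            stacklevel=3,
        )
    weights, _ = nnls(design, target.values)
    return {name: float(w) for name, w in zip(names, weights)}


def fit_components(
    corrected: Spectrum,
    library: ComponentLibrary,
    components: tuple[str, ...] = STRUCTURAL_COMPONENTS,
) -> UnmixResult:
    """Full-grid nonnegative least-squares fit of the structural components.

    Intended for the baseline-removed spectrum; every wavelength carries
    information, so no window restriction applies here.
    """
    if corrected.grid != library.grid:
        raise GridMismatchError("spectrum and library are on different grids")
    weights = _nnls_fit(corrected, library, tuple(components))
    recon = reconstruct(library, weights)
    rms, rmax = _residuals(corrected, recon)
    return UnmixResult(
        weights=weights,
        reconstructed=recon,
        residual_rms=rms,
        residual_max=rmax,
        method="component_fit",
    )


def full_reconstruction(
    mu_a: Spectrum,
    library: ComponentLibrary,
    fit_window: np.ndarray | None = None,
    method: str = "two_step",
    components: tuple[str, ...] = STRUCTURAL_COMPONENTS,
) -> UnmixResult:
    """Reconstruct mu_a from all six components.

    ``two_step`` (reference): fit the pigment baseline over band-free
    wavelengths, subtract it, fit the structural components on the full
    grid, and report the merged weights; the reconstructed spectrum is
    the component sum plus the baseline.  ``joint``: a single six-
    component nonnegative least-squares fit on the full grid.
    """
    if mu_a.grid != library.grid:
        raise GridMismatchError("mu_a and library are on different grids")
    if method == "two_step":
        base = fit_baseline(mu_a, library, fit_window)
        corrected = subtract_baseline(mu_a, base)
        comp = fit_components(corrected, library, components)
        weights = {"melanin": base.p_mel, "lipofuscin": base.p_lip, **comp.weights}
        recon = reconstruct(library, weights)
        rms, rmax = _residuals(mu_a, recon)
        return UnmixResult(
            weights=weights,
            reconstructed=recon,
            residual_rms=rms,
            residual_max=rmax,
            method="two_step",
            baseline_fit=base,
        )
    if method == "joint":
        names = tuple(PIGMENTS) + tuple(components)
        weights = _nnls_fit(mu_a, library, names)
        recon = reconstruct(library, weights)
        rms, rmax = _residuals(mu_a, recon)
        return UnmixResult(
            weights=weights,
            reconstructed=recon,
            residual_rms=rms,
            residual_max=rmax,
            method="joint",
        )
    raise ValueError(f"unknown method {method!r}; expected 'two_step' or 'joint'")
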