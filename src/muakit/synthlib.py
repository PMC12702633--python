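"""Synthetic component spectra and integrating-sphere measurement ensembles.

No spectral data ship with this package, so this module provides two
generators that emulate the study conditions of an ex vivo lung
spectroscopy experiment:

* a parametric six-component spectral library (melanin, lipofuscin,
  water, DNA, oxy-hemoglobin, structural proteins) with the band
  positions known for these chromophores — proteins near 230 nm, DNA near
  260 nm, HbO with its 275 nm band, 412 nm Soret band and 540/570 nm
  Q-bands, water near 974 nm, and both pigments as broadband,
  wavelength-decreasing curves; and

* total transmittance / total reflectance measurement pairs consistent
  with the direct-calculation relation
  :math:`\\mu_a = (1 - (T_t + R_t))/d` for a chosen ground-truth weight
  vector, sample thickness, and additive measurement noise.

All component spectra are normalized onto [0, 1] (shift-then-scale), so
fitted weights carry the cm^-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    Spectrum,
    WavelengthGrid,
    normalize_spectrum,
)

__all__ = [
    "COMPONENT_NAMES",
    "PIGMENTS",
    "STRUCTURAL_COMPONENTS",
    "LUNG_REFERENCE_WEIGHTS",
    "UnknownComponentError",
    "InfeasibleConfigurationError",
    "ComponentLibrary",
    "SynthConfig",
    "make_component",
    "make_library",
    "synth_measurements",
    "synth_lung_mu_a",
]

#: The six chromophores of the lung absorption model.
COMPONENT_NAMES = ("melanin", "lipofuscin", "water", "dna", "hbo", "proteins")

#: Broadband pigments forming the aging baseline.
PIGMENTS = ("melanin", "lipofuscin")

#: Non-pigment components fitted after baseline removal.
STRUCTURAL_COMPONENTS = ("water", "dna", "hbo", "proteins")

#: Reference ground-truth weight vector for an adult (~3 year) ex vivo
#: rabbit-lung mixture; the generator's default study condition.  Weights
#: multiply normalized component spectra, so they carry cm^-1.
LUNG_REFERENCE_WEIGHTS = {
    "water": 0.67,
    "melanin": 2.85,
    "lipofuscin": 2.85,
    "dna": 3.53,
    "proteins": 2.90,
    "hbo": 12.62,
}


class UnknownComponentError(KeyError):
    """Component name outside the six-chromophore model."""


class InfeasibleConfigurationError(ValueError):
    """Ground truth violates the thin-sample regime mu_a * d <= 1."""


# Band-shape defaults.  Pigments are decaying exponentials
# exp(-(lambda-200)/tau) with melanin decaying faster than lipofuscin;
# chromophore bands are Gaussians at their known centres.  Amplitudes are
# relative within a component (normalization rescales them); widths are
# kept narrow enough that between-band wavelengths stay pigment-dominated,
# which is what makes the two-step baseline-then-components fit separable.
_DEFAULTS: dict[str, dict[str, float]] = {
    "melanin": {"tau": 175.0},
    "lipofuscin": {"tau": 250.0},
    "water": {"center": 974.0, "sigma": 20.0, "tail_amp": 0.01, "tail_tau": 40.0},
    "dna": {"center": 260.0, "sigma": 10.0, "bg_amp": 0.02, "bg_tau": 30.0},
    "hbo": {
        "uv_center": 275.0,
        "uv_amp": 0.25,
        "uv_sigma": 10.0,
        "soret_center": 412.0,
        "soret_amp": 1.0,
        "soret_sigma": 8.0,
        "q1_center": 540.0,
        "q1_amp": 0.22,
        "q1_sigma": 7.0,
        "q2_center": 576.0,
        "q2_amp": 0.25,
        "q2_sigma": 7.0,
    },
    "proteins": {
        "center": 230.0,
        "sigma": 9.0,
        "shoulder_center": 278.0,
        "shoulder_amp": 0.25,
        "shoulder_sigma": 9.0,
    },
}


def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def make_component(
    name: str,
    grid: WavelengthGrid | None = None,
    **params: float,
) -> Spectrum:
    """Build one normalized component spectrum.

    Parameters
    ----------
    name : str
        One of :data:`COMPONENT_NAMES`.
    grid : WavelengthGrid, optional
        Defaults to the canonical 200–1000 nm grid.
    **params
        Overrides for the component's shape parameters (band centres in
        nm, Gaussian widths ``sigma`` in nm, exponential decay constants
        ``tau`` in nm, relative amplitudes).

    Returns
    -------
    Spectrum
        unit ``normalized``: min 0, max 1 on ``grid``.
    """
    if name not in COMPONENT_NAMES:
        raise UnknownComponentError(
            f"unknown component {name!r}; expected one of {COMPONENT_NAMES}"
        )
    defaults = dict(_DEFAULTS[name])
    unknown = set(params) - set(defaults)
    if unknown:
        raise TypeError(f"unknown parameters for {name}: {sorted(unknown)}")
    p = {**defaults, **params}
    grid = grid or WavelengthGrid.canonical()
    lam = grid.values

    if name in PIGMENTS:
        raw = np.exp(-(lam - lam[0]) / p["tau"])
    elif name == "water":
        raw = _gauss(lam, p["center"], p["sigma"]) + p["tail_amp"] * np.exp(
            -(lam - lam[0]) / p["tail_tau"]
        )
    elif name == "dna":
        raw = _gauss(lam, p["center"], p["sigma"]) + p["bg_amp"] * np.exp(
            -(lam - lam[0]) / p["bg_tau"]
        )
    elif name == "hbo":
        raw = (
            p["uv_amp"] * _gauss(lam, p["uv_center"], p["uv_sigma"])
            + p["soret_amp"] * _gauss(lam, p["soret_center"], p["soret_sigma"])
            + p["q1_amp"] * _gauss(lam, p["q1_center"], p["q1_sigma"])
            + p["q2_amp"] * _gauss(lam, p["q2_center"], p["q2_sigma"])
        )
    else:  # proteins
        raw = _gauss(lam, p["center"], p["sigma"]) + p["shoulder_amp"] * _gauss(
            lam, p["shoulder_center"], p["shoulder_sigma"]
        )
    return normalize_spectrum(Spectrum(grid, raw, "cm^-1"))


@dataclass(frozen=True)
class ComponentLibrary:
    """Named, normalized component spectra on one shared grid."""

    components: dict[str, Spectrum]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("empty component library")
        grids = {s.grid for s in self.components.values()}
        if len(grids) != 1:
            raise ValueError("library components are not on a shared grid")
        for name, spec in self.components.items():
            if spec.unit != "normalized":
                raise ValueError(f"component {name!r} is not normalized")

    @property
    def grid(self) -> WavelengthGrid:
        return next(iter(self.components.values())).grid

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.components)

    def __getitem__(self, name: str) -> Spectrum:
        try:
            return self.components[name]
        except KeyError:
            raise UnknownComponentError(
                f"component {name!r} not in library {self.names}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def subset(self, names: tuple[str, ...] | list[str]) -> "ComponentLibrary":
        return ComponentLibrary({n: self[n] for n in names})

    def design_matrix(self, names: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        """(n_wavelengths, n_components) matrix of component columns."""
        names = tuple(names) if names is not None else self.names
        return np.column_stack([self[n].values for n in names])


def make_library(
    grid: WavelengthGrid | None = None,
    overrides: dict[str, dict[str, float]] | None = None,
) -> ComponentLibrary:
    """Generate all six components on one grid.

    ``overrides`` maps component name to shape-parameter overrides, e.g.
    ``{"water": {"center": 980.0}}``.
    """
    grid = grid or WavelengthGrid.canonical()
    overrides = overrides or {}
    unknown = set(overrides) - set(COMPONENT_NAMES)
    if unknown:
        raise UnknownComponentError(f"unknown components in overrides: {sorted(unknown)}")
    return ComponentLibrary(
        {name: make_component(name, grid, **overrides.get(name, {})) for name in COMPONENT_NAMES}
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic measurement ensemble.

    Defaults mirror the emulated experiment: 10 samples of 0.5 mm
    thickness on the canonical grid.  ``transmit_fraction`` splits the
    non-absorbed light between transmittance and reflectance (the
    direct-calculation relation only constrains their sum).  ``noise_sd``
    is the standard deviation of additive Gaussian noise applied
    independently to T_t and R_t, in fraction units.
    """

    true_weights: dict[str, float] = field(
        default_factory=lambda: dict(LUNG_REFERENCE_WEIGHTS)
    )
    thickness_cm: float = 0.05
    transmit_fraction: float = 0.5
    noise_sd: float = 0.0
    n_samples: int = 10
    seed: int = 0
    flat_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness_cm <= 0:
            raise ValueError("thickness_cm must be positive")
        if self.flat_offset < 0:
            raise ValueError("flat_offset must be nonnegative")
        if not 0.0 < self.transmit_fraction < 1.0:
            raise ValueError("transmit_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _weighted_sum(library: ComponentLibrary, weights: dict[str, float]) -> np.ndarray:
    total = np.zeros(library.grid.n_points)
    for name, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for {name!r}: {w}")
        total += w * library[name].values
    return total


def synth_measurements(library: ComponentLibrary, config: SynthConfig):
    """Generate T_t/R_t measurement pairs for known ground-truth weights.

    The noiseless core satisfies ``T_t + R_t = 1 - mu_a * d`` with
    ``T_t = transmit_fraction * (1 - mu_a * d)``; per-sample Gaussian
    noise (sd ``config.noise_sd``) is then added independently to both
    spectra and each is clipped to [0, 1].  Reproducible for a fixed
    seed.

    Returns
    -------
    list of MeasurementPair

    Raises
    ------
    InfeasibleConfigurationError
        If ``mu_a * d > 1`` anywhere on the grid, where the
        direct-calculation relation would yield a nonphysical spectrum.
    """
    from .mua import MeasurementPair  # local import avoids a cycle

    mu_a = _weighted_sum(library, config.true_weights) + config.flat_offset
    absorbed = mu_a * config.thickness_cm
    if absorbed.max() > 1.0:
        lam_bad = library.grid.values[int(np.argmax(absorbed))]
        raise InfeasibleConfigurationError(
            f"mu_a * d reaches {absorbed.max():.3f} > 1 (worst at {lam_bad:.0f} nm); "
            "reduce weights or thickness"
        )
    core_t = config.transmit_fraction * (1.0 - absorbed)
    core_r = (1.0 - config.transmit_fraction) * (1.0 - absorbed)
    rng = np.random.default_rng(config.seed)
    pairs = []
    for i in range(config.n_samples):
        t = core_t.copy()
        r = core_r.copy()
        if config.noise_sd > 0:
            t = t + rng.normal(0.0, config.noise_sd, t.size)
            r = r + rng.normal(0.0, config.noise_sd, r.size)
        t = np.clip(t, 0.0, 1.0)
        r = np.clip(r, 0.0, 1.0)
        pairs.append(
            MeasurementPair(
                sample_id=f"sample_{i + 1:02d}",
                transmittance=Spectrum(library.grid, t, "fraction"),
                reflectance=Spectrum(library.grid, r, "fraction"),
                thickness_cm=config.thickness_cm,
            )
        )
    return pairs


def synth_lung_mu_a(
    library: ComponentLibrary,
    weights: dict[str, float] | None = None,
    flat_offset: float = 0.8,
) -> Spectrum:
    """Lung-like absorption spectrum: chromophore mixture plus a flat floor.

    Measured tissue spectra retain a flat residual absorption floor
    between the chromophore bands (unmodeled attenuation such as
    scattering escape); ``flat_offset`` (cm^-1) emulates it.  With
    ``flat_offset=0`` this is the pure weighted-sum mixture.
    """
    weights = weights if weights is not None else dict(LUNG_REFERENCE_WEIGHTS)
    if flat_offset < 0:
        raise ValueError("flat_offset must be nonnegative")
    return Spectrum(
        library.grid, _weighted_sum(library, weights) + flat_offset, "cm^-1"
    )
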