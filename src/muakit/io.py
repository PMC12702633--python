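"""Readers, writers, run configuration, and the pipeline orchestrator.

Spectra travel as two-column delimited text (comma or tab), header
``wavelength_nm,<name>``, one row per wavelength, written at full
precision — the common denominator of spectrometer exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baseline as _baseline
from . import foldratio as _foldratio
from . import mua as _mua
from . import physiology as _physiology
from . import synthlib as _synthlib
from . import unmix as _unmix
from .spectra import Spectrum, WavelengthGrid, normalize_spectrum, resample

__all__ = [
    "ParseError",
    "RunConfig",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_library",
    "write_library",
    "read_measurements",
    "write_measurements",
    "read_key_values",
    "write_key_values",
    "run_pipeline",
]

log = logging.getLogger("muakit")

WAVELENGTH_COLUMN = "wavelength_nm"


class ParseError(ValueError):
    pass


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        with open(path) as handle:
            header = handle.readline()
        sep = "\t" if "\t" in header else ","
        # round_trip parsing keeps writer/reader lossless at full precision
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError as exc:
        raise ParseError(f"{path}: cannot read file ({exc})") from exc
    except Exception as exc:  # csv structure
        raise ParseError(f"{path}: cannot parse delimited text ({exc})") from exc
    if WAVELENGTH_COLUMN not in frame.columns:
        raise ParseError(
            f"{path}: missing {WAVELENGTH_COLUMN!r} column (found {list(frame.columns)})"
        )
    return frame


def _numeric(frame: pd.DataFrame, column: str, path) -> np.ndarray:
    values = pd.to_numeric(frame[column], errors="coerce")
    bad = values.index[values.isna() & frame[column].notna()]
    if len(bad) or values.isna().any():
        row = int((bad if len(bad) else values.index[values.isna()])[0]) + 2
        raise ParseError(f"{path}: non-numeric value in column {column!r} at line {row}")
    return values.to_numpy(dtype=float)


def read_spectrum_table(path, column: str | None = None, unit: str = "cm^-1") -> Spectrum:
    """Read one spectrum from a two-column delimited text file.

    ``column`` defaults to the first non-wavelength column.  Wavelengths
    must be strictly increasing and uniformly spaced.
    """
    path = Path(path)
    frame = _read_table(path)
    if column is None:
        others = [c for c in frame.columns if c != WAVELENGTH_COLUMN]
        if not others:
            raise ParseError(f"{path}: no value column")
        column = others[0]
    elif column not in frame.columns:
        raise ParseError(f"{path}: missing column {column!r}")
    lam = _numeric(frame, WAVELENGTH_COLUMN, path)
    vals = _numeric(frame, column, path)
    if np.any(np.diff(lam) <= 0):
        row = int(np.argmax(np.diff(lam) <= 0)) + 3  # header + 1-based + next row
        raise ParseError(f"{path}: wavelengths not strictly increasing near line {row}")
    try:
        grid = WavelengthGrid.from_values(lam)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return Spectrum(grid, vals, unit)


def write_spectrum_table(path, spectrum: Spectrum, name: str = "value") -> None:
    """Write a spectrum at full (round-trip) precision."""
    with open(path, "w") as handle:
        handle.write(f"{WAVELENGTH_COLUMN},{name}\n")
        for lam, value in zip(spectrum.wavelengths, spectrum.values):
            handle.write(f"{float(lam)!r},{float(value)!r}\n")


def write_library(directory, library: _synthlib.ComponentLibrary) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, spec in library.components.items():
        write_spectrum_table(directory / f"{name}.csv", spec, name)


def read_library(directory, grid: WavelengthGrid | None = None) -> _synthlib.ComponentLibrary:
    """Read ``<component>.csv`` files; resample and renormalize onto ``grid``."""
    directory = Path(directory)
    components = {}
    for name in _synthlib.COMPONENT_NAMES:
        path = directory / f"{name}.csv"
        spec = read_spectrum_table(path, unit="cm^-1")
        if grid is not None and spec.grid != grid:
            spec = resample(spec, grid)
        components[name] = normalize_spectrum(spec)
    return _synthlib.ComponentLibrary(components)


def write_measurements(directory, pairs) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        write_spectrum_table(directory / f"{pair.sample_id}_Tt.csv", pair.transmittance, "Tt")
        write_spectrum_table(directory / f"{pair.sample_id}_Rt.csv", pair.reflectance, "Rt")


def read_measurements(directory, thickness_cm: float):
    """Read ``<sample>_Tt.csv`` / ``<sample>_Rt.csv`` pairs from a directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise ParseError(f"no such sample directory: {directory}")
    pairs = []
    for t_path in sorted(directory.glob("*_Tt.csv")):
        sample_id = t_path.name[: -len("_Tt.csv")]
        r_path = directory / f"{sample_id}_Rt.csv"
        if not r_path.exists():
            raise ParseError(f"{t_path}: missing matching reflectance file {r_path.name}")
        pairs.append(
            _mua.MeasurementPair(
                sample_id=sample_id,
                transmittance=read_spectrum_table(t_path, unit="fraction"),
                reflectance=read_spectrum_table(r_path, unit="fraction"),
                thickness_cm=thickness_cm,
            )
        )
    if not pairs:
        raise ParseError(f"no *_Tt.csv files in {directory}")
    return pairs


def write_key_values(path, mapping: dict) -> None:
    with open(path, "w") as handle:
        for key, value in mapping.items():
            handle.write(f"{key} = {value!r}\n" if isinstance(value, str) else f"{key} = {value}\n")


def read_key_values(path) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}: expected 'key = value' at line {lineno}")
        key, _, value = line.partition("=")
        try:
            out[key.strip()] = float(value)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value at line {lineno}") from exc
    return out


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    samples_dir: Path
    out_dir: Path
    thickness_mm: float = 0.5
    water_fraction: float = 80.0
    blood_preset: str = "rabbit42"
    allow_nonphysical: bool = False
    fit_window_short_cutoff: float = _baseline.DEFAULT_SHORT_CUTOFF
    fit_window_long_cutoff: float = _baseline.DEFAULT_LONG_CUTOFF
    floor_window: tuple[float, float] = (800.0, 850.0)
    seed: int = 0
    library_dir: Path | None = None
    bands: tuple = field(default_factory=lambda: _foldratio.DEFAULT_BANDS)

    def __post_init__(self) -> None:
        self.samples_dir = Path(self.samples_dir)
        self.out_dir = Path(self.out_dir)
        if not self.samples_dir.is_dir():
            raise ParseError(f"samples_dir does not exist: {self.samples_dir}")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.blood_preset not in _physiology.BLOOD_PRESETS:
            raise ValueError(
                f"unknown blood preset {self.blood_preset!r}; "
                f"available: {sorted(_physiology.BLOOD_PRESETS)}"
            )
        if self.library_dir is not None:
            self.library_dir = Path(self.library_dir)
            if not self.library_dir.is_dir():
                raise ParseError(f"library_dir does not exist: {self.library_dir}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "floor_window" in raw:
            raw["floor_window"] = tuple(raw["floor_window"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full chain and write the report bundle.

    Stages: direct calculation and ensemble statistics; pigment baseline
    fit and removal; fold-ratios before/after; two-step component
    reconstruction; concentrations with SD propagation; blood-volume
    back-calculation.  Deterministic for a fixed configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thickness_cm = config.thickness_mm / 10.0

    pairs = read_measurements(config.samples_dir, thickness_cm)
    log.info("read %d measurement pairs from %s", len(pairs), config.samples_dir)
    stats = _mua.mu_a_ensemble(pairs, allow_nonphysical=config.allow_nonphysical)
    grid = stats.mean.grid

    if config.library_dir is not None:
        library = read_library(config.library_dir, grid)
    else:
        library = _synthlib.make_library(grid)

    window = _baseline.default_fit_window(
        grid,
        short_cutoff=config.fit_window_short_cutoff,
        long_cutoff=config.fit_window_long_cutoff,
    )
    fit = _baseline.fit_baseline(stats.mean, library, window)
    corrected = _baseline.subtract_baseline(stats.mean, fit)
    floor = _baseline.flat_floor(corrected, *config.floor_window)
    log.info(
        "baseline fit: p_mel=%.4f p_lip=%.4f over %d window points; floor=%.4f cm^-1",
        fit.p_mel, fit.p_lip, window.size, floor,
    )

    result = _unmix.full_reconstruction(stats.mean, library, window)
    table = _physiology.ensemble_concentrations(
        stats, library, config.water_fraction, window
    )
    breakdown = _physiology.blood_volume_chain(
        table["hbo"],
        _physiology.BLOOD_PRESETS[config.blood_preset],
        config.water_fraction,
    )
    composition = _physiology.whole_blood_composition(
        _physiology.BLOOD_PRESETS[config.blood_preset]
    )

    original = _foldratio.fold_ratios(stats.mean, fit, config.bands)
    removed = _foldratio.fold_ratios(corrected, floor, config.bands)

    paths = {name: out / name for name in (
        "mua_mean_sd.csv", "baseline.csv", "weights.txt", "recon.csv",
        "foldratios.csv", "concentrations.csv", "blood.txt",
    )}

    pd.DataFrame({
        WAVELENGTH_COLUMN: grid.values,
        "mean": stats.mean.values,
        "sd": stats.sd.values,
        "n": stats.n,
    }).to_csv(paths["mua_mean_sd.csv"], index=False)

    pd.DataFrame({
        WAVELENGTH_COLUMN: grid.values,
        "baseline": fit.baseline.values,
        "corrected": corrected.values,
    }).to_csv(paths["baseline.csv"], index=False)

    write_key_values(paths["weights.txt"], {
        **{f"p_{k}": v for k, v in result.weights.items()},
        "residual_rms": result.residual_rms,
        "residual_max": result.residual_max,
        "baseline_floor": floor,
    })

    pd.DataFrame({
        WAVELENGTH_COLUMN: grid.values,
        "observed": stats.mean.values,
        "reconstructed": result.reconstructed.values,
        "residual": stats.mean.values - result.reconstructed.values,
    }).to_csv(paths["recon.csv"], index=False)

    merged = original.to_frame().merge(
        removed.to_frame(), on="band", suffixes=("_original", "_corrected")
    )
    merged[["band", "peak_nm_original", "fold_ratio_original", "fold_ratio_corrected"]].rename(
        columns={"peak_nm_original": "peak_nm"}
    ).to_csv(paths["foldratios.csv"], index=False)

    conc_frame = pd.DataFrame({
        "component": list(table.concentrations),
        "concentration_pct": list(table.concentrations.values()),
        "sd_pct": [table.sds[k] for k in table.concentrations],
    })
    conc_frame.to_csv(paths["concentrations.csv"], index=False)

    write_key_values(paths["blood.txt"], {
        "hb_in_tissue_pct": breakdown.hb_in_tissue,
        "hb_fraction_of_blood_pct": breakdown.hb_fraction_of_blood,
        "non_hb_blood_in_tissue_pct": breakdown.non_hb_blood_in_tissue,
        "bvc_pct": breakdown.bvc,
        "cellular_non_hb_in_tissue_pct": breakdown.cellular_non_hb_in_tissue,
        "plasma_in_tissue_pct": breakdown.plasma_in_tissue,
        "non_plasma_water_pct": breakdown.non_plasma_water,
        **{f"whole_blood_{k}_pct": v for k, v in composition.items()},
    })
    log.info("pipeline outputs written to %s", out)
    return paths
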