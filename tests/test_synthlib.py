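import numpy as np
import pytest

from muakit.mua import mu_a_from_measurement
from muakit.synthlib import (
    COMPONENT_NAMES,
    InfeasibleConfigurationError,
    SynthConfig,
    UnknownComponentError,
    make_component,
    make_library,
    synth_lung_mu_a,
    synth_measurements,
)
from muakit.unmix import reconstruct


def local_maxima(values):
    """Indices that are strictly higher than both neighbours."""
    return (
        np.nonzero((values[1:-1] > values[:-2]) & (values[1:-1] > values[2:]))[0] + 1
    )


class TestComponentShapes:
    @pytest.mark.parametrize("name", COMPONENT_NAMES)
    def test_normalization_contract(self, library, name):
        values = library[name].values
        assert values.min() == pytest.approx(0.0, abs=1e-12)
        assert values.max() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "name, lo, hi",
        [
            ("proteins", 225, 240),
            ("dna", 255, 265),
            ("hbo", 405, 420),
            ("water", 965, 985),
        ],
    )
    def test_band_positions(self, library, name, lo, hi):
        spec = library[name]
        peak = spec.wavelengths[np.argmax(spec.values)]
        assert lo <= peak <= hi

    def test_hbo_soret_maximum_at_412(self, library):
        spec = library["hbo"]
        assert spec.wavelengths[np.argmax(spec.values)] == 412.0

    def test_hbo_q_bands_are_local_maxima(self, library):
        spec = library["hbo"]
        lam = spec.wavelengths[local_maxima(spec.values)]
        assert any(530 <= v <= 550 for v in lam)
        assert any(560 <= v <= 580 for v in lam)

    @pytest.mark.parametrize("name", ["melanin", "lipofuscin"])
    def test_pigments_strictly_decreasing_above_300(self, library, name):
        spec = library[name]
        mask = spec.wavelengths >= 300
        assert np.all(np.diff(spec.values[mask]) < 0)

    def test_melanin_broadband_decrease(self, library):
        mel = library["melanin"]
        assert mel.value_at(300) > mel.value_at(600) > mel.value_at(900)

    def test_melanin_decays_faster_than_lipofuscin(self, library):
        # pigment ordering drives the baseline shape
        mel, lip = library["melanin"], library["lipofuscin"]
        assert mel.value_at(600) < lip.value_at(600)

    def test_unknown_component_rejected(self, grid):
        with pytest.raises(UnknownComponentError):
            make_component("collagen", grid)

    def test_unknown_parameter_rejected(self, grid):
        with pytest.raises(TypeError):
            make_component("water", grid, centre=980.0)


class TestMakeLibrary:
    def test_deterministic(self, grid):
        a = make_library(grid)
        b = make_library(grid)
        for name in COMPONENT_NAMES:
            assert np.array_equal(a[name].values, b[name].values)

    def test_override_passes_through(self, grid, library):
        lib = make_library(grid, overrides={"water": {"center": 980.0}})
        water = lib["water"]
        assert water.wavelengths[np.argmax(water.values)] == 980.0
        for name in COMPONENT_NAMES:
            if name != "water":
                assert np.array_equal(lib[name].values, library[name].values)

    def test_unknown_override_component_rejected(self, grid):
        with pytest.raises(UnknownComponentError):
            make_library(grid, overrides={"elastin": {}})


class TestSynthMeasurements:
    def test_zero_absorption_limit(self, library):
        config = SynthConfig(true_weights={}, noise_sd=0.0, n_samples=1)
        (pair,) = synth_measurements(library, config)
        total = pair.transmittance.values + pair.reflectance.values
        assert np.allclose(total, 1.0, atol=1e-15)

    def test_noiseless_round_trip_recovers_mu_a(self, library, lung_weights):
        config = SynthConfig(true_weights=lung_weights, noise_sd=0.0, n_samples=1)
        (pair,) = synth_measurements(library, config)
        recovered = mu_a_from_measurement(pair)
        truth = reconstruct(library, lung_weights)
        rel = np.abs(recovered.values - truth.values) / np.abs(truth.values)
        assert rel.max() < 1e-12

    def test_transmit_fraction_splits_nonabsorbed_light(self, library, lung_weights):
        config = SynthConfig(
            true_weights=lung_weights, transmit_fraction=0.7, noise_sd=0.0, n_samples=1
        )
        (pair,) = synth_measurements(library, config)
        total = pair.transmittance.values + pair.reflectance.values
        assert np.allclose(pair.transmittance.values, 0.7 * total, atol=1e-12)

    def test_same_seed_bit_identical(self, library, lung_weights):
        config = SynthConfig(true_weights=lung_weights, noise_sd=0.01, seed=7)
        a = synth_measurements(library, config)
        b = synth_measurements(library, config)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.transmittance.values, pb.transmittance.values)
            assert np.array_equal(pa.reflectance.values, pb.reflectance.values)

    def test_different_seeds_differ(self, library, lung_weights):
        base = dict(true_weights=lung_weights, noise_sd=0.01)
        a = synth_measurements(library, SynthConfig(seed=1, **base))
        b = synth_measurements(library, SynthConfig(seed=2, **base))
        assert not np.array_equal(a[0].transmittance.values, b[0].transmittance.values)

    def test_flat_offset_shifts_recovered_mu_a(self, library, lung_weights):
        config = SynthConfig(
            true_weights=lung_weights, noise_sd=0.0, n_samples=1, flat_offset=0.8
        )
        (pair,) = synth_measurements(library, config)
        recovered = mu_a_from_measurement(pair)
        truth = reconstruct(library, lung_weights)
        assert np.allclose(recovered.values - truth.values, 0.8, atol=1e-10)

    def test_infeasible_configuration_rejected(self, library):
        config = SynthConfig(true_weights={"hbo": 50.0}, thickness_cm=0.05)
        with pytest.raises(InfeasibleConfigurationError):
            synth_measurements(library, config)

    def test_ensemble_mean_converges_as_sqrt_n(self, library, lung_weights):
        truth = reconstruct(library, lung_weights)

        def mean_error(n, seed):
            config = SynthConfig(
                true_weights=lung_weights, noise_sd=0.01, n_samples=n, seed=seed
            )
            pairs = synth_measurements(library, config)
            stack = np.vstack(
                [
                    mu_a_from_measurement(p, allow_nonphysical=True).values
                    for p in pairs
                ]
            )
            return np.sqrt(np.mean((stack.mean(axis=0) - truth.values) ** 2))

        err_small = mean_error(10, seed=3)
        err_large = mean_error(1000, seed=3)
        # 100x the samples should shrink the error about 10-fold
        assert err_large < err_small / 3


class TestSynthLung:
    def test_flat_offset_adds_constant(self, library, lung_weights):
        plain = synth_lung_mu_a(library, lung_weights, flat_offset=0.0)
        offset = synth_lung_mu_a(library, lung_weights, flat_offset=0.8)
        assert np.allclose(offset.values - plain.values, 0.8, atol=1e-12)

    def test_negative_offset_rejected(self, library):
        with pytest.raises(ValueError):
            synth_lung_mu_a(library, flat_offset=-0.1)
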