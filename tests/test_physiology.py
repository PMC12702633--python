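import numpy as np
import pytest

from muakit.physiology import (
    BLOOD_PRESETS,
    BloodModel,
    blood_volume_chain,
    concentration_sd,
    hb_fraction_of_blood,
    rounded_blood_volume_chain,
    weights_to_concentrations,
    whole_blood_composition,
)
from muakit.unmix import reconstruct

LUNG_FITTED_WEIGHTS = {
    "water": 0.67,
    "melanin": 2.85,
    "lipofuscin": 2.85,
    "dna": 3.53,
    "proteins": 2.90,
    "hbo": 12.62,
}


class TestWeightsToConcentrations:
    def test_lung_weight_vector_converts_to_reference_concentrations(self):
        table = weights_to_concentrations(LUNG_FITTED_WEIGHTS, water_fraction=80.0)
        assert table["water"] == 80.0
        assert table["melanin"] == pytest.approx(2.30, abs=0.005)
        assert table["lipofuscin"] == pytest.approx(2.30, abs=0.005)
        assert table["dna"] == pytest.approx(2.85, abs=0.005)
        assert table["hbo"] == pytest.approx(10.20, abs=0.005)
        # the stated rescaling yields 2.3434 for proteins; 2.35 at two
        # decimals is a rounding of an unrounded upstream weight
        assert table["proteins"] == pytest.approx(2.34, abs=0.005)

    def test_single_non_water_component_takes_full_remainder(self):
        table = weights_to_concentrations({"water": 0.5, "hbo": 3.0}, 80.0)
        assert table["hbo"] == pytest.approx(20.0)

    def test_water_weight_does_not_enter_rescaling(self):
        a = weights_to_concentrations({"water": 0.1, "hbo": 2.0, "dna": 1.0}, 80.0)
        b = weights_to_concentrations({"water": 9.0, "hbo": 2.0, "dna": 1.0}, 80.0)
        assert a.concentrations == b.concentrations

    @pytest.mark.parametrize("water_fraction", [20.0, 50.0, 80.0, 99.0])
    def test_concentrations_always_sum_to_one_hundred(self, rng, water_fraction):
        weights = {"water": float(rng.random())}
        for i, name in enumerate(("a", "b", "c", "d")):
            weights[name] = float(rng.uniform(0, 10))
        table = weights_to_concentrations(weights, water_fraction)
        assert table.total == pytest.approx(100.0, abs=1e-12)
        non_water = sum(v for k, v in table.concentrations.items() if k != "water")
        assert non_water == pytest.approx(100.0 - water_fraction, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            weights_to_concentrations({"water": 1.0, "hbo": 0.0}, 80.0)
        with pytest.raises(ValueError):
            weights_to_concentrations({"hbo": 1.0}, 80.0)
        with pytest.raises(ValueError):
            weights_to_concentrations({"water": 1.0, "hbo": -1.0}, 80.0)


class TestHbFractionOfBlood:
    def test_mid_range_rabbit_hematocrit(self):
        f = hb_fraction_of_blood(BLOOD_PRESETS["rabbit42"])
        assert f == pytest.approx(38.95)
        assert round(f) == 39

    def test_textbook_hematocrit_45(self):
        assert hb_fraction_of_blood(BLOOD_PRESETS["textbook45"]) == pytest.approx(41.8)

    def test_zero_hemoglobin_in_rbc(self):
        model = BloodModel(hematocrit=42, hb_fraction_of_rbc=0.0)
        assert hb_fraction_of_blood(model) == 0.0

    def test_hematocrit_below_other_cells_rejected(self):
        with pytest.raises(ValueError):
            hb_fraction_of_blood(BloodModel(hematocrit=1.0, other_cells=2.0))


class TestWholeBloodComposition:
    def test_textbook_breakdown(self):
        composition = whole_blood_composition(BLOOD_PRESETS["textbook45"])
        assert composition["hemoglobin"] == pytest.approx(41.8)
        assert composition["rbc_membranes"] == pytest.approx(2.2)
        assert composition["other_cells"] == pytest.approx(1.0)
        assert composition["plasma"] == pytest.approx(55.0)
        assert composition["albumin"] == pytest.approx(2.1, abs=0.05)

    def test_cellular_and_plasma_parts_conserve_blood_volume(self):
        for model in BLOOD_PRESETS.values():
            c = whole_blood_composition(model)
            total = c["hemoglobin"] + c["rbc_membranes"] + c["other_cells"] + c["plasma"]
            assert total == pytest.approx(100.0, abs=1e-12)

    def test_no_plasma_protein_means_no_albumin(self):
        model = BloodModel(hematocrit=45, plasma_protein_fraction=0.0)
        assert whole_blood_composition(model)["albumin"] == 0.0


class TestBloodVolumeChain:
    def test_printed_chain_reproduces_reference_breakdown(self):
        out = rounded_blood_volume_chain(10.2, BLOOD_PRESETS["rabbit42"], 80.0)
        assert out.hb_fraction_of_blood == 39.0
        assert out.non_hb_blood_in_tissue == pytest.approx(15.9)
        assert out.bvc == pytest.approx(26.1)
        assert out.cellular_non_hb_in_tissue == pytest.approx(0.8)
        assert out.plasma_in_tissue == pytest.approx(15.1)
        assert out.non_plasma_water == pytest.approx(64.9)

    def test_zero_hemoglobin_collapses_chain(self):
        out = blood_volume_chain(0.0, BLOOD_PRESETS["rabbit42"], 80.0)
        assert out.bvc == 0.0
        assert out.non_hb_blood_in_tissue == 0.0
        assert out.plasma_in_tissue == 0.0
        assert out.non_plasma_water == 80.0

    @pytest.mark.parametrize("hb_in_tissue", [1.0, 5.5, 10.2, 15.0])
    @pytest.mark.parametrize("preset", sorted(BLOOD_PRESETS))
    def test_decomposition_identities_hold_exactly(self, hb_in_tissue, preset):
        out = blood_volume_chain(hb_in_tissue, BLOOD_PRESETS[preset], 80.0)
        assert out.bvc == pytest.approx(
            out.hb_in_tissue + out.non_hb_blood_in_tissue, abs=1e-12
        )
        assert out.plasma_in_tissue == pytest.approx(
            out.non_hb_blood_in_tissue - out.cellular_non_hb_in_tissue, abs=1e-12
        )
        assert out.non_plasma_water == pytest.approx(
            out.water_fraction - out.plasma_in_tissue, abs=1e-12
        )

    def test_unrounded_convention_available(self):
        out = blood_volume_chain(
            10.2, BLOOD_PRESETS["rabbit42"], 80.0, round_hb_fraction=False
        )
        assert out.hb_fraction_of_blood == pytest.approx(38.95)
        assert out.non_hb_blood_in_tissue == pytest.approx(10.2 * 61.05 / 38.95)

    def test_inconsistent_model_rejected(self):
        with pytest.raises(ValueError):
            blood_volume_chain(40.0, BLOOD_PRESETS["rabbit42"], water_fraction=20.0)


class TestConcentrationSd:
    def test_zero_spectral_sd_gives_zero_concentration_sd(self, library, lung_weights):
        mean = reconstruct(library, lung_weights)
        zero = mean.with_values(np.zeros(mean.values.size))
        sds = concentration_sd(mean, zero, library)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in sds.values())

    def test_noise_on_hbo_bands_dominates_hbo_sd(self, library, lung_weights):
        """Spectral SD concentrated on the hemoglobin bands propagates into
        the largest concentration SD for hemoglobin."""
        mean = reconstruct(library, lung_weights)
        sd = mean.with_values(0.5 * library["hbo"].values)
        sds = concentration_sd(mean, sd, library)
        non_water = {k: v for k, v in sds.items() if k != "water"}
        assert max(non_water, key=non_water.get) == "hbo"

    def test_negative_sd_rejected(self, library, lung_weights):
        mean = reconstruct(library, lung_weights)
        bad = mean.with_values(np.full(mean.values.size, -1.0))
        with pytest.raises(ValueError):
            concentration_sd(mean, bad, library)
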