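"""Synthetic mouse-pancreas phantom: label maps, forward models, sections."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from betaquant import phantom
from betaquant.mr_quant import AcquisitionParams, fit_t1_vfa
from betaquant.phantom import (
    COMPARTMENTS,
    IsletPlacementError,
    PhantomSpec,
    build_label_map,
    rip1tag2_spec,
    simulate_pet_volume,
    simulate_section,
    simulate_secretion_table,
    simulate_vfa_stacks,
)


class TestSpecInvariants:
    def test_default_mn_table_has_reported_pattern(self, default_spec):
        mn = default_spec.mn_mM
        assert mn["1h"]["exocrine"] > mn["1h"]["islet"]
        assert mn["24h"]["islet"] > mn["24h"]["exocrine"]

    def test_endocrine_elemental_enrichment(self, default_spec):
        el = default_spec.elemental_abundance
        for iso in ("44Ca", "64Zn"):
            assert el[iso]["islet"] > el[iso]["exocrine"]

    def test_inverted_mn_table_rejected(self):
        mn = phantom._default_mn()
        mn["1h"]["exocrine"], mn["1h"]["islet"] = mn["1h"]["islet"], mn["1h"]["exocrine"]
        with pytest.raises(ValueError):
            PhantomSpec(mn_mM=mn)


class TestLabelMap:
    def test_no_islets_yields_background_and_exocrine_only(self):
        spec = PhantomSpec(islet_count=0)
        lv = build_label_map(spec)
        assert set(np.unique(lv.labels)) == {0, 1}

    def test_deterministic_for_fixed_seed(self):
        a = build_label_map(PhantomSpec(rng_seed=3))
        b = build_label_map(PhantomSpec(rng_seed=3))
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_islet_count_equals_connected_components(self, label_map, default_spec):
        n = ndimage.label(label_map.labels == COMPARTMENTS["islet"])[1]
        assert n == default_spec.islet_count

    def test_islets_embedded_in_exocrine_and_separated(self, label_map):
        # the one-voxel shell around the islet mask holds no islet or
        # insulinoma voxels: components cannot touch each other or the tumor
        islets = label_map.labels == COMPARTMENTS["islet"]
        shell = ndimage.binary_dilation(islets, ndimage.generate_binary_structure(3, 3)) & ~islets
        assert set(np.unique(label_map.labels[shell])) <= {
            COMPARTMENTS["background"], COMPARTMENTS["exocrine"]}

    def test_insulinoma_variant_adds_component(self):
        lv = build_label_map(rip1tag2_spec(rng_seed=1))
        assert (lv.labels == COMPARTMENTS["insulinoma"]).sum() > 100

    def test_impossible_placement_names_islet_index(self):
        spec = PhantomSpec(islet_count=3000, islet_diameter_mean_um=800.0)
        with pytest.raises(IsletPlacementError, match=r"islet \d+"):
            build_label_map(spec)


class TestVfaForwardModel:
    def test_noise_free_signal_matches_forward_model(self, label_map, noisefree_spec,
                                                     acq_two_angle):
        from betaquant.mr_quant import spgr_signal
        stacks = simulate_vfa_stacks(label_map, noisefree_spec, "pre", acq_two_angle)
        exo = label_map.labels == COMPARTMENTS["exocrine"]
        for angle, vol in zip(acq_two_angle.flip_deg, stacks):
            expected = spgr_signal(1.0, 1.0, acq_two_angle, angle)  # exocrine T1=1 s
            np.testing.assert_allclose(vol.data[exo], expected, rtol=1e-12)

    def test_effective_t1_halved_by_contrast(self, label_map):
        # 1/(1/1.0 + 5.0 * 0.2) = 0.5 s
        spec = PhantomSpec(rng_seed=7, relaxivity_r1=5.0, noise_sigma_mr=0.0)
        eff = phantom._effective_t1(spec, label_map.labels, "1h")
        exo = label_map.labels == COMPARTMENTS["exocrine"]
        np.testing.assert_allclose(eff[exo], 0.5, rtol=1e-12)

    def test_deterministic_noise_for_fixed_seed(self, label_map, default_spec,
                                                acq_two_angle):
        a = simulate_vfa_stacks(label_map, default_spec, "1h", acq_two_angle)
        b = simulate_vfa_stacks(label_map, default_spec, "1h", acq_two_angle)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    @pytest.mark.parametrize("angles", [(4.0, 22.0), (4.0, 14.0, 27.0)])
    def test_forward_inverse_consistency(self, label_map, noisefree_spec, angles):
        """Noise-free simulate -> fit recovers every compartment T1 to 1e-6."""
        acq = AcquisitionParams(flip_deg=angles)
        stacks = simulate_vfa_stacks(label_map, noisefree_spec, "24h", acq)
        fit = fit_t1_vfa(stacks, acq)
        t1_true = phantom._effective_t1(noisefree_spec, label_map.labels, "24h")
        assert fit.validity.all()
        np.testing.assert_allclose(fit.t1_s.data, t1_true, rtol=1e-6)

    def test_label_conservation(self, label_map, noisefree_spec, acq_two_angle):
        # every compartment keeps its voxel count in any derived volume
        stacks = simulate_vfa_stacks(label_map, noisefree_spec, "1h", acq_two_angle)
        values, counts = np.unique(stacks[0].data, return_counts=True)
        label_counts = sorted(np.unique(label_map.labels, return_counts=True)[1])
        assert sorted(counts) == label_counts

    def test_rician_option_changes_noise_but_not_seedability(self, label_map):
        spec_r = PhantomSpec(rng_seed=5, mr_noise_model="rician")
        acq = AcquisitionParams(flip_deg=(4.0, 22.0))
        a = simulate_vfa_stacks(label_map, spec_r, "1h", acq)
        b = simulate_vfa_stacks(label_map, spec_r, "1h", acq)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert np.all(a[0].data >= 0)   # magnitude images are non-negative

    def test_unknown_timepoint_rejected(self, label_map, default_spec, acq_two_angle):
        with pytest.raises(ValueError):
            simulate_vfa_stacks(label_map, default_spec, "2h", acq_two_angle)


class TestPetForwardModel:
    def test_compartment_uptake_ratio_by_construction(self, label_map):
        spec = dataclasses.replace(PhantomSpec(rng_seed=7), noise_sigma_pet=0.0)
        vol = simulate_pet_volume(label_map, spec, "1h")
        exo = vol.data[label_map.labels == 1].mean()
        islet = vol.data[label_map.labels == 2].mean()
        assert islet / exo == pytest.approx(3.0 / 0.5, rel=1e-12)

    def test_activity_halves_after_one_half_life(self, label_map):
        # 24h frame activity = uptake * 2^(-24/12.7) of the injection-time value
        spec = PhantomSpec(rng_seed=7, noise_sigma_pet=0.0)
        vol = simulate_pet_volume(label_map, spec, "24h")
        exo = vol.data[label_map.labels == 1].mean()
        expected = 0.4 / 100.0 * spec.injected_dose_kBq * 2.0 ** (-24.0 / 12.7)
        assert exo == pytest.approx(expected, rel=1e-12)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(injected_dose_kBq=0.0)

    def test_unknown_timepoint_rejected(self, label_map, default_spec):
        with pytest.raises(ValueError):
            simulate_pet_volume(label_map, default_spec, "48h")


class TestSections:
    def _mid_slice(self, label_map):
        return label_map.labels[:, :, label_map.labels.shape[2] // 2]

    def test_mn_exocrine_dominant_at_1h(self, label_map, default_spec):
        _, maps = simulate_section(self._mid_slice(label_map), default_spec, "1h")
        mn = maps["55Mn"].intensity
        lab = phantom._resample_labels_2d(self._mid_slice(label_map), 150.0, 60.0)
        assert mn[lab == 1].mean() > mn[lab == 2].mean()

    def test_mn_islet_retained_at_24h(self, label_map, default_spec):
        _, maps = simulate_section(self._mid_slice(label_map), default_spec, "24h")
        mn = maps["55Mn"].intensity
        lab = phantom._resample_labels_2d(self._mid_slice(label_map), 150.0, 60.0)
        assert mn[lab == 2].mean() > mn[lab == 1].mean()

    def test_uniform_abundance_zero_noise_gives_constant_maps(self, label_map):
        el = {iso: {c: 10.0 for c in COMPARTMENTS} for iso in
              ("44Ca", "64Zn", "65Cu", "55Mn", "13C")}
        # keep the Ca/Zn endocrine check satisfied with an epsilon bump
        for iso in ("44Ca", "64Zn"):
            el[iso]["islet"] = el[iso]["insulinoma"] = 10.0 + 1e-12
        mn = {tp: {c: 0.0 for c in COMPARTMENTS} for tp in ("pre", "1h", "24h")}
        mn["1h"]["exocrine"], mn["24h"]["islet"] = 1e-12, 1e-12
        spec = PhantomSpec(elemental_abundance=el, mn_mM=mn,
                           noise_sigma_msi=0.0, noise_sigma_autorad=0.0)
        _, maps = simulate_section(self._mid_slice(label_map), spec, "pre")
        assert np.ptp(maps["13C"].intensity) == 0.0

    def test_empty_slice_rejected(self, default_spec):
        with pytest.raises(ValueError):
            simulate_section(np.zeros((10, 10), dtype=int), default_spec, "1h")

    def test_pixel_sizes_default_to_modality_resolutions(self, label_map, default_spec):
        autorad, maps = simulate_section(self._mid_slice(label_map), default_spec, "1h")
        assert autorad.pixel_size_um == 50.0
        assert all(m.pixel_size_um == 60.0 for m in maps.values())


class TestSecretionTable:
    def test_noise_free_table_recovers_true_index(self):
        from betaquant.secretion import enhancement_index
        df = simulate_secretion_table(groups={"control": (2, 14.0)},
                                      replicate_cv=0.0, rng_seed=1)
        for _, sub in df.groupby("mouse_id"):
            assert enhancement_index(sub) == pytest.approx(14.0, rel=1e-12)

    def test_table_schema_and_glucose_series(self):
        df = simulate_secretion_table(rng_seed=2)
        assert set(df.columns) == {"mouse_id", "group", "timepoint", "glucose_mM",
                                   "rep1", "rep2", "rep3"}
        assert set(df["glucose_mM"]) == {3, 6, 8, 10, 15, 30}

    def test_deterministic_for_fixed_seed(self):
        a = simulate_secretion_table(rng_seed=4)
        b = simulate_secretion_table(rng_seed=4)
        assert a.equals(b)
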