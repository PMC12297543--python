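"""Digital phantom: geometry, ground truth, degradation model, population."""

import dataclasses

import numpy as np
import pytest

import ctfree_gfr as cg
from ctfree_gfr.phantom import (REFERRAL_POPULATION_MIX, PhantomSpec,
                                degrade_to_spect, generate_case,
                                sample_population)
from ctfree_gfr.volume import LEFT_KIDNEY, RIGHT_KIDNEY, Volume3D


def _case(**overrides):
    return generate_case(PhantomSpec.desk(**overrides))


class TestGenerateCase:
    def test_post_total_nephrectomy_removes_the_kidney(self):
        case = _case(category="post_total_nephrectomy", side="left", seed=1)
        assert case.labels.class_count(LEFT_KIDNEY) == 0
        assert case.labels.class_count(RIGHT_KIDNEY) > 0
        assert set(case.true_pct_id) == {RIGHT_KIDNEY}

    def test_seeding_contract_bit_identical(self):
        a = _case(seed=7)
        b = _case(seed=7)
        for attr in ("mu_map", "activity", "primary_spect", "scatter_spect",
                     "quantitative_spect"):
            assert np.array_equal(getattr(a, attr).data, getattr(b, attr).data)
        assert np.array_equal(a.labels.data, b.labels.data)
        assert a.true_pct_id == b.true_pct_id

    def test_forced_uptake_fraction_fixes_true_pct_id(self):
        case = _case(kidney_uptake_fraction_range=(0.04, 0.04),
                     background_uptake_fraction=0.0, seed=2)
        assert case.true_pct_id[RIGHT_KIDNEY] == pytest.approx(4.0)
        assert case.true_pct_id[LEFT_KIDNEY] == pytest.approx(4.0)

    def test_mu_values_within_tissue_table_envelope(self):
        case = _case(seed=3)
        mu = case.mu_map.data
        assert mu.min() >= 0.0
        assert mu.max() <= 0.5
        # air outside the body, soft tissue as the bulk in-body value
        assert mu[0, 0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_labels_only_inside_body(self):
        case = _case(seed=4)
        kidney_mu = case.mu_map.data[case.labels.data > 0]
        assert (kidney_mu > 0.05).all()

    def test_activity_bounded_by_injection(self):
        case = _case(seed=5)
        total = case.activity.data.sum() * case.activity.voxel_volume_ml
        assert total <= case.injected_activity_MBq + 1e-9

    def test_tumor_case_has_cold_nodule_inside_label(self):
        case = _case(category="renal_tumor", side="right", seed=6)
        in_kidney = case.activity.data[case.labels.data == RIGHT_KIDNEY]
        assert (in_kidney == 0).any() and (in_kidney > 0).any()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(category="post_total_nephrectomy", side="both")
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(8, 64, 64))
        with pytest.raises(ValueError):
            PhantomSpec(kidney_uptake_fraction_range=(0.3, 0.5),
                        background_uptake_fraction=0.5)
        with pytest.raises(ValueError):
            PhantomSpec(category="appendicitis")

    def test_grid_too_small_for_kidneys(self):
        with pytest.raises(ValueError, match="too small"):
            generate_case(PhantomSpec(grid_shape=(16, 16, 16), voxel_size_mm=1.0))


class TestDegradeToSpect:
    def _uniform_inputs(self, mu_value=0.0):
        act = Volume3D(np.zeros((8, 8, 8)), (4.0,) * 3)
        act.data[4, 4, 4] = 5.0
        act.data[2, 3, 1] = 1.0
        mu = Volume3D(np.full((8, 8, 8), mu_value), (4.0,) * 3)
        return act, mu

    def test_no_attenuation_no_blur_no_noise_is_proportional(self):
        act, mu = self._uniform_inputs(0.0)
        primary, _, quant = degrade_to_spect(act, mu, psf_fwhm_mm=0.0,
                                             counts_scale=100.0, seed=0,
                                             noise=False)[0:3]
        assert np.allclose(primary.data, 100.0 * act.data)
        assert np.allclose(quant.data, act.data)

    def test_attenuation_only_removes_counts(self):
        act, mu = self._uniform_inputs(0.2)
        primary, _, _ = degrade_to_spect(act, mu, 0.0, 100.0, seed=0, noise=False)
        assert primary.data.sum() <= 100.0 * act.data.sum() + 1e-9

    def test_monotone_in_attenuation(self):
        act, _ = self._uniform_inputs()
        sums = []
        for mu_val in (0.0, 0.1, 0.2, 0.4):
            mu = Volume3D(np.full((8, 8, 8), mu_val), (4.0,) * 3)
            p, _, _ = degrade_to_spect(act, mu, 6.0, 100.0, seed=0, noise=False)
            sums.append(p.data.sum())
        assert sums == sorted(sums, reverse=True)

    def test_noise_seeding_contract(self):
        act, mu = self._uniform_inputs(0.1)
        a = degrade_to_spect(act, mu, 6.0, 100.0, seed=9)
        b = degrade_to_spect(act, mu, 6.0, 100.0, seed=9)
        c = degrade_to_spect(act, mu, 6.0, 100.0, seed=10)
        assert np.array_equal(a[0].data, b[0].data)
        assert not np.array_equal(a[0].data, c[0].data)

    def test_negative_counts_scale_rejected(self):
        act, mu = self._uniform_inputs()
        with pytest.raises(ValueError):
            degrade_to_spect(act, mu, 6.0, -1.0, seed=0)


class TestSamplePopulation:
    def test_referral_mix_category_counts(self, desk_spec):
        cases = sample_population(100, seed=11, base_spec=desk_spec)
        n_partial = sum(c.category == "post_partial_nephrectomy" for c in cases)
        # expectation 52 of 100; allow a generous multinomial band
        assert 37 <= n_partial <= 67

    def test_single_normal_case_has_two_kidneys(self, desk_spec):
        (case,) = sample_population(1, mix={"normal": 1.0}, seed=1,
                                    base_spec=desk_spec)
        assert case.labels.class_count(RIGHT_KIDNEY) > 0
        assert case.labels.class_count(LEFT_KIDNEY) > 0

    def test_deterministic_under_seed(self, desk_spec):
        a = sample_population(3, seed=5, base_spec=desk_spec)
        b = sample_population(3, seed=5, base_spec=desk_spec)
        for ca, cb in zip(a, b):
            assert ca.category == cb.category
            assert np.array_equal(ca.primary_spect.data, cb.primary_spect.data)

    def test_bad_arguments_rejected(self, desk_spec):
        with pytest.raises(ValueError):
            sample_population(0, base_spec=desk_spec)
        with pytest.raises(ValueError):
            sample_population(2, mix={"normal": 0.7}, base_spec=desk_spec)
        with pytest.raises(ValueError):
            sample_population(2, mix={"martian": 1.0}, base_spec=desk_spec)

    def test_default_mix_matches_population_table(self):
        assert sum(REFERRAL_POPULATION_MIX.values()) == pytest.approx(1.0)
        assert REFERRAL_POPULATION_MIX["post_partial_nephrectomy"] == pytest.approx(
            516 / 992
        )


def test_pct_id_conservation_on_undegraded_activity(desk_spec):
    """Quantifying the raw activity map with the true labels reproduces the
    recorded ground truth for every category."""
    for cat, side in [("normal", "both"), ("renal_tumor", "left"),
                      ("urinary_stone", "right"),
                      ("post_partial_nephrectomy", "both"),
                      ("post_total_nephrectomy", "right")]:
        spec = dataclasses.replace(desk_spec, category=cat, side=side, seed=21)
        case = generate_case(spec)
        pct = cg.percent_injected_dose(case.activity, case.labels,
                                       case.injected_activity_MBq)
        for cls, truth in case.true_pct_id.items():
            assert pct[cls] == pytest.approx(truth, rel=1e-9), (cat, cls)
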