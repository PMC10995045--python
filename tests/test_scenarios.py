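"""Morphology perturbations, sweeps, impairment and compensation."""

from dataclasses import replace

import numpy as np
import pytest

from kneeflex.errors import ParameterError
from kneeflex.knee_geometry import PoseConfig, mtu_length
from kneeflex.mtu_model import solve_isometric_equilibrium
from kneeflex.personalization import build_baseline_model, default_config
from kneeflex.scenarios import (ACSA_SWEEP_BOUNDS_PCT, DEFAULT_ANGLES,
                                LENGTH_SWEEP_BOUNDS_PCT, apply_quad_atrophy,
                                apply_radial_atrophy, apply_sarcomere_loss,
                                apply_sarcomere_shortening, baseline_moments,
                                impair_st_to_match, joint_moment,
                                percent_grid, run_sweep,
                                synergist_compensation)


class TestJointMoment:
    def test_all_zero_activations_give_zero_resultant(self, baseline_model):
        acts = {n: 0.0 for n in baseline_model.params}
        res = joint_moment(baseline_model, PoseConfig(45.0), acts)
        assert res.resultant_nm[0] == 0.0

    def test_resultant_is_flexor_minus_extensor(self, baseline_result):
        assert np.allclose(baseline_result.resultant_nm,
                           baseline_result.flexor_nm
                           - baseline_result.extensor_nm)

    def test_doubling_all_fmax_doubles_moments(self, baseline_model):
        doubled = baseline_model.copy()
        for n, p in baseline_model.params.items():
            doubled.params[n] = replace(p, f_max=2 * p.f_max)
        a = joint_moment(baseline_model, PoseConfig(60.0))
        b = joint_moment(doubled, PoseConfig(60.0))
        # normalized equilibrium state is F_max-invariant, so moments
        # scale exactly linearly
        assert b.flexor_nm[0] == pytest.approx(2 * a.flexor_nm[0], rel=1e-9)
        assert b.extensor_nm[0] == pytest.approx(2 * a.extensor_nm[0], rel=1e-9)

    def test_unknown_muscle_activation_rejected(self, baseline_model):
        with pytest.raises(ParameterError):
            joint_moment(baseline_model, PoseConfig(45.0), {"soleus": 1.0})


class TestBaselineMoments:
    def test_within_reference_windows(self, baseline_result, experimental_stats):
        for i, angle in enumerate(DEFAULT_ANGLES):
            lo, hi = experimental_stats[angle].contra_window
            assert lo <= baseline_result.resultant_nm[i] <= hi

    def test_deep_flexion_weaker_than_extension(self, baseline_result):
        assert baseline_result.resultant_nm[3] < baseline_result.resultant_nm[0]

    def test_recomputation_bit_identical(self, baseline_model, baseline_result):
        again = baseline_moments(baseline_model)
        assert np.array_equal(again.resultant_nm, baseline_result.resultant_nm)

    def test_st_share_rises_with_flexion(self, baseline_result):
        share = (baseline_result.per_muscle_nm["semitendinosus"]
                 / baseline_result.flexor_nm)
        assert share[3] > share[0]  # 90 deg vs 15 deg


class TestRadialAtrophy:
    def test_zero_delta_is_identity(self, baseline_model):
        out = apply_radial_atrophy(baseline_model, 0.0)
        assert out.params[out.st_name] == baseline_model.params[out.st_name]

    def test_fmax_follows_acsa(self, baseline_model):
        out = apply_radial_atrophy(baseline_model, -0.22)
        assert out.params[out.st_name].f_max == pytest.approx(708.0 * 0.78,
                                                              rel=1e-9)

    def test_active_force_scales_near_linearly(self, baseline_model):
        """Tendon elasticity makes force scaling slightly sub-linear."""
        st = baseline_model.params[baseline_model.st_name]
        out = apply_radial_atrophy(baseline_model, -0.22)
        for theta in DEFAULT_ANGLES:
            l_mtu = mtu_length(baseline_model.geometry,
                               baseline_model.st_name, PoseConfig(theta))
            f0 = solve_isometric_equilibrium(st, l_mtu, 1.0).f_active
            f1 = solve_isometric_equilibrium(out.params[out.st_name],
                                             l_mtu, 1.0).f_active
            ratio = f1 / f0
            assert 0.78 <= ratio <= 0.78 * 1.03  # compliance helps, <=3%

    def test_out_of_bounds_delta_rejected_without_override(self, baseline_model):
        with pytest.raises(ParameterError):
            apply_radial_atrophy(baseline_model, -0.5)
        apply_radial_atrophy(baseline_model, -0.5, allow_out_of_bounds=True)


class TestSarcomereMechanisms:
    def test_loss_preserves_anatomical_normalized_length(self, baseline_model):
        out = apply_sarcomere_loss(baseline_model, -0.10)
        st0 = baseline_model.params[baseline_model.st_name]
        st1 = out.params[out.st_name]
        norm0 = baseline_model.st_morphology.lf_anat / (st0.lf_o * 100)
        norm1 = out.st_morphology.lf_anat / (st1.lf_o * 100)
        assert norm1 == norm0  # exact ratio preservation
        assert st1.lf_o * 100 == pytest.approx(21.02 * 0.9, abs=5e-3)

    def test_shortening_leaves_lfo_bit_identical(self, baseline_model):
        out = apply_sarcomere_shortening(baseline_model, -0.17)
        assert out.params[out.st_name].lf_o == \
            baseline_model.params[baseline_model.st_name].lf_o
        assert out.st_morphology.lf_anat == pytest.approx(22.5 * 0.83)
        assert out.st_morphology.l_sarc == pytest.approx(2.89 * 0.83)

    def test_loss_weakens_deep_flexion(self, baseline_model, baseline_result):
        out = apply_sarcomere_loss(baseline_model, -0.17)
        res = baseline_moments(out)
        assert res.resultant_nm[3] < baseline_result.resultant_nm[3]

    def test_shortening_strengthens_long_lengths_hip_flexed(self, baseline_model):
        """At hip 90 (longer MTU) a shortened muscle produces more force."""
        out = apply_sarcomere_shortening(baseline_model, -0.17)
        pose = PoseConfig(90.0, hip_angle_deg=90.0)
        l_mtu = mtu_length(baseline_model.geometry,
                           baseline_model.st_name, pose)
        f0 = solve_isometric_equilibrium(
            baseline_model.params[baseline_model.st_name], l_mtu, 1.0).f_active
        f1 = solve_isometric_equilibrium(out.params[out.st_name],
                                         l_mtu, 1.0).f_active
        assert f1 > f0


class TestSweeps:
    def test_grid_counts(self):
        assert percent_grid(*ACSA_SWEEP_BOUNDS_PCT).size == 31
        assert percent_grid(*LENGTH_SWEEP_BOUNDS_PCT).size == 12

    def test_acsa_sweep_iteration_count(self, baseline_model, baseline_result):
        sw = run_sweep(baseline_model, "acsa", baseline=baseline_result)
        assert sw.rel_diff.shape == (31, 4)

    def test_combined_sweep_is_cartesian_product(self, baseline_model,
                                                 baseline_result):
        sw = run_sweep(baseline_model, "acsa_length", baseline=baseline_result)
        assert sw.rel_diff.shape == (31 * 12, 4)

    def test_median_between_min_and_max(self, baseline_model, baseline_result):
        sw = run_sweep(baseline_model, "sarcomere_length",
                       baseline=baseline_result)
        assert np.all(sw.min <= sw.median) and np.all(sw.median <= sw.max)

    def test_quad_atrophy_only_raises_resultant(self, baseline_model,
                                                baseline_result):
        """Reduced antagonist co-contraction lifts the resultant moment."""
        res = baseline_moments(apply_quad_atrophy(baseline_model))
        assert np.all(res.resultant_nm > baseline_result.resultant_nm)

    def test_resultant_monotone_in_st_fmax(self, baseline_model):
        pose = PoseConfig(90.0)
        st = baseline_model.params[baseline_model.st_name]
        values = []
        for scale in (1.0, 0.8, 0.6, 0.4, 0.2):
            m = baseline_model.copy()
            m.params[m.st_name] = replace(st, f_max=st.f_max * scale)
            values.append(joint_moment(m, pose).resultant_nm[0])
        assert np.all(np.diff(values) < 0)

    def test_unknown_condition_rejected(self, baseline_model):
        with pytest.raises(ParameterError):
            run_sweep(baseline_model, "everything")


class TestImpairmentAndCompensation:
    def test_impairment_hits_target(self, baseline_model):
        imp = impair_st_to_match(baseline_model, 60.0, -0.187)
        assert imp.achieved
        assert abs(imp.achieved_rel_diff - (-0.187)) < 1e-4
        assert 0 < imp.st_fmax_scale < 1

    def test_mild_target_still_requires_impairment(self, baseline_model):
        # quadriceps atrophy lifts the unimpaired difference above zero,
        # so even a small deficit needs ST down-scaling
        imp = impair_st_to_match(baseline_model, 15.0, -0.02)
        assert imp.achieved and imp.st_fmax_scale < 1

    def test_unreachable_target_reports_floor(self, baseline_model):
        imp = impair_st_to_match(baseline_model, 15.0, -0.95)
        assert not imp.achieved
        assert imp.st_fmax_scale == 0.0
        assert imp.floor_rel_diff > -0.95

    def test_compensation_ordering_and_insufficiency(self, baseline_model,
                                                     experimental_stats):
        required = {}
        for angle in DEFAULT_ANGLES:
            imp = impair_st_to_match(baseline_model, angle,
                                     experimental_stats[angle].diff_mean)
            comp = synergist_compensation(imp, baseline_model)
            required[angle] = comp.required_pct
        assert required[15.0] is not None
        assert required[45.0] is not None
        assert required[60.0] is not None
        assert required[15.0] <= required[45.0] <= required[60.0]
        assert required[90.0] is None  # insufficient even at +20%

    def test_compensation_steps_monotone(self, baseline_model):
        imp = impair_st_to_match(baseline_model, 60.0, -0.187)
        comp = synergist_compensation(imp, baseline_model)
        assert np.all(np.diff(comp.rel_diff) > 0)
        assert comp.steps_pct[0] == 1 and comp.steps_pct[-1] == 20
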