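"""Hill-type curve and fiber-tendon equilibrium solver tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kneeflex.errors import ParameterError
from kneeflex.mtu_model import (MTUState, MuscleTendonParams,
                                active_fiber_force_at, active_force_length,
                                passive_force_length, pennation_angle,
                                solve_isometric_equilibrium,
                                tendon_force_strain, total_fiber_force_at)


def make_params(**kwargs) -> MuscleTendonParams:
    base = dict(name="test", f_max=1000.0, lf_o=0.10, lt_s=0.20,
                alpha_o=0.0, gamma=0.20, eps_t0=0.049)
    base.update(kwargs)
    return MuscleTendonParams(**base)


class TestActiveForceLength:
    @pytest.mark.parametrize("l_norm, gamma, expected", [
        (1.0, 0.2, 1.0),
        (1.2, 0.2, math.exp(-0.2)),
        (0.5, 0.45, math.exp(-0.25 / 0.45)),
    ])
    def test_closed_form(self, l_norm, gamma, expected):
        assert active_force_length(l_norm, gamma) == pytest.approx(expected,
                                                                   rel=1e-12)

    @given(st.floats(0.01, 0.99))
    def test_symmetric_about_optimum(self, d):
        assert active_force_length(1 + d) == pytest.approx(
            active_force_length(1 - d), rel=1e-12)

    def test_unit_maximum(self):
        grid = np.linspace(0.3, 1.9, 2001)
        vals = active_force_length(grid)
        assert np.all(vals <= 1.0)
        assert active_force_length(1.0) == 1.0

    @pytest.mark.parametrize("l_norm, gamma", [(-0.5, 0.2), (0.0, 0.2),
                                               (1.0, 0.0), (1.0, -1.0)])
    def test_invalid_inputs(self, l_norm, gamma):
        with pytest.raises(ParameterError):
            active_force_length(l_norm, gamma)


class TestPassiveForceLength:
    def test_zero_at_and_below_optimum(self):
        assert passive_force_length(0.9) == 0.0
        assert passive_force_length(1.0) == 0.0

    def test_unity_at_strain_limit(self):
        assert passive_force_length(1.6) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_and_continuous_above_optimum(self):
        grid = np.linspace(1.0, 1.8, 5001)
        vals = passive_force_length(grid)
        assert np.all(np.diff(vals) > 0)
        assert np.max(np.abs(np.diff(vals))) < 1e-2  # no jumps


class TestTendonForceStrain:
    def test_slack_gives_zero(self):
        assert tendon_force_strain(-0.01, 0.049) == 0.0
        assert tendon_force_strain(0.0, 0.049) == 0.0

    def test_exactly_one_at_nominal_strain(self):
        assert tendon_force_strain(0.049, 0.049) == 1.0

    def test_monotone_and_in_unit_interval_below_nominal(self):
        eps = np.linspace(1e-6, 0.049, 4001)
        vals = tendon_force_strain(eps, 0.049)
        assert np.all(np.diff(vals) > 0)
        assert 0 < tendon_force_strain(0.02, 0.049) < 1

    def test_continuity_on_fine_grid(self):
        # jumps bounded by slope * step across toe/linear junction
        eps = np.arange(-0.001, 0.06, 1e-6)
        vals = tendon_force_strain(eps, 0.049)
        assert np.max(np.abs(np.diff(vals))) < 1e-4


class TestPennation:
    def test_parallel_fibered(self):
        p = make_params(alpha_o=0.0)
        assert pennation_angle(0.05, p) == 0.0

    def test_identity_at_optimum(self):
        p = make_params(alpha_o=0.3)
        assert pennation_angle(p.lf_o, p) == pytest.approx(0.3, rel=1e-12)

    def test_closed_form_at_double_length(self):
        p = make_params(alpha_o=0.2)
        assert pennation_angle(2 * p.lf_o, p) == pytest.approx(
            math.asin(math.sin(0.2) / 2), rel=1e-12)


class TestEquilibrium:
    def test_rigid_tendon_limit(self):
        p = make_params(eps_t0=1e-9)
        l_mtu = p.lt_s + 0.95 * p.lf_o
        state = solve_isometric_equilibrium(p, l_mtu, 1.0)
        assert state.l_fiber == pytest.approx(l_mtu - p.lt_s, abs=1e-7)

    def test_slack_passive_free_state(self):
        p = make_params()
        state = solve_isometric_equilibrium(p, p.lt_s + 0.9 * p.lf_o, 0.0)
        assert state.f_active == 0.0
        assert state.f_passive == 0.0
        assert state.tendon_strain == pytest.approx(0.0, abs=1e-12)

    def test_geometric_closure_and_force_balance(self):
        p = make_params(alpha_o=0.25)
        for a in (0.01, 0.075, 1.0):
            for frac in np.linspace(0.75, 1.25, 11):
                l_mtu = frac * (p.lt_s + p.lf_o)
                s = solve_isometric_equilibrium(p, l_mtu, a)
                closure = s.l_fiber * math.cos(s.pennation) + s.l_tendon
                assert closure == pytest.approx(l_mtu, abs=1e-12)
                assert abs(s.residual) < 1e-8 * p.f_max
                assert min(s.f_active, s.f_passive, s.f_tendon) >= 0

    def test_matches_brute_force_grid_oracle(self):
        """Solver fiber length equals brute-force residual minimization.

        Oracle: evaluate |residual| on a dense grid of fiber projections
        (coarse pass over the whole bracket, then a 10^6-point grid around
        the coarse minimum), independent of the bracketing root-finder.
        """
        rng = np.random.default_rng(42)

        def oracle_fiber_length(p, l_mtu, a):
            h = p.lf_o * math.sin(p.alpha_o)

            def abs_res(grid):
                lf = np.hypot(grid, h)
                cosa = grid / lf
                eps = (l_mtu - grid) / p.lt_s - 1.0
                res = (a * active_force_length(lf / p.lf_o, p.gamma)
                       + passive_force_length(lf / p.lf_o)) * cosa \
                    - tendon_force_strain(eps, p.eps_t0)
                return np.abs(res)

            lo = min(1e-4 * p.lf_o, 0.5 * l_mtu)
            hi = l_mtu * (1 - 1e-12)
            coarse = np.linspace(lo, hi, 10_000)
            i = int(np.argmin(abs_res(coarse)))
            step = coarse[1] - coarse[0]
            fine = np.linspace(max(lo, coarse[i] - 2 * step),
                               min(hi, coarse[i] + 2 * step), 1_000_000)
            best = fine[int(np.argmin(abs_res(fine)))]
            return math.hypot(best, h)

        for _ in range(100):
            p = make_params(
                f_max=float(rng.uniform(100, 3000)),
                lf_o=float(rng.uniform(0.05, 0.4)),
                lt_s=float(rng.uniform(0.08, 0.45)),
                alpha_o=float(rng.uniform(0.0, 0.45)),
            )
            a = float(rng.uniform(0.05, 1.0))
            l_mtu = float(rng.uniform(0.85, 1.2)) * (p.lt_s + p.lf_o)
            state = solve_isometric_equilibrium(p, l_mtu, a)
            assert abs(state.l_fiber - oracle_fiber_length(p, l_mtu, a)) \
                < 1e-6 * p.lf_o

    def test_active_force_monotone_in_activation(self):
        p = make_params()
        l_mtu = p.lt_s + 0.95 * p.lf_o
        forces = [active_fiber_force_at(p, l_mtu, a)
                  for a in np.linspace(0, 1, 11)]
        assert forces[0] == 0.0
        assert np.all(np.diff(forces) >= 0)

    def test_optimum_yields_f_max(self):
        # a rigid-ish tendon puts the fiber exactly at l_mtu - lt_s
        p = make_params(eps_t0=1e-9)
        force = active_fiber_force_at(p, p.lt_s + p.lf_o, 1.0)
        assert force == pytest.approx(p.f_max, rel=1e-5)

    def test_total_force_bounded_by_fmax_plus_passive(self):
        p = make_params()
        for frac in np.linspace(0.8, 1.3, 21):
            s = solve_isometric_equilibrium(p, frac * (p.lt_s + p.lf_o), 1.0)
            bound = p.f_max * (1.0 + passive_force_length(s.l_fiber / p.lf_o))
            assert s.f_active + s.f_passive <= bound + 1e-9

    def test_invalid_activation(self):
        p = make_params()
        with pytest.raises(ParameterError):
            solve_isometric_equilibrium(p, 0.3, 1.5)

    def test_state_invariant_fields(self):
        p = make_params()
        s = solve_isometric_equilibrium(p, p.lt_s + p.lf_o, 0.5)
        assert isinstance(s, MTUState)
        assert s.f_tendon == pytest.approx(s.f_active + s.f_passive,
                                           abs=1e-8 * p.f_max)
        assert total_fiber_force_at(p, p.lt_s + p.lf_o, 0.5) == pytest.approx(
            s.f_active + s.f_passive, rel=1e-9)
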