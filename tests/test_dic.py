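"""DIC engine: timescale weights, sensitivity matrix, threshold, solves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurodegen import ConductanceVector
from neurodegen.dic import (
    DICTargets,
    NoThresholdError,
    _log_partition,
    compensate,
    dic_at,
    dic_curves,
    sensitivity_matrix,
    threshold_voltage,
    timescale_weights,
    zero_sensitivity_direction,
)
from neurodegen.simulate import calcium_steady_state, input_conductance


class TestTimescaleWeights:
    def test_gate_at_fast_reference_gets_pure_fast_weight(self):
        w = _log_partition(1.0, 1.0, 10.0, 100.0)
        assert np.allclose(w, [1.0, 0.0, 0.0])

    def test_geometric_mean_splits_half_half(self):
        w = _log_partition(np.sqrt(10.0), 1.0, 10.0, 100.0)
        assert np.allclose(w, [0.5, 0.5, 0.0])
        w2 = _log_partition(np.sqrt(1000.0), 1.0, 10.0, 100.0)
        assert np.allclose(w2, [0.0, 0.5, 0.5])

    def test_slower_than_ultraslow_reference_is_pure_ultraslow(self):
        assert np.allclose(_log_partition(500.0, 1.0, 10.0, 100.0), [0, 0, 1])

    @given(V=st.floats(-80.0, -20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weights_partition_unity_at_any_voltage(self, V, stg):
        W = timescale_weights(stg, V)
        assert np.allclose(W.w.sum(axis=0), 1.0)
        assert np.all((W.w >= 0) & (W.w <= 1))

    def test_reference_timescales_ordered(self, stg, stg_burster):
        W = timescale_weights(stg, -50.0)
        tf, ts, tu = W.refs
        assert tf < ts < tu


class TestSensitivityMatrix:
    def test_columns_match_finite_difference_of_dic_map(self, stg, stg_burster):
        """S columns are the derivatives of the frozen-calcium DIC map."""
        V = -50.0
        ca = calcium_steady_state(stg, stg_burster, V)
        S = sensitivity_matrix(stg, stg_burster, V, frozen_ca=ca).S

        def fdic(vals):
            g = ConductanceVector(stg, vals)
            return sensitivity_matrix(stg, g, V, frozen_ca=ca).S @ vals

        for j in range(stg.N - 1):  # leak column is the normaliser itself
            h = max(1e-6 * stg_burster.values[j], 1e-7)
            vp = stg_burster.values.copy()
            vm = stg_burster.values.copy()
            vp[j] += h
            vm[j] -= h
            col = (fdic(vp) - fdic(vm)) / (2 * h)
            assert np.allclose(col, S[:, j], rtol=1e-4, atol=1e-9)

    def test_linear_in_gbar_at_fixed_background(self, stg, stg_burster):
        V = -52.0
        ca = calcium_steady_state(stg, stg_burster, V)
        S = sensitivity_matrix(stg, stg_burster, V, frozen_ca=ca).S
        g1 = stg_burster.values
        rng = np.random.default_rng(0)
        g2 = g1 * rng.uniform(0.5, 1.5, g1.size)
        left = S @ (g1 + g2)
        assert np.allclose(left, S @ g1 + S @ g2, rtol=1e-12)

    def test_zero_gated_conductances_give_pure_leak_dics(self, stg):
        vals = np.zeros(stg.N)
        vals[-1] = 0.02
        g = ConductanceVector(stg, vals)
        d = dic_at(stg, g, -60.0)
        assert d[0] == pytest.approx(1.0)  # leak/gleak in the fast row
        assert d[1] == pytest.approx(0.0, abs=1e-12)
        assert d[2] == pytest.approx(0.0, abs=1e-12)

    def test_gleak_zero_rejected(self, stg):
        vals = np.ones(stg.N)
        vals[-1] = 0.0
        with pytest.raises(ValueError, match="gleak"):
            sensitivity_matrix(stg, ConductanceVector(stg, vals), -50.0)

    def test_da_dic_sum_matches_iv_slope(self, da, da_spiker):
        """gleak * (gf+gs+gu) equals the steady-state I-V slope up to the
        NMDA baseline channel, which sits outside the analysis space."""
        V = -75.0
        total = da_spiker.gleak * float(np.sum(dic_at(da, da_spiker, V)))
        gin = input_conductance(da, da_spiker, V)
        assert total == pytest.approx(gin, rel=0.2)


class TestScaleInvariance:
    def test_dics_invariant_under_homogeneous_scaling_frozen_ca(self, stg, stg_burster):
        V = -50.0
        ca = calcium_steady_state(stg, stg_burster, V)
        d1 = dic_at(stg, stg_burster, V, frozen_ca=ca)
        d2 = dic_at(stg, stg_burster.scaled(3.0), V, frozen_ca=ca)
        assert np.allclose(d1, d2, rtol=1e-12)

    def test_da_curves_and_threshold_exactly_scale_invariant(self, da, da_spiker):
        p1 = dic_curves(da, da_spiker)
        p2 = dic_curves(da, da_spiker.scaled(5.0))
        assert np.allclose(p1.gf, p2.gf, rtol=1e-10)
        assert np.allclose(p1.gs, p2.gs, rtol=1e-10)
        assert np.allclose(p1.gu, p2.gu, rtol=1e-10)
        assert p1.V_th == pytest.approx(p2.V_th, abs=2e-3)


class TestThresholdVoltage:
    def test_burster_threshold_in_subthreshold_range(self, stg, stg_burster):
        vth = threshold_voltage(stg, stg_burster)
        assert -60.0 < vth < -30.0
        # the fast DIC changes sign at vth
        lo = dic_at(stg, stg_burster, vth - 0.5)[0]
        hi = dic_at(stg, stg_burster, vth + 0.5)[0]
        assert lo > 0 > hi

    def test_passive_membrane_has_no_threshold(self, stg):
        vals = np.zeros(stg.N)
        vals[-1] = 0.02
        with pytest.raises(NoThresholdError, match="no threshold"):
            threshold_voltage(stg, ConductanceVector(stg, vals))

    def test_accepted_burster_has_regenerative_slow_dic(self, stg, stg_burster):
        vth = threshold_voltage(stg, stg_burster)
        assert dic_at(stg, stg_burster, vth)[1] < 0


class TestCompensate:
    def test_identity_round_trip(self, stg, stg_burster):
        vth = threshold_voltage(stg, stg_burster)
        d = dic_at(stg, stg_burster, vth)
        t = DICTargets(V_th=vth, gf=d[0], gs=d[1], gu=d[2])
        warped = stg_burster.replace(Na=1000.0, CaS=3.0, H=0.1)
        sol = compensate(stg, warped, ["Na", "CaS", "H"], t)
        assert sol is not None
        for nm in ("Na", "CaS", "H"):
            assert sol[nm] == pytest.approx(stg_burster[nm], rel=1e-6)

    def test_random_feasible_solve_hits_targets(self, da, da_dic_pop, da_config):
        t = da_config.dic_targets
        g = da_dic_pop.member(0)
        warped = g.replace(**{nm: 2.0 * g[nm] + 0.01 for nm in da_config.solve_channels})
        sol = compensate(da, warped, list(da_config.solve_channels), t)
        assert sol is not None
        resid = dic_at(da, sol, t.V_th) - t.vector
        assert np.max(np.abs(resid)) < 1e-8

    def test_infeasible_targets_return_rejection_signal(self, da, da_spiker):
        # a hugely restorative slow DIC cannot be met with non-negative
        # calcium conductances: the solve must signal reject-and-resample
        t = DICTargets(V_th=-65.0, gs=+500.0, gu=2.0)
        assert compensate(da, da_spiker, ["Na", "CaL", "ERG"], t) is None

    def test_gleak_cannot_be_solved(self, stg, stg_burster):
        t = DICTargets(V_th=-50.0, gs=-1.0, gu=0.0)
        with pytest.raises(ValueError, match="gleak"):
            compensate(stg, stg_burster, ["Na", "CaS", "leak"], t)


class TestZeroSensitivityDirection:
    def test_orthogonal_to_slow_sensitivities(self, da, da_spiker):
        # calcium-free model: the direction is exactly orthogonal to the
        # slow row of the sensitivity matrix
        vth = threshold_voltage(da, da_spiker)
        d = zero_sensitivity_direction(da, da_spiker, ["CaL", "CaN"], V=vth)
        s = sensitivity_matrix(da, da_spiker, vth).columns(["CaL", "CaN"])[1]
        assert abs(s @ d) < 1e-6 * np.linalg.norm(s)
        assert np.linalg.norm(d) == pytest.approx(1.0)
        assert d[0] >= 0

    def test_first_order_flatness_along_direction(self, stg, stg_burster):
        """Moving along the direction changes gs at second order only,
        while a perpendicular move changes it at first order."""
        vth = threshold_voltage(stg, stg_burster)
        d = zero_sensitivity_direction(stg, stg_burster, ["A", "CaS"], V=vth)
        i = [stg.index("A"), stg.index("CaS")]

        def gs_of(eps, direction):
            vals = stg_burster.values.copy()
            vals[i] += eps * direction
            return dic_at(stg, ConductanceVector(stg, vals), vth)[1]

        base = gs_of(0.0, d)
        eps = 0.05
        along1 = abs(gs_of(eps, d) - base)
        along2 = abs(gs_of(2 * eps, d) - base)
        perp1 = abs(gs_of(eps, np.array([-d[1], d[0]])) - base)
        assert along1 < 0.02 * perp1  # first-order term suppressed
        assert 2.5 < along2 / along1 < 5.5  # remaining term is quadratic

    def test_stg_a_cas_direction_has_positive_slope(self, stg, stg_burster):
        d = zero_sensitivity_direction(stg, stg_burster, ["A", "CaS"])
        assert d[0] > 0 and d[1] > 0  # opposite slow roles -> positive corr

    def test_da_cal_can_direction_has_negative_slope(self, da, da_spiker):
        d = zero_sensitivity_direction(da, da_spiker, ["CaL", "CaN"])
        assert d[0] > 0 and d[1] < 0  # same slow role -> negative corr
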