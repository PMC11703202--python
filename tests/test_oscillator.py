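"""Two-ODE oscillator: vector field, phase plane, temperature mapping."""

from dataclasses import replace

import numpy as np
import pytest

from cyclescale import oscillator as osc
from cyclescale import periods as per
from cyclescale.scaling_laws import RateScalingCurve, q10_from_ea


def test_reference_config_is_consistent(ref_params):
    assert ref_params.eps < 1  # relaxation regime
    assert ref_params.deg.direction == "increasing"
    assert ref_params.wee1.direction == "decreasing"


class TestRhs:
    def test_activation_term_vanishes_when_fully_active(self, ref_params):
        # cyc == cdk1a: no inactive complexes left to activate
        dc, da = osc.rhs((40.0, 40.0), ref_params)
        assert da <= 0

    def test_vanishing_synthesis_leaves_origin_stationary(self, ref_params):
        p = replace(ref_params, ks=1e-12)
        dc, da = osc.rhs((0.0, 0.0), p)
        assert abs(dc) < 1e-9 and da == 0

    def test_rhs_zero_at_computed_fixed_point(self, ref_params):
        fp = osc.fixed_points(ref_params)[0]
        dc, da = osc.rhs(fp.state, ref_params)
        assert abs(dc) < 1e-6
        assert abs(da) < 1e-4  # da carries the 1/eps factor


class TestSimulate:
    def test_reference_set_oscillates_with_sawtooth_cyclin(self, ref_trajectory, ref_period):
        assert ref_period.oscillating
        # sawtooth: slow rise, fast fall of cyclin -> strong skewness of dcyc
        cyc = ref_trajectory["cyc"][5000:]
        d = np.diff(cyc)
        assert np.abs(d.min()) > 2 * d.max()

    def test_no_synthesis_decays_to_origin(self, ref_params, fast_sim):
        p = replace(ref_params, ks=1e-9)
        ts = fast_sim.run(p)
        assert ts["cyc"][-1] < 1e-3
        assert not per.detect_period(ts).oscillating

    def test_ordering_invariant_region(self, ref_params, fast_sim):
        ts = osc.simulate(ref_params, t_end=200.0, init=(10.0, 5.0), rtol=1e-8, atol=1e-10)
        assert ts["cdk1a"].min() > -1e-6
        assert np.all(ts["cdk1a"] <= ts["cyc"] + 1e-6)

    def test_period_robust_to_smaller_eps(self, ref_params):
        base = per.detect_period(osc.simulate(ref_params, t_end=400, rtol=1e-7, method="LSODA"))
        p = replace(ref_params, eps=ref_params.eps / 10)
        small = per.detect_period(osc.simulate(p, t_end=400, rtol=1e-7, method="LSODA"))
        assert small.period == pytest.approx(base.period, rel=0.05)

    def test_rate_time_rescaling_divides_period(self, ref_params):
        lam = 2.0
        base = per.detect_period(osc.simulate(ref_params, t_end=400, rtol=1e-7, method="LSODA"))
        p = replace(
            ref_params,
            ks=ref_params.ks * lam,
            kd=ref_params.kd * lam,
            ka=ref_params.ka * lam,
            ki=ref_params.ki * lam,
        )
        fast = per.detect_period(osc.simulate(p, t_end=200, rtol=1e-7, method="LSODA"))
        assert fast.period == pytest.approx(base.period / lam, rel=0.01)

    def test_invalid_horizon_rejected(self, ref_params):
        with pytest.raises(ValueError):
            osc.simulate(ref_params, t_end=-1.0)


class TestPhasePlane:
    def test_cyclin_nullcline_depends_only_on_ks_kd_ratio(self, ref_params):
        grid = np.linspace(1.0, 80.0, 50)
        n1 = osc.nullclines(ref_params, grid)
        p2 = replace(ref_params, ks=ref_params.ks * 3, kd=ref_params.kd * 3)
        n2 = osc.nullclines(p2, grid)
        np.testing.assert_allclose(n1["cyclin_nullcline"], n2["cyclin_nullcline"], rtol=1e-12)

    def test_cdk1_nullcline_depends_only_on_ka_ki_ratio(self, ref_params):
        grid = np.linspace(1.0, 80.0, 50)
        n1 = osc.nullclines(ref_params, grid)
        p2 = replace(ref_params, ka=ref_params.ka * 5, ki=ref_params.ki * 5)
        n2 = osc.nullclines(p2, grid)
        np.testing.assert_allclose(n1["cdk1_nullcline"], n2["cdk1_nullcline"], rtol=1e-12)

    def test_cdk1_nullcline_is_s_shaped(self, ref_params):
        grid = np.linspace(0.5, 80.0, 2000)
        nc = osc.nullclines(ref_params, grid)["cdk1_nullcline"]
        sign_changes = np.sum(np.diff(np.sign(np.diff(nc))) != 0)
        assert sign_changes >= 2  # two folds

    def test_reference_has_single_unstable_fixed_point(self, ref_params):
        fps = osc.fixed_points(ref_params)
        assert len(fps) == 1
        assert not fps[0].stable
        assert fps[0].arrest_class == "none"

    def test_low_synthesis_gives_interphase_arrest(self, ref_params):
        fps = osc.fixed_points(replace(ref_params, ks=ref_params.ks * 0.1))
        stable = [fp for fp in fps if fp.stable]
        assert stable and stable[0].arrest_class == "interphase-like"

    def test_high_synthesis_gives_m_phase_arrest(self, ref_params):
        fps = osc.fixed_points(replace(ref_params, ks=ref_params.ks * 4.0))
        stable = [fp for fp in fps if fp.stable]
        assert stable and stable[0].arrest_class == "m-phase-like"

    def test_fixed_points_lie_on_both_nullclines(self, ref_params):
        for fp in osc.fixed_points(ref_params):
            nc = osc.nullclines(ref_params, np.array([fp.state.cdk1a]))
            assert nc["cyclin_nullcline"][0] == pytest.approx(fp.state.cyc, rel=1e-6)
            assert nc["cdk1_nullcline"][0] == pytest.approx(fp.state.cyc, rel=1e-6)


class TestTemperatureMap:
    def test_anchoring_returns_reference_values(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(ref_params, 20.0, {"ks": 75e3, "kd": 40e3})
        p20 = pmap.params_at(20.0)
        assert p20.ks == pytest.approx(ref_params.ks, rel=1e-12)
        assert p20.kd == pytest.approx(ref_params.kd, rel=1e-12)
        assert p20.eps == pytest.approx(ref_params.eps, rel=1e-12)

    def test_equal_energies_preserve_ratios(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(
            ref_params, 20.0, {k: 75e3 for k in ("ks", "kd", "ka", "ki")}
        )
        for t in [12.0, 28.0]:
            p = pmap.params_at(t)
            assert p.ks / p.kd == pytest.approx(ref_params.ks / ref_params.kd, rel=1e-10)
            assert p.ka / p.ki == pytest.approx(ref_params.ka / ref_params.ki, rel=1e-10)

    def test_energy_imbalance_makes_ratio_increase_with_temperature(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(ref_params, 20.0, {"ks": 113e3, "kd": 40e3})
        ratios = [pmap.params_at(t).ks / pmap.params_at(t).kd for t in np.arange(10, 31, 5)]
        assert np.all(np.diff(ratios) > 0)

    def test_q10_of_mapped_rate_matches_closed_form(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(ref_params, 20.0, {"ks": 75e3})
        ratio = pmap.params_at(30.0).ks / pmap.params_at(20.0).ks
        assert ratio == pytest.approx(q10_from_ea(75e3, 20.0), rel=1e-10)

    def test_extrapolation_warns(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(
            ref_params, 20.0, {"ks": 75e3}, interval_c=(15.0, 25.0)
        )
        with pytest.warns(UserWarning, match="extrapolating"):
            pmap.params_at(30.0)

    def test_scaled_map_preserves_temperature_dependence(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(ref_params, 20.0, {"ks": 75e3})
        s = pmap.scaled(synthesis=2.0)
        r_base = pmap.params_at(28.0).ks / pmap.params_at(12.0).ks
        r_scaled = s.params_at(28.0).ks / s.params_at(12.0).ks
        assert r_scaled == pytest.approx(r_base, rel=1e-12)
        assert s.params_at(20.0).ks == pytest.approx(2.0 * ref_params.ks, rel=1e-12)

    def test_missing_curve_rejected(self, ref_params):
        pmap = osc.TemperatureParameterMap.arrhenius(ref_params, 20.0, {})
        with pytest.raises(ValueError):
            osc.TemperatureParameterMap(
                {"ks": pmap.curves["ks"]}, ref_params.deg, ref_params.cdc25, ref_params.wee1
            )
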