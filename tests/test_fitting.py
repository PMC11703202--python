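"""Scaling-law fitting pipeline: binning, the four fitters, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from cyclescale import fitting
from cyclescale.scaling_laws import (
    ArrheniusLaw,
    DoubleExpLaw,
    PowerExpLaw,
    QuadExpLaw,
    RateScalingCurve,
)
from cyclescale.synth import EmbryoGenSpec, gen_embryo_timings


def _dataset(temps, durations):
    rows = [
        {"unit_id": f"u{i}", "temperature_c": t, "interval_name": "cleavage", "duration_min": d}
        for i, (t, d) in enumerate(zip(temps, durations))
    ]
    return fitting.TimingDataset(pd.DataFrame(rows))


def _binned_from_law(law, temps):
    temps = np.asarray(temps, dtype=float)
    return fitting.BinnedMedians(temps, law.duration(temps), np.ones_like(temps))


class TestBinMedians:
    def test_rounding_collects_into_integer_bins(self):
        b = fitting.bin_medians(_dataset([18.2, 18.4, 17.9], [30.0, 32.0, 34.0]))
        assert list(b.temperature_c) == [18.0]
        assert b.median_duration[0] == 32.0
        assert b.n_per_bin[0] == 3

    def test_single_record(self):
        b = fitting.bin_medians(_dataset([21.0], [17.5]))
        assert list(b.temperature_c) == [21.0]
        assert b.median_duration[0] == 17.5

    def test_round_half_to_even(self):
        b = fitting.bin_medians(_dataset([18.5, 19.5], [10.0, 20.0]))
        # both round to even bins: 18 and 20
        assert list(b.temperature_c) == [18.0, 20.0]

    def test_duplicate_durations_share_median(self):
        b = fitting.bin_medians(_dataset([20.0, 20.1], [25.0, 25.0]))
        assert b.median_duration[0] == 25.0

    def test_exclusion_list_drops_bins(self):
        ds = _dataset([12.0, 13.0, 14.0], [40.0, 35.0, 30.0])
        b = fitting.bin_medians(ds.exclude_temperatures([12.0]))
        assert 12.0 not in b.temperature_c


class TestFitArrhenius:
    def test_exact_recovery_on_noiseless_data(self):
        law = ArrheniusLaw.from_anchor(30.0, 75e3, 20.0)
        fr = fitting.fit_arrhenius(_binned_from_law(law, np.arange(12, 22)))
        assert fr.law.ea == pytest.approx(75e3, rel=1e-10)
        assert fr.mse_log < 1e-20

    def test_two_points_interpolate(self):
        law = ArrheniusLaw.from_anchor(30.0, 60e3, 20.0)
        fr = fitting.fit_arrhenius(_binned_from_law(law, [15.0, 25.0]))
        assert fr.mse_log < 1e-20

    def test_fewer_than_two_bins_fails(self):
        with pytest.raises(fitting.FitError):
            fitting.fit_arrhenius(_binned_from_law(ArrheniusLaw(1.0, 60e3), [20.0]))

    def test_scale_equivariance_of_ea(self):
        law = ArrheniusLaw.from_anchor(30.0, 80e3, 20.0)
        b1 = _binned_from_law(law, np.arange(12, 22))
        b2 = fitting.BinnedMedians(b1.temperature_c, 60.0 * b1.median_duration, b1.n_per_bin)
        fr1, fr2 = fitting.fit_arrhenius(b1), fitting.fit_arrhenius(b2)
        assert fr2.law.ea == pytest.approx(fr1.law.ea, rel=1e-10)
        assert fr2.law.prefactor_a != pytest.approx(fr1.law.prefactor_a)

    def test_noisy_recovery_within_ci(self, rng):
        spec = EmbryoGenSpec(
            true_law=ArrheniusLaw.from_anchor(30.0, 75e3, 20.0),
            temperatures=np.arange(12, 22),
            n_per_temperature=200,
            noise_cv=0.05,
            seed=7,
        )
        ds = gen_embryo_timings(spec)
        br = fitting.bootstrap_ea(ds, n_boot=200, seed=11)
        assert br.ci_90[0] <= 75.0 <= br.ci_90[1]


class TestLinearizableFitters:
    def test_quad_exp_exact_recovery(self):
        gen = QuadExpLaw(a=50.0, ea=-30e3, b=150.0)
        fr = fitting.fit_quad_exp(_binned_from_law(gen, np.arange(10, 31, 2)))
        assert fr.mse_log < 1e-18
        assert fr.law.ea == pytest.approx(gen.ea, rel=1e-6)
        assert fr.law.b == pytest.approx(gen.b, rel=1e-6)

    def test_quad_exp_b0_recovers_arrhenius_form(self):
        gen = QuadExpLaw(a=30.0, ea=-60e3, b=0.0)
        fr = fitting.fit_quad_exp(_binned_from_law(gen, np.arange(10, 31, 2)))
        assert fr.law.ea == pytest.approx(-60e3, rel=1e-6)
        assert abs(fr.law.b) < 1e-6

    def test_power_exp_exact_recovery(self):
        gen = PowerExpLaw(a=1e-4, b=2.5, ea=-40e3)
        fr = fitting.fit_power_exp(_binned_from_law(gen, np.arange(8, 33, 2)))
        assert fr.mse_log < 1e-16
        assert fr.law.b == pytest.approx(2.5, rel=1e-4)

    def test_idempotence_on_own_fit(self):
        gen = QuadExpLaw(a=50.0, ea=-30e3, b=150.0)
        fr1 = fitting.fit_quad_exp(_binned_from_law(gen, np.arange(10, 31, 2)))
        fr2 = fitting.fit_quad_exp(_binned_from_law(fr1.law, np.arange(10, 31, 2)))
        assert fr2.law.ea == pytest.approx(fr1.law.ea, rel=1e-8)


class TestFitDoubleExp:
    @pytest.fixture
    def u_shaped(self):
        # duration minimum near 26C (branches cross at 27C)
        return RateScalingCurve.biphasic(1 / 30.0, 70e3, 250e3, t_ref=20.0, t_cross=27.0).duration_law

    def test_exact_recovery_on_own_generator(self, u_shaped):
        b = _binned_from_law(u_shaped, np.arange(10, 35))
        fr = fitting.fit_double_exp(b, arrhenius_interval=(10.0, 20.0))
        assert fr.mse_log <= 1e-10

    def test_never_worse_than_single_exponential(self, u_shaped):
        b = _binned_from_law(u_shaped, np.arange(10, 35))
        se = fitting.fit_arrhenius(b)
        de = fitting.fit_double_exp(b, arrhenius_interval=(10.0, 20.0))
        assert de.mse_log <= se.mse_log

    def test_recovers_duration_minimum_location(self, u_shaped):
        grid = np.linspace(10.0, 35.0, 2000)
        t_true = grid[np.argmin(u_shaped.duration(grid))]
        b = _binned_from_law(u_shaped, np.arange(10, 35))
        fr = fitting.fit_double_exp(b, arrhenius_interval=(10.0, 20.0))
        t_fit = grid[np.argmin(fr.law.duration(grid))]
        assert abs(t_fit - t_true) <= 0.5

    def test_pure_arrhenius_data_falls_back_to_one_branch(self):
        law = ArrheniusLaw.from_anchor(30.0, 75e3, 20.0)
        b = _binned_from_law(law, np.arange(12, 25))
        with pytest.warns(UserWarning, match="single branch"):
            fr = fitting.fit_double_exp(b, arrhenius_interval=(12.0, 24.0))
        assert fr.mse_log < 1e-15


class TestCompareFits:
    def test_unit_invariant_ordering(self):
        gen = RateScalingCurve.biphasic(1 / 30.0, 70e3, 250e3, 20.0, 27.0).duration_law
        b_min = _binned_from_law(gen, np.arange(10, 35))
        b_sec = fitting.BinnedMedians(b_min.temperature_c, 60.0 * b_min.median_duration, b_min.n_per_bin)

        def table(b):
            fits = {
                "SE": fitting.fit_arrhenius(b),
                "DE": fitting.fit_double_exp(b, (10.0, 20.0)),
            }
            return fitting.compare_fits(b, fits).sort_values("mse_log")["law"].tolist()

        assert table(b_min) == table(b_sec)

    def test_se_on_arrhenius_data_is_perfect(self):
        law = ArrheniusLaw.from_anchor(30.0, 75e3, 20.0)
        b = _binned_from_law(law, np.arange(12, 22))
        t = fitting.compare_fits(b, {"SE": fitting.fit_arrhenius(b)})
        assert t["mse_log"].iloc[0] < 1e-20


class TestBootstrap:
    def test_noiseless_data_yields_degenerate_distribution(self):
        spec = EmbryoGenSpec(
            true_law=ArrheniusLaw.from_anchor(30.0, 75e3, 20.0),
            temperatures=np.arange(12, 22),
            n_per_temperature=10,
            noise_cv=0.0,
            seed=0,
        )
        br = fitting.bootstrap_ea(gen_embryo_timings(spec), n_boot=100, seed=1)
        assert np.allclose(br.ea_samples, 75.0, rtol=1e-10)

    def test_seeded_determinism(self):
        spec = EmbryoGenSpec(
            true_law=ArrheniusLaw.from_anchor(30.0, 75e3, 20.0),
            temperatures=np.arange(12, 22),
            n_per_temperature=20,
            noise_cv=0.1,
            seed=5,
        )
        ds = gen_embryo_timings(spec)
        a = fitting.bootstrap_ea(ds, n_boot=150, seed=99)
        b = fitting.bootstrap_ea(ds, n_boot=150, seed=99)
        assert np.array_equal(a.ea_samples, b.ea_samples)

    def test_small_n_boot_rejected(self):
        spec = EmbryoGenSpec(
            true_law=ArrheniusLaw.from_anchor(30.0, 75e3, 20.0),
            temperatures=[15.0, 20.0],
            n_per_temperature=3,
            seed=0,
        )
        with pytest.raises(ValueError):
            fitting.bootstrap_ea(gen_embryo_timings(spec), n_boot=10)
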