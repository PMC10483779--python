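"""Segmentation, fitting stages and bootstrap behaviour."""

import numpy as np
import pytest

from rbale import synthetic_data as sd
from rbale.errors import ConfigurationError
from rbale.estimation import (
    BatchSlice,
    MonodFitConfig,
    RbaleFitConfig,
    bootstrap_ci,
    fit_monod_hierarchical,
    fit_rbale,
    loglinear_mu,
    per_batch_rates,
    segment_and_normalize,
)


class TestSegmentation:
    def test_sixteen_batches_give_sixteen_slices(self, ds_constant_noisy):
        slices = segment_and_normalize(
            ds_constant_noisy.timeseries, ds_constant_noisy.events
        )
        assert len(slices) == 16
        assert [s.batch for s in slices] == list(range(1, 17))

    def test_detection_matches_event_log(self, ds_constant_noiseless):
        """Transfer detection from signal drops recovers the logged batch
        windows to within one measurement cycle."""
        by_log = segment_and_normalize(
            ds_constant_noiseless.timeseries, ds_constant_noiseless.events
        )
        detected = segment_and_normalize(ds_constant_noiseless.timeseries)
        assert len(detected) == len(by_log)
        for a, b in zip(detected, by_log):
            assert abs(a.t[0] - b.t[0]) <= 0.25 + 1e-9
            assert a.well == b.well

    def test_slices_start_near_threshold_over_f_dil(self, ds_constant_noiseless):
        slices = segment_and_normalize(
            ds_constant_noiseless.timeseries, ds_constant_noiseless.events
        )
        for s in slices[1:]:
            # start = previous trigger reading / 17; trigger overshoots 60 by
            # at most one cycle of growth
            assert 60 / 17 <= s.bs[0] <= 60 / 17 * np.exp(0.41 * 0.25) + 1e-9

    def test_short_slice_flagged_excluded(self):
        ts = sd.gen_rbale_dataset(sd.glucose_validation(seed=0, cv=0.0)).timeseries
        short = BatchSlice(batch=1, well="A1", group="A", t=[0, 0.25], bs=[8, 9])
        assert segment_and_normalize(ts)[0].include
        from rbale.estimation import _apply_min_points

        assert not _apply_min_points([short], 4)[0].include


class TestLogLinearOracle:
    def test_exact_on_noiseless_exponential(self):
        t = np.arange(0, 5, 0.25)
        s = BatchSlice(batch=1, well="A1", group="A", t=t, bs=8 * np.exp(0.2 * t))
        assert loglinear_mu(s) == pytest.approx(0.2, abs=1e-9)

    def test_constant_signal_gives_zero(self):
        s = BatchSlice(batch=1, well="A1", group="A", t=np.arange(5.0), bs=np.full(5, 8.0))
        assert loglinear_mu(s) == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_rejected(self):
        s = BatchSlice(batch=1, well="A1", group="A", t=np.arange(3.0), bs=[1.0, -1.0, 2.0])
        with pytest.raises(ValueError):
            loglinear_mu(s)

    def test_agrees_with_model_fit_on_noiseless_data(
        self, ds_constant_noiseless, fit_constant_noiseless
    ):
        slices = segment_and_normalize(
            ds_constant_noiseless.timeseries, ds_constant_noiseless.events
        )
        oracle = np.array([loglinear_mu(s) for s in slices])
        model = fit_constant_noiseless.estimates["mu"]
        assert np.max(np.abs(model - oracle) / oracle) < 0.01


class TestFitRbale:
    def test_noiseless_exact_recovery(self, fit_constant_noiseless):
        f = fit_constant_noiseless
        assert f.converged
        assert np.max(np.abs(f.estimates["mu"] - 0.41)) < 1e-6
        assert f.estimates["f_dil"] == pytest.approx(17.0, abs=1e-6)
        assert f.estimates["X0"] == pytest.approx(8.0, abs=1e-6)

    def test_noisy_recovery_within_five_percent(self, fit_constant_noisy):
        mu = fit_constant_noisy.estimates["mu"]
        assert abs(mu.mean() - 0.41) / 0.41 < 0.05
        assert np.max(np.abs(mu - 0.41) / 0.41) < 0.05

    def test_switching_trend_recovered(self, fit_switching_noisy):
        """Stepwise-increasing truth reproduces the monotone rise with the
        correct plateau values at both ends."""
        mu = fit_switching_noisy.estimates["mu"]
        truth = np.array(sd.ETOH_R3_MU_SCHEDULE)
        assert np.max(np.abs(mu - truth) / truth) < 0.05
        # monotone trend up to estimation noise
        assert mu[-1] > mu[4] > mu[0]

    def test_exclusion_mask_is_explicit_config(self, ds_constant_noisy):
        fit = fit_rbale(
            ds_constant_noisy.timeseries,
            ds_constant_noisy.events,
            RbaleFitConfig(n_starts=2, exclude_batches=(1,)),
        )
        assert fit.estimates["included"][0] is False
        assert all(fit.estimates["included"][1:])

    def test_multistart_objective_monotone_in_n_starts(self, ds_constant_noisy):
        objs = []
        for n in (1, 3, 6):
            f = fit_rbale(
                ds_constant_noisy.timeseries,
                ds_constant_noisy.events,
                RbaleFitConfig(n_starts=n, seed=0),
            )
            objs.append(f.objective)
        assert objs[0] >= objs[1] - 1e-12 >= objs[2] - 2e-12

    def test_calibration_fit_requires_fixed_x0(self, ds_constant_noisy):
        with pytest.raises(ConfigurationError):
            fit_rbale(
                ds_constant_noisy.timeseries,
                ds_constant_noisy.events,
                RbaleFitConfig(fit_calibration=True),
            )

    def test_rates_table_shape(self, fit_constant_noisy, ds_constant_noisy):
        slices = segment_and_normalize(
            ds_constant_noisy.timeseries, ds_constant_noisy.events
        )
        df = per_batch_rates(fit_constant_noisy, slices)
        assert list(df.columns) == ["group", "batch", "mu_est", "ci_lo", "ci_hi", "n_points"]
        assert len(df) == 16
        assert (df["n_points"] >= 4).all()


class TestFitMonod:
    def test_noiseless_exact_recovery(self, ds_bioreactor_noiseless):
        fit = fit_monod_hierarchical(
            ds_bioreactor_noiseless.tables, MonodFitConfig(n_starts=1)
        )
        assert fit.converged
        assert abs(fit.estimates["mu_max"] - 0.15) / 0.15 < 1e-4
        assert abs(fit.estimates["Y_XS"] - 0.45) / 0.45 < 1e-4

    def test_noisy_recovery_within_five_percent(self, ds_bioreactor_noisy):
        fit = fit_monod_hierarchical(
            ds_bioreactor_noisy.tables, MonodFitConfig(n_starts=2)
        )
        assert abs(fit.estimates["mu_max"] - 0.15) / 0.15 < 0.05
        assert abs(fit.estimates["Y_XS"] - 0.45) / 0.45 < 0.05
        # K_S is weakly identifiable when S0 >> K_S: interval spans >= 1 OoM
        assert "K_S" in fit.meta["weakly_identifiable"]
        lo, hi = fit.ci["K_S"]
        assert hi / max(lo, 1e-12) >= 10

    def test_too_few_points_rejected(self, ds_bioreactor_noisy):
        short = ds_bioreactor_noisy.tables.groupby("reactor").head(3)
        with pytest.raises(ConfigurationError):
            fit_monod_hierarchical(short)


@pytest.fixture(scope="module")
def small_fit():
    ds = sd.gen_rbale_dataset(sd.glucose_validation(seed=11, cv=0.02, n_batches=4))
    return fit_rbale(ds.timeseries, ds.events, RbaleFitConfig(n_starts=2))


class TestBootstrap:
    def test_same_seed_identical_intervals(self, small_fit):
        a = bootstrap_ci(small_fit, n_boot=30, seed=5)
        b = bootstrap_ci(small_fit, n_boot=30, seed=5)
        assert a.ci == b.ci

    def test_noiseless_interval_width_collapses(self):
        ds = sd.gen_rbale_dataset(sd.glucose_validation(seed=11, cv=0.0, n_batches=4))
        fit = fit_rbale(ds.timeseries, ds.events, RbaleFitConfig(n_starts=1))
        bf = bootstrap_ci(fit, n_boot=20, seed=1)
        for lo, hi in bf.ci.values():
            assert hi - lo < 1e-6

    def test_intervals_bracket_estimates(self, small_fit):
        bf = bootstrap_ci(small_fit, n_boot=40, seed=2)
        for i, b in enumerate(small_fit.estimates["batches"]):
            lo, hi = bf.ci[f"mu[{b}]"]
            assert lo <= small_fit.estimates["mu"][i] * 1.05
            assert hi >= small_fit.estimates["mu"][i] * 0.95

    def test_unconverged_fit_rejected(self):
        from rbale.estimation import FitResult

        with pytest.raises(ConfigurationError):
            bootstrap_ci(FitResult(estimates={}, converged=False))
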