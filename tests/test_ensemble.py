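import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microcast.ensemble import (
    EnsembleConfig,
    build_interval,
    detect_outliers,
    ensemble_forecast,
    train_ensemble,
)
from microcast.forecasters import RfConfig
from microcast.io import AbundanceSeries
from microcast.preprocess import ScalerParams, WindowConfig, make_windows, transform


def _cfg(**kwargs):
    kwargs.setdefault("n_members", 3)
    return EnsembleConfig(**kwargs)


class TestConfig:
    def test_single_member_rejected(self):
        with pytest.raises(ValueError, match="std undefined"):
            EnsembleConfig(n_members=1)

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            EnsembleConfig(n_members=3, seeds=[1, 1, 2])

    def test_z_must_match_coverage(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EnsembleConfig(n_members=2, coverage=0.95, z=2.5)
        assert EnsembleConfig(n_members=2, coverage=0.95).z == pytest.approx(
            1.959964, abs=1e-6
        )

    def test_derived_member_seeds_are_distinct_and_reproducible(self):
        a = _cfg(base_seed=7).member_seeds()
        b = _cfg(base_seed=7).member_seeds()
        assert a == b and len(set(a)) == 3


class TestBuildInterval:
    def test_closed_form_three_member_cell(self):
        members = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        fc = build_interval(members, _cfg(z=1.96))
        assert fc.mean[0, 0] == 2.0
        assert fc.std[0, 0] == pytest.approx(1.0)
        assert fc.lower[0, 0] == pytest.approx(0.04)
        assert fc.upper[0, 0] == pytest.approx(3.96)

    def test_identical_members_collapse_to_a_point(self):
        members = np.full((4, 2, 2), 5.0)
        fc = build_interval(members, _cfg(n_members=4))
        np.testing.assert_array_equal(fc.lower, 5.0)
        np.testing.assert_array_equal(fc.upper, 5.0)

    def test_seeded_normal_members_recover_draw_parameters(self):
        rng = np.random.default_rng(0)
        mu, sigma = 3.0, 0.5
        members = rng.normal(mu, sigma, size=(200, 50, 2))
        fc = build_interval(members, _cfg(n_members=200))
        assert np.mean(fc.mean) == pytest.approx(mu, abs=0.01)
        assert np.mean(fc.std) == pytest.approx(sigma, abs=0.01)

    def test_nan_member_named_in_error(self):
        members = np.zeros((3, 2, 2))
        members[1, 0, 1] = np.nan
        with pytest.raises(ValueError, match="member 1"):
            build_interval(members, _cfg())

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.5, 0.999), st.floats(0.5, 0.999))
    def test_interval_width_monotone_in_coverage(self, c1, c2):
        lo_c, hi_c = sorted((c1, c2))
        members = np.random.default_rng(0).normal(size=(5, 3, 2))
        narrow = build_interval(members, EnsembleConfig(n_members=5, coverage=lo_c))
        wide = build_interval(members, EnsembleConfig(n_members=5, coverage=hi_c))
        assert ((wide.upper - wide.lower) >= (narrow.upper - narrow.lower) - 1e-12).all()

    def test_back_transform_commutes_with_interval_construction(self):
        rng = np.random.default_rng(1)
        members_scaled = rng.uniform(size=(10, 4, 3))
        params = ScalerParams(
            minimum=pd.Series({"a": 0.0, "b": 10.0, "c": 5.0}),
            maximum=pd.Series({"a": 100.0, "b": 30.0, "c": 5.0}),
        )
        cfg = _cfg(n_members=10)
        fc_abs = build_interval(members_scaled, cfg, genus_names=list("abc")
                                ).to_absolute(params)
        from microcast.preprocess import inverse_transform

        members_abs = np.stack(
            [inverse_transform(m, params) for m in members_scaled]
        )
        direct = build_interval(members_abs, cfg, scale="absolute")
        np.testing.assert_allclose(fc_abs.lower, direct.lower, atol=1e-12)
        np.testing.assert_allclose(fc_abs.upper, direct.upper, atol=1e-12)


class TestTrainEnsemble:
    def _windows(self):
        rng = np.random.default_rng(0)
        series = AbundanceSeries(
            data=pd.DataFrame(
                rng.uniform(0, 1, size=(30, 2)), columns=["a", "b"],
                index=[str(t) for t in range(30)],
            )
        )
        return make_windows(series, WindowConfig(lag=3))

    def test_members_differ_on_noisy_series(self):
        windows = self._windows()
        members = train_ensemble(
            _cfg(n_members=2, seeds=[1, 2]), RfConfig(n_trees=10), windows
        )
        a = members[0].predict_batch(windows.X)
        b = members[1].predict_batch(windows.X)
        assert not np.array_equal(a, b)

    def test_member_count_respected(self):
        members = train_ensemble(_cfg(), RfConfig(n_trees=3), self._windows())
        assert len(members) == 3


class TestDetectOutliers:
    def _interval(self, lower, upper, genera=("g",)):
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        mean = (lower + upper) / 2
        from microcast.ensemble import EnsembleForecast

        return EnsembleForecast(
            member_predictions=np.stack([mean, mean]),
            mean=mean, std=(upper - lower) / (2 * 1.96),
            lower=lower, upper=upper, z=1.96, scale="absolute",
            genus_names=list(genera),
        )

    def test_value_above_interval_flagged_with_exceedance(self):
        iv = self._interval([[0.04]], [[3.96]])
        report = detect_outliers(np.array([[5.0]]), iv)
        row = report.flags.iloc[0]
        assert row["direction"] == "above"
        assert row["exceedance"] == pytest.approx(1.04)

    def test_boundary_equal_value_is_not_an_outlier(self):
        iv = self._interval([[0.04]], [[3.96]])
        assert detect_outliers(np.array([[3.96]]), iv).n_flags == 0
        assert detect_outliers(np.array([[0.04]]), iv).n_flags == 0

    def test_below_direction_and_sorting(self):
        iv = self._interval([[1.0, 1.0], [1.0, 1.0]], [[2.0, 2.0], [2.0, 2.0]],
                            genera=("b", "a"))
        report = detect_outliers(
            np.array([[0.5, 3.0], [1.5, 0.0]]), iv, timestamps=[10, 20]
        )
        assert list(report.flags["timestamp"]) == [10, 10, 20]
        assert list(report.flags["direction"]) == ["above", "below", "below"]
        # genus ties at t=10 resolved alphabetically
        assert list(report.flags["genus"]) == ["a", "b", "a"]

    def test_missing_observation_row_skipped(self):
        iv = self._interval([[1.0], [1.0]], [[2.0], [2.0]])
        observed = np.array([[np.nan], [5.0]])
        report = detect_outliers(observed, iv)
        assert report.n_flags == 1
        assert report.flags.iloc[0]["timestamp"] == 1

    def test_scaled_interval_requires_scaler(self):
        iv = self._interval([[0.0]], [[1.0]])
        iv.scale = "scaled"
        with pytest.raises(ValueError, match="scaler"):
            detect_outliers(np.array([[0.5]]), iv)

    def test_report_round_trips_through_tsv(self, tmp_path):
        iv = self._interval([[1.0]], [[2.0]])
        report = detect_outliers(np.array([[5.0]]), iv)
        report.write(tmp_path / "flags.tsv")
        from microcast.ensemble import OutlierReport

        back = OutlierReport.read(tmp_path / "flags.tsv")
        assert back.cells() == report.cells()


class TestCalibration:
    def test_iid_normal_members_flag_rate_near_nominal(self):
        """Members and observation drawn i.i.d. from the same normal law."""
        rng = np.random.default_rng(123)
        n_trials = 20000
        members = rng.normal(10.0, 2.0, size=(50, n_trials, 1))
        observed = rng.normal(10.0, 2.0, size=(n_trials, 1))
        fc = build_interval(members, EnsembleConfig(n_members=50))
        flagged = (observed < fc.lower) | (observed > fc.upper)
        rate = flagged.mean()
        assert 0.035 < rate < 0.065


class TestEndToEndSpike:
    def test_injected_spike_flagged_by_rf_ensemble(self):
        from microcast.pipeline import detect_on_test, prepare
        from microcast.simulate import (
            GenusProcessSpec,
            ShiftEvent,
            SyntheticTruth,
            generate,
        )

        truth = SyntheticTruth(
            specs={
                "g0": GenusProcessSpec(baseline=1000.0, seasonal_amplitude=200.0,
                                       seasonal_period=20, ar_coefficient=0.3,
                                       noise_sd=20.0),
                "g1": GenusProcessSpec(baseline=500.0, seasonal_amplitude=100.0,
                                       seasonal_period=20, phase=1.0,
                                       ar_coefficient=0.3, noise_sd=10.0),
            },
            events=[ShiftEvent(timestep=90, genus="g0", magnitude=8.0,
                               units="sd")],
            seed=21, T=100,
        )
        series, meta, labels = generate(truth)
        prep = prepare(series, meta)
        result = detect_on_test(
            prep, EnsembleConfig(n_members=5, base_seed=3),
            RfConfig(n_trees=20, split_criterion="squared_error"),
        )
        assert (90, "g0") in result.report.cells()
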