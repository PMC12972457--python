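"""Clock protocol components: MI selection, imputation, fitting, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpclock import BetaMatrix, ClockConfig, InputError, SimConfig
from mpclock import clockkit, synthio


def _beta(values: np.ndarray, ages: np.ndarray, channel: str = "converted") -> BetaMatrix:
    samples = [f"S{i+1}" for i in range(values.shape[1])]
    return BetaMatrix(
        values=pd.DataFrame(values, index=[f"L{i:05d}" for i in range(values.shape[0])],
                            columns=samples),
        ages=pd.Series(ages, index=samples),
        channel=channel,
    )


class TestKsgMI:
    def test_matches_sklearn_reference(self):
        # dual-route check: same estimator as the field-standard library
        from sklearn.feature_selection import mutual_info_regression

        rng = np.random.default_rng(5)
        X = rng.uniform(0, 100, (28, 250))
        X[:, :10] += 5 * rng.normal(size=(28, 1))  # mixed dependence levels
        y = rng.uniform(4, 24, 28)
        mine = clockkit.ksg_mi(X, y, seed=0)
        ref = mutual_info_regression(X, y, n_neighbors=3, random_state=0)
        assert np.abs(mine - ref).max() < 1e-8

    def test_informative_feature_scores_high(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(4, 24, 28)
        X = np.column_stack([y, rng.uniform(0, 100, 28)])
        mi = clockkit.ksg_mi(X, y, seed=0)
        assert mi[0] > 1.0 and mi[1] < mi[0]


class TestSelectFeatures:
    def _matrix(self, n_loci=50, n_samples=28, seed=0):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 100, (n_loci, n_samples))
        ages = np.sort(rng.uniform(4, 24, n_samples))
        return _beta(values, ages)

    def test_age_identical_locus_selected(self):
        bm = self._matrix()
        values = bm.values.copy()
        values.iloc[0] = bm.ages.to_numpy()
        selected = clockkit.select_features_mi(values, bm.ages, 0.20, seed=1)
        assert "L00000" in selected

    def test_infinite_threshold_selects_nothing(self):
        bm = self._matrix()
        assert clockkit.select_features_mi(bm.values, bm.ages, float("inf")) == []

    def test_noise_locus_rarely_passes_threshold(self):
        # null-simulation oracle: a single pure-noise locus at n=28 stays
        # below 0.20 nats in at least 95% of seeds
        rng = np.random.default_rng(2024)
        n_seeds, exceed = 200, 0
        for s in range(n_seeds):
            x = rng.uniform(0, 100, (28, 1))
            y = rng.uniform(4, 24, 28)
            exceed += clockkit.ksg_mi(x, y, seed=s)[0] >= 0.20
        assert exceed / n_seeds <= 0.05

    def test_preconditions(self):
        bm = self._matrix(n_samples=6)
        with pytest.raises(InputError):
            clockkit.select_features_mi(bm.values, bm.ages, 0.2)
        bm = self._matrix()
        with pytest.raises(InputError):
            clockkit.select_features_mi(
                bm.values, pd.Series(10.0, index=bm.ages.index), 0.2
            )


class TestImpute:
    def test_identity_without_missing(self):
        bm = _beta(np.arange(20.0).reshape(4, 5), np.linspace(4, 24, 5))
        out = clockkit.impute_missing(bm, k=2)
        pd.testing.assert_frame_equal(out.values, bm.values)

    def test_single_missing_entry_imputed_as_locus_mean(self):
        values = np.array([[10.0, 20.0, 30.0, np.nan], [1.0, 2.0, 3.0, 4.0]])
        bm = _beta(values, np.array([4.0, 10.0, 16.0, 22.0]))
        out = clockkit.impute_missing(bm, k=3)
        assert out.values.iloc[0, 3] == pytest.approx(20.0)
        assert out.values.iloc[1].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_all_missing_locus_dropped(self):
        values = np.array([[np.nan, np.nan, np.nan], [1.0, 2.0, 3.0]])
        bm = _beta(values, np.array([4.0, 14.0, 24.0]))
        out = clockkit.impute_missing(bm, k=2)
        assert list(out.values.index) == ["L00001"]

    def test_masking_oracle_rmse_below_twice_noise(self):
        # hide known entries of a smooth matrix; KNN imputation should
        # recover them to within twice the per-entry noise level
        noise_sd = 2.0
        rng = np.random.default_rng(6)
        baseline = rng.uniform(20, 80, size=(120, 1))
        truth = baseline + rng.normal(0, noise_sd, size=(120, 24))
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.05
        masked[holes] = np.nan
        bm = _beta(masked, np.linspace(4, 24, 24))
        out = clockkit.impute_missing(bm, k=5)
        rmse = np.sqrt(np.mean((out.values.to_numpy()[holes] - truth[holes]) ** 2))
        assert rmse < 2 * noise_sd


class TestFitClock:
    def _cfg(self, **kw):
        kw.setdefault("n_iterations", 2)
        return ClockConfig(seed=3, **kw)

    def test_perfect_feature_recovers_age(self):
        rng = np.random.default_rng(7)
        ages = np.sort(rng.uniform(4, 24, 38))
        X = pd.DataFrame({"L0": ages}, index=[f"S{i}" for i in range(38)])
        rep = clockkit.fit_clock(
            X.iloc[:28], ages[:28], self._cfg(), X.iloc[28:], ages[28:]
        )
        assert rep.test_score > 0.99
        assert rep.test_mae < 0.5

    def test_pure_noise_features_shrink_to_mean(self):
        rng = np.random.default_rng(8)
        scores = []
        for _ in range(8):
            ages = rng.uniform(4, 24, 38)
            X = pd.DataFrame(
                rng.uniform(0, 100, (38, 20)), index=[f"S{i}" for i in range(38)]
            )
            rep = clockkit.fit_clock(
                X.iloc[:28], ages[:28], self._cfg(), X.iloc[28:], ages[28:]
            )
            scores.append(rep.test_score)
        assert np.mean(scores) <= 0.05

    def test_duplicated_feature_is_redundant(self):
        rng = np.random.default_rng(9)
        ages = np.sort(rng.uniform(4, 24, 38))
        f = ages + rng.normal(0, 1.0, 38)
        idx = [f"S{i}" for i in range(38)]
        X1 = pd.DataFrame({"L0": f}, index=idx)
        X2 = pd.DataFrame({"L0": f, "L0b": f}, index=idx)
        rep1 = clockkit.fit_clock(X1.iloc[:28], ages[:28], self._cfg(), X1.iloc[28:], ages[28:])
        rep2 = clockkit.fit_clock(X2.iloc[:28], ages[:28], self._cfg(), X2.iloc[28:], ages[28:])
        assert np.allclose(rep1.predictions, rep2.predictions, atol=0.3)

    def test_zero_features_degrades_to_mean_predictor(self):
        ages = np.linspace(4, 24, 12)
        X = pd.DataFrame(index=[f"S{i}" for i in range(12)])
        rep = clockkit.fit_clock(X.iloc[:9], ages[:9], self._cfg(), X.iloc[9:], ages[9:])
        assert rep.intercept == pytest.approx(np.mean(ages[:9]))
        assert (rep.predictions == rep.intercept).all()


@pytest.fixture(scope="module")
def small_run():
    cfg = SimConfig(n_loci=400, n_samples=38, seed=12)
    conv, unconv, _ = synthio.simulate_array_cohort(cfg)
    channels = {
        "converted": clockkit.impute_missing(conv),
        "unconverted": clockkit.impute_missing(unconv),
    }
    reps = clockkit.repeated_evaluation(channels, ClockConfig(n_iterations=4, seed=12))
    return channels, reps


class TestRepeatedEvaluation:
    def test_schema_one_replicate_per_condition_per_iteration(self, small_run):
        _, reps = small_run
        seen = {(r.iteration, r.condition) for r in reps}
        conditions = {"converted", "unconverted", "both", "dummy", "permuted"}
        assert seen == {(i, c) for i in range(4) for c in conditions}

    def test_dummy_mae_matches_closed_form(self, small_run):
        channels, reps = small_run
        ages = channels["converted"].ages
        for rep in reps:
            if rep.condition == "dummy":
                mean_train = ages.loc[rep.train_samples].mean()
                expected = (ages.loc[rep.test_samples] - mean_train).abs().mean()
                assert rep.test_mae == pytest.approx(expected, abs=1e-12)
                assert rep.intercept == pytest.approx(mean_train)

    def test_conditions_share_splits_within_iteration(self, small_run):
        _, reps = small_run
        by_iter = {}
        for rep in reps:
            by_iter.setdefault(rep.iteration, []).append(rep)
        for group in by_iter.values():
            first = group[0]
            for rep in group[1:]:
                assert rep.train_samples == first.train_samples
                assert rep.test_samples == first.test_samples

    def test_mismatched_channels_rejected(self, small_run):
        channels, _ = small_run
        bad_ages = channels["converted"].ages * 2
        bad = BetaMatrix(
            values=channels["converted"].values, ages=bad_ages, channel="x"
        )
        with pytest.raises(InputError):
            clockkit.repeated_evaluation(
                {"converted": bad, "unconverted": channels["unconverted"]},
                ClockConfig(n_iterations=1),
            )


class TestCompareConditions:
    @staticmethod
    def _reps(groups: dict[str, list[float]]):
        reps = []
        for cond, scores in groups.items():
            for i, s in enumerate(scores):
                reps.append(
                    clockkit._mean_predictor_replicate(
                        i, "dummy", np.array([10.0]), np.array([10.0 + s]), ["a"], ["b"]
                    )
                )
                reps[-1].condition = cond
                reps[-1].test_score = s
        return reps

    def test_two_groups_f_equals_t_squared(self):
        a = [0.1, 0.4, 0.3, 0.5, 0.2]
        b = [0.6, 0.9, 0.7, 0.8, 1.0]
        summary = clockkit.compare_conditions(self._reps({"a": a, "b": b}))
        t = stats.ttest_ind(a, b, equal_var=True).statistic
        assert summary.anova_f == pytest.approx(t**2, rel=1e-12)

    def test_identical_groups_give_f_zero_p_one(self):
        summary = clockkit.compare_conditions(
            self._reps({"a": [0.5, 0.5], "b": [0.5, 0.5], "c": [0.5, 0.5]})
        )
        assert summary.anova_f == 0.0 and summary.anova_p == 1.0
        assert not summary.tukey["reject"].any()

    def test_three_groups_match_hand_computed_sums_of_squares(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 5.0, 8.0]}
        summary = clockkit.compare_conditions(self._reps(groups))
        data = [np.array(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert summary.anova_f == pytest.approx(f_oracle, rel=1e-12)

    def test_single_replicate_condition_excluded(self):
        summary = clockkit.compare_conditions(
            self._reps({"a": [0.1, 0.2, 0.3], "b": [0.4, 0.5, 0.9], "c": [0.7]})
        )
        assert summary.excluded == ["c"]
        assert set(summary.groups) == {"a", "b"}


class TestAgeAcceleration:
    def test_identity_and_negation(self):
        resid = pd.Series([1.0, -2.0, 0.5, 3.0], index=list("abcd"))
        r, p = clockkit.correlate_acceleration(resid, resid)
        assert r == pytest.approx(1.0)
        r, _ = clockkit.correlate_acceleration(resid, -resid)
        assert r == pytest.approx(-1.0)

    def test_too_few_shared_samples_is_undefined(self):
        a = pd.Series([1.0, 2.0], index=["a", "b"])
        b = pd.Series([1.0, 2.0], index=["b", "c"])
        r, p = clockkit.correlate_acceleration(a, b)
        assert np.isnan(r) and np.isnan(p)

    def test_acceleration_is_prediction_residual(self):
        ages = pd.Series([10.0, 20.0], index=["S1", "S2"])
        rep = clockkit._mean_predictor_replicate(
            0, "dummy", np.array([12.0, 18.0]), ages.to_numpy(), ["S3"], ["S1", "S2"]
        )
        resid = clockkit.age_acceleration(rep, ages)
        assert resid.tolist() == [5.0, -5.0]
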