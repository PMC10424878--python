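import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bruteforce import pairwise_auroc
from prosirs import (
    ModelSpec,
    all_model_specs,
    calibration_metrics,
    descriptor_group_tests,
    discrimination_metrics,
    fit_cox_ph,
    fit_logistic_cv,
    ranking_scores,
)
from prosirs.evaluation import combination_chi2_tests


def logistic_rows(rng, n=300, beta_lam=0.0, beta0=-0.5):
    lam = rng.uniform(0, 1, size=n)
    trend = rng.uniform(-1, 1, size=n)
    changes = rng.integers(0, 40, size=n)
    p = 1 / (1 + np.exp(-(beta0 + beta_lam * lam)))
    return pd.DataFrame(
        {
            "lambda_mean": lam,
            "lambda_trend": trend,
            "n_changes": changes,
            "outcome": (rng.uniform(size=n) < p).astype(int),
        }
    )


class TestModelSpecs:
    def test_exactly_seven_distinct_nonempty_subsets(self):
        specs = all_model_specs()
        assert len(specs) == 7
        assert len({s.predictors for s in specs}) == 7
        assert all(s.predictors for s in specs)
        names = {s.name for s in specs}
        assert {"S~Lambda", "S~Delta", "S~C", "S~Lambda+Delta+C"} <= names

    def test_empty_or_unknown_predictors_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(())
        with pytest.raises(ValueError):
            ModelSpec(("spo2",))


class TestLogisticCV:
    def test_every_row_scored_once_out_of_fold(self):
        rng = np.random.default_rng(0)
        rows = logistic_rows(rng, n=200, beta_lam=2.0)
        res = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=1)
        assert len(res.probabilities) == len(rows)
        assert np.isfinite(res.probabilities).all()
        assert ((res.probabilities > 0) & (res.probabilities < 1)).all()

    def test_no_signal_gives_null_or_and_auroc(self):
        rng = np.random.default_rng(1)
        rows = logistic_rows(rng, n=2000, beta_lam=0.0)
        res = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=1)
        or_lam = res.coefficients.set_index("term").loc["lambda_mean", "odds_ratio"]
        assert 0.6 < or_lam < 1.6
        auroc, *_ = discrimination_metrics(res.probabilities, rows["outcome"])
        assert abs(auroc - 0.5) < 0.06

    def test_positive_lambda_coefficient_recovered_across_seeds(self):
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            rows = logistic_rows(rng, n=300, beta_lam=2.5)
            res = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=seed)
            coef = res.coefficients.set_index("term").loc["lambda_mean", "coef"]
            recovered.append(coef > 0)
        assert all(recovered)

    def test_deterministic_given_seed_and_single_class_rejected(self):
        rng = np.random.default_rng(2)
        rows = logistic_rows(rng, n=150, beta_lam=1.0)
        a = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=7)
        b = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=7)
        assert np.array_equal(a.probabilities, b.probabilities)
        rows["outcome"] = 1
        with pytest.raises(ValueError, match="class"):
            fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), seed=7)

    def test_perfect_separation_flagged_not_fatal(self):
        rows = pd.DataFrame(
            {
                "lambda_mean": np.r_[np.zeros(20), np.ones(20)],
                "lambda_trend": 0.0,
                "n_changes": 0,
                "outcome": np.r_[np.zeros(20, int), np.ones(20, int)],
            }
        )
        res = fit_logistic_cv(rows, ModelSpec(("lambda_mean",)), k_folds=5, seed=0)
        assert res.separation_flagged
        assert np.isfinite(res.probabilities).all()


class TestDiscrimination:
    def test_perfect_ranking_and_all_ties(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert discrimination_metrics(np.arange(10) / 10, y)[0] == 1.0
        assert discrimination_metrics(np.full(10, 0.3), y)[0] == 0.5

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.choice([0.1, 0.25, 0.5, 0.5, 0.9], size=500)
        y = rng.integers(0, 2, size=500)
        auroc, *_ = discrimination_metrics(p, y)
        assert auroc == pytest.approx(pairwise_auroc(p, y), abs=1e-12)

    def test_cutoff_maximises_youden_lowest_on_ties(self):
        # probabilities 0.2/0.4/0.8; both 0.4 and 0.8 reach the same Youden sum
        p = np.array([0.2, 0.2, 0.4, 0.8])
        y = np.array([0, 0, 1, 1])
        auroc, cutoff, sens, spec = discrimination_metrics(p, y)
        assert auroc == 1.0
        assert cutoff == 0.4  # lowest of the tied optima
        assert sens == 1.0 and spec == 1.0

    def test_sensitivity_specificity_consistent_with_cutoff(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        y = (rng.uniform(size=200) < p).astype(int)
        _, cutoff, sens, spec = discrimination_metrics(p, y)
        called = p >= cutoff
        assert sens == pytest.approx(called[y == 1].mean())
        assert spec == pytest.approx((~called)[y == 0].mean())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            discrimination_metrics(np.array([0.2, 0.8]), np.array([1, 1]))


class TestCalibration:
    def test_true_probabilities_give_unit_slope_zero_intercept(self):
        slopes, intercepts = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.05, 0.95, size=10_000)
            y = (rng.uniform(size=10_000) < p).astype(int)
            slope, intercept, dslope, dintercept = calibration_metrics(p, y)
            slopes.append(slope)
            intercepts.append(intercept)
            assert dslope == abs(slope - 1) and dintercept == abs(intercept)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)
        assert np.mean(intercepts) == pytest.approx(0.0, abs=0.05)

    def test_doubling_log_odds_roughly_halves_slope(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.9, size=20_000)
        y = (rng.uniform(size=20_000) < p).astype(int)
        logit = np.log(p / (1 - p))
        p2 = 1 / (1 + np.exp(-2 * logit))
        slope, *_ = calibration_metrics(p2, y)
        assert slope == pytest.approx(0.5, abs=0.07)

    def test_constant_probabilities_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            slope, *_ = calibration_metrics(np.full(50, 0.5), np.r_[np.zeros(25), np.ones(25)])
        assert np.isnan(slope)

    def test_degenerate_probabilities_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            calibration_metrics(
                np.array([0.0, 0.2, 0.8, 1.0] * 10),
                np.array([0, 0, 1, 1] * 10),
            )


class TestRankingScores:
    def _grid(self, aurocs):
        rows = []
        for (scheme, model), value in aurocs.items():
            rows.append({"scheme": scheme, "model": model, "auroc": value})
        return pd.DataFrame(rows)

    def test_best_everywhere_scores_one_worst_everywhere_zero(self):
        schemes = [f"w{i}" for i in range(5)]
        models = ["m1", "m2", "m3", "m4"]
        aurocs = {}
        for j, m in enumerate(models):
            for i, s in enumerate(schemes):
                aurocs[(s, m)] = 0.5 + 0.05 * i + 0.001 * j  # w4 best, w0 worst in every model
        s_w, _ = ranking_scores(self._grid(aurocs), contributing_models=models)
        assert s_w["w4"] == 1.0
        assert s_w["w0"] == 0.0

    def test_identical_aurocs_share_score(self):
        aurocs = {}
        for m in ("m1", "m2"):
            aurocs[("a", m)] = 0.7
            aurocs[("b", m)] = 0.7
            aurocs[("c", m)] = 0.6
        s_w, _ = ranking_scores(self._grid(aurocs))
        assert s_w["a"] == s_w["b"]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        aurocs = {
            (f"w{i}", f"m{j}"): float(rng.uniform(0.5, 0.9)) for i in range(6) for j in range(3)
        }
        s_w1, s_m1 = ranking_scores(self._grid(aurocs))
        squashed = {k: float(1 / (1 + np.exp(-5 * v))) for k, v in aurocs.items()}
        s_w2, s_m2 = ranking_scores(self._grid(squashed))
        pd.testing.assert_series_equal(s_w1, s_w2)
        pd.testing.assert_series_equal(s_m1, s_m2)

    def test_incomplete_grid_rejected_with_missing_cells(self):
        grid = self._grid({("a", "m1"): 0.6, ("a", "m2"): 0.7, ("b", "m1"): 0.8})
        with pytest.raises(ValueError, match="missing"):
            ranking_scores(grid)

    def test_model_scores_average_within_scheme_ranks(self):
        aurocs = {
            ("a", "m1"): 0.9,
            ("a", "m2"): 0.6,
            ("b", "m1"): 0.8,
            ("b", "m2"): 0.7,
        }
        _, s_m = ranking_scores(self._grid(aurocs))
        assert s_m["m1"] == 1.0 and s_m["m2"] == 0.0


class TestCoxPH:
    @staticmethod
    def survival_rows(rng, n=250, beta_lam=0.0):
        lam = rng.uniform(0, 1, size=n)
        trend = rng.uniform(-1, 1, size=n)
        changes = rng.integers(0, 40, size=n).astype(float)
        hazard = 0.001 * np.exp(beta_lam * lam)
        t_event = rng.exponential(1 / hazard)
        censor = rng.exponential(1500, size=n)
        time = np.minimum(t_event, censor)
        return pd.DataFrame(
            {
                "lambda_mean": lam,
                "lambda_trend": trend,
                "n_changes": changes,
                "outcome": (t_event <= censor).astype(int),
                "time_to_event": np.maximum(time, 1.0),
            }
        )

    def test_null_omnibus_type_i_error_near_nominal(self):
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng(50_000 + seed)
            rows = self.survival_rows(rng, n=120, beta_lam=0.0)
            rejections += fit_cox_ph(rows)["omnibus_p"] < 0.05
        assert rejections / n_reps == pytest.approx(0.05, abs=0.04)

    def test_lambda_shortening_time_gives_hazard_ratio_above_one(self):
        for seed in range(5):
            rng = np.random.default_rng(60_000 + seed)
            rows = self.survival_rows(rng, n=300, beta_lam=1.5)
            fit = fit_cox_ph(rows)
            assert fit["hazard_ratios"]["lambda_mean"] > 1.0

    def test_constant_predictor_flagged(self):
        rng = np.random.default_rng(77)
        rows = self.survival_rows(rng, n=100, beta_lam=1.0)
        rows["n_changes"] = 5.0
        fit = fit_cox_ph(rows)
        assert fit["dropped_constant"] == ["n_changes"]

    def test_all_censored_rejected(self):
        rng = np.random.default_rng(78)
        rows = self.survival_rows(rng, n=50)
        rows["outcome"] = 0
        with pytest.raises(ValueError, match="censored"):
            fit_cox_ph(rows)


class TestGroupTests:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(21)
        base = pd.DataFrame(
            {
                "lambda_mean": rng.uniform(0, 1, size=60),
                "lambda_trend": rng.uniform(-1, 1, size=60),
                "n_changes": rng.integers(0, 30, size=60),
            }
        )
        rows = pd.concat(
            [base.assign(outcome=0), base.assign(outcome=1)], ignore_index=True
        )
        table = descriptor_group_tests(rows)
        assert (table["p_value"] > 0.9).all()

    def test_table_layout_mean_sd_per_group(self):
        rng = np.random.default_rng(22)
        rows = pd.DataFrame(
            {
                "lambda_mean": rng.uniform(0, 1, size=40),
                "lambda_trend": rng.uniform(-1, 1, size=40),
                "n_changes": rng.integers(0, 30, size=40),
                "outcome": rng.integers(0, 2, size=40),
            }
        )
        table = descriptor_group_tests(rows)
        assert list(table["descriptor"]) == ["Lambda", "Delta", "C"]
        for col in ("mean_sepsis", "sd_sepsis", "mean_control", "sd_control", "p_value"):
            assert np.isfinite(table[col]).all()

    def test_rank_sum_p_matches_exact_enumeration_small_n(self):
        """Exact permutation oracle for the two-sided rank-sum test, n <= 8 per group."""
        rng = np.random.default_rng(23)
        x = rng.uniform(size=6)
        y = rng.uniform(size=7)
        rows = pd.DataFrame(
            {
                "lambda_mean": np.r_[x, y],
                "lambda_trend": 0.5,
                "n_changes": 1,
                "outcome": np.r_[np.ones(6, int), np.zeros(7, int)],
            }
        )
        p_pkg = descriptor_group_tests(rows).set_index("descriptor").loc["Lambda", "p_value"]
        pooled = np.r_[x, y]
        ranks = stats.rankdata(pooled)
        observed = ranks[:6].sum()
        count = 0
        total = 0
        mu = len(x) * (len(pooled) + 1) / 2
        for combo in itertools.combinations(range(13), 6):
            stat = ranks[list(combo)].sum()
            if abs(stat - mu) >= abs(observed - mu) - 1e-12:
                count += 1
            total += 1
        assert p_pkg == pytest.approx(count / total, abs=0.02)

    def test_combination_chi2_on_person_minute_counts(self):
        freq = pd.DataFrame(
            {
                "group": ["g1", "g1", "g2", "g2"],
                "combination": ["none", "TC", "none", "TC"],
                "minutes": [900, 100, 500, 500],
                "percent": [90.0, 10.0, 50.0, 50.0],
            }
        )
        out = combination_chi2_tests(freq).set_index("combination")
        table = np.array([[100, 900], [500, 500]])
        expected = stats.chi2_contingency(table, correction=False).pvalue
        assert out.loc["TC", "p_value"] == pytest.approx(expected)
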