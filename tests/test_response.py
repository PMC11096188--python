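"""Response-model machinery: screening, fitting, selection, ROC, DeLong, LOOCV, Youden."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from liquidmrd import response
from liquidmrd.response import ModelInput

from conftest import brute_force_auc, exhaustive_permutation_p


def synthetic_frame(n=200, beta0=-1.0, beta1=2.0, seed=0) -> pd.DataFrame:
    """Cohort with one informative standardized predictor and one pure noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    noise = rng.normal(0, 1, n)
    p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
    y = rng.binomial(1, p)
    return pd.DataFrame({"signal": x, "noise": noise, "outcome": y})


class TestCramersV:
    def test_perfect_association(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert response.cramers_v(x, x) == pytest.approx(1.0)

    def test_independence(self):
        x = [0] * 10 + [1] * 10
        y = ([0] * 5 + [1] * 5) * 2
        assert response.cramers_v(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_chi2(self):
        # 2x2 table [[8,2],[2,8]]: chi2 = 7.2, n = 20 -> V = sqrt(0.36) = 0.6
        x = [0] * 10 + [1] * 10
        y = [0] * 8 + [1] * 2 + [0] * 2 + [1] * 8
        assert response.cramers_v(x, y) == pytest.approx(0.6)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="single level"):
            response.cramers_v([1, 1, 1, 1], [0, 1, 0, 1])


class TestLogisticFit:
    def test_recovers_known_coefficients(self):
        df = synthetic_frame(n=200, seed=1)
        fit = response.fit_logistic(df, ["signal"])
        # independent oracle: direct likelihood maximization
        y = df["outcome"].to_numpy(float)
        x = df["signal"].to_numpy(float)

        def nll(b):
            eta = b[0] + b[1] * x
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        oracle = minimize(nll, [0.0, 0.0], method="Nelder-Mead").x
        assert fit.coefficients["intercept"] == pytest.approx(oracle[0], abs=1e-3)
        assert fit.coefficients["signal"] == pytest.approx(oracle[1], abs=1e-3)
        assert abs(fit.coefficients["signal"] - 2.0) < 0.3
        assert abs(fit.coefficients["intercept"] - (-1.0)) < 0.3

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame(
            {"x": np.arange(10, dtype=float), "outcome": [0] * 5 + [1] * 5}
        )
        fit = response.fit_logistic(df, ["x"])
        assert fit.separation_flag
        assert response.roc_auc(fit.fitted_probs, df["outcome"]) == 1.0

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 6, "outcome": [0, 1, 0, 1, 0, 1]})
        with pytest.raises(ValueError, match="constant"):
            response.fit_logistic(df, ["x"])

    def test_single_class_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "outcome": [1, 1]})
        with pytest.raises(ValueError, match="classes"):
            response.fit_logistic(df, ["x"])


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert response.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert response.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_worked_example(self):
        assert response.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_equals_brute_force_concordance(self):
        """Exact agreement with the all-pairs oracle on every random input n <= 12."""
        rng = np.random.default_rng(2)
        for n in range(4, 13):
            for _ in range(20):
                y = np.zeros(n, int)
                y[rng.choice(n, rng.integers(1, n), replace=False)] = 1
                if y.sum() in (0, n):
                    continue
                s = np.round(rng.uniform(0, 1, n), 1)  # coarse grid forces ties
                assert response.roc_auc(s, y) == pytest.approx(
                    brute_force_auc(s, y), abs=1e-12
                )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.01, 0.99, 30)
        y = rng.binomial(1, s)
        base = response.roc_auc(s, y)
        for f in (np.log, np.sqrt, lambda v: v**3, lambda v: 1 / (1 + np.exp(-5 * v))):
            assert response.roc_auc(f(s), y) == pytest.approx(base, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            response.roc_auc([0.1, 0.9], [1, 1])


class TestDelong:
    def test_all_tied_scores_give_p_one(self):
        res = response.delong_test([0.5] * 8, [0, 0, 1, 1, 0, 1, 0, 1])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_strong_separation_large_n(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0, 1], 100)
        s = rng.normal(0, 1, 200) + 2.0 * y
        assert response.delong_pvalue(s, y) < 0.001

    def test_small_sample_worked_example(self):
        """The 4-point AUC=0.75 case against the exhaustive mid-p permutation oracle."""
        s, y = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        dl = response.delong_pvalue(s, y)
        perm = exhaustive_permutation_p(s, y, midp=True)
        assert abs(dl - perm) <= 0.05

    def test_typical_agreement_with_permutation_at_n12(self):
        """Median |DeLong - exhaustive permutation| <= 0.05 over seeded n=12 cases;
        the asymptotic test is slightly anti-conservative case by case."""
        rng = np.random.default_rng(42)
        gaps = []
        for _ in range(40):
            y = np.zeros(12, int)
            y[rng.choice(12, 6, replace=False)] = 1
            s = rng.normal(0, 1, 12) + rng.uniform(0, 1.5) * y
            gaps.append(
                abs(response.delong_pvalue(s, y) - exhaustive_permutation_p(s, y))
            )
        assert float(np.median(gaps)) <= 0.05

    def test_degenerate_perfect_auc(self):
        res = response.delong_test([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.degenerate and res.p_value == 0.0


class TestYouden:
    def test_perfectly_separated(self):
        r = response.youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.youden_index == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_all_equal_scores(self):
        r = response.youden_cutoff([0.4] * 6, [0, 1, 0, 1, 0, 1])
        assert r.youden_index == pytest.approx(0.0)

    def test_tie_broken_toward_sensitivity(self):
        # J = 0.5 both at threshold 0.35 (sens 1.0) and 0.8 (sens 0.5)
        r = response.youden_cutoff([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.youden_index == pytest.approx(0.5)
        assert r.sensitivity == 1.0 and r.specificity == 0.5
        assert r.threshold == pytest.approx(0.35)

    def test_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 15)
        y = rng.binomial(1, 0.5, 15)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        r = response.youden_cutoff(s, y)
        best_j = max(
            ((s >= t) & (y == 1)).sum() / (y == 1).sum()
            + ((s < t) & (y == 0)).sum() / (y == 0).sum()
            - 1.0
            for t in np.unique(s)
        )
        assert r.youden_index == pytest.approx(best_j)


class TestLoocv:
    def test_null_predictors_near_chance(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"noise": rng.normal(0, 1, 40), "outcome": rng.binomial(1, 0.5, 40)}
        )
        auc = response.loocv_auc(df, ["noise"])
        assert 0.35 <= auc <= 0.65

    def test_informative_predictor_high_auc(self):
        df = synthetic_frame(n=40, beta1=3.0, seed=8)
        assert response.loocv_auc(df, ["signal"]) > 0.85

    def test_minimal_n_contract(self):
        df = pd.DataFrame(
            {"x": [0.1, 0.9, 0.2, 0.8, 0.3, 0.7], "outcome": [0, 1, 0, 1, 0, 1]}
        )
        assert 0.0 <= response.loocv_auc(df, ["x"]) <= 1.0

    def test_too_small_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0], "outcome": [0, 1]})
        with pytest.raises(ValueError):
            response.loocv_auc(df, ["x"])


class TestSelection:
    @pytest.mark.parametrize("mode", response.SELECTION_MODES)
    def test_informative_beats_noise(self, mode):
        df = synthetic_frame(n=200, seed=9)
        model = response.select_model(
            df, mode=mode, predictors=["signal", "noise"], with_loocv=False
        )
        assert "signal" in model.selected_predictors

    def test_aic_modes_match_exhaustive_enumeration(self):
        df = synthetic_frame(n=200, seed=10)
        oracle = response.exhaustive_best_subset(df, ["signal", "noise"])
        for mode in ("forward", "reverse", "stepwise"):
            model = response.select_model(
                df, mode=mode, predictors=["signal", "noise"], with_loocv=False
            )
            assert sorted(model.selected_predictors) == sorted(oracle)

    def test_all_noise_gives_intercept_only(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "n1": rng.normal(0, 1, 60),
                "n2": rng.normal(0, 1, 60),
                "outcome": rng.binomial(1, 0.5, 60),
            }
        )
        model = response.select_model(
            df, mode="forward", predictors=["n1", "n2"], with_loocv=False
        )
        assert model.intercept_only_flag
        assert model.auc == 0.5

    def test_complementary_mge_predictors_both_retained(self):
        """Pre- and post-treatment burden each add information when the
        outcome depends on their difference."""
        rng = np.random.default_rng(12)
        n = 200
        pre = rng.normal(3, 1, n)
        post = rng.normal(2, 1, n)
        p = 1 / (1 + np.exp(-(pre - post - 1)))
        df = pd.DataFrame(
            {"mge_pre": pre, "mge_post": post, "outcome": rng.binomial(1, p)}
        )
        oracle = response.exhaustive_best_subset(df, ["mge_pre", "mge_post"])
        assert sorted(oracle) == ["mge_post", "mge_pre"]
        model = response.select_model(
            df, mode="stepwise", predictors=["mge_pre", "mge_post"], with_loocv=False
        )
        assert sorted(model.selected_predictors) == sorted(oracle)

    def test_manual_mode_screens_and_selects(self):
        df = synthetic_frame(n=200, seed=13)
        model = response.select_model(
            df, mode="manual", predictors=["signal", "noise"], with_loocv=False
        )
        assert "signal" in model.selected_predictors
        assert "noise" not in model.selected_predictors

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            response.select_model(synthetic_frame(20), mode="backward_only")


class TestFoldChangeAndInputs:
    @pytest.mark.parametrize(
        "resp, nonresp, expected",
        [(3072.48, 448.24, 6.85), (5.0, 5.0, 1.0), (100.0, 400.0, 0.25)],
    )
    def test_ratio(self, resp, nonresp, expected):
        assert response.mge_fold_change(resp, nonresp) == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            response.mge_fold_change(10.0, 0.0)

    def test_inputs_to_frame_transform_and_exclusion(self):
        inputs = [
            ModelInput("A", 1000.0, 10.0, True),
            ModelInput("B", 100.0, 90.0, False),
            ModelInput("C", 50.0, 60.0, False),  # negative change
            ModelInput("X", 91017.0, 2751.0, False),
        ]
        df = response.inputs_to_frame(inputs, exclude_ids=["X"])
        assert "X" not in df.index
        assert df.loc["A", "mge_pre"] == pytest.approx(np.log10(1001.0))
        assert df.loc["C", "mge_change"] == pytest.approx(-np.log10(11.0))
        assert ModelInput("A", 1000.0, 10.0, True).mge_change == 990.0
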