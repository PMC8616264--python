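"""Stratified splits, LASSO limits, consensus rule, AUC statistic."""

import numpy as np
import pandas as pd
import pytest

from mbdpipe.classify import (
    consensus_select,
    evaluate_auc,
    fit_lasso_logistic,
    one_vs_rest,
    run_protocol,
    stratified_split,
)


def _labels(n_case, n_ctrl):
    idx = [f"c{i}" for i in range(n_case)] + [f"n{i}" for i in range(n_ctrl)]
    return pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=idx)


class TestSplit:
    def test_80_20_counts(self):
        plan = stratified_split(_labels(10, 10), seed=1)
        assert len(plan.train_ids) == 16 and len(plan.test_ids) == 4
        train = pd.Index(plan.train_ids)
        assert sum(train.str.startswith("c")) == 8
        assert sum(train.str.startswith("n")) == 8

    def test_deterministic_under_seed(self):
        a = stratified_split(_labels(12, 16), seed=7)
        b = stratified_split(_labels(12, 16), seed=7)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_distinct_seeds_distinct_plans(self):
        plans = {stratified_split(_labels(30, 30), seed=s).train_ids
                 for s in range(100)}
        assert len(plans) == 100

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            stratified_split(_labels(1, 10), seed=0)


def _toy_xy(seed=0, n=120, p=20, effect=2.0, informative=3):
    rng = np.random.default_rng(seed)
    y = pd.Series([1] * (n // 2) + [0] * (n // 2),
                  index=[f"s{i}" for i in range(n)])
    X = pd.DataFrame(rng.normal(size=(n, p)), index=y.index,
                     columns=[f"f{j}" for j in range(p)])
    for j in range(informative):
        X.iloc[:, j] += effect * y.values
    return X, y


class TestLasso:
    def test_huge_lambda_all_zero(self):
        X, y = _toy_xy()
        fit = fit_lasso_logistic(X, y, lambda_grid=np.array([1e6]), seed=0)
        assert (fit.coefficients == 0).all()

    def test_tiny_lambda_separable_training_fit(self):
        X, y = _toy_xy(effect=6.0, n=60)
        fit = fit_lasso_logistic(X, y, lambda_grid=np.array([1e-6]), folds=3, seed=0)
        p = fit.predict_proba(X)
        dev = -2 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert dev < 0.05

    def test_chosen_lambda_minimizes_cv_deviance(self):
        X, y = _toy_xy()
        fit = fit_lasso_logistic(X, y, seed=1)
        assert fit.chosen_lambda == fit.lambda_grid[np.argmin(fit.cv_deviance)]

    def test_informative_features_selected(self):
        X, y = _toy_xy(seed=3)
        fit = fit_lasso_logistic(X, y, seed=3)
        assert {"f0", "f1", "f2"} <= set(fit.nonzero_features())

    def test_coefficients_on_original_scale(self):
        X, y = _toy_xy(seed=4)
        X2 = X.copy()
        X2["f0"] = X2["f0"] * 10  # rescaling a column rescales its coefficient
        grid = np.array([0.05, 0.02, 0.01])
        fit1 = fit_lasso_logistic(X, y, lambda_grid=grid, seed=4)
        fit2 = fit_lasso_logistic(X2, y, lambda_grid=grid, seed=4)
        # internal standardization makes the fit scale-equivariant, up to
        # solver tolerance
        assert fit2.coefficients["f0"] == pytest.approx(
            fit1.coefficients["f0"] / 10, rel=0.02
        )


class TestConsensus:
    def _fit_like(self, nonzero):
        from mbdpipe.classify import LassoFit

        coef = pd.Series(0.0, index=[f"f{j}" for j in range(5)])
        coef[list(nonzero)] = 1.0
        return LassoFit(np.array([1.0]), 1.0, coef, 0.0, np.array([0.0]),
                        coef * 0, coef * 0 + 1)

    def test_all_repeats_rule_is_strict(self):
        fits = [self._fit_like({"f0", "f1"}) for _ in range(99)]
        fits.append(self._fit_like({"f0"}))
        rep = consensus_select(fits)
        assert rep.consensus_set == ["f0"]
        assert rep.nonzero_counts["f1"] == 99

    def test_empty_fits_error(self):
        with pytest.raises(ValueError):
            consensus_select([])


class TestAuc:
    def test_perfect_ranking(self):
        assert evaluate_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties(self):
        assert evaluate_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pairwise_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.uniform(size=n), 1)  # coarse scores force ties
        wins = 0.0
        pos, neg = s[y == 1], s[y == 0]
        for a in pos:
            for b in neg:
                wins += 1.0 if a > b else (0.5 if a == b else 0.0)
        assert evaluate_auc(s, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(9)
        s = rng.uniform(size=2000)
        y = rng.integers(0, 2, size=2000)
        assert abs(evaluate_auc(s, y) - 0.5) < 0.05


class TestProtocol:
    def test_reproducible_under_master_seed(self):
        X, y = _toy_xy(seed=5)
        a = run_protocol(X, y, n_repeats=5, seed=11)
        b = run_protocol(X, y, n_repeats=5, seed=11)
        assert a.consensus_set == b.consensus_set
        assert a.auc_per_repeat == b.auc_per_repeat

    def test_strong_signal_recovered(self):
        X, y = _toy_xy(seed=6, effect=3.0)
        rep = run_protocol(X, y, n_repeats=10, seed=2)
        assert set(rep.consensus_set) >= {"f0", "f1", "f2"}
        assert rep.auc_median > 0.9

    def test_k_top_restriction(self):
        X, y = _toy_xy(seed=7)
        ranking = [f"f{j}" for j in range(20)]
        rep = run_protocol(X, y, feature_ranking=ranking, k_top=5,
                           n_repeats=3, seed=0)
        assert set(rep.nonzero_counts.index) == set(ranking[:5])
        with pytest.raises(ValueError):
            run_protocol(X, y, feature_ranking=ranking, k_top=50, n_repeats=2, seed=0)

    def test_one_vs_rest_reduces_to_symmetric_binary(self):
        rng = np.random.default_rng(8)
        n = 90
        y = pd.Series(["a"] * 45 + ["b"] * 45, index=[f"s{i}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, 10)), index=y.index,
                         columns=[f"f{j}" for j in range(10)])
        X.iloc[:45, 0] += 3.0
        reports = one_vs_rest(X, y, n_repeats=5, seed=1)
        assert set(reports) == {"a", "b"}
        assert "f0" in reports["a"].consensus_set
        assert "f0" in reports["b"].consensus_set
        assert reports["a"].auc_median > 0.9 and reports["b"].auc_median > 0.9

    def test_class_exclusive_signals_in_multiclass(self):
        rng = np.random.default_rng(10)
        n = 120
        y = pd.Series(["a"] * 40 + ["b"] * 40 + ["c"] * 40,
                      index=[f"s{i}" for i in range(n)])
        X = pd.DataFrame(rng.normal(size=(n, 12)), index=y.index,
                         columns=[f"f{j}" for j in range(12)])
        X.iloc[:40, 0] += 3.0      # f0 marks class a
        X.iloc[40:80, 1] += 3.0    # f1 marks class b
        X.iloc[80:, 2] += 3.0      # f2 marks class c
        reports = one_vs_rest(X, y, n_repeats=5, seed=2)
        assert "f0" in reports["a"].consensus_set
        assert "f1" in reports["b"].consensus_set
        assert "f2" in reports["c"].consensus_set
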