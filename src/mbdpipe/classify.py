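"""Repeated class-balanced LASSO selection and ROC evaluation.

The protocol: split the cohort into class-balanced 80/20 train/test
sets, fit an L1-penalized (alpha = 1) logistic regression on the
training set with the penalty lambda chosen by 10-fold cross-validated
deviance (lambda.min convention), score the held-out test set, and
repeat (100 times by default) with fresh splits.  Features with a
non-zero coefficient in *every* repeat form the consensus classifier
set; performance is summarized by the distribution of held-out AUCs.
Multi-class cohorts run the same protocol one-vs-all-others per class.

Features are standardized inside each fit on training data only (no
test leakage); coefficients are reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .counting import FeatureCountMatrix
from .diffmeth import size_factors

__all__ = [
    "SplitPlan",
    "LassoFit",
    "ConsensusReport",
    "stratified_split",
    "fit_lasso_logistic",
    "consensus_select",
    "evaluate_auc",
    "run_protocol",
    "one_vs_rest",
    "normalized_log2_counts",
]

TRAIN_FRAC = 0.8
N_REPEATS = 100
N_FOLDS = 10
LAMBDA_N = 12
LAMBDA_MIN_RATIO = 1e-2


@dataclass(frozen=True)
class SplitPlan:
    """One class-balanced train/test partition of a cohort."""

    repeat_index: int
    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class LassoFit:
    """A CV-tuned L1 logistic fit with coefficients on the original scale."""

    lambda_grid: np.ndarray
    chosen_lambda: float
    coefficients: pd.Series
    intercept: float
    cv_deviance: np.ndarray
    center: pd.Series
    scale: pd.Series

    def nonzero_features(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        z = self.intercept + X[self.coefficients.index].to_numpy() @ \
            self.coefficients.to_numpy()
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ConsensusReport:
    """Aggregate of the repeated split/fit/evaluate protocol."""

    label: str
    n_repeats: int
    nonzero_counts: pd.Series
    consensus_set: list
    auc_per_repeat: list
    repeat_seeds: list

    @property
    def auc_median(self) -> float:
        return float(np.median(self.auc_per_repeat))

    @property
    def auc_iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.auc_per_repeat, [25, 75])
        return float(lo), float(hi)


def stratified_split(
    labels: pd.Series,
    train_frac: float = TRAIN_FRAC,
    seed: int = 0,
    repeat_index: int = 0,
) -> SplitPlan:
    """Class-balanced train/test partition, deterministic under seed.

    Per class, ``round(train_frac * n_class)`` samples (half-up) go to
    training, the rest to test.
    """
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(labels.unique()):
        ids = np.array(labels.index[labels == cls])
        if ids.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(ids)
        n_train = int(np.floor(train_frac * ids.size + 0.5))
        n_train = min(max(n_train, 1), ids.size - 1)
        train += perm[:n_train].tolist()
        test += perm[n_train:].tolist()
    return SplitPlan(repeat_index, tuple(train), tuple(test), seed)


def default_lambda_grid(X: np.ndarray, y: np.ndarray,
                        n: int = LAMBDA_N,
                        min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    """Log-spaced grid from the smallest all-zero lambda downward."""
    ybar = y.mean()
    lam_max = np.abs(X.T @ (y - ybar)).max() / len(y)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n)


def fit_lasso_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = N_FOLDS,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> LassoFit:
    """L1-penalized logistic regression tuned by K-fold CV deviance.

    ``lambda`` parametrizes the per-sample penalty
    (1/n) sum loglik + lambda * ||beta||_1, so the solver's inverse
    regularization is C = 1/(n * lambda).  The chosen lambda minimizes
    mean out-of-fold binomial deviance; the reported model is a refit on
    the full training data at that lambda.
    """
    yv = np.asarray(y, dtype=float)
    classes = np.unique(yv)
    if classes.size != 2:
        raise ValueError("binary labels required")
    yb = (yv == classes.max()).astype(float)

    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - center) / scale).to_numpy()

    if lambda_grid is None:
        lambda_grid = default_lambda_grid(Z, yb)
    lambda_grid = np.asarray(lambda_grid, dtype=float)

    folds_eff = int(min(folds, np.bincount(yb.astype(int)).min()))
    if folds_eff < 2:
        raise ValueError("cannot build stratified CV folds: a class is too small")
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)

    dev = np.zeros((folds_eff, lambda_grid.size))
    with sklearn.config_context(assume_finite=True):
        for f, (tr, va) in enumerate(skf.split(Z, yb)):
            for l, lam in enumerate(lambda_grid):
                model = _l1_fit(Z[tr], yb[tr], lam)
                p = _proba(model, Z[va])
                dev[f, l] = -2.0 * np.mean(
                    yb[va] * np.log(p) + (1.0 - yb[va]) * np.log1p(-p)
                )
        cv_dev = dev.mean(axis=0)
        best = int(np.argmin(cv_dev))
        chosen = float(lambda_grid[best])

        final = _l1_fit(Z, yb, chosen)
    coef_std = final.coef_.ravel()
    coef = pd.Series(coef_std / scale.to_numpy(), index=X.columns)
    intercept = float(final.intercept_[0] - np.sum(coef_std * center.to_numpy()
                                                   / scale.to_numpy()))
    return LassoFit(lambda_grid, chosen, coef, intercept, cv_dev, center, scale)


def _l1_fit(Z, y, lam):
    C = 1.0 / (len(y) * lam)
    return LogisticRegression(
        l1_ratio=1, C=C, solver="liblinear", max_iter=1000, tol=1e-4,
        random_state=0
    ).fit(Z, y)


def _proba(model, Z):
    p = model.predict_proba(Z)[:, 1]
    return np.clip(p, 1e-12, 1.0 - 1e-12)


def consensus_select(fits: list[LassoFit], aucs: list[float] | None = None,
                     seeds: list[int] | None = None,
                     label: str = "case") -> ConsensusReport:
    """Features with non-zero coefficients in every repeat."""
    if not fits:
        raise ValueError("need at least one fit")
    counts = sum((f.coefficients != 0.0).astype(int) for f in fits)
    consensus = sorted(counts.index[counts == len(fits)])
    return ConsensusReport(
        label=label,
        n_repeats=len(fits),
        nonzero_counts=counts,
        consensus_set=list(consensus),
        auc_per_repeat=list(aucs or []),
        repeat_seeds=list(seeds or []),
    )


def evaluate_auc(scores, labels) -> float:
    """Rank-based AUC: Mann-Whitney U / (n_pos * n_neg), ties count 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("test set must contain both classes")
    pos = y == classes.max()
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = pd.Series(s).rank(method="average").to_numpy()
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def run_protocol(
    X: pd.DataFrame,
    y: pd.Series,
    feature_ranking: list[str] | None = None,
    k_top: int | None = None,
    n_repeats: int = N_REPEATS,
    folds: int = N_FOLDS,
    train_frac: float = TRAIN_FRAC,
    seed: int = 0,
    label: str = "case",
) -> ConsensusReport:
    """Full repeated split/fit/score protocol on a binary cohort.

    ``feature_ranking``/``k_top`` restrict the predictor matrix to the
    top-ranked features before any modeling.  Repeat seeds derive from
    the master seed by a counter, so the whole report is reproducible.
    """
    if feature_ranking is not None:
        if k_top is not None:
            if k_top > len(feature_ranking):
                raise ValueError("k_top exceeds ranked features available")
            feature_ranking = feature_ranking[:k_top]
        X = X[feature_ranking]
    elif k_top is not None:
        X = X.iloc[:, :k_top]

    fits, aucs, seeds = [], [], []
    for r in range(n_repeats):
        seed_r = int((seed * 1_000_003 + r) % (2**31 - 1))
        plan = stratified_split(y, train_frac=train_frac, seed=seed_r,
                                repeat_index=r)
        Xtr, ytr = X.loc[list(plan.train_ids)], y.loc[list(plan.train_ids)]
        Xte, yte = X.loc[list(plan.test_ids)], y.loc[list(plan.test_ids)]
        fit = fit_lasso_logistic(Xtr, ytr, folds=folds, seed=seed_r)
        fits.append(fit)
        aucs.append(evaluate_auc(fit.predict_proba(Xte), yte))
        seeds.append(seed_r)
    return consensus_select(fits, aucs, seeds, label=label)


def one_vs_rest(
    X: pd.DataFrame,
    y: pd.Series,
    feature_ranking: dict[str, list[str]] | None = None,
    k_top: int | None = None,
    n_repeats: int = N_REPEATS,
    folds: int = N_FOLDS,
    seed: int = 0,
) -> dict[str, ConsensusReport]:
    """One-vs-all-others protocol per class of a multiclass cohort."""
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    reports = {}
    for i, cls in enumerate(classes):
        yb = (y == cls).astype(int)
        ranking = feature_ranking.get(cls) if feature_ranking else None
        reports[cls] = run_protocol(
            X, yb, feature_ranking=ranking, k_top=k_top,
            n_repeats=n_repeats, folds=folds, seed=seed + i, label=str(cls),
        )
    return reports


def normalized_log2_counts(m: FeatureCountMatrix) -> pd.DataFrame:
    """Samples x features predictor matrix: log2(count/size_factor + 1)."""
    s = size_factors(m)
    return np.log2(m.counts.div(s, axis=1) + 1.0).T
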