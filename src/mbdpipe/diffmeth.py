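"""Negative-binomial Wald differential methylation on feature counts.

The model for feature *i* in sample *j* is

    K_ij ~ NB(mu_ij, alpha_i),   mu_ij = s_j * 2**(beta_i0 + beta_i1 * x_j)

with per-sample size factors ``s_j`` (median-of-ratios, rescaled to
geometric mean 1), per-feature dispersion ``alpha_i``
(Var = mu + alpha * mu**2), and ``x_j`` = 1 for case samples.  The group
coefficient beta_i1 is the case-vs-control log2 fold change; it is
tested with a Wald z = beta_i1 / se(beta_i1), the se taken from the
Fisher information of the converged IRLS fit, with two-sided normal
p-values and Benjamini-Hochberg adjustment.  Differentially methylated
CpG islands (DMCGIs) are called at q < 0.1 and fold change > 2, both
strict inequalities.

With a two-level group factor the IRLS normal equations decouple into
one weighted intercept fit per group, so the solver runs vectorized
over all features at once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .counting import FeatureCountMatrix
from .intervals import region_sort_key

__all__ = [
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "call_dmcgi",
    "top_features",
    "run_diffmeth",
]

ALPHA_FLOOR = 1e-8
Q_MAX = 0.1
FC_MIN = 2.0
MAX_IRLS_ITER = 100
DEVIANCE_TOL = 1e-8
_ETA_MIN = -50.0  # log-scale floor keeping all-zero groups numerically sane


def size_factors(m: FeatureCountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    For each feature with nonzero counts in every sample, the ratio of
    each sample's count to the feature's geometric mean is formed; a
    sample's factor is the median of its ratios.  Factors are rescaled
    so their geometric mean is exactly 1, making the normalized scale
    depth-neutral.
    """
    df = m.counts if isinstance(m, FeatureCountMatrix) else m
    counts = df.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "consider a pseudo-reference fallback"
        )
    log_counts = np.log(counts[all_pos])
    log_geo = log_counts.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_counts - log_geo, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=df.columns, name="size_factor")


def _resolve_groups(groups: pd.Series, control, case):
    labels = list(pd.unique(groups))
    if control is None or case is None:
        if len(labels) != 2:
            raise ValueError(
                f"groups are {labels}; specify control= and case= explicitly"
            )
        lowered = [str(x).lower() for x in labels]
        if control is None:
            control = labels[lowered.index("control")] if "control" in lowered else labels[0]
        if case is None:
            case = next(x for x in labels if x != control)
    return control, case


def _group_masks(groups: pd.Series, control: str, case: str):
    ctrl = (groups == control).to_numpy()
    cse = (groups == case).to_numpy()
    if ctrl.sum() < 2 or cse.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return ctrl, cse


def estimate_dispersions(
    m: FeatureCountMatrix,
    s: pd.Series,
    control: str | None = None,
    case: str | None = None,
    trend_weight: float = 0.5,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.Series:
    """Per-feature NB dispersion by within-group moments with trend shrinkage.

    For each group the method-of-moments estimate
    ``alpha_g = (var - mean * c) / mean**2`` is formed on size-factor
    normalized counts (``c`` is the group mean of 1/s_j, the Poisson
    variance inflation that normalization introduces), pooled across the
    two groups with df weights and floored at ``alpha_floor``; the
    pooled estimates are then shrunk toward a fitted mean-dispersion
    trend ``alpha(mu) = a1/mu + a0`` by weighted averaging in log space
    (``trend_weight`` toward the trend).
    """
    control, case = _resolve_groups(m.groups, control, case)
    ctrl, cse = _group_masks(m.groups, control, case)
    sv = s.reindex(m.counts.columns).to_numpy()
    y = m.counts.to_numpy(dtype=float) / sv

    num = np.zeros(y.shape[0])
    den = 0.0
    mu_all = np.zeros(y.shape[0])
    n_total = ctrl.sum() + cse.sum()
    for mask in (ctrl, cse):
        yg = y[:, mask]
        n_g = int(mask.sum())
        mean_g = yg.mean(axis=1)
        var_g = yg.var(axis=1, ddof=1)
        c_g = float(np.mean(1.0 / sv[mask]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = (var_g - mean_g * c_g) / mean_g**2
        a_g = np.where(mean_g > 0, np.nan_to_num(a_g), 0.0)
        num += (n_g - 1) * a_g
        den += n_g - 1
        mu_all += mean_g * (n_g / n_total)
    alpha_raw = np.maximum(num / den, alpha_floor)
    alpha = _shrink_to_trend(alpha_raw, mu_all, trend_weight, alpha_floor)
    return pd.Series(alpha, index=m.counts.index, name="dispersion")


def _shrink_to_trend(alpha_raw, mu, w, alpha_floor):
    ok = (mu > 0) & (alpha_raw > alpha_floor)
    if ok.sum() >= 10:
        X = np.column_stack([np.ones(int(ok.sum())), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_raw[ok], rcond=None)
        a0, a1 = max(float(coef[0]), 0.0), max(float(coef[1]), 0.0)
        trend = a0 + np.divide(a1, mu, out=np.full_like(mu, np.inf), where=mu > 0)
    else:
        trend = np.full_like(mu, float(np.median(alpha_raw)))
    trend = np.where(np.isfinite(trend) & (trend > 0), trend, alpha_raw)
    trend = np.maximum(trend, alpha_floor)
    return np.maximum(
        np.exp(w * np.log(trend) + (1.0 - w) * np.log(alpha_raw)), alpha_floor
    )


def _fit_group(Kg: np.ndarray, sg: np.ndarray, alpha: np.ndarray):
    """IRLS fit of a per-feature intercept NB GLM on one sample group.

    Returns (eta, sum_weights, converged): eta is the natural-log group
    mean on the size-factor-normalized scale; sum_weights is the Fisher
    information contribution of the group.
    """
    mean0 = (Kg / sg).mean(axis=1)
    eta = np.log(mean0 + 0.5)
    dev = _nb_deviance(Kg, sg, eta, alpha)
    converged = np.zeros(Kg.shape[0], dtype=bool)
    for _ in range(MAX_IRLS_ITER):
        mu = sg * np.exp(eta)[:, None]
        w = mu / (1.0 + alpha[:, None] * mu)
        sw = w.sum(axis=1)
        active = ~converged & (sw > 0)
        if not active.any():
            break
        z = eta[:, None] + (Kg - mu) / mu
        eta_new = np.where(active, (w * z).sum(axis=1) / np.where(sw > 0, sw, 1.0), eta)
        eta_new = np.maximum(eta_new, _ETA_MIN)
        dev_new = _nb_deviance(Kg, sg, eta_new, alpha)
        converged |= active & (np.abs(dev - dev_new) < DEVIANCE_TOL)
        eta, dev = eta_new, dev_new
    mu = sg * np.exp(eta)[:, None]
    sw = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return eta, sw, converged


def _nb_deviance(Kg, sg, eta, alpha):
    mu = sg * np.exp(eta)[:, None]
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(Kg > 0, Kg * np.log(np.where(Kg > 0, Kg, 1.0) / mu), 0.0)
        nb = term1 - (Kg + 1.0 / a) * np.log1p(a * (Kg - mu) / (1.0 + a * mu))
        pois = term1 - (Kg - mu)
    dev = np.where(alpha[:, None] > 1e-12, nb, pois)
    return 2.0 * dev.sum(axis=1)


def nb_wald_test(
    m: FeatureCountMatrix,
    s: pd.Series,
    alpha: pd.Series,
    control: str | None = None,
    case: str | None = None,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of the case-vs-control effect.

    Returns a DataFrame indexed by feature_id with columns ``base_mean``
    (mean normalized count), ``log2fc``, ``se`` (of log2fc), ``wald_p``,
    ``q``, ``direction``, ``converged``, ``is_dmr`` and ``is_fc_pass``.
    Features with zero counts everywhere, or that fail to converge, keep
    their point estimates but have missing p/q and are excluded from the
    BH family.
    """
    control, case = _resolve_groups(m.groups, control, case)
    ctrl, cse = _group_masks(m.groups, control, case)
    sv = s.reindex(m.counts.columns).to_numpy(dtype=float)
    av = alpha.reindex(m.counts.index).to_numpy(dtype=float)
    K = m.counts.to_numpy(dtype=float)
    base_mean = (K / sv).mean(axis=1)

    eta_c, w_c, conv_c = _fit_group(K[:, ctrl], sv[ctrl], av)
    eta_t, w_t, conv_t = _fit_group(K[:, cse], sv[cse], av)
    converged = conv_c & conv_t

    ln2 = np.log(2.0)
    b1_ln = eta_t - eta_c
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ln = np.sqrt(1.0 / w_c + 1.0 / w_t)
        z = b1_ln / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    all_zero = K.sum(axis=1) == 0
    usable = converged & ~all_zero & np.isfinite(p)
    p = np.where(usable, p, np.nan)

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": b1_ln / ln2,
            "se": se_ln / ln2,
            "wald_p": p,
            "q": bh_adjust(p),
            "converged": converged & ~all_zero,
        },
        index=m.counts.index,
    )
    res.loc[all_zero, ["log2fc", "se"]] = np.nan
    res["direction"] = np.where(res["log2fc"] > 0, "hyper", "hypo")
    res["is_dmr"] = res["q"] < q_max
    res["is_fc_pass"] = res["log2fc"].abs() > np.log2(fc_min)
    return res


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing p-values are allowed: they are excluded from the family size
    m and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def call_dmcgi(
    results: pd.DataFrame, q_max: float = Q_MAX, fc_min: float = FC_MIN
) -> tuple[list[str], list[str]]:
    """Hyper- and hypomethylated DMCGI calls at strict q and FC thresholds.

    hyper: q < q_max and fold change > fc_min;
    hypo:  q < q_max and fold change < 1/fc_min.
    Returns region-sorted feature-id lists.
    """
    lfc_min = np.log2(fc_min)
    sig = results["q"] < q_max
    hyper = results.index[sig & (results["log2fc"] > lfc_min)]
    hypo = results.index[sig & (results["log2fc"] < -lfc_min)]
    key = _safe_region_key
    return sorted(hyper, key=key), sorted(hypo, key=key)


def _safe_region_key(feature_id: str):
    try:
        return (0,) + tuple(region_sort_key(feature_id))
    except Exception:
        return (1, feature_id)


def top_features(
    results: pd.DataFrame,
    k: int,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
) -> list[str]:
    """Top-k called hypermethylated DMCGIs ranked by fold change.

    Descending log2 fold change; ties broken by ascending q, then by
    feature id, so the ranking is invariant to input row order.
    """
    hyper, _ = call_dmcgi(results, q_max=q_max, fc_min=fc_min)
    if k > len(hyper):
        raise ValueError(f"requested top {k} but only {len(hyper)} DMCGIs called")
    sub = results.loc[hyper]
    ranked = sub.sort_values(
        ["log2fc", "q"], ascending=[False, True], kind="mergesort"
    )
    # stable final tie-break on feature id
    ranked = ranked.iloc[
        np.lexsort((ranked.index, ranked["q"].to_numpy(), -ranked["log2fc"].to_numpy()))
    ]
    return list(ranked.index[:k])


def run_diffmeth(
    m: FeatureCountMatrix,
    control: str | None = None,
    case: str | None = None,
    q_max: float = Q_MAX,
    fc_min: float = FC_MIN,
) -> pd.DataFrame:
    """Size factors + dispersions + Wald test in one call."""
    s = size_factors(m)
    alpha = estimate_dispersions(m, s, control=control, case=case)
    return nb_wald_test(
        m, s, alpha, control=control, case=case, q_max=q_max, fc_min=fc_min
    )
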