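"""Array-style (450K-like) differential methylation and island aggregation.

Beta values are per-CpG-site methylation fractions in [0, 1].  Sites are
tested between two groups with a two-group linear-model F-test (df1 = 1,
identical to the squared pooled-variance t), effect size is the
difference of group mean betas (delta beta), and hypermethylated DMCs
(delta > 0.2, BH-FDR q < 0.1) are collapsed to their CpG islands for
intersection with sequencing-derived island calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust
from .intervals import region_sort_key

__all__ = [
    "BetaMatrix",
    "dmc_test",
    "call_dmc",
    "sites_to_island_set",
    "collapse_island_betas",
]

DELTA_MIN = 0.2
Q_MAX = 0.1


@dataclass
class BetaMatrix:
    """CpG sites (or islands) x samples methylation fractions.

    betas : DataFrame indexed by site_id, one column per sample, in [0, 1].
    island_id : Series site_id -> island region string (NaN = not on an island).
    groups : Series sample -> group label (e.g. tumor/normal/pbmc).
    """

    betas: pd.DataFrame
    island_id: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        vals = self.betas.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValueError("beta values must lie in [0, 1]")
        self.island_id = self.island_id.reindex(self.betas.index)
        self.groups = self.groups.reindex(self.betas.columns)
        if self.groups.isna().any():
            raise ValueError("group label missing for some samples")

    def to_tsv(self, path: str | Path) -> None:
        out = self.betas.copy()
        out.insert(0, "island_id", self.island_id)
        out.to_csv(path, sep="\t", index_label="site_id")

    @classmethod
    def from_tsv(cls, beta_path: str | Path, samples_path: str | Path) -> "BetaMatrix":
        df = pd.read_csv(beta_path, sep="\t", index_col="site_id")
        island = df.pop("island_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        groups = sheet.set_index("sample")["group"]
        return cls(df, island, groups.reindex(df.columns))


def dmc_test(b: BetaMatrix, comparator: str, case: str = "tumor") -> pd.DataFrame:
    """Per-site two-group F-test of beta values, case vs. comparator.

    Returns a DataFrame (index site_id) with columns ``delta_beta``
    (mean case - mean comparator), ``f_stat``, ``p``, ``q`` and
    ``degenerate`` (zero pooled variance with unequal means: p forced
    to 0 and flagged).
    """
    g = b.groups
    x = b.betas.loc[:, g[g == case].index].to_numpy(dtype=float)
    y = b.betas.loc[:, g[g == comparator].index].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    delta = m1 - m2
    ss = ((x - m1[:, None]) ** 2).sum(axis=1) + ((y - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    pooled = ss / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = delta**2 / (pooled * (1.0 / n1 + 1.0 / n2))
    p = stats.f.sf(f, 1, df2)
    degenerate = (pooled == 0) & (delta != 0)
    p = np.where(pooled == 0, np.where(delta == 0, 1.0, 0.0), p)
    f = np.where(pooled == 0, np.where(delta == 0, 0.0, np.inf), f)
    res = pd.DataFrame(
        {"delta_beta": delta, "f_stat": f, "p": p, "degenerate": degenerate},
        index=b.betas.index,
    )
    res["q"] = bh_adjust(res["p"].to_numpy())
    res["is_dmc"] = call_dmc(res)
    return res


def call_dmc(r: pd.DataFrame, delta_min: float = DELTA_MIN,
             q_max: float = Q_MAX) -> pd.Series:
    """Hypermethylated DMC flag: delta_beta > delta_min and q < q_max (strict)."""
    return (r["delta_beta"] > delta_min) & (r["q"] < q_max)


def sites_to_island_set(dmcs: pd.DataFrame | pd.Index,
                        mapping: pd.Series | Mapping[str, str]) -> list[str]:
    """Collapse DMC sites to their unique CpG islands, sorted by region.

    Sites without an island annotation are excluded.
    """
    if isinstance(dmcs, pd.DataFrame):
        sites = dmcs.index[dmcs["is_dmc"]] if "is_dmc" in dmcs else dmcs.index
    else:
        sites = dmcs
    mapping = pd.Series(mapping) if not isinstance(mapping, pd.Series) else mapping
    islands = mapping.reindex(sites).dropna().unique().tolist()
    return sorted(islands, key=region_sort_key)


def collapse_island_betas(b: BetaMatrix) -> BetaMatrix:
    """Average member-site betas per island; drops non-island sites.

    Neighboring CpG sites are positively correlated, so the unweighted
    island mean is a stable single summary per island and sample.
    """
    mapped = b.island_id.dropna()
    if mapped.empty:
        raise ValueError("no island-mapped sites to collapse")
    collapsed = b.betas.loc[mapped.index].groupby(mapped).mean()
    collapsed = collapsed.loc[sorted(collapsed.index, key=region_sort_key)]
    island_ids = pd.Series(collapsed.index, index=collapsed.index)
    return BetaMatrix(collapsed, island_ids, b.groups)
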