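"""Fragment-to-feature counting and count-matrix row filters.

Each sequenced fragment increments exactly one CpG feature: the feature
with maximal base overlap, with ties broken by class priority
(island > shore > shelf > inter) and then by leftmost feature.  Single
assignment keeps per-class read percentages a true partition of the
library, which is what makes downstream TPM shares interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CLASS_PRIORITY, CpGFeature, GenomicInterval

__all__ = ["FeatureCountMatrix", "count_fragments", "filter_matrix", "subset_islands"]


@dataclass
class FeatureCountMatrix:
    """Features x samples integer counts with class and group metadata.

    counts : DataFrame indexed by feature_id (region string), one column
        per sample.
    feature_class : Series mapping feature_id -> class.
    groups : Series mapping sample id -> group label.
    """

    counts: pd.DataFrame
    feature_class: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.is_unique:
            raise ValueError("duplicate feature ids")
        self.feature_class = self.feature_class.reindex(self.counts.index)
        if self.feature_class.isna().any():
            raise ValueError("feature_class missing for some features")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            raise ValueError("group label missing for some samples")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "class", self.feature_class)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path
                 ) -> "FeatureCountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col="feature_id")
        sheet = pd.read_csv(samples_path, sep="\t")
        groups = sheet.set_index("sample")["group"]
        cls_col = df.pop("class")
        return cls(df, cls_col, groups.reindex(df.columns))


def count_fragments(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    features: Sequence[CpGFeature],
    groups: Mapping[str, str] | pd.Series | None = None,
) -> FeatureCountMatrix:
    """Assign per-sample fragments to features and build the count matrix.

    Parameters
    ----------
    fragments : mapping sample id -> list of fragment intervals.
    features : classified CpG annotation (need not be sorted).
    groups : optional sample -> group labels; defaults to "unlabeled".
    """
    order = list(range(len(features)))
    # per-chromosome arrays sorted by start for binary search
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom in {f.interval.chrom for f in features}:
        idx = sorted(
            (i for i in order if features[i].interval.chrom == chrom),
            key=lambda i: features[i].interval.start,
        )
        starts = np.array([features[i].interval.start for i in idx])
        ends = np.array([features[i].interval.end for i in idx])
        by_chrom[chrom] = (starts, ends, idx)

    feature_ids = [f.feature_id for f in features]
    samples = list(fragments)
    counts = np.zeros((len(features), len(samples)), dtype=np.int64)

    for j, sample in enumerate(samples):
        for frag in fragments[sample]:
            i = _assign(frag, features, by_chrom)
            if i is not None:
                counts[i, j] += 1

    groups = pd.Series(dict(groups) if groups is not None else
                       {s: "unlabeled" for s in samples})
    return FeatureCountMatrix(
        pd.DataFrame(counts, index=feature_ids, columns=samples),
        pd.Series([f.feature_class for f in features], index=feature_ids),
        groups,
    )


def _assign(frag, features, by_chrom):
    """Index of the feature receiving this fragment, or None if unmappable."""
    entry = by_chrom.get(frag.chrom)
    if entry is None:
        return None
    starts, ends, idx = entry
    lo = int(np.searchsorted(ends, frag.start, side="left"))
    hi = int(np.searchsorted(starts, frag.end, side="right"))
    best = None  # (-overlap, priority, start, feature index)
    for k in range(lo, hi):
        i = idx[k]
        ov = features[i].interval.overlap_bp(frag)
        if ov <= 0:
            continue
        key = (-ov, CLASS_PRIORITY[features[i].feature_class],
               features[i].interval.start, i)
        if best is None or key < best:
            best = key
    if best is not None:
        return best[3]
    # zero overlap (fragment beyond annotated bases): book to nearest inter
    inter = [i for i in idx if features[i].feature_class == "inter"]
    if not inter:
        return None
    return min(
        inter,
        key=lambda i: min(abs(features[i].interval.start - frag.end),
                          abs(frag.start - features[i].interval.end)),
    )


def filter_matrix(m: FeatureCountMatrix) -> FeatureCountMatrix:
    """Drop inter-CpG rows and rows with zero counts in every sample."""
    keep = (m.feature_class != "inter") & (m.counts.sum(axis=1) > 0)
    if not keep.any():
        raise ValueError("filtering removed every row; degenerate input matrix")
    return FeatureCountMatrix(
        m.counts.loc[keep], m.feature_class.loc[keep], m.groups
    )


def subset_islands(m: FeatureCountMatrix) -> FeatureCountMatrix:
    """Restrict the matrix to island-class rows."""
    keep = m.feature_class == "island"
    return FeatureCountMatrix(
        m.counts.loc[keep], m.feature_class.loc[keep], m.groups
    )
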