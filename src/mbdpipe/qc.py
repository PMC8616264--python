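"""Capture-reaction and sequencing-level quality metrics.

Spike-in qPCR recovery and specificity gate the methylation-capture
reaction; TPM shares per CpG feature class, the non-CpG/CpG coverage
ratio ("noise"), and the CpG density at peak coverage summarize how
strongly the library is enriched for methylated, CpG-dense fragments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import FeatureCountMatrix
from .intervals import FEATURE_CLASSES

__all__ = [
    "SpikeInCt",
    "QcSummary",
    "recovery",
    "capture_specificity",
    "specificity_gate",
    "tpm_normalize",
    "class_coverage_fractions",
    "noise_and_peak",
]

SPECIFICITY_THRESHOLD = 99.0  # percent; capture must reach this before sequencing


@dataclass(frozen=True)
class SpikeInCt:
    """qPCR cycle thresholds for methylated/unmethylated spike-in controls."""

    ct_meth_input: float
    ct_meth_enriched: float
    ct_unmeth_input: float
    ct_unmeth_enriched: float
    input_dilution: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ct_meth_input", "ct_meth_enriched",
                     "ct_unmeth_input", "ct_unmeth_enriched"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if self.input_dilution < 1:
            raise ValueError("input_dilution must be >= 1")

    def specificity(self) -> float:
        rm = recovery(self.ct_meth_input, self.ct_meth_enriched, self.input_dilution)
        ru = recovery(self.ct_unmeth_input, self.ct_unmeth_enriched, self.input_dilution)
        return capture_specificity(rm, ru)


@dataclass
class QcSummary:
    recovery_meth: float
    recovery_unmeth: float
    specificity: float
    pct_noncpg_reads: float
    noise: float
    cpg_density_at_peak: float
    class_coverage_pct: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def recovery(ct_input: float, ct_enriched: float, input_dilution: float = 1.0) -> float:
    """Percent recovery of a spike-in control from qPCR Ct values.

    The unenriched aliquot is measured at ``input_dilution``-fold
    dilution, so its Ct is first corrected by log2(dilution).  One cycle
    difference corresponds to one doubling; values may exceed 100% with
    noisy Ct measurements and are reported uncapped.
    """
    if input_dilution < 1:
        raise ValueError("input_dilution must be >= 1")
    return 100.0 * 2.0 ** ((ct_input - math.log2(input_dilution)) - ct_enriched)


def capture_specificity(recovery_meth: float, recovery_unmeth: float) -> float:
    """Capture specificity, percent: (1 - unmeth/meth recovery) x 100."""
    if recovery_meth <= 0:
        raise ValueError("recovery of methylated control must be positive")
    return (1.0 - recovery_unmeth / recovery_meth) * 100.0


def specificity_gate(specificity: float,
                     threshold: float = SPECIFICITY_THRESHOLD) -> bool:
    """True when the capture reaction passes the specificity gate (>= threshold)."""
    return specificity >= threshold


def tpm_normalize(counts: FeatureCountMatrix | pd.DataFrame,
                  lengths: pd.Series) -> pd.DataFrame:
    """Length-normalized per-million scaling; each sample column sums to 1e6."""
    df = counts.counts if isinstance(counts, FeatureCountMatrix) else counts
    lengths = lengths.reindex(df.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every feature needs a positive length")
    rate = df.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    return 1e6 * rate / totals


def class_coverage_fractions(tpm: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """Per-sample percent of normalized reads on each feature class.

    Returns a samples x classes DataFrame whose four class columns sum
    to 100, plus a derived ``extended_islands`` column
    (island + shore + shelf), the CpG-island-centered territory.
    """
    classes = classes.reindex(tpm.index)
    if classes.isna().any():
        raise ValueError("every feature must have a class")
    shares = tpm.groupby(classes).sum().T
    for c in FEATURE_CLASSES:
        if c not in shares:
            shares[c] = 0.0
    shares = 100.0 * shares[list(FEATURE_CLASSES)].div(shares[list(FEATURE_CLASSES)].sum(axis=1), axis=0)
    shares["extended_islands"] = shares[["island", "shore", "shelf"]].sum(axis=1)
    return shares


def noise_and_peak(fragment_cpg_counts: np.ndarray,
                   coverage: np.ndarray) -> tuple[float, int]:
    """Enrichment noise ratio and CpG density at the coverage peak.

    noise = mean coverage of fragments carrying no CpG divided by mean
    coverage of fragments carrying at least one CpG.  The peak density
    is the CpG-count bin (width 1) whose fragments accumulate the
    highest total coverage; ties report the lower density.
    """
    cpg = np.asarray(fragment_cpg_counts)
    cov = np.asarray(coverage, dtype=float)
    if cpg.size == 0 or cpg.size != cov.size:
        raise ValueError("need matching, non-empty tallies and coverage")
    with_cpg = cpg >= 1
    if not with_cpg.any():
        raise ValueError("no CpG-containing fragments; cannot define noise")
    mean_non = cov[~with_cpg].mean() if (~with_cpg).any() else 0.0
    noise = float(mean_non / cov[with_cpg].mean())
    densities = np.unique(cpg)
    totals = np.array([cov[cpg == d].sum() for d in densities])
    peak = int(densities[int(np.argmax(totals))])  # argmax takes first => lower density
    return noise, peak
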