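"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's input surface, each with ground
truth, so every downstream stage is testable without external data:

* ``simulate_counts`` -- negative-binomial feature counts with
  library-size variation, capture bias toward CpG-dense classes, and a
  planted set of case-hypermethylated islands at a chosen fold change
  (plus a small hypomethylated minority, mirroring the strong
  hyper/hypo asymmetry of tumor CpG-island methylation).
* ``simulate_betas`` -- Beta-distributed array-style site methylation
  for tumor / adjacent-normal / PBMC groups, with a planted mean shift
  at islands overlapping the count-side plantings.
* ``simulate_spikein`` -- qPCR cycle thresholds for methylated and
  unmethylated spike-in controls under chosen capture efficiencies.

Defaults encode the study conditions the pipeline targets: 12 cases vs
16 controls, ~7% of islands planted hypermethylated at fold change 4,
NB dispersion 0.05, 2-fold library-size spread, and an array cohort of
21 tumor / 21 normal / 61 PBMC samples with a planted delta-beta of
0.35 on a baseline island methylation of 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arraydm import BetaMatrix
from .counting import FeatureCountMatrix
from .intervals import CpGFeature, GenomicInterval, derive_feature_classes
from .qc import SpikeInCt

__all__ = [
    "CountSimConfig",
    "BetaSimConfig",
    "Truth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_betas",
    "simulate_spikein",
    "simulate_fragments",
    "write_sample_sheet",
]

#: Capture-bias multipliers: expected per-feature coverage relative to
#: inter-CpG background.  Chosen so island reads dominate the library
#: even though islands are a small share of the genome.
CLASS_BIAS = {"island": 30.0, "shore": 8.0, "shelf": 3.0, "inter": 1.0}


@dataclass
class CountSimConfig:
    """Parameters of the NB count simulator (see module docstring)."""

    n_cases: int = 12
    n_controls: int = 16
    baseline_mean: float = 50.0
    dispersion: float = 0.05
    dispersion_jitter_sd: float = 0.0
    libsize_range: tuple[float, float] = (0.5, 2.0)
    planted_fraction: float = 0.07
    planted_fc: float = 4.0
    hypo_fraction: float = 0.002
    mean_jitter_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_fc <= 0:
            raise ValueError("planted_fc must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.hypo_fraction <= 1:
            raise ValueError("hypo_fraction must be in [0, 1]")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be 0 < lo <= hi")


@dataclass
class BetaSimConfig:
    """Parameters of the array-style beta-value simulator."""

    n_sites_per_island: int = 5
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"tumor": 21, "normal": 21, "pbmc": 61}
    )
    base_beta: float = 0.2
    delta: float = 0.35
    concentration: float = 50.0
    overlap_with_counts: float = 1.0
    n_unmapped_sites: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.base_beta <= 1:
            raise ValueError("base_beta must be in [0, 1]")
        if not 0 <= self.base_beta + self.delta <= 1:
            raise ValueError("base_beta + delta must stay in [0, 1]")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not 0 <= self.overlap_with_counts <= 1:
            raise ValueError("overlap_with_counts must be in [0, 1]")


@dataclass
class Truth:
    """Ground truth emitted alongside a simulated dataset."""

    planted_hyper: list[str]
    planted_hypo: list[str]
    libsize_factors: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Truth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_annotation(
    n_islands: int,
    island_size: tuple[int, int] = (500, 2000),
    gap_size: tuple[int, int] = (10_000, 40_000),
    islands_per_chrom: int = 100,
    seed: int = 0,
) -> tuple[list[CpGFeature], dict[str, int]]:
    """Random toy CpG-island annotation expanded to a full class partition.

    Islands of uniform-random size are laid down with uniform-random
    inter-island gaps across as many synthetic chromosomes as needed;
    the island list is then expanded into the island/shore/shelf/inter
    partition.  Returns (features, chrom_sizes).
    """
    rng = np.random.default_rng(seed)
    islands: list[GenomicInterval] = []
    chrom_sizes: dict[str, int] = {}
    remaining = n_islands
    c = 0
    while remaining > 0:
        c += 1
        chrom = f"chr{c}"
        k = min(islands_per_chrom, remaining)
        pos = 1
        for _ in range(k):
            pos += int(rng.integers(gap_size[0], gap_size[1] + 1))
            size = int(rng.integers(island_size[0], island_size[1] + 1))
            islands.append(GenomicInterval(chrom, pos, pos + size - 1))
            pos += size
        chrom_sizes[chrom] = pos + int(rng.integers(gap_size[0], gap_size[1] + 1))
        remaining -= k
    return derive_feature_classes(islands, chrom_sizes), chrom_sizes


def simulate_counts(
    cfg: CountSimConfig, features: Sequence[CpGFeature]
) -> tuple[FeatureCountMatrix, Truth]:
    """Draw an NB count matrix over ``features`` with planted island effects.

    Control-group expectation for feature *i* is
    ``libsize_j * baseline_mean * bias(class_i) * jitter_i``; planted
    hypermethylated islands have their case-group mean multiplied by
    ``planted_fc`` (hypomethylated: divided).  Identical config and seed
    give an identical matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(features)
    if n == 0:
        raise ValueError("no features supplied")
    classes = np.array([f.feature_class for f in features])
    ids = np.array([f.feature_id for f in features])

    bias = np.array([CLASS_BIAS[c] for c in classes])
    jitter = np.exp(rng.normal(0.0, cfg.mean_jitter_sd, size=n))
    mu0 = cfg.baseline_mean * bias * jitter

    island_idx = np.flatnonzero(classes == "island")
    n_hyper = int(round(cfg.planted_fraction * island_idx.size))
    n_hypo = int(round(cfg.hypo_fraction * n_hyper))
    planted = rng.choice(island_idx, size=min(n_hyper + n_hypo, island_idx.size),
                         replace=False)
    hyper_idx, hypo_idx = planted[:n_hyper], planted[n_hyper:]

    samples = [f"case_{i+1}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i+1}" for i in range(cfg.n_controls)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_cases + ["control"] * cfg.n_controls, index=samples
    )
    lib = rng.uniform(*cfg.libsize_range, size=len(samples))

    fc = np.ones(n)
    fc[hyper_idx] = cfg.planted_fc
    fc[hypo_idx] = 1.0 / cfg.planted_fc
    is_case = (groups == "case").to_numpy()
    mean = mu0[:, None] * np.where(is_case[None, :], fc[:, None], 1.0) * lib[None, :]

    alpha = np.full(n, cfg.dispersion)
    if cfg.dispersion_jitter_sd > 0:
        alpha = alpha * np.exp(rng.normal(0.0, cfg.dispersion_jitter_sd, size=n))
    counts = _nb_draw(rng, mean, alpha[:, None])

    fcm = FeatureCountMatrix(
        pd.DataFrame(counts, index=ids, columns=samples),
        pd.Series(classes, index=ids),
        groups,
    )
    truth = Truth(
        planted_hyper=sorted(ids[hyper_idx]),
        planted_hypo=sorted(ids[hypo_idx]),
        libsize_factors=dict(zip(samples, lib.tolist())),
    )
    return fcm, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray):
    """NB(mu, alpha) with Var = mu + alpha mu^2; alpha = 0 falls back to Poisson."""
    out = np.empty(mean.shape, dtype=np.int64)
    pois = np.broadcast_to(alpha, mean.shape) <= 0
    if pois.any():
        out[pois] = rng.poisson(np.broadcast_to(mean, mean.shape)[pois])
    if (~pois).any():
        a = np.broadcast_to(alpha, mean.shape)[~pois]
        mu = np.broadcast_to(mean, mean.shape)[~pois]
        r = 1.0 / a
        p = r / (r + mu)
        out[~pois] = rng.negative_binomial(r, p)
    return out


def simulate_betas(
    cfg: BetaSimConfig, islands: Sequence[CpGFeature], truth: Truth
) -> tuple[BetaMatrix, list[str]]:
    """Array-style site betas for tumor/normal/PBMC groups.

    Tumor samples have mean ``base_beta + delta`` at planted islands
    (an ``overlap_with_counts`` fraction of the count-side planted
    hypermethylated islands); all other island/group combinations have
    mean ``base_beta``.  Returns the matrix and the list of islands
    actually planted on the array side.
    """
    rng = np.random.default_rng(cfg.seed)
    island_ids = [f.feature_id for f in islands if f.feature_class == "island"]
    missing = set(truth.planted_hyper) - set(island_ids)
    if missing:
        raise ValueError(f"truth islands absent from annotation: {sorted(missing)[:3]}")
    n_overlap = int(round(cfg.overlap_with_counts * len(truth.planted_hyper)))
    planted = sorted(
        rng.choice(truth.planted_hyper, size=n_overlap, replace=False).tolist()
    ) if n_overlap else []
    planted_set = set(planted)

    samples, labels = [], []
    for g, n_g in cfg.groups.items():
        samples += [f"{g}_{i+1}" for i in range(n_g)]
        labels += [g] * n_g
    groups = pd.Series(labels, index=samples)
    is_tumor = (groups == "tumor").to_numpy()

    site_ids, site_island, rows = [], [], []
    for isl in island_ids:
        hot = isl in planted_set
        for k in range(cfg.n_sites_per_island):
            mean = np.where(is_tumor & hot, cfg.base_beta + cfg.delta, cfg.base_beta)
            a = mean * cfg.concentration
            b = (1.0 - mean) * cfg.concentration
            rows.append(rng.beta(a, b))
            site_ids.append(f"{isl}|s{k+1}")
            site_island.append(isl)
    for k in range(cfg.n_unmapped_sites):
        a = cfg.base_beta * cfg.concentration
        b = (1.0 - cfg.base_beta) * cfg.concentration
        rows.append(rng.beta(a, b, size=len(samples)))
        site_ids.append(f"unmapped|s{k+1}")
        site_island.append(None)

    betas = pd.DataFrame(np.vstack(rows), index=site_ids, columns=samples)
    bm = BetaMatrix(betas, pd.Series(site_island, index=site_ids, dtype=object), groups)
    return bm, planted


def simulate_spikein(
    capture_eff_meth: float,
    capture_eff_unmeth: float,
    ct_input: float = 24.0,
    efficiency_qpcr: float = 2.0,
    noise_sd: float = 0.0,
    input_dilution: float = 1.0,
    seed: int = 0,
) -> SpikeInCt:
    """Spike-in qPCR Ct quadruple under chosen capture efficiencies.

    A capture efficiency e < 1 delays amplification of the enriched
    aliquot by log_base(1/e) cycles (base = qPCR amplification factor,
    2 for perfect efficiency); optional Gaussian Ct noise on the
    enriched wells.  The unenriched aliquot is measured at
    ``input_dilution``-fold dilution, so its reported Ct is raised by
    log2(dilution); the dilution factor is carried in the result so the
    recovery formula can correct for it.
    """
    if not (0 < capture_eff_meth <= 1) or not (0 < capture_eff_unmeth <= 1):
        raise ValueError("capture efficiencies must be in (0, 1]")
    if not (1 < efficiency_qpcr <= 2):
        raise ValueError("qPCR amplification base must be in (1, 2]")
    rng = np.random.default_rng(seed)
    base = np.log(efficiency_qpcr)

    def enriched(eff: float) -> float:
        ct = ct_input - np.log(eff) / base
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        return float(ct)

    # the measured (diluted) input Ct is ct_input + log2(dilution)
    ct_in = ct_input + float(np.log2(input_dilution))
    return SpikeInCt(
        ct_meth_input=ct_in,
        ct_meth_enriched=enriched(capture_eff_meth),
        ct_unmeth_input=ct_in,
        ct_unmeth_enriched=enriched(capture_eff_unmeth),
        input_dilution=input_dilution,
    )


def simulate_fragments(
    features: Sequence[CpGFeature],
    n_fragments: int,
    fragment_length: int = 167,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Capture-biased fragments: each fragment starts inside a feature
    drawn with probability proportional to class bias x feature length."""
    rng = np.random.default_rng(seed)
    sizes = np.array([f.interval.size for f in features], dtype=float)
    weights = sizes * np.array([CLASS_BIAS[f.feature_class] for f in features])
    probs = weights / weights.sum()
    picks = rng.choice(len(features), size=n_fragments, p=probs)
    frags = []
    for i in picks:
        iv = features[i].interval
        start = int(rng.integers(iv.start, iv.end + 1))
        frags.append(GenomicInterval(iv.chrom, start, start + fragment_length - 1))
    return frags


def write_sample_sheet(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )
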