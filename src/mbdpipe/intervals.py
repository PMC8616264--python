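"""Genomic intervals, CpG feature classes, and BED/region-string I/O.

Coordinate convention: in memory every interval is 1-based with an
inclusive end, so ``size = end - start + 1``.  On disk, BED files follow
the standard 0-based half-open convention; the readers/writers in this
module are the only place the offset changes.

CpG features partition each annotated chromosome into four classes:
``island`` (CpG-dense regions supplied by the caller), ``shore`` (up to
2 kb flanking an island), ``shelf`` (the next 2 kb band, i.e. 2-4 kb from
an island), and ``inter`` (everything else).  Flanks of nearby islands
are truncated at the midpoint of the gap, which is equivalent to
assigning every base to its nearest island (ties go to the leftmost).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "CpGFeature",
    "FEATURE_CLASSES",
    "CLASS_PRIORITY",
    "parse_region",
    "interval_size",
    "region_sort_key",
    "derive_feature_classes",
    "genome_fraction_by_class",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
]

#: Feature classes in capture-priority order (island outranks shore, ...).
FEATURE_CLASSES = ("island", "shore", "shelf", "inter")
CLASS_PRIORITY = {c: i for i, c in enumerate(FEATURE_CLASSES)}

SHORE_BP = 2000
SHELF_BP = 2000

_REGION_RE = re.compile(r"^(?P<chrom>[\w.]+):(?P<start>\d+)-(?P<end>\d+)$")


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted as an interval."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) precedes start ({self.start}) on {self.chrom}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class CpGFeature:
    """A classified CpG annotation feature.

    ``feature_id`` is the canonical region string and serves as the
    identity key throughout the pipeline.
    """

    interval: GenomicInterval
    feature_class: str

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def feature_id(self) -> str:
        return self.interval.region


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string (1-based inclusive)."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    start, end = int(m["start"]), int(m["end"])
    if end < start:
        raise RegionParseError(f"inverted bounds in region string: {text!r}")
    if start < 1:
        raise RegionParseError(f"non-positive start in region string: {text!r}")
    return GenomicInterval(m["chrom"], start, end)


def interval_size(iv: GenomicInterval) -> int:
    """Length of the interval in base pairs (end - start + 1)."""
    return iv.size


def _chrom_key(chrom: str):
    m = re.match(r"^chr(\d+)$", chrom)
    return (0, int(m.group(1)), "") if m else (1, 0, chrom)


def region_sort_key(region: str):
    """Sort key placing chr1..chr22 numerically before other chromosomes."""
    iv = parse_region(region)
    return (*_chrom_key(iv.chrom), iv.start, iv.end)


def derive_feature_classes(
    islands: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    shore_bp: int = SHORE_BP,
    shelf_bp: int = SHELF_BP,
) -> list[CpGFeature]:
    """Expand an island list into a full island/shore/shelf/inter partition.

    Every base of every chromosome in ``chrom_sizes`` is assigned to
    exactly one feature.  Bases between two islands belong to the nearer
    one (midpoint truncation, ties to the left island); the first
    ``shore_bp`` bases from an island edge are shore, the next
    ``shelf_bp`` are shelf, the remainder inter.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for iv in islands:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"island {iv.region} on unknown chromosome")
        if iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(
                f"island {iv.region} extends past chromosome end "
                f"({chrom_sizes[iv.chrom]})"
            )
        by_chrom[iv.chrom].append(iv)

    out: list[CpGFeature] = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping islands {a.region} and {b.region}")
        if not ivs:
            out.append(CpGFeature(GenomicInterval(chrom, 1, size), "inter"))
            continue
        for i, isl in enumerate(ivs):
            out.append(CpGFeature(isl, "island"))
            # left flank territory: from the midpoint with the previous
            # island (exclusive) or base 1, up to the island start
            left_bound = 1 if i == 0 else (ivs[i - 1].end + isl.start) // 2 + 1
            out.extend(
                _flank_features(chrom, left_bound, isl.start - 1, isl.start,
                                left_side=True, shore_bp=shore_bp, shelf_bp=shelf_bp)
            )
            # right flank territory: up to the midpoint with the next island
            right_bound = size if i == len(ivs) - 1 else (isl.end + ivs[i + 1].start) // 2
            out.extend(
                _flank_features(chrom, isl.end + 1, right_bound, isl.end,
                                left_side=False, shore_bp=shore_bp, shelf_bp=shelf_bp)
            )
    out.sort(key=lambda f: (_chrom_key(f.interval.chrom), f.interval.start))
    return out


def _flank_features(
    chrom: str, lo: int, hi: int, edge: int, left_side: bool,
    shore_bp: int, shelf_bp: int,
) -> list[CpGFeature]:
    """Classify the bases [lo, hi] flanking an island edge into shore/shelf/inter."""
    if hi < lo:
        return []
    feats = []
    if left_side:
        # distance of base p from the island is edge - p (edge = island start)
        bands = [
            ("shore", max(lo, edge - shore_bp), hi),
            ("shelf", max(lo, edge - shore_bp - shelf_bp), min(hi, edge - shore_bp - 1)),
            ("inter", lo, min(hi, edge - shore_bp - shelf_bp - 1)),
        ]
    else:
        bands = [
            ("shore", lo, min(hi, edge + shore_bp)),
            ("shelf", max(lo, edge + shore_bp + 1), min(hi, edge + shore_bp + shelf_bp)),
            ("inter", max(lo, edge + shore_bp + shelf_bp + 1), hi),
        ]
    for cls, a, b in bands:
        if b >= a:
            feats.append(CpGFeature(GenomicInterval(chrom, a, b), cls))
    return feats


def genome_fraction_by_class(
    features: Sequence[CpGFeature], chrom_sizes: Mapping[str, int]
) -> dict[str, float]:
    """Percent of the genome covered by each feature class.

    Requires that ``features`` partition the chromosomes in
    ``chrom_sizes`` exactly (no gaps, no overlaps).
    """
    if not features:
        raise ValueError("empty feature list cannot partition a genome")
    total = sum(chrom_sizes.values())
    covered: dict[str, int] = {c: 0 for c in FEATURE_CLASSES}
    by_chrom: dict[str, list[CpGFeature]] = {}
    for f in features:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
        covered[f.feature_class] += f.interval.size
    for chrom, feats in by_chrom.items():
        if chrom not in chrom_sizes:
            raise ValueError(f"feature chromosome {chrom} not in chrom_sizes")
        feats = sorted(feats, key=lambda f: f.interval.start)
        pos = 1
        for f in feats:
            if f.interval.start != pos:
                raise ValueError(
                    f"features do not partition {chrom}: gap/overlap at {pos}"
                )
            pos = f.interval.end + 1
        if pos != chrom_sizes[chrom] + 1:
            raise ValueError(f"features do not cover {chrom} to its end")
    if set(chrom_sizes) - set(by_chrom):
        raise ValueError("some chromosomes have no features")
    return {c: 100.0 * covered[c] / total for c in FEATURE_CLASSES}


# ---------------------------------------------------------------------------
# I/O: BED (0-based half-open on disk) and chrom.sizes

def write_bed(path: str | Path, items: Iterable[GenomicInterval | CpGFeature]) -> None:
    """Write intervals or features as BED3/BED4 (name column = class)."""
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, CpGFeature):
                iv, name = it.interval, it.feature_class
                fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")
            else:
                fh.write(f"{it.chrom}\t{it.start - 1}\t{it.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval] | list[CpGFeature]:
    """Read a BED3 (intervals) or BED4 (classified features) file."""
    intervals: list[GenomicInterval] = []
    features: list[CpGFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns")
            iv = GenomicInterval(parts[0], int(parts[1]) + 1, int(parts[2]))
            if len(parts) >= 4 and parts[3] in FEATURE_CLASSES:
                features.append(CpGFeature(iv, parts[3]))
            else:
                intervals.append(iv)
    if features and intervals:
        raise ValueError(f"{path}: mixed classified and unclassified BED rows")
    return features if features else intervals


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes
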