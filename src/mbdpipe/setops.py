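"""Set algebra over CpG-island identifier sets.

Tumor-derived islands are the three-way intersection of the plasma
case-vs-control calls with the two tissue-side comparisons (tumor vs
adjacent normal, tumor vs PBMC); cancer-type-specific islands are those
in exactly one cancer type's set.  Island identity is the exact region
string -- the sequencing and array sides are harmonized to the same
island annotation before any intersection, so coordinate matching is
unnecessary (an optional >= 1 bp overlap matcher is available for
annotations that differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from .intervals import parse_region, region_sort_key

__all__ = [
    "IslandSet",
    "VennCounts",
    "tumor_derived",
    "overlap_percent",
    "venn3",
    "type_specific",
    "overlap_match",
    "read_island_set",
    "write_island_set",
]


@dataclass(frozen=True)
class IslandSet:
    """A labelled set of island region strings."""

    label: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        for m in self.members:
            parse_region(m)  # validates region-string identity keys

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members, key=region_sort_key)


@dataclass(frozen=True)
class VennCounts:
    """Exact 7-region counts of a three-set Venn decomposition."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    labels: tuple[str, str, str]

    @property
    def union_size(self) -> int:
        return (self.a_only + self.b_only + self.c_only
                + self.ab_only + self.ac_only + self.bc_only + self.abc)

    @property
    def set_sizes(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.a_only + self.ab_only + self.ac_only + self.abc,
            b: self.b_only + self.ab_only + self.bc_only + self.abc,
            c: self.c_only + self.ac_only + self.bc_only + self.abc,
        }

    @property
    def unique_counts(self) -> dict[str, int]:
        a, b, c = self.labels
        return {a: self.a_only, b: self.b_only, c: self.c_only}

    @property
    def total_specific(self) -> int:
        return self.a_only + self.b_only + self.c_only


def tumor_derived(
    plasma: IslandSet, tumor_vs_normal: IslandSet, tumor_vs_pbmc: IslandSet
) -> IslandSet:
    """Plasma islands supported by both tissue-side comparisons."""
    return IslandSet(
        f"{plasma.label}|tumor_derived",
        plasma.members & tumor_vs_normal.members & tumor_vs_pbmc.members,
    )


def overlap_percent(n_overlap: int, n_total: int) -> float:
    """Overlap share as a percent rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_overlap <= n_total:
        raise ValueError("need 0 <= n_overlap <= n_total")
    pct = Decimal(100 * n_overlap) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def venn3(a: IslandSet, b: IslandSet, c: IslandSet) -> VennCounts:
    """Counts of the seven exclusive regions of a three-set Venn diagram."""
    A, B, C = a.members, b.members, c.members
    abc = A & B & C
    return VennCounts(
        a_only=len(A - B - C),
        b_only=len(B - A - C),
        c_only=len(C - A - B),
        ab_only=len((A & B) - C),
        ac_only=len((A & C) - B),
        bc_only=len((B & C) - A),
        abc=len(abc),
        labels=(a.label, b.label, c.label),
    )


def type_specific(a: IslandSet, b: IslandSet, c: IslandSet) -> dict[str, IslandSet]:
    """Members belonging to exactly one of the three sets, per label."""
    return {
        a.label: IslandSet(a.label, a.members - b.members - c.members),
        b.label: IslandSet(b.label, b.members - a.members - c.members),
        c.label: IslandSet(c.label, c.members - a.members - b.members),
    }


def overlap_match(query: IslandSet, reference: IslandSet,
                  min_bp: int = 1) -> IslandSet:
    """Coordinate-overlap fallback matcher (>= min_bp shared bases).

    Off the main path: used only when two island annotations differ and
    exact region-string identity cannot be assumed.
    """
    ref = [parse_region(r) for r in reference.members]
    kept = []
    for q in query.members:
        qi = parse_region(q)
        if any(qi.overlap_bp(r) >= min_bp for r in ref):
            kept.append(q)
    return IslandSet(query.label, kept)


def read_island_set(path: str | Path, label: str | None = None) -> IslandSet:
    """One region string per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return IslandSet(label or Path(path).stem, lines)


def write_island_set(s: IslandSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(s.sorted_members()) + "\n")
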