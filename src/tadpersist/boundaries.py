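"""Between-condition boundary/TAD comparison and cell-type conservation.

Boundary matching is any-overlap of the (merged, typically 200-kb)
boundary intervals — equivalent to requiring termini within one boundary
width of each other — with greedy one-to-one pairing by descending
overlap length.  Merged-domain detection asks, for every knockdown
domain, which control domains lie >= ``coverage_frac`` of their length
inside it; two or more absorbed domains make a merge event.  Conservation
stratification single-linkage-clusters boundaries across a cell-type
panel and labels clusters specific (k=1) / common (2 <= k <= n−1) /
constitutive (k=n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, IntervalSet
from .simulate import MergeEvent

__all__ = [
    "BoundaryComparison",
    "MergeEvent",
    "compare_boundaries",
    "detect_merged_tads",
    "stratify_conservation",
]


@dataclass
class BoundaryComparison:
    maintained: list[tuple[int, int]]  # (index in A, index in B)
    lost_from_a: list[int]
    gained_in_b: list[int]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "maintained": len(self.maintained),
            "lost_from_a": len(self.lost_from_a),
            "gained_in_b": len(self.gained_in_b),
        }


def compare_boundaries(
    boundaries_a: IntervalSet, boundaries_b: IntervalSet
) -> BoundaryComparison:
    """One-to-one matching of two merged boundary sets by any-overlap.

    Candidate pairs are taken greedily by descending overlap length
    (deterministic tie-break on indices).  Unmatched A boundaries are
    lost, unmatched B boundaries gained; |A| = maintained + lost and
    |B| = maintained + gained by construction."""
    for name, s in (("A", boundaries_a), ("B", boundaries_b)):
        if not s.is_disjoint():
            raise ValueError(f"boundary set {name} has internal overlaps; merge first")
    a = list(boundaries_a.sorted())
    b = list(boundaries_b.sorted())
    pairs: list[tuple[int, int, int]] = []  # (overlap, ia, ib)
    bj = 0
    b_by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, iv in enumerate(b):
        b_by_chrom.setdefault(iv.chrom, []).append((j, iv))
    for i, iva in enumerate(a):
        for j, ivb in b_by_chrom.get(iva.chrom, []):
            ov = iva.overlap_length(ivb)
            if ov > 0:
                pairs.append((ov, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    maintained: list[tuple[int, int]] = []
    for ov, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        maintained.append((i, j))
    maintained.sort()
    lost = [i for i in range(len(a)) if i not in used_a]
    gained = [j for j in range(len(b)) if j not in used_b]
    comp = BoundaryComparison(maintained, lost, gained)
    assert len(a) == len(maintained) + len(lost)
    assert len(b) == len(maintained) + len(gained)
    return comp


def detect_merged_tads(
    tads_a: IntervalSet,
    tads_b: IntervalSet,
    coverage_frac: float = 0.8,
    boundary_flank: int = 100_000,
) -> list[MergeEvent]:
    """Merge events of condition-A domains into larger condition-B domains.

    With arguments swapped the same routine reports subdivisions.  For
    each B domain the A domains with >= ``coverage_frac`` of their length
    inside it are collected; >= 2 such domains form a
    :class:`MergeEvent`.  Dissolved boundaries are the absorbed-domain
    termini strictly inside the absorbing interior, more than
    ``boundary_flank`` from its termini."""
    for name, s in (("A", tads_a), ("B", tads_b)):
        if not s.is_disjoint():
            raise ValueError(f"TAD set {name} has internal overlaps")
    a_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in tads_a.sorted():
        a_by_chrom.setdefault(iv.chrom, []).append(iv)
    events: list[MergeEvent] = []
    for ivb in tads_b.sorted():
        absorbed: list[GenomicInterval] = []
        for iva in a_by_chrom.get(ivb.chrom, []):
            ov = iva.overlap_length(ivb)
            if ov >= coverage_frac * iva.length:
                absorbed.append(iva)
        if len(absorbed) < 2:
            continue
        lo, hi = ivb.start + boundary_flank, ivb.end - boundary_flank
        dissolved = sorted(
            {
                t
                for iva in absorbed
                for t in (iva.start, iva.end)
                if lo < t < hi
            }
        )
        events.append(
            MergeEvent(absorbing=ivb, absorbed=tuple(absorbed), dissolved=tuple(dissolved))
        )
    return events


def stratify_conservation(
    panel: list[tuple[str, IntervalSet]] | dict[str, IntervalSet],
) -> pd.DataFrame:
    """Single-linkage clustering of boundaries across a cell-type panel.

    Boundaries from all members are pooled and chained wherever two
    overlap; each cluster's representative is the union span, k is the
    number of distinct contributing cell types and the stratum follows
    k: specific (1), common (2..n−1), constitutive (n).  A chain of
    pairwise-overlapping boundaries counts as one cluster (a documented
    property of single linkage).  The result is independent of panel
    order."""
    items = list(panel.items()) if isinstance(panel, dict) else list(panel)
    if len(items) < 2:
        raise ValueError("panel must contain >= 2 cell types")
    names = [n for n, _ in items]
    tagged: list[tuple[str, int, int, int]] = []  # chrom, start, end, member idx
    for m, (_, s) in enumerate(items):
        for iv in s:
            tagged.append((iv.chrom, iv.start, iv.end, m))
    tagged.sort()
    n_ct = len(items)
    rows: list[dict] = []

    def emit(chrom: str, start: int, end: int, members: set[int]) -> None:
        k = len(members)
        stratum = (
            "specific" if k == 1 else ("constitutive" if k == n_ct else "common")
        )
        row = {"chrom": chrom, "start": start, "end": end, "k": k, "stratum": stratum}
        for m, name in enumerate(names):
            row[name] = m in members
        rows.append(row)

    cur: tuple[str, int, int, set[int]] | None = None
    for chrom, start, end, m in tagged:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur = (cur[0], cur[1], max(cur[2], end), cur[3] | {m})
        else:
            if cur is not None:
                emit(*cur)
            cur = (chrom, start, end, {m})
    if cur is not None:
        emit(*cur)
    cols = ["chrom", "start", "end", "k", "stratum", *names]
    return pd.DataFrame(rows, columns=cols)
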