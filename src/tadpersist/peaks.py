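"""Classification of binding sites by persistence across conditions.

A reference site is *persistent* when it is present (any-overlap) in
every replicate of every condition, *lost* when present in every
baseline (wild-type and control-RNAi) replicate but absent from all
knockdown replicates, and *other* when replicate support is mixed.
*Gained* sites are knockdown peaks with no baseline counterpart and are
kept as a separate list — they are not part of the reference partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeLayout, IntervalSet, overlap_flags

__all__ = [
    "PeakCollection",
    "ClassifiedPeaks",
    "build_reference",
    "classify_persistence",
    "constitutive_fraction",
    "compare_persistent_sets",
]

LABELS = ("persistent", "lost", "other")


@dataclass
class PeakCollection:
    """condition name -> per-replicate peak sets, all on one layout."""

    conditions: dict[str, list[IntervalSet]]
    layout: GenomeLayout | None = None
    baseline_conditions: tuple[str, ...] = ("wildtype", "control_rnai")
    knockdown_condition: str = "ctcf_rnai"

    def __post_init__(self) -> None:
        for cond, reps in self.conditions.items():
            if not reps:
                raise ValueError(f"condition {cond!r} has no replicates")

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.conditions]
        if missing:
            raise ValueError(f"missing condition(s): {', '.join(missing)}")

    def replicate_items(self) -> list[tuple[str, int, IntervalSet]]:
        out = []
        for cond in self.conditions:
            for r, s in enumerate(self.conditions[cond]):
                out.append((cond, r, s))
        return out


def build_reference(
    collection: PeakCollection, mode: str = "union-of-baseline"
) -> IntervalSet:
    """Merge baseline replicate peaks into a single reference set.

    ``union-of-baseline`` fuses any overlapping peaks across baseline
    replicates; ``intersection`` additionally requires every merged
    interval to be supported by each baseline replicate."""
    collection.require(*collection.baseline_conditions)
    pooled: list = []
    for cond in collection.baseline_conditions:
        for s in collection.conditions[cond]:
            pooled.extend(s)
    if not pooled:
        raise ValueError("empty baseline: no peaks to build a reference from")
    union = IntervalSet(pooled, layout=collection.layout).merged()
    if mode == "union-of-baseline":
        return union
    if mode == "intersection":
        keep = np.ones(len(union), dtype=bool)
        for cond in collection.baseline_conditions:
            for s in collection.conditions[cond]:
                keep &= overlap_flags(union, s)
        return IntervalSet(
            [iv for iv, k in zip(union, keep) if k],
            layout=collection.layout,
            is_sorted=True,
        )
    raise ValueError(f"unknown reference mode {mode!r}")


@dataclass
class ClassifiedPeaks:
    reference: IntervalSet
    labels: np.ndarray  # one of LABELS per reference interval
    presence: pd.DataFrame  # bool, one column per condition/replicate
    gained: IntervalSet

    @property
    def counts(self) -> dict[str, int]:
        out = {lbl: int((self.labels == lbl).sum()) for lbl in LABELS}
        out["reference"] = len(self.reference)
        out["gained"] = len(self.gained)
        return out

    def subset(self, label: str) -> IntervalSet:
        return IntervalSet(
            [iv for iv, l in zip(self.reference, self.labels) if l == label],
            layout=self.reference.layout,
            is_sorted=True,
        )


def classify_persistence(
    collection: PeakCollection,
    min_overlap: int = 1,
    reference: IntervalSet | None = None,
    reference_mode: str = "union-of-baseline",
) -> ClassifiedPeaks:
    """Label every reference peak persistent / lost / other and extract
    the gained set.

    The labels partition the reference; the classification is invariant
    to replicate ordering and to peak order within files because it only
    consults per-replicate presence flags."""
    collection.require(*collection.baseline_conditions, collection.knockdown_condition)
    if reference is None:
        reference = build_reference(collection, mode=reference_mode)
    items = collection.replicate_items()
    presence = pd.DataFrame(
        {
            f"{cond}/rep{r + 1}": overlap_flags(reference, s, min_overlap)
            for cond, r, s in items
        }
    )
    base_cols = [
        c for c in presence.columns
        if c.split("/")[0] in collection.baseline_conditions
    ]
    kd_cols = [
        c for c in presence.columns
        if c.split("/")[0] == collection.knockdown_condition
    ]
    in_all = presence.all(axis=1).to_numpy()
    in_all_base = presence[base_cols].all(axis=1).to_numpy()
    in_no_kd = ~presence[kd_cols].any(axis=1).to_numpy()
    labels = np.where(
        in_all, "persistent", np.where(in_all_base & in_no_kd, "lost", "other")
    )
    # gained: merged knockdown peaks with no baseline support
    kd_pool: list = []
    for s in collection.conditions[collection.knockdown_condition]:
        kd_pool.extend(s)
    kd_union = IntervalSet(kd_pool, layout=collection.layout).merged()
    base_pool: list = []
    for cond in collection.baseline_conditions:
        for s in collection.conditions[cond]:
            base_pool.extend(s)
    base_union = IntervalSet(base_pool, layout=collection.layout).merged()
    hit = overlap_flags(kd_union, base_union, min_overlap)
    gained = IntervalSet(
        [iv for iv, h in zip(kd_union, hit) if not h],
        layout=collection.layout,
        is_sorted=True,
    )
    return ClassifiedPeaks(
        reference=reference, labels=labels, presence=presence, gained=gained
    )


def constitutive_fraction(
    classified: ClassifiedPeaks, panel: list[IntervalSet] | dict[str, IntervalSet]
) -> dict[str, dict]:
    """Per-label fraction of sites present (any-overlap) in every panel
    member.  Empty label classes report fraction None rather than 0."""
    sets = list(panel.values()) if isinstance(panel, dict) else list(panel)
    if not sets:
        raise ValueError("panel must be non-empty")
    in_all = np.ones(len(classified.reference), dtype=bool)
    for s in sets:
        in_all &= overlap_flags(classified.reference, s)
    out: dict[str, dict] = {}
    for lbl in LABELS:
        sel = classified.labels == lbl
        n = int(sel.sum())
        k = int((sel & in_all).sum())
        out[lbl] = {
            "n": n,
            "n_constitutive": k,
            "fraction": (k / n) if n else None,
        }
    return out


def compare_persistent_sets(set_a: IntervalSet, set_b: IntervalSet) -> dict[str, int]:
    """Venn-style overlap counts between two site sets.

    ``a_shared`` counts A intervals hitting >= 1 B interval (and vice
    versa for ``b_shared``); the two can differ when one interval spans
    several on the other side, so both are reported.  ``shared`` is an
    alias for ``a_shared``.  a_only + a_shared = |A| always."""
    a_hit = overlap_flags(set_a, set_b)
    b_hit = overlap_flags(set_b, set_a)
    return {
        "a_only": int((~a_hit).sum()),
        "a_shared": int(a_hit.sum()),
        "b_shared": int(b_hit.sum()),
        "b_only": int((~b_hit).sum()),
        "shared": int(a_hit.sum()),
    }
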