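"""Permutation, positional and gene-set enrichment statistics.

The observed/expected machinery mirrors the classic shuffle test: the
query intervals are re-placed uniformly at random across the allowed
chromosomes (lengths preserved, optionally mutually non-overlapping,
with a bounded number of rejection attempts per interval) and the
overlap count with a fixed test set is recomputed over ``n_shuffles``
permutations.  The ratio observed / mean(shuffled) is the enrichment;
the add-one empirical p-value is reported alongside as a convenience —
it is a property of the permutation scheme, not of any analytical null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    Occupancy,
    overlap_count,
)

__all__ = [
    "ShuffleConfig",
    "EnrichmentResult",
    "PositionalProfile",
    "shuffle_intervals",
    "observed_expected_ratio",
    "positional_profile",
    "welch_distance_test",
    "housekeeping_enrichment",
]


@dataclass(frozen=True)
class ShuffleConfig:
    n_shuffles: int = 1000
    max_tries: int = 10_000
    forbid_overlap: bool = True
    chromosomes: tuple[str, ...] | None = None  # default: all in layout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.max_tries < 1:
            raise ValueError("max_tries must be >= 1")


def shuffle_intervals(
    iset: IntervalSet,
    layout: GenomeLayout,
    config: ShuffleConfig,
    rng: np.random.Generator | None = None,
) -> IntervalSet:
    """Random re-placement of every interval, lengths preserved.

    Each interval independently picks a chromosome with probability
    proportional to its number of valid start positions there, then a
    uniform start.  With ``forbid_overlap`` a placement colliding with an
    already placed interval is rejected and redrawn, up to ``max_tries``
    attempts, after which the offending interval is reported."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chroms = list(config.chromosomes) if config.chromosomes else list(layout.names)
    lengths = np.array([layout.length(c) for c in chroms], dtype=np.int64)
    occ = Occupancy()
    out: list[GenomicInterval] = []
    for iv in iset:
        valid = np.maximum(lengths - iv.length + 1, 0)
        total = valid.sum()
        if total <= 0:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} fits on no allowed chromosome"
            )
        probs = valid / total
        placed = False
        for _ in range(config.max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            start = int(rng.integers(0, valid[ci]))
            end = start + iv.length
            if config.forbid_overlap and occ.conflicts(chroms[ci], start, end):
                continue
            if config.forbid_overlap:
                occ.add(chroms[ci], start, end)
            out.append(GenomicInterval(chroms[ci], start, end, name=iv.name))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place interval {iv.chrom}:{iv.start}-{iv.end} "
                f"within {config.max_tries} tries"
            )
    return IntervalSet(out, layout=layout).sorted()


@dataclass
class EnrichmentResult:
    observed: int
    expected_mean: float
    expected_sd: float
    ratio: float | None  # None when expected_mean == 0
    p_enrich: float
    p_deplete: float
    n_shuffles: int


def observed_expected_ratio(
    query: IntervalSet,
    test: IntervalSet,
    layout: GenomeLayout,
    config: ShuffleConfig,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Overlap enrichment of ``query`` against ``test`` versus the
    shuffle null.  The statistic is the number of query intervals hitting
    the test set; both tails use the add-one empirical estimator, so p is
    never exactly zero."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    observed = overlap_count(query, test)
    null = np.empty(config.n_shuffles, dtype=np.int64)
    for s in range(config.n_shuffles):
        shuffled = shuffle_intervals(query, layout, config, rng=rng)
        null[s] = overlap_count(shuffled, test)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if config.n_shuffles > 1 else 0.0
    ratio = (observed / mean) if mean > 0 else None
    n = config.n_shuffles
    p_enrich = (1 + int((null >= observed).sum())) / (n + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (n + 1)
    return EnrichmentResult(
        observed=observed,
        expected_mean=mean,
        expected_sd=sd,
        ratio=ratio,
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        n_shuffles=n,
    )


@dataclass
class PositionalProfile:
    offsets: np.ndarray  # bin-centre offsets from the anchor point (bp)
    density: np.ndarray  # mean feature count per anchor per bin
    anchor_coverage: np.ndarray  # anchors contributing to each bin
    n_anchors: int
    flank: int
    profile_bin: int


def positional_profile(
    features: IntervalSet,
    anchors: IntervalSet,
    flank: int = 500_000,
    profile_bin: int = 10_000,
    anchor_point: str = "midpoint",
    layout: GenomeLayout | None = None,
) -> PositionalProfile:
    """Average feature density in signed-offset bins around anchors.

    Feature midpoints are binned by offset from each anchor's midpoint
    (or start, with ``anchor_point='edge'``) into 2·flank/profile_bin
    bins.  When a layout is supplied, anchors truncated by a chromosome
    end contribute only their covered bins and each bin is normalised by
    the number of anchors actually covering it."""
    if len(anchors) == 0:
        raise ValueError("anchors must be non-empty")
    if (2 * flank) % profile_bin != 0:
        raise ValueError("2*flank must be a multiple of profile_bin")
    n_bins = 2 * flank // profile_bin
    counts = np.zeros(n_bins, dtype=np.float64)
    coverage = np.zeros(n_bins, dtype=np.float64)
    mids_by_chrom: dict[str, np.ndarray] = {}
    for iv in features:
        mids_by_chrom.setdefault(iv.chrom, [])  # type: ignore[arg-type]
    tmp: dict[str, list[int]] = {c: [] for c in mids_by_chrom}
    for iv in features:
        tmp[iv.chrom].append(iv.midpoint)
    mids_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tmp.items()}
    edges = np.arange(-flank, flank + profile_bin, profile_bin)
    for anchor in anchors:
        centre = anchor.midpoint if anchor_point == "midpoint" else anchor.start
        lo_bp, hi_bp = centre - flank, centre + flank
        if layout is not None:
            clen = layout.length(anchor.chrom)
            lo_cov = max(lo_bp, 0)
            hi_cov = min(hi_bp, clen)
        else:
            lo_cov, hi_cov = lo_bp, hi_bp
        b0 = (lo_cov - lo_bp) // profile_bin
        b1 = n_bins - (hi_bp - hi_cov) // profile_bin
        coverage[b0:b1] += 1
        mids = mids_by_chrom.get(anchor.chrom)
        if mids is None or mids.size == 0:
            continue
        sel = mids[(mids >= lo_cov) & (mids < hi_cov)]
        if sel.size:
            binned = (sel - lo_bp) // profile_bin
            np.add.at(counts, binned, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(coverage > 0, counts / coverage, 0.0)
    offsets = edges[:-1] + profile_bin // 2
    return PositionalProfile(
        offsets=offsets,
        density=density,
        anchor_coverage=coverage,
        n_anchors=len(anchors),
        flank=flank,
        profile_bin=profile_bin,
    )


def welch_distance_test(
    distances_a: np.ndarray, distances_b: np.ndarray
) -> dict[str, float]:
    """Welch two-sample t-test (unequal variances) on two distance
    samples, e.g. per-site distance-to-boundary for two site classes.

    Returns t, the Welch–Satterthwaite degrees of freedom and the
    two-sided p.  Samples with fewer than two values, or with zero
    variance in both groups, are rejected."""
    a = np.asarray(distances_a, dtype=np.float64)
    b = np.asarray(distances_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
        raise ValueError("undefined variance: both samples are constant")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(min(p, 1.0))}


def housekeeping_enrichment(
    genes: IntervalSet,
    flags: np.ndarray,
    strata: pd.DataFrame,
    window: int = 100_000,
    n_strata: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric housekeeping enrichment per conservation stratum.

    ``strata`` is the conservation table (columns chrom/start/end/k); a
    result row is produced for every presence count k = 1..n.  For each
    stratum, n = genes with any part within ``window`` of any stratum
    boundary, k = housekeeping genes among them, drawn against the
    population of all genes.  Both exact tails are reported; the
    Bonferroni factor is fixed at the number of strata tested (empty
    strata included, for conservativeness)."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(genes):
        raise ValueError("flags length must equal number of genes")
    if len(genes) == 0:
        raise ValueError("no genes supplied")
    from .genome import overlap_flags as _ovf

    ks = sorted(strata["k"].unique()) if len(strata) else []
    k_max = int(strata["k"].max()) if len(strata) else 0
    all_k = list(range(1, k_max + 1))
    n_tests = n_strata if n_strata is not None else max(len(all_k), 1)
    N = len(genes)
    K = int(flags.sum())
    rows: list[dict] = []
    for k in all_k:
        sub = strata[strata["k"] == k]
        if len(sub):
            widened = IntervalSet(
                [
                    GenomicInterval(r.chrom, max(0, r.start - window), r.end + window)
                    for r in sub.itertuples()
                ]
            )
            near = _ovf(genes, widened)
        else:
            near = np.zeros(N, dtype=bool)
        n = int(near.sum())
        kk = int((near & flags).sum())
        if n == 0:
            rows.append(
                {
                    "k": k, "N": N, "K": K, "n": 0, "k_hk": 0,
                    "fold": float("nan"),
                    "p_enrich": float("nan"), "p_deplete": float("nan"),
                    "p_enrich_bonf": float("nan"), "p_deplete_bonf": float("nan"),
                    "empty": True,
                }
            )
            continue
        fold = (kk / n) / (K / N) if K > 0 else float("nan")
        p_enrich = float(stats.hypergeom.sf(kk - 1, N, K, n))
        p_deplete = float(stats.hypergeom.cdf(kk, N, K, n))
        rows.append(
            {
                "k": k, "N": N, "K": K, "n": n, "k_hk": kk,
                "fold": fold,
                "p_enrich": p_enrich, "p_deplete": p_deplete,
                "p_enrich_bonf": min(1.0, p_enrich * n_tests),
                "p_deplete_bonf": min(1.0, p_deplete * n_tests),
                "empty": False,
            }
        )
    return pd.DataFrame(rows)
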