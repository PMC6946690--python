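"""Core genomic data types, interval algebra and plain-text I/O.

Coordinates are BED-style 0-based half-open everywhere in the package;
touching intervals do not overlap.  Strand is ignored throughout: every
intersection performed downstream (peaks vs boundaries, genes vs
boundaries, boundary vs boundary) is strandless.  1-based coordinates
appear only in display strings, never internally.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "GenomeLayout",
    "GenomicInterval",
    "IntervalSet",
    "ContactMatrix",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_contact_matrix",
    "write_contact_matrix",
    "overlap_flags",
    "overlap_count",
    "distance_to_nearest",
]


class FormatError(ValueError):
    """Raised when an input file is malformed (parse or validation failure)."""


# ---------------------------------------------------------------------------
# layout


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus the binning resolution.

    The layout is the coordinate frame for every other object: interval
    validation, bin arithmetic and contact-matrix shapes all derive from
    it.  ``bin_size`` may be left unset by :func:`read_chrom_sizes` and
    attached later with :meth:`with_bin_size`.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.bin_size is not None and self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")

    # -- basic accessors ----------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in layout") from None

    def rank(self, chrom: str) -> int:
        return self.names.index(chrom)

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return replace(self, bin_size=bin_size)

    # -- bin arithmetic -----------------------------------------------------
    def _require_bins(self) -> int:
        if self.bin_size is None:
            raise ValueError("layout has no bin_size attached")
        return self.bin_size

    def n_bins(self, chrom: str) -> int:
        bs = self._require_bins()
        return math.ceil(self.length(chrom) / bs)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_offset(self, chrom: str) -> int:
        """Global index of the chromosome's first bin (bins-BED ordering)."""
        off = 0
        for name in self.names:
            if name == chrom:
                return off
            off += self.n_bins(name)
        raise KeyError(f"chromosome {chrom!r} not in layout")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


def read_chrom_sizes(path: str | Path, bin_size: int | None = None) -> GenomeLayout:
    """Read a two-column ``name<TAB>length`` chrom.sizes file.

    Order is preserved; ``bin_size`` is attached if given (it is not part
    of the file format).
    """
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            name, length_s = parts
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {length_s!r}") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise FormatError(f"{path}: empty chrom.sizes file")
    return GenomeLayout(tuple(entries), bin_size=bin_size)


# ---------------------------------------------------------------------------
# intervals


@dataclass(frozen=True, order=False)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    ``sorted`` means ordered by (chromosome rank in the layout if one is
    attached, else lexicographic chromosome name; start; end).  Most
    operations sort lazily and cache per-chromosome coordinate arrays.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        layout: GenomeLayout | None = None,
        is_sorted: bool = False,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.layout = layout
        self.is_sorted = is_sorted
        self._arrays_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    # -- ordering -----------------------------------------------------------
    def _key(self, iv: GenomicInterval) -> tuple:
        if self.layout is not None and iv.chrom in self.layout.names:
            crank: object = self.layout.rank(iv.chrom)
        else:
            crank = iv.chrom
        return (isinstance(crank, str), crank, iv.start, iv.end)

    def sorted(self) -> "IntervalSet":
        if self.is_sorted:
            return self
        return IntervalSet(
            sorted(self.intervals, key=self._key), layout=self.layout, is_sorted=True
        )

    def validate(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        layout = layout or self.layout
        if layout is not None:
            for iv in self.intervals:
                if iv.chrom not in layout.names:
                    raise FormatError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > layout.length(iv.chrom):
                    raise FormatError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {layout.length(iv.chrom)}"
                    )
        return self

    # -- per-chromosome coordinate arrays ------------------------------------
    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Sorted (starts, ends) arrays per chromosome (cached)."""
        if self._arrays_cache is None:
            s = self.sorted()
            out: dict[str, tuple[list[int], list[int]]] = {}
            for iv in s:
                starts, ends = out.setdefault(iv.chrom, ([], []))
                starts.append(iv.start)
                ends.append(iv.end)
            self._arrays_cache = {
                c: (np.asarray(st, dtype=np.int64), np.asarray(en, dtype=np.int64))
                for c, (st, en) in out.items()
            }
        return self._arrays_cache

    # -- algebra --------------------------------------------------------------
    def merged(self) -> "IntervalSet":
        """Union of all intervals: overlapping (not merely touching)
        intervals are fused; names of fused members are joined with ';'."""
        s = self.sorted()
        out: list[GenomicInterval] = []
        cur: GenomicInterval | None = None
        names: list[str] = []
        for iv in s:
            if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
                if iv.name:
                    names.append(iv.name)
                if iv.end > cur.end:
                    cur = replace(cur, end=iv.end)
                continue
            if cur is not None:
                out.append(replace(cur, name=";".join(names) if names else cur.name))
            cur = iv
            names = [iv.name] if iv.name else []
        if cur is not None:
            out.append(replace(cur, name=";".join(names) if names else cur.name))
        return IntervalSet(out, layout=self.layout, is_sorted=True)

    def is_disjoint(self) -> bool:
        s = self.sorted()
        for prev, nxt in zip(s.intervals, s.intervals[1:]):
            if nxt.chrom == prev.chrom and nxt.start < prev.end:
                return False
        return True

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def complement(self, layout: GenomeLayout) -> "IntervalSet":
        """Genome minus the union of this set."""
        merged = self.merged()
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        out: list[GenomicInterval] = []
        for chrom in layout.names:
            pos = 0
            for iv in by_chrom.get(chrom, []):
                if iv.start > pos:
                    out.append(GenomicInterval(chrom, pos, iv.start))
                pos = max(pos, iv.end)
            clen = layout.length(chrom)
            if pos < clen:
                out.append(GenomicInterval(chrom, pos, clen))
        return IntervalSet(out, layout=layout, is_sorted=True)


# ---------------------------------------------------------------------------
# BED I/O

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(path: str | Path, layout: GenomeLayout | None = None) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    Columns 4 (name) and 5 (score) are captured when present; track,
    browser and comment lines are skipped.  Malformed records raise
    :class:`FormatError` naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if layout is not None:
                if chrom not in layout.names:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > layout.length(chrom):
                    raise FormatError(
                        f"{path}:{lineno}: end {end} exceeds chromosome length "
                        f"{layout.length(chrom)}"
                    )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score: float | None = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric score {parts[4]!r}") from None
            intervals.append(GenomicInterval(chrom, start, end, name=name, score=score))
    return IntervalSet(intervals, layout=layout).sorted()


def _fmt_score(score: float) -> str:
    return f"{int(score)}" if float(score).is_integer() else repr(float(score))


def write_bed(iset: IntervalSet, path: str | Path) -> None:
    """Write BED; columns 4-5 are emitted when any interval carries them."""
    has_name = any(iv.name is not None for iv in iset)
    has_score = any(iv.score is not None for iv in iset)
    with open(path, "w", encoding="utf-8") as fh:
        for iv in iset:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score:
                cols.append(iv.name if iv.name is not None else ".")
            if has_score:
                cols.append(_fmt_score(iv.score) if iv.score is not None else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# contact matrices


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome.

    ``mask[i]`` flags bins excluded from analysis (low coverage after
    balancing, or unmappable); masked rows/columns are zeroed.  ``biases``
    holds per-bin balancing factors so that raw ≈ balanced · bᵢ · bⱼ.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray | None = None
    biases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_bins,):
                raise ValueError("mask length must equal n_bins")
        if self.biases is not None:
            self.biases = np.asarray(self.biases, dtype=np.float64)
            if self.biases.shape != (self.n_bins,):
                raise ValueError("biases length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def read_contact_matrix(
    bins_path: str | Path, counts_path: str | Path, layout: GenomeLayout
) -> dict[str, ContactMatrix]:
    """Read a bins BED plus sparse upper-triangular count triples.

    The bins BED enumerates consecutive fixed-width bins and defines the
    global bin indexing used by the triples file; only the last bin of a
    chromosome may be short.  Triples must satisfy bin_i <= bin_j;
    missing pairs are zero and the lower triangle is mirrored.
    """
    bins = read_bed(bins_path, layout=None)
    # bins must appear in file order; read_bed sorts, so re-read raw order
    order: list[GenomicInterval] = []
    with open(bins_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            parts = line.split()
            order.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    del bins
    if not order:
        raise FormatError(f"{bins_path}: no bins")
    bs = layout._require_bins()
    # validate bin grid chromosome by chromosome
    chrom_slices: dict[str, tuple[int, int]] = {}
    i = 0
    while i < len(order):
        chrom = order[i].chrom
        j = i
        pos = 0
        while j < len(order) and order[j].chrom == chrom:
            iv = order[j]
            if iv.start != pos:
                raise FormatError(f"{bins_path}: bins not consecutive on {chrom} at {iv.start}")
            width = iv.end - iv.start
            last_on_chrom = j + 1 == len(order) or order[j + 1].chrom != chrom
            if width != bs and not last_on_chrom:
                raise FormatError(
                    f"{bins_path}: non-uniform bin width {width} on {chrom} (expected {bs})"
                )
            if width > bs:
                raise FormatError(f"{bins_path}: bin wider than bin_size on {chrom}")
            pos = iv.end
            j += 1
        if chrom in chrom_slices:
            raise FormatError(f"{bins_path}: chromosome {chrom} appears in two runs")
        if chrom not in layout.names:
            raise FormatError(f"{bins_path}: unknown chromosome {chrom!r}")
        chrom_slices[chrom] = (i, j)
        i = j
    matrices = {
        chrom: np.zeros((hi - lo, hi - lo), dtype=np.float64)
        for chrom, (lo, hi) in chrom_slices.items()
    }
    # global bin -> (chrom, local index)
    chrom_of = np.empty(len(order), dtype=object)
    local = np.empty(len(order), dtype=np.int64)
    for chrom, (lo, hi) in chrom_slices.items():
        chrom_of[lo:hi] = chrom
        local[lo:hi] = np.arange(hi - lo)
    n_total = len(order)
    with open(counts_path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{counts_path}:{lineno}: expected 3 columns")
            try:
                bi, bj, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError:
                raise FormatError(f"{counts_path}:{lineno}: non-numeric triple") from None
            if bi < 0 or bj < 0 or bi >= n_total or bj >= n_total:
                raise FormatError(f"{counts_path}:{lineno}: bin index out of range")
            if bi > bj:
                raise FormatError(
                    f"{counts_path}:{lineno}: lower-triangle triple ({bi},{bj})"
                )
            if c < 0:
                raise FormatError(f"{counts_path}:{lineno}: negative count {c}")
            if chrom_of[bi] != chrom_of[bj]:
                raise FormatError(
                    f"{counts_path}:{lineno}: inter-chromosomal pair "
                    f"({chrom_of[bi]},{chrom_of[bj]}); matrices are per-chromosome"
                )
            m = matrices[chrom_of[bi]]
            li, lj = local[bi], local[bj]
            m[li, lj] += c
            if li != lj:
                m[lj, li] += c
    return {
        chrom: ContactMatrix(chrom, bs, matrices[chrom]) for chrom in matrices
    }


def write_contact_matrix(
    matrices: Mapping[str, ContactMatrix],
    layout: GenomeLayout,
    bins_path: str | Path,
    counts_path: str | Path,
) -> None:
    """Emit the bins BED and upper-triangular non-zero count triples."""
    bs = layout._require_bins()
    offsets: dict[str, int] = {}
    with open(bins_path, "w", encoding="utf-8") as fh:
        off = 0
        for chrom in layout.names:
            if chrom not in matrices:
                continue
            offsets[chrom] = off
            n = matrices[chrom].n_bins
            clen = layout.length(chrom)
            for b in range(n):
                fh.write(f"{chrom}\t{b * bs}\t{min((b + 1) * bs, clen)}\n")
            off += n
    with open(counts_path, "w", encoding="utf-8") as fh:
        for chrom in layout.names:
            if chrom not in matrices:
                continue
            m = matrices[chrom].counts
            off = offsets[chrom]
            iu, ju = np.nonzero(np.triu(m))
            for li, lj in zip(iu, ju):
                c = m[li, lj]
                cs = f"{int(c)}" if float(c).is_integer() else repr(float(c))
                fh.write(f"{off + li}\t{off + lj}\t{cs}\n")


# ---------------------------------------------------------------------------
# interval algebra


def overlap_flags(
    query: IntervalSet, reference: IntervalSet, min_overlap: int = 1
) -> np.ndarray:
    """Boolean flag per query interval (in input order): overlaps at least
    one reference interval by >= ``min_overlap`` bp."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    flags = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(reference) == 0:
        return flags
    if min_overlap == 1:
        ref = reference.merged().chrom_arrays()
        for qi, iv in enumerate(query):
            arr = ref.get(iv.chrom)
            if arr is None:
                continue
            starts, ends = arr
            k = int(np.searchsorted(starts, iv.end, side="left")) - 1
            if k >= 0 and ends[k] > iv.start:
                flags[qi] = True
        return flags
    # general minimum-overlap: reference may not be merged (a single
    # reference interval must provide the full min_overlap)
    ref = reference.chrom_arrays()
    for qi, iv in enumerate(query):
        arr = ref.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr
        ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
        if np.any(ov >= min_overlap):
            flags[qi] = True
    return flags


def overlap_count(
    query: IntervalSet, reference: IntervalSet, min_overlap: int = 1
) -> int:
    """Number of query intervals overlapping >=1 reference interval by
    >= ``min_overlap`` bp; each query interval counts at most once."""
    return int(overlap_flags(query, reference, min_overlap).sum())


def distance_to_nearest(query: IntervalSet, anchors: IntervalSet) -> np.ndarray:
    """Distance (bp) from each query interval to the nearest anchor.

    0 on any overlap, otherwise the gap between the facing half-open
    boundaries.  Queries on chromosomes carrying no anchor get NaN
    (undefined, flagged rather than dropped).  Order follows the query's
    input order.
    """
    out = np.full(len(query), np.nan, dtype=np.float64)
    if len(anchors) == 0:
        return out
    anch = anchors.merged().chrom_arrays()
    for qi, iv in enumerate(query):
        arr = anch.get(iv.chrom)
        if arr is None:
            continue
        starts, ends = arr
        j = int(np.searchsorted(ends, iv.start, side="right"))
        if j < len(starts) and starts[j] < iv.end:
            out[qi] = 0.0
            continue
        best = math.inf
        if j > 0:
            best = min(best, iv.start - ends[j - 1])
        if j < len(starts):
            best = min(best, starts[j] - iv.end)
        out[qi] = float(best)
    return out


# ---------------------------------------------------------------------------
# shared occupancy helper (non-overlap bookkeeping for placement loops)


class Occupancy:
    """Per-chromosome sorted bookkeeping of placed disjoint intervals."""

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        k = bisect.bisect_left(starts, end)
        if k < len(starts) and starts[k] < end:
            return True
        if k > 0 and ends[k - 1] > start:
            return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        k = bisect.bisect_left(starts, start)
        starts.insert(k, start)
        ends.insert(k, end)
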