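"""Core genomic data types and interval arithmetic.

Every stage of the pipeline works on plain genomic intervals
(0-based, half-open, BED convention). This module provides the genome
layout (chromosome lengths plus the pericentromere/distal-euchromatin
partition), an interval container, and the handful of interval
operations the analysis needs: merge, intersect, coverage, reciprocal
overlap, sliding windows, random placement (shuffling) and
nearest-feature distances. The semantics mirror the corresponding
bedtools subcommands (merge, intersect, makewindows, shuffle, closest)
so results can be cross-checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "GenomeLayout",
    "merge_intervals",
    "intersect",
    "subtract",
    "complement",
    "coverage",
    "reciprocal_overlap",
    "sliding_windows",
    "shuffle_intervals",
    "distance_to_nearest",
    "count_overlapping",
    "overlap_bp_per_interval",
    "read_bed",
    "write_bed",
    "read_genome_file",
    "write_genome_file",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """An ordered collection of intervals with an optional label.

    May contain overlapping intervals unless produced by :func:`merge_intervals`.
    Iteration and indexing yield :class:`Interval` objects; bulk operations
    use per-chromosome numpy arrays internally.
    """

    def __init__(self, intervals: Iterable[Interval] = (), label: str = ""):
        self.intervals: list[Interval] = sorted(intervals)
        self.label = label

    @classmethod
    def from_arrays(
        cls,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        label: str = "",
    ) -> "IntervalSet":
        return cls(
            (Interval(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends)),
            label=label,
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, label={self.label!r})"

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one chromosome."""
        starts = np.array([iv.start for iv in self.intervals if iv.chrom == chrom])
        ends = np.array([iv.end for iv in self.intervals if iv.chrom == chrom])
        return starts, ends

    def total_bp(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return sum(iv.length for iv in self.intervals)

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)


@dataclass
class GenomeLayout:
    """Chromosome lengths plus the PER/DEU compartment partition.

    Each chromosome is split into a pericentromeric (PER) compartment,
    given explicitly, and its complement, the distal euchromatin (DEU).
    The two compartments partition the chromosome without overlap.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    per_intervals: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"chromosome {name!r} needs a positive length")
        for iv in self.per_intervals:
            L = self.chrom_lengths.get(iv.chrom)
            if L is None:
                raise ValueError(f"PER interval on unknown chromosome {iv.chrom!r}")
            if iv.end > L:
                raise ValueError(f"PER interval {iv} exceeds chromosome length {L}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    @property
    def deu_intervals(self) -> IntervalSet:
        """Distal euchromatin: the complement of PER within each chromosome."""
        return complement(self.per_intervals, self)

    def contains(self, iv: Interval) -> bool:
        L = self.chrom_lengths.get(iv.chrom)
        return L is not None and 0 <= iv.start < iv.end <= L

    def validate_set(self, s: IntervalSet) -> None:
        for iv in s:
            if not self.contains(iv):
                raise ValueError(f"interval {iv} outside genome bounds")


# ---------------------------------------------------------------------------
# interval arithmetic


def _merged_arrays(s: IntervalSet, chrom: str, gap: int = 0):
    """Merged (starts, ends) for one chromosome, closing gaps <= gap."""
    starts, ends = s.by_chrom(chrom)
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s0, e0 in zip(starts[1:], ends[1:]):
        if s0 - out_e[-1] <= gap:
            out_e[-1] = max(out_e[-1], e0)
        else:
            out_s.append(s0)
            out_e.append(e0)
    return np.array(out_s), np.array(out_e)


def merge_intervals(s: IntervalSet, gap: int = 0, genome: GenomeLayout | None = None) -> IntervalSet:
    """Merge overlapping/adjacent intervals; close gaps of up to ``gap`` bp.

    Output intervals are pairwise separated by more than ``gap`` bp and
    cover at least the union of the input. Equivalent to
    ``bedtools merge -d gap``.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if genome is not None:
        genome.validate_set(s)
    out: list[Interval] = []
    for chrom in s.chroms():
        ms, me = _merged_arrays(s, chrom, gap)
        out.extend(Interval(chrom, int(a), int(b)) for a, b in zip(ms, me))
    return IntervalSet(out, label=s.label)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact base-pair intersection of the unions of ``a`` and ``b``."""
    out: list[Interval] = []
    chroms_b = set(b.chroms())
    for chrom in a.chroms():
        if chrom not in chroms_b:
            continue
        as_, ae = _merged_arrays(a, chrom)
        bs, be = _merged_arrays(b, chrom)
        i = j = 0
        while i < len(as_) and j < len(bs):
            lo = max(as_[i], bs[j])
            hi = min(ae[i], be[j])
            if lo < hi:
                out.append(Interval(chrom, int(lo), int(hi)))
            if ae[i] < be[j]:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base pairs of ``a``'s union not covered by ``b``."""
    out: list[Interval] = []
    for chrom in a.chroms():
        as_, ae = _merged_arrays(a, chrom)
        bs, be = _merged_arrays(b, chrom)
        for s0, e0 in zip(as_, ae):
            cur = s0
            for bs0, be0 in zip(bs, be):
                if be0 <= cur:
                    continue
                if bs0 >= e0:
                    break
                if bs0 > cur:
                    out.append(Interval(chrom, int(cur), int(bs0)))
                cur = max(cur, be0)
                if cur >= e0:
                    break
            if cur < e0:
                out.append(Interval(chrom, int(cur), int(e0)))
    return IntervalSet(out)


def complement(s: IntervalSet, genome: GenomeLayout) -> IntervalSet:
    """Genomic complement of ``s`` over every chromosome of the genome."""
    whole = IntervalSet(
        Interval(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names
    )
    return subtract(whole, s)


def coverage(s: IntervalSet, genome: GenomeLayout) -> tuple[int, float]:
    """(bp covered by the union of ``s``, fraction of the genome covered)."""
    bp = merge_intervals(s).total_bp()
    return bp, bp / genome.total_length if genome.total_length else 0.0


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); 0 for different chromosomes."""
    inter = a.overlap_bp(b)
    if inter == 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def sliding_windows(genome: GenomeLayout, size: int, step: int) -> IntervalSet:
    """Sliding windows over every chromosome (bedtools makewindows behavior).

    A window starts at every multiple of ``step`` below the chromosome
    length; windows running past the chromosome end are clipped.
    """
    if not (0 < step <= size):
        raise ValueError("need size >= step > 0")
    out = []
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        for start in range(0, L, step):
            out.append(Interval(chrom, start, min(start + size, L)))
    return IntervalSet(out)


def shuffle_intervals(
    s: IntervalSet,
    genome: GenomeLayout,
    rng: np.random.Generator | int,
    same_chrom: bool = False,
    within: IntervalSet | None = None,
) -> IntervalSet:
    """Randomly re-place each interval, preserving its length.

    Placement is uniform over all allowed start positions genome-wide:
    the target chromosome is drawn with probability proportional to the
    number of start positions that fit the interval (bedtools shuffle
    default). ``same_chrom=True`` keeps each interval on its own
    chromosome (bedtools ``-chrom``). ``within`` restricts placement to a
    set of allowed intervals (each shuffled interval must fit entirely
    inside one of them, like ``-incl`` with full containment).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if within is not None:
        allowed = merge_intervals(within)
        regions = [(iv.chrom, iv.start, iv.end) for iv in allowed]
    else:
        regions = [(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names]

    lengths = s.lengths()
    if same_chrom:
        iv_chroms = np.array([iv.chrom for iv in s])
        slots = _placement_slots(lengths, regions, iv_chroms)
    else:
        slots = _placement_slots(lengths, regions)
    ks, starts = _draw_placements(lengths, regions, slots, rng)
    out = [
        Interval(regions[ks[i]][0], int(starts[i]), int(starts[i] + lengths[i]))
        for i in range(len(lengths))
    ]
    return IntervalSet(out, label=s.label)


def _placement_slots(
    lengths: np.ndarray,
    regions: Sequence[tuple[str, int, int]],
    iv_chroms: np.ndarray | None = None,
) -> np.ndarray:
    """slots[i, r]: number of start positions on region r fitting interval i."""
    region_sizes = np.array([e - st for _, st, e in regions], dtype=np.int64)
    slots = np.maximum(0, region_sizes[None, :] - lengths[:, None] + 1)
    if iv_chroms is not None:
        chrom_of = np.array([r[0] for r in regions])
        slots = np.where(chrom_of[None, :] == iv_chroms[:, None], slots, 0)
    totals = slots.sum(axis=1)
    if np.any(totals <= 0):
        bad = lengths[totals <= 0].max()
        raise ValueError(f"no placement fits interval of length {bad}")
    return slots


def _draw_placements(
    lengths: np.ndarray,
    regions: Sequence[tuple[str, int, int]],
    slots: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement draw: (region index, genomic start) per interval."""
    n = len(lengths)
    totals = slots.sum(axis=1)
    cum = np.cumsum(slots, axis=1)
    # draw the region by inverse CDF, then the offset uniformly within it
    pick = (rng.random(n) * totals).astype(np.int64)
    ks = (cum.T > pick).argmax(axis=0) if n else np.array([], dtype=int)
    offs = (rng.random(n) * slots[np.arange(n), ks]).astype(np.int64)
    region_starts = np.array([r[1] for r in regions], dtype=np.int64)
    return ks, region_starts[ks] + offs


#: sentinel for "no feature on this chromosome"
NO_NEIGHBOR = np.nan


def distance_to_nearest(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Signed distance from each interval of ``a`` to its nearest ``b`` feature.

    0 when overlapping; positive when the nearest feature lies downstream
    (higher coordinates), negative upstream; magnitude is the gap between
    the closest edges. NaN when chromosome has no ``b`` feature.
    """
    dists = np.full(len(a), NO_NEIGHBOR)
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in b.chroms():
        merged[chrom] = _merged_arrays(b, chrom)
    for i, iv in enumerate(a):
        if iv.chrom not in merged:
            continue
        bs, be = merged[iv.chrom]
        # nearest on the left: largest end <= ... ; overlap check first
        j = np.searchsorted(bs, iv.end, side="left")
        if j > 0 and be[j - 1] > iv.start:
            dists[i] = 0
            continue
        best = None
        if j > 0:  # nearest feature entirely to the left
            best = -(iv.start - be[j - 1])
        if j < len(bs):  # nearest feature to the right
            d = bs[j] - iv.end
            if best is None or d < abs(best) or (d == abs(best) and d >= 0):
                best = d
        dists[i] = best
    return dists


def count_overlapping(a: IntervalSet, b: IntervalSet) -> int:
    """Number of intervals in ``a`` overlapping >= 1 bp of ``b``'s union."""
    merged = {chrom: _merged_arrays(b, chrom) for chrom in b.chroms()}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in a:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    n = 0
    for chrom, pairs in by_chrom.items():
        if chrom not in merged:
            continue
        bs, be = merged[chrom]
        arr = np.array(pairs, dtype=np.int64)
        j = np.searchsorted(bs, arr[:, 1], side="left")
        ok = j > 0
        hit = np.zeros(len(arr), dtype=bool)
        hit[ok] = be[j[ok] - 1] > arr[ok, 0]
        n += int(hit.sum())
    return n


def overlaps_mask(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean per interval of ``a``: does it overlap ``b``'s union >= 1 bp."""
    out = np.zeros(len(a), dtype=bool)
    merged = {chrom: _merged_arrays(b, chrom) for chrom in b.chroms()}
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(a):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        if chrom not in merged:
            continue
        bs, be = merged[chrom]
        starts = np.array([a[i].start for i in idx])
        ends = np.array([a[i].end for i in idx])
        j = np.searchsorted(bs, ends, side="left")
        ok = j > 0
        hit = np.zeros(len(idx), dtype=bool)
        hit[ok] = be[j[ok] - 1] > starts[ok]
        out[np.array(idx)] = hit
    return out


def overlap_bp_per_interval(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """bp of ``b``'s union covered by each interval of ``a``."""
    out = np.zeros(len(a), dtype=np.int64)
    merged = {chrom: _merged_arrays(b, chrom) for chrom in b.chroms()}
    for i, iv in enumerate(a):
        if iv.chrom not in merged:
            continue
        bs, be = merged[iv.chrom]
        lo = np.searchsorted(be, iv.start, side="right")
        hi = np.searchsorted(bs, iv.end, side="left")
        if hi > lo:
            inter = np.minimum(be[lo:hi], iv.end) - np.maximum(bs[lo:hi], iv.start)
            out[i] = inter.sum()
    return out


# ---------------------------------------------------------------------------
# BED / genome-file IO (tab-separated, 0-based half-open)


def read_bed(path: str | Path, label: str = "") -> IntervalSet:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return IntervalSet(out, label=label or Path(path).stem)


def read_bed_named(path: str | Path) -> dict[str, IntervalSet]:
    """Read a BED file whose name column groups intervals into tracks."""
    tracks: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            tracks.setdefault(name, []).append(Interval(f[0], int(f[1]), int(f[2])))
    return {name: IntervalSet(ivs, label=name) for name, ivs in tracks.items()}


def write_bed(
    s: IntervalSet,
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(s):
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                row.append(str(names[i]) if names is not None else ".")
                row.append(str(scores[i]) if scores is not None else ".")
            fh.write("\t".join(row) + "\n")


def read_genome_file(path: str | Path, per_bed: str | Path | None = None) -> GenomeLayout:
    """Read a bedtools-style two-column chrom/length file, plus optional PER BED."""
    names, lengths = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, length = line.split("\t")[:2]
            names.append(chrom)
            lengths[chrom] = int(length)
    per = read_bed(per_bed, label="PER") if per_bed else IntervalSet(label="PER")
    return GenomeLayout(names, lengths, per)


def write_genome_file(genome: GenomeLayout, path: str | Path, per_bed: str | Path | None = None) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.chrom_lengths[chrom]}\n")
    if per_bed is not None:
        write_bed(genome.per_intervals, per_bed)
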