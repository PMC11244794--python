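"""CO regions, per-hybrid coldspots, conserved coldspots and clustering.

The CO landscape of each hybrid is reduced to *CO regions*: 10 kb
sliding windows (5 kb step) containing at least one crossover, merged
when closer than 1 kb. The complement gaps of at least 1 Mb are the
hybrid's *coldspots*, provided they contain segregating markers (a gap
without markers could simply be invisible to the assay and is reported
separately, not catalogued).

Coldspots from all hybrids are then clustered by genomic position and
size: first grouped at >= 1 bp overlap, then connected at >= 50%
reciprocal overlap; loosely spanning components are refined by
complete-linkage hierarchical clustering on a Jaccard-type distance,
cutting the dendrogram at 0.3. Clusters occurring in a single hybrid
are *unique*, in two or more *shared*. Base pairs without CO in every
hybrid are *conserved coldspots*, computed independently as the direct
intersection of the per-hybrid coldspot sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .crossover_detection import CrossoverEvent, MarkerSet, events_to_intervals
from .genome_model import (
    GenomeLayout,
    Interval,
    IntervalSet,
    complement,
    coverage,
    intersect,
    merge_intervals,
    overlap_bp_per_interval,
    reciprocal_overlap,
)

__all__ = [
    "CoRegionSet",
    "Coldspot",
    "ColdspotCluster",
    "build_co_regions",
    "detect_coldspots",
    "conserved_coldspots",
    "jaccard_distance",
    "cluster_coldspots",
    "marey_rate",
    "coldspots_to_frame",
    "clusters_to_frame",
    "read_genetic_map",
]


@dataclass
class CoRegionSet:
    """Merged CO-containing windows of one hybrid."""

    hybrid_id: str
    intervals: IntervalSet
    window_counts: pd.DataFrame | None = None  # per selected window CO counts

    def coverage(self, genome: GenomeLayout) -> tuple[int, float]:
        return coverage(self.intervals, genome)


@dataclass
class Coldspot:
    """A >= 1 Mb CO-free region of one hybrid, supported by markers."""

    hybrid_id: str
    interval: Interval
    marker_count: int
    deu_bp: int = 0
    per_bp: int = 0

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass
class ColdspotCluster:
    """A cross-hybrid cluster of coldspots with its unique/shared class."""

    cluster_id: int
    members: list[Coldspot]
    component_id: int
    reclustered: bool = False

    @property
    def hybrids(self) -> list[str]:
        return sorted({c.hybrid_id for c in self.members})

    @property
    def cls(self) -> str:
        return "unique" if len(self.hybrids) == 1 else "shared"

    @property
    def span(self) -> Interval:
        chrom = self.members[0].interval.chrom
        return Interval(
            chrom,
            min(c.interval.start for c in self.members),
            max(c.interval.end for c in self.members),
        )


def build_co_regions(
    events: Sequence[CrossoverEvent],
    genome: GenomeLayout,
    window: int = 10_000,
    step: int = 5_000,
    merge_gap: int = 1_000,
    hybrid_id: str | None = None,
) -> CoRegionSet:
    """CO regions: CO-containing sliding windows merged within ``merge_gap``.

    Windows are enumerated implicitly: a window ``[i*step, i*step+window)``
    is selected iff it overlaps at least one CO interval.
    """
    hybrid = hybrid_id if hybrid_id is not None else (events[0].hybrid_id if events else "")
    selected: dict[str, set[int]] = {}
    for e in events:
        L = genome.chrom_lengths[e.chrom]
        # windows overlapping [start, end): i*step < end and i*step + window > start
        lo = max(0, -(-(e.left_marker - window + 1) // step))  # ceil
        hi = (e.right_marker - 1) // step  # inclusive
        hi = min(hi, (L - 1) // step)
        idx = selected.setdefault(e.chrom, set())
        idx.update(range(lo, hi + 1))
    rows = []
    intervals = []
    counts: dict[tuple[str, int], int] = {}
    for e in events:
        lo = max(0, -(-(e.left_marker - window + 1) // step))
        hi = min((e.right_marker - 1) // step, (genome.chrom_lengths[e.chrom] - 1) // step)
        for i in range(lo, hi + 1):
            counts[(e.chrom, i)] = counts.get((e.chrom, i), 0) + 1
    for chrom, idx in selected.items():
        L = genome.chrom_lengths[chrom]
        for i in sorted(idx):
            start = i * step
            end = min(start + window, L)
            intervals.append(Interval(chrom, start, end))
            rows.append((chrom, start, end, counts[(chrom, i)]))
    merged = merge_intervals(IntervalSet(intervals), gap=merge_gap)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cos"])
    return CoRegionSet(hybrid_id=hybrid, intervals=merged, window_counts=frame)


def detect_coldspots(
    regions: CoRegionSet,
    genome: GenomeLayout,
    markers: MarkerSet | None = None,
    min_size: int = 1_000_000,
) -> tuple[list[Coldspot], list[Coldspot]]:
    """CO-free gaps >= ``min_size`` per chromosome, annotated with markers.

    Returns (catalogued coldspots, zero-marker gaps). Gaps are clipped to
    chromosome ends; terminal gaps count. Without a marker set, every
    gap is catalogued with ``marker_count = -1`` (unknown).
    """
    gaps = complement(regions.intervals, genome)
    per = genome.per_intervals
    kept: list[Coldspot] = []
    flagged: list[Coldspot] = []
    for iv in gaps:
        if iv.length < min_size:
            continue
        n_markers = (
            markers.count_in(iv.chrom, iv.start, iv.end) if markers is not None else -1
        )
        one = IntervalSet([iv])
        per_bp = int(overlap_bp_per_interval(one, per)[0]) if len(per) else 0
        cs = Coldspot(
            hybrid_id=regions.hybrid_id,
            interval=iv,
            marker_count=n_markers,
            deu_bp=iv.length - per_bp,
            per_bp=per_bp,
        )
        if n_markers == 0:
            flagged.append(cs)
        else:
            kept.append(cs)
    return kept, flagged


def conserved_coldspots(
    per_hybrid: dict[str, Sequence[Coldspot]], genome: GenomeLayout
) -> tuple[IntervalSet, dict]:
    """Base pairs coldspot in every provided hybrid, with DEU/PER split."""
    sets = []
    for hybrid, spots in per_hybrid.items():
        sets.append(IntervalSet((c.interval for c in spots), label=hybrid))
    if not sets or any(len(s) == 0 for s in sets):
        return IntervalSet(label="conserved"), {
            "n_hybrids": len(sets),
            "bp": 0,
            "fraction": 0.0,
            "deu_bp": 0,
            "per_bp": 0,
        }
    conserved = merge_intervals(sets[0])
    for s in sets[1:]:
        conserved = intersect(conserved, s)
    bp, frac = coverage(conserved, genome)
    per_bp = coverage(intersect(conserved, genome.per_intervals), genome)[0] if len(genome.per_intervals) else 0
    conserved.label = "conserved"
    return conserved, {
        "n_hybrids": len(sets),
        "bp": bp,
        "fraction": frac,
        "deu_bp": bp - per_bp,
        "per_bp": per_bp,
    }


def jaccard_distance(i: Interval, j: Interval) -> float:
    """d = (f - 2I)/(f - I) with f = |i|+|j|, I = |i∩j|; equals 1 - Jaccard."""
    if i.chrom != j.chrom:
        return 1.0
    inter = i.overlap_bp(j)
    f = i.length + j.length
    return (f - 2 * inter) / (f - inter)


def cluster_coldspots(
    coldspots: Sequence[Coldspot],
    span_ratio: float = 1.5,
    edge_reciprocal_overlap: float = 0.5,
    cut_height: float = 0.3,
) -> list[ColdspotCluster]:
    """Cluster coldspots from all hybrids into unique/shared clusters.

    1. Transitive closure of >= 1 bp overlap defines coarse groups.
    2. Within a group, coldspots are connected when their reciprocal
       overlap reaches ``edge_reciprocal_overlap``; connected components
       are taken.
    3. A component spanning at least ``span_ratio`` times its smallest
       member (span = rightmost end - leftmost start) is refined by
       complete-linkage hierarchical clustering on the pairwise
       :func:`jaccard_distance`, cutting the dendrogram strictly below
       ``cut_height``; otherwise it is one cluster.

    Input order does not matter: members are canonically sorted before
    linkage, so the result is deterministic.
    """
    spots = sorted(
        coldspots, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.hybrid_id)
    )
    clusters: list[ColdspotCluster] = []
    next_cluster = 0
    next_component = 0

    # step 1: coarse grouping at >= 1 bp overlap (sweep per chromosome)
    groups: list[list[Coldspot]] = []
    cur: list[Coldspot] = []
    cur_end = -1
    cur_chrom = None
    for cs in spots:
        iv = cs.interval
        if cur and iv.chrom == cur_chrom and iv.start < cur_end:
            cur.append(cs)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                groups.append(cur)
            cur = [cs]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cur:
        groups.append(cur)

    for group in groups:
        # step 2: reciprocal-overlap graph and its connected components
        g = nx.Graph()
        g.add_nodes_from(range(len(group)))
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                if (
                    reciprocal_overlap(group[a].interval, group[b].interval)
                    >= edge_reciprocal_overlap
                ):
                    g.add_edge(a, b)
        for comp in sorted(nx.connected_components(g), key=min):
            members = [group[i] for i in sorted(comp)]
            component_id = next_component
            next_component += 1
            span = max(c.interval.end for c in members) - min(
                c.interval.start for c in members
            )
            smallest = min(c.length for c in members)
            if len(members) > 1 and span >= span_ratio * smallest:
                # step 3: refine by complete linkage on jaccard distance
                n = len(members)
                dm = np.zeros((n, n))
                for a in range(n):
                    for b in range(a + 1, n):
                        dm[a, b] = dm[b, a] = jaccard_distance(
                            members[a].interval, members[b].interval
                        )
                Z = linkage(squareform(dm, checks=False), method="complete")
                # keep merges with linkage distance strictly below the cut
                labels = fcluster(Z, t=np.nextafter(cut_height, 0), criterion="distance")
                for lab in sorted(set(labels)):
                    sub = [members[i] for i in range(n) if labels[i] == lab]
                    clusters.append(
                        ColdspotCluster(next_cluster, sub, component_id, reclustered=True)
                    )
                    next_cluster += 1
            else:
                clusters.append(ColdspotCluster(next_cluster, members, component_id))
                next_cluster += 1
    return clusters


def marey_rate(genetic_map: pd.DataFrame) -> pd.DataFrame:
    """Local recombination rate (cM/Mb) from a Marey map.

    ``genetic_map`` has columns ``bp`` and ``cM``. Pairs breaking
    monotonicity (cM decreasing with bp) are flagged and excluded; the
    rate is the finite-difference slope between consecutive retained
    markers, assigned to the inter-marker interval.
    """
    gm = genetic_map.sort_values("bp").reset_index(drop=True)
    keep = []
    best = -np.inf
    flags = []
    for i, cm in enumerate(gm["cM"]):
        if cm >= best:
            keep.append(i)
            best = cm
        else:
            flags.append(i)
    sub = gm.iloc[keep].reset_index(drop=True)
    rows = []
    for i in range(len(sub) - 1):
        dbp = sub.loc[i + 1, "bp"] - sub.loc[i, "bp"]
        if dbp <= 0:
            continue
        dcm = sub.loc[i + 1, "cM"] - sub.loc[i, "cM"]
        rows.append(
            (int(sub.loc[i, "bp"]), int(sub.loc[i + 1, "bp"]), dcm / dbp * 1e6)
        )
    out = pd.DataFrame(rows, columns=["start", "end", "cM_per_Mb"])
    out.attrs["n_flagged"] = len(flags)
    return out


# ---------------------------------------------------------------------------
# tables / IO


def coldspots_to_frame(coldspots: Sequence[Coldspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.hybrid_id,
                c.interval.chrom,
                c.interval.start,
                c.interval.end,
                c.length,
                c.marker_count,
                c.deu_bp,
                c.per_bp,
            )
            for c in coldspots
        ],
        columns=["hybrid", "chrom", "start", "end", "length", "markers", "deu_bp", "per_bp"],
    )


def clusters_to_frame(clusters: Sequence[ColdspotCluster]) -> pd.DataFrame:
    rows = []
    for cl in clusters:
        for c in cl.members:
            rows.append(
                (
                    cl.cluster_id,
                    cl.cls,
                    cl.component_id,
                    len(cl.members),
                    len(cl.hybrids),
                    c.hybrid_id,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "class",
            "component_id",
            "n_members",
            "n_hybrids",
            "hybrid",
            "chrom",
            "start",
            "end",
        ],
    )


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (bp, cM)."""
    return pd.read_csv(path, sep="\t", names=["bp", "cM"], comment="#", header=0)
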