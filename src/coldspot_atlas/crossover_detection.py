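"""Crossover calling from phased linked-read molecules.

A pooled-gamete linked-read library yields long DNA molecules, each from
a single gamete. After phasing against the segregating SNP markers of a
hybrid, every molecule is an ordered run of haplotype calls (parent A,
parent B, or wildcard where phasing was ambiguous). A single switch from
one parental haplotype to the other along a molecule marks a meiotic
crossover (CO); the CO is localized to the interval between the two
flanking markers, and its *resolution* is defined as 1/distance between
those markers.

This module segments molecules into haplotype blocks, calls at most one
CO per molecule, and applies the quality filters: block marker/read
support, molecule span (to guard against multiple molecules sharing a
droplet barcode), wildcard fraction, and a resolution cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_model import Interval, IntervalSet

__all__ = [
    "MarkerSet",
    "MoleculeCall",
    "HaplotypeBlock",
    "CrossoverEvent",
    "CoFilterParams",
    "segment_haplotypes",
    "call_crossover",
    "detect_crossovers",
    "filter_high_resolution",
    "read_molecules_tsv",
    "write_molecules_tsv",
    "read_markers_tsv",
    "read_markers_vcf",
    "write_markers_tsv",
    "events_to_frame",
    "events_to_intervals",
    "write_events",
    "read_events_tsv",
    "summarize_events",
]

WILDCARD = "?"


class MarkerSet:
    """Segregating SNP markers per chromosome.

    Positions are stored 0-based internally (VCF input is converted).
    Markers must be biallelic and strictly increasing per chromosome;
    upstream quality filtering (heterozygous parents, homopolymers,
    copy-number regions) is assumed already done.
    """

    def __init__(self, positions: dict[str, np.ndarray], alleles: dict[str, tuple] | None = None):
        self.positions = {}
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions on {chrom} not strictly increasing")
            self.positions[chrom] = pos
        self.alleles = alleles or {}

    def __len__(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def count_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass
class MoleculeCall:
    """One phased molecule: ordered marker positions with haplotype calls."""

    molecule_id: str
    chrom: str
    positions: np.ndarray  # bp, strictly increasing
    haplotypes: np.ndarray  # 'A' | 'B' | '?' per marker
    reads: np.ndarray  # supporting read count per marker

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=object)
        self.reads = np.asarray(self.reads, dtype=np.int64)
        if np.any(np.diff(self.positions) < 0):
            raise ValueError(f"molecule {self.molecule_id}: positions not sorted")

    @property
    def span(self) -> int:
        return int(self.positions[-1] - self.positions[0]) if len(self.positions) else 0


@dataclass
class HaplotypeBlock:
    haplotype: str
    positions: np.ndarray
    n_markers: int
    n_reads: int

    @property
    def first(self) -> int:
        return int(self.positions[0])

    @property
    def last(self) -> int:
        return int(self.positions[-1])


@dataclass
class CrossoverEvent:
    """A crossover localized between two flanking markers.

    ``resolution = 1 / distance`` where distance is the bp gap between
    the bounding markers; smaller intervals are better resolved.
    """

    hybrid_id: str
    chrom: str
    left_marker: int
    right_marker: int
    molecule_id: str
    block_stats: tuple = ()  # ((markers, reads) left block, (markers, reads) right)

    @property
    def distance(self) -> int:
        return self.right_marker - self.left_marker

    @property
    def resolution(self) -> float:
        return 1.0 / self.distance

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.left_marker, self.right_marker)


@dataclass
class CoFilterParams:
    """Quality filters applied to putative recombinant molecules.

    ``max_molecule_span`` guards against chimeric "molecules" assembled
    from multiple real molecules sharing one droplet barcode; set it to
    the upper tail of the expected molecule-length distribution.
    """

    min_resolution: float = 0.001  # bp^-1, i.e. bounding distance < 1 kb
    max_molecule_span: int = 200_000
    min_markers_per_block: int = 3
    min_reads_per_block: int = 2
    max_wildcard_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(
            self.min_resolution,
            self.max_molecule_span,
            self.min_markers_per_block,
            self.min_reads_per_block,
            self.max_wildcard_fraction,
        ) < 0:
            raise ValueError("filter parameters must be >= 0")


def segment_haplotypes(mol: MoleculeCall) -> tuple[list[HaplotypeBlock], int]:
    """Split a molecule into maximal runs of identical haplotype.

    Wildcard calls belong to no block; their count is returned alongside.
    """
    blocks: list[HaplotypeBlock] = []
    wildcards = 0
    cur_hap = None
    cur_pos: list[int] = []
    cur_reads = 0
    for pos, hap, reads in zip(mol.positions, mol.haplotypes, mol.reads):
        if hap == WILDCARD:
            wildcards += 1
            continue
        if hap != cur_hap:
            if cur_hap is not None:
                blocks.append(
                    HaplotypeBlock(cur_hap, np.array(cur_pos), len(cur_pos), cur_reads)
                )
            cur_hap, cur_pos, cur_reads = hap, [], 0
        cur_pos.append(int(pos))
        cur_reads += int(reads)
    if cur_hap is not None:
        blocks.append(HaplotypeBlock(cur_hap, np.array(cur_pos), len(cur_pos), cur_reads))
    return blocks, wildcards


def call_crossover(
    mol: MoleculeCall,
    params: CoFilterParams,
    hybrid_id: str = "",
) -> tuple[CrossoverEvent | None, str]:
    """Call at most one CO from a molecule; returns (event, reason).

    An event is emitted iff the molecule segments into exactly two
    haplotype blocks, each with enough markers and reads, the molecule
    span is within the expected molecule size, and the wildcard fraction
    is acceptable. Molecules with >= 3 blocks (double switches,
    gene-conversion-like or noisy) are discarded whole.
    """
    blocks, wildcards = segment_haplotypes(mol)
    n_called = sum(b.n_markers for b in blocks)
    if n_called < 2:
        return None, "too-few-markers"
    if len(blocks) == 1:
        return None, "non-recombinant"
    if len(blocks) > 2:
        return None, "multi-switch"
    total = n_called + wildcards
    if total and wildcards / total > params.max_wildcard_fraction:
        return None, "wildcard-fraction"
    if mol.span > params.max_molecule_span:
        return None, "span"
    left, right = blocks
    for b in (left, right):
        if b.n_markers < params.min_markers_per_block:
            return None, "block-markers"
        if b.n_reads < params.min_reads_per_block:
            return None, "block-reads"
    event = CrossoverEvent(
        hybrid_id=hybrid_id,
        chrom=mol.chrom,
        left_marker=left.last,
        right_marker=right.first,
        molecule_id=mol.molecule_id,
        block_stats=((left.n_markers, left.n_reads), (right.n_markers, right.n_reads)),
    )
    return event, "ok"


def detect_crossovers(
    molecules: Iterable[MoleculeCall],
    params: CoFilterParams | None = None,
    hybrid_id: str = "",
) -> tuple[list[CrossoverEvent], dict[str, int]]:
    """Call COs over a molecule pool; returns events and per-reason tallies."""
    params = params or CoFilterParams()
    events: list[CrossoverEvent] = []
    tally: dict[str, int] = {}
    for mol in molecules:
        event, reason = call_crossover(mol, params, hybrid_id=hybrid_id)
        tally[reason] = tally.get(reason, 0) + 1
        if event is not None:
            events.append(event)
    return events, tally


def filter_high_resolution(
    events: Sequence[CrossoverEvent], threshold: float = 0.001
) -> list[CrossoverEvent]:
    """Keep events with resolution strictly above ``threshold``.

    The default keeps COs whose bounding markers are less than 1 kb
    apart; a stricter 0.002 grade (< 500 bp) is used for motif-level
    localisation.
    """
    return [e for e in events if e.resolution > threshold]


# ---------------------------------------------------------------------------
# IO


def read_molecules_tsv(path: str | Path) -> list[MoleculeCall]:
    """Read the molecule table: molecule_id, chrom, marker_pos, haplotype, n_reads."""
    df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str, "haplotype": str})
    mols = []
    for (mid, chrom), grp in df.groupby(["molecule_id", "chrom"], sort=False):
        grp = grp.sort_values("marker_pos")
        mols.append(
            MoleculeCall(
                molecule_id=str(mid),
                chrom=str(chrom),
                positions=grp["marker_pos"].to_numpy(),
                haplotypes=grp["haplotype"].to_numpy(),
                reads=grp["n_reads"].to_numpy(),
            )
        )
    return mols


def write_molecules_tsv(molecules: Iterable[MoleculeCall], path: str | Path) -> None:
    rows = []
    for mol in molecules:
        for pos, hap, reads in zip(mol.positions, mol.haplotypes, mol.reads):
            rows.append((mol.molecule_id, mol.chrom, int(pos), hap, int(reads)))
    pd.DataFrame(
        rows, columns=["molecule_id", "chrom", "marker_pos", "haplotype", "n_reads"]
    ).to_csv(path, sep="\t", index=False)


def read_markers_tsv(path: str | Path) -> MarkerSet:
    """Markers TSV with columns chrom, pos (0-based), ref, alt."""
    df = pd.read_csv(path, sep="\t")
    positions = {
        str(chrom): np.sort(grp["pos"].to_numpy())
        for chrom, grp in df.groupby("chrom", sort=False)
    }
    return MarkerSet(positions)


def read_markers_vcf(path: str | Path) -> MarkerSet:
    """Read biallelic PASS SNPs from a VCF (1-based, converted to 0-based)."""
    from cyvcf2 import VCF

    positions: dict[str, list[int]] = {}
    for rec in VCF(str(path)):
        if rec.FILTER is not None:  # None == PASS
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        positions.setdefault(rec.CHROM, []).append(rec.POS - 1)
    return MarkerSet({c: np.array(sorted(set(p))) for c, p in positions.items()})


def write_markers_tsv(markers: MarkerSet, path: str | Path) -> None:
    rows = [
        (chrom, int(pos), "A", "T")
        for chrom, arr in markers.positions.items()
        for pos in arr
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def events_to_frame(events: Sequence[CrossoverEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "hybrid": [e.hybrid_id for e in events],
            "chrom": [e.chrom for e in events],
            "start": [e.left_marker for e in events],
            "end": [e.right_marker for e in events],
            "distance": [e.distance for e in events],
            "resolution": [e.resolution for e in events],
            "molecule_id": [e.molecule_id for e in events],
        }
    )


def events_to_intervals(events: Sequence[CrossoverEvent], label: str = "") -> IntervalSet:
    return IntervalSet(
        (Interval(e.chrom, e.left_marker, e.right_marker) for e in events), label=label
    )


def write_events(events: Sequence[CrossoverEvent], tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Write the event table; optionally BED6 (name=molecule, score~resolution)."""
    events_to_frame(events).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for e in events:
                score = round(1e6 * e.resolution)
                fh.write(
                    f"{e.chrom}\t{e.left_marker}\t{e.right_marker}\t"
                    f"{e.molecule_id}\t{score}\t.\n"
                )


def read_events_tsv(path: str | Path) -> list[CrossoverEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        CrossoverEvent(
            hybrid_id=str(r.hybrid),
            chrom=str(r.chrom),
            left_marker=int(r.start),
            right_marker=int(r.end),
            molecule_id=str(getattr(r, "molecule_id", "")),
        )
        for r in df.itertuples()
    ]


def summarize_events(events: Sequence[CrossoverEvent]) -> dict:
    """Per-hybrid summary: CO count and mean +/- sd bounding distance (kb)."""
    if not events:
        return {"n_events": 0, "mean_distance_kb": np.nan, "sd_distance_kb": np.nan}
    d = np.array([e.distance for e in events], dtype=float) / 1e3
    return {
        "n_events": len(events),
        "mean_distance_kb": float(d.mean()),
        "sd_distance_kb": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
    }
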