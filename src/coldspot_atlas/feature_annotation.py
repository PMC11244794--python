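"""Gene-feature assignment for crossovers and coldspot gene reports.

Crossover intervals are assigned a single gene-feature label (exon, UTR,
intron, 1 kb upstream/downstream flank, or intergenic) with a fixed
priority order, and counted by distance-to-gene bands. Coldspots are
linked to the genes they span; runs of >= 20 linked genes form "coldspot
gene groups", the unit in which linkage drag keeps alleles co-inherited.
Trait annotations (resistance genes, agronomic loci) come from an
external two-column table and are tested for enrichment inside coldspots
with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeLayout, Interval, IntervalSet, merge_intervals

__all__ = [
    "GeneModel",
    "ColdspotGeneGroup",
    "FEATURE_PRIORITY",
    "feature_tracks",
    "assign_feature",
    "assign_features",
    "count_genic_cos",
    "coldspot_gene_report",
    "genes_to_intervals",
    "read_genes_gff3",
    "write_genes_gff3",
    "read_trait_table",
]

#: single-label priority when a CO interval touches several features
FEATURE_PRIORITY = ("exon", "utr5", "utr3", "intron", "upstream1kb", "downstream1kb")


@dataclass
class GeneModel:
    """A protein-coding gene model with strand-aware 1 kb flanks."""

    gene_id: str
    chrom: str
    start: int  # transcript span, 0-based half-open
    end: int
    strand: str  # '+' | '-'
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s},{e}) outside gene {self.gene_id}")
        if not self.exons:
            self.exons = [(self.start, self.end)]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [
            (ex[i][1], ex[i + 1][0])
            for i in range(len(ex) - 1)
            if ex[i + 1][0] > ex[i][1]
        ]

    def upstream_flank(self, size: int = 1000, chrom_length: int | None = None) -> tuple[int, int] | None:
        """1 kb (default) upstream of the TSS on the gene strand, clipped."""
        if self.strand == "+":
            s, e = self.start - size, self.start
        else:
            s, e = self.end, self.end + size
        return _clip(s, e, chrom_length)

    def downstream_flank(self, size: int = 1000, chrom_length: int | None = None) -> tuple[int, int] | None:
        if self.strand == "+":
            s, e = self.end, self.end + size
        else:
            s, e = self.start - size, self.start
        return _clip(s, e, chrom_length)


def _clip(s: int, e: int, L: int | None) -> tuple[int, int] | None:
    s = max(0, s)
    if L is not None:
        e = min(e, L)
    return (s, e) if e > s else None


def genes_to_intervals(genes: Sequence[GeneModel], flank: int = 0, genome: GenomeLayout | None = None) -> IntervalSet:
    """Gene spans, optionally widened by ``flank`` bp on both sides."""
    out = []
    for g in genes:
        L = genome.chrom_lengths.get(g.chrom) if genome else None
        span = _clip(g.start - flank, g.end + flank, L)
        if span:
            out.append(Interval(g.chrom, span[0], span[1]))
    return IntervalSet(out, label="genes")


def feature_tracks(genes: Sequence[GeneModel], genome: GenomeLayout | None = None) -> dict[str, IntervalSet]:
    """Per-feature interval tracks derived from the gene models."""
    tracks: dict[str, list[Interval]] = {k: [] for k in FEATURE_PRIORITY}
    for g in genes:
        L = genome.chrom_lengths.get(g.chrom) if genome else None
        # exon track = coding exon parts; UTR bases keep their own label
        utrs = sorted(g.utr5 + g.utr3)
        for s, e in g.exons:
            cur = s
            for us, ue in utrs:
                if ue <= cur or us >= e:
                    continue
                if us > cur:
                    tracks["exon"].append(Interval(g.chrom, cur, us))
                cur = max(cur, ue)
            if cur < e:
                tracks["exon"].append(Interval(g.chrom, cur, e))
        for s, e in g.utr5:
            tracks["utr5"].append(Interval(g.chrom, s, e))
        for s, e in g.utr3:
            tracks["utr3"].append(Interval(g.chrom, s, e))
        for s, e in g.introns():
            tracks["intron"].append(Interval(g.chrom, s, e))
        up = g.upstream_flank(chrom_length=L)
        if up:
            tracks["upstream1kb"].append(Interval(g.chrom, *up))
        down = g.downstream_flank(chrom_length=L)
        if down:
            tracks["downstream1kb"].append(Interval(g.chrom, *down))
    return {k: IntervalSet(v, label=k) for k, v in tracks.items()}


def assign_feature(
    co: Interval, tracks: dict[str, IntervalSet], gene_spans: IntervalSet | None = None
) -> tuple[str, bool]:
    """Primary feature label of a CO interval plus a multi-gene flag.

    The first class in priority order with >= 1 bp overlap wins; with no
    overlap anywhere the label is ``intergenic``.
    """
    label = "intergenic"
    for feat in FEATURE_PRIORITY:
        track = tracks.get(feat)
        if track and any(co.overlap_bp(iv) > 0 for iv in track if iv.chrom == co.chrom):
            label = feat
            break
    multi = False
    if gene_spans is not None:
        n_genes = sum(
            1 for iv in gene_spans if iv.chrom == co.chrom and co.overlap_bp(iv) > 0
        )
        multi = n_genes > 1
    return label, multi


def assign_features(
    cos: IntervalSet, genes: Sequence[GeneModel], genome: GenomeLayout | None = None
) -> pd.DataFrame:
    """Label every CO interval; returns a table with label and multi-gene flag."""
    from .genome_model import overlaps_mask

    tracks = feature_tracks(genes, genome)
    spans = genes_to_intervals(genes)
    masks = {
        feat: overlaps_mask(cos, track) if len(track) else np.zeros(len(cos), bool)
        for feat, track in tracks.items()
    }
    labels = np.full(len(cos), "intergenic", dtype=object)
    for feat in reversed(FEATURE_PRIORITY):  # highest priority assigned last
        labels[masks[feat]] = feat
    # multi-gene flag: number of distinct (unmerged) gene spans overlapped
    multi = np.zeros(len(cos), dtype=bool)
    by_chrom_starts: dict[str, np.ndarray] = {}
    by_chrom_ends: dict[str, np.ndarray] = {}
    for chrom in spans.chroms():
        st, en = spans.by_chrom(chrom)
        by_chrom_starts[chrom] = np.sort(st)
        by_chrom_ends[chrom] = np.sort(en)
    for i, co in enumerate(cos):
        if co.chrom not in by_chrom_starts:
            continue
        st, en = by_chrom_starts[co.chrom], by_chrom_ends[co.chrom]
        n = np.searchsorted(st, co.end, "left") - np.searchsorted(en, co.start, "right")
        multi[i] = n > 1
    rows = [(co.chrom, co.start, co.end) for co in cos]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["feature"] = labels
    df["multi_gene"] = multi
    return df


def count_genic_cos(
    cos: IntervalSet,
    genes: Sequence[GeneModel],
    genome: GenomeLayout | None = None,
    flank: int = 1000,
    far_flank: int = 3000,
) -> tuple[int, int, int]:
    """Partition COs by distance to genes: within +/-1 kb, 1-3 kb, beyond.

    "Within" means >= 1 bp overlap with a gene span widened by ``flank``;
    the middle band overlaps the ``far_flank`` widening only.
    """
    from .genome_model import overlaps_mask

    near = genes_to_intervals(genes, flank=flank, genome=genome)
    far = genes_to_intervals(genes, flank=far_flank, genome=genome)
    in_near = overlaps_mask(cos, near)
    in_far = overlaps_mask(cos, far)
    n_within = int(in_near.sum())
    n_mid = int((~in_near & in_far).sum())
    n_beyond = int((~in_far).sum())
    return n_within, n_mid, n_beyond


@dataclass
class ColdspotGeneGroup:
    """Genes co-trapped inside one coldspot (>= ``min_genes`` => a group)."""

    coldspot: Interval
    hybrid_id: str
    gene_ids: list[str]
    trait_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def coldspot_gene_report(
    coldspots: Sequence,  # Coldspot objects or (hybrid_id, Interval) pairs
    genes: Sequence[GeneModel],
    trait_table: dict[str, str] | None = None,
    min_genes: int = 20,
) -> tuple[list[ColdspotGeneGroup], dict]:
    """Assign genes to coldspots (>= 1 bp overlap) and summarize.

    Returns the groups reaching ``min_genes`` members and a summary with
    total coldspot genes, trait-gene counts, and a Fisher test of
    trait-gene enrichment among coldspot genes vs the rest of the genome.
    A gene spanning coldspots of several hybrids is counted in each.
    """
    trait_table = trait_table or {}
    groups: list[ColdspotGeneGroup] = []
    coldspot_gene_ids: set[str] = set()
    for cs in coldspots:
        hybrid = getattr(cs, "hybrid_id", "")
        iv = getattr(cs, "interval", cs if isinstance(cs, Interval) else None)
        if iv is None:
            hybrid, iv = cs
        members = [
            g.gene_id
            for g in genes
            if g.chrom == iv.chrom and g.interval.overlap_bp(iv) > 0
        ]
        coldspot_gene_ids.update(members)
        traits = [gid for gid in members if gid in trait_table]
        groups.append(ColdspotGeneGroup(iv, hybrid, members, traits))

    big_groups = [g for g in groups if g.n_genes >= min_genes]
    n_genes = len(genes)
    n_cs_genes = len(coldspot_gene_ids)
    n_trait = sum(1 for g in genes if g.gene_id in trait_table)
    n_trait_cs = sum(1 for gid in coldspot_gene_ids if gid in trait_table)
    table = [
        [n_trait_cs, n_cs_genes - n_trait_cs],
        [n_trait - n_trait_cs, (n_genes - n_cs_genes) - (n_trait - n_trait_cs)],
    ]
    if min(min(row) for row in table) >= 0 and n_genes > n_cs_genes:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        odds, p = np.nan, np.nan
    summary = {
        "n_coldspot_genes": n_cs_genes,
        "fraction_of_genes": n_cs_genes / n_genes if n_genes else np.nan,
        "n_trait_genes_in_coldspots": n_trait_cs,
        "n_groups_min_genes": len(big_groups),
        "trait_odds_ratio": float(odds),
        "trait_p_value": float(p),
    }
    return big_groups, summary


# ---------------------------------------------------------------------------
# IO


def read_genes_gff3(path: str | Path) -> list[GeneModel]:
    """Minimal GFF3 gene-model reader (gene/exon/UTR rows, ID/Parent attrs)."""
    meta: dict[str, tuple[str, int, int, str]] = {}  # gid -> (chrom, start, end, strand)
    order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    children: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, kind, start, end, _, strand, _, attrs = f[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            start0, end0 = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
            if kind == "gene":
                gid = attr.get("ID", f"{chrom}:{start}")
                meta[gid] = (chrom, start0, end0, strand)
                order.append(gid)
            elif kind == "mRNA":
                mrna_to_gene[attr.get("ID", "")] = attr.get("Parent", "")
            elif kind in ("exon", "five_prime_UTR", "three_prime_UTR"):
                parent = attr.get("Parent", "")
                gid = mrna_to_gene.get(parent, parent)
                children.setdefault(gid, {}).setdefault(kind, []).append((start0, end0))
    genes = []
    for gid in order:
        chrom, start0, end0, strand = meta[gid]
        kids = children.get(gid, {})
        # exon Parent attributes may point at the mRNA, resolved lazily above
        for mid, parent in mrna_to_gene.items():
            if parent == gid and mid in children:
                for kind, spans in children[mid].items():
                    kids.setdefault(kind, []).extend(spans)
        genes.append(
            GeneModel(
                gid,
                chrom,
                start0,
                end0,
                strand,
                exons=sorted(set(kids.get("exon", []))),
                utr5=sorted(set(kids.get("five_prime_UTR", []))),
                utr3=sorted(set(kids.get("three_prime_UTR", []))),
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_genes_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\t.\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in sorted(g.exons):
                fh.write(f"{g.chrom}\t.\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n")
            for s, e in sorted(g.utr5):
                fh.write(
                    f"{g.chrom}\t.\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            for s, e in sorted(g.utr3):
                fh.write(
                    f"{g.chrom}\t.\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )


def read_trait_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV: gene_id <tab> trait label."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":
                continue
            out[parts[0]] = parts[1] if len(parts) > 1 else "trait"
    return out
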