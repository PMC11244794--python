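"""Synthetic pooled-pollen corpora with planted ground truth.

The generator emulates the statistical structure of a linked-read
pollen-sequencing experiment on a hybrid between a reference cultivar
and a wild relative, at a scale small enough for routine testing:

* a genome of a few chromosomes, each split into a centered
  pericentromeric (PER) block and distal euchromatin (DEU);
* segregating SNP markers at compartment-specific densities;
* long DNA molecules with log-normal lengths, carrying per-marker
  haplotype calls, into which single crossovers are planted with a
  distally-biased landscape modulated by SV- and TE-dependent
  multipliers and hard-blocked inside planted coldspot regions;
* feature tracks: TE superfamilies with compartment bias, gene models,
  accessible-chromatin regions, and three SV call sets (wild inbred,
  F1 pollen, reference self) wired so the parental-SV filter has an
  exactly known expected output.

Everything derives from one seed; per-stage generators are spawned
deterministically, so a corpus is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .crossover_detection import (
    CrossoverEvent,
    MarkerSet,
    MoleculeCall,
    WILDCARD,
    write_markers_tsv,
    write_molecules_tsv,
    write_events,
)
from .feature_annotation import GeneModel, write_genes_gff3
from .genome_model import (
    GenomeLayout,
    Interval,
    IntervalSet,
    merge_intervals,
    write_bed,
    write_genome_file,
)
from .sv_filtering import SVCall, write_svs_tsv

__all__ = [
    "TeTrackConfig",
    "SimConfig",
    "HybridCorpus",
    "Corpus",
    "simulate_genome",
    "simulate_markers",
    "simulate_molecules",
    "simulate_svs",
    "simulate_features",
    "simulate_corpus",
    "write_corpus",
]


@dataclass
class TeTrackConfig:
    """One TE superfamily track: coverage target, compartment, CO effect."""

    coverage: float  # fraction of the target compartment covered
    compartment: str  # 'DEU' | 'PER' | 'both' (hard bias)
    co_multiplier: float  # multiplies the local CO rate inside elements
    mean_length: int = 5_000


def _default_te_tracks() -> dict[str, TeTrackConfig]:
    # retrotransposons dense in PER and CO-suppressing; a DNA-transposon
    # family in DEU enriched with COs
    return {
        "Gypsy": TeTrackConfig(0.35, "PER", 0.2, 8_000),
        "Copia": TeTrackConfig(0.15, "PER", 0.3, 6_000),
        "Stowaway": TeTrackConfig(0.05, "DEU", 2.0, 500),
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    Molecule lengths, marker densities and noise rates are
    order-of-magnitude stand-ins for a 10x-style linked-read library;
    the CO landscape parameters encode a distally-concentrated
    recombination pattern (~90% of COs in DEU) with strong suppression
    inside structural variants.
    """

    hybrids: tuple[str, ...] = ("PM", "NE", "CH", "HB", "PN")
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    per_fraction: float = 0.6  # PER block centered on each chromosome

    marker_density_deu: float = 1.0e-3  # markers per bp
    marker_density_per: float = 5.0e-4

    n_molecules: int = 10_000
    molecule_mean_length: float = 50_000.0
    molecule_sd_length: float = 40_000.0
    molecule_max_length: int = 200_000
    mean_reads_per_marker: float = 2.0

    co_rate: float = 0.1  # fraction of molecules carrying one CO
    deu_co_weight: float = 0.9
    per_co_weight: float = 0.1

    sv_count: int = 250
    sv_deu_fraction: float = 0.61  # DEU:PER SV count ratio ~1.55:1
    sv_median_length_deu: float = 4_000.0
    sv_median_length_per: float = 10_000.0
    sv_length_sigma: float = 1.0  # log-normal shape
    sv_min_length: int = 60
    sv_del_fraction: float = 0.75
    sv_other_fraction: float = 0.05  # non-DEL/INV types passing through readers
    sv_suppression: float = 0.05  # CO-rate multiplier inside SVs > 1 kb
    parental_fraction: float = 0.8  # inbred SVs re-observed in the pollen pool
    self_overlap_fraction: float = 0.1  # parental SVs masked by a self SV

    te_tracks: dict[str, TeTrackConfig] = field(default_factory=_default_te_tracks)

    gene_count: int = 3_000
    gene_deu_fraction: float = 0.85
    gene_mean_length: int = 3_000
    gene_co_multiplier: float = 3.0  # CO-rate preference inside gene bodies
    acr_count: int = 2_000
    acr_mean_length: int = 733
    acr_overlap_prob: float = 0.7  # probability an ACR is placed at a gene TSS

    n_shared_coldspots: int = 2  # planted CO-free blocks present in all hybrids
    n_unique_coldspots: int = 1  # extra CO-free blocks per hybrid
    coldspot_length: int = 2_000_000

    wildcard_rate: float = 0.0  # per-marker chance of an ambiguous call
    flip_rate: float = 0.0  # per-marker chance of a flipped call
    double_switch_rate: float = 0.0  # contaminant molecules with two switches

    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [
            ("per_fraction", self.per_fraction),
            ("co_rate", self.co_rate),
            ("parental_fraction", self.parental_fraction),
            ("self_overlap_fraction", self.self_overlap_fraction),
            ("acr_overlap_prob", self.acr_overlap_prob),
            ("wildcard_rate", self.wildcard_rate),
            ("flip_rate", self.flip_rate),
            ("double_switch_rate", self.double_switch_rate),
        ]:
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.per_fraction >= 1:
            raise ValueError("per_fraction must be < 1")
        if min(self.deu_co_weight, self.per_co_weight) < 0:
            raise ValueError("CO weights must be >= 0")


@dataclass
class HybridCorpus:
    """Everything simulated for one hybrid, including the planted truth."""

    hybrid_id: str
    markers: MarkerSet
    molecules: list[MoleculeCall]
    truth_events: list[CrossoverEvent]
    sv_sets: dict[str, list[SVCall]]  # wild_inbred | f1_pollen | self
    truth_retained_svs: list[SVCall]
    planted_coldspots: IntervalSet


@dataclass
class Corpus:
    config: SimConfig
    genome: GenomeLayout
    te_tracks: dict[str, IntervalSet]
    genes: list[GeneModel]
    acrs: IntervalSet
    hybrids: dict[str, HybridCorpus]


# ---------------------------------------------------------------------------
# stage generators


def _spawn(seed: int, *salt: int) -> np.random.Generator:
    """Deterministic sub-stream generator for one stage."""
    return np.random.default_rng(np.random.SeedSequence([seed, *salt]))


def simulate_genome(cfg: SimConfig) -> GenomeLayout:
    """Chromosomes of equal length with a centered PER block."""
    names = [f"ch{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    lengths = {c: cfg.chrom_length for c in names}
    per = []
    if cfg.per_fraction > 0:
        half_gap = (1 - cfg.per_fraction) / 2
        for c in names:
            L = lengths[c]
            start = int(round(L * half_gap))
            end = start + int(round(L * cfg.per_fraction))
            per.append(Interval(c, start, min(end, L)))
    return GenomeLayout(names, lengths, IntervalSet(per, label="PER"))


def simulate_markers(
    cfg: SimConfig, genome: GenomeLayout, rng: np.random.Generator | None = None
) -> MarkerSet:
    """Poisson marker placement at compartment-specific densities."""
    if min(cfg.marker_density_deu, cfg.marker_density_per) < 0:
        raise ValueError("marker densities must be >= 0")
    rng = rng if rng is not None else _spawn(cfg.seed, 1)
    positions: dict[str, np.ndarray] = {}
    per = {iv.chrom: iv for iv in genome.per_intervals}
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        segs = []
        p = per.get(chrom)
        if p is None:
            segs.append((0, L, cfg.marker_density_deu))
        else:
            segs.append((0, p.start, cfg.marker_density_deu))
            segs.append((p.start, p.end, cfg.marker_density_per))
            segs.append((p.end, L, cfg.marker_density_deu))
        pos: list[np.ndarray] = []
        for s, e, dens in segs:
            if e <= s or dens <= 0:
                continue
            n = rng.poisson(dens * (e - s))
            pos.append(rng.integers(s, e, size=n))
        allpos = np.unique(np.concatenate(pos)) if pos else np.array([], dtype=np.int64)
        positions[chrom] = allpos
    return MarkerSet(positions)


def _membership(points: np.ndarray, s: IntervalSet, chrom: str) -> np.ndarray:
    """Boolean: is each point covered by the (merged) set on this chromosome."""
    ms, me = merge_intervals(s).by_chrom(chrom) if len(s) else (np.array([]), np.array([]))
    if len(ms) == 0:
        return np.zeros(len(points), dtype=bool)
    j = np.searchsorted(ms, points, side="right") - 1
    ok = j >= 0
    out = np.zeros(len(points), dtype=bool)
    out[ok] = me[j[ok]] > points[ok]
    return out


def _overlaps(starts: np.ndarray, ends: np.ndarray, s: IntervalSet, chrom: str) -> np.ndarray:
    """Boolean: does each [start, end) overlap the (merged) set by >= 1 bp."""
    ms, me = merge_intervals(s).by_chrom(chrom) if len(s) else (np.array([]), np.array([]))
    if len(ms) == 0:
        return np.zeros(len(starts), dtype=bool)
    j = np.searchsorted(ms, ends, side="left")
    ok = j > 0
    out = np.zeros(len(starts), dtype=bool)
    out[ok] = me[j[ok] - 1] > starts[ok]
    return out


def _sample_lengths(rng, mean: float, sd: float, max_len: int, n: int) -> np.ndarray:
    """Log-normal lengths with given natural-scale mean/sd, truncated at max."""
    sigma2 = np.log(1 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    x = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.minimum(x, max_len).astype(np.int64)


def _place_in_compartment(
    rng, genome: GenomeLayout, compartment: IntervalSet, length: int
) -> Interval | None:
    """Uniform placement of an interval fully inside one compartment block."""
    blocks = [iv for iv in compartment if iv.length >= length]
    if not blocks:
        return None
    slots = np.array([iv.length - length + 1 for iv in blocks], dtype=float)
    k = rng.choice(len(blocks), p=slots / slots.sum())
    b = blocks[k]
    start = int(rng.integers(b.start, b.end - length + 1))
    return Interval(b.chrom, start, start + length)


def _plant_coldspots(
    cfg: SimConfig, genome: GenomeLayout, rng
) -> tuple[IntervalSet, dict[str, list[Interval]]]:
    """Non-overlapping DEU blocks: shared ones for all hybrids, unique per hybrid."""
    from .genome_model import subtract

    deu = genome.deu_intervals
    taken: list[Interval] = []

    def place() -> Interval:
        # sample uniformly over the remaining free DEU space that still fits
        free = subtract(deu, IntervalSet(taken)) if taken else deu
        segs = [iv for iv in free if iv.length >= cfg.coldspot_length]
        if not segs:
            raise ValueError(
                "planted coldspots exceed the available DEU space; "
                "reduce their number/length or enlarge the genome"
            )
        slots = np.array([iv.length - cfg.coldspot_length + 1 for iv in segs], dtype=float)
        seg = segs[rng.choice(len(segs), p=slots / slots.sum())]
        start = int(rng.integers(seg.start, seg.end - cfg.coldspot_length + 1))
        iv = Interval(seg.chrom, start, start + cfg.coldspot_length)
        taken.append(iv)
        return iv

    shared = IntervalSet([place() for _ in range(cfg.n_shared_coldspots)], label="shared")
    unique = {
        h: [place() for _ in range(cfg.n_unique_coldspots)] for h in cfg.hybrids
    }
    return shared, unique


def simulate_molecules(
    cfg: SimConfig,
    genome: GenomeLayout,
    markers: MarkerSet,
    rng: np.random.Generator | None = None,
    co_multiplier_tracks: Sequence[tuple[IntervalSet, float]] = (),
    blocked: IntervalSet | None = None,
    hybrid_id: str = "",
) -> tuple[list[MoleculeCall], list[CrossoverEvent]]:
    """Molecules with planted single crossovers and the planted truth.

    The CO position is drawn over inter-marker gaps with weight
    proportional to gap length times a per-bp rate: the compartment base
    rate (DEU vs PER weight share), times every multiplier track
    covering the gap midpoint (TE superfamilies, SVs), and zero inside
    ``blocked`` regions (planted coldspots). Each recombinant molecule
    carries exactly one switch with at least three markers on each side;
    contaminant double-switch molecules and per-marker wildcard/flip
    noise are added at the configured rates.
    """
    if len(markers) == 0:
        raise ValueError("markers required")
    rng = rng if rng is not None else _spawn(cfg.seed, 2)

    deu_bp = sum(iv.length for iv in genome.deu_intervals)
    per_bp = sum(iv.length for iv in genome.per_intervals)
    rate_deu = cfg.deu_co_weight / deu_bp if deu_bp else 0.0
    rate_per = cfg.per_co_weight / per_bp if per_bp else 0.0

    # per-chromosome gap weights
    gap_w: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        pos = markers.positions.get(chrom, np.array([], dtype=np.int64))
        if len(pos) < 2:
            gap_w[chrom] = np.array([])
            continue
        mids = (pos[:-1] + pos[1:]) // 2
        lens = np.diff(pos).astype(float)
        in_per = _membership(mids, genome.per_intervals, chrom)
        w = np.where(in_per, rate_per, rate_deu) * lens
        # multipliers and blocks act on the whole candidate CO interval, so
        # a planted CO never straddles a suppressed/blocked feature edge
        left_pos, right_pos = pos[:-1], pos[1:]
        for track, mult in co_multiplier_tracks:
            inside = _overlaps(left_pos, right_pos, track, chrom)
            w[inside] *= mult
        if blocked is not None and len(blocked):
            w[_overlaps(left_pos, right_pos, blocked, chrom)] = 0.0
        # a CO needs 3 flanking markers on both sides
        if len(w) >= 5:
            w[:2] = 0.0
            w[-2:] = 0.0
        else:
            w[:] = 0.0
        gap_w[chrom] = w

    chrom_tot = np.array([gap_w[c].sum() for c in genome.chrom_names])
    if chrom_tot.sum() <= 0:
        raise ValueError("no eligible CO positions (check weights/markers)")
    chrom_p = chrom_tot / chrom_tot.sum()

    n_rec = rng.binomial(cfg.n_molecules, cfg.co_rate)
    molecules: list[MoleculeCall] = []
    truth: list[CrossoverEvent] = []
    lengths_all = _sample_lengths(
        rng, cfg.molecule_mean_length, cfg.molecule_sd_length, cfg.molecule_max_length, cfg.n_molecules
    )

    def finish(mid, chrom, pos, haps, split_idx=None):
        reads = 1 + rng.poisson(max(cfg.mean_reads_per_marker - 1, 0), size=len(pos))
        haps = np.array(haps, dtype=object)
        if cfg.flip_rate > 0:
            flip = rng.random(len(pos)) < cfg.flip_rate
            haps[flip] = np.where(haps[flip] == "A", "B", "A")
        if cfg.wildcard_rate > 0:
            wc = rng.random(len(pos)) < cfg.wildcard_rate
            haps[wc] = WILDCARD
        molecules.append(MoleculeCall(mid, chrom, pos, haps, reads))

    # recombinant molecules, one per planted CO
    for k in range(n_rec):
        chrom = genome.chrom_names[rng.choice(len(genome.chrom_names), p=chrom_p)]
        w = gap_w[chrom]
        pos = markers.positions[chrom]
        gi = rng.choice(len(w), p=w / w.sum())
        left, right = int(pos[gi]), int(pos[gi + 1])
        need_lo, need_hi = int(pos[gi - 2]), int(pos[gi + 3])
        length = int(lengths_all[k])
        length = max(length, need_hi - need_lo + 2)
        L = genome.chrom_lengths[chrom]
        length = min(length, L)
        lo_start = max(0, need_hi + 1 - length)
        hi_start = min(need_lo, L - length)
        start = int(rng.integers(lo_start, hi_start + 1)) if hi_start >= lo_start else lo_start
        i0, i1 = np.searchsorted(pos, (start, start + length))
        span_pos = pos[i0:i1]
        hap1, hap2 = ("A", "B") if rng.random() < 0.5 else ("B", "A")
        haps = [hap1 if p <= left else hap2 for p in span_pos]
        mid = f"{hybrid_id}mol{k:06d}"
        finish(mid, chrom, span_pos, haps)
        truth.append(
            CrossoverEvent(
                hybrid_id=hybrid_id,
                chrom=chrom,
                left_marker=left,
                right_marker=right,
                molecule_id=mid,
            )
        )

    # non-recombinant molecules (some made double-switch contaminants)
    chrom_len_p = np.array(
        [genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float
    )
    chrom_len_p /= chrom_len_p.sum()
    for k in range(n_rec, cfg.n_molecules):
        chrom = genome.chrom_names[rng.choice(len(genome.chrom_names), p=chrom_len_p)]
        L = genome.chrom_lengths[chrom]
        length = int(min(lengths_all[k], L))
        start = int(rng.integers(0, L - length + 1))
        pos = markers.positions[chrom]
        i0, i1 = np.searchsorted(pos, (start, start + length))
        span_pos = pos[i0:i1]
        hap = "A" if rng.random() < 0.5 else "B"
        haps = [hap] * len(span_pos)
        if (
            cfg.double_switch_rate > 0
            and len(span_pos) >= 9
            and rng.random() < cfg.double_switch_rate
        ):
            # gene-conversion-like contaminant: short opposite tract inside
            a = int(rng.integers(3, len(span_pos) - 5))
            b = int(rng.integers(a + 1, min(a + 3, len(span_pos) - 3)))
            other = "B" if hap == "A" else "A"
            for i in range(a, b + 1):
                haps[i] = other
        finish(f"{hybrid_id}mol{k:06d}", chrom, span_pos, haps)

    return molecules, truth


def simulate_svs(
    cfg: SimConfig, genome: GenomeLayout, rng: np.random.Generator | None = None
) -> tuple[dict[str, list[SVCall]], list[SVCall]]:
    """Three SV call sets with an exactly known filter outcome.

    A fraction ``parental_fraction`` of the wild-inbred SVs is
    re-observed in the F1 pollen set (breakpoints jittered but always
    above the 50% reciprocal-overlap matching threshold); of those, a
    fraction ``self_overlap_fraction`` gets an overlapping self SV.
    The returned truth set holds the DEL/INV parental SVs without self
    overlap — exactly what the filter chain must retain.
    """
    rng = rng if rng is not None else _spawn(cfg.seed, 3)
    deu = genome.deu_intervals
    per = genome.per_intervals
    inbred: list[SVCall] = []
    pollen: list[SVCall] = []
    self_svs: list[SVCall] = []
    truth: list[SVCall] = []
    placed: list[Interval] = []

    for i in range(cfg.sv_count):
        in_deu = rng.random() < cfg.sv_deu_fraction
        comp = deu if in_deu else (per if len(per) else deu)
        median = cfg.sv_median_length_deu if in_deu else cfg.sv_median_length_per
        length = max(
            cfg.sv_min_length,
            int(rng.lognormal(np.log(median), cfg.sv_length_sigma)),
        )
        iv = None
        for _ in range(100):
            cand = _place_in_compartment(rng, genome, comp, length)
            if cand is not None and all(cand.overlap_bp(t) == 0 for t in placed):
                iv = cand
                break
        if iv is None:
            continue
        placed.append(iv)
        u = rng.random()
        if u < cfg.sv_other_fraction:
            svtype = "other"
        elif u < cfg.sv_other_fraction + cfg.sv_del_fraction:
            svtype = "DEL"
        else:
            svtype = "INV"
        sv = SVCall(iv.chrom, iv.start, iv.end, svtype, source="wild_inbred")
        inbred.append(sv)
        is_parental = rng.random() < cfg.parental_fraction
        if is_parental:
            # jitter breakpoints by < 20% of length: reciprocal overlap stays >= 0.5
            jig = max(1, length // 5)
            ds = int(rng.integers(-jig, jig + 1))
            de = int(rng.integers(-jig, jig + 1))
            s2 = max(0, iv.start + ds)
            e2 = min(genome.chrom_lengths[iv.chrom], iv.end + de)
            if e2 - s2 < max(1, length // 2):
                s2, e2 = iv.start, iv.end
            pollen.append(SVCall(iv.chrom, s2, e2, svtype, source="f1_pollen"))
            masked = rng.random() < cfg.self_overlap_fraction
            if masked:
                # a self SV overlapping this parental SV
                mid = (iv.start + iv.end) // 2
                half = max(1, length // 4)
                self_svs.append(
                    SVCall(
                        iv.chrom,
                        max(0, mid - half),
                        min(genome.chrom_lengths[iv.chrom], mid + half),
                        "DEL",
                        source="self",
                    )
                )
            elif svtype in ("DEL", "INV"):
                truth.append(sv)
    return {"wild_inbred": inbred, "f1_pollen": pollen, "self": self_svs}, truth


def simulate_features(
    cfg: SimConfig, genome: GenomeLayout, rng: np.random.Generator | None = None
) -> dict:
    """Reference-genome feature tracks: TEs, gene models, ACRs, one SV trio."""
    rng = rng if rng is not None else _spawn(cfg.seed, 4)

    te_tracks: dict[str, IntervalSet] = {}
    for name, tcfg in sorted(cfg.te_tracks.items()):
        if tcfg.compartment == "PER":
            comp = genome.per_intervals
        elif tcfg.compartment == "DEU":
            comp = genome.deu_intervals
        else:
            comp = IntervalSet(
                Interval(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names
            )
        target_bp = tcfg.coverage * sum(iv.length for iv in comp)
        ivs: list[Interval] = []
        covered = 0
        while covered < target_bp:
            length = max(50, int(rng.exponential(tcfg.mean_length)))
            iv = _place_in_compartment(rng, genome, comp, length)
            if iv is None:
                break
            ivs.append(iv)
            covered += length
        te_tracks[name] = IntervalSet(ivs, label=name)

    genes: list[GeneModel] = []
    for i in range(cfg.gene_count):
        comp = genome.deu_intervals if rng.random() < cfg.gene_deu_fraction else genome.per_intervals
        if len(comp) == 0:
            comp = genome.deu_intervals
        length = max(500, int(rng.exponential(cfg.gene_mean_length)))
        iv = _place_in_compartment(rng, genome, comp, length)
        if iv is None:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        cuts = np.sort(rng.integers(iv.start, iv.end, size=2 * n_exons - 2)) if n_exons > 1 else np.array([])
        bounds = [iv.start, *cuts.tolist(), iv.end]
        exons = [
            (int(bounds[2 * j]), int(bounds[2 * j + 1]))
            for j in range(n_exons)
            if bounds[2 * j + 1] > bounds[2 * j]
        ]
        utr_len = min(200, max(1, exons[0][1] - exons[0][0] - 1))
        utr5 = [(exons[0][0], exons[0][0] + utr_len)] if strand == "+" else [(exons[-1][1] - utr_len, exons[-1][1])]
        utr3 = [(exons[-1][1] - utr_len, exons[-1][1])] if strand == "+" else [(exons[0][0], exons[0][0] + utr_len)]
        genes.append(
            GeneModel(
                f"gene{i:05d}", iv.chrom, iv.start, iv.end, strand, exons=exons,
                utr5=[(s, e) for s, e in utr5 if e > s],
                utr3=[(s, e) for s, e in utr3 if e > s],
            )
        )

    acrs: list[Interval] = []
    for _ in range(cfg.acr_count):
        length = max(100, int(rng.exponential(cfg.acr_mean_length)))
        if genes and rng.random() < cfg.acr_overlap_prob:
            g = genes[int(rng.integers(0, len(genes)))]
            center = g.tss + int(rng.integers(-500, 501))
            L = genome.chrom_lengths[g.chrom]
            s = max(0, min(center - length // 2, L - length))
            acrs.append(Interval(g.chrom, s, s + length))
        else:
            iv = _place_in_compartment(
                rng,
                genome,
                IntervalSet(Interval(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names),
                length,
            )
            if iv is not None:
                acrs.append(iv)

    sv_sets, truth_svs = simulate_svs(cfg, genome, rng)
    return {
        "te_tracks": te_tracks,
        "genes": genes,
        "acrs": IntervalSet(acrs, label="ACR"),
        "sv_sets": sv_sets,
        "truth_retained_svs": truth_svs,
    }


def simulate_corpus(cfg: SimConfig) -> Corpus:
    """Full multi-hybrid corpus from one seed."""
    genome = simulate_genome(cfg)
    features = simulate_features(cfg, genome, _spawn(cfg.seed, 4))
    shared_cs, unique_cs = _plant_coldspots(cfg, genome, _spawn(cfg.seed, 5))

    hybrids: dict[str, HybridCorpus] = {}
    for hi, hybrid in enumerate(cfg.hybrids):
        markers = simulate_markers(cfg, genome, _spawn(cfg.seed, 10 + hi, 1))
        sv_sets, truth_svs = simulate_svs(cfg, genome, _spawn(cfg.seed, 10 + hi, 3))
        blocked = IntervalSet(
            list(shared_cs) + unique_cs[hybrid], label=f"{hybrid}_planted_coldspots"
        )
        sv_big = IntervalSet(
            [sv.interval for sv in sv_sets["wild_inbred"] if sv.length > 1000]
        )
        mult_tracks: list[tuple[IntervalSet, float]] = [
            (track, cfg.te_tracks[name].co_multiplier)
            for name, track in features["te_tracks"].items()
        ]
        if cfg.gene_co_multiplier != 1.0 and features["genes"]:
            gene_spans = IntervalSet(g.interval for g in features["genes"])
            mult_tracks.append((gene_spans, cfg.gene_co_multiplier))
        if len(sv_big):
            mult_tracks.append((sv_big, cfg.sv_suppression))
        molecules, truth = simulate_molecules(
            cfg,
            genome,
            markers,
            _spawn(cfg.seed, 10 + hi, 2),
            co_multiplier_tracks=mult_tracks,
            blocked=blocked,
            hybrid_id=hybrid,
        )
        hybrids[hybrid] = HybridCorpus(
            hybrid_id=hybrid,
            markers=markers,
            molecules=molecules,
            truth_events=truth,
            sv_sets=sv_sets,
            truth_retained_svs=truth_svs,
            planted_coldspots=blocked,
        )
    return Corpus(
        config=cfg,
        genome=genome,
        te_tracks=features["te_tracks"],
        genes=features["genes"],
        acrs=features["acrs"],
        hybrids=hybrids,
    )


def write_corpus(corpus: Corpus, outdir: str | Path) -> None:
    """Write the corpus in the formats the pipeline reads, plus truth files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome_file(corpus.genome, out / "genome.tsv", out / "per.bed")
    with open(out / "te_tracks.bed", "w") as fh:
        for name, track in sorted(corpus.te_tracks.items()):
            for iv in track:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    write_genes_gff3(corpus.genes, out / "genes.gff3")
    write_bed(corpus.acrs, out / "acrs.bed")
    for hybrid, hc in corpus.hybrids.items():
        write_markers_tsv(hc.markers, out / f"markers_{hybrid}.tsv")
        write_molecules_tsv(hc.molecules, out / f"molecules_{hybrid}.tsv")
        write_events(hc.truth_events, out / f"truth_events_{hybrid}.tsv")
        write_bed(hc.planted_coldspots, out / f"planted_coldspots_{hybrid}.bed")
        for source, svs in hc.sv_sets.items():
            write_svs_tsv(svs, out / f"svs_{hybrid}_{source}.tsv")
        write_svs_tsv(hc.truth_retained_svs, out / f"truth_retained_svs_{hybrid}.tsv")
    cfg = asdict(corpus.config)
    cfg["te_tracks"] = {k: asdict(v) for k, v in corpus.config.te_tracks.items()}
    cfg["hybrids"] = list(corpus.config.hybrids)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg, "seed": corpus.config.seed}, fh, sort_keys=True)
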