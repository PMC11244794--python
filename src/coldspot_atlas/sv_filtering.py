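"""Structural-variant filtering for F1-heterozygous ("parental") SVs.

Three call sets enter the filter, all against the same reference:

* ``wild_inbred`` — SVs of the wild parent genome vs the reference;
* ``f1_pollen``  — SVs genotyped in the pooled F1 pollen reads. A wild
  SV that is heterozygous in the wild parent may not be inherited by the
  F1, so only inbred SVs re-observed in the pollen pool are kept; these
  are the *parental SVs* that make the F1 structurally heterozygous.
* ``self``       — SVs between the reference assembly and the
  re-sequenced reference accession itself: assembly/calling artifacts
  used as an exclusion mask.

Retained are parental SVs of type DEL or INV that do not overlap any
self SV. Size classes: >=50 bp (detection floor), >1 kb (analysis set,
where recombination suppression is concentrated) and INV >30 kb
(reporting class for large inversions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_model import Interval, IntervalSet, reciprocal_overlap

__all__ = [
    "SVCall",
    "SvFilterParams",
    "match_sv_calls",
    "subtract_self_svs",
    "apply_size_classes",
    "filter_parental_svs",
    "svs_to_intervals",
    "read_svs_tsv",
    "write_svs_tsv",
    "read_svs_vcf",
]

SV_TYPES = ("DEL", "INV")


@dataclass(frozen=True, order=True)
class SVCall:
    """One structural-variant call (caller type recorded verbatim)."""

    chrom: str
    start: int
    end: int
    type: str  # DEL | INV | other
    source: str = ""  # wild_inbred | f1_pollen | self
    genotype: str = "."

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"SV length must be >= 1: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


@dataclass
class SvFilterParams:
    min_detect_len: int = 50
    min_analysis_len: int = 1000  # ">1 kb", strict
    min_inv_report_len: int = 30_000
    match_reciprocal_overlap: float = 0.5
    breakpoint_tolerance: int = 0  # optional alternative matching mode

    def __post_init__(self) -> None:
        if not (0 < self.match_reciprocal_overlap <= 1):
            raise ValueError("reciprocal overlap must be in (0, 1]")
        if min(self.min_detect_len, self.min_analysis_len, self.min_inv_report_len) <= 0:
            raise ValueError("size thresholds must be positive")


def match_sv_calls(
    inbred: Sequence[SVCall],
    pollen: Sequence[SVCall],
    params: SvFilterParams | None = None,
) -> tuple[list[SVCall], list[SVCall]]:
    """Keep inbred SVs re-observed in the pollen pool (parental SVs).

    An inbred call is retained iff some pollen call of the same type
    reaches the reciprocal-overlap threshold (the inbred coordinates are
    kept). Same-locus calls of conflicting type are returned separately
    as a discordance list.
    """
    params = params or SvFilterParams()
    by_chrom: dict[str, list[SVCall]] = {}
    for sv in pollen:
        by_chrom.setdefault(sv.chrom, []).append(sv)
    parental: list[SVCall] = []
    discordant: list[SVCall] = []
    for sv in inbred:
        matched = False
        type_clash = False
        for cand in by_chrom.get(sv.chrom, ()):
            ro = reciprocal_overlap(sv.interval, cand.interval)
            if ro >= params.match_reciprocal_overlap:
                if cand.type == sv.type:
                    matched = True
                    break
                type_clash = True
        if matched:
            parental.append(sv)
        elif type_clash:
            discordant.append(sv)
    return parental, discordant


def subtract_self_svs(
    parental: Sequence[SVCall], self_svs: Sequence[SVCall]
) -> list[SVCall]:
    """Keep DEL/INV parental SVs with zero bp overlap against any self SV."""
    kept = []
    for sv in parental:
        if sv.type not in SV_TYPES:
            continue
        if any(sv.interval.overlap_bp(m.interval) > 0 for m in self_svs):
            continue
        kept.append(sv)
    return kept


def apply_size_classes(
    svs: Sequence[SVCall], params: SvFilterParams | None = None
) -> dict[str, list[SVCall]]:
    """Label SVs with every size class they satisfy.

    ``detect``: length >= 50 bp; ``analysis``: length > 1 kb (the set all
    downstream association statistics use); ``inv_report``: inversions
    > 30 kb.
    """
    params = params or SvFilterParams()
    return {
        "detect": [sv for sv in svs if sv.length >= params.min_detect_len],
        "analysis": [sv for sv in svs if sv.length > params.min_analysis_len],
        "inv_report": [
            sv
            for sv in svs
            if sv.type == "INV" and sv.length > params.min_inv_report_len
        ],
    }


def filter_parental_svs(
    inbred: Sequence[SVCall],
    pollen: Sequence[SVCall],
    self_svs: Sequence[SVCall],
    params: SvFilterParams | None = None,
) -> dict:
    """Full filter chain: match -> DEL/INV & self-mask -> size classes."""
    params = params or SvFilterParams()
    parental, discordant = match_sv_calls(inbred, pollen, params)
    retained = subtract_self_svs(parental, self_svs)
    classes = apply_size_classes(retained, params)
    return {
        "parental": parental,
        "discordant": discordant,
        "retained": retained,
        **classes,
    }


def svs_to_intervals(svs: Sequence[SVCall], label: str = "") -> IntervalSet:
    return IntervalSet((sv.interval for sv in svs), label=label)


# ---------------------------------------------------------------------------
# IO


def read_svs_tsv(path: str | Path, source: str = "") -> list[SVCall]:
    """TSV with columns chrom, start, end, type (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return [
        SVCall(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            source=source or str(getattr(r, "source", "")),
        )
        for r in df.itertuples()
    ]


def write_svs_tsv(svs: Iterable[SVCall], path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.type, s.source) for s in svs],
        columns=["chrom", "start", "end", "type", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_svs_vcf(path: str | Path, source: str = "") -> list[SVCall]:
    """Read SV records from a VCF using SVTYPE/END (symbolic <DEL>/<INV> alleles)."""
    from cyvcf2 import VCF

    out = []
    for rec in VCF(str(path)):
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            continue
        end = rec.INFO.get("END")
        if end is None:
            svlen = rec.INFO.get("SVLEN")
            if svlen is None:
                continue
            end = rec.POS + abs(int(svlen))
        start = rec.POS - 1  # VCF is 1-based; POS is the base before the event
        svtype = str(svtype)
        out.append(
            SVCall(
                chrom=rec.CHROM,
                start=start,
                end=int(end),
                type=svtype if svtype in SV_TYPES else "other",
                source=source,
            )
        )
    return out
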