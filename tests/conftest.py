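"""Shared fixtures: toy genomes, brute-force interval oracles, one corpus."""

from __future__ import annotations

import numpy as np
import pytest

from coldspot_atlas.genome_model import GenomeLayout, Interval, IntervalSet
from coldspot_atlas.pipeline import make_fixture
from coldspot_atlas.synthetic_data import simulate_corpus


# ---------------------------------------------------------------------------
# per-base bitmap oracles (independent of the interval engine)


def bitmap(intervals: IntervalSet, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(L, dtype=bool) for c, L in lengths.items()}
    for iv in intervals:
        out[iv.chrom][iv.start : iv.end] = True
    return out


def bitmap_to_intervals(bm: dict[str, np.ndarray]) -> list[tuple[str, int, int]]:
    out = []
    for chrom in sorted(bm):
        arr = bm[chrom].astype(np.int8)
        d = np.diff(np.concatenate([[0], arr, [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def bitmap_merge(intervals, lengths, gap):
    """Oracle for merge: close gaps of <= gap bp between occupied runs."""
    bm = bitmap(intervals, lengths)
    for chrom, arr in bm.items():
        runs = bitmap_to_intervals({chrom: arr})
        for (_, _, e1), (_, s2, _) in zip(runs, runs[1:]):
            if s2 - e1 <= gap:
                arr[e1:s2] = True
    return bitmap_to_intervals(bm)


@pytest.fixture
def toy_genome() -> GenomeLayout:
    """Two 100 kb chromosomes, PER = the middle 40 kb of each."""
    return GenomeLayout(
        ["c1", "c2"],
        {"c1": 100_000, "c2": 100_000},
        IntervalSet([Interval("c1", 30_000, 70_000), Interval("c2", 30_000, 70_000)], "PER"),
    )


def random_intervalset(rng, lengths, n_max=12) -> IntervalSet:
    out = []
    for chrom, L in lengths.items():
        for _ in range(rng.integers(0, n_max + 1)):
            s = int(rng.integers(0, L - 1))
            e = int(rng.integers(s + 1, min(L, s + 1 + rng.integers(1, L // 3 + 2)) + 1))
            out.append(Interval(chrom, s, min(e, L)))
    return IntervalSet(out)


@pytest.fixture(scope="session")
def corpus():
    """The standard noise-free 5-hybrid test corpus (planted truth known)."""
    return simulate_corpus(make_fixture(seed=11))
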