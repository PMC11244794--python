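"""Association statistics for the crossover landscape.

Permutation tests randomize the placement of the CO intervals across
the genome (length-preserving shuffles) and compare the observed number
of feature-overlapping COs with the null distribution; the z-score sign
reads as enrichment (+) or suppression (−). Cross-hybrid similarity is
quantified by Fisher's exact test on co-occupied genome windows and by
Spearman correlation of windowed CO counts. The CO landscape itself is
summarized as a Gaussian kernel density (bandwidth 100 kb) and as
window count tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import (
    GenomeLayout,
    Interval,
    IntervalSet,
    count_overlapping,
    coverage,
    distance_to_nearest,
    intersect,
    merge_intervals,
    overlap_bp_per_interval,
    shuffle_intervals,
    sliding_windows,
)

__all__ = [
    "PermutationResult",
    "permutation_enrichment",
    "genic_enrichment",
    "overlap_fisher",
    "landscape_density",
    "landscape_correlation",
    "window_counts",
    "sv_distance_profile",
    "spearman_feature_correlation",
    "enrichment_table",
    "bh_adjust",
]


@dataclass
class PermutationResult:
    """Observed vs permuted feature overlap of a CO set."""

    observed: int
    null_mean: float
    null_sd: float
    n_perm: int
    seed: int
    null: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    degenerate: bool = False

    @property
    def z_score(self) -> float:
        if self.degenerate or self.null_sd == 0:
            return np.nan
        return (self.observed - self.null_mean) / self.null_sd

    @property
    def empirical_p(self) -> float:
        """Two-sided empirical p with a +1 pseudo-count (never zero)."""
        if self.degenerate or len(self.null) == 0:
            return 1.0
        dev = abs(self.observed - self.null_mean)
        r = int(np.sum(np.abs(self.null - self.null_mean) >= dev))
        return (r + 1) / (self.n_perm + 1)

    @property
    def normal_p(self) -> float:
        """Two-sided normal-tail p from the z-score (for extreme tails)."""
        z = self.z_score
        return np.nan if np.isnan(z) else float(2 * stats.norm.sf(abs(z)))


def permutation_enrichment(
    cos: IntervalSet,
    features: IntervalSet,
    genome: GenomeLayout,
    n_perm: int = 10_000,
    seed: int = 0,
    within: IntervalSet | None = None,
    same_chrom: bool = False,
) -> PermutationResult:
    """Permutation test of CO-feature overlap.

    The observed statistic is the number of CO intervals overlapping the
    feature set by >= 1 bp; the null comes from ``n_perm`` uniform
    length-preserving shuffles of the CO set (restricted to ``within``
    when given, e.g. one compartment).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(features) == 0:
        raise ValueError("feature set is empty")
    from .genome_model import _draw_placements, _merged_arrays, _placement_slots

    rng = np.random.default_rng(seed)
    observed = count_overlapping(cos, features)

    if within is not None:
        allowed = merge_intervals(within)
        regions = [(iv.chrom, iv.start, iv.end) for iv in allowed]
    else:
        regions = [(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names]
    lengths = cos.lengths()
    iv_chroms = np.array([iv.chrom for iv in cos]) if same_chrom else None
    slots = _placement_slots(lengths, regions, iv_chroms)
    merged = {chrom: _merged_arrays(features, chrom) for chrom in features.chroms()}
    region_chrom = [r[0] for r in regions]

    null = np.empty(n_perm)
    for k in range(n_perm):
        ks, starts = _draw_placements(lengths, regions, slots, rng)
        ends = starts + lengths
        hits = 0
        for r, chrom in enumerate(region_chrom):
            if chrom not in merged:
                continue
            sel = ks == r
            if not sel.any():
                continue
            bs, be = merged[chrom]
            j = np.searchsorted(bs, ends[sel], side="left")
            ok = j > 0
            sub = np.zeros(int(sel.sum()), dtype=bool)
            sub[ok] = be[j[ok] - 1] > starts[sel][ok]
            hits += int(sub.sum())
        null[k] = hits
    sd = float(null.std(ddof=0))
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=sd,
        n_perm=n_perm,
        seed=seed,
        null=null,
        degenerate=sd == 0,
    )


def genic_enrichment(
    cos: IntervalSet,
    genes: IntervalSet,
    compartment: IntervalSet,
    genome: GenomeLayout,
    n_perm: int = 10_000,
    seed: int = 0,
    flank: int = 1000,
) -> PermutationResult:
    """Gene enrichment of the COs inside one compartment (DEU or PER).

    COs are restricted to the compartment; shuffles are placed within the
    same compartment only; gene intervals are widened by ``flank`` bp.
    """
    comp = merge_intervals(compartment)
    sub = IntervalSet(
        [iv for iv, bp in zip(cos, overlap_bp_per_interval(cos, comp)) if bp > 0],
        label=cos.label,
    )
    if len(sub) == 0:
        return PermutationResult(0, 0.0, 0.0, n_perm, seed, degenerate=True)
    flanked = IntervalSet(
        Interval(
            iv.chrom,
            max(0, iv.start - flank),
            min(genome.chrom_lengths[iv.chrom], iv.end + flank),
        )
        for iv in genes
    )
    # a CO wider than every allowed slot cannot be shuffled inside the
    # compartment; clip such events to their compartment overlap
    max_slot = max(iv.length for iv in comp)
    clipped = IntervalSet(
        [
            iv
            if iv.length <= max_slot
            else next(iter(intersect(IntervalSet([iv]), comp)))
            for iv in sub
        ],
        label=sub.label,
    )
    return permutation_enrichment(
        clipped, flanked, genome, n_perm=n_perm, seed=seed, within=comp
    )


def overlap_fisher(
    cos_a: IntervalSet,
    cos_b: IntervalSet,
    genome: GenomeLayout,
    window: int = 10_000,
) -> dict:
    """Fisher's exact test of window co-occupancy by two CO sets.

    The genome is tiled into non-overlapping ``window`` bp windows; each
    window is scored for containing a CO of either set; the 2x2 table of
    window counts is tested two-sided. ``shared_fraction`` = windows with
    both / windows with either.
    """
    if len(cos_a) == 0 or len(cos_b) == 0:
        return {
            "odds_ratio": np.nan,
            "p_value": np.nan,
            "shared_fraction": np.nan,
            "table": None,
            "degenerate": True,
        }
    tiles = sliding_windows(genome, window, window)
    in_a = overlap_bp_per_interval(tiles, cos_a) > 0
    in_b = overlap_bp_per_interval(tiles, cos_b) > 0
    both = int(np.sum(in_a & in_b))
    only_a = int(np.sum(in_a & ~in_b))
    only_b = int(np.sum(~in_a & in_b))
    neither = int(np.sum(~in_a & ~in_b))
    table = [[both, only_a], [only_b, neither]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    either = both + only_a + only_b
    return {
        "odds_ratio": float(odds),
        "p_value": float(p),
        "shared_fraction": both / either if either else np.nan,
        "table": table,
        "degenerate": False,
    }


def landscape_density(
    cos: IntervalSet,
    genome: GenomeLayout,
    bandwidth: float = 100_000,
    grid: int = 10_000,
) -> pd.DataFrame:
    """Gaussian KDE of CO midpoints per chromosome (bandwidth in bp).

    The density is scaled so that its trapezoid integral over a
    chromosome approximates that chromosome's CO count (events per bp,
    times count).
    """
    if len(cos) == 0:
        raise ValueError("need at least one CO")
    rows = []
    for chrom in genome.chrom_names:
        mids = np.array([iv.midpoint for iv in cos if iv.chrom == chrom], dtype=float)
        L = genome.chrom_lengths[chrom]
        xs = np.arange(0, L + 1, grid, dtype=float)
        if len(mids) == 0:
            dens = np.zeros_like(xs)
        else:
            # sum of Gaussian kernels, one per CO midpoint
            z = (xs[:, None] - mids[None, :]) / bandwidth
            dens = np.exp(-0.5 * z**2).sum(axis=1) / (bandwidth * np.sqrt(2 * np.pi))
        rows.append(
            pd.DataFrame({"chrom": chrom, "pos": xs.astype(int), "density": dens})
        )
    return pd.concat(rows, ignore_index=True)


def window_counts(
    cos: IntervalSet, genome: GenomeLayout, window: int = 500_000, step: int = 50_000
) -> pd.DataFrame:
    """CO counts (>= 1 bp overlap) in sliding windows, genome-wide."""
    tiles = sliding_windows(genome, window, step)
    counts = np.zeros(len(tiles), dtype=int)
    # per chromosome, compute the window index range each event touches
    tile_list = list(tiles)
    index_of = {}
    for k, w in enumerate(tile_list):
        index_of.setdefault(w.chrom, []).append(k)
    for iv in cos:
        ks = index_of.get(iv.chrom)
        if not ks:
            continue
        lo = max(0, -(-(iv.start - window + 1) // step))
        hi = min((iv.end - 1) // step, len(ks) - 1)
        for i in range(lo, hi + 1):
            counts[ks[i]] += 1
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in tile_list],
            "start": [w.start for w in tile_list],
            "end": [w.end for w in tile_list],
            "count": counts,
        }
    )


def landscape_correlation(
    cos_by_hybrid: dict[str, IntervalSet],
    genome: GenomeLayout,
    window: int = 500_000,
    step: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of windowed CO counts across hybrids.

    Returns (rho matrix, p-value matrix) as symmetric DataFrames with a
    unit diagonal; pairs with a constant count vector get NaN.
    """
    if len(cos_by_hybrid) < 2:
        raise ValueError("need at least two hybrids")
    vectors = {
        h: window_counts(cos, genome, window, step)["count"].to_numpy()
        for h, cos in cos_by_hybrid.items()
    }
    hybrids = list(vectors)
    rho = pd.DataFrame(np.eye(len(hybrids)), index=hybrids, columns=hybrids)
    pval = pd.DataFrame(np.zeros((len(hybrids), len(hybrids))), index=hybrids, columns=hybrids)
    for i, a in enumerate(hybrids):
        for j in range(i + 1, len(hybrids)):
            b = hybrids[j]
            if np.all(vectors[a] == vectors[a][0]) or np.all(vectors[b] == vectors[b][0]):
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(vectors[a], vectors[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def sv_distance_profile(
    cos: IntervalSet,
    svs: IntervalSet,
    genome: GenomeLayout,
    n_perm: int = 0,
    seed: int = 0,
    bins: np.ndarray | None = None,
) -> dict:
    """Signed CO-to-nearest-SV distances, with an optional shuffled null band.

    Distances are signed (negative: nearest SV upstream, positive:
    downstream, 0: overlapping). The null band holds one histogram per
    length-preserving shuffle of the CO set.
    """
    if len(cos) == 0 or len(svs) == 0:
        raise ValueError("both interval sets must be non-empty")
    observed = distance_to_nearest(cos, svs)
    if bins is None:
        bins = np.linspace(-100_000, 100_000, 41)
    obs_hist, _ = np.histogram(observed[~np.isnan(observed)], bins=bins)
    null_hists = []
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = shuffle_intervals(cos, genome, rng)
        d = distance_to_nearest(perm, svs)
        h, _ = np.histogram(d[~np.isnan(d)], bins=bins)
        null_hists.append(h)
    return {
        "distances": observed,
        "bins": bins,
        "observed_hist": obs_hist,
        "null_hists": np.array(null_hists),
    }


def spearman_feature_correlation(
    feature_cov: np.ndarray, co_counts: np.ndarray
) -> tuple[float, float]:
    """Spearman rho of per-window feature coverage vs CO count."""
    feature_cov = np.asarray(feature_cov)
    co_counts = np.asarray(co_counts)
    if len(feature_cov) != len(co_counts):
        raise ValueError("window vectors must be aligned")
    if np.all(feature_cov == feature_cov[0]) or np.all(co_counts == co_counts[0]):
        return np.nan, np.nan
    r, p = stats.spearmanr(feature_cov, co_counts)
    return float(r), float(p)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


def enrichment_table(
    cos: IntervalSet,
    feature_tracks: dict[str, IntervalSet],
    genome: GenomeLayout,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of COs against several feature tracks.

    One row per track (e.g. TE superfamily) with observed counts, null
    moments, z-score and raw/BH-adjusted empirical p-values.
    """
    rows = []
    for k, (name, track) in enumerate(sorted(feature_tracks.items())):
        res = permutation_enrichment(
            cos, track, genome, n_perm=n_perm, seed=seed + k
        )
        rows.append(
            (
                name,
                res.observed,
                res.null_mean,
                res.null_sd,
                res.z_score,
                res.empirical_p,
                res.normal_p,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["feature", "observed", "null_mean", "null_sd", "z", "p_raw", "p_normal"],
    )
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    return df
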