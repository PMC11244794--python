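"""Permutation tests, Fisher overlap, landscapes, distance profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldspot_atlas.enrichment_stats import (
    bh_adjust,
    enrichment_table,
    genic_enrichment,
    landscape_correlation,
    landscape_density,
    overlap_fisher,
    permutation_enrichment,
    spearman_feature_correlation,
    sv_distance_profile,
    window_counts,
)
from coldspot_atlas.genome_model import (
    GenomeLayout,
    Interval,
    IntervalSet,
    shuffle_intervals,
)


@pytest.fixture
def genome():
    return GenomeLayout(["c1", "c2"], {"c1": 2_000_000, "c2": 2_000_000})


def uniform_cos(rng, genome, n, width=1_000):
    out = []
    for _ in range(n):
        chrom = genome.chrom_names[rng.integers(0, len(genome.chrom_names))]
        s = int(rng.integers(0, genome.chrom_lengths[chrom] - width))
        out.append(Interval(chrom, s, s + width))
    return IntervalSet(out)


class TestPermutationEnrichment:
    def test_cos_inside_features_strongly_enriched(self, genome):
        """COs planted inside a 10% feature set: observed n, null ~ 0.1 n."""
        rng = np.random.default_rng(1)
        features = IntervalSet(
            [Interval("c1", 0, 200_000), Interval("c2", 0, 200_000)]
        )  # 10% of the genome
        cos = IntervalSet(
            [
                Interval("c1", int(s), int(s) + 500)
                for s in rng.integers(0, 199_500, size=500)
            ]
        )
        res = permutation_enrichment(cos, features, genome, n_perm=1000, seed=2)
        assert res.observed == 500
        assert res.null_mean == pytest.approx(0.1 * 500, rel=0.25)
        assert res.z_score > 10
        assert res.empirical_p == pytest.approx(1 / 1001)

    def test_cos_outside_features_suppressed(self, genome):
        features = IntervalSet([Interval("c1", 0, 1_000_000)])
        cos = IntervalSet(
            [Interval("c2", s, s + 500) for s in range(0, 300_000, 3_000)]
        )
        res = permutation_enrichment(cos, features, genome, n_perm=500, seed=3)
        assert res.observed == 0
        assert res.z_score < -3

    def test_whole_genome_features_degenerate(self, genome):
        features = IntervalSet(
            Interval(c, 0, genome.chrom_lengths[c]) for c in genome.chrom_names
        )
        cos = IntervalSet([Interval("c1", 10, 1_000)])
        res = permutation_enrichment(cos, features, genome, n_perm=200, seed=4)
        assert res.degenerate
        assert res.observed == len(cos)
        assert np.isnan(res.z_score) and res.empirical_p == 1.0

    def test_reproducible_for_fixed_seed(self, genome):
        rng = np.random.default_rng(0)
        cos = uniform_cos(rng, genome, 100)
        features = IntervalSet([Interval("c1", 500_000, 800_000)])
        a = permutation_enrichment(cos, features, genome, n_perm=300, seed=9)
        b = permutation_enrichment(cos, features, genome, n_perm=300, seed=9)
        assert np.array_equal(a.null, b.null) and a.observed == b.observed

    def test_null_matches_library_shuffle_route(self, genome):
        """The fast permutation core agrees statistically with shuffle_intervals."""
        rng = np.random.default_rng(12)
        cos = uniform_cos(rng, genome, 200)
        features = IntervalSet([Interval("c1", 0, 400_000)])
        res = permutation_enrichment(cos, features, genome, n_perm=2000, seed=5)
        null2 = []
        srng = np.random.default_rng(777)
        from coldspot_atlas.genome_model import count_overlapping

        for _ in range(400):
            null2.append(
                count_overlapping(shuffle_intervals(cos, genome, srng), features)
            )
        assert res.null_mean == pytest.approx(np.mean(null2), rel=0.1)
        assert res.null_sd == pytest.approx(np.std(null2), rel=0.35)


class TestGenicEnrichment:
    def test_cos_only_in_genes_positive(self, genome):
        deu = IntervalSet([Interval("c1", 0, 1_000_000), Interval("c2", 0, 1_000_000)])
        rng = np.random.default_rng(6)
        genes = IntervalSet(
            [Interval("c1", int(s), int(s) + 3_000) for s in range(0, 900_000, 30_000)]
        )
        cos = IntervalSet(
            [
                Interval("c1", int(s) + 500, int(s) + 1_500)
                for s in rng.choice(range(0, 900_000, 30_000), size=200)
            ]
        )
        res = genic_enrichment(cos, genes, deu, genome, n_perm=500, seed=7)
        assert res.z_score > 3

    def test_empty_compartment_flagged(self, genome):
        deu = IntervalSet([Interval("c1", 0, 1_000_000)])
        cos = IntervalSet([Interval("c2", 1_500_000, 1_501_000)])
        res = genic_enrichment(cos, IntervalSet([Interval("c1", 0, 10_000)]), deu, genome)
        assert res.degenerate and res.observed == 0


class TestOverlapFisher:
    def test_identical_sets(self, genome):
        cos = IntervalSet([Interval("c1", s, s + 1_000) for s in range(0, 500_000, 50_000)])
        res = overlap_fisher(cos, cos, genome)
        assert res["shared_fraction"] == 1.0
        assert np.isinf(res["odds_ratio"])
        assert res["p_value"] < 1e-6

    def test_hand_table_matches_hypergeometric(self, genome):
        # construct window occupancy giving table [[10,5],[5,80]]
        w = 10_000
        cos_a, cos_b = [], []
        k = 0
        for n, (a, b) in [(10, (1, 1)), (5, (1, 0)), (5, (0, 1)), (80, (0, 0))]:
            for _ in range(n):
                start = k * w
                chrom = "c1" if start < 2_000_000 else "c2"
                s = start % 2_000_000
                if a:
                    cos_a.append(Interval(chrom, s + 100, s + 200))
                if b:
                    cos_b.append(Interval(chrom, s + 300, s + 400))
                k += 1
        small = GenomeLayout(["c1"], {"c1": 1_000_000})
        res = overlap_fisher(IntervalSet(cos_a), IntervalSet(cos_b), small, window=w)
        assert res["table"] == [[10, 5], [5, 80]]
        _, p_oracle = stats.fisher_exact([[10, 5], [5, 80]])
        assert res["p_value"] == pytest.approx(p_oracle)

    def test_empty_set_degenerate(self, genome):
        res = overlap_fisher(IntervalSet(), IntervalSet([Interval("c1", 0, 10)]), genome)
        assert res["degenerate"] and np.isnan(res["p_value"])

    def test_exhaustive_fisher_equals_hypergeometric_oracle(self):
        """scipy's two-sided Fisher == direct hypergeometric enumeration."""
        rng = np.random.default_rng(0)
        checked = 0
        for total in range(2, 51, 4):
            for _ in range(40):
                a, b, c = rng.multinomial(total, [1 / 3, 1 / 3, 1 / 3])[:3]
                d = total - a - b - c
                if d < 0:
                    continue
                table = np.array([[a, b], [c, d]])
                _, p = stats.fisher_exact(table)
                # oracle: sum hypergeometric pmf over tables at least as extreme
                M, n, N = table.sum(), a + b, a + c
                support = np.arange(max(0, n + N - M), min(n, N) + 1)
                pmf = stats.hypergeom.pmf(support, M, n, N)
                p_oracle = pmf[pmf <= pmf[support == a] * (1 + 1e-9)].sum()
                assert p == pytest.approx(p_oracle, abs=1e-9)
                checked += 1
        assert checked > 300


class TestLandscape:
    def test_single_co_unimodal_at_midpoint(self, genome):
        cos = IntervalSet([Interval("c1", 999_000, 1_001_000)])
        track = landscape_density(cos, genome)
        sub = track[track.chrom == "c1"]
        assert sub.loc[sub.density.idxmax(), "pos"] == 1_000_000

    def test_two_distant_cos_two_equal_modes(self, genome):
        cos = IntervalSet(
            [Interval("c1", 499_000, 501_000), Interval("c1", 1_499_000, 1_501_000)]
        )
        track = landscape_density(cos, genome)
        sub = track[track.chrom == "c1"].reset_index(drop=True)
        d1 = sub.loc[sub.pos == 500_000, "density"].iloc[0]
        d2 = sub.loc[sub.pos == 1_500_000, "density"].iloc[0]
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_integral_matches_co_count(self, genome):
        """Trapezoid integral per chromosome ~ CO count (1% tolerance)."""
        rng = np.random.default_rng(8)
        cos = IntervalSet(
            [
                Interval("c1", int(s), int(s) + 1_000)
                for s in rng.integers(400_000, 1_600_000, size=37)
            ]
        )
        track = landscape_density(cos, genome, bandwidth=50_000, grid=5_000)
        sub = track[track.chrom == "c1"]
        integral = np.trapezoid(sub.density.to_numpy(), sub.pos.to_numpy())
        assert integral == pytest.approx(37, rel=0.01)

    def test_window_counts_match_direct_overlap(self, genome):
        rng = np.random.default_rng(10)
        cos = uniform_cos(rng, genome, 60)
        wc = window_counts(cos, genome, window=500_000, step=50_000)
        for row in wc.sample(40, random_state=0).itertuples():
            expect = sum(
                1
                for iv in cos
                if iv.chrom == row.chrom and iv.start < row.end and iv.end > row.start
            )
            assert row.count == expect

    def test_correlation_matrix_properties(self, genome):
        rng = np.random.default_rng(11)
        shared = uniform_cos(rng, genome, 150)
        a = IntervalSet(list(shared) + list(uniform_cos(rng, genome, 30)), label="A")
        b = IntervalSet(list(shared) + list(uniform_cos(rng, genome, 30)), label="B")
        c = uniform_cos(rng, genome, 150)
        rho, p = landscape_correlation({"A": a, "B": b, "C": c}, genome)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.loc["A", "B"] == rho.loc["B", "A"]
        assert rho.loc["A", "B"] > rho.loc["A", "C"]
        assert p.loc["A", "B"] < 1e-10

    def test_constant_vector_flagged(self, genome):
        empty_chrom = IntervalSet([Interval("c1", 0, 500)])
        with_cos = IntervalSet([Interval("c1", 0, 500), Interval("c2", 0, 500)])
        rho, _ = landscape_correlation(
            {"A": empty_chrom, "B": with_cos}, genome, window=2_000_000, step=2_000_000
        )
        assert np.isnan(rho.loc["A", "B"])


class TestDistanceProfile:
    def test_all_cos_inside_svs(self, genome):
        svs = IntervalSet([Interval("c1", 100_000, 200_000)])
        cos = IntervalSet([Interval("c1", 150_000, 151_000)] * 5)
        prof = sv_distance_profile(cos, svs, genome)
        assert np.all(prof["distances"] == 0)

    def test_spike_at_plus_5kb(self, genome):
        svs = IntervalSet(
            [Interval("c1", s, s + 10_000) for s in range(100_000, 900_000, 100_000)]
        )
        cos = IntervalSet(
            [Interval("c1", s - 6_000, s - 5_000) for s in range(100_000, 900_000, 100_000)]
        )
        prof = sv_distance_profile(cos, svs, genome)
        assert np.all(prof["distances"] == 5_000)

    def test_null_band_reproducible(self, genome):
        rng = np.random.default_rng(13)
        cos = uniform_cos(rng, genome, 40)
        svs = uniform_cos(rng, genome, 10, width=20_000)
        p1 = sv_distance_profile(cos, svs, genome, n_perm=20, seed=3)
        p2 = sv_distance_profile(cos, svs, genome, n_perm=20, seed=3)
        assert np.array_equal(p1["null_hists"], p2["null_hists"])


class TestFeatureCorrelation:
    def test_perfect_rank_agreement(self):
        x = np.arange(50, dtype=float)
        rho, p = spearman_feature_correlation(x, x**2)
        assert rho == pytest.approx(1.0)

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(14)
        rho, _ = spearman_feature_correlation(rng.random(2000), rng.random(2000))
        assert abs(rho) < 0.1

    def test_constant_flagged(self):
        rho, p = spearman_feature_correlation(np.ones(10), np.arange(10))
        assert np.isnan(rho)


def test_bh_adjust_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.9])
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all((0 <= adj) & (adj <= 1))


def test_enrichment_table_columns(genome):
    rng = np.random.default_rng(15)
    cos = uniform_cos(rng, genome, 50)
    tracks = {
        "fam1": IntervalSet([Interval("c1", 0, 300_000)]),
        "fam2": IntervalSet([Interval("c2", 0, 300_000)]),
    }
    df = enrichment_table(cos, tracks, genome, n_perm=100, seed=0)
    assert list(df["feature"]) == ["fam1", "fam2"]
    assert {"observed", "z", "p_raw", "p_adj"} <= set(df.columns)
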