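"""CO regions, coldspot detection, conserved intersection, clustering, Marey."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coldspot_atlas.coldspot_catalog import (
    Coldspot,
    build_co_regions,
    cluster_coldspots,
    clusters_to_frame,
    coldspots_to_frame,
    conserved_coldspots,
    detect_coldspots,
    jaccard_distance,
    marey_rate,
)
from coldspot_atlas.crossover_detection import CrossoverEvent, MarkerSet, detect_crossovers
from coldspot_atlas.genome_model import (
    GenomeLayout,
    Interval,
    IntervalSet,
    coverage,
    intersect,
    merge_intervals,
)

from conftest import bitmap, bitmap_to_intervals


def ev(chrom, left, right, hybrid="H"):
    return CrossoverEvent(hybrid, chrom, left, right, "m")


def cs(chrom, start, end, hybrid="H"):
    return Coldspot(hybrid, Interval(chrom, start, end), marker_count=5)


class TestCoRegions:
    def test_two_cos_one_region(self):
        """COs at 12 kb and 13 kb: windows [5k,15k) + [10k,20k) -> [5k,20k)."""
        g = GenomeLayout(["c"], {"c": 40_000})
        regions = build_co_regions([ev("c", 12_000, 12_001), ev("c", 13_000, 13_001)], g)
        assert [(i.chrom, i.start, i.end) for i in regions.intervals] == [("c", 5_000, 20_000)]

    def test_no_cos(self):
        g = GenomeLayout(["c"], {"c": 40_000})
        assert len(build_co_regions([], g).intervals) == 0

    def test_co_spanning_window_boundary_counts_for_both(self):
        g = GenomeLayout(["c"], {"c": 40_000})
        regions = build_co_regions([ev("c", 9_900, 10_100)], g)
        wins = set(map(tuple, regions.window_counts[["start", "end"]].to_numpy()))
        assert (5_000, 15_000) in wins and (10_000, 20_000) in wins
        assert (0, 10_000) in wins  # overlaps [9900,10000)

    def test_windows_against_overlap_oracle(self):
        """Selected windows == enumerate-all-windows oracle on random events."""
        rng = np.random.default_rng(3)
        g = GenomeLayout(["c"], {"c": 200_000})
        for _ in range(50):
            events = [
                ev("c", s, s + int(rng.integers(1, 3_000)))
                for s in rng.integers(0, 190_000, size=rng.integers(1, 10))
            ]
            events = [e for e in events if e.right_marker <= 200_000]
            regions = build_co_regions(events, g)
            # oracle: materialize every window, test overlap directly
            expected = []
            for start in range(0, 200_000, 5_000):
                end = min(start + 10_000, 200_000)
                if any(e.left_marker < end and e.right_marker > start for e in events):
                    expected.append(Interval("c", start, end))
            merged = merge_intervals(IntervalSet(expected), gap=1_000)
            assert list(regions.intervals) == list(merged)


class TestColdspots:
    def make_regions(self, intervals, hybrid="H"):
        from coldspot_atlas.coldspot_catalog import CoRegionSet

        return CoRegionSet(hybrid, IntervalSet(intervals))

    def test_complement_and_min_size(self):
        g = GenomeLayout(["c"], {"c": 30_000_000})
        regions = self.make_regions([Interval("c", 5_000_000, 5_020_000)])
        markers = MarkerSet({"c": np.arange(1_000, 30_000_000, 10_000)})
        spots, flagged = detect_coldspots(regions, g, markers)
        assert [(c.interval.start, c.interval.end) for c in spots] == [
            (0, 5_000_000),
            (5_020_000, 30_000_000),
        ]
        assert flagged == []

    def test_sub_mb_gap_not_a_coldspot(self):
        g = GenomeLayout(["c"], {"c": 3_000_000})
        regions = self.make_regions(
            [Interval("c", 0, 1_100_000), Interval("c", 2_000_000, 3_000_000)]
        )
        markers = MarkerSet({"c": np.arange(100, 3_000_000, 5_000)})
        spots, _ = detect_coldspots(regions, g, markers)
        assert spots == []  # the 0.9 Mb gap is below the floor

    def test_zero_marker_gap_flagged_not_catalogued(self):
        g = GenomeLayout(["c"], {"c": 4_000_000})
        regions = self.make_regions([Interval("c", 1_500_000, 1_600_000)])
        markers = MarkerSet({"c": np.arange(100, 1_500_000, 5_000)})  # left arm only
        spots, flagged = detect_coldspots(regions, g, markers)
        assert [(c.interval.start, c.interval.end) for c in spots] == [(0, 1_500_000)]
        assert [(c.interval.start, c.interval.end) for c in flagged] == [
            (1_600_000, 4_000_000)
        ]
        assert flagged[0].marker_count == 0

    def test_coldspots_never_overlap_own_co_regions(self, corpus):
        for hybrid, hc in corpus.hybrids.items():
            events, _ = detect_crossovers(hc.molecules, hybrid_id=hybrid)
            regions = build_co_regions(events, corpus.genome, hybrid_id=hybrid)
            spots, _ = detect_coldspots(regions, corpus.genome, hc.markers)
            spot_set = IntervalSet([c.interval for c in spots])
            assert len(intersect(spot_set, regions.intervals)) == 0

    def test_deu_per_split_sums_to_length(self, corpus):
        hc = corpus.hybrids["PM"]
        events, _ = detect_crossovers(hc.molecules, hybrid_id="PM")
        regions = build_co_regions(events, corpus.genome, hybrid_id="PM")
        spots, _ = detect_coldspots(regions, corpus.genome, hc.markers)
        assert spots, "fixture corpus must contain coldspots"
        for c in spots:
            assert c.deu_bp + c.per_bp == c.length


class TestConserved:
    def test_identical_in_all_five(self):
        g = GenomeLayout(["c"], {"c": 10_000_000})
        per_hybrid = {h: [cs("c", 0, 3_000_000, h)] for h in "ABCDE"}
        conserved, info = conserved_coldspots(per_hybrid, g)
        assert [(i.start, i.end) for i in conserved] == [(0, 3_000_000)]
        assert info["bp"] == 3_000_000
        assert info["fraction"] == pytest.approx(0.3)

    def test_one_hybrid_with_hole(self):
        g = GenomeLayout(["c"], {"c": 10_000_000})
        per_hybrid = {h: [cs("c", 0, 3_000_000, h)] for h in "ABCD"}
        per_hybrid["E"] = [cs("c", 0, 1_000_000, "E"), cs("c", 1_200_000, 3_000_000, "E")]
        conserved, info = conserved_coldspots(per_hybrid, g)
        assert [(i.start, i.end) for i in conserved] == [
            (0, 1_000_000),
            (1_200_000, 3_000_000),
        ]

    def test_empty_hybrid_gives_empty_conserved(self):
        g = GenomeLayout(["c"], {"c": 10_000_000})
        per_hybrid = {"A": [cs("c", 0, 2_000_000, "A")], "B": []}
        conserved, info = conserved_coldspots(per_hybrid, g)
        assert len(conserved) == 0 and info["bp"] == 0


class TestJaccardDistance:
    def test_examples(self):
        a = Interval("c", 0, 100)
        assert jaccard_distance(a, a) == 0.0
        assert jaccard_distance(a, Interval("c", 500, 600)) == 1.0
        assert jaccard_distance(a, Interval("c", 50, 150)) == pytest.approx(2 / 3)
        assert jaccard_distance(a, Interval("d", 0, 100)) == 1.0

    @given(
        s1=st.integers(0, 1000), l1=st.integers(1, 1000),
        s2=st.integers(0, 1000), l2=st.integers(1, 1000),
    )
    @settings(max_examples=300, derandomize=True)
    def test_equals_one_minus_jaccard(self, s1, l1, s2, l2):
        i, j = Interval("c", s1, s1 + l1), Interval("c", s2, s2 + l2)
        inter = i.overlap_bp(j)
        union = i.length + j.length - inter
        assert jaccard_distance(i, j) == pytest.approx(1 - inter / union)


class TestClustering:
    def test_five_identical_coldspots_one_shared_cluster(self):
        spots = [cs("c", 0, 1_000_000, h) for h in "ABCDE"]
        clusters = cluster_coldspots(spots)
        assert len(clusters) == 1
        assert clusters[0].cls == "shared" and len(clusters[0].members) == 5

    def test_weak_overlap_two_unique_clusters(self):
        """0.1 Mb overlap of two 1 Mb spots: reciprocal 0.1 < 0.5, no edge."""
        spots = [cs("c", 0, 1_000_000, "A"), cs("c", 900_000, 2_000_000, "A")]
        clusters = cluster_coldspots(spots)
        assert len(clusters) == 2
        assert all(c.cls == "unique" for c in clusters)

    def test_narrow_component_single_cluster(self):
        """Three 1 Mb spots spanning 1.4 Mb < 1.5 Mb: no re-clustering."""
        spots = [
            cs("c", 0, 1_000_000, "A"),
            cs("c", 200_000, 1_200_000, "B"),
            cs("c", 400_000, 1_400_000, "C"),
        ]
        clusters = cluster_coldspots(spots)
        assert len(clusters) == 1 and not clusters[0].reclustered
        assert clusters[0].cls == "shared"

    def test_wide_component_is_reclustered(self):
        """A chained component spanning >= 1.5x its smallest member splits."""
        spots = [
            cs("c", 0, 1_000_000, "A"),
            cs("c", 450_000, 1_450_000, "B"),  # d(A,B) = 0.6..., chained
            cs("c", 900_000, 1_900_000, "C"),
        ]
        clusters = cluster_coldspots(spots)
        assert all(c.reclustered for c in clusters)
        # complete linkage at 0.3: only near-identical members stay together
        assert len(clusters) == 3

    def test_singleton(self):
        clusters = cluster_coldspots([cs("c", 0, 1_500_000, "A")])
        assert len(clusters) == 1 and clusters[0].cls == "unique"

    def test_permutation_invariance(self, corpus):
        rng = np.random.default_rng(0)
        spots = []
        for hybrid, hc in corpus.hybrids.items():
            events, _ = detect_crossovers(hc.molecules, hybrid_id=hybrid)
            regions = build_co_regions(events, corpus.genome, hybrid_id=hybrid)
            spots.extend(detect_coldspots(regions, corpus.genome, hc.markers)[0])
        ref = clusters_to_frame(cluster_coldspots(spots)).sort_values(
            ["chrom", "start", "hybrid"]
        ).reset_index(drop=True)
        for _ in range(3):
            shuffled = list(spots)
            rng.shuffle(shuffled)
            got = clusters_to_frame(cluster_coldspots(shuffled)).sort_values(
                ["chrom", "start", "hybrid"]
            ).reset_index(drop=True)
            pd.testing.assert_frame_equal(
                ref.drop(columns=["cluster_id", "component_id"]),
                got.drop(columns=["cluster_id", "component_id"]),
            )

    def test_every_coldspot_in_exactly_one_cluster(self, corpus):
        spots = []
        for hybrid, hc in corpus.hybrids.items():
            events, _ = detect_crossovers(hc.molecules, hybrid_id=hybrid)
            regions = build_co_regions(events, corpus.genome, hybrid_id=hybrid)
            spots.extend(detect_coldspots(regions, corpus.genome, hc.markers)[0])
        clusters = cluster_coldspots(spots)
        member_keys = [
            (c.hybrid_id, c.interval.chrom, c.interval.start, c.interval.end)
            for cl in clusters
            for c in cl.members
        ]
        assert len(member_keys) == len(spots)
        assert len(set(member_keys)) == len(spots)


class TestMareyRate:
    def test_linear_map(self):
        gm = pd.DataFrame({"bp": [0, 1_000_000, 2_000_000], "cM": [0.0, 1.0, 2.0]})
        out = marey_rate(gm)
        assert list(out["cM_per_Mb"]) == pytest.approx([1.0, 1.0])

    def test_flat_segment_is_zero_rate(self):
        gm = pd.DataFrame({"bp": [0, 1_000_000, 2_000_000], "cM": [0.0, 0.0, 3.0]})
        out = marey_rate(gm)
        assert list(out["cM_per_Mb"]) == pytest.approx([0.0, 3.0])

    def test_decreasing_pairs_flagged(self):
        gm = pd.DataFrame(
            {"bp": [0, 1_000_000, 2_000_000, 3_000_000], "cM": [0.0, 2.0, 1.0, 3.0]}
        )
        out = marey_rate(gm)
        assert out.attrs["n_flagged"] == 1
        assert list(out["cM_per_Mb"]) == pytest.approx([2.0, 0.5])
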