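"""Coverage, counting, hallmark statistics, normalization and clustering."""

import numpy as np
import pandas as pd
import pytest

from mitosrna import (
    Alignment,
    CircularGenome,
    CountMatrix,
    Feature,
    build_coverage,
    build_index,
    chromosome_distribution,
    feature_counts,
    five_prime_arm_read_fraction,
    hierarchical_cluster,
    length_distribution,
    log2_normalize,
    numt_overlap,
    positional_nucleotide_freq,
    reads_per_kb,
    size_factors,
    trna_arm_coverage,
)
from mitosrna.profiles import CoverageTrack
from mitosrna.readprep import CollapsedLibrary


def aln(start, length, strand="+", ref="mt"):
    return Alignment("A" * length, ref, start, strand, 0)


@pytest.fixture
def genome100():
    rng = np.random.default_rng(0)
    return CircularGenome("mt", "".join(rng.choice(list("ACGT"), size=100)))


class TestCoverage:
    def test_mass_conservation_simple(self, genome100):
        track = build_coverage(
            [(aln(0, 5), 1), (aln(50, 5), 1)], genome100
        )
        assert track.depth_plus.sum() == 10
        assert track.depth_minus.sum() == 0

    def test_count_weighting(self, genome100):
        track = build_coverage([(aln(3, 5), 7)], genome100)
        assert (track.depth_plus[3:8] == 7).all()
        assert track.depth_plus.sum() == 35

    def test_wrapping_read_splits_at_junction(self, genome100):
        track = build_coverage([(aln(97, 6), 2)], genome100)
        assert (track.depth_plus[97:] == 2).all()
        assert (track.depth_plus[:3] == 2).all()
        assert track.total_mass == 12

    def test_against_interval_stabbing_oracle(self, genome100):
        rng = np.random.default_rng(5)
        weighted = [
            (
                aln(int(rng.integers(0, 100)), int(rng.integers(18, 30)),
                    str(rng.choice(["+", "-"]))),
                int(rng.integers(1, 9)),
            )
            for _ in range(50)
        ]
        track = build_coverage(weighted, genome100)
        for strand in "+-":
            expected = np.zeros(100, dtype=int)
            for a, count in weighted:
                if a.strand != strand:
                    continue
                for offset in range(a.length):
                    expected[(a.start + offset) % 100] += count
            assert (track.depth(strand) == expected).all()


class TestFeatureCounts:
    features = [
        Feature("A", "protein_coding", 90, 130, "+"),
        Feature("B", "protein_coding", 130, 180, "+"),
    ]

    def test_five_prime_containment(self):
        cm = feature_counts([(aln(100, 25), 3)], self.features, 200)
        assert cm.counts.loc[("A", "+"), "sample"] == 3

    def test_spanning_read_counted_once_by_five_prime(self):
        cm = feature_counts([(aln(128, 22), 1)], self.features, 200)
        assert cm.counts.loc[("A", "+"), "sample"] == 1
        assert ("B", "+") not in cm.counts.index

    def test_minus_strand_five_prime_is_right_edge(self):
        # read [128, 150) on '-': biological 5' end at 149, inside B
        cm = feature_counts([(aln(128, 22, "-"), 1)], self.features, 200)
        assert cm.counts.loc[("B", "-"), "sample"] == 1

    def test_conservation_with_intergenic(self):
        rng = np.random.default_rng(2)
        weighted = [
            (aln(int(rng.integers(0, 180)), 20,
                 str(rng.choice(["+", "-"]))), int(rng.integers(1, 5)))
            for _ in range(40)
        ]
        cm = feature_counts(weighted, self.features, 200)
        assert cm.counts["sample"].sum() == sum(c for _, c in weighted)


class TestTrnaArms:
    trna_plus = Feature("t1", "tRNA", 100, 170, "+", anticodon_start=133)
    trna_minus = Feature("t2", "tRNA", 100, 170, "-", anticodon_start=133)

    def track(self, depth_intervals, strand="+"):
        plus = np.zeros(300, dtype=int)
        minus = np.zeros(300, dtype=int)
        arr = plus if strand == "+" else minus
        for (s, e), d in depth_intervals:
            arr[s:e] = d
        return CoverageTrack("mt", plus, minus)

    def test_five_prime_only_coverage(self):
        track = self.track([((100, 133), 10)])
        (arm,) = trna_arm_coverage(track, [self.trna_plus])
        assert arm.mean_5prime == 10
        assert arm.mean_3prime == 0
        assert arm.frac_5prime == 1.0

    def test_equal_arms_give_half(self):
        track = self.track([((100, 133), 4), ((136, 170), 4)])
        (arm,) = trna_arm_coverage(track, [self.trna_plus])
        assert arm.frac_5prime == 0.5

    def test_minus_strand_arms_are_mirrored(self):
        # depth on [136, 170) of the minus strand = biological 5' arm
        track = self.track([((136, 170), 6)], strand="-")
        (arm,) = trna_arm_coverage(track, [self.trna_minus])
        assert arm.mean_5prime == 6
        assert arm.mean_3prime == 0

    def test_anticodon_excluded_from_both_arms(self):
        track = self.track([((133, 136), 99)])
        (arm,) = trna_arm_coverage(track, [self.trna_plus])
        assert arm.mean_5prime == 0 and arm.mean_3prime == 0
        assert arm.frac_5prime is None

    def test_zero_length_arm_rejected_naming_the_trna(self):
        # an anticodon flush against either end would leave an empty arm;
        # such tRNAs are rejected at construction, by id
        with pytest.raises(ValueError, match="t3"):
            Feature("t3", "tRNA", 100, 136, "+", anticodon_start=100)
        with pytest.raises(ValueError, match="t3"):
            Feature("t3", "tRNA", 100, 136, "+", anticodon_start=133)

    def test_read_level_arm_fraction(self):
        # three reads with 5' end in the 5' arm, one in the 3' arm
        weighted = [(aln(105, 20), 2), (aln(120, 20), 1), (aln(140, 20), 1)]
        frac = five_prime_arm_read_fraction(weighted, [self.trna_plus], 300)
        assert frac == 3 / 4


class TestLengthDistribution:
    def test_subset_mode_sums_to_100(self):
        entries = {"A" * 20: 50, "C" * 25: 50}
        assert length_distribution(entries) == {20: 50.0, 25: 50.0}

    def test_library_mode_uses_external_denominator(self):
        entries = {"A" * 20: 50, "C" * 25: 50}
        out = length_distribution(entries, denominator_reads=1000)
        assert out == {20: 5.0, 25: 5.0}

    def test_empty_subset_is_empty(self):
        assert length_distribution({}) == {}


class TestPositionalFrequencies:
    def test_all_reads_start_with_u(self):
        entries = {"T" + "A" * 19: 5, "T" + "C" * 19: 5}
        freq = positional_nucleotide_freq(entries, positions=(1,))
        assert freq.loc[1, "U"] == 1.0

    def test_balanced_position_ten(self):
        entries = {
            "G" * 9 + b + "G" * 10: 1 for b in "ACGT"
        }
        freq = positional_nucleotide_freq(entries, positions=(10,))
        assert np.allclose(freq.loc[10], 0.25)

    def test_short_reads_excluded_from_late_positions(self):
        # the length-5 reads cannot contribute to position 10's denominator
        freq = positional_nucleotide_freq(
            {"AAAAA": 100, "A" * 9 + "C" * 11: 1}, positions=(10,)
        )
        assert freq.loc[10, "C"] == 1.0

    def test_rows_sum_to_one_weighted(self):
        entries = {"TACGTACGTACGTACGTAC": 7, "GACGTACGTAAGTACGTAC": 3}
        freq = positional_nucleotide_freq(entries)
        assert np.allclose(freq.sum(axis=1), 1.0)
        assert freq.loc[1, "U"] == 0.7


class TestDensity:
    def test_worked_density(self):
        assert round(reads_per_kb(100, 16_299), 3) == 6.135

    def test_zero_reads(self):
        assert reads_per_kb(0, 1000) == 0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            reads_per_kb(10, 0)

    def test_density_ratio_matches_construction(self):
        mt = reads_per_kb(500, 4000)
        nuc = reads_per_kb(500, 16_000)
        assert mt / nuc == 4.0


class TestSizeFactors:
    def test_median_of_ratios_worked_example(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        sf = size_factors(counts)
        assert np.allclose(sf.values, [0.7071, 1.4142], atol=5e-5)

    def test_identical_samples_have_unit_factors(self):
        counts = pd.DataFrame({f"s{i}": [5, 9, 14] for i in range(4)})
        assert np.allclose(size_factors(counts), 1.0)

    def test_scale_equivariance_against_fixed_reference(self):
        # against a fixed per-feature reference, scaling one sample's counts
        # by c scales exactly that sample's factor by c
        rng = np.random.default_rng(8)
        for _ in range(25):
            counts = pd.DataFrame(
                rng.integers(1, 200, size=(8, 4)).astype(float),
                columns=list("abcd"),
            )
            ref = np.exp(np.log(counts.to_numpy()).mean(axis=1))
            base = size_factors(counts, reference=ref)
            c = 3.0
            scaled = counts.copy()
            scaled["b"] = scaled["b"] * c
            out = size_factors(scaled, reference=ref)
            assert np.isclose(out["b"], base["b"] * c)
            for other in "acd":
                assert np.isclose(out[other], base[other])

    def test_self_referential_factors_scale_as_ratios(self):
        # without a fixed reference the geometric-mean reference itself
        # shifts, so only factor *ratios* are equivariant: f_b/f_j gains c
        rng = np.random.default_rng(18)
        counts = pd.DataFrame(
            rng.integers(1, 200, size=(8, 4)).astype(float),
            columns=list("abcd"),
        )
        base = size_factors(counts)
        c = 5.0
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * c
        out = size_factors(scaled)
        for other in "acd":
            assert np.isclose(
                out["b"] / out[other], c * base["b"] / base[other]
            )

    def test_no_common_feature_suggests_fallback(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        sf = size_factors(counts, allow_pseudo_reference=True)
        assert (sf > 0).all()


class TestLog2Normalize:
    def matrix(self, values):
        counts = pd.DataFrame({"s1": values})
        return CountMatrix(counts, pd.Series({"s1": 1.0}))

    def test_zero_maps_to_zero(self):
        assert log2_normalize(self.matrix([0])).iloc[0, 0] == 0.0

    def test_exact_power(self):
        assert log2_normalize(self.matrix([15])).iloc[0, 0] == 4.0

    def test_joint_doubling_invariance(self):
        counts = pd.DataFrame({"s1": [12, 30]})
        one = log2_normalize(CountMatrix(counts, pd.Series({"s1": 2.0})))
        two = log2_normalize(
            CountMatrix(counts * 2, pd.Series({"s1": 4.0}))
        )
        assert np.allclose(one.values, two.values)


class TestHierarchicalClustering:
    def test_identical_samples_merge_first(self):
        data = pd.DataFrame(
            {"A": [1, 2, 3, 4], "B": [1, 2, 3, 4], "C": [9, 1, 7, 2]}
        )
        Z, order = hierarchical_cluster(data, metric="euclidean")
        # first merge joins leaves 0 and 1 (A and B) at height 0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == 0.0
        assert set(order) == {"A", "B", "C"}

    def test_pearson_distance_of_self_is_zero(self):
        data = pd.DataFrame({"A": [1.0, 2, 3, 5], "B": [2.0, 4, 6, 10]})
        Z, _ = hierarchical_cluster(data, metric="pearson")
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame({"A": [1, 2]}))

    @pytest.mark.parametrize("metric", ["euclidean", "pearson"])
    def test_merge_heights_match_naive_agglomeration(self, metric):
        rng = np.random.default_rng(4)
        for _ in range(5):
            data = pd.DataFrame(
                rng.normal(size=(10, 6)),
                columns=[f"s{i}" for i in range(6)],
            )
            Z, _ = hierarchical_cluster(data, metric=metric,
                                        linkage="average")
            X = data.T.to_numpy()
            if metric == "pearson":
                dist = 1.0 - np.corrcoef(X)
            else:
                dist = np.sqrt(
                    ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
                )
            heights = naive_average_linkage_heights(dist)
            assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-9)


def naive_average_linkage_heights(dist):
    """Heights of successive average-linkage merges, computed from scratch
    (unweighted pair-group averaging over the original point pairs)."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a, b)
        ] + [merged]
    return heights


class TestChromosomeDistribution:
    def test_all_hits_on_one_chromosome(self):
        rng = np.random.default_rng(9)
        chr1 = "".join(rng.choice(list("ACGT"), size=400))
        chr2 = "".join(rng.choice(list("ACGT"), size=400))
        idx = build_index([("chr1", chr1, False), ("chr2", chr2, False)])
        lib = CollapsedLibrary(
            "s", {chr2[10:30]: 5, chr2[100:125]: 5}
        )
        out = chromosome_distribution(lib, idx)
        assert out["nuclear_mappable_fraction_reads"] == 1.0
        assert list(out["per_chromosome_counts"].index) == ["chr2"]

    def test_absent_sequence_stays_unmapped(self):
        idx = build_index([("chr1", "ACGT" * 100, False)])
        lib = CollapsedLibrary("s", {"TTGGCCAATTGGCCAATTGG": 4})
        out = chromosome_distribution(lib, idx)
        assert out["nuclear_mappable_fraction_reads"] == 0.0
        assert out["per_chromosome_counts"].empty


class TestNumtOverlap:
    def test_constructed_enrichment(self):
        numts = {"chr1": [(0, 100)]}
        lengths = {"chr1": 1000}
        alns = [(aln(10, 20, ref="chr1"), 1), (aln(50, 20, ref="chr1"), 3)]
        out = numt_overlap(alns, numts, lengths)
        assert out["observed_fraction"] == 1.0
        assert out["expected_fraction"] == 0.1
        assert out["enrichment_ratio"] == pytest.approx(10.0)

    def test_uniform_placement_ratio_near_one(self):
        rng = np.random.default_rng(12)
        length = 10_000
        numts = {"chr1": [(2000, 3000)]}
        alns = [
            (aln(int(rng.integers(0, length - 20)), 20, ref="chr1"), 1)
            for _ in range(10_000)
        ]
        out = numt_overlap(alns, numts, {"chr1": length})
        p = out["expected_fraction"]
        se_ratio = np.sqrt(p * (1 - p) / 10_000) / p
        assert abs(out["enrichment_ratio"] - 1.0) <= 3 * se_ratio + 0.02

    def test_no_alignments_in_numts(self):
        out = numt_overlap(
            [(aln(500, 20, ref="chr1"), 2)], {"chr1": [(0, 100)]},
            {"chr1": 1000},
        )
        assert out["observed_fraction"] == 0.0

    def test_empty_numt_set_is_undefined(self):
        out = numt_overlap([(aln(5, 20, ref="chr1"), 1)], {}, {"chr1": 1000})
        assert out["enrichment_ratio"] is None
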