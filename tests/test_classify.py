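"""Hierarchical classification and the miRNA isoform taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosrna import (
    CollapsedLibrary,
    ReferenceSet,
    SimulationSpec,
    build_index,
    class_summary_table,
    classify_hierarchical,
    classify_isoform,
    collapse,
    isoform_composition,
    select_mt_associated,
    simulate_library,
)
from mitosrna.classify import ClassifiedSequence


def seq_of(base, n=22):
    return (base * n)[:n]


class TestSelectMtAssociated:
    def test_sub_library_totals(self):
        genome = "ACGTTGCTAGGCTAGCTAACGGATCCGATCGATTAGCCGGATAGCATCGA" * 2
        idx = build_index([("mt", genome, True)], max_query_len=35)
        inside1, inside2 = genome[5:25], genome[40:65]
        outside = ["TGCAATTGCAACCGGTTAAC", "GGGGGCCCCCAAAAATTTTT",
                   "ATATATATATATATATATAT"]
        lib = CollapsedLibrary(
            "s",
            {inside1: 10, inside2: 20, outside[0]: 30, outside[1]: 30,
             outside[2]: 10},
        )
        sub, placements = select_mt_associated(lib, idx)
        assert sub.total_sequences == 2
        assert sub.total_reads == 30
        assert sub.total_reads / lib.total_reads == 0.3
        assert set(placements) == {inside1, inside2}

    def test_empty_library(self):
        idx = build_index([("mt", "ACGT" * 20, True)])
        lib = CollapsedLibrary("s", {})
        sub, placements = select_mt_associated(lib, idx)
        assert sub.total_reads == 0 and placements == {}

    def test_recovers_generated_mt_fraction(self):
        # library with mostly nuclear background and a small mt share
        from mitosrna import make_toy_references

        refs = make_toy_references(seed=3)
        spec = SimulationSpec(seed=3, n_reads=200_000, mt_fraction=0.009)
        reads, truth = simulate_library(spec, refs)
        lib = collapse(reads, "s")
        idx = build_index([(refs.genome.id, refs.genome.sequence, True)])
        sub, _ = select_mt_associated(lib, idx)
        frac = sub.total_reads / lib.total_reads
        # generation fills the mt quota first, so the realized fraction can
        # only exceed the target by the final template's copies
        assert abs(frac - 0.009) < 3 * np.sqrt(0.009 * 0.991 / 200_000) + 1e-3


class TestSequentialPrecedence:
    def make_sets(self, shared):
        mirna = ReferenceSet(
            "mirna",
            precursors={"p1": "AAGG" + shared + "CCTT"},
            canonical={"p1": (4, 4 + len(shared))},
        )
        pirna = ReferenceSet("pirna", sequences={"x": shared})
        ncrna = ReferenceSet("ncrna", sequences={"y": seq_of("G", 30)})
        return mirna, pirna, ncrna

    def test_mirna_wins_over_pirna(self):
        shared = "ACGTTGCATGCAAGCTTACGAT"
        lib = CollapsedLibrary("s", {shared: 5})
        out = classify_hierarchical(lib, *self.make_sets(shared))
        assert out[0].label == "miRNA"

    def test_no_match_falls_through_to_unannotated(self):
        lib = CollapsedLibrary("s", {"TTTTTAAAAATTTTTAAAAA": 2})
        out = classify_hierarchical(
            lib, *self.make_sets("ACGTTGCATGCAAGCTTACGAT")
        )
        assert out[0].label == "unannotated"
        assert out[0].matched_ref_id is None

    def test_enlarging_pirna_set_never_relabels_mirna(self):
        shared = "ACGTTGCATGCAAGCTTACGAT"
        lib = CollapsedLibrary("s", {shared: 5})
        mirna, pirna, ncrna = self.make_sets(shared)
        before = classify_hierarchical(lib, mirna, pirna, ncrna)
        bigger = ReferenceSet(
            "pirna", sequences={**pirna.sequences, "extra": shared + "AA"}
        )
        after = classify_hierarchical(lib, mirna, bigger, ncrna)
        assert before[0].label == after[0].label == "miRNA"

    def test_exact_lookup_agrees_with_alignment_on_read_length_entries(self):
        entries = {
            f"e{i}": s
            for i, s in enumerate(
                ["ACGTTGCATGCAAGCTTACGAT", "GGATCCTTAAGGCCTTGGATCC"]
            )
        }
        ref = ReferenceSet("pirna", sequences=entries)
        queries = list(entries.values()) + ["TTTTTAAAAACCCCCGGGGGAT"]
        for q in queries:
            assert (ref.match(q, 0) is not None) == ref.contains_exact(q)


class TestIsoformTaxonomy:
    @pytest.mark.parametrize(
        "read,expected",
        [
            ((10, 32), "canonical"),
            ((10, 28), "isomiR"),
            ((5, 20), "paramiR"),
            ((20, 36), "circumiR"),
            ((10, 36), "circumiR"),  # same 5' end, 3'-extended
            ((5, 32), "paramiR"),  # 5'-extended, same 3' end
        ],
    )
    def test_worked_examples(self, read, expected):
        assert classify_isoform(read, (10, 32)) == expected

    def test_non_overlapping_is_an_error(self):
        with pytest.raises(ValueError, match="not an isoform"):
            classify_isoform((40, 55), (10, 32))

    def test_containment_uses_nearest_anchor_with_paramir_ties(self):
        # read strictly contains canonical: 5' anchor nearer -> paramiR
        assert classify_isoform((8, 40), (10, 32)) == "paramiR"
        # 3' anchor nearer -> circumiR
        assert classify_isoform((2, 33), (10, 32)) == "circumiR"
        # equidistant -> paramiR
        assert classify_isoform((7, 35), (10, 32)) == "paramiR"

    def test_every_overlapping_interval_gets_exactly_one_category(self):
        cats = set()
        for rs in range(0, 60):
            for re in range(rs + 1, 61):
                if re <= 10 or rs >= 32:
                    continue
                cat = classify_isoform((rs, re), (10, 32))
                assert cat in ("canonical", "isomiR", "paramiR", "circumiR")
                cats.add(cat)
        assert cats == {"canonical", "isomiR", "paramiR", "circumiR"}

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(min_value=-100, max_value=100),
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=1, max_value=40),
    )
    def test_invariant_under_common_shift(self, shift, rs, length):
        canonical = (10, 32)
        read = (rs, rs + length)
        if read[1] <= canonical[0] or read[0] >= canonical[1]:
            return
        shifted = classify_isoform(
            (read[0] + shift, read[1] + shift),
            (canonical[0] + shift, canonical[1] + shift),
        )
        assert shifted == classify_isoform(read, canonical)


class TestIsoformComposition:
    def mk(self, cat, count, seq):
        return ClassifiedSequence(seq, count, "miRNA", "p1", cat)

    def test_all_canonical(self):
        out = isoform_composition([self.mk("canonical", 5, "A" * 22)])
        assert out == {"canonical": 1.0}

    def test_normalization(self):
        out = isoform_composition(
            [self.mk("isomiR", 90, "A" * 20), self.mk("paramiR", 10, "C" * 20)]
        )
        assert out == {"isomiR": 0.9, "paramiR": 0.1}

    def test_empty_mirna_subset_is_empty(self):
        assert isoform_composition([]) == {}


class TestRecoveryOnSimulatedData:
    def test_partition_and_read_conservation(self, toy_refs, sim_mt_library):
        mt_lib = sim_mt_library["mt_library"]
        classified = classify_hierarchical(
            mt_lib, toy_refs.mirna, toy_refs.pirna, toy_refs.ncrna
        )
        assert len(classified) == mt_lib.total_sequences
        table = class_summary_table(classified)
        assert table["reads"].sum() == mt_lib.total_reads
        assert table["sequences"].sum() == mt_lib.total_sequences

    def test_labels_match_generator_truth_exactly(self, toy_refs,
                                                  sim_mt_library):
        mt_lib = sim_mt_library["mt_library"]
        truth = dict(
            zip(sim_mt_library["truth"].sequence,
                sim_mt_library["truth"].true_class)
        )
        classified = classify_hierarchical(
            mt_lib, toy_refs.mirna, toy_refs.pirna, toy_refs.ncrna
        )
        assert all(c.label == truth[c.sequence] for c in classified)

    def test_paramir_dominated_isoform_recovery(self, toy_refs):
        spec = SimulationSpec(
            seed=11,
            n_reads=12_000,
            mt_fraction=1.0,
            class_mixture={"miRNA": 1.0},
            isoform_mixture={"paramiR": 0.95, "isomiR": 0.05},
        )
        reads, truth = simulate_library(spec, toy_refs)
        lib = collapse(reads)
        idx = build_index([(toy_refs.genome.id, toy_refs.genome.sequence,
                            True)])
        mt_lib, _ = select_mt_associated(lib, idx)
        classified = classify_hierarchical(
            mt_lib, toy_refs.mirna, toy_refs.pirna, toy_refs.ncrna
        )
        frac = isoform_composition(classified)["paramiR"]
        n_unique = mt_lib.total_sequences
        assert abs(frac - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / n_unique)
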