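"""Hierarchical classification of mitochondria-associated small RNAs.

Sequences that align to the mitochondrial genome (mitosRNAs) are tested
against reference databases in a fixed order — miRNA, then piRNA, then other
ncRNA — and receive the first label whose database they match; the remainder
is "unannotated". A read matches a database when it aligns end-to-end, sense
strand, within one of the database entries (for miRNAs, within a precursor
hairpin). Sequential precedence makes ties impossible.

miRNA-labelled reads additionally receive an isoform category relative to the
canonical mature sequence annotated on their precursor:

* canonical — identical interval;
* isomiR    — same 5' end (hence same seed, nucleotides 2-8), 3'-trimmed;
* paramiR   — overlap anchored at the canonical 5' side;
* circumiR  — overlap anchored at the canonical 3' side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import Alignment, KmerIndex, align_all, best_hit, build_index
from .readprep import CollapsedLibrary

__all__ = [
    "ReferenceSet",
    "ClassifiedSequence",
    "ISOFORM_CATEGORIES",
    "CLASS_LABELS",
    "select_mt_associated",
    "classify_hierarchical",
    "classify_isoform",
    "isoform_composition",
    "class_summary_table",
]

log = logging.getLogger(__name__)

CLASS_LABELS = ("miRNA", "piRNA", "ncRNA", "unannotated")
ISOFORM_CATEGORIES = ("canonical", "isomiR", "paramiR", "circumiR")
SEED_LEN = 7  # nucleotides 2-8 of the mature miRNA


@dataclass
class ReferenceSet:
    """A named database of sncRNA sequences.

    For the miRNA set, ``precursors`` holds hairpin sequences and
    ``canonical`` the mature interval (0-based half-open) on each precursor;
    reads are matched against the precursors so isoform placement is known.
    For piRNA/ncRNA sets only ``sequences`` is used.
    """

    name: str
    sequences: dict[str, str] = field(default_factory=dict)
    precursors: dict[str, str] = field(default_factory=dict)
    canonical: dict[str, tuple[int, int]] = field(default_factory=dict)
    _index: KmerIndex | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for pid, (cs, ce) in self.canonical.items():
            if pid not in self.precursors:
                raise ValueError(f"canonical interval for unknown precursor {pid}")
            if not (0 <= cs < ce <= len(self.precursors[pid])):
                raise ValueError(
                    f"canonical interval [{cs}, {ce}) outside precursor {pid}"
                )

    @property
    def match_targets(self) -> dict[str, str]:
        """Sequences reads are aligned against (precursors for miRNA)."""
        return self.precursors if self.precursors else self.sequences

    def index(self, k: int = 12, max_query_len: int = 35) -> KmerIndex:
        if self._index is None:
            refs = [(rid, seq, False) for rid, seq in self.match_targets.items()]
            # seed length must not exceed the shortest entry
            shortest = min((len(s) for _, s, _ in refs), default=k)
            self._index = build_index(
                refs, k=min(k, shortest), max_query_len=max_query_len
            )
        return self._index

    def match(self, seq: str, max_mismatches: int = 0) -> Alignment | None:
        """Best sense-strand end-to-end placement within any entry, or None."""
        hits = [
            a
            for a in align_all(seq, self.index(), max_mismatches)
            if a.strand == "+"
        ]
        return best_hit(hits)

    def contains_exact(self, seq: str) -> bool:
        """Identity lookup: is ``seq`` verbatim one of the entries? Agrees
        with :meth:`match` at 0 mismatches when entries have read length."""
        return seq in set(self.match_targets.values())


@dataclass(frozen=True)
class ClassifiedSequence:
    sequence: str
    count: int
    label: str
    matched_ref_id: str | None = None
    isoform: str | None = None

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.matched_ref_id is None) != (self.label == "unannotated"):
            raise ValueError("matched_ref_id present iff label != unannotated")
        if self.isoform is not None and self.label != "miRNA":
            raise ValueError("isoform category only applies to miRNA labels")


def select_mt_associated(
    lib: CollapsedLibrary, mt_index: KmerIndex, max_mismatches: int = 0
) -> tuple[CollapsedLibrary, dict[str, Alignment]]:
    """Sub-library of sequences with at least one mitochondrial placement.

    Returns the mitochondria-associated sub-library and, per sequence, its
    best placement on the mitochondrial genome. Reads/sequences totals of the
    sub-library give the "associated with MT" tallies; the fraction of input
    reads they represent is total_reads(sub) / total_reads(lib).
    """
    placements: dict[str, Alignment] = {}
    for seq in lib.entries:
        hit = best_hit(align_all(seq, mt_index, max_mismatches))
        if hit is not None:
            placements[seq] = hit
    return lib.subset(placements), placements


def classify_isoform(
    read_interval: tuple[int, int], canonical: tuple[int, int]
) -> str:
    """Isoform category of a read placed on a precursor.

    Both intervals are 0-based half-open on the same precursor and strand.
    The rule is total and deterministic: after the canonical and isomiR cases,
    a read is paramiR when the overlap is anchored at the canonical 5' side
    (rs <= cs and re <= ce), circumiR when anchored at the 3' side (rs >= cs
    and re >= ce); reads strictly containing or strictly inside the canonical
    go to the category whose anchor end is nearer, ties to paramiR.
    """
    rs, re = read_interval
    cs, ce = canonical
    if re <= cs or rs >= ce:
        raise ValueError(
            f"read [{rs}, {re}) does not overlap canonical [{cs}, {ce}): "
            "not an isoform of this canonical"
        )
    if rs == cs and re == ce:
        return "canonical"
    if rs == cs and re < ce:
        return "isomiR"
    if rs <= cs and re <= ce:
        return "paramiR"
    if rs >= cs and re >= ce:
        return "circumiR"
    # strict containment either way: nearest anchor wins, ties -> paramiR
    return "paramiR" if abs(rs - cs) <= abs(re - ce) else "circumiR"


def classify_hierarchical(
    mt_lib: CollapsedLibrary,
    mirna: ReferenceSet,
    pirna: ReferenceSet,
    ncrna: ReferenceSet,
    max_mismatches: int = 0,
) -> list[ClassifiedSequence]:
    """Assign each unique sequence its first matching class label.

    Reference sets are tested in the fixed order miRNA -> piRNA -> ncRNA;
    unmatched sequences are "unannotated". Labels are assigned once per unique
    sequence and read counts inherit the label (collapse-then-classify). For
    miRNA matches the isoform category is derived from the placement on the
    precursor versus its canonical mature interval.
    """
    out: list[ClassifiedSequence] = []
    for seq in sorted(mt_lib.entries):
        count = mt_lib.entries[seq]
        hit = mirna.match(seq, max_mismatches)
        if hit is not None:
            isoform = None
            canonical = mirna.canonical.get(hit.ref_id)
            if canonical is not None:
                try:
                    isoform = classify_isoform(
                        (hit.start, hit.start + hit.length), canonical
                    )
                except ValueError:
                    isoform = None  # placement outside the canonical's reach
            out.append(
                ClassifiedSequence(seq, count, "miRNA", hit.ref_id, isoform)
            )
            continue
        hit = pirna.match(seq, max_mismatches)
        if hit is not None:
            out.append(ClassifiedSequence(seq, count, "piRNA", hit.ref_id))
            continue
        hit = ncrna.match(seq, max_mismatches)
        if hit is not None:
            out.append(ClassifiedSequence(seq, count, "ncRNA", hit.ref_id))
            continue
        out.append(ClassifiedSequence(seq, count, "unannotated"))
    return out


def class_summary_table(
    classified: Sequence[ClassifiedSequence], sample_id: str = "sample"
) -> pd.DataFrame:
    """Reads and sequences per class (one row per class, fixed order)."""
    rows = []
    for label in CLASS_LABELS:
        subset = [c for c in classified if c.label == label]
        rows.append(
            {
                "sample": sample_id,
                "class": label,
                "reads": sum(c.count for c in subset),
                "sequences": len(subset),
            }
        )
    return pd.DataFrame(rows)


def isoform_composition(
    classified: Sequence[ClassifiedSequence],
) -> dict[str, float]:
    """Read-weighted fraction of each isoform category among miRNA reads.

    Fractions sum to 1 over the categories present; an empty miRNA subset
    yields an empty table (logged warning).
    """
    counts: dict[str, int] = {}
    for c in classified:
        if c.label == "miRNA" and c.isoform is not None:
            counts[c.isoform] = counts.get(c.isoform, 0) + c.count
    total = sum(counts.values())
    if total == 0:
        log.warning("isoform_composition: no miRNA reads")
        return {}
    return {
        cat: counts[cat] / total for cat in ISOFORM_CATEGORIES if cat in counts
    }
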