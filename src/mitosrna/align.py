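"""Deterministic end-to-end alignment of small RNA reads.

A k-mer index over the (junction-extended) reference drives an exact,
exhaustive search for every full-length placement of a query with at most
``max_mismatches`` Hamming mismatches, on both strands. Circular references
are indexed over their junction-extended form so placements that wrap the
origin are found and reported once, with the start reduced modulo the genome
length.

This replaces a seed-and-extend aligner at desk scale with a contract that is
simple to state and to verify: the hit set equals a brute-force Hamming scan
over every offset and strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome import reverse_complement

__all__ = ["Alignment", "KmerIndex", "build_index", "align_all", "best_hit",
           "alignments_to_bed6", "alignments_to_sam"]

log = logging.getLogger(__name__)

DEFAULT_K = 12
DEFAULT_MAX_QUERY_LEN = 35


@dataclass(frozen=True)
class Alignment:
    """A full-length placement of a query on a reference.

    ``start`` is 0-based on the reference forward strand; for strand '-' the
    reverse complement of the query matches the reference window starting
    there. ``wraps_junction`` marks placements crossing the circular origin.
    """

    query: str
    ref_id: str
    start: int
    strand: str
    mismatches: int
    wraps_junction: bool = False

    @property
    def length(self) -> int:
        return len(self.query)

    @property
    def end(self) -> int:
        """Exclusive end on the forward strand (may exceed the reference
        length for wrapping placements; reduce modulo length if needed)."""
        return self.start + len(self.query)

    def five_prime_end(self, ref_length: int | None = None) -> int:
        """Reference coordinate of the biological 5' end of the read."""
        pos = self.start if self.strand == "+" else self.start + self.length - 1
        return pos % ref_length if ref_length else pos


class KmerIndex:
    """Postings of every k-mer of each reference (junction-extended when
    circular) to its sorted start positions."""

    def __init__(
        self,
        references: Sequence[tuple[str, str, bool]],
        k: int = DEFAULT_K,
        max_query_len: int = DEFAULT_MAX_QUERY_LEN,
    ):
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        self.k = k
        self.max_query_len = max_query_len
        self.refs: dict[str, tuple[str, int, bool]] = {}
        self.postings: dict[str, dict[str, list[int]]] = {}
        for ref_id, seq, circular in references:
            if ref_id in self.refs:
                raise ValueError(f"duplicate reference id {ref_id!r}")
            seq = seq.upper()
            length = len(seq)
            if circular and length > 1:
                overhang = min(max_query_len - 1, length - 1)
                ext = seq + seq[:overhang]
            else:
                ext = seq
            self.refs[ref_id] = (ext, length, circular)
            table: dict[str, list[int]] = {}
            if k > len(ext):
                log.warning(
                    "k=%d exceeds reference %s length %d; empty postings",
                    k, ref_id, len(ext),
                )
            for i in range(len(ext) - k + 1):
                table.setdefault(ext[i : i + k], []).append(i)
            self.postings[ref_id] = table

    @property
    def ref_ids(self) -> list[str]:
        return sorted(self.refs)

    def ref_length(self, ref_id: str) -> int:
        return self.refs[ref_id][1]


def build_index(
    references: Sequence[tuple[str, str, bool]],
    k: int = DEFAULT_K,
    max_query_len: int = DEFAULT_MAX_QUERY_LEN,
) -> KmerIndex:
    """Build a :class:`KmerIndex` over (id, sequence, circular) references."""
    return KmerIndex(references, k=k, max_query_len=max_query_len)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit; N never matches anything."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidate_starts(
    query: str, ext: str, table: dict[str, list[int]], k: int,
    n_starts: int, max_mismatches: int,
) -> Iterable[int]:
    """Candidate placements for one oriented query.

    Seed lookup is complete only when some k-window of the query is guaranteed
    exact (pigeonhole: more windows than max_mismatches*k); otherwise fall
    back to scanning every start (references here are a few Kb at most).
    """
    q = len(query)
    n_windows = q - k + 1
    if n_windows >= 1 and n_windows > max_mismatches * k:
        seen: set[int] = set()
        for off in range(n_windows):
            for pos in table.get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start < n_starts:
                    seen.add(start)
        return sorted(seen)
    return range(n_starts)


def align_all(
    query: str, index: KmerIndex, max_mismatches: int = 0
) -> list[Alignment]:
    """Every end-to-end placement of ``query`` with <= max_mismatches.

    Both strands are searched; each circular placement is reported exactly
    once with its start reduced modulo the reference length. Results are
    sorted by (ref_id, start, strand).
    """
    query = query.upper()
    q = len(query)
    hits: list[Alignment] = []
    if q == 0:
        return hits
    for ref_id in index.ref_ids:
        ext, length, circular = index.refs[ref_id]
        if q > len(ext):
            continue
        # starts < length for circular refs (modular dedup); for linear refs
        # the window must fit entirely.
        n_starts = length if circular else max(0, len(ext) - q + 1)
        n_starts = min(n_starts, len(ext) - q + 1)
        table = index.postings[ref_id]
        for strand, oriented in (("+", query), ("-", reverse_complement(query))):
            for start in _candidate_starts(
                oriented, ext, table, index.k, n_starts, max_mismatches
            ):
                mm = _mismatches(oriented, ext[start : start + q], max_mismatches)
                if mm <= max_mismatches:
                    hits.append(
                        Alignment(
                            query=query,
                            ref_id=ref_id,
                            start=start,
                            strand=strand,
                            mismatches=mm,
                            wraps_junction=circular and start + q > length,
                        )
                    )
    hits.sort(key=lambda a: (a.ref_id, a.start, a.strand))
    return hits


def best_hit(alignments: Sequence[Alignment]) -> Alignment | None:
    """Deterministic single placement for a multi-mapping read.

    Minimal mismatches; ties broken by strand ('+' before '-'), then smallest
    start, then lexicographic ref_id. Returns None for an empty list.
    """
    if not alignments:
        return None
    return min(
        alignments,
        key=lambda a: (a.mismatches, a.strand != "+", a.start, a.ref_id),
    )


def alignments_to_bed6(
    alignments: Iterable[Alignment], name_prefix: str = "aln"
) -> str:
    """BED6 export (0-based half-open; score column carries mismatches)."""
    lines = []
    for i, a in enumerate(alignments, start=1):
        lines.append(
            f"{a.ref_id}\t{a.start}\t{a.end}\t{name_prefix}{i}\t"
            f"{a.mismatches}\t{a.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def alignments_to_sam(
    alignments: Iterable[Alignment], ref_lengths: dict[str, int]
) -> str:
    """Minimal SAM export: header plus mandatory fields, ungapped CIGAR."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for ref_id in sorted(ref_lengths):
        lines.append(f"@SQ\tSN:{ref_id}\tLN:{ref_lengths[ref_id]}")
    for i, a in enumerate(alignments, start=1):
        flag = 16 if a.strand == "-" else 0
        seq = a.query if a.strand == "+" else reverse_complement(a.query)
        lines.append(
            "\t".join(
                [
                    f"read{i}",
                    str(flag),
                    a.ref_id,
                    str(a.start + 1),
                    "255",
                    f"{a.length}M",
                    "*",
                    "0",
                    "0",
                    seq,
                    "*",
                    f"NM:i:{a.mismatches}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
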