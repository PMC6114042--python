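"""FASTQ ingestion, adapter trimming, read collapsing and low-count filtering.

Small-RNA libraries are handled as *collapsed* libraries: a map from unique
sequence to read count. The duality between total reads and total distinct
sequences runs through every downstream summary. After collapsing, sequences
seen five times or fewer are removed by default to suppress inconsistent
low-abundance species.

Reads are kept in DNA alphabet (T, not U); reporting layers may display U.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "CollapsedLibrary",
    "read_fastq",
    "trim_adapter",
    "collapse",
    "filter_low_count",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "write_collapsed_tsv",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 35
DEFAULT_COUNT_FILTER = 5


@dataclass(frozen=True)
class CollapsedLibrary:
    """Unique sequence -> read count map for one sample.

    ``total_reads`` is the sum of counts, ``total_sequences`` the number of
    distinct sequences; dropped_reads records reads excluded by the length
    window during collapsing.
    """

    sample_id: str
    entries: Mapping[str, int]
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    dropped_reads: int = 0

    def __post_init__(self) -> None:
        for seq, count in self.entries.items():
            if count <= 0:
                raise ValueError(f"non-positive count for {seq}")
            if not (self.min_len <= len(seq) <= self.max_len):
                raise ValueError(
                    f"sequence of length {len(seq)} outside window "
                    f"[{self.min_len}, {self.max_len}]"
                )

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def total_sequences(self) -> int:
        return len(self.entries)

    def subset(self, sequences: Iterable[str]) -> "CollapsedLibrary":
        """Sub-library restricted to the given sequences (order-insensitive)."""
        keep = {s: self.entries[s] for s in sequences if s in self.entries}
        return CollapsedLibrary(
            sample_id=self.sample_id,
            entries=keep,
            min_len=self.min_len,
            max_len=self.max_len,
        )


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a (possibly gzipped) FASTQ file.

    Qualities are discarded: the pipeline operates on collapsed sequences.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()  # '+'
            fh.readline()  # quality
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record header: {header!r}")
            yield seq


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Strip a literal 3' adapter from a read.

    The suffix starting at the leftmost exact occurrence of an adapter prefix
    (of length >= ``min_overlap``, up to the full adapter) is removed. Reads
    without a qualifying occurrence are returned unchanged; no-match is not an
    error.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(read), len(adapter)
    for i in range(n):
        span = min(m, n - i)
        if span < min_overlap:
            break
        if read[i : i + span] == adapter[:span]:
            return read[:i]
    return read


def collapse(
    reads: Iterable[str],
    sample_id: str = "sample",
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> CollapsedLibrary:
    """Merge identical reads into (sequence, count) entries.

    Reads outside the [min_len, max_len] window are dropped and tallied in
    ``dropped_reads``. An empty input yields an empty library (logged, not an
    error). The result is invariant to the order of the input reads.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    counts: dict[str, int] = {}
    dropped = 0
    total = 0
    for read in reads:
        total += 1
        if min_len <= len(read) <= max_len:
            counts[read] = counts.get(read, 0) + 1
        else:
            dropped += 1
    if total == 0:
        log.info("collapse(%s): empty input", sample_id)
    return CollapsedLibrary(
        sample_id=sample_id,
        entries=counts,
        min_len=min_len,
        max_len=max_len,
        dropped_reads=dropped,
    )


def filter_low_count(
    lib: CollapsedLibrary, max_removed_count: int = DEFAULT_COUNT_FILTER
) -> CollapsedLibrary:
    """Remove sequences whose count is <= ``max_removed_count``.

    With the default threshold of 5, sequences with five counts or fewer are
    excluded. Idempotent; totals are recomputed.
    """
    if max_removed_count < 0:
        raise ValueError("max_removed_count must be >= 0")
    keep = {s: c for s, c in lib.entries.items() if c > max_removed_count}
    return CollapsedLibrary(
        sample_id=lib.sample_id,
        entries=keep,
        min_len=lib.min_len,
        max_len=lib.max_len,
        dropped_reads=lib.dropped_reads,
    )


def write_collapsed_fasta(lib: CollapsedLibrary, path: str | Path) -> None:
    """Serialize as FASTA with ``>seq<i>_x<count>`` headers (collapsed-read
    dialect), sequences in deterministic (sequence-sorted) order."""
    lines = []
    for i, seq in enumerate(sorted(lib.entries), start=1):
        lines.append(f">seq{i}_x{lib.entries[seq]}")
        lines.append(seq)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_collapsed_fasta(
    path: str | Path, sample_id: str = "sample"
) -> CollapsedLibrary:
    """Read a ``>seq<i>_x<count>`` FASTA back into a collapsed library."""
    entries: dict[str, int] = {}
    count = None
    min_len, max_len = DEFAULT_MIN_LEN, DEFAULT_MAX_LEN
    lens: list[int] = []
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        if line.startswith(">"):
            count = int(line.rsplit("_x", 1)[1])
        else:
            entries[line] = entries.get(line, 0) + (count or 1)
            lens.append(len(line))
    if lens:
        min_len, max_len = min(min_len, *lens), max(max_len, *lens)
    return CollapsedLibrary(
        sample_id=sample_id, entries=entries, min_len=min_len, max_len=max_len
    )


def write_collapsed_tsv(lib: CollapsedLibrary, path: str | Path) -> None:
    """Two-column TSV: sequence, count (sequence-sorted)."""
    lines = ["sequence\tcount"]
    for seq in sorted(lib.entries):
        lines.append(f"{seq}\t{lib.entries[seq]}")
    Path(path).write_text("\n".join(lines) + "\n")
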