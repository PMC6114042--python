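"""Circular mitochondrial genome model and feature annotation.

The mitochondrial genome is a small circular DNA: coordinates wrap around the
junction between the last and first base of the reference FASTA. Everything
downstream (alignment, coverage, feature counting) relies on the coordinate
arithmetic defined here.

Conventions
-----------
* Internal coordinates are 0-based half-open intervals on the heavy strand,
  where "heavy" is operationally the strand stored in the reference FASTA and
  "light" is its reverse complement.
* GFF3 I/O converts to/from the standard 1-based inclusive dialect; BED stays
  0-based half-open.
* tRNA features carry their anticodon position as an annotation attribute
  (``anticodon_start``); the 5'/3' arms used by the profiling statistics are
  the regions on either side of the anticodon triplet.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CircularGenome",
    "Feature",
    "FEATURE_KINDS",
    "load_genome",
    "load_annotation",
    "write_annotation",
    "junction_extended",
    "reverse_complement",
    "feature_census",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("protein_coding", "rRNA", "tRNA", "D_loop", "other")

# GFF3 "type" column values accepted for each internal kind
_GFF_TYPE_MAP = {
    "trna": "tRNA",
    "rrna": "rRNA",
    "d_loop": "D_loop",
    "d-loop": "D_loop",
    "gene": "protein_coding",
    "protein_coding": "protein_coding",
    "cds": "protein_coding",
    "mrna": "protein_coding",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A single circular (or optionally linear) reference sequence.

    Attributes
    ----------
    id : non-empty record identifier.
    sequence : uppercase DNA over {A,C,G,T,N}.
    is_circular : whether coordinate arithmetic wraps the junction.
    """

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        seq = self.sequence.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence contains characters outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fragment(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the junction when circular.

        ``end`` may exceed the genome length by less than one full turn.
        """
        n = self.length
        if not (0 <= start < n):
            raise ValueError(f"start {start} outside [0, {n})")
        if end < start or end - start > n:
            raise ValueError(f"invalid interval [{start}, {end}) on length {n}")
        if end <= n:
            return self.sequence[start:end]
        if not self.is_circular:
            raise ValueError("interval beyond end of a linear genome")
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on the genome (0-based half-open, heavy strand).

    Features spanning the junction are represented as two linked sub-intervals
    sharing a ``feature_id`` prefix; no single Feature wraps.
    """

    feature_id: str
    kind: str
    start: int
    end: int
    strand: str
    name: str = ""
    anticodon_start: int | None = None
    anticodon_len: int = 3

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.kind == "tRNA":
            if self.anticodon_start is None:
                raise ValueError(
                    f"tRNA feature {self.feature_id} lacks anticodon_start"
                )
            if not (
                self.start < self.anticodon_start
                and self.anticodon_start + self.anticodon_len < self.end
            ):
                raise ValueError(
                    f"tRNA {self.feature_id}: anticodon "
                    f"[{self.anticodon_start}, "
                    f"{self.anticodon_start + self.anticodon_len}) must lie "
                    f"strictly inside [{self.start}, {self.end})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def load_genome(fasta: str | Path) -> CircularGenome:
    """Load a single-record FASTA as a circular genome.

    Raises
    ------
    FileNotFoundError, ValueError
        Multi-record files, empty sequences and non-ACGTN characters are
        rejected with a message naming the problem.
    """
    fasta = Path(fasta)
    if not fasta.exists():
        raise FileNotFoundError(str(fasta))
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one sequence in {fasta.name}, "
            f"found {len(records)} records"
        )
    rec = records[0]
    return CircularGenome(id=rec.id, sequence=str(rec.seq).upper())


def junction_extended(genome: CircularGenome, overhang: int) -> str:
    """Linearized circular sequence with the first ``overhang`` bases appended.

    Alignments starting at positions >= length - overhang can then be found on
    the extended string and reported modulo the genome length.
    """
    if not (0 <= overhang < genome.length):
        raise ValueError(
            f"overhang must be in [0, {genome.length}), got {overhang}"
        )
    return genome.sequence + genome.sequence[:overhang]


def _validate_features(
    features: Sequence[Feature], genome: CircularGenome
) -> None:
    for f in features:
        if f.end > genome.length:
            raise ValueError(
                f"feature {f.feature_id} [{f.start}, {f.end}) exceeds genome "
                f"length {genome.length}"
            )


def load_annotation(
    path: str | Path,
    genome: CircularGenome,
    dialect: str | None = None,
) -> list[Feature]:
    """Load features from GFF3 (1-based inclusive) or BED6 (0-based half-open).

    The dialect is inferred from the extension (.gff/.gff3 vs .bed) unless
    passed explicitly. Coordinates are converted to internal 0-based half-open.
    tRNA records must carry an ``anticodon_start`` attribute (GFF3, 1-based);
    BED input lacks attributes, so its features are typed via an optional 7th
    column and may not declare tRNAs without an 8th anticodon column.
    """
    path = Path(path)
    if dialect is None:
        ext = path.suffix.lower()
        if ext in (".gff", ".gff3"):
            dialect = "gff3"
        elif ext == ".bed":
            dialect = "bed"
        else:
            raise ValueError(
                f"cannot infer annotation dialect from extension {ext!r}"
            )
    if dialect == "gff3":
        features = _load_gff3(path)
    elif dialect == "bed":
        features = _load_bed(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _validate_features(features, genome)
    return features


def _load_gff3(path: Path) -> list[Feature]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[Feature] = []
    for rec in db.all_features(order_by=("start",)):
        kind = _GFF_TYPE_MAP.get(rec.featuretype.lower())
        if kind is None:
            # fall back to a biotype attribute, else "other"
            biotype = (rec.attributes.get("biotype") or [""])[0].lower()
            kind = _GFF_TYPE_MAP.get(biotype, "other")
        fid = (rec.attributes.get("ID") or [rec.id or ""])[0]
        name = (rec.attributes.get("Name") or [fid])[0]
        anticodon = rec.attributes.get("anticodon_start")
        anticodon_start = int(anticodon[0]) - 1 if anticodon else None
        anticodon_len = int(
            (rec.attributes.get("anticodon_len") or ["3"])[0]
        )
        features.append(
            Feature(
                feature_id=fid,
                kind=kind,
                start=rec.start - 1,  # GFF3 is 1-based inclusive
                end=rec.end,
                strand=rec.strand if rec.strand in ("+", "-") else "+",
                name=name,
                anticodon_start=anticodon_start,
                anticodon_len=anticodon_len,
            )
        )
    return features


def _load_bed(path: Path) -> list[Feature]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    features: list[Feature] = []
    for _, row in df.iterrows():
        kind = row[6] if len(row) > 6 and isinstance(row[6], str) else "other"
        anticodon = (
            int(row[7]) if len(row) > 7 and not pd.isna(row[7]) else None
        )
        features.append(
            Feature(
                feature_id=str(row[3]),
                kind=kind,
                start=int(row[1]),
                end=int(row[2]),
                strand=str(row[5]) if len(row) > 5 else "+",
                name=str(row[3]),
                anticodon_start=anticodon,
            )
        )
    return features


def write_annotation(
    features: Iterable[Feature], path: str | Path, genome_id: str = "genome"
) -> None:
    """Write features as GFF3 (round-trips with :func:`load_annotation`)."""
    lines = ["##gff-version 3"]
    for f in features:
        attrs = [f"ID={f.feature_id}", f"Name={f.name or f.feature_id}"]
        if f.anticodon_start is not None:
            attrs.append(f"anticodon_start={f.anticodon_start + 1}")
            attrs.append(f"anticodon_len={f.anticodon_len}")
        lines.append(
            "\t".join(
                [
                    genome_id,
                    "mitosrna",
                    f.kind,
                    str(f.start + 1),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def feature_census(features: Iterable[Feature]) -> dict[str, int]:
    """Count features by kind, e.g. ``{"tRNA": 22, "rRNA": 2, ...}``."""
    census: dict[str, int] = {}
    for f in features:
        census[f.kind] = census.get(f.kind, 0) + 1
    return census
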