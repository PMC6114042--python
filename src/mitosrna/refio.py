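"""File I/O for reference databases and toy reference bundles.

Reference sncRNA databases travel as FASTA; the miRNA set additionally has a
precursor FASTA and a sidecar GFF3 giving each precursor's canonical mature
interval (1-based inclusive, on precursor coordinates). NUMT intervals are
BED3.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import ReferenceSet
from .genome import write_annotation
from .simulate import ToyReferences

__all__ = [
    "read_fasta_dict",
    "write_fasta_dict",
    "load_mirna_set",
    "load_sequence_set",
    "read_numt_bed",
    "write_numt_bed",
    "write_toy_references",
]


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta_dict(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def load_mirna_set(
    mature_fasta: str | Path,
    precursor_fasta: str | Path,
    canonical_gff: str | Path,
) -> ReferenceSet:
    """miRNA reference set: matures, precursors, canonical intervals.

    The sidecar GFF3 has one line per precursor with seqid = precursor id and
    1-based inclusive mature coordinates.
    """
    canonical: dict[str, tuple[int, int]] = {}
    for line in Path(canonical_gff).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        canonical[cols[0]] = (int(cols[3]) - 1, int(cols[4]))
    return ReferenceSet(
        name="mirna",
        sequences=read_fasta_dict(mature_fasta),
        precursors=read_fasta_dict(precursor_fasta),
        canonical=canonical,
    )


def load_sequence_set(name: str, fasta: str | Path) -> ReferenceSet:
    return ReferenceSet(name=name, sequences=read_fasta_dict(fasta))


def read_numt_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    numts: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end = line.split("\t")[:3]
        numts.setdefault(chrom, []).append((int(start), int(end)))
    return {c: sorted(v) for c, v in numts.items()}


def write_numt_bed(
    numts: Mapping[str, list[tuple[int, int]]], path: str | Path
) -> None:
    lines = [
        f"{chrom}\t{s}\t{e}\tNUMT"
        for chrom in sorted(numts)
        for s, e in sorted(numts[chrom])
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_toy_references(refs: ToyReferences, outdir: str | Path) -> dict:
    """Serialize a toy reference bundle; returns the path map.

    Emits: mitochondrial FASTA + GFF3, nuclear FASTA, NUMT BED, the three
    database FASTAs and the canonical-interval sidecar GFF3.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mt_fasta": outdir / "mt.fa",
        "mt_gff": outdir / "mt.gff3",
        "nuclear_fasta": outdir / "nuclear.fa",
        "numt_bed": outdir / "numts.bed",
        "mirna_mature": outdir / "mirna_mature.fa",
        "mirna_precursor": outdir / "mirna_precursor.fa",
        "mirna_canonical": outdir / "mirna_canonical.gff3",
        "pirna_fasta": outdir / "pirna.fa",
        "ncrna_fasta": outdir / "ncrna.fa",
    }
    write_fasta_dict({refs.genome.id: refs.genome.sequence}, paths["mt_fasta"])
    write_annotation(refs.features, paths["mt_gff"], genome_id=refs.genome.id)
    write_fasta_dict(refs.nuclear, paths["nuclear_fasta"])
    write_numt_bed(refs.numts, paths["numt_bed"])
    write_fasta_dict(refs.mirna.sequences, paths["mirna_mature"])
    write_fasta_dict(refs.mirna.precursors, paths["mirna_precursor"])
    lines = ["##gff-version 3"]
    for pid in sorted(refs.mirna.canonical):
        cs, ce = refs.mirna.canonical[pid]
        lines.append(
            f"{pid}\tmitosrna\tmature_miRNA\t{cs + 1}\t{ce}\t.\t+\t.\tID={pid}-mature"
        )
    paths["mirna_canonical"].write_text("\n".join(lines) + "\n")
    write_fasta_dict(refs.pirna.sequences, paths["pirna_fasta"])
    write_fasta_dict(refs.ncrna.sequences, paths["ncrna_fasta"])
    return {k: str(v) for k, v in paths.items()}
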