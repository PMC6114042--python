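"""Synthetic data with known ground truth for every pipeline statistic.

Builds a toy circular mitochondrial genome with a D-loop, rRNAs, anticodon-
annotated tRNAs and protein-coding genes; a toy nuclear genome whose
chromosomes carry verbatim NUMT copies of selected mitochondrial segments;
and three pairwise-disjoint sncRNA reference databases (miRNA precursors with
canonical mature intervals, piRNA entries, other-ncRNA entries) anchored at
disjoint mitochondrial loci.

Seeded read libraries are then drawn with controlled class mixture, length
peaks, first-position U and tenth-position A frequencies, tRNA 5'-arm bias,
strand bias, per-sequence duplication and NUMT embedding. Every read is an
exact substring of its source (positional composition is achieved by
*selecting* sites whose genomic bases match the drawn target, never by
mutating reads), so zero-mismatch alignment and classification recover the
generating truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ReferenceSet
from .genome import CircularGenome, Feature, reverse_complement

__all__ = [
    "SimulationSpec",
    "ToyReferences",
    "make_toy_references",
    "make_mouse_like_annotation",
    "simulate_library",
    "write_fastq",
    "write_truth_table",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# maximum piRNA/ncRNA/unannotated read length the toy loci are sized for
L_MAX = 27

# --- toy mitochondrial layout (0-based half-open on a 4000 nt circle) -------
MT_LENGTH = 4000
_D_LOOP = (0, 400)
_RRNA1 = (400, 700)
_RRNA2 = (700, 1100)
# tRNAs: (start, end, strand, anticodon_start)
_TRNAS = {
    "tRNA1": (1100, 1172, "+", 1134),
    "tRNA2": (1200, 1272, "+", 1234),
    "tRNA3": (1300, 1372, "-", 1334),
    "tRNA4": (1400, 1472, "+", 1434),
}
_GENES = {"P1": (1500, 2300, "+"), "P2": (2300, 3100, "-"), "P3": (3100, 3900, "+")}

# miRNA precursors: 70 nt windows inside P1, canonical mature at [25, 47)
_PRECURSORS = {"pre1": 1520, "pre2": 1620, "pre3": 1720}
_PRE_LEN = 70
_CANONICAL = (25, 47)

# piRNA loci away from tRNAs: (window, strand, embedded)
_PIRNA_OTHER = {
    "DL1": ((10, 200), "+", True),
    "DLn": ((10, 200), "-", True),
    "DL2": ((210, 390), "+", False),
    "DL2n": ((210, 390), "-", False),
    "RR1": ((400, 555), "+", True),
    "RR2": ((560, 700), "+", False),
}
_TRNA_EMBEDDED = {"tRNA1": True, "tRNA2": False, "tRNA3": True, "tRNA4": False}
_TRNA_FLANK = 28  # db entries extend past the gene so 3'-arm reads fit

_NCRNA = {"NC1": ((3150, 3250), "+", True), "NC2": ((3350, 3450), "+", False)}
_UNANNOT = {"U1": ((2360, 2540), "-", True), "U2": ((2600, 2800), "-", False)}

# mt segments copied verbatim into the nuclear genome (the NUMTs)
_EMBED_SEGMENTS = [
    (0, 200),
    (400, 555),
    (1100, 1200),
    (1272, 1372),
    (1500, 1700),
    (2360, 2540),
    (3150, 3250),
]
_NUCLEAR_LEN = 8000
# (segment index -> (chromosome, insertion offset))
_NUMT_PLACEMENT = {
    0: ("chr1", 500),
    2: ("chr1", 1500),
    4: ("chr1", 3000),
    6: ("chr1", 5000),
    1: ("chr2", 800),
    3: ("chr2", 2500),
    5: ("chr2", 4200),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters of one synthetic small-RNA library.

    Defaults emulate the observables reported for mouse germ-cell libraries:
    mitochondria-associated reads are under 1% of the library; of those,
    piRNAs dominate (80-90%) with miRNAs around 8%; read lengths peak at
    19/21/25/27 nt; first-position U and tenth-position A frequencies are
    unbiased (0.25); over 80% of tRNA-derived piRNAs start in the 5' arm; and
    roughly three quarters of mitochondrial loci are duplicated in the
    nuclear genome.  ``duplication`` is the mean copy number per unique
    sequence (copies ~ 1 + Poisson(duplication - 1)).
    """

    seed: int = 0
    n_reads: int = 50_000
    mt_fraction: float = 0.009
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "piRNA": 0.85,
            "miRNA": 0.08,
            "ncRNA": 0.05,
            "unannotated": 0.02,
        }
    )
    length_peaks: Mapping[int, float] = field(
        default_factory=lambda: {19: 0.30, 21: 0.30, 25: 0.20, 27: 0.20}
    )
    p_U1: float = 0.25
    p_A10: float = 0.25
    arm5_bias: float = 0.85
    trna_fraction: float = 0.80
    strand_bias: float = 0.70
    duplication: float = 7.0
    nuclear_embed_fraction: float = 0.75
    isoform_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.05,
            "isomiR": 0.45,
            "paramiR": 0.45,
            "circumiR": 0.05,
        }
    )
    min_len: int = 18
    max_len: int = 35

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        for name in ("mt_fraction", "p_U1", "p_A10", "arm5_bias",
                     "trna_fraction", "strand_bias", "nuclear_embed_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for mix, label in ((self.class_mixture, "class_mixture"),
                           (self.isoform_mixture, "isoform_mixture")):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} weights must sum to 1")
        if self.duplication < 1.0:
            raise ValueError("duplication (mean copies) must be >= 1")
        if not self.length_peaks:
            raise ValueError("length_peaks must be non-empty")


@dataclass
class ToyReferences:
    """Toy genomes, annotation and reference databases with locus truth."""

    genome: CircularGenome
    features: list[Feature]
    mirna: ReferenceSet
    pirna: ReferenceSet
    ncrna: ReferenceSet
    nuclear: dict[str, str]
    numts: dict[str, list[tuple[int, int]]]
    embedded_segments: list[tuple[int, int]]
    precursor_starts: dict[str, int]

    @property
    def trnas(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "tRNA"]


def _cell(seq: str, e: int, strand: str) -> tuple[str, str]:
    """(base at read position 1, base at position 10) for 5' end ``e``."""
    if strand == "+":
        return seq[e], seq[e + 9]
    return _COMP[seq[e]], _COMP[seq[e - 9]]


def _group_positions() -> dict[tuple, list[tuple[int, str, str]]]:
    """piRNA 5'-end sampling groups -> [(e, strand, locus_id)].

    tRNA groups are keyed (True/False embedded, '5'/'3' arm); other-locus
    groups (True/False embedded, '+'/'-' strand). Margins guarantee that any
    read length up to L_MAX fits inside the corresponding database entry.
    """
    groups: dict[tuple, list[tuple[int, str, str]]] = {}
    for tid, (start, end, strand, ac) in _TRNAS.items():
        emb = _TRNA_EMBEDDED[tid]
        if strand == "+":
            arm5 = range(start, ac)
            arm3 = range(ac + 3, end)
        else:
            arm5 = range(ac + 3, end)
            arm3 = range(start, ac)
        groups.setdefault(("trna", emb, "5"), []).extend(
            (e, strand, tid) for e in arm5
        )
        groups.setdefault(("trna", emb, "3"), []).extend(
            (e, strand, tid) for e in arm3
        )
    for lid, ((w0, w1), strand, emb) in _PIRNA_OTHER.items():
        if strand == "+":
            es = range(w0, w1 - L_MAX + 1)
        else:
            es = range(w0 + L_MAX - 1, w1)
        groups.setdefault(("other", emb, strand), []).extend(
            (e, strand, lid) for e in es
        )
    return groups


def _repair_sequence(seq: list[str]) -> None:
    """Adjust bases so every (group x position-1/10 base pair) cell is
    populated, making exact positional-composition sampling feasible."""
    groups = _group_positions()
    all_cells = [(b1, b10) for b1 in _BASES for b10 in _BASES]
    for _ in range(500):
        changed = False
        for key in sorted(groups):
            positions = groups[key]
            cells: dict[tuple[str, str], list[tuple[int, str, str]]] = {}
            for e, strand, lid in positions:
                cells.setdefault(_cell(seq, e, strand), []).append(
                    (e, strand, lid)
                )
            missing = sorted(c for c in all_cells if c not in cells)
            if not missing:
                continue
            b1, b10 = missing[0]
            donor = max(sorted(cells), key=lambda c: len(cells[c]))
            e, strand, _lid = cells[donor][len(cells[donor]) // 2]
            if strand == "+":
                seq[e], seq[e + 9] = b1, b10
            else:
                seq[e], seq[e - 9] = _COMP[b1], _COMP[b10]
            changed = True
        if not changed:
            return
    raise RuntimeError("could not populate positional-composition cells")


def _check_disjoint(sets: Sequence[ReferenceSet]) -> None:
    """No entry of one reference set may occur within another set's entries;
    hierarchical precedence must never be exercised by accident."""
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i == j:
                continue
            for sa in a.match_targets.values():
                for sb in b.match_targets.values():
                    probe = sa if len(sa) <= len(sb) else sb
                    other = sb if probe is sa else sa
                    if probe in other:
                        raise RuntimeError(
                            f"reference sets {a.name}/{b.name} share sequence"
                        )


def make_toy_references(seed: int = 0) -> ToyReferences:
    """Deterministic toy reference bundle for a given seed."""
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(_BASES), size=MT_LENGTH))
    _repair_sequence(seq)
    mt_seq = "".join(seq)
    genome = CircularGenome(id="mt_toy", sequence=mt_seq)

    features = [
        Feature("D_loop", "D_loop", *_D_LOOP, "+", name="D-loop"),
        Feature("rRNA1", "rRNA", *_RRNA1, "+", name="12S-like"),
        Feature("rRNA2", "rRNA", *_RRNA2, "+", name="16S-like"),
    ]
    for tid, (start, end, strand, ac) in _TRNAS.items():
        features.append(
            Feature(tid, "tRNA", start, end, strand, name=tid,
                    anticodon_start=ac)
        )
    for gid, (start, end, strand) in _GENES.items():
        features.append(Feature(gid, "protein_coding", start, end, strand,
                                name=gid))

    # reference databases ---------------------------------------------------
    precursors = {
        pid: mt_seq[s : s + _PRE_LEN] for pid, s in _PRECURSORS.items()
    }
    mirna = ReferenceSet(
        name="mirna",
        sequences={
            f"{pid}-mature": p[_CANONICAL[0] : _CANONICAL[1]]
            for pid, p in precursors.items()
        },
        precursors=precursors,
        canonical={pid: _CANONICAL for pid in precursors},
    )
    pirna_entries: dict[str, str] = {}
    for tid, (start, end, strand, _ac) in _TRNAS.items():
        if strand == "+":
            window = mt_seq[start : end + _TRNA_FLANK]
        else:
            window = reverse_complement(mt_seq[start - _TRNA_FLANK : end])
        pirna_entries[f"pi-{tid}"] = window
    for lid, ((w0, w1), strand, _emb) in _PIRNA_OTHER.items():
        window = mt_seq[w0:w1]
        pirna_entries[f"pi-{lid}"] = (
            window if strand == "+" else reverse_complement(window)
        )
    pirna = ReferenceSet(name="pirna", sequences=pirna_entries)
    ncrna = ReferenceSet(
        name="ncrna",
        sequences={
            f"nc-{lid}": mt_seq[w0:w1]
            for lid, ((w0, w1), _s, _e) in _NCRNA.items()
        },
    )
    _check_disjoint([mirna, pirna, ncrna])

    # nuclear genome with NUMT insertions -----------------------------------
    nuclear = {
        chrom: list(rng.choice(list(_BASES), size=_NUCLEAR_LEN))
        for chrom in ("chr1", "chr2")
    }
    numts: dict[str, list[tuple[int, int]]] = {"chr1": [], "chr2": []}
    for seg_idx, (chrom, offset) in sorted(_NUMT_PLACEMENT.items()):
        s, e = _EMBED_SEGMENTS[seg_idx]
        nuclear[chrom][offset : offset + (e - s)] = list(mt_seq[s:e])
        numts[chrom].append((offset, offset + (e - s)))
    nuclear_seqs = {c: "".join(v) for c, v in nuclear.items()}

    return ToyReferences(
        genome=genome,
        features=features,
        mirna=mirna,
        pirna=pirna,
        ncrna=ncrna,
        nuclear=nuclear_seqs,
        numts={c: sorted(v) for c, v in numts.items()},
        embedded_segments=list(_EMBED_SEGMENTS),
        precursor_starts=dict(_PRECURSORS),
    )


def _draw_length(rng: np.random.Generator, peaks: Mapping[int, float]) -> int:
    lengths = sorted(peaks)
    weights = np.array([peaks[k] for k in lengths], dtype=float)
    weights /= weights.sum()
    return int(rng.choice(lengths, p=weights))


def _read_from_5prime(mt_seq: str, e: int, strand: str, length: int) -> str:
    if strand == "+":
        return mt_seq[e : e + length]
    return reverse_complement(mt_seq[e - length + 1 : e + 1])


def _pirna_template(
    rng: np.random.Generator,
    spec: SimulationSpec,
    refs: ToyReferences,
    groups: Mapping[tuple, list[tuple[int, str, str]]],
) -> dict:
    mt_seq = refs.genome.sequence
    embedded = bool(rng.random() < spec.nuclear_embed_fraction)
    is_trna = bool(rng.random() < spec.trna_fraction)
    length = _draw_length(rng, spec.length_peaks)
    b1 = "T" if rng.random() < spec.p_U1 else str(rng.choice(list("ACG")))
    b10 = "A" if rng.random() < spec.p_A10 else str(rng.choice(list("CGT")))
    if is_trna:
        arm = "5" if rng.random() < spec.arm5_bias else "3"
        pool = groups[("trna", embedded, arm)]
    else:
        arm = None
        strand = "+" if rng.random() < spec.strand_bias else "-"
        pool = groups[("other", embedded, strand)]
    candidates = [
        (e, s, lid) for e, s, lid in pool if _cell(mt_seq, e, s) == (b1, b10)
    ]
    e, strand, locus = candidates[int(rng.integers(len(candidates)))]
    seq = _read_from_5prime(mt_seq, e, strand, length)
    return {
        "sequence": seq,
        "true_class": "piRNA",
        "source": locus,
        "strand": strand,
        "arm": arm,
        "isoform": None,
        "nuclear_embedded": embedded,
    }


def _mirna_template(
    rng: np.random.Generator, spec: SimulationSpec, refs: ToyReferences
) -> dict:
    embedded = bool(rng.random() < spec.nuclear_embed_fraction)
    pid = (
        str(rng.choice(["pre1", "pre2"])) if embedded else "pre3"
    )
    cats = sorted(spec.isoform_mixture)
    probs = np.array([spec.isoform_mixture[c] for c in cats], dtype=float)
    cat = str(rng.choice(cats, p=probs / probs.sum()))
    cs, ce = _CANONICAL
    if cat == "canonical":
        rs, re = cs, ce
    elif cat == "isomiR":
        rs, re = cs, ce - int(rng.integers(1, 5))
    elif cat == "paramiR":
        rs = cs - int(rng.integers(1, 6))
        re = ce - int(rng.integers(0, 5))
    else:  # circumiR
        rs = cs + int(rng.integers(1, 5))
        re = ce + int(rng.integers(0, 6))
    seq = refs.mirna.precursors[pid][rs:re]
    return {
        "sequence": seq,
        "true_class": "miRNA",
        "source": pid,
        "strand": "+",
        "arm": None,
        "isoform": cat,
        "nuclear_embedded": embedded,
    }


def _window_template(
    rng: np.random.Generator,
    spec: SimulationSpec,
    refs: ToyReferences,
    loci: Mapping[str, tuple[tuple[int, int], str, bool]],
    true_class: str,
) -> dict:
    embedded = bool(rng.random() < spec.nuclear_embed_fraction)
    choices = sorted(
        lid for lid, (_w, _s, emb) in loci.items() if emb == embedded
    )
    lid = str(rng.choice(choices))
    (w0, w1), strand, _emb = loci[lid]
    length = _draw_length(rng, spec.length_peaks)
    if strand == "+":
        e = int(rng.integers(w0, w1 - length + 1))
    else:
        e = int(rng.integers(w0 + length - 1, w1))
    seq = _read_from_5prime(refs.genome.sequence, e, strand, length)
    return {
        "sequence": seq,
        "true_class": true_class,
        "source": lid,
        "strand": strand,
        "arm": None,
        "isoform": None,
        "nuclear_embedded": embedded,
    }


def _background_template(
    rng: np.random.Generator, spec: SimulationSpec, refs: ToyReferences
) -> dict:
    """A non-mitochondrial read from the nuclear genome, clear of NUMTs."""
    length = _draw_length(rng, spec.length_peaks)
    chrom = str(rng.choice(sorted(refs.nuclear)))
    chrom_seq = refs.nuclear[chrom]
    blocked = refs.numts.get(chrom, [])
    while True:
        start = int(rng.integers(0, len(chrom_seq) - length + 1))
        if all(start + length <= s or start >= e for s, e in blocked):
            break
    window = chrom_seq[start : start + length]
    strand = "+" if rng.random() < spec.strand_bias else "-"
    seq = window if strand == "+" else reverse_complement(window)
    return {
        "sequence": seq,
        "true_class": "background",
        "source": chrom,
        "strand": strand,
        "arm": None,
        "isoform": None,
        "nuclear_embedded": False,
    }


def simulate_library(
    spec: SimulationSpec, refs: ToyReferences
) -> tuple[list[str], pd.DataFrame]:
    """Draw a seeded read library and its per-unique-sequence truth table.

    Returns the reads in emission order and a DataFrame with one row per
    unique sequence (class, source locus, strand, arm, isoform, copy count,
    NUMT-embedded flag) that accounts for every emitted read.
    """
    if spec.trna_fraction > 0 and not refs.trnas:
        raise ValueError("spec draws tRNA reads but references have no tRNA")
    if max(spec.length_peaks) > L_MAX:
        raise ValueError(
            f"length peaks above {L_MAX} nt exceed the toy locus windows"
        )
    rng = np.random.default_rng(spec.seed)
    groups = _group_positions()
    classes = sorted(spec.class_mixture)
    class_probs = np.array(
        [spec.class_mixture[c] for c in classes], dtype=float
    )
    class_probs /= class_probs.sum()

    n_mt = int(round(spec.n_reads * spec.mt_fraction))
    reads: list[str] = []
    truth: dict[str, dict] = {}

    def emit(template: dict) -> None:
        copies = 1 + int(rng.poisson(spec.duplication - 1.0))
        seq = template["sequence"]
        rec = truth.get(seq)
        if rec is None:
            template = dict(template, copies=copies)
            truth[seq] = template
        else:
            if rec["true_class"] != template["true_class"]:
                raise RuntimeError("sequence collision across classes")
            rec["copies"] += copies
        reads.extend([seq] * copies)

    while len(reads) < n_mt:
        cls = classes[int(rng.choice(len(classes), p=class_probs))]
        if cls == "piRNA":
            emit(_pirna_template(rng, spec, refs, groups))
        elif cls == "miRNA":
            emit(_mirna_template(rng, spec, refs))
        elif cls == "ncRNA":
            emit(_window_template(rng, spec, refs, _NCRNA, "ncRNA"))
        else:
            emit(_window_template(rng, spec, refs, _UNANNOT, "unannotated"))
    while len(reads) < spec.n_reads:
        emit(_background_template(rng, spec, refs))

    table = pd.DataFrame(
        [dict(sequence=s, **{k: v for k, v in rec.items() if k != "sequence"})
         for s, rec in truth.items()]
    )
    return reads, table


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    """Emit reads as FASTQ with constant quality 'I' (deterministic bytes)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# --- synthetic mirror of the mouse mitochondrial annotation -----------------

_MOUSE_LIKE_PLAN: list[tuple[str, str, int, str]] = [
    ("mt-Tf", "tRNA", 68, "+"), ("mt-Rnr1", "rRNA", 955, "+"),
    ("mt-Tv", "tRNA", 69, "+"), ("mt-Rnr2", "rRNA", 1571, "+"),
    ("mt-Tl1", "tRNA", 75, "+"), ("mt-Nd1", "protein_coding", 956, "+"),
    ("mt-Ti", "tRNA", 69, "+"), ("mt-Tq", "tRNA", 72, "-"),
    ("mt-Tm", "tRNA", 68, "+"), ("mt-Nd2", "protein_coding", 1038, "+"),
    ("mt-Tw", "tRNA", 69, "+"), ("mt-Ta", "tRNA", 69, "-"),
    ("mt-Tn", "tRNA", 73, "-"), ("mt-Tc", "tRNA", 66, "-"),
    ("mt-Ty", "tRNA", 68, "-"), ("mt-Co1", "protein_coding", 1545, "+"),
    ("mt-Ts1", "tRNA", 70, "-"), ("mt-Td", "tRNA", 68, "+"),
    ("mt-Co2", "protein_coding", 684, "+"), ("mt-Tk", "tRNA", 70, "+"),
    ("mt-Atp8", "protein_coding", 204, "+"),
    ("mt-Atp6", "protein_coding", 681, "+"),
    ("mt-Co3", "protein_coding", 784, "+"), ("mt-Tg", "tRNA", 68, "+"),
    ("mt-Nd3", "protein_coding", 346, "+"), ("mt-Tr", "tRNA", 65, "+"),
    ("mt-Nd4l", "protein_coding", 297, "+"),
    ("mt-Nd4", "protein_coding", 1378, "+"), ("mt-Th", "tRNA", 69, "+"),
    ("mt-Ts2", "tRNA", 59, "+"), ("mt-Tl2", "tRNA", 71, "+"),
    ("mt-Nd5", "protein_coding", 1824, "+"),
    ("mt-Nd6", "protein_coding", 519, "-"), ("mt-Te", "tRNA", 69, "-"),
    ("mt-Cytb", "protein_coding", 1144, "+"), ("mt-Tt", "tRNA", 67, "+"),
    ("mt-Tp", "tRNA", 66, "-"),
]
MOUSE_LIKE_LENGTH = 16_299


def make_mouse_like_annotation() -> list[Feature]:
    """Synthetic stand-in for the mouse mitochondrial gene annotation.

    Mirrors the real gene census and order of the ~16.3 Kb mouse mtDNA — 37
    genes (13 protein-coding, 22 tRNA, 2 rRNA) followed by the D-loop — with
    gene lengths close to the real ones but synthetic coordinates laid out
    end to end. It is NOT the Ensembl annotation; use it where only the
    census and structure matter.
    """
    features: list[Feature] = []
    pos = 0
    for name, kind, length, strand in _MOUSE_LIKE_PLAN:
        ac = pos + length // 2 - 1 if kind == "tRNA" else None
        features.append(
            Feature(name, kind, pos, pos + length, strand, name=name,
                    anticodon_start=ac)
        )
        pos += length
    features.append(
        Feature("D-loop", "D_loop", pos, MOUSE_LIKE_LENGTH, "+", name="D-loop")
    )
    return features
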