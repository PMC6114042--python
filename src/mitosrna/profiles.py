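"""Characterization statistics for mitochondria-associated small RNAs.

Strand-resolved coverage tracks, 5'-end feature counting, tRNA arm coverage
around the anticodon, read length distributions, positional nucleotide
frequencies (the 1U/10A piRNA hallmarks), reads-per-Kb density,
median-of-ratios count normalization with log2 transform, hierarchical
clustering, nuclear re-mapping with per-chromosome distribution, and NUMT
overlap enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .align import Alignment, KmerIndex, align_all, best_hit
from .genome import CircularGenome, Feature
from .readprep import CollapsedLibrary

__all__ = [
    "CoverageTrack",
    "CountMatrix",
    "ArmCoverage",
    "build_coverage",
    "feature_counts",
    "trna_arm_coverage",
    "five_prime_arm_read_fraction",
    "length_distribution",
    "positional_nucleotide_freq",
    "reads_per_kb",
    "size_factors",
    "log2_normalize",
    "hierarchical_cluster",
    "chromosome_distribution",
    "numt_overlap",
    "coverage_to_bedgraph",
]

log = logging.getLogger(__name__)

WeightedAlignments = Iterable[tuple[Alignment, int]]


@dataclass
class CoverageTrack:
    """Per-position read depth on each strand of one reference."""

    ref_id: str
    depth_plus: np.ndarray
    depth_minus: np.ndarray

    @property
    def length(self) -> int:
        return len(self.depth_plus)

    @property
    def total_mass(self) -> int:
        """Summed depth over both strands; equals the summed aligned lengths
        of the contributing reads weighted by read count (conservation)."""
        return int(self.depth_plus.sum() + self.depth_minus.sum())

    def depth(self, strand: str) -> np.ndarray:
        return self.depth_plus if strand == "+" else self.depth_minus


@dataclass
class CountMatrix:
    """Feature x sample raw counts with optional per-sample size factors."""

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if self.size_factors is not None and len(self.size_factors) != len(
            self.counts.columns
        ):
            raise ValueError("one size factor per sample required")

    def with_size_factors(self, allow_pseudo_reference: bool = False
                          ) -> "CountMatrix":
        sf = size_factors(self.counts, allow_pseudo_reference)
        return CountMatrix(self.counts, sf)

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not computed")
        return self.counts / self.size_factors

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return log2_normalize(self, pseudocount)


@dataclass(frozen=True)
class ArmCoverage:
    """Depth summary of a tRNA's two arms on its own strand.

    ``frac_5prime`` = mean5' / (mean5' + mean3'), or None when both arms have
    zero depth.
    """

    trna_id: str
    mean_5prime: float
    mean_3prime: float

    @property
    def frac_5prime(self) -> float | None:
        total = self.mean_5prime + self.mean_3prime
        if total == 0:
            return None
        return self.mean_5prime / total


def build_coverage(
    alignments: WeightedAlignments, genome: CircularGenome
) -> CoverageTrack:
    """Accumulate per-position depth; wrapping reads split at the junction.

    Every aligned read adds its collapsed count to each covered position on
    its strand, so the track's total mass equals the count-weighted summed
    aligned lengths.
    """
    n = genome.length
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    for aln, count in alignments:
        start = aln.start % n
        end = start + aln.length
        if aln.length > n or not (0 <= start < n):
            raise ValueError(f"alignment outside genome: {aln}")
        track = plus if aln.strand == "+" else minus
        if end <= n:
            track[start:end] += count
        else:
            track[start:] += count
            track[: end - n] += count
    return CoverageTrack(genome.id, plus, minus)


def feature_counts(
    alignments: WeightedAlignments,
    features: Sequence[Feature],
    ref_length: int,
    sample_id: str = "sample",
) -> CountMatrix:
    """Count reads per (feature, read strand) by the biological 5'-end rule.

    A read is assigned to the unique feature containing its 5' end (start for
    '+', end-1 for '-', modulo the genome length); reads whose 5' end lies in
    no feature accumulate in "intergenic" rows. Conservation: assigned plus
    intergenic reads equal the total aligned reads.
    """
    rows: dict[tuple[str, str], int] = {}
    for aln, count in alignments:
        pos = aln.five_prime_end(ref_length)
        hit = next((f for f in features if f.contains(pos)), None)
        key = (hit.feature_id if hit else "intergenic", aln.strand)
        rows[key] = rows.get(key, 0) + count
    index = pd.MultiIndex.from_tuples(
        sorted(rows), names=["feature", "strand"]
    )
    df = pd.DataFrame(
        {sample_id: [rows[k] for k in sorted(rows)]}, index=index
    )
    return CountMatrix(df)


def _arm_intervals(trna: Feature) -> tuple[tuple[int, int], tuple[int, int]]:
    """(5' arm, 3' arm) reference intervals in biological orientation.

    The anticodon triplet itself belongs to neither arm. For '-' strand tRNAs
    the biological 5' arm sits at higher reference coordinates.
    """
    ac0 = trna.anticodon_start
    ac1 = ac0 + trna.anticodon_len
    if trna.strand == "+":
        arm5, arm3 = (trna.start, ac0), (ac1, trna.end)
    else:
        arm5, arm3 = (ac1, trna.end), (trna.start, ac0)
    for lo, hi in (arm5, arm3):
        if hi <= lo:
            raise ValueError(f"zero-length arm in tRNA {trna.feature_id}")
    return arm5, arm3


def trna_arm_coverage(
    track: CoverageTrack,
    trnas: Sequence[Feature],
    stat: str = "mean",
) -> list[ArmCoverage]:
    """Average (or median) depth over each tRNA's 5' and 3' arm.

    Depth is taken on the strand of the tRNA; anticodon positions are
    excluded. ``stat`` selects mean (default) or median.
    """
    reducer = np.mean if stat == "mean" else np.median
    out = []
    for trna in trnas:
        depth = track.depth(trna.strand)
        (a5, b5), (a3, b3) = _arm_intervals(trna)
        out.append(
            ArmCoverage(
                trna_id=trna.feature_id,
                mean_5prime=float(reducer(depth[a5:b5])),
                mean_3prime=float(reducer(depth[a3:b3])),
            )
        )
    return out


def five_prime_arm_read_fraction(
    alignments: WeightedAlignments,
    trnas: Sequence[Feature],
    ref_length: int,
) -> float | None:
    """Count-weighted fraction of tRNA-arm reads whose 5' end is in a 5' arm.

    The denominator is all reads whose biological 5' end lies in either arm
    of any tRNA; None when that denominator is zero.
    """
    in5 = 0
    total = 0
    arms = [(_arm_intervals(t), t) for t in trnas]
    for aln, count in alignments:
        pos = aln.five_prime_end(ref_length)
        for ((a5, b5), (a3, b3)), _t in arms:
            if a5 <= pos < b5:
                in5 += count
                total += count
                break
            if a3 <= pos < b3:
                total += count
                break
    if total == 0:
        return None
    return in5 / total


def length_distribution(
    entries: Mapping[str, int], denominator_reads: int | None = None
) -> dict[int, float]:
    """Percentage of reads at each length.

    With the default denominator (the subset's own reads) percentages sum to
    100; passing the full library total instead gives percentages of the
    whole library, which sum to <= 100.
    """
    by_len: dict[int, int] = {}
    for seq, count in entries.items():
        by_len[len(seq)] = by_len.get(len(seq), 0) + count
    total = denominator_reads if denominator_reads is not None else sum(
        by_len.values()
    )
    if total == 0:
        log.warning("length_distribution: empty subset")
        return {}
    return {n: 100.0 * c / total for n, c in sorted(by_len.items())}


def positional_nucleotide_freq(
    entries: Mapping[str, int], positions: Sequence[int] = (1, 10)
) -> pd.DataFrame:
    """Base frequency at 1-based read positions, count-weighted.

    Reads shorter than a queried position are excluded from that position's
    denominator. T is reported as U. Rows are positions, columns A/C/G/U;
    each row sums to 1 (when any read qualifies).
    """
    bases = ("A", "C", "G", "U")
    table = pd.DataFrame(0.0, index=list(positions), columns=list(bases))
    for pos in positions:
        counts = dict.fromkeys(bases, 0)
        total = 0
        for seq, count in entries.items():
            if len(seq) >= pos:
                base = seq[pos - 1].replace("T", "U")
                if base in counts:
                    counts[base] += count
                    total += count
        if total:
            for b in bases:
                table.loc[pos, b] = counts[b] / total
    return table


def reads_per_kb(n_reads: int, genome_length: int) -> float:
    """Read density per kilobase of genome."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return n_reads / (genome_length / 1000.0)


def size_factors(
    counts: pd.DataFrame,
    allow_pseudo_reference: bool = False,
    reference: np.ndarray | None = None,
) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    For each feature the geometric mean across samples defines a reference
    pseudo-sample; a sample's factor is the median over features of its count
    divided by that reference. Only features with nonzero counts in every
    sample qualify; if none do, ``allow_pseudo_reference=True`` switches to
    geometric means over the positive counts only.

    A fixed per-feature ``reference`` may be supplied instead (e.g. the
    geometric means of a baseline matrix); against a fixed reference,
    scaling one sample's counts by c scales exactly that sample's factor
    by c.
    """
    mat = counts.to_numpy(dtype=float)
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if len(ref) != mat.shape[0]:
            raise ValueError("reference length must equal feature count")
        usable = ref > 0
        if not usable.any():
            raise ValueError("reference has no positive entries")
        ratios = mat[usable] / ref[usable, None]
        return pd.Series(
            np.nanmedian(ratios, axis=0), index=counts.columns,
            name="size_factor",
        )
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any():
        ref = np.exp(np.log(mat[all_positive]).mean(axis=1))
        ratios = mat[all_positive] / ref[:, None]
    elif allow_pseudo_reference:
        any_positive = (mat > 0).any(axis=1)
        if not any_positive.any():
            raise ValueError("count matrix is all zeros")
        sub = mat[any_positive]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(sub), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
    else:
        raise ValueError(
            "no feature has nonzero counts in every sample; pass "
            "allow_pseudo_reference=True to use a positive-count reference"
        )
    factors = np.nanmedian(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log2_normalize(matrix: CountMatrix, pseudocount: float = 1.0
                   ) -> pd.DataFrame:
    """log2(raw / size_factor + pseudocount), entry-wise.

    The pseudocount (default 1) keeps zero counts finite at exactly 0.
    """
    if matrix.size_factors is None:
        raise ValueError("size factors not computed")
    return np.log2(matrix.counts / matrix.size_factors + pseudocount)


def hierarchical_cluster(
    data: pd.DataFrame,
    axis: str = "columns",
    metric: str = "pearson",
    linkage: str = "average",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of matrix rows or columns.

    ``metric`` is Pearson-correlation distance (1 - r, the default) or
    euclidean; ``linkage`` average (default) or complete. Ties are broken by
    input order, so the merge tree is deterministic. Returns the linkage
    matrix and the ordered leaf labels.
    """
    if metric not in ("pearson", "euclidean"):
        raise ValueError(f"unknown metric {metric!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    X = data.T if axis == "columns" else data
    labels = list(X.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    if metric == "pearson":
        dist = 1.0 - np.corrcoef(X.to_numpy(dtype=float))
        condensed = squareform(dist, checks=False)
    else:
        condensed = pdist(X.to_numpy(dtype=float))
    Z = sch.linkage(condensed, method=linkage)
    order = [labels[i] for i in sch.leaves_list(Z)]
    return Z, order


def chromosome_distribution(
    mt_lib: CollapsedLibrary,
    nuclear_index: KmerIndex,
    max_mismatches: int = 0,
    size_factor: float | None = None,
) -> dict:
    """Re-map mitochondria-associated sequences to nuclear references.

    Reports the fraction of reads (and of unique sequences) with at least one
    nuclear placement, and per-chromosome best-hit read counts, optionally
    divided by the sample's size factor.
    """
    per_chrom: dict[str, int] = {}
    mapped_reads = 0
    mapped_seqs = 0
    for seq, count in mt_lib.entries.items():
        hit = best_hit(align_all(seq, nuclear_index, max_mismatches))
        if hit is not None:
            mapped_reads += count
            mapped_seqs += 1
            per_chrom[hit.ref_id] = per_chrom.get(hit.ref_id, 0) + count
    total_reads = mt_lib.total_reads
    total_seqs = mt_lib.total_sequences
    counts = pd.Series(per_chrom, dtype=float).sort_index()
    if size_factor is not None:
        counts = counts / size_factor
    return {
        "nuclear_mappable_fraction_reads": (
            mapped_reads / total_reads if total_reads else 0.0
        ),
        "nuclear_mappable_fraction_sequences": (
            mapped_seqs / total_seqs if total_seqs else 0.0
        ),
        "per_chromosome_counts": counts,
    }


def numt_overlap(
    nuclear_alignments: WeightedAlignments,
    numt_intervals: Mapping[str, Sequence[tuple[int, int]]],
    chrom_lengths: Mapping[str, int],
) -> dict:
    """Overlap of nuclear-mapped reads with NUMT intervals.

    Observed = count-weighted fraction of nuclear alignments overlapping a
    NUMT by at least one base. Expected = NUMT bases / nuclear bases, the
    fraction a uniformly placed read set would approach. The enrichment ratio
    observed/expected is ~1 when placement is unbiased with respect to NUMTs;
    with an empty NUMT set the ratio is undefined (None, logged).
    """
    numt_bases = sum(
        e - s for ivs in numt_intervals.values() for s, e in ivs
    )
    total_bases = sum(chrom_lengths.values())
    expected = numt_bases / total_bases if total_bases else 0.0
    overlapping = 0
    total = 0
    for aln, count in nuclear_alignments:
        total += count
        for s, e in numt_intervals.get(aln.ref_id, ()):
            if aln.start < e and aln.end > s:
                overlapping += count
                break
    observed = overlapping / total if total else 0.0
    if expected == 0:
        log.warning("numt_overlap: empty NUMT set, enrichment undefined")
        ratio = None
    else:
        ratio = observed / expected
    return {
        "observed_fraction": observed,
        "expected_fraction": expected,
        "enrichment_ratio": ratio,
        "n_reads": total,
    }


def coverage_to_bedgraph(track: CoverageTrack, strand: str,
                         log_transform: bool = False) -> str:
    """bedGraph export of one strand (runs of equal depth merged).

    ``log_transform`` emits log10(1 + depth), the scale used for circular
    genome plots.
    """
    depth = track.depth(strand).astype(float)
    if log_transform:
        depth = np.log10(1.0 + depth)
    lines = []
    run_start = 0
    for i in range(1, track.length + 1):
        if i == track.length or depth[i] != depth[run_start]:
            val = depth[run_start]
            if val != 0:
                out = f"{val:.4f}" if log_transform else f"{int(val)}"
                lines.append(f"{track.ref_id}\t{run_start}\t{i}\t{out}")
            run_start = i
    return "\n".join(lines) + ("\n" if lines else "")
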