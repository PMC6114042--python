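# Methods

## The analysis model

Mitochondrial small RNAs (mitosRNAs) are identified by exact-or-near-exact
end-to-end alignment of collapsed small RNA-seq sequences to the circular
mitochondrial genome, then partitioned into functional classes by sequential
matching against reference databases. The pipeline treats the library as a
multiset of unique sequences with multiplicities; every statistic is defined
twice, over reads (count-weighted) and over unique sequences, because the two
views diverge strongly in highly duplicated small RNA libraries.

### Coordinates and strand conventions

Internal coordinates are 0-based half-open on the "heavy" strand, which is
operationally the strand of the reference FASTA; "light" is its reverse
complement. GFF3 I/O converts to/from 1-based inclusive at the boundary; BED
stays half-open. The circle is handled by junction extension: a circular
reference of length L is indexed over `seq + seq[:max_read_len - 1]`, the
minimal extension in which every wrapping placement appears exactly once;
reported starts are reduced mod L and wrapping placements carry a flag.
The biological 5′ end of a placement is `start` on '+' and `start + len - 1`
on '−'; it drives feature assignment and tRNA-arm statistics.

### Alignment

The aligner finds **all** full-length placements of a query with Hamming
distance ≤ m on both strands (no gaps, no quality weighting — appropriate
for 18–35 nt reads against references of kilobase scale). Candidate starts
come from a k-mer index (k = 12 by default); by pigeonhole the seed lookup is
complete whenever the query has more k-windows than m·k, and the
implementation falls back to scanning every offset otherwise, so the hit set
is always exactly the exhaustive-scan set (property-tested against a
brute-force oracle). `N` matches nothing, including another `N`. Multi-mapped
sequences contribute once through a deterministic best hit (fewest
mismatches, then '+' before '−', then smallest start, then lexicographic
reference id); an all-hits mode remains available for coverage-style
analyses. Defaults: m = 0 for database classification, m configurable (0–2
typical) for genome mapping; the upstream tools this replaces do not document
their settings, so both limits are exposed in the run configuration.

### Hierarchical classification

Databases are tested in the fixed order miRNA → piRNA → other ncRNA; a
sequence receives the first matching label, making ties impossible, and falls
through to *unannotated*. A sequence matches a database when it aligns
end-to-end, sense strand, **within** one of the entries (for miRNAs, within a
precursor hairpin) — the semantics of mapping reads against a database index.
A plain identity lookup is provided as a cross-check; it coincides with
alignment membership at 0 mismatches exactly when entries have read length,
which is how the equivalence is exercised in the tests. Labels are assigned
once per unique sequence and read counts inherit them (collapse-then-
classify).

### Isoform taxonomy

For a read placed at [r_s, r_e) on a precursor whose canonical mature
interval is [c_s, c_e):

| rule (checked in order) | category |
|---|---|
| r_s = c_s, r_e = c_e | canonical |
| r_s = c_s, r_e < c_e | isomiR (same 5′ end ⇒ same seed, 3′-trimmed) |
| r_s ≤ c_s, r_e ≤ c_e | paramiR (5′-anchored overlap) |
| r_s ≥ c_s, r_e ≥ c_e | circumiR (3′-anchored overlap) |
| otherwise (strict containment either way) | nearest anchor; tie → paramiR |

The verbal definitions of paramiR/circumiR leave three cases open: a read
that extends the canonical 3′ end while sharing its 5′ start (assigned
circumiR by the ≥/≥ rule, since only its 3′ region departs from the
canonical), and reads strictly containing or strictly inside the canonical,
which go to whichever anchor end is nearer (|r_s − c_s| vs |r_e − c_e|), ties
to paramiR. These choices make the rule total and deterministic — every
interval overlapping the canonical receives exactly one category, which the
acceptance suite verifies by enumeration — and are invariant under a common
coordinate shift. Non-overlapping intervals are an error, and placements
whose overlap is shorter than the 7 nt seed should not be fed to the rule.

### tRNA arms

Arms are defined by the anticodon: 5′ arm = gene start to anticodon start,
3′ arm = anticodon end to gene end, in biological orientation (mirrored for
light-strand tRNAs); the anticodon triplet belongs to neither arm, keeping
them disjoint. Two statistics are reported deliberately: the per-arm mean
(or median — both available, mean is the default) coverage depth, and the
read-level share of tRNA reads whose 5′ end lies in a 5′ arm. They answer
different questions and differ numerically: a fragment starting in the 5′
arm can extend across the anticodon and raise 3′-arm *depth*, so the depth
ratio understates the 5′-arm *origin* share (e.g. an 85% 5′-origin library
shows per-tRNA depth fractions near 0.63).

### Normalization, transform, clustering

Size factors are median-of-ratios: features with nonzero counts in every
sample define a geometric-mean reference; sample j's factor is the median of
k_ij / reference_i. When no feature is positive everywhere, an explicit
fallback computes geometric means over positive counts only. A fixed
external reference can also be supplied, in which case scaling one sample's
counts by c scales exactly its factor by c; for the self-referential
estimator only factor *ratios* have that equivariance (the geometric-mean
reference itself absorbs c^(1/m)), which is the form the property tests
assert. The expression transform is log2(k/s + 1); the pseudocount of 1
keeps the abundant zeros of per-isoform matrices at exactly 0. Clustering is
agglomerative with Pearson-correlation distance (1 − r) and average linkage
by default (euclidean/complete available), ties broken by input order so the
tree is reproducible; scipy performs the agglomeration and a from-scratch
averaging oracle checks the merge heights in the tests.

### Nuclear re-mapping and NUMTs

Mitochondria-associated sequences are re-aligned to the nuclear references;
the mappable fraction is reported over both reads and unique sequences
(either may be the quantity of interest; they differ). Per-chromosome counts
use best hits and can be divided by the sample's size factor. NUMT overlap
compares the count-weighted fraction of nuclear placements intersecting a
NUMT interval (≥1 bp) with the genomic NUMT base fraction; their ratio is ~1
for placement unbiased with respect to NUMTs. Because overlap is by any
base, reads of length ℓ overlap an interval with probability slightly above
its base fraction (edge effect of order (ℓ−1)/L per interval), which the
tolerance of the uniform-placement test accounts for explicitly.

## The synthetic-data generator

The generator is first-class, tested code: it emits the study conditions the
pipeline is meant to measure, with per-unique-sequence ground truth (class,
source locus, strand, arm, isoform, copy count, NUMT-embedding flag)
accounting for every read.

Defaults emulate the observables of mouse germ-cell small RNA libraries:
mitochondrial fraction 0.9% of reads; class mixture piRNA 0.85 / miRNA 0.08 /
ncRNA 0.05 / unannotated 0.02; read-length peaks 19/21/25/27 nt with weights
0.30/0.30/0.20/0.20; first-position U and tenth-position A probabilities
0.25 each (no 1U/10A bias); 80% of piRNA reads tRNA-derived, of which 85%
start in the 5′ arm; strand bias 0.7 toward the heavy strand; mean copy
number 7 per unique sequence (copies ~ 1 + Poisson(6), which places a
substantial minority of sequences at or below the 5-count filter threshold);
75% of mitochondrial source loci duplicated into the nuclear genome as
NUMTs. Two dials beyond these — the tRNA-derived share and the isoform
mixture (default isomiR 0.45 / paramiR 0.45 / canonical 0.05 /
circumiR 0.05) — exist because the corresponding observables need a truth
value to recover.

Design points:

- **Reads are exact substrings of their source.** Positional composition is
  achieved by *site selection*: per piRNA read, target bases for positions 1
  and 10 are drawn from (p_U1, p_A10) and a 5′-end site whose genomic bases
  match is chosen uniformly from the admissible locus group. At build time
  the toy genome sequence is locally repaired so that every (locus-group ×
  base-pair) cell is non-empty; sampling therefore never relaxes a
  constraint and the generated marginals are exactly binomial, which is what
  lets recovery tests use plain binomial oracles.
- **Reference databases are pairwise disjoint by construction** (verified,
  including substring containment across sets), so classification truth is
  unambiguous and recovery at 0 mismatches is exactly 100%.
- **NUMTs are verbatim copies** of designated mitochondrial segments placed
  in two toy nuclear chromosomes; each class has source loci both inside and
  outside the embedded segments, so the nuclear-mappable fraction is a free
  dial. Background (non-mitochondrial) reads are drawn from the nuclear
  genome clear of NUMTs, exercising the mitochondrial selection step with
  realistic negatives.
- Same spec + seed ⇒ byte-identical FASTQ and reference files.

What the generator does **not** emulate: sequencing errors and quality
variation, adapter read-through beyond a literal 3′ adapter, mammalian
genome scale (toy loci are hundreds of nt; the real mouse repertoire is
sampled from ~16.3 kb of mtDNA against a 2.7 Gb nucleus), expression
heterogeneity across loci of the same class, and ping-pong-correlated piRNA
pairs. Passing recovery tests therefore demonstrates correctness of the
measurement machinery under the stated mixture model, not robustness to
sequencing noise or to repetitive-genome multi-mapping at scale.

For tests and examples the simulated problem sizes are 3,000–50,000 reads
per library (and 200,000 where a sub-1% mitochondrial fraction must be
resolved) over a 4 kb toy mitochondrial genome — sizes chosen so the full
suite exercises every code path in seconds while leaving all statistical
tolerances at 3 standard errors.

A separate builder provides a *synthetic mirror* of the mouse mitochondrial
annotation — the real gene census and order (13 protein-coding genes, 22
tRNAs, 2 rRNAs, then the D-loop) with realistic gene lengths laid end to end
on a 16,299 nt genome — for tests where only census and structure matter; it
is not the Ensembl annotation and is labelled accordingly.

## Tolerances and numerical choices

- Statistical recovery tests use 3 standard errors. For count-weighted read
  fractions the SE is computed as sqrt(p(1−p)·Σc²)/Σc over the contributing
  unique-sequence counts c — duplicated reads are not independent draws, so
  a read-level binomial SE would be too tight; where n distinct templates
  are compared directly, sqrt(p(1−p)/n) applies.
- Percentages in emitted tables are printed at 2 decimals with
  round-half-even, always next to a full-precision column, so every printed
  percentage recomputes exactly from its numerator and denominator columns.
- Degenerate inputs: empty libraries collapse to empty libraries (logged,
  not an error); an empty miRNA subset yields an empty isoform table; an
  empty NUMT set leaves the enrichment ratio undefined (None) with a
  warning; zero-length tRNA arms cannot be constructed (feature invariants
  reject an anticodon flush against either gene end, naming the tRNA).
- The ≤5-count filter applies per library, matching per-sample reporting; it
  is idempotent and conserves reads (total after = total before − removed).

## Known limitations

- Ungapped alignment only; an indel-bearing read is simply unmapped.
- Database matching is sense-strand; antisense matches to a database entry
  are not counted as class members.
- The aligner's exhaustive contract is designed for references up to tens of
  kilobases (mitochondrial genomes, toy chromosomes, sncRNA databases);
  whole mammalian nuclear genomes are out of scope at desk scale.
- Features spanning the circular junction must be pre-split into two
  sub-intervals in the annotation.
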