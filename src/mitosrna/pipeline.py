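"""End-to-end orchestration: FASTQ in, summary tables and tracks out.

Stages per sample: ingest and optionally adapter-trim the FASTQ, collapse to
unique sequences, drop low-count sequences, select the mitochondria-
associated sub-library, classify it hierarchically, and compute the full
profile suite. Joint stages build the cross-sample count matrices,
median-of-ratios normalization and hierarchical clustering.

Every output table is TSV; percentages carry both a 2-decimal (round-half-
even) column and a full-precision column. A manifest records every parameter
and seed so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .align import build_index
from .classify import (
    CLASS_LABELS,
    class_summary_table,
    classify_hierarchical,
    isoform_composition,
    select_mt_associated,
)
from .genome import load_annotation, load_genome
from .profiles import (
    CountMatrix,
    build_coverage,
    chromosome_distribution,
    coverage_to_bedgraph,
    feature_counts,
    five_prime_arm_read_fraction,
    hierarchical_cluster,
    length_distribution,
    numt_overlap,
    positional_nucleotide_freq,
    reads_per_kb,
    size_factors,
    trna_arm_coverage,
)
from .readprep import (
    collapse,
    filter_low_count,
    read_fastq,
    trim_adapter,
)
from .refio import load_mirna_set, load_sequence_set, read_numt_bed, read_fasta_dict

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    genome_fasta: str
    annotation: str
    fastq: dict[str, str]  # sample id -> FASTQ path
    mirna_mature: str
    mirna_precursor: str
    mirna_canonical: str
    pirna_fasta: str
    ncrna_fasta: str
    output_dir: str
    nuclear_fasta: str | None = None
    numt_bed: str | None = None
    adapter: str | None = None
    adapter_min_overlap: int = 5
    min_len: int = 18
    max_len: int = 35
    count_filter: int = 5
    mt_max_mismatches: int = 0
    db_max_mismatches: int = 0
    nuclear_max_mismatches: int = 0
    cluster_metric: str = "pearson"
    cluster_linkage: str = "average"
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**data)
        except TypeError as exc:
            raise StageError("config", str(exc)) from exc

    def validate(self) -> None:
        paths = [self.genome_fasta, self.annotation, self.mirna_mature,
                 self.mirna_precursor, self.mirna_canonical,
                 self.pirna_fasta, self.ncrna_fasta,
                 *self.fastq.values()]
        if self.nuclear_fasta:
            paths.append(self.nuclear_fasta)
        if self.numt_bed:
            paths.append(self.numt_bed)
        for p in paths:
            if not Path(p).exists():
                raise StageError("config", f"missing input file: {p}")
        if self.min_len > self.max_len:
            raise StageError("config", "min_len > max_len")
        if not self.fastq:
            raise StageError("config", "no FASTQ inputs configured")


def _pct(numer: int, denom: int) -> tuple[str, float]:
    """(2-decimal round-half-even string, full-precision value)."""
    exact = 100.0 * numer / denom if denom else 0.0
    return f"{round(exact, 2):.2f}", exact


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.time()
        try:
            result = fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        log.info("stage %s done in %.2fs", name, time.time() - t0)
        return result

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to the output directory.

    Returns a dict of the main in-memory results (per-sample summaries and
    cross-sample matrices) so the pipeline is equally usable as a library
    call.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = _stage("load_genome")(load_genome, config.genome_fasta)
    features = _stage("load_annotation")(
        load_annotation, config.annotation, genome
    )
    mirna = _stage("load_references")(
        load_mirna_set, config.mirna_mature, config.mirna_precursor,
        config.mirna_canonical,
    )
    pirna = load_sequence_set("pirna", config.pirna_fasta)
    ncrna = load_sequence_set("ncrna", config.ncrna_fasta)
    mt_index = build_index(
        [(genome.id, genome.sequence, True)], max_query_len=config.max_len
    )
    nuclear_index = None
    numts = None
    nuclear_lengths: dict[str, int] = {}
    if config.nuclear_fasta:
        nuclear = read_fasta_dict(config.nuclear_fasta)
        nuclear_lengths = {c: len(s) for c, s in nuclear.items()}
        nuclear_index = build_index(
            [(c, s, False) for c, s in sorted(nuclear.items())],
            max_query_len=config.max_len,
        )
        if config.numt_bed:
            numts = read_numt_bed(config.numt_bed)

    trnas = [f for f in features if f.kind == "tRNA"]
    results: dict = {"samples": {}, "config": asdict(config)}
    lib_rows, class_frames, iso_rows = [], [], []
    length_rows, posfreq_rows, arm_rows, density_rows = [], [], [], []
    chrom_rows, numt_rows = [], []
    mirna_counts: dict[str, dict[str, int]] = {}
    pirna_gene_counts: dict[str, dict[tuple[str, str], int]] = {}

    for sample, fastq_path in sorted(config.fastq.items()):
        def ingest():
            reads = read_fastq(fastq_path)
            if config.adapter:
                reads = (
                    trim_adapter(r, config.adapter, config.adapter_min_overlap)
                    for r in reads
                )
            return collapse(reads, sample, config.min_len, config.max_len)

        lib = _stage("collapse")(ingest)
        lib = _stage("filter")(filter_low_count, lib, config.count_filter)
        mt_lib, placements = _stage("select_mt")(
            select_mt_associated, lib, mt_index, config.mt_max_mismatches
        )
        classified = _stage("classify")(
            classify_hierarchical, mt_lib, mirna, pirna, ncrna,
            config.db_max_mismatches,
        )
        weighted = [
            (placements[seq], mt_lib.entries[seq]) for seq in sorted(mt_lib.entries)
        ]
        labels = {c.sequence: c for c in classified}

        # --- library summary (reads/sequences duality) ---------------------
        pct_r, pct_r_exact = _pct(mt_lib.total_reads, lib.total_reads)
        pct_s, pct_s_exact = _pct(mt_lib.total_sequences, lib.total_sequences)
        lib_rows.append(
            {
                "sample": sample,
                "total_reads": lib.total_reads,
                "mt_reads": mt_lib.total_reads,
                "pct_mt_reads": pct_r,
                "pct_mt_reads_exact": pct_r_exact,
                "total_sequences": lib.total_sequences,
                "mt_sequences": mt_lib.total_sequences,
                "pct_mt_sequences": pct_s,
                "pct_mt_sequences_exact": pct_s_exact,
            }
        )

        class_frames.append(class_summary_table(classified, sample))
        iso = isoform_composition(classified)
        for cat, frac in iso.items():
            iso_rows.append({"sample": sample, "isoform": cat,
                             "fraction": frac})

        # --- per-sequence assignments --------------------------------------
        per_seq = pd.DataFrame(
            {
                "sequence": [c.sequence for c in classified],
                "count": [c.count for c in classified],
                "class": [c.label for c in classified],
                "matched_ref": [c.matched_ref_id or "" for c in classified],
                "isoform": [c.isoform or "" for c in classified],
                "mt_start": [placements[c.sequence].start for c in classified],
                "mt_strand": [placements[c.sequence].strand for c in classified],
            }
        )
        per_seq.to_csv(outdir / f"per_sequence_{sample}.tsv", sep="\t",
                       index=False)

        # --- coverage and feature counts -----------------------------------
        track = _stage("coverage")(build_coverage, weighted, genome)
        for strand, tag in (("+", "plus"), ("-", "minus")):
            (outdir / f"coverage_{sample}_{tag}.bedgraph").write_text(
                coverage_to_bedgraph(track, strand)
            )
        fc = feature_counts(weighted, features, genome.length, sample)
        fc.counts.to_csv(outdir / f"feature_counts_{sample}.tsv", sep="\t")

        # --- piRNA-centric statistics --------------------------------------
        pirna_entries = {
            c.sequence: c.count for c in classified if c.label == "piRNA"
        }
        pirna_weighted = [
            (placements[s], c) for s, c in sorted(pirna_entries.items())
        ]
        pirna_track = build_coverage(pirna_weighted, genome)
        for arm in trna_arm_coverage(pirna_track, trnas):
            arm_rows.append(
                {
                    "sample": sample,
                    "trna": arm.trna_id,
                    "mean_5prime": arm.mean_5prime,
                    "mean_3prime": arm.mean_3prime,
                    "frac_5prime": (
                        "" if arm.frac_5prime is None else arm.frac_5prime
                    ),
                }
            )
        arm_frac = five_prime_arm_read_fraction(
            pirna_weighted, trnas, genome.length
        )
        results["samples"].setdefault(sample, {})[
            "pirna_5prime_arm_read_fraction"
        ] = arm_frac

        for mode, entries, denom in (
            ("library", dict(mt_lib.entries), lib.total_reads),
            ("pirna_subset", pirna_entries, None),
        ):
            for length, pct in length_distribution(entries, denom).items():
                length_rows.append(
                    {"sample": sample, "mode": mode, "length": length,
                     "pct_reads": pct}
                )
        freq = positional_nucleotide_freq(pirna_entries)
        for pos in freq.index:
            for base in freq.columns:
                posfreq_rows.append(
                    {"sample": sample, "position": pos, "base": base,
                     "frequency": freq.loc[pos, base]}
                )

        density_rows.append(
            {
                "sample": sample,
                "mt_reads_per_kb": reads_per_kb(
                    mt_lib.total_reads, genome.length
                ),
                "library_reads_per_nuclear_kb": (
                    reads_per_kb(lib.total_reads, sum(nuclear_lengths.values()))
                    if nuclear_lengths
                    else ""
                ),
            }
        )

        # --- nuclear re-mapping and NUMT overlap ---------------------------
        if nuclear_index is not None:
            dist = _stage("nuclear_map")(
                chromosome_distribution, mt_lib, nuclear_index,
                config.nuclear_max_mismatches,
            )
            for chrom, count in dist["per_chromosome_counts"].items():
                chrom_rows.append(
                    {"sample": sample, "chromosome": chrom, "reads": count}
                )
            chrom_rows.append(
                {
                    "sample": sample,
                    "chromosome": "__fraction_mapped_reads__",
                    "reads": dist["nuclear_mappable_fraction_reads"],
                }
            )
            results["samples"][sample]["nuclear"] = dist
            if numts:
                from .align import align_all, best_hit

                nuc_weighted = []
                for seq, count in sorted(mt_lib.entries.items()):
                    hit = best_hit(
                        align_all(seq, nuclear_index,
                                  config.nuclear_max_mismatches)
                    )
                    if hit is not None:
                        nuc_weighted.append((hit, count))
                overlap = numt_overlap(nuc_weighted, numts, nuclear_lengths)
                numt_rows.append({"sample": sample, **{
                    k: ("" if v is None else v) for k, v in overlap.items()
                }})
                results["samples"][sample]["numt"] = overlap

        # --- cross-sample matrices -----------------------------------------
        for c in classified:
            if c.label == "miRNA" and c.isoform is not None:
                key = f"{c.matched_ref_id}|{c.isoform}"
                mirna_counts.setdefault(key, {}).setdefault(sample, 0)
                mirna_counts[key][sample] += c.count
        for aln, count in pirna_weighted:
            pos = aln.five_prime_end(genome.length)
            feat = next((f for f in features if f.contains(pos)), None)
            key = (feat.feature_id if feat else "intergenic", aln.strand)
            pirna_gene_counts.setdefault(sample, {}).setdefault(key, 0)
            pirna_gene_counts[sample][key] += count

        results["samples"][sample].update(
            {
                "library": lib,
                "mt_library": mt_lib,
                "classified": classified,
                "isoform_composition": iso,
                "coverage": track,
            }
        )

    # --- joint outputs ------------------------------------------------------
    library_summary = pd.DataFrame(lib_rows)
    library_summary.to_csv(outdir / "library_summary.tsv", sep="\t",
                           index=False)
    class_table = pd.concat(class_frames, ignore_index=True)
    class_table.to_csv(outdir / "class_table.tsv", sep="\t", index=False)
    pd.DataFrame(iso_rows).to_csv(outdir / "isoform_composition.tsv",
                                  sep="\t", index=False)
    pd.DataFrame(length_rows).to_csv(outdir / "length_histograms.tsv",
                                     sep="\t", index=False)
    pd.DataFrame(posfreq_rows).to_csv(outdir / "position_1_10_freq.tsv",
                                      sep="\t", index=False)
    pd.DataFrame(arm_rows).to_csv(outdir / "arm_table.tsv", sep="\t",
                                  index=False)
    pd.DataFrame(density_rows).to_csv(outdir / "density_table.tsv", sep="\t",
                                      index=False)
    if chrom_rows:
        pd.DataFrame(chrom_rows).to_csv(outdir / "chromosome_table.tsv",
                                        sep="\t", index=False)
    if numt_rows:
        pd.DataFrame(numt_rows).to_csv(outdir / "numt_table.tsv", sep="\t",
                                       index=False)

    samples = sorted(config.fastq)
    if mirna_counts:
        mat = pd.DataFrame(mirna_counts).T.reindex(columns=samples).fillna(0)
        mat.index.name = "isoform_id"
        cm = CountMatrix(mat)
        try:
            cm = cm.with_size_factors()
        except ValueError:
            cm = cm.with_size_factors(allow_pseudo_reference=True)
        log2 = cm.log2(config.pseudocount)
        log2.to_csv(outdir / "mirna_isoform_log2.tsv", sep="\t")
        if len(samples) >= 2 and len(mat) >= 2:
            _, order = hierarchical_cluster(
                log2, axis="columns", metric=config.cluster_metric,
                linkage=config.cluster_linkage,
            )
            (outdir / "cluster_leaf_order.txt").write_text(
                "\n".join(order) + "\n"
            )
            results["cluster_leaf_order"] = order
        results["mirna_matrix"] = cm
    if pirna_gene_counts:
        keys = sorted({k for d in pirna_gene_counts.values() for k in d})
        mat = pd.DataFrame(
            {
                s: [pirna_gene_counts.get(s, {}).get(k, 0) for k in keys]
                for s in samples
            },
            index=pd.MultiIndex.from_tuples(keys, names=["feature", "strand"]),
        )
        mat.to_csv(outdir / "pirna_gene_counts.tsv", sep="\t")
        results["pirna_gene_matrix"] = CountMatrix(mat)

    manifest = {
        "mitosrna_version": __version__,
        "config": asdict(config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    results["library_summary"] = library_summary
    results["class_table"] = class_table
    return results
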