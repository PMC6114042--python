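"""The all-in-one pipeline: files in, report bundle out.

Serializes toy references and two simulated FASTQ libraries to disk, builds a
RunConfig and executes every stage, then lists the emitted tables. The same
run is available from the shell as `mitosrna simulate ...` + `mitosrna run
--config config.yaml`.
"""

import tempfile
from pathlib import Path

from mitosrna import RunConfig, run_pipeline
from mitosrna.refio import write_toy_references
from mitosrna.simulate import (
    SimulationSpec,
    make_toy_references,
    simulate_library,
    write_fastq,
)

root = Path(tempfile.mkdtemp(prefix="mitosrna_demo_"))
refs = make_toy_references(seed=5)
paths = write_toy_references(refs, root / "refs")

fastqs = {}
for i, sample in enumerate(["germline", "zygote"]):
    spec = SimulationSpec(seed=5 + i, n_reads=10_000, mt_fraction=0.05)
    reads, _ = simulate_library(spec, refs)
    fq = root / f"{sample}.fastq"
    write_fastq(reads, fq)
    fastqs[sample] = str(fq)

config = RunConfig(
    genome_fasta=paths["mt_fasta"],
    annotation=paths["mt_gff"],
    fastq=fastqs,
    mirna_mature=paths["mirna_mature"],
    mirna_precursor=paths["mirna_precursor"],
    mirna_canonical=paths["mirna_canonical"],
    pirna_fasta=paths["pirna_fasta"],
    ncrna_fasta=paths["ncrna_fasta"],
    nuclear_fasta=paths["nuclear_fasta"],
    numt_bed=paths["numt_bed"],
    output_dir=str(root / "results"),
    seed=5,
)
results = run_pipeline(config)

print(results["library_summary"].to_string(index=False))
print()
print("emitted files:")
for path in sorted((root / "results").iterdir()):
    print(" ", path.name)
print(
    "\nEach percentage column recomputes exactly from its numerator and\n"
    "denominator columns; the manifest reproduces the run bit for bit."
)
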