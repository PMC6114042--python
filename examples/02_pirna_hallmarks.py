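"""piRNA hallmark statistics: tRNA arms, read lengths, 1U/10A composition.

For the piRNA-classified reads of a simulated library: the share of reads
whose 5' end lies in a tRNA 5' arm (the dominant production mode for
mitochondrial piRNAs), the read-length distribution over the piRNA subset,
and the nucleotide frequencies at positions 1 and 10.
"""

from mitosrna import (
    SimulationSpec,
    build_coverage,
    build_index,
    classify_hierarchical,
    collapse,
    five_prime_arm_read_fraction,
    length_distribution,
    make_toy_references,
    positional_nucleotide_freq,
    select_mt_associated,
    simulate_library,
    trna_arm_coverage,
)

refs = make_toy_references(seed=2)
spec = SimulationSpec(seed=2, n_reads=20_000, mt_fraction=1.0)
reads, _ = simulate_library(spec, refs)

lib = collapse(reads)
mt_index = build_index([(refs.genome.id, refs.genome.sequence, True)])
mt_lib, placements = select_mt_associated(lib, mt_index)
classified = classify_hierarchical(mt_lib, refs.mirna, refs.pirna, refs.ncrna)

pirna = {c.sequence: c.count for c in classified if c.label == "piRNA"}
weighted = [(placements[s], c) for s, c in sorted(pirna.items())]

arm5 = five_prime_arm_read_fraction(weighted, refs.trnas, refs.genome.length)
print(f"piRNA reads starting in a tRNA 5' arm: {100 * arm5:.1f}%")

track = build_coverage(weighted, refs.genome)
for arm in trna_arm_coverage(track, refs.trnas):
    print(
        f"  {arm.trna_id}: mean depth 5'={arm.mean_5prime:.1f} "
        f"3'={arm.mean_3prime:.1f} frac5'={arm.frac_5prime:.2f}"
    )

print("piRNA read-length distribution (% of piRNA reads):")
for length, pct in length_distribution(pirna).items():
    print(f"  {length} nt: {pct:.1f}%")

freq = positional_nucleotide_freq(pirna)
print("base frequencies at read positions 1 and 10 (U == T):")
print(freq.round(3).to_string())
print(
    "Near-uniform frequencies at both positions mean no 1U/10A bias, the\n"
    "hallmark pattern that separates these reads from nuclear piRNAs."
)
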