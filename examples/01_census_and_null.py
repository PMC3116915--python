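"""Oligonucleotide census of a simulated genome against a Markov null.

Simulates a 300 kb genome carrying two REPIN families, counts k-mers over
both strands for a range of k, and compares the most-abundant counts with
the maxima observed in random genomes of identical dinucleotide content.
Planted repeats tower over everything the null can produce.
"""

import repinscan as rs
from repinscan.simulate import GI_SEED, GII_SEED

cfg = rs.SimulationConfig(
    genome_length=300_000,
    gene_density=0.6,
    families=[
        rs.RepinFamilySpec("GI", GI_SEED, 71, 40),
        rs.RepinFamilySpec("GII", GII_SEED, 110, 20),
    ],
    n_singlets=10,
)
genome, truth = rs.simulate_genome(cfg, seed=1)
print(f"simulated genome: {len(genome):,} bp, {len(genome.features)} genes, "
      f"{len(truth.repins)} planted REPINs")

profile = rs.dinucleotide_profile(genome)
null = rs.max_kmer_null(profile, [12, 16, 20], n_genomes=5, seed=2)

print(f"\n{'k':>3} {'most abundant':>18} {'count':>6} {'null max':>9}")
for k in (12, 16, 20):
    kmer, count = rs.most_abundant(rs.count_kmers(genome, k))
    print(f"{k:>3} {kmer[:18]:>18} {count:>6} {max(null[k]):>9}")

print(
    "\nThe null max is what chance alone produces in a genome of the same "
    "dinucleotide content;\ncounts far above it flag genuine repeat families "
    "(the planted arms occur ~80-120x here)."
)
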