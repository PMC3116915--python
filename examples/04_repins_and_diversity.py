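"""REPIN validation: orientation, hairpin folding, and singlet decay.

Size-2 clusters are classified by arm orientation and spacing; inverted
doublets at the family spacing are REPINs. The consensus REPIN is folded
with a maximum-base-pairing DP to show the arms pair into a long hairpin,
and pairwise-identity resampling shows doublet arms are more conserved
than lone (decayed) singlets.
"""

import repinscan as rs
from repinscan.simulate import GI_SEED

cfg = rs.SimulationConfig(
    genome_length=250_000,
    gene_density=0.6,
    families=[rs.RepinFamilySpec("GI", GI_SEED, 71, 40)],
    n_singlets=15,
)
genome, truth = rs.simulate_genome(cfg, seed=7)
space = rs.extragenic_space(genome)
pool = rs.family_pool([GI_SEED], 1, labels=["GI"])
occ = [o for o in rs.match_in_space(pool, genome, space) if o.extragenic]

repins, report = rs.detect_repins(occ, genome=genome)
print(f"{report.n_doublets} doublets: {report.fraction_inverted:.0%} inverted, "
      f"{len(repins)} REPINs at the family spacing")

seqs = [genome.sequence[r.span[0] : r.span[1]] for r in repins]
cons, ident = rs.consensus(seqs)
fold = rs.fold_hairpin(cons)
print(f"\nconsensus REPIN ({len(cons)} bp, mean column identity "
      f"{sum(ident) / len(ident):.2f}):")
print(cons)
print(fold.structure)
print(f"hairpin: {fold.n_pairs} base pairs "
      f"({fold.n_pairs * 2 / len(cons):.0%} of bases paired)")

clusters, _ = rs.find_clusters(occ)
pools = {(p.group, p.context): p for p in rs.partition_by_context(occ, clusters, masks={})}
singlets = pools[("GI", "singlet")]
doublets = pools[("GI", "doublet")]
ra = rs.resample_mean_identity(singlets, n_reps=10_000, seed=8)
rb = rs.resample_mean_identity(doublets, n_reps=10_000, seed=9)
sig = rs.nonoverlap_significance(ra, rb)
print(f"\nmean pairwise identity: singlets {float(ra.means.mean()):.3f} "
      f"(n={len(singlets)}), doublets {float(rb.means.mean()):.3f} (n={len(doublets)})")
print(f"distributions overlap: {sig.overlap} "
      f"(max singlet mean {sig.max_a:.3f} < min doublet mean {sig.min_b:.3f})")
print(
    "\nDoublet arms are near-identical while singlets have drifted: consistent "
    "with doublets\nbeing the replicating (selected) unit and singlets their "
    "decaying remnants."
)
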