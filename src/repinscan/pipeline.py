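"""End-to-end orchestration: census -> threshold -> grouping -> expansion ->
spatial nulls -> REPIN detection -> diversity, with a parameter manifest so
every run is reproducible."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import census as _census
from .diversity import partition_by_context, resample_mean_identity, nonoverlap_significance
from .expansion import GROUP_MASKS, family_pool, match_in_space, false_positive_rate
from .genome import GeneFeature, GenomeRecord, extragenic_space
from .grouping import group_kmers
from .nullmodels import dinucleotide_profile, max_kmer_null
from .repin import detect_repins
from .spatial import (
    find_clusters,
    simulate_singlet_null,
    singlet_doublet_ratio,
)

logger = logging.getLogger("repinscan")

__all__ = ["PipelineReport", "run_pipeline", "compare_genomes"]


@dataclass
class PipelineReport:
    manifest: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    groups: list = field(default_factory=list)
    occurrences: list = field(default_factory=list)
    repins: list = field(default_factory=list)
    orientation: object | None = None


def run_pipeline(
    genome: GenomeRecord,
    comparison_genome: GenomeRecord | None = None,
    k: int = 16,
    d: int = 2,
    seed: int = 1,
    n_null_genomes: int = 10,
    n_fp_reps: int = 0,
    n_placement_reps: int = 200,
    n_identity_reps: int = 1000,
    max_gap: int = 400,
    masks: dict | None = None,
) -> PipelineReport:
    """Run the full REP/REPIN discovery analysis on one genome.

    The over-representation threshold is the most-abundant k-mer count of
    the comparison genome when one is given, else the maximum across
    ``n_null_genomes`` Markov null genomes. Stochastic stage sizes
    (``n_*_reps``) are dialled down by default so the pipeline is usable on
    simulated genomes; raise them for production runs.
    """
    manifest = {
        "genome": genome.id,
        "k": k,
        "d": d,
        "seed": seed,
        "comparison_genome": comparison_genome.id if comparison_genome else None,
        "n_null_genomes": n_null_genomes,
        "n_fp_reps": n_fp_reps,
        "n_placement_reps": n_placement_reps,
        "n_identity_reps": n_identity_reps,
        "max_gap": max_gap,
    }
    report = PipelineReport(manifest=manifest)

    logger.info("census: k=%d on %s (%d bp)", k, genome.id, len(genome))
    cen = _census.count_kmers(genome, k)
    if comparison_genome is not None:
        threshold = _census.most_abundant(_census.count_kmers(comparison_genome, k))[1]
        manifest["threshold_source"] = "comparison"
    else:
        profile = dinucleotide_profile(genome)
        null = max_kmer_null(profile, [k], n_genomes=n_null_genomes, seed=seed)
        threshold = max(null[k])
        manifest["threshold_source"] = "markov_null"
    manifest["threshold"] = threshold
    over = _census.overrepresented(cen, threshold)
    report.tables["overrepresented"] = pd.DataFrame(over.members, columns=["kmer", "count"])
    if not over.members:
        logger.warning("no over-represented %d-mers above %d", k, threshold)
        return report

    logger.info("grouping %d over-represented %d-mers", len(over.members), k)
    groups = group_kmers(over, genome)
    report.groups = groups
    report.tables["groups"] = pd.DataFrame(
        [(g.label, g.seed, m) for g in groups for m in g.members],
        columns=["group", "seed", "member"],
    )

    seeds = [g.seed for g in groups]
    labels = [g.label for g in groups]
    pool = family_pool(seeds, d, labels=labels, masks=None)
    space = extragenic_space(genome)
    occ = match_in_space(pool, genome, space)
    extragenic_occ = [o for o in occ if o.extragenic]
    report.occurrences = extragenic_occ
    manifest["n_occurrences"] = len(occ)
    manifest["n_extragenic"] = len(extragenic_occ)
    if n_fp_reps > 0:
        fp = false_positive_rate(pool, genome, space, n_reps=n_fp_reps, seed=seed)
        report.tables["false_positive"] = pd.DataFrame(
            [{"d": fp.d, "rate": fp.rate, "real_count": fp.real_count, "n_reps": fp.n_reps}]
        )

    clusters, spectrum = find_clusters(extragenic_occ, max_gap=max_gap)
    null = simulate_singlet_null(
        space,
        n_segments=len(extragenic_occ),
        n_reps=n_placement_reps,
        seed=seed,
        max_gap=max_gap,
        observed_spectrum=spectrum,
    )
    report.tables["cluster_spectrum"] = null.table()
    ratio = singlet_doublet_ratio(spectrum)
    manifest["singlet_doublet_ratio"] = ratio

    repins, orientation = detect_repins(extragenic_occ, max_gap=max_gap, genome=genome)
    report.repins = repins
    report.orientation = orientation
    report.tables["repins"] = pd.DataFrame(
        [
            {
                "group": r.group,
                "left": r.left_end.position,
                "right": r.right_end.position,
                "spacing": r.spacing,
            }
            for r in repins
        ]
    )

    pools = partition_by_context(extragenic_occ, clusters, masks=masks if masks is not None else GROUP_MASKS)
    rows = []
    for p in pools:
        row = {"group": p.group, "context": p.context, "n": len(p)}
        if len(p) >= 2:
            rs = resample_mean_identity(p, n_reps=n_identity_reps, seed=seed)
            row["mean_identity"] = float(rs.means.mean())
            row["sd_identity"] = float(rs.means.std(ddof=1)) if n_identity_reps > 1 else 0.0
        rows.append(row)
    report.tables["diversity"] = pd.DataFrame(rows)
    by_key = {(p.group, p.context): p for p in pools}
    sig_rows = []
    for g in sorted({p.group for p in pools}):
        a, b = by_key.get((g, "singlet")), by_key.get((g, "doublet"))
        if a and b and len(a) >= 2 and len(b) >= 2:
            ra = resample_mean_identity(a, n_reps=n_identity_reps, seed=seed)
            rb = resample_mean_identity(b, n_reps=n_identity_reps, seed=seed + 1)
            rep = nonoverlap_significance(ra, rb)
            sig_rows.append(
                {"group": g, "max_singlet_mean": rep.max_a, "min_doublet_mean": rep.min_b,
                 "overlap": rep.overlap, "p_bound": rep.p_bound}
            )
    report.tables["diversity_significance"] = pd.DataFrame(sig_rows)
    logger.info("pipeline complete: %d groups, %d occurrences, %d REPINs",
                len(groups), len(extragenic_occ), len(repins))
    return report


def compare_genomes(
    entries: list[tuple[GenomeRecord, GeneFeature]],
    d: int = 2,
    max_gap: int = 400,
) -> pd.DataFrame:
    """Per-RAYT singlet:doublet ratios across genomes.

    Each entry is a genome plus the annotated RAYT gene feature next to
    which the REP seed is sought. Genomes whose RAYT yields no extragenic
    flank sequence are skipped with a warning.
    """
    rows = []
    for genome, rayt in entries:
        try:
            hit = _census.scan_rayt_flanks(genome, rayt)
        except ValueError as exc:
            logger.warning("skipping %s: %s", genome.id, exc)
            continue
        pool = family_pool([hit.kmer], d, labels=["REP"])
        space = extragenic_space(genome)
        occ = [o for o in match_in_space(pool, genome, space) if o.extragenic]
        _, spectrum = find_clusters(occ, max_gap=max_gap)
        ratio = singlet_doublet_ratio(spectrum) if spectrum else None
        classification = (
            "no-reps" if not spectrum
            else "singlet-only" if ratio is None
            else "singlet-dominated" if ratio > 2
            else "doublet-dominated"
        )
        rows.append(
            {
                "genome": genome.id,
                "rayt_start": rayt.start,
                "seed": hit.kmer,
                "seed_genome_count": hit.genome_count,
                "n_extragenic": len(occ),
                "singlets": spectrum.get(1, 0),
                "doublets": spectrum.get(2, 0),
                "ratio": ratio,
                "classification": classification,
            }
        )
    return pd.DataFrame(rows)
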