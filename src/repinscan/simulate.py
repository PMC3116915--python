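"""Synthetic genomes, annotations, and short reads with full truth tables.

The generator emulates the statistical structure the analysis assumes: an
order-1 Markov (by default GC-biased i.i.d.) background, annotated gene
intervals at bacterial coding density, REPIN families planted in the
intergenic space as inverted 16-mer arms flanking a partly
self-complementary spacer, decayed lone singlets, optional tandem arrays,
and reads sampled from molecules with or without REPIN excisions.
Every planted element is recorded in a truth table so detection stages can
be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .expansion import RepOccurrence
from .genome import GeneFeature, GenomeRecord, reverse_complement
from .nullmodels import BASES, decode, encode
from .repin import REP_LEN

__all__ = [
    "RepinFamilySpec",
    "TandemArraySpec",
    "ReadSpec",
    "ExcisionSpec",
    "SimulationConfig",
    "PlantedRepin",
    "TruthTable",
    "ReadTruth",
    "simulate_genome",
    "simulate_reads",
    "evaluate",
    "PrecisionRecall",
    "write_fastq",
    "GI_SEED",
    "GII_SEED",
    "GIII_SEED",
]

# The SBW25 group seeds, reused as defaults so simulated families carry the
# real motif composition.
GI_SEED = "GTGGGAGGGGGCTTGC"
GII_SEED = "GTGAGCGGGCTTGCCC"
GIII_SEED = "GAGGGAGCTTGCTCCC"


@dataclass
class RepinFamilySpec:
    label: str
    seed: str
    spacing: int  # start-to-start distance between the two arms
    copies: int


@dataclass
class TandemArraySpec:
    pattern: list[tuple[str, int]]  # (family label, start-to-start gap to next)
    n_units: int = 2


@dataclass
class ReadSpec:
    n_reads: int | None = None
    coverage: float | None = None
    min_len: int = 36
    max_len: int = 76
    error_rate: float = 0.0


@dataclass
class ExcisionSpec:
    repin_indices: list[int]
    fraction: float = 1.0
    tail_keep: int = 6


@dataclass
class SimulationConfig:
    genome_length: int = 5_000_000
    gc_content: float = 0.60  # Pseudomonas-like
    gene_density: float = 0.85
    gene_length_mean: float = 1000.0
    gene_length_sd: float = 400.0
    families: list[RepinFamilySpec] = field(
        default_factory=lambda: [
            RepinFamilySpec("GI", GI_SEED, 71, 200),
            RepinFamilySpec("GII", GII_SEED, 110, 100),
        ]
    )
    n_singlets: int = 50
    mu_singlet: float = 0.05
    mu_doublet: float = 0.005
    tandem_arrays: list[TandemArraySpec] = field(default_factory=list)
    min_element_separation: int = 500
    spacer_scramble: float = 0.2  # fraction of spacer stem positions decoupled


@dataclass
class PlantedRepin:
    left_pos: int
    right_pos: int
    spacing: int
    group: str
    left_kmer: str
    right_kmer: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_pos, self.right_pos + REP_LEN)


@dataclass
class TruthTable:
    occurrences: list[RepOccurrence]
    contexts: list[str]  # parallel to occurrences
    repins: list[PlantedRepin]
    arrays: list[tuple[int, int]]  # spans
    genes: list[GeneFeature]
    seed: int


def _mutate(seq: str, mu: float, rng: np.random.Generator) -> str:
    if mu <= 0:
        return seq
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < mu):
        out[i] = BASES[(BASES.index(out[i]) + rng.integers(1, 4)) % 4]
    return "".join(out)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=n, p=p).astype(np.int8))


def _spacer(length: int, gc: float, scramble: float, rng: np.random.Generator) -> str:
    """Spacer biased toward self-complementarity: a stem whose two sides are
    reverse complements except at a scrambled fraction of positions."""
    if length <= 0:
        return ""
    half = length // 2
    left = _random_dna(half, gc, rng)
    right = list(reverse_complement(left))
    for i in np.flatnonzero(rng.random(half) < scramble):
        right[i] = BASES[rng.integers(0, 4)]
    mid = _random_dna(length - 2 * half, gc, rng)
    return left + mid + "".join(right)


def _background(length: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _layout(
    config: SimulationConfig, piece_lens: list[int], rng: np.random.Generator
) -> tuple[list[GeneFeature], list[int]]:
    """Alternate genes and intergenic gaps, widening randomly chosen gaps
    into element slots.

    Most bacterial intergenic gaps are short (operon-internal); planted
    elements live in widened gaps flanked by half the minimum separation on
    each side, so any two elements are parted by at least one gene plus two
    margins (> 400 bp) and never overlap a gene. Returns the gene features
    and one start coordinate per piece (in the order given).
    """
    L = config.genome_length
    d = config.gene_density
    mean_gap = max(20.0, config.gene_length_mean * (1 - d) / max(d, 1e-6))
    margin = config.min_element_separation // 2
    genes: list[GeneFeature] = []
    starts: list[int] = [0] * len(piece_lens)
    todo = list(rng.permutation(len(piece_lens))) if piece_lens else []
    pos = 0
    per_cycle = config.gene_length_mean + mean_gap
    while pos < L:
        gap = int(rng.exponential(mean_gap)) + 20
        remaining_cycles = max(1.0, (L - pos) / per_cycle)
        # oversample the insertion rate so stragglers land before the end
        p_insert = min(1.0, 1.5 * len(todo) / remaining_cycles)
        if todo and rng.random() < p_insert:
            pi = todo[-1]
            slot = margin + piece_lens[pi] + margin
            if pos + gap + slot + 200 < L:
                starts[pi] = pos + gap + margin
                todo.pop()
                gap += slot + int(rng.exponential(mean_gap))
        start = pos + gap
        glen = int(np.clip(rng.normal(config.gene_length_mean, config.gene_length_sd), 150, 5000))
        # stop laying genes once the remainder is needed for stragglers
        needed = sum(piece_lens[pi] + 2 * margin for pi in todo)
        if start + glen > L or (todo and start + glen + needed + margin > L):
            break
        genes.append(GeneFeature(start=start, end=start + glen,
                                 strand="+" if rng.random() < 0.5 else "-", kind="gene"))
        pos = start + glen
    # stragglers go into the gene-free tail, still margin-separated
    tail = (genes[-1].end if genes else 0) + margin
    while todo:
        pi = todo[-1]
        if tail + piece_lens[pi] + margin > L:
            raise ValueError(
                f"genome too short for planted elements: {len(todo)} of "
                f"{len(piece_lens)} unplaced"
            )
        starts[pi] = tail
        tail += piece_lens[pi] + 2 * margin
        todo.pop()
    return genes, starts


def simulate_genome(
    config: SimulationConfig | None = None, seed: int = 1
) -> tuple[GenomeRecord, TruthTable]:
    """Generate a genome, its gene annotation, and the planted-element truth.

    Every planted element (REPIN, singlet, tandem array) sits wholly within
    intergenic space with more than ``min_element_separation`` bp to its
    nearest planted neighbour, so each REPIN forms its own cluster and
    singlets stay singlets.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(seed)
    L = config.genome_length

    # assemble the planted pieces first, then lay out genes around them
    pieces: list[tuple[str, list[tuple[int, str, str, str, str]], str]] = []
    # each piece: (sequence, [(offset, strand, kmer, group, context)], kind)
    for fam in config.families:
        for _ in range(fam.copies):
            arm_l = _mutate(fam.seed, config.mu_doublet, rng)
            arm_r = _mutate(fam.seed, config.mu_doublet, rng)
            spacer = _spacer(fam.spacing - REP_LEN, config.gc_content,
                             config.spacer_scramble, rng)
            seq = arm_l + spacer + reverse_complement(arm_r)
            occs = [
                (0, "+", arm_l, fam.label, "doublet"),
                (fam.spacing, "-", arm_r, fam.label, "doublet"),
            ]
            pieces.append((seq, occs, "repin"))
    fam_cycle = config.families or [RepinFamilySpec("GI", GI_SEED, 71, 0)]
    for i in range(config.n_singlets):
        fam = fam_cycle[i % len(fam_cycle)]
        kmer = _mutate(fam.seed, config.mu_singlet, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        seq = kmer if strand == "+" else reverse_complement(kmer)
        pieces.append((seq, [(0, strand, kmer, fam.label, "singlet")], "singlet"))
    fam_by_label = {f.label: f for f in config.families}
    for arr in config.tandem_arrays:
        seq_parts = []
        occs = []
        offset = 0
        steps = arr.pattern * arr.n_units
        for i, (label, gap) in enumerate(steps):
            fam = fam_by_label[label]
            occs.append((offset, "+", fam.seed, label, "cluster"))
            last = i == len(steps) - 1
            filler = "" if last else _random_dna(gap - REP_LEN, config.gc_content, rng)
            seq_parts.append(fam.seed + filler)
            offset += gap
        pieces.append(("".join(seq_parts), occs, "array"))

    genes, starts = _layout(config, [len(p[0]) for p in pieces], rng)

    codes = _background(L, config, rng)
    occurrences: list[RepOccurrence] = []
    contexts: list[str] = []
    repins: list[PlantedRepin] = []
    arrays: list[tuple[int, int]] = []
    for start, (seq, occs, kind) in zip(starts, pieces):
        codes[start : start + len(seq)] = encode(seq)
        for off, strand, kmer, group, context in occs:
            occurrences.append(
                RepOccurrence(
                    position=start + off,
                    strand=strand,
                    matched_kmer=kmer,
                    group=group,
                    distance_to_seed=0,
                    extragenic=True,
                )
            )
            contexts.append(context)
        if kind == "array":
            arrays.append((start, start + len(seq)))
    # planted REPINs recover from occurrence pairs rather than piece order
    occ_sorted = sorted(
        (o for o, c in zip(occurrences, contexts) if c == "doublet"),
        key=lambda o: o.position,
    )
    for a, b in zip(occ_sorted[0::2], occ_sorted[1::2]):
        repins.append(
            PlantedRepin(
                left_pos=a.position,
                right_pos=b.position,
                spacing=b.position - a.position,
                group=a.group,
                left_kmer=a.matched_kmer,
                right_kmer=b.matched_kmer,
            )
        )

    genome = GenomeRecord(id=f"sim_{seed}", sequence=decode(codes), features=genes)
    order_idx = sorted(range(len(occurrences)), key=lambda i: occurrences[i].position)
    truth = TruthTable(
        occurrences=[occurrences[i] for i in order_idx],
        contexts=[contexts[i] for i in order_idx],
        repins=sorted(repins, key=lambda r: r.left_pos),
        arrays=arrays,
        genes=genes,
        seed=seed,
    )
    return genome, truth


@dataclass
class ReadTruth:
    junction_reads: dict[str, int]  # read id -> index of excised REPIN
    n_alt_reads: int
    alt_junctions: list[int]  # junction coordinate in the excised allele
    excised: list[int]


def simulate_reads(
    genome: GenomeRecord,
    truth: TruthTable,
    read_spec: ReadSpec | None = None,
    seed: int = 1,
    excision: ExcisionSpec | None = None,
) -> tuple[list[tuple[str, str]], ReadTruth]:
    """Sample reads uniformly from reference and (optionally) excised alleles.

    With an ``ExcisionSpec``, a ``fraction`` of molecules carries all listed
    REPIN excisions (footprint from the left arm start to ``tail_keep``
    short of the right arm end, as for genomic excision screens). Reads are
    drawn with uniform starts, lengths uniform in [min_len, max_len], either
    orientation, and optional uniform substitution errors.
    """
    if read_spec is None:
        read_spec = ReadSpec()
    rng = np.random.default_rng(seed)
    ref = genome.sequence
    mean_len = (read_spec.min_len + read_spec.max_len) / 2
    n_reads = read_spec.n_reads
    if n_reads is None:
        cov = read_spec.coverage if read_spec.coverage is not None else 10.0
        n_reads = math.ceil(cov * len(ref) / mean_len)

    alt = ref
    alt_junctions: list[int] = []
    excised = list(excision.repin_indices) if excision else []
    if excision and excised:
        cuts = sorted(
            (
                (truth.repins[i].left_pos, truth.repins[i].right_pos + REP_LEN - excision.tail_keep)
                for i in excised
            ),
        )
        parts = []
        prev = 0
        removed = 0
        for s, e in cuts:
            parts.append(ref[prev:s])
            alt_junctions.append(s - removed)
            removed += e - s
            prev = e
        parts.append(ref[prev:])
        alt = "".join(parts)
    frac = excision.fraction if excision else 0.0

    reads: list[tuple[str, str]] = []
    junction_reads: dict[str, int] = {}
    n_alt = 0
    lens = rng.integers(read_spec.min_len, read_spec.max_len + 1, size=n_reads)
    from_alt = rng.random(n_reads) < frac
    flips = rng.random(n_reads) < 0.5
    for i in range(n_reads):
        src = alt if from_alt[i] else ref
        rl = int(lens[i])
        start = int(rng.integers(0, len(src) - rl + 1))
        seq = src[start : start + rl]
        if read_spec.error_rate > 0:
            seq = _mutate(seq, read_spec.error_rate, rng)
        if flips[i]:
            seq = reverse_complement(seq)
        rid = f"read_{i}"
        if from_alt[i]:
            n_alt += 1
            for jidx, j in enumerate(alt_junctions):
                if start <= j - 12 and j + 12 <= start + rl:
                    junction_reads[rid] = excised[jidx]
                    break
        reads.append((rid, seq))
    return reads, ReadTruth(
        junction_reads=junction_reads,
        n_alt_reads=n_alt,
        alt_junctions=alt_junctions,
        excised=excised,
    )


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


@dataclass
class PrecisionRecall:
    precision: float | None
    recall: float | None
    f1: float | None
    n_matched: int
    n_detected: int
    n_true: int


def evaluate(
    detected_positions: list[int], true_positions: list[int], tolerance: int = 2
) -> PrecisionRecall:
    """Greedy position matching within a bp tolerance."""
    det = sorted(detected_positions)
    tru = sorted(true_positions)
    i = j = matched = 0
    while i < len(det) and j < len(tru):
        if abs(det[i] - tru[j]) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif det[i] < tru[j]:
            i += 1
        else:
            j += 1
    precision = matched / len(det) if det else None
    recall = matched / len(tru) if tru else None
    f1 = None
    if precision and recall and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return PrecisionRecall(
        precision=precision,
        recall=recall,
        f1=f1,
        n_matched=matched,
        n_detected=len(det),
        n_true=len(tru),
    )
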