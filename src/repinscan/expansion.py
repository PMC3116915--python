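"""Degenerate family expansion: Hamming balls, genome matching, and
false-positive estimation on randomized extragenic space.

A REP family is a seed 16-mer plus every 16-mer within Hamming distance d
(default up to 4). Because the three SBW25 seeds lie 6-9 substitutions
apart, balls overlap for d >= 3; ``family_pool`` resolves the overlap either
by dropping 16-mers reachable from more than one seed (``shared="drop"``,
the default, which matches the published pool counts) or by assigning them
to the nearest seed (``shared="nearest"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np

from .genome import ExtragenicSpace, GenomeRecord, reverse_complement
from .nullmodels import randomize_extragenic

__all__ = [
    "DegenerateSet",
    "RepOccurrence",
    "FalsePositiveEstimate",
    "hamming_ball",
    "family_pool",
    "match_in_space",
    "count_matches",
    "false_positive_rate",
    "hamming",
    "GROUP_MASKS",
]

# Group-specific invariant bases (1-based position within the 16-mer).
GROUP_MASKS: dict[str, dict[int, str]] = {
    "GII": {2: "T", 6: "C"},
    "GIII": {6: "A", 13: "T"},
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def _ball(seed: str, d: int, mask: dict[int, str] | None = None) -> set[str]:
    """All sequences within Hamming distance d of seed; masked (1-based)
    positions are held fixed."""
    if d < 0:
        raise ValueError("d must be >= 0")
    n = len(seed)
    free = [i for i in range(n) if mask is None or (i + 1) not in mask]
    alts = {c: [x for x in "ACGT" if x != c] for c in "ACGT"}
    out = {seed}
    for r in range(1, d + 1):
        for pos in combinations(free, r):
            for subs in product(*[alts[seed[p]] for p in pos]):
                s = list(seed)
                for p, c in zip(pos, subs):
                    s[p] = c
                out.add("".join(s))
    return out


@dataclass
class DegenerateSet:
    """A set of degenerate 16-mers with their seed-group assignments."""

    seeds: list[str]
    d: int
    sequences: set[str]
    assignment: dict[str, str]  # member -> group label
    labels: list[str]
    masks: dict[str, dict[int, str]] | None = None
    n_shared_dropped: int = 0

    def __len__(self) -> int:
        return len(self.sequences)


def hamming_ball(
    seeds: str | list[str], d: int, mask: dict[int, str] | None = None
) -> set[str]:
    """Deduplicated union of Hamming balls of radius d around the seeds."""
    if isinstance(seeds, str):
        seeds = [seeds]
    out: set[str] = set()
    for s in seeds:
        out |= _ball(s, d, mask)
    return out


def family_pool(
    seeds: list[str],
    d: int,
    labels: list[str] | None = None,
    masks: dict[str, dict[int, str]] | None = None,
    shared: str = "drop",
) -> DegenerateSet:
    """Build the degenerate search pool for a set of group seeds.

    ``shared="drop"`` removes every sequence reachable from more than one
    seed (no unique group assignment exists for it); ``shared="nearest"``
    keeps such sequences, assigning each to its nearest seed with ties
    broken in favour of masked groups, then lexicographically by label.
    """
    if labels is None:
        from .grouping import roman

        labels = [f"G{roman(i + 1)}" for i in range(len(seeds))]
    balls = []
    for seed, label in zip(seeds, labels):
        mask = masks.get(label) if masks else None
        balls.append(_ball(seed, d, mask))
    assignment: dict[str, str] = {}
    shared_seqs: set[str] = set()
    for ball, label in zip(balls, labels):
        for s in ball:
            if s in assignment:
                shared_seqs.add(s)
            else:
                assignment[s] = label
    if shared == "drop":
        for s in shared_seqs:
            del assignment[s]
        dropped = len(shared_seqs)
    elif shared == "nearest":
        masked = set(masks) if masks else set()
        for s in shared_seqs:
            cands = [
                (hamming(s, seed), 0 if label in masked else 1, label)
                for seed, label, ball in zip(seeds, labels, balls)
                if s in ball
            ]
            assignment[s] = min(cands)[2]
        dropped = 0
    else:
        raise ValueError(f"unknown shared policy {shared!r}")
    return DegenerateSet(
        seeds=list(seeds),
        d=d,
        sequences=set(assignment),
        assignment=assignment,
        labels=list(labels),
        masks=masks,
        n_shared_dropped=dropped,
    )


@dataclass(frozen=True)
class RepOccurrence:
    """One genomic match of a family member.

    ``matched_kmer`` is stored in seed orientation: a reverse-strand hit at
    ``position`` means rc(matched_kmer) appears on the forward strand there.
    """

    position: int
    strand: str
    matched_kmer: str
    group: str
    distance_to_seed: int
    extragenic: bool


def match_in_space(
    degenerate_set: DegenerateSet,
    genome: GenomeRecord | str,
    space: ExtragenicSpace | None = None,
    extragenic_only: bool = False,
) -> list[RepOccurrence]:
    """All genomic windows (both strands) matching the degenerate set.

    One occurrence per (position, strand); a window whose forward and
    reverse-complement forms both match yields a single '+' occurrence.
    """
    if not degenerate_set.sequences:
        raise ValueError("empty degenerate set")
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    k = len(next(iter(degenerate_set.sequences)))
    pool = degenerate_set.assignment
    seed_of = dict(zip(degenerate_set.labels, degenerate_set.seeds))
    out: list[RepOccurrence] = []
    intervals = space.intervals if space is not None else None
    ptr = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        member, strand = None, "+"
        if w in pool:
            member = w
        else:
            rc = reverse_complement(w)
            if rc in pool:
                member, strand = rc, "-"
        if member is None:
            continue
        extragenic = True
        if intervals is not None:
            while ptr < len(intervals) and intervals[ptr][1] < i + k:
                ptr += 1
            extragenic = (
                ptr < len(intervals)
                and intervals[ptr][0] <= i
                and i + k <= intervals[ptr][1]
            )
        if extragenic_only and not extragenic:
            continue
        group = pool[member]
        out.append(
            RepOccurrence(
                position=i,
                strand=strand,
                matched_kmer=member,
                group=group,
                distance_to_seed=hamming(member, seed_of[group]),
                extragenic=extragenic,
            )
        )
    return out


def count_matches(degenerate_set: DegenerateSet, parts: list[str]) -> int:
    """Number of matching windows (both strands, one per footprint) across a
    list of sequences; windows do not cross part boundaries."""
    pool = degenerate_set.sequences
    k = len(next(iter(pool)))
    n = 0
    for part in parts:
        part = part.upper()
        for i in range(len(part) - k + 1):
            w = part[i : i + k]
            if w in pool or reverse_complement(w) in pool:
                n += 1
    return n


@dataclass
class FalsePositiveEstimate:
    d: int
    rate: float | None
    n_reps: int
    per_rep_counts: list[int]
    real_count: int


def false_positive_rate(
    degenerate_set: DegenerateSet,
    genome: GenomeRecord | str,
    space: ExtragenicSpace,
    n_reps: int = 100,
    seed: int = 1,
) -> FalsePositiveEstimate:
    """Fraction of extragenic matches expected by chance.

    Each replicate regenerates every extragenic interval from its own
    dinucleotide profile and recounts matches; the rate is the mean
    randomized count divided by the real count (None if no real matches).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    real_parts = [seq[s:e] for s, e in space.intervals]
    real = count_matches(degenerate_set, real_parts)
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_reps):
        rand_parts = randomize_extragenic(space, seq, int(rng.integers(0, 2**31 - 1)))
        counts.append(count_matches(degenerate_set, rand_parts))
    rate = None if real == 0 else float(np.mean(counts)) / real
    return FalsePositiveEstimate(
        d=degenerate_set.d, rate=rate, n_reps=n_reps, per_rep_counts=counts, real_count=real
    )
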