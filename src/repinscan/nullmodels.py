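"""Order-1 Markov null genomes and randomized extragenic space.

The null genome preserves the dinucleotide content of the leading and
lagging strand separately: transition probabilities are measured on the top
strand of the first replichore half and on the bottom strand (reverse
complement) of the second half, then each half is regenerated from its own
chain. The split point defaults to floor(L/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ExtragenicSpace, GenomeRecord, reverse_complement

__all__ = [
    "DinucleotideProfile",
    "RandomGenome",
    "dinucleotide_profile",
    "generate_random_genome",
    "max_kmer_null",
    "randomize_extragenic",
]

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}


def encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3; any other character -> 4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _B2I.items():
        lut[ord(b)] = i
    return lut[arr]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _transition_counts(seq: str) -> tuple[np.ndarray, np.ndarray]:
    codes = encode(seq)
    valid = codes < 4
    a, b = codes[:-1], codes[1:]
    ok = valid[:-1] & valid[1:]
    counts = np.zeros((4, 4), dtype=np.int64)
    np.add.at(counts, (a[ok], b[ok]), 1)
    marg = np.bincount(codes[valid], minlength=4).astype(np.int64)
    return counts, marg


def _normalise(counts: np.ndarray) -> np.ndarray:
    rows = counts.sum(axis=1, keepdims=True).astype(float)
    rows[rows == 0] = 1.0
    return counts / rows


@dataclass
class DinucleotideProfile:
    """Per-replichore-half conditional next-base probabilities."""

    half1_transitions: np.ndarray
    half2_transitions: np.ndarray
    half1_initial: np.ndarray
    half2_initial: np.ndarray
    source_length: int
    split: int

    def __post_init__(self) -> None:
        for m in (self.half1_transitions, self.half2_transitions):
            rows = m.sum(axis=1)
            # an all-zero row marks a state never observed in the source
            if not np.all(np.isclose(rows, 1.0, atol=1e-9) | np.isclose(rows, 0.0)):
                raise ValueError("transition matrix rows must sum to 1 (or 0 if unseen)")
            if (m < 0).any():
                raise ValueError("negative transition probability")

    def to_dict(self) -> dict:
        return {
            "half1_transitions": self.half1_transitions.tolist(),
            "half2_transitions": self.half2_transitions.tolist(),
            "half1_initial": self.half1_initial.tolist(),
            "half2_initial": self.half2_initial.tolist(),
            "source_length": self.source_length,
            "split": self.split,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DinucleotideProfile":
        return cls(
            np.asarray(d["half1_transitions"], dtype=float),
            np.asarray(d["half2_transitions"], dtype=float),
            np.asarray(d["half1_initial"], dtype=float),
            np.asarray(d["half2_initial"], dtype=float),
            int(d["source_length"]),
            int(d["split"]),
        )


@dataclass
class RandomGenome:
    sequence: str
    profile: DinucleotideProfile
    seed: int


def dinucleotide_profile(
    genome: GenomeRecord | str, split: int | None = None
) -> DinucleotideProfile:
    """Measure the two-half dinucleotide profile of a genome.

    Top strand over ``[0, split)``; bottom strand (reverse complement) over
    ``[split, L)``. ``split`` defaults to ``L // 2``.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    L = len(seq)
    if L < 2:
        raise ValueError("genome shorter than 2 bases")
    if split is None:
        split = L // 2
    split = max(1, min(L - 1, split))
    c1, m1 = _transition_counts(seq[:split])
    c2, m2 = _transition_counts(reverse_complement(seq[split:]))
    return DinucleotideProfile(
        half1_transitions=_normalise(c1),
        half2_transitions=_normalise(c2),
        half1_initial=m1 / max(1, m1.sum()),
        half2_initial=m2 / max(1, m2.sum()),
        source_length=L,
        split=split,
    )


def sample_chain(
    transitions: np.ndarray, initial: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample an order-1 Markov chain of length n over 4 states."""
    if n <= 0:
        return np.zeros(0, dtype=np.int8)
    # Pre-draw, for every position, a candidate next state conditional on
    # each possible current state; the sequential pass is then a cheap lookup.
    nxt = np.empty((n, 4), dtype=np.int8)
    for s in range(4):
        p = transitions[s]
        if p.sum() == 0:
            p = np.full(4, 0.25)
        nxt[:, s] = rng.choice(4, size=n, p=p / p.sum())
    out = np.empty(n, dtype=np.int8)
    state = int(rng.choice(4, p=initial / initial.sum()))
    out[0] = state
    row = nxt
    for i in range(1, n):
        state = row[i, state]
        out[i] = state
    return out


def generate_random_genome(profile: DinucleotideProfile, seed: int) -> RandomGenome:
    """Generate one null genome from a two-half dinucleotide profile.

    The first ``split`` bases come from the half-1 chain on the top strand;
    the remainder is generated as a bottom-strand chain from the half-2
    profile and reverse-complemented into top-strand orientation.
    """
    rng = np.random.default_rng(seed)
    L, split = profile.source_length, profile.split
    first = decode(sample_chain(profile.half1_transitions, profile.half1_initial, split, rng))
    second_bottom = decode(
        sample_chain(profile.half2_transitions, profile.half2_initial, L - split, rng)
    )
    return RandomGenome(
        sequence=first + reverse_complement(second_bottom), profile=profile, seed=seed
    )


def max_kmer_null(
    profile: DinucleotideProfile,
    k_range: range | list[int],
    n_genomes: int = 100,
    seed: int = 1,
) -> dict[int, list[int]]:
    """Distribution of the most-abundant k-mer count in null genomes.

    Returns, for each k, the per-replicate maximum combined-strand count.
    """
    from .census import count_kmers, most_abundant

    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[int, list[int]] = {k: [] for k in k_range}
    for _ in range(n_genomes):
        g = generate_random_genome(profile, int(rng.integers(0, 2**31 - 1)))
        for k in k_range:
            census = count_kmers(g.sequence, k)
            out[k].append(most_abundant(census)[1])
    return out


def randomize_extragenic(
    space: ExtragenicSpace, genome: GenomeRecord | str, seed: int
) -> list[str]:
    """Replace each extragenic interval by an order-1 Markov string.

    Each interval gets its own single-strand dinucleotide profile and exact
    length; intervals shorter than 2 bp are copied verbatim.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    rng = np.random.default_rng(seed)
    out = []
    for s, e in space.intervals:
        part = seq[s:e]
        if len(part) < 2:
            out.append(part)
            continue
        counts, marg = _transition_counts(part)
        trans = _normalise(counts)
        init = marg / max(1, marg.sum())
        codes = sample_chain(trans, init, len(part), rng)
        out.append(decode(codes))
    return out
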