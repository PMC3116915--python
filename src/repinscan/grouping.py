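"""Greedy grouping of over-represented k-mers by shared genomic context.

The algorithm pops the most abundant remaining k-mer as a group seed,
extracts every genomic occurrence of the seed (both orientations) padded
with flanking DNA, concatenates the occurrences with '|' separators, and
assigns every remaining k-mer found as a substring of that context string
(in either orientation) to the seed's group. Repeats until the input list
is empty. Group labels GI, GII, ... follow discovery order, i.e. descending
seed abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .census import OverrepresentedSet
from .genome import GenomeRecord, reverse_complement

__all__ = ["SequenceGroup", "group_kmers", "roman"]


def roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
            (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class SequenceGroup:
    label: str
    seed: str
    members: list[str]
    context_string: str = ""


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def build_context_string(genome_seq: str, kmer: str, flank: int = 20) -> str:
    """All genomic occurrences of kmer or rc(kmer), each padded with ``flank``
    bp on both sides (clipped at contig ends), joined by '|'."""
    k = len(kmer)
    positions = set(_find_all(genome_seq, kmer))
    rc = reverse_complement(kmer)
    if rc != kmer:
        positions |= set(_find_all(genome_seq, rc))
    pieces = [
        genome_seq[max(0, p - flank) : min(len(genome_seq), p + k + flank)]
        for p in sorted(positions)
    ]
    return "|".join(pieces)


def group_kmers(
    members: OverrepresentedSet | list[tuple[str, int]],
    genome: GenomeRecord | str,
    flank: int = 20,
) -> list[SequenceGroup]:
    """Partition over-represented k-mers into sequence groups (GI, GII, ...)."""
    if isinstance(members, OverrepresentedSet):
        items = list(members.members)
    else:
        items = sorted(members, key=lambda kv: (-kv[1], kv[0]))
    if not items:
        raise ValueError("empty input set")
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    remaining = [w for w, _ in items]  # already count desc, then lexicographic
    groups: list[SequenceGroup] = []
    while remaining:
        seed = remaining.pop(0)
        context = build_context_string(seq, seed, flank=flank)
        assigned = [seed]
        rest = []
        for w in remaining:
            if w in context or reverse_complement(w) in context:
                assigned.append(w)
            else:
                rest.append(w)
        remaining = rest
        groups.append(
            SequenceGroup(
                label=f"G{roman(len(groups) + 1)}",
                seed=seed,
                members=assigned,
                context_string=context,
            )
        )
    return groups
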