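"""Exhaustive k-mer counting and over-representation calls.

Counting slides a window of step 1 over the genome. Under the default
"combined" policy the count of a k-mer w is the number of forward-strand
windows equal to w plus the number equal to rc(w), so count(w) == count(rc(w))
and the census total is twice the number of valid windows. Windows containing
a non-ACGT character are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import GeneFeature, GenomeRecord, extragenic_space, reverse_complement

__all__ = [
    "KmerCensus",
    "OverrepresentedSet",
    "count_kmers",
    "count_kmers_in_parts",
    "most_abundant",
    "overrepresented",
    "scan_rayt_flanks",
    "RaytFlankReport",
]

_ACGT = frozenset("ACGT")


@dataclass
class KmerCensus:
    k: int
    counts: dict[str, int]
    strand_policy: str = "combined"
    source: str = ""
    # per-strand policy keeps the reverse-strand map separately
    reverse_counts: dict[str, int] | None = None


@dataclass
class OverrepresentedSet:
    k: int
    threshold: int
    members: list[tuple[str, int]]  # (kmer, count), count desc then lexicographic


def _forward_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    n = len(seq)
    if set(seq) <= _ACGT:
        for i in range(n - k + 1):
            w = seq[i : i + k]
            counts[w] = counts.get(w, 0) + 1
        return counts
    # next position >= i holding a non-ACGT character, for window exclusion
    bad = [i for i, c in enumerate(seq) if c not in _ACGT]
    import bisect

    for i in range(n - k + 1):
        j = bisect.bisect_left(bad, i)
        if j < len(bad) and bad[j] < i + k:
            continue
        w = seq[i : i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def count_kmers(
    genome: GenomeRecord | str, k: int, strand_policy: str = "combined"
) -> KmerCensus:
    """Census all k-mers of a genome (both strands)."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    source = genome.id if isinstance(genome, GenomeRecord) else ""
    return count_kmers_in_parts([seq], k, strand_policy, source=source)


def count_kmers_in_parts(
    parts: list[str], k: int, strand_policy: str = "combined", source: str = ""
) -> KmerCensus:
    """Census over a list of sequences; windows never cross part boundaries."""
    if k < 1 or all(k > len(p) for p in parts):
        raise ValueError(f"k={k} out of range")
    fwd: dict[str, int] = {}
    for p in parts:
        p = p.upper()
        for w, c in _forward_counts(p, k).items():
            fwd[w] = fwd.get(w, 0) + c
    if strand_policy == "per-strand":
        rev = {reverse_complement(w): c for w, c in fwd.items()}
        return KmerCensus(k=k, counts=fwd, strand_policy=strand_policy, source=source,
                          reverse_counts=rev)
    if strand_policy != "combined":
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    combined: dict[str, int] = {}
    for w, c in fwd.items():
        rc = reverse_complement(w)
        combined[w] = c + fwd.get(rc, 0)
        if rc not in combined:
            combined[rc] = combined[w]
    return KmerCensus(k=k, counts=combined, strand_policy="combined", source=source)


def most_abundant(census: KmerCensus) -> tuple[str, int]:
    """The k-mer with the highest count; ties go to the lexicographically
    smallest k-mer."""
    if not census.counts:
        raise ValueError("empty census")
    best = max(census.counts.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
    return best


def overrepresented(census: KmerCensus, threshold: int) -> OverrepresentedSet:
    """All k-mers with count strictly greater than ``threshold``, sorted by
    count descending then lexicographically."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    members = sorted(
        ((w, c) for w, c in census.counts.items() if c > threshold),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return OverrepresentedSet(k=census.k, threshold=threshold, members=members)


def longest_palindromic_core(kmer: str) -> str:
    """Longest substring equal to its own reverse complement."""
    best = ""
    n = len(kmer)
    for i in range(n):
        for j in range(i + 2, n + 1):
            sub = kmer[i:j]
            if len(sub) > len(best) and sub == reverse_complement(sub):
                best = sub
    return best


@dataclass
class RaytFlankReport:
    kmer: str
    genome_count: int
    flank_count: int
    palindromic_core: str


def scan_rayt_flanks(
    genome: GenomeRecord,
    rayt_feature: GeneFeature,
    k: int = 16,
    flank_window: int = 1000,
    genome_census: KmerCensus | None = None,
) -> RaytFlankReport:
    """Candidate REP seed from the non-coding DNA flanking a RAYT gene.

    Extracts up to ``flank_window`` bp of extragenic sequence on each side of
    the RAYT feature, censuses its k-mers, and returns the candidate with the
    highest genome-wide combined-strand count, together with a palindromicity
    report (the longest self-reverse-complementary substring).
    """
    if rayt_feature not in genome.features:
        raise ValueError("RAYT feature not found in genome annotations")
    space = extragenic_space(genome)
    windows = [
        (max(0, rayt_feature.start - flank_window), rayt_feature.start),
        (rayt_feature.end, min(len(genome), rayt_feature.end + flank_window)),
    ]
    parts = []
    for ws, we in windows:
        for s, e in space.intervals:
            lo, hi = max(s, ws), min(e, we)
            if hi - lo >= k:
                parts.append(genome.sequence[lo:hi])
    if not parts:
        raise ValueError("no extragenic flank sequence of length >= k near RAYT")
    flank_census = count_kmers_in_parts(parts, k)
    if genome_census is None:
        genome_census = count_kmers(genome, k)
    best = max(
        flank_census.counts,
        key=lambda w: (genome_census.counts.get(w, 0), [-ord(c) for c in w]),
    )
    return RaytFlankReport(
        kmer=best,
        genome_count=genome_census.counts.get(best, 0),
        flank_count=flank_census.counts[best],
        palindromic_core=longest_palindromic_core(best),
    )
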