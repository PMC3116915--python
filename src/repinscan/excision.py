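"""Alignment-free excision screens over raw short reads.

A REPIN excision leaves a junction joining the 12 bp immediately 5' of the
excision footprint to the 12 bp immediately 3' of it. Because reads are
shorter than the intact element, no read from an unexcised molecule can
contain both flanks; a read carrying the left flank followed by the right
flank (within a small gap) therefore witnesses an excision. A second screen
targets singlet palindromes via a degenerate 18-mer seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np

from .genome import GenomeRecord, reverse_complement
from .repin import REPIN, DEFAULT_TAIL_KEEP, excision_footprint

__all__ = [
    "FlankPair",
    "ExcisionEvent",
    "SingletSeedSet",
    "build_flank_index",
    "screen_reads",
    "build_singlet_seed_set",
    "screen_singlet_excisions",
    "iter_reads",
    "GI_PALINDROME_SEED",
]

GI_PALINDROME_SEED = "GGGGGCTTGCCCCCTCCC"


@dataclass(frozen=True)
class FlankPair:
    repin_id: str
    left_flank: str
    right_flank: str
    locus: tuple[int, int]
    truncated: bool = False


@dataclass(frozen=True)
class ExcisionEvent:
    repin_id: str
    read_id: str
    junction_offset: int  # position of the left flank's end within the read
    gap: int
    strand: str


def build_flank_index(
    repins: list[REPIN],
    genome: GenomeRecord | str,
    flank_len: int = 12,
    tail_keep: int = DEFAULT_TAIL_KEEP,
) -> list[FlankPair]:
    """One (left, right) flank pair per REPIN, taken immediately outside the
    excision footprint. REPINs too close to a contig end get truncated,
    flagged flanks."""
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    pairs = []
    for i, r in enumerate(repins):
        fp = excision_footprint(r, tail_keep=tail_keep)
        left = seq[max(0, fp.start - flank_len) : fp.start]
        right = seq[fp.end : fp.end + flank_len]
        pairs.append(
            FlankPair(
                repin_id=f"repin_{i}",
                left_flank=left,
                right_flank=right,
                locus=(fp.start, fp.end),
                truncated=len(left) < flank_len or len(right) < flank_len,
            )
        )
    return pairs


def iter_reads(source):
    """Yield (read_id, sequence) from a FASTQ path (.gz accepted), an open
    handle, or an iterable of (id, seq) pairs / SeqRecords."""
    from Bio import SeqIO

    if isinstance(source, str):
        opener = gzip.open if source.endswith(".gz") else open
        with opener(source, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec.id, str(rec.seq).upper()
        return
    for item in source:
        if hasattr(item, "seq"):
            yield item.id, str(item.seq).upper()
        else:
            rid, seq = item
            yield rid, seq.upper()


def screen_reads(
    reads,
    flank_index: list[FlankPair],
    max_gap: int = 10,
    min_read_len: int = 36,
) -> list[ExcisionEvent]:
    """Find reads reporting a left flank followed by its right flank.

    Both read orientations are screened; flank matching is exact. A read
    yields one event per flank pair at the first junction found.
    """
    usable = [p for p in flank_index if not p.truncated]
    if not usable:
        return []
    flank_len = len(usable[0].left_flank)
    by_left: dict[str, list[FlankPair]] = {}
    for p in usable:
        by_left.setdefault(p.left_flank, []).append(p)
    events = []
    for rid, seq in iter_reads(reads):
        if len(seq) < min_read_len:
            continue
        hit: set[str] = set()
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            n = len(s)
            for i in range(n - flank_len + 1):
                cands = by_left.get(s[i : i + flank_len])
                if not cands:
                    continue
                jstart = i + flank_len
                for p in cands:
                    if p.repin_id in hit:
                        continue
                    for gap in range(0, max_gap + 1):
                        r0 = jstart + gap
                        if r0 + flank_len > n:
                            break
                        if s[r0 : r0 + flank_len] == p.right_flank:
                            hit.add(p.repin_id)
                            events.append(
                                ExcisionEvent(
                                    repin_id=p.repin_id,
                                    read_id=rid,
                                    junction_offset=jstart,
                                    gap=gap,
                                    strand=strand,
                                )
                            )
                            break
    return events


@dataclass
class SingletSeedSet:
    seed: str
    max_mismatch: int
    matched_positions: list[tuple[int, str]]  # (position, strand)
    slack: int = 3


def build_singlet_seed_set(
    genome: GenomeRecord | str,
    seed: str = GI_PALINDROME_SEED,
    max_mismatch: int = 5,
) -> SingletSeedSet:
    """All genome positions whose k-mer is within ``max_mismatch`` of the
    seed on either strand (vectorized Hamming scan)."""
    from .nullmodels import encode

    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    k = len(seed)
    arr = encode(seq)
    n_win = len(seq) - k + 1
    if n_win <= 0:
        return SingletSeedSet(seed=seed, max_mismatch=max_mismatch, matched_positions=[])
    positions: list[tuple[int, str]] = []
    fwd = encode(seed)
    rev = encode(reverse_complement(seed))
    dist_f = np.zeros(n_win, dtype=np.int16)
    dist_r = np.zeros(n_win, dtype=np.int16)
    for j in range(k):
        col = arr[j : j + n_win]
        dist_f += col != fwd[j]
        dist_r += col != rev[j]
    for pos in np.flatnonzero((dist_f <= max_mismatch) | (dist_r <= max_mismatch)):
        strand = "+" if dist_f[pos] <= dist_r[pos] else "-"
        positions.append((int(pos), strand))
    return SingletSeedSet(seed=seed, max_mismatch=max_mismatch, matched_positions=positions)


def screen_singlet_excisions(
    reads,
    genome: GenomeRecord | str,
    seed_set: SingletSeedSet,
    slack: int = 3,
    flank_len: int = 12,
    max_gap: int = 10,
    min_read_len: int = 36,
) -> list[ExcisionEvent]:
    """Screen reads for excisions of singlet palindromes.

    For every matched seed position, candidate excised intervals extend the
    seed k-mer by 0..slack bp independently on each side; flank pairs are
    built for every candidate and the reads screened as for REPINs.
    """
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    k = len(seed_set.seed)
    index: list[FlankPair] = []
    seen = set()
    for pos, _strand in seed_set.matched_positions:
        for a in range(slack + 1):
            for b in range(slack + 1):
                s, e = pos - a, pos + k + b
                if s - flank_len < 0 or e + flank_len > len(seq) or (s, e) in seen:
                    continue
                seen.add((s, e))
                index.append(
                    FlankPair(
                        repin_id=f"singlet_{pos}_{a}_{b}",
                        left_flank=seq[s - flank_len : s],
                        right_flank=seq[e : e + flank_len],
                        locus=(s, e),
                    )
                )
    return screen_reads(reads, index, max_gap=max_gap, min_read_len=min_read_len)
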