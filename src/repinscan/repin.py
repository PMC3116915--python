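"""REPIN validation: orientation of doublets, hairpin folding, consensus
building, excision footprints, and tandem-array detection.

A REPIN is a REP doublet whose two 16-mer arms occur in inverted-convergent
orientation (left arm in seed orientation on '+', right arm the reverse
complement) at the group's characteristic start-to-start spacing (71 bp for
GI, 110 bp for GII in SBW25), so that the arms can pair into a long hairpin
in single-stranded DNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .expansion import RepOccurrence
from .genome import GenomeRecord, reverse_complement
from .spatial import DEFAULT_MAX_GAP, find_clusters

__all__ = [
    "REPIN",
    "FoldResult",
    "TandemArray",
    "OrientationReport",
    "detect_repins",
    "fold_hairpin",
    "consensus",
    "excision_footprint",
    "ExcisionFootprint",
    "find_tandem_arrays",
]

REP_LEN = 16
DEFAULT_TAIL_KEEP = 6

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = _WC | {("G", "T"), ("T", "G")}


@dataclass
class FoldResult:
    structure: str
    n_pairs: int
    unpaired_5prime_tail: int


def fold_hairpin(seq: str, min_loop: int = 3, allow_gt: bool = False) -> FoldResult:
    """Maximum-base-pair nested secondary structure (Nussinov-style DP).

    Watson-Crick pairs only by default (``allow_gt`` adds G.T wobbles);
    hairpin loops span at least ``min_loop`` unpaired bases; pseudoknots are
    not considered. The traceback is deterministic: when pairing and
    not-pairing score equally, the pairing with the outermost partner is
    taken, which favours long contiguous stems.
    """
    s = seq.upper()
    n = len(s)
    pairs = _WOBBLE if allow_gt else _WC
    can = [[(s[i], s[j]) in pairs for j in range(n)] for i in range(n)]
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j]: max pairs in s[i..j]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if can[k][j]:
                    v = (dp[i][k - 1] if k > i else 0) + 1 + dp[k + 1][j - 1]
                    if v > best:
                        best = v
            dp[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j > i:
            if dp[i][j] == (dp[i][j - 1] if j - 1 >= i else 0):
                # prefer pairing j when it still achieves the optimum
                paired = False
                for k in range(i, j - min_loop):
                    if can[k][j]:
                        v = (dp[i][k - 1] if k > i else 0) + 1 + dp[k + 1][j - 1]
                        if v == dp[i][j]:
                            structure[k], structure[j] = "(", ")"
                            if k > i:
                                traceback(i, k - 1)
                            i, j = k + 1, j - 1
                            paired = True
                            break
                if not paired:
                    j -= 1
                continue
            for k in range(i, j - min_loop):
                if can[k][j]:
                    v = (dp[i][k - 1] if k > i else 0) + 1 + dp[k + 1][j - 1]
                    if v == dp[i][j]:
                        structure[k], structure[j] = "(", ")"
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break

    if n:
        traceback(0, n - 1)
    struct = "".join(structure)
    n_pairs = struct.count("(")
    tail = len(struct) - len(struct.lstrip(".")) if n_pairs else n
    return FoldResult(structure=struct, n_pairs=n_pairs, unpaired_5prime_tail=tail)


@dataclass
class REPIN:
    left_end: RepOccurrence
    right_end: RepOccurrence
    spacing: int
    group: str
    spacer_seq: str = ""
    hairpin: FoldResult | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_end.position, self.right_end.position + REP_LEN)


@dataclass
class OrientationReport:
    n_doublets: int
    n_plus_minus: int  # left arm in seed orientation, right arm reversed
    n_minus_plus: int  # the same inverted geometry with seed roles swapped
    n_tandem: int  # co-oriented arms: a direct repeat, not hairpin-capable
    n_mixed_group: int
    n_spacing_rejected: int

    @property
    def fraction_inverted(self) -> float | None:
        """Fraction of doublets arranged as inverted repeats; None when
        there are no doublets.

        Because combined-strand counting fixes the seed orientation only up
        to reverse complement, (+,-) and (-,+) doublets are the same
        physical geometry — two arms that are reverse complements of each
        other, able to pair into a hairpin. Both count as inverted; only
        co-oriented (tandem) arms do not.
        """
        if self.n_doublets == 0:
            return None
        return (self.n_plus_minus + self.n_minus_plus) / self.n_doublets


def _modal_spacings(doublets) -> dict[str, int]:
    by_group: dict[str, Counter] = {}
    for a, b in doublets:
        by_group.setdefault(a.group, Counter())[b.position - a.position] += 1
    return {g: c.most_common(1)[0][0] for g, c in by_group.items()}


def detect_repins(
    occurrences: list[RepOccurrence],
    spacing_windows: dict[str, tuple[int, int]] | None = None,
    max_gap: int = DEFAULT_MAX_GAP,
    genome: GenomeRecord | str | None = None,
    spacing_tolerance: int = 5,
    fold: bool = False,
) -> tuple[list[REPIN], OrientationReport]:
    """Classify size-2 clusters and emit validated REPINs.

    A doublet becomes a REPIN when both arms belong to one group, the arms
    lie on opposite strands (an inverted repeat, the hairpin geometry), and
    the start-to-start spacing falls within the group's window. Windows
    default to each group's modal doublet spacing plus or minus
    ``spacing_tolerance``.
    """
    clusters, _ = find_clusters(occurrences, max_gap=max_gap)
    doublets = [tuple(c) for c in clusters if len(c) == 2]
    same_group = [(a, b) for a, b in doublets if a.group == b.group]
    if spacing_windows is None:
        spacing_windows = {
            g: (m - spacing_tolerance, m + spacing_tolerance)
            for g, m in _modal_spacings(same_group).items()
        }
    seq = None
    if genome is not None:
        seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
    repins = []
    n_pm = n_mp = n_tan = n_rej = 0
    for a, b in doublets:
        if a.group != b.group:
            continue
        if a.strand == b.strand:
            n_tan += 1
            continue
        if a.strand == "+":
            n_pm += 1
        else:
            n_mp += 1
        spacing = b.position - a.position
        lo, hi = spacing_windows.get(a.group, (spacing, spacing))
        if not (lo <= spacing <= hi):
            n_rej += 1
            continue
        spacer = ""
        if seq is not None:
            spacer = seq[a.position + REP_LEN : b.position]
        r = REPIN(left_end=a, right_end=b, spacing=spacing, group=a.group, spacer_seq=spacer)
        if fold and seq is not None:
            r.hairpin = fold_hairpin(seq[a.position : b.position + REP_LEN])
        repins.append(r)
    report = OrientationReport(
        n_doublets=len(doublets),
        n_plus_minus=n_pm,
        n_minus_plus=n_mp,
        n_tandem=n_tan,
        n_mixed_group=len(doublets) - len(same_group),
        n_spacing_rejected=n_rej,
    )
    return repins, report


_IUPAC_OF = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def consensus(sequences: list[str]) -> tuple[str, list[float]]:
    """Positional majority consensus with per-column identity.

    Sequences must be equal length (REPINs of one group share spacing, so no
    gapped alignment is needed). Ties become IUPAC ambiguity codes; identity
    is the fraction of sequences carrying the majority base.
    """
    if not sequences:
        raise ValueError("empty input")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    cons, ident = [], []
    n = len(sequences)
    for col in range(L):
        counts = Counter(s[col] for s in sequences)
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        cons.append(next(iter(tied)) if len(tied) == 1 else _IUPAC_OF.get(tied, "N"))
        ident.append(top / n)
    return "".join(cons), ident


@dataclass
class ExcisionFootprint:
    """The asymmetric interval removed by a putative REPIN excision.

    Runs from the start of the left 16-mer to ``tail_keep`` bases short of
    the right 16-mer's end, mirroring the observed deletion junctions that
    leave the last ~6 bp of the right arm intact.
    """

    start: int
    end: int
    tail_keep: int
    excised_seq: str = ""
    retained_tail: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def excision_footprint(
    repin: REPIN, genome: GenomeRecord | str | None = None, tail_keep: int = DEFAULT_TAIL_KEEP
) -> ExcisionFootprint:
    start = repin.left_end.position
    end = repin.right_end.position + REP_LEN - tail_keep
    if end <= start:
        raise ValueError("tail_keep too large for this REPIN")
    excised = retained = ""
    if genome is not None:
        seq = genome.sequence if isinstance(genome, GenomeRecord) else genome.upper()
        excised = seq[start:end]
        retained = seq[end : repin.right_end.position + REP_LEN]
    return ExcisionFootprint(
        start=start, end=end, tail_keep=tail_keep, excised_seq=excised, retained_tail=retained
    )


@dataclass
class TandemArray:
    unit_pattern: list[tuple[str, int]]  # (group label, spacing to next)
    n_units: int
    orientation: str
    span: tuple[int, int]
    occurrences: list = field(default_factory=list)


def find_tandem_arrays(
    occurrences: list[RepOccurrence],
    tolerance: int = 2,
    max_gap: int = DEFAULT_MAX_GAP,
    min_units: int = 2,
) -> list[TandemArray]:
    """Find runs of occurrences repeating a (group, spacing) unit.

    Scans each cluster for maximal runs in which group labels repeat with
    period 1 or 2 and the corresponding spacings agree within ``tolerance``
    bp; a run must cover at least ``min_units`` full units.
    """
    clusters, _ = find_clusters(occurrences, max_gap=max_gap)
    arrays: list[TandemArray] = []
    for cluster in clusters:
        occ = sorted(cluster, key=lambda o: o.position)
        m = len(occ)
        if m < 3:
            continue
        gaps = [occ[i + 1].position - occ[i].position for i in range(m - 1)]
        labels = [o.group for o in occ]
        used = [False] * m

        def periodic_end(i: int, period: int) -> int:
            """Last occurrence index of the maximal period-p run from i."""
            e = i
            while e + 1 < m:
                nxt = e + 1
                if nxt - period >= i and labels[nxt] != labels[nxt - period]:
                    break
                # the gap entering nxt must echo the gap one period earlier
                if e - period >= i and abs(gaps[e] - gaps[e - period]) > tolerance:
                    break
                e = nxt
            return e

        for period in (2, 1):
            i = 0
            while i < m:
                if used[i]:
                    i += 1
                    continue
                e = periodic_end(i, period)
                n_occ = e - i + 1
                n_units = n_occ // period
                if n_units >= min_units and n_occ >= 3 and not any(used[i : i + n_occ]):
                    unit = [(labels[i + t], gaps[i + t]) for t in range(period)]
                    strands = Counter(o.strand for o in occ[i : i + n_occ])
                    arrays.append(
                        TandemArray(
                            unit_pattern=unit,
                            n_units=n_units,
                            orientation=strands.most_common(1)[0][0],
                            span=(occ[i].position, occ[i + n_occ - 1].position + REP_LEN),
                            occurrences=occ[i : i + n_occ],
                        )
                    )
                    for t in range(i, i + n_occ):
                        used[t] = True
                    i += n_occ
                else:
                    i += 1
    return arrays
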