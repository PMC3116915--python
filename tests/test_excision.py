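import numpy as np
import pytest

import repinscan as rs
from repinscan.excision import GI_PALINDROME_SEED
from repinscan.genome import reverse_complement
from repinscan.repin import REP_LEN


def _detected_repins(small_occurrences):
    genome, truth, occ = small_occurrences
    repins, _ = rs.detect_repins(occ, genome=genome)
    return genome, truth, repins


def test_build_flank_index_planted(small_occurrences):
    genome, truth, repins = _detected_repins(small_occurrences)
    pairs = rs.build_flank_index(repins, genome)
    assert len(pairs) == len(repins)
    for r, p in zip(repins, pairs):
        s, e = p.locus
        assert genome.sequence[s - 12 : s] == p.left_flank
        assert genome.sequence[e : e + 12] == p.right_flank
        assert s == r.left_end.position
        assert e == r.right_end.position + REP_LEN - 6


def test_flank_len_zero_refused(small_occurrences):
    genome, _, repins = _detected_repins(small_occurrences)
    with pytest.raises(ValueError):
        rs.build_flank_index(repins, genome, flank_len=0)


def test_screen_reads_constructed():
    pad = "CATCATCATCAT"
    pair = rs.FlankPair("repin_0", "ACGTACGTACGT", "TTTTGGGGCCCC", (0, 0))
    read_hit = ("r1", pad + pair.left_flank + pair.right_flank + pad)
    read_left_only = ("r2", pad + pair.left_flank + "ACGTACCGTTGG" + pad)
    events = rs.screen_reads([read_hit, read_left_only], [pair], max_gap=10)
    assert len(events) == 1
    ev = events[0]
    assert ev.read_id == "r1"
    assert ev.gap == 0
    assert ev.junction_offset == len(pad) + 12


def test_screen_reads_reverse_orientation_and_gap():
    pad = "CATCATCATCAT"
    pair = rs.FlankPair("repin_0", "ACGTACGTACGT", "TTTTGGGGCCCC", (0, 0))
    junction = pair.left_flank + "CACA" + pair.right_flank
    read_rc = ("r1", reverse_complement(pad + junction + pad))
    events = rs.screen_reads([read_rc], [pair], max_gap=10)
    assert len(events) == 1
    assert events[0].strand == "-"
    assert events[0].gap == 4
    assert rs.screen_reads([read_rc], [pair], max_gap=2) == []


def test_short_reads_filtered():
    pair = rs.FlankPair("repin_0", "ACGTACGTACGT", "TTTTGGGGCCCC", (0, 0))
    short = ("r1", pair.left_flank + pair.right_flank)  # 24 bp < 36
    assert rs.screen_reads([short], [pair], min_read_len=36) == []


def test_excision_screen_end_to_end(small_occurrences):
    """One fully excised REPIN at 50x on the simulated genome: every
    junction-spanning read is detected and nothing else fires."""
    genome, truth, repins = _detected_repins(small_occurrences)
    pairs = rs.build_flank_index(repins, genome)
    spec = rs.ExcisionSpec(repin_indices=[0], fraction=1.0)
    reads, rtruth = rs.simulate_reads(
        genome, truth, rs.ReadSpec(coverage=50.0), seed=21, excision=spec
    )
    events = rs.screen_reads(reads, pairs)
    assert len(rtruth.junction_reads) >= 1
    got = {e.read_id for e in events}
    # recall: every junction-spanning read found
    assert set(rtruth.junction_reads) <= got
    # precision: nothing outside the truth set
    assert got <= set(rtruth.junction_reads)
    # event identity points at the excised REPIN locus
    planted = truth.repins[0]
    for e in events:
        idx = int(e.repin_id.split("_")[1])
        assert repins[idx].left_end.position == pytest.approx(planted.left_pos, abs=0)


def test_negative_control_no_events(small_occurrences):
    genome, truth, repins = _detected_repins(small_occurrences)
    pairs = rs.build_flank_index(repins, genome)
    reads, _ = rs.simulate_reads(genome, truth, rs.ReadSpec(n_reads=4000), seed=5)
    assert rs.screen_reads(reads, pairs) == []


def test_junction_reconstruction_byte_exact(small_occurrences):
    """The junction implied by an event equals the genomic sequence with
    the footprint removed."""
    genome, truth, repins = _detected_repins(small_occurrences)
    pairs = rs.build_flank_index(repins, genome)
    spec = rs.ExcisionSpec(repin_indices=[2], fraction=1.0)
    reads, rtruth = rs.simulate_reads(
        genome, truth, rs.ReadSpec(coverage=60.0), seed=33, excision=spec
    )
    events = rs.screen_reads(reads, pairs)
    assert events
    by_id = {p.repin_id: p for p in pairs}
    read_seq = dict(reads)
    for ev in events[:5]:
        p = by_id[ev.repin_id]
        s, e = p.locus
        expected_junction = genome.sequence[s - 12 : s] + genome.sequence[e : e + 12]
        seq = read_seq[ev.read_id]
        if ev.strand == "-":
            seq = reverse_complement(seq)
        window = seq[ev.junction_offset - 12 : ev.junction_offset + 12]
        assert window == expected_junction


def test_singlet_seed_set_genome_is_seed():
    got = rs.build_singlet_seed_set(GI_PALINDROME_SEED, max_mismatch=5)
    assert len(got.matched_positions) == 1
    assert got.matched_positions[0][0] == 0


def test_singlet_seed_set_matches_brute_force():
    rng = np.random.default_rng(17)
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    seq = seq[:700] + GI_PALINDROME_SEED + seq[700:]
    got = rs.build_singlet_seed_set(seq, max_mismatch=3)
    k = len(GI_PALINDROME_SEED)
    rc = reverse_complement(GI_PALINDROME_SEED)
    expect = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        df = sum(a != b for a, b in zip(w, GI_PALINDROME_SEED))
        dr = sum(a != b for a, b in zip(w, rc))
        if min(df, dr) <= 3:
            expect.append(i)
    assert [p for p, _ in got.matched_positions] == expect


def test_singlet_seed_zero_mismatch_random_genome_empty():
    rng = np.random.default_rng(23)
    seq = "".join(rng.choice(list("ACGT"), size=100_000))
    got = rs.build_singlet_seed_set(seq, max_mismatch=0)
    assert len(got.matched_positions) == 0  # expectation 2(L-17)/4^18 ~ 1e-6


def test_screen_singlet_excisions_planted():
    """A read spanning a planted singlet excision with 2 bp slack is found;
    slack=0 misses the inexact excision."""
    rng = np.random.default_rng(29)
    bg = "".join(rng.choice(list("ACGT"), size=4000))
    pos = 2000
    seq = bg[:pos] + GI_PALINDROME_SEED + bg[pos:]
    seed_set = rs.build_singlet_seed_set(seq, max_mismatch=0)
    assert [p for p, _ in seed_set.matched_positions] == [pos]
    # excise the palindrome plus 2 extra bp each side
    a = b = 2
    left = seq[pos - a - 20 : pos - a]
    right = seq[pos + 18 + b : pos + 18 + b + 20]
    read = ("r1", left[-20:] + right[:20])
    events = rs.screen_singlet_excisions([read], seq, seed_set, slack=3)
    assert len(events) >= 1
    assert all(ev.read_id == "r1" for ev in events)
    assert rs.screen_singlet_excisions([read], seq, seed_set, slack=0) == []
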