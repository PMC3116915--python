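import numpy as np
import pytest

import repinscan as rs
from repinscan.expansion import RepOccurrence
from repinscan.genome import reverse_complement
from repinscan.repin import REP_LEN, excision_footprint
from repinscan.simulate import GI_SEED

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def brute_force_max_pairs(s, min_loop=3):
    """Exhaustive recursion over all nested structures (independent of the
    DP): base i is unpaired, or pairs with some k > i + min_loop."""

    def rec(i, j):
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in WC:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1) if s else 0


def test_fold_trivials():
    r = rs.fold_hairpin("AAAAAA")
    assert r.n_pairs == 0
    assert r.structure == "......"
    r = rs.fold_hairpin("GGGAAAACCC")
    assert r.n_pairs == 3
    assert r.structure == "(((....)))"


def test_fold_structure_well_formed():
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
        r = rs.fold_hairpin(s)
        assert len(r.structure) == len(s)
        # balanced and nested
        depth = 0
        for c in r.structure:
            depth += 1 if c == "(" else -1 if c == ")" else 0
            assert depth >= 0
        assert depth == 0
        assert r.structure.count("(") == r.n_pairs
        # paired partners are WC and min-loop respected
        stack = []
        for i, c in enumerate(r.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                assert (s[j], s[i]) in WC
                assert i - j > 3


def test_fold_matches_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    cases = ["GCGCAAAGCGC", "ATATATATATAT", "GGGGAAAACCCC"]
    cases += [
        "".join(rng.choice(list("ACGT"), size=int(n)))
        for n in rng.integers(4, 13, size=25)
    ]
    for s in cases:
        assert rs.fold_hairpin(s).n_pairs == brute_force_max_pairs(s)


def test_fold_consensus_repin_hairpin():
    """A planted GI-geometry REPIN folds with the left arm pairing the
    right arm: at least 16 pairs and a long stem."""
    spacer = "GCCGGC" + "AAAA" + "GCCGGC"  # partly self-complementary
    seq = GI_SEED + spacer + reverse_complement(GI_SEED)
    r = rs.fold_hairpin(seq)
    assert r.n_pairs >= 16


def _occ(pos, strand, group="GI", kmer=GI_SEED):
    return RepOccurrence(
        position=pos, strand=strand, matched_kmer=kmer, group=group,
        distance_to_seed=0, extragenic=True,
    )


def test_detect_repins_constructed_positive_and_negative():
    # inverted pair at spacing 71 -> REPIN; co-oriented pair -> not
    occ = [_occ(1000, "+"), _occ(1071, "-"), _occ(5000, "+"), _occ(5071, "+")]
    repins, report = rs.detect_repins(occ, spacing_windows={"GI": (66, 76)})
    assert len(repins) == 1
    assert repins[0].spacing == 71
    assert report.n_doublets == 2
    assert report.n_plus_minus == 1
    assert report.n_tandem == 1
    assert report.fraction_inverted == 0.5


def test_detect_repins_spacing_window():
    occ = [_occ(1000, "+"), _occ(1090, "-")]  # spacing 90: outside 71 +/- 5
    repins, report = rs.detect_repins(occ, spacing_windows={"GI": (66, 76)})
    assert repins == []
    assert report.n_spacing_rejected == 1


def test_detect_repins_mixed_group_excluded():
    occ = [_occ(1000, "+", "GI"), _occ(1071, "-", "GII")]
    repins, report = rs.detect_repins(occ, spacing_windows={"GI": (66, 76)})
    assert repins == []
    assert report.n_mixed_group == 1


def test_detect_repins_on_simulated_truth(small_occurrences):
    genome, truth, occ = small_occurrences
    repins, report = rs.detect_repins(occ, genome=genome)
    ev = rs.evaluate(
        [r.left_end.position for r in repins], [p.left_pos for p in truth.repins]
    )
    assert ev.precision == 1.0
    assert ev.recall >= 0.9
    assert report.fraction_inverted == 1.0
    for r in repins[:10]:
        assert len(r.spacer_seq) == r.spacing - REP_LEN


def test_consensus():
    c, ident = rs.consensus(["ACGT", "ACGT", "ACGT"])
    assert c == "ACGT"
    assert ident == [1.0, 1.0, 1.0, 1.0]
    c, ident = rs.consensus(["AAAA", "AAAA", "CAAA"])
    assert c[0] == "A"
    assert ident[0] == pytest.approx(2 / 3)
    c, _ = rs.consensus(["AT", "CT"])
    assert c[0] == "M"  # A/C tie -> IUPAC
    with pytest.raises(ValueError):
        rs.consensus([])


def test_consensus_identity_tracks_mutation_rate():
    rng = np.random.default_rng(6)
    mu = 0.1
    base = GI_SEED * 3
    seqs = []
    for _ in range(200):
        s = list(base)
        for i in np.flatnonzero(rng.random(len(s)) < mu):
            s[i] = "ACGT"[(("ACGT".index(s[i])) + int(rng.integers(1, 4))) % 4]
        seqs.append("".join(s))
    _, ident = rs.consensus(seqs)
    assert abs(float(np.mean(ident)) - (1 - mu)) < 0.02


def test_excision_footprint_geometry():
    occ_l, occ_r = _occ(1000, "+"), _occ(1071, "-")
    (repin,), _ = rs.detect_repins([occ_l, occ_r], spacing_windows={"GI": (66, 76)})
    fp = excision_footprint(repin, tail_keep=6)
    assert fp.length == 71 + 16 - 6 == 81
    fp0 = excision_footprint(repin, tail_keep=0)
    assert fp0.length == 87
    assert (fp0.start, fp0.end) == (1000, 1087)


def test_excision_footprint_conservation(small_occurrences):
    """Excised piece plus retained tail reconstitutes the locus byte-exactly."""
    genome, _, occ = small_occurrences
    repins, _ = rs.detect_repins(occ, genome=genome)
    r = repins[0]
    fp = excision_footprint(r, genome=genome)
    locus = genome.sequence[r.left_end.position : r.right_end.position + REP_LEN]
    assert fp.excised_seq + fp.retained_tail == locus
    assert len(fp.retained_tail) == 6


def test_tandem_array_planted():
    # [GI -112- GIII -72-] x 3: six occurrences, alternating groups
    pos, labels = [], []
    p = 10_000
    for _ in range(3):
        pos += [p, p + 112]
        labels += ["GI", "GIII"]
        p += 184
    occ = [_occ(pp, "+", g) for pp, g in zip(pos, labels)]
    arrays = rs.find_tandem_arrays(occ, tolerance=2)
    assert len(arrays) == 1
    arr = arrays[0]
    assert arr.n_units == 3
    assert len(arr.occurrences) == 6
    assert arr.unit_pattern == [("GI", 112), ("GIII", 72)]
    assert arr.orientation == "+"


def test_tandem_array_single_unit_rejected():
    occ = [_occ(1000, "+", "GI"), _occ(1112, "+", "GIII")]
    assert rs.find_tandem_arrays(occ, tolerance=2) == []


def test_tandem_array_random_positions_none():
    rng = np.random.default_rng(13)
    for trial in range(10):
        pos = np.sort(rng.choice(20_000, size=12, replace=False))
        occ = [
            _occ(int(p), "+", "GI" if i % 2 == 0 else "GIII")
            for i, p in enumerate(pos)
        ]
        assert rs.find_tandem_arrays(occ, tolerance=2) == []
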