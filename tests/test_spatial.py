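from collections import Counter
from itertools import combinations

import numpy as np
import pytest

import repinscan as rs
from repinscan.genome import ExtragenicSpace
from repinscan.spatial import cluster_spectrum, place_segments

TABLE3_OBSERVED = Counter(
    {1: 267, 2: 431, 3: 26, 4: 12, 5: 1, 6: 6, 7: 5, 8: 5, 9: 3, 12: 2}
)


def test_next_neighbor_trivial():
    assert list(rs.next_neighbor_distances([0, 71])) == [71]
    assert list(rs.next_neighbor_distances([5])) == []


def test_next_neighbor_matches_sort_then_diff_oracle():
    rng = np.random.default_rng(2)
    pos = rng.integers(0, 10_000, size=200)
    got = rs.next_neighbor_distances(pos.tolist())
    expect = np.diff(np.sort(pos))
    assert np.array_equal(got, expect)


def test_find_clusters_worked_example():
    # occurrences at 0, 350, 850: gaps 350 (<400) and 500 (>=400)
    clusters, spectrum = rs.find_clusters([0, 350, 850])
    assert [len(c) for c in clusters] == [2, 1]
    assert spectrum == Counter({2: 1, 1: 1})


def test_find_clusters_single():
    clusters, spectrum = rs.find_clusters([42])
    assert spectrum == Counter({1: 1})


def _components_oracle(positions, max_gap=400):
    """O(n^2) connected-components reference: edges between any two
    positions closer than max_gap."""
    pos = sorted(positions)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in combinations(range(n), 2):
        if abs(pos[i] - pos[j]) < max_gap:
            parent[find(i)] = find(j)
    sizes = Counter()
    comp = Counter(find(i) for i in range(n))
    for c in comp.values():
        sizes[c] += 1
    return sizes


def test_find_clusters_equals_components_oracle():
    rng = np.random.default_rng(9)
    for _ in range(60):
        n = int(rng.integers(1, 40))
        pos = sorted(int(p) for p in rng.integers(0, 6000, size=n))
        _, spectrum = rs.find_clusters(pos)
        assert spectrum == _components_oracle(pos)
        assert cluster_spectrum(pos) == spectrum


def test_spectrum_partition_conservation():
    rng = np.random.default_rng(10)
    pos = sorted(int(p) for p in rng.integers(0, 100_000, size=500))
    _, spectrum = rs.find_clusters(pos)
    assert sum(size * c for size, c in spectrum.items()) == len(pos)


def test_count_doublet_units():
    assert rs.count_doublet_units(TABLE3_OBSERVED) == 560
    assert rs.count_doublet_units(Counter({1: 100})) == 0
    assert rs.count_doublet_units(Counter({3: 1, 5: 1, 7: 1})) == 6


def test_doublet_spectrum_fold_down():
    # odd clusters fold into the next lower even size; singlets are dropped
    assert rs.doublet_spectrum(TABLE3_OBSERVED) == Counter(
        {2: 457, 4: 13, 6: 11, 8: 8, 12: 2}
    )


def test_singlet_doublet_ratio():
    assert rs.singlet_doublet_ratio(Counter({1: 267, 2: 431})) == pytest.approx(267 / 431)
    assert rs.singlet_doublet_ratio(Counter({1: 4, 2: 1})) == 4.0
    assert rs.singlet_doublet_ratio(Counter({1: 10, 2: 5})) == 2.0
    assert rs.singlet_doublet_ratio(Counter({1: 3})) is None
    with pytest.raises(ValueError):
        rs.singlet_doublet_ratio(Counter())


def test_place_segments_conservation_and_bounds():
    rng = np.random.default_rng(3)
    intervals = [(0, 500), (700, 900), (1500, 1600)]
    for _ in range(20):
        pos = place_segments(intervals, 12, 16, rng)
        assert len(pos) == 12
        assert all(
            any(s <= p and p + 16 <= e for s, e in intervals) for p in pos
        )
        assert (np.diff(pos) >= 16).all()


def test_place_segments_capacity_error():
    rng = np.random.default_rng(3)
    # 10 x 16 bp cannot fit in 50 bp: fails the capacity pre-check or the
    # bounded-retry rejection loop, depending on how it is requested
    with pytest.raises(ValueError):
        place_segments([(0, 50)], 40, 16, rng)  # more segments than starts
    with pytest.raises(RuntimeError):
        place_segments([(0, 50)], 4, 16, rng, max_tries=50)  # crowded


def test_singlet_null_single_segment():
    space = ExtragenicSpace(intervals=[(0, 1000)], source_genome="g")
    null = rs.simulate_singlet_null(space, n_segments=1, n_reps=50, seed=1)
    nd = null.by_size[1]
    assert nd.expected_mean == 1.0
    assert nd.expected_sd == 0.0


def test_singlet_null_saturated_space():
    """A space of exactly n x seg_len forces adjacent placement: one cluster."""
    space = ExtragenicSpace(intervals=[(0, 48)], source_genome="g")
    null = rs.simulate_singlet_null(space, n_segments=3, seg_len=16, n_reps=5, seed=1)
    assert null.by_size[3].expected_mean == 3 / 3  # one size-3 cluster per rep


def test_doublet_null_even_sizes_and_tails():
    space = ExtragenicSpace(intervals=[(0, 30_000)], source_genome="g")
    obs = Counter({2: 8, 4: 1})
    null = rs.simulate_doublet_null(
        space, n_segments=10, seg_len=71, n_reps=100, seed=2, observed_spectrum=obs
    )
    assert all(size % 2 == 0 for size in null.by_size)
    nd = null.by_size[2]
    assert nd.observed == 8
    assert nd.p_le is not None and nd.p_ge is not None
    assert nd.p_le + nd.p_ge >= 1.0  # both tails include equality


def test_doublet_null_vs_exhaustive_two_segments():
    """Two 71 bp doublet segments in one small interval: the chance they
    cluster (start gap < 400) from exhaustive enumeration of placements
    matches the simulated spectrum within 3 SE."""
    lo, hi = 0, 700
    seg, gap = 71, 400
    valid = hi - lo - seg + 1  # 630 possible starts per segment
    pairs = together = 0
    for a in range(valid):
        for b in range(valid):
            if abs(b - a) < seg:
                continue  # overlapping placements rejected
            pairs += 1
            lo_s, hi_s = min(a, b), max(a, b)
            # the two doublet segments merge when the REP-position gap
            # (second REP of the left segment to first REP of the right,
            # i.e. start diff minus (seg_len - 16)) is under max_gap
            if hi_s - lo_s - (seg - 16) < gap:
                together += 1
    p_join = together / pairs
    space = ExtragenicSpace(intervals=[(lo, hi)], source_genome="g")
    n_reps = 400
    null = rs.simulate_doublet_null(
        space, n_segments=2, seg_len=seg, n_reps=n_reps, seed=5, max_gap=gap
    )
    mean4 = null.by_size.get(4)
    observed_p = mean4.expected_mean if mean4 else 0.0
    se = np.sqrt(p_join * (1 - p_join) / n_reps)
    assert abs(observed_p - p_join) < 3 * se + 1e-9


def test_null_table_output():
    space = ExtragenicSpace(intervals=[(0, 5000)], source_genome="g")
    null = rs.simulate_singlet_null(space, n_segments=5, n_reps=20, seed=1)
    df = null.table()
    assert {"cluster_size", "expected_mean", "expected_sd"} <= set(df.columns)
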