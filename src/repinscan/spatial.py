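"""Spatial statistics: neighbour distances, cluster chaining, and
random-placement null models over extragenic space.

A cluster is a maximal left-to-right chain of occurrences in which each
consecutive start-to-start gap is below ``max_gap`` (default 400 bp). The
null models place non-overlapping segments uniformly at random wholly
within extragenic intervals and recompute the cluster-size spectrum per
replicate, yielding empirical means, SDs, and tail proportions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome import ExtragenicSpace

__all__ = [
    "NullDistribution",
    "PlacementNull",
    "next_neighbor_distances",
    "find_clusters",
    "cluster_spectrum",
    "simulate_singlet_null",
    "simulate_doublet_null",
    "count_doublet_units",
    "doublet_spectrum",
    "singlet_doublet_ratio",
    "place_segments",
]

DEFAULT_MAX_GAP = 400


def _positions(occurrences) -> np.ndarray:
    if len(occurrences) and hasattr(occurrences[0], "position"):
        pos = np.array([o.position for o in occurrences], dtype=np.int64)
    else:
        pos = np.asarray(occurrences, dtype=np.int64)
    return pos


def next_neighbor_distances(occurrences) -> np.ndarray:
    """Successive start-to-start differences of position-sorted occurrences."""
    pos = np.sort(_positions(occurrences))
    if len(pos) < 2:
        return np.zeros(0, dtype=np.int64)
    return np.diff(pos)


def find_clusters(occurrences, max_gap: int = DEFAULT_MAX_GAP):
    """Chain occurrences left to right while the start-to-start gap is
    strictly below ``max_gap``.

    Returns ``(clusters, spectrum)`` where clusters is a list of lists of the
    input occurrences and spectrum maps cluster size -> number of clusters.
    """
    occ = sorted(occurrences, key=lambda o: o.position if hasattr(o, "position") else o)
    clusters: list[list] = []
    cur: list = []
    prev = None
    for o in occ:
        p = o.position if hasattr(o, "position") else o
        if prev is not None and p - prev < max_gap:
            cur.append(o)
        else:
            if cur:
                clusters.append(cur)
            cur = [o]
        prev = p
    if cur:
        clusters.append(cur)
    spectrum = Counter(len(c) for c in clusters)
    return clusters, spectrum


def cluster_spectrum(positions, max_gap: int = DEFAULT_MAX_GAP) -> Counter:
    """Cluster-size spectrum of an array of positions (vectorized)."""
    pos = np.sort(_positions(positions))
    if len(pos) == 0:
        return Counter()
    breaks = np.diff(pos) >= max_gap
    # cluster sizes are run lengths between breaks
    idx = np.flatnonzero(breaks)
    sizes = np.diff(np.concatenate(([0], idx + 1, [len(pos)])))
    return Counter(int(s) for s in sizes)


@dataclass
class NullDistribution:
    statistic: str
    observed: float | None
    expected_mean: float
    expected_sd: float
    p_le: float | None
    p_ge: float | None
    n_reps: int


@dataclass
class PlacementNull:
    """Null-model summary per cluster size, plus the per-replicate spectra."""

    by_size: dict[int, NullDistribution]
    n_reps: int
    n_segments: int
    seg_len: int
    distance_histogram: Counter | None = None

    def table(self):
        import pandas as pd

        rows = []
        for size in sorted(self.by_size):
            nd = self.by_size[size]
            rows.append(
                {
                    "cluster_size": size,
                    "observed": nd.observed,
                    "expected_mean": nd.expected_mean,
                    "expected_sd": nd.expected_sd,
                    "p_le": nd.p_le,
                    "p_ge": nd.p_ge,
                }
            )
        return pd.DataFrame(rows)


def place_segments(
    intervals: list[tuple[int, int]],
    n: int,
    seg_len: int,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Uniformly place n non-overlapping segments wholly inside intervals.

    Returns sorted genome start coordinates. Placement is rejection
    sampling: colliding segments are redrawn, up to ``max_tries`` rounds.
    """
    lens = np.array([e - s for s, e in intervals], dtype=np.int64)
    starts = np.array([s for s, _ in intervals], dtype=np.int64)
    valid = np.maximum(0, lens - seg_len + 1)
    cum = np.concatenate(([0], np.cumsum(valid)))
    total = int(cum[-1])
    if total < n:
        raise ValueError("extragenic space too small for requested segments")

    def draw(m: int) -> np.ndarray:
        u = rng.integers(0, total, size=m)
        iv = np.searchsorted(cum, u, side="right") - 1
        return starts[iv] + (u - cum[iv])

    pos = np.sort(draw(n))
    for _ in range(max_tries):
        bad = np.flatnonzero(np.diff(pos) < seg_len)
        if len(bad) == 0:
            return pos
        keep = np.ones(len(pos), dtype=bool)
        keep[bad + 1] = False  # redraw the right-hand member of each collision
        pos = np.sort(np.concatenate([pos[keep], draw(int((~keep).sum()))]))
    raise RuntimeError("placement failed: space too crowded")


def _null_from_spectra(
    spectra: list[Counter],
    observed: Counter | None,
    n_reps: int,
    n_segments: int,
    seg_len: int,
    distance_histogram: Counter | None = None,
) -> PlacementNull:
    sizes = set()
    for sp in spectra:
        sizes |= set(sp)
    if observed:
        sizes |= set(observed)
    by_size = {}
    for size in sorted(sizes):
        vals = np.array([sp.get(size, 0) for sp in spectra], dtype=float)
        obs = observed.get(size, 0) if observed is not None else None
        p_le = p_ge = None
        if obs is not None:
            p_le = float(np.mean(obs <= vals))
            p_ge = float(np.mean(obs >= vals))
        by_size[size] = NullDistribution(
            statistic=f"clusters_of_size_{size}",
            observed=obs,
            expected_mean=float(vals.mean()),
            expected_sd=float(vals.std(ddof=1)) if n_reps > 1 else 0.0,
            p_le=p_le,
            p_ge=p_ge,
            n_reps=n_reps,
        )
    return PlacementNull(
        by_size=by_size,
        n_reps=n_reps,
        n_segments=n_segments,
        seg_len=seg_len,
        distance_histogram=distance_histogram,
    )


def simulate_singlet_null(
    space: ExtragenicSpace,
    n_segments: int = 1053,
    seg_len: int = 16,
    n_reps: int = 10_000,
    seed: int = 1,
    max_gap: int = DEFAULT_MAX_GAP,
    observed_spectrum: Counter | None = None,
    collect_distances: bool = False,
) -> PlacementNull:
    """Random placement of short segments: the singlet/cluster null model."""
    rng = np.random.default_rng(seed)
    spectra = []
    dist_hist: Counter | None = Counter() if collect_distances else None
    for _ in range(n_reps):
        pos = place_segments(space.intervals, n_segments, seg_len, rng)
        spectra.append(cluster_spectrum(pos, max_gap))
        if dist_hist is not None:
            dist_hist.update(int(d) for d in np.diff(pos))
    return _null_from_spectra(
        spectra, observed_spectrum, n_reps, n_segments, seg_len, dist_hist
    )


def simulate_doublet_null(
    space: ExtragenicSpace,
    n_segments: int = 560,
    seg_len: int = 71,
    n_reps: int = 10_000,
    seed: int = 1,
    max_gap: int = DEFAULT_MAX_GAP,
    observed_spectrum: Counter | None = None,
    rep_len: int = 16,
) -> PlacementNull:
    """Random placement of doublet-sized segments.

    Each placed segment stands for a REP doublet and contributes two REP
    positions (its start and ``seg_len - rep_len`` downstream); the spectrum
    is reported in REP units, i.e. cluster sizes 2, 4, 6, ...
    """
    rng = np.random.default_rng(seed)
    offset = seg_len - rep_len
    spectra = []
    for _ in range(n_reps):
        pos = place_segments(space.intervals, n_segments, seg_len, rng)
        reps = np.sort(np.concatenate([pos, pos + offset]))
        spectra.append(cluster_spectrum(reps, max_gap))
    return _null_from_spectra(spectra, observed_spectrum, n_reps, n_segments, seg_len)


def doublet_spectrum(rep_spectrum: Counter) -> Counter:
    """Fold a REP cluster-size spectrum into doublet units.

    Singlets are omitted; a cluster with an odd number of REPs counts
    toward the next lower (even) cluster size.
    """
    out: Counter = Counter()
    for size, count in rep_spectrum.items():
        if size >= 2:
            out[2 * (size // 2)] += count
    return out


def count_doublet_units(spectrum: Counter) -> int:
    """Total doublet units: sum of floor(size/2) over clusters of size >= 2."""
    return sum((size // 2) * count for size, count in spectrum.items() if size >= 2)


def singlet_doublet_ratio(spectrum: Counter) -> float | None:
    """REP occurrences in singleton clusters per size-2 cluster.

    Ratios above two indicate REPs occur predominantly as singlets. Returns
    None when there are no doublets.
    """
    if not spectrum:
        raise ValueError("empty spectrum")
    doublets = spectrum.get(2, 0)
    if doublets == 0:
        return None
    return spectrum.get(1, 0) / doublets
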