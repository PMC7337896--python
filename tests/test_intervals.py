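"""Interval algebra against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from erbscluster.intervals import (
    GenomicInterval,
    IntervalSet,
    merge_with_gap,
    nearest_neighbor_distances,
    overlaps_any,
    sort_intervals,
    subsample,
    window_around,
)
from conftest import random_interval_set


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def merge_oracle(intervals, gap):
    """Union-find transitive closure of the pairwise gap <= d relation."""
    ivs = list(intervals)
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            g = ivs[i].gap_to(ivs[j])
            if g is not None and g <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    spans = sorted(
        (g[0].chrom, min(x.start for x in g), max(x.end for x in g))
        for g in groups.values()
    )
    return spans


def nnd_oracle(intervals, mode="edge"):
    ivs = list(intervals)
    out = []
    for i, a in enumerate(ivs):
        best = None
        for j, b in enumerate(ivs):
            if i == j or a.chrom != b.chrom:
                continue
            d = abs(a.midpoint - b.midpoint) if mode == "midpoint" else a.gap_to(b)
            best = d if best is None else min(best, d)
        out.append(None if best is None else int(best))
    return out


# ---------------------------------------------------------------------------
# GenomicInterval / sorting
# ---------------------------------------------------------------------------


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 20, 10)


def test_sort_two_elements_and_idempotence():
    s = IntervalSet([GenomicInterval("chr1", 10, 20), GenomicInterval("chr1", 0, 5)])
    srt = sort_intervals(s)
    assert [(iv.start, iv.end) for iv in srt] == [(0, 5), (10, 20)]
    assert srt.is_sorted
    assert sort_intervals(srt).intervals == srt.intervals


def test_sort_matches_naive_sort(rng):
    s = random_interval_set(rng, 50)
    expected = sorted(s.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    assert sort_intervals(s).intervals == expected


# ---------------------------------------------------------------------------
# merge_with_gap
# ---------------------------------------------------------------------------


def test_merge_simple_cases():
    s = IntervalSet([GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 5300, 5600)])
    merged = merge_with_gap(s, 10_000)
    assert [(iv.start, iv.end) for iv in merged] == [(0, 5600)]

    s2 = IntervalSet([GenomicInterval("chr1", 0, 300), GenomicInterval("chr1", 15_000, 15_300)])
    merged2 = merge_with_gap(s2, 10_000)
    assert [(iv.start, iv.end) for iv in merged2] == [(0, 300), (15_000, 15_300)]


def test_merge_gap_boundary_inclusive():
    # gap of exactly d merges; book-ended intervals merge at d=0
    s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
    assert len(merge_with_gap(s, 100)) == 1
    assert len(merge_with_gap(s, 99)) == 2
    b = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)])
    assert len(merge_with_gap(b, 0)) == 1


@pytest.mark.parametrize("gap", [0, 1000, 10_000])
def test_merge_matches_union_find_oracle(rng, gap):
    for _ in range(8):
        s = random_interval_set(rng, 200, n_chroms=3, span=100_000)
        got = [(iv.chrom, iv.start, iv.end) for iv in merge_with_gap(s, gap)]
        assert sorted(got) == merge_oracle(s, gap)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(
    hst.lists(
        hst.tuples(hst.integers(0, 5000), hst.integers(1, 300), hst.integers(0, 1)),
        min_size=1,
        max_size=40,
    ),
    hst.integers(0, 2000),
)
def test_merge_idempotent_and_monotone(raw, gap):
    s = IntervalSet([GenomicInterval(f"chr{c + 1}", a, a + w) for a, w, c in raw])
    merged = merge_with_gap(s, gap)
    # idempotence
    assert merge_with_gap(merged, gap).intervals == merged.intervals
    # monotone: larger gap, no more clusters
    assert len(merge_with_gap(s, gap + 500)) <= len(merged)
    # every input bp is covered by exactly one output interval
    for iv in s:
        covering = [m for m in merged if m.overlaps(iv)]
        assert len(covering) == 1
        assert covering[0].start <= iv.start and covering[0].end >= iv.end


# ---------------------------------------------------------------------------
# nearest_neighbor_distances
# ---------------------------------------------------------------------------


def test_nnd_symmetric_pair_and_overlap():
    s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 600, 700)])
    assert nearest_neighbor_distances(s).per_interval == [500, 500]
    s2 = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 200)])
    assert nearest_neighbor_distances(s2).per_interval == [0, 0]


def test_nnd_omits_chromosome_singletons():
    s = IntervalSet(
        [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 300, 400),
            GenomicInterval("chr2", 0, 100),
        ]
    )
    res = nearest_neighbor_distances(s)
    assert res.per_interval == [200, 200, None]
    assert res.n_omitted == 1
    assert res.values == [200, 200]


def test_nnd_empty_set_errors():
    with pytest.raises(ValueError):
        nearest_neighbor_distances(IntervalSet([]))


@pytest.mark.parametrize("mode", ["edge", "midpoint"])
def test_nnd_matches_all_pairs_oracle(rng, mode):
    for _ in range(10):
        s = random_interval_set(rng, 100, n_chroms=3, span=50_000)
        got = nearest_neighbor_distances(s, mode=mode).per_interval
        assert got == nnd_oracle(s, mode)


# ---------------------------------------------------------------------------
# overlaps_any
# ---------------------------------------------------------------------------


def test_overlap_half_open_semantics():
    s = IntervalSet([GenomicInterval("chr1", 19, 30)])
    assert overlaps_any(GenomicInterval("chr1", 10, 20), s)
    s2 = IntervalSet([GenomicInterval("chr1", 20, 30)])
    assert not overlaps_any(GenomicInterval("chr1", 10, 20), s2)
    assert not overlaps_any(GenomicInterval("chr2", 19, 30), s)


def test_overlaps_any_matches_exhaustive_scan(rng):
    s = random_interval_set(rng, 100, span=20_000)
    queries = random_interval_set(rng, 100, span=20_000)
    for q in queries:
        assert overlaps_any(q, s) == any(q.overlaps(m) for m in s)


# ---------------------------------------------------------------------------
# subsample
# ---------------------------------------------------------------------------


def test_subsample_full_and_deterministic(rng):
    s = random_interval_set(rng, 10)
    full = subsample(s, 10, seed=1)
    assert sorted(iv.key() for iv in full) == sorted(iv.key() for iv in s)
    assert subsample(s, 3, seed=5).intervals == subsample(s, 3, seed=5).intervals
    with pytest.raises(ValueError):
        subsample(s, 11, seed=0)


def test_subsample_inclusion_frequency(rng):
    # each of 10 members should be included in ~half of size-5 samples
    s = random_interval_set(rng, 10)
    keys = [iv.key() for iv in s]
    counts = dict.fromkeys(keys, 0)
    n_rep = 10_000
    for seed in range(n_rep):
        for iv in subsample(s, 5, seed=seed):
            counts[iv.key()] += 1
    se = np.sqrt(0.5 * 0.5 / n_rep)
    # 4 SE: ten simultaneous binomial checks need a multiplicity allowance
    for k in keys:
        assert abs(counts[k] / n_rep - 0.5) < 4 * se


# ---------------------------------------------------------------------------
# window_around
# ---------------------------------------------------------------------------


def test_window_around_basic_and_clipped():
    w = window_around("chr1", 500_000, 100_000)
    assert (w.start, w.end) == (400_000, 600_000)
    wc = window_around("chr1", 50_000, 100_000)
    assert (wc.start, wc.end) == (0, 150_000)
    wr = window_around("chr1", 90, 100, chrom_length=120)
    assert (wr.start, wr.end) == (0, 120)
    with pytest.raises(ValueError):
        window_around("chr1", 100, 0)


@settings(derandomize=True, deadline=None, max_examples=100)
@given(hst.integers(0, 10**7), hst.integers(1, 10**6))
def test_window_length_property(pos, radius):
    w = window_around("chr1", pos, radius)
    if pos >= radius:
        assert w.length == 2 * radius
    else:
        assert w.length == pos + radius
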