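"""ERE scanning against naive per-window oracles and palindrome properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from erbscluster.intervals import GenomicInterval, IntervalSet
from erbscluster.io import DictGenome
from erbscluster.motifs import (
    EreModel,
    annotate_erbs,
    reverse_complement,
    scan_full_ere,
    scan_half_ere,
)

CONSENSUS = "AGGTCAGGGTGACCT"  # a concrete full ERE (spacer GGG)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def naive_full_scan(seq, model):
    """Count mismatches window by window, position by position."""
    cons = model.full_consensus.upper()
    constrained = set(model.constrained_positions)
    hits = []
    for off in range(len(seq) - len(cons) + 1):
        mm = sum(
            1
            for k in constrained
            if seq[off + k] != cons[k]
        )
        if mm <= model.max_mismatch:
            hits.append((off, mm))
    return hits


def naive_half_scan(seq, model):
    half = model.half_consensus.upper()
    rc = reverse_complement(half)
    hits = []
    for off in range(len(seq) - len(half) + 1):
        win = seq[off : off + len(half)]
        if win == half:
            hits.append((off, "+"))
        if win == rc:
            hits.append((off, "-"))
    full = naive_full_scan(seq, model)
    out = []
    for off, strand in hits:
        if any(off < f + model.width and f < off + len(half) for f, _ in full):
            continue
        out.append((off, strand))
    return sorted(out)


# ---------------------------------------------------------------------------
# reverse complement
# ---------------------------------------------------------------------------


def test_reverse_complement_basics():
    assert reverse_complement("AGGTCA") == "TGACCT"
    assert reverse_complement("N") == "N"
    with pytest.raises(ValueError):
        reverse_complement("AXGT")


@settings(derandomize=True, deadline=None, max_examples=50)
@given(hst.text(alphabet="ACGTN", min_size=0, max_size=60))
def test_reverse_complement_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


# ---------------------------------------------------------------------------
# full-ERE scan
# ---------------------------------------------------------------------------


def test_exact_consensus_hit():
    hits = scan_full_ere(CONSENSUS, EreModel(max_mismatch=0))
    assert [(h.offset, h.strand, h.mismatches) for h in hits] == [(0, "+", 0)]


def test_mismatch_counting_and_cutoff():
    two_mm = "C" + CONSENSUS[1:-1] + "A"  # first and last constrained positions altered
    hits = scan_full_ere(two_mm, EreModel(max_mismatch=2))
    assert [(h.offset, h.mismatches) for h in hits] == [(0, 2)]
    three_mm = "C" + CONSENSUS[1:4] + "A" + CONSENSUS[5:-1] + "A"
    assert scan_full_ere(three_mm, EreModel(max_mismatch=2)) == []


def test_spacer_never_counts_as_mismatch():
    for spacer in ("AAA", "TTT", "CGC"):
        seq = "AGGTCA" + spacer + "TGACCT"
        hits = scan_full_ere(seq, EreModel(max_mismatch=0))
        assert [(h.offset, h.mismatches) for h in hits] == [(0, 0)]


def test_n_counts_as_mismatch_at_constrained_positions():
    seq = "NGGTCAGGGTGACCT"
    hits = scan_full_ere(seq, EreModel(max_mismatch=2))
    assert [(h.offset, h.mismatches) for h in hits] == [(0, 1)]
    assert scan_full_ere("AGGTCANNNTGACCT", EreModel(max_mismatch=0)) != []


def test_short_sequence_returns_empty():
    assert scan_full_ere("AGGTCA", EreModel()) == []


def test_full_scan_matches_naive_rescan(rng):
    model = EreModel(max_mismatch=2)
    for _ in range(300):
        seq = random_seq(rng, 50)
        got = [(h.offset, h.mismatches) for h in scan_full_ere(seq, model)]
        assert got == naive_full_scan(seq, model)


def test_palindrome_mirror_property(rng):
    """Scanning the reverse complement yields mirrored offsets, equal mismatches."""
    model = EreModel(max_mismatch=2)
    for _ in range(100):
        seq = random_seq(rng, 60)
        fwd = [(h.offset, h.mismatches) for h in scan_full_ere(seq, model)]
        rev = [(h.offset, h.mismatches) for h in scan_full_ere(reverse_complement(seq), model)]
        mirrored = sorted((len(seq) - model.width - o, m) for o, m in rev)
        assert fwd == mirrored


def test_hit_monotonicity_in_mismatch_tolerance(rng):
    for _ in range(50):
        seq = random_seq(rng, 80)
        prev: set = set()
        for k in range(0, 4):
            hits = {h.offset for h in scan_full_ere(seq, EreModel(max_mismatch=k))}
            assert prev <= hits
            prev = hits


# ---------------------------------------------------------------------------
# half-ERE scan
# ---------------------------------------------------------------------------


def test_half_site_both_strands():
    plus = scan_half_ere("TTAGGTCATT")
    assert [(h.offset, h.strand) for h in plus] == [(2, "+")]
    minus = scan_half_ere("TTTGACCTTT")
    assert [(h.offset, h.strand) for h in minus] == [(2, "-")]


def test_half_hits_inside_full_windows_are_excluded():
    # exact consensus: both hexamers are present but belong to the full ERE
    assert scan_half_ere(CONSENSUS) == []
    assert scan_half_ere(CONSENSUS, exclude_full=False) != []


def test_half_scan_matches_naive_rescan(rng):
    model = EreModel(max_mismatch=2)
    for _ in range(200):
        seq = random_seq(rng, 100)
        got = [(h.offset, h.strand) for h in scan_half_ere(seq, model)]
        assert got == naive_half_scan(seq, model)


# ---------------------------------------------------------------------------
# site annotation
# ---------------------------------------------------------------------------


def test_annotate_planted_and_homopolymer_sites(rng):
    bg = random_seq(rng, 100)
    planted = bg[:40] + CONSENSUS + bg[55:]
    genome = DictGenome({"chr1": planted + "T" * 100})
    sites = IntervalSet(
        [
            GenomicInterval("chr1", 0, 100, name="planted"),
            GenomicInterval("chr1", 100, 200, name="poly_t"),
        ]
    )
    recs = {r.name: r for r in annotate_erbs(sites, genome)}
    assert recs["planted"].has_full_ere
    assert recs["planted"].best_full_mismatches == 0
    assert not recs["poly_t"].has_full_ere
    assert recs["poly_t"].n_half_sites == 0
    assert recs["poly_t"].best_full_mismatches is None


def test_annotate_out_of_bounds_site_names_site(tiny_genome):
    sites = IntervalSet([GenomicInterval("chr1", 9_990, 10_100, name="edge_site")])
    with pytest.raises(ValueError, match="edge_site"):
        annotate_erbs(sites, tiny_genome)


def test_annotation_recovers_simulation_truth(small_bundle):
    """Every planted motif within tolerance is found, nothing else."""
    recs = {r.name: r for r in annotate_erbs(small_bundle.sites, small_bundle.genome)}
    for row in small_bundle.truth.sites.itertuples():
        rec = recs[row.name]
        assert rec.has_full_ere == bool(row.planted_full)
        if row.planted_full:
            assert rec.best_full_mismatches == row.planted_mismatches
        assert rec.n_half_sites == row.planted_n_half
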