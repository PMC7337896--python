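"""Shared fixtures: small deterministic genomes, site sets and simulations."""

import numpy as np
import pytest

from erbscluster.intervals import GenomicInterval, IntervalSet
from erbscluster.io import DictGenome
from erbscluster.simulate import SimConfig, simulate


def random_interval_set(rng, n, n_chroms=2, span=200_000, max_len=500):
    """Random, possibly overlapping intervals for oracle comparisons."""
    ivs = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def tiny_genome():
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = {
        c: bases[rng.integers(0, 4, size=10_000)].tobytes().decode()
        for c in ("chr1", "chr2")
    }
    return DictGenome(seqs)


@pytest.fixture(scope="session")
def small_bundle():
    """One small but fully structured simulated landscape."""
    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=20_000_000,
        n_sites=400,
        n_genes=150,
        n_control_sites=2000,
        n_background_k27ac=80,
    )
    return simulate(cfg)
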