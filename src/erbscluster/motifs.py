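"""Estrogen response element (ERE) detection.

The full ERE is the palindromic consensus AGGTCAnnnTGACCT: two AGGTCA
half-sites in inverted orientation around a 3-bp spacer. A "full" hit allows a
configurable number of mismatches counted over the 12 constrained positions
only (the spacer never contributes); because the constrained consensus is its
own reverse complement, a single forward scan covers both strands and every
matching window is reported once on "+". Half-sites are exact AGGTCA matches
on either strand, with hits inside reported full-ERE windows excluded from the
half-site count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .io import Genome, extract_sequence

__all__ = [
    "EreModel",
    "MotifHit",
    "ErbsRecord",
    "reverse_complement",
    "scan_full_ere",
    "scan_half_ere",
    "annotate_erbs",
]

FULL_CONSENSUS = "AGGTCAnnnTGACCT"
HALF_CONSENSUS = "AGGTCA"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ALPHABET = frozenset(b"ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EreModel:
    """Mismatch-tolerance model of the ERE.

    ``max_mismatch`` (default 2) bounds mismatches over the 12 constrained
    positions of the full consensus; spacer positions (lower-case ``n``) are
    unconstrained. Half-site matches are always exact.
    """

    full_consensus: str = FULL_CONSENSUS
    half_consensus: str = HALF_CONSENSUS
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatch <= len(self.constrained_positions):
            raise ValueError("max_mismatch must lie in [0, number of constrained positions]")
        core = {i: b for i, b in enumerate(self.full_consensus.upper()) if i in set(self.constrained_positions)}
        n = len(self.full_consensus)
        comp = dict(zip("ACGT", "TGCA"))
        for i, b in core.items():
            j = n - 1 - i
            if j in core and comp[b] != core[j]:
                raise ValueError("constrained consensus must be palindromic")

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.full_consensus) if c.upper() != "N")

    @property
    def width(self) -> int:
        return len(self.full_consensus)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence within a scanned sequence (0-based offset)."""

    offset: int
    strand: str
    kind: str  # "full" | "half"
    mismatches: int


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    bad = set(arr.tobytes()) - _ALPHABET
    if bad:
        raise ValueError(
            f"sequence contains characters outside ACGTN: {sorted(chr(b) for b in bad)}"
        )
    return arr


def scan_full_ere(seq: str | np.ndarray, model: EreModel | None = None) -> list[MotifHit]:
    """All windows matching the full ERE within the model's mismatch tolerance.

    N counts as a mismatch at constrained positions. Sequences shorter than
    the motif return an empty list.
    """
    model = model or EreModel()
    arr = _encode(seq) if isinstance(seq, str) else seq
    w = model.width
    n_win = len(arr) - w + 1
    if n_win <= 0:
        return []
    cons = model.full_consensus.upper().encode("ascii")
    mm = np.zeros(n_win, dtype=np.int16)
    for pos in model.constrained_positions:
        mm += arr[pos : pos + n_win] != cons[pos]
    offsets = np.nonzero(mm <= model.max_mismatch)[0]
    return [MotifHit(int(o), "+", "full", int(mm[o])) for o in offsets]


def _exact_occurrences(seq: str, pattern: str) -> list[int]:
    out, start = [], seq.find(pattern)
    while start != -1:
        out.append(start)
        start = seq.find(pattern, start + 1)
    return out


def scan_half_ere(
    seq: str, model: EreModel | None = None, exclude_full: bool = True
) -> list[MotifHit]:
    """Exact half-site (AGGTCA) matches on either strand.

    The half-site is not palindromic, so reverse-strand hits are exact matches
    to its reverse complement (TGACCT). With ``exclude_full`` (the default,
    feeding ``n_half_sites``), hits overlapping any reported full-ERE window
    are dropped.
    """
    model = model or EreModel()
    seq = seq.upper()
    half = model.half_consensus.upper()
    hw = len(half)
    hits = [MotifHit(o, "+", "half", 0) for o in _exact_occurrences(seq, half)]
    hits += [
        MotifHit(o, "-", "half", 0)
        for o in _exact_occurrences(seq, reverse_complement(half))
    ]
    if exclude_full:
        full_windows = [(h.offset, h.offset + model.width) for h in scan_full_ere(seq, model)]
        hits = [
            h
            for h in hits
            if not any(h.offset < fe and fs < h.offset + hw for fs, fe in full_windows)
        ]
    return sorted(hits, key=lambda h: (h.offset, h.strand))


@dataclass
class ErbsRecord:
    """An ER binding site with its motif annotation and basal-H3K27ac flag.

    ``basal_k27ac`` is ``None`` until the activity stage marks it against a
    vehicle-condition H3K27ac peak set.
    """

    interval: GenomicInterval
    summit: int | None = None
    has_full_ere: bool = False
    best_full_mismatches: int | None = None
    n_half_sites: int = 0
    basal_k27ac: bool | None = None

    def __post_init__(self) -> None:
        if self.has_full_ere != (self.best_full_mismatches is not None):
            raise ValueError(
                "best_full_mismatches must be present exactly when has_full_ere is true"
            )

    @property
    def name(self) -> str | None:
        return self.interval.name


def annotate_erbs(
    sites: IntervalSet | Sequence[GenomicInterval],
    genome: Genome,
    model: EreModel | None = None,
) -> list[ErbsRecord]:
    """Scan every site's full interval and build one :class:`ErbsRecord` each."""
    model = model or EreModel()
    records = []
    for iv in sites:
        try:
            seq = extract_sequence(genome, iv)
        except (KeyError, ValueError) as exc:
            label = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
            raise ValueError(f"site {label}: {exc}") from exc
        full = scan_full_ere(seq, model)
        half = scan_half_ere(seq, model, exclude_full=True)
        best = min((h.mismatches for h in full), default=None)
        summit = None
        if iv.extra and len(iv.extra) == 4:  # narrowPeak: last column is summit offset
            try:
                off = int(iv.extra[-1])
                summit = iv.start + off if off >= 0 else None
            except ValueError:
                summit = None
        records.append(
            ErbsRecord(
                interval=iv,
                summit=summit,
                has_full_ere=bool(full),
                best_full_mismatches=best,
                n_half_sites=len(half),
            )
        )
    return records
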