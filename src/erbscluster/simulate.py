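"""Synthetic regulatory-landscape generator with a machine-readable truth record.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without external data:

* a random genome (uniform i.i.d. nucleotides) served block-wise by a
  counter-based PRNG, so arbitrarily large chromosomes cost nothing until a
  slice is actually fetched;
* an ER binding-site set with an excess of close (<= 10 kb) neighbor pairs
  over uniform placement;
* full EREs (0-2 constrained-position mismatches) and half EREs planted into
  site sequences, with site backgrounds redrawn until they carry no chance
  motif, so the planted annotation is exact;
* basal H3K27ac peaks attached to a subset of sites plus uniform background
  peaks;
* genes whose up-regulation is statistically coupled to nearby active
  clusters: a gene flagged "coupled" gets an active cluster planted inside its
  TSS window, and active material is kept out of a safety-dilated window of
  every uncoupled gene, so the planted per-gene truth is exact by
  construction. A coupled gene whose window is fully blocked has its TSS
  resampled (flag-flip as a recorded last resort).

Everything is deterministic in the config seed: same config, byte-identical
file bundle.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import warnings
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .io import GeneRecord, write_bed, write_fasta, write_gene_table
from .motifs import EreModel, reverse_complement, scan_full_ere, scan_half_ere

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "SimulatedGenome",
    "simulate",
    "write_bundle",
    "truth_compare",
    "DiscrepancyReport",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulatedGenome:
    """Uniform-random genome addressable by (chrom, start, end).

    Bases are generated per fixed-size block from a Philox counter keyed by
    (seed, chromosome, block), so any slice is reproducible without holding
    the chromosome in memory. Planted site sequences are stored as overrides
    applied on fetch.
    """

    def __init__(self, lengths: Mapping[str, int], seed: int, block_size: int = 65536):
        self._lengths = dict(lengths)
        self._seed = int(seed)
        self._block = int(block_size)
        self._chrom_index = {c: i for i, c in enumerate(self._lengths)}
        self._overrides: dict[str, list[tuple[int, np.ndarray]]] = {
            c: [] for c in self._lengths
        }

    @property
    def lengths(self) -> Mapping[str, int]:
        return self._lengths

    def add_override(self, chrom: str, start: int, seq: str) -> None:
        """Replace genome bases at [start, start+len(seq)); overrides must not overlap."""
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
        if start < 0 or start + len(arr) > self._lengths[chrom]:
            raise ValueError(f"override outside {chrom} bounds")
        ovs = self._overrides[chrom]
        pos = bisect.bisect_left(ovs, start, key=lambda t: t[0])
        if pos > 0 and ovs[pos - 1][0] + len(ovs[pos - 1][1]) > start:
            raise ValueError("overlapping override")
        if pos < len(ovs) and ovs[pos][0] < start + len(arr):
            raise ValueError("overlapping override")
        ovs.insert(pos, (start, arr))

    def _block_bases(self, chrom: str, block_idx: int) -> np.ndarray:
        ss = np.random.SeedSequence(
            entropy=self._seed, spawn_key=(self._chrom_index[chrom], block_idx)
        )
        rng = np.random.Generator(np.random.Philox(ss))
        return _BASES[rng.integers(0, 4, size=self._block)]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._lengths:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > self._lengths[chrom] or start >= end:
            raise ValueError(
                f"request {chrom}:{start}-{end} outside chromosome bounds"
            )
        ovs = self._overrides[chrom]
        if ovs:
            # fast path: a single override covering the whole request
            lo0 = bisect.bisect_left(ovs, start, key=lambda t: t[0] + len(t[1]))
            if lo0 < len(ovs):
                os_, oarr = ovs[lo0]
                if os_ <= start and os_ + len(oarr) >= end:
                    return oarr[start - os_ : end - os_].tobytes().decode("ascii")
        first, last = start // self._block, (end - 1) // self._block
        chunks = [self._block_bases(chrom, b) for b in range(first, last + 1)]
        arr = np.concatenate(chunks)[start - first * self._block : end - first * self._block]
        if ovs:
            lo = bisect.bisect_left(ovs, start, key=lambda t: t[0] + len(t[1]))
            for os_, oarr in ovs[lo:]:
                if os_ >= end:
                    break
                s = max(os_, start)
                e = min(os_ + len(oarr), end)
                if s < e:
                    arr[s - start : e - start] = oarr[s - os_ : e - os_]
        return arr.tobytes().decode("ascii")


@dataclass
class SimConfig:
    """Parameters of the synthetic regulatory landscape.

    Defaults are a desk-scale analogue of the study system: 3000 ER sites and
    2000 genes on a 600 Mb genome give the same gene and active-cluster
    densities per TSS window as ~20,000 genes on a human genome, 40% of sites
    placed as <=10 kb neighbor pairs, and coupling probabilities matching the
    reported active-cluster proportions near up- (0.28) and other (0.09)
    genes.
    """

    n_chroms: int = 4
    chrom_length: int = 150_000_000
    n_sites: int = 3000
    site_width: int = 200
    f_pair: float = 0.4
    pair_gap_max: int = 10_000
    p_full_ere: float = 0.3
    p_half_ere: float = 0.3
    p_basal_k27ac: float = 0.25
    full_ere_max_planted_mismatch: int = 2
    n_background_k27ac: int = 500
    k27_width: int = 400
    n_genes: int = 2000
    frac_up: float = 0.15
    frac_down: float = 0.15
    pi_active: float = 0.28
    pi_baseline: float = 0.09
    subtype_mmp17: float = 0.8
    coupling_radius: int = 100_000
    merge_gap: int = 10_000
    fc_base_mean: float = 1.0
    fc_shift: float = 0.5
    fc_sd: float = 0.8
    fc_not_sd: float = 0.3
    n_control_sites: int = 12_000
    control_width: int | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("f_pair", "p_full_ere", "p_half_ere", "p_basal_k27ac",
                     "pi_active", "pi_baseline", "subtype_mmp17", "frac_up", "frac_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        genome_bp = self.n_chroms * self.chrom_length
        if self.n_sites * self.site_width > 0.05 * genome_bp:
            raise ValueError("site footprint exceeds 5% of the genome; placement infeasible")
        if self.site_width < 40:
            raise ValueError("site_width must be at least 40 bp to hold a planted motif")
        if not 0 <= self.full_ere_max_planted_mismatch <= 2:
            raise ValueError("full_ere_max_planted_mismatch must lie in [0, 2]")
        if self.pair_gap_max < self.k27_width or self.merge_gap < self.k27_width:
            raise ValueError("pair_gap_max and merge_gap must be at least k27_width")

    @property
    def run_id(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class SimTruth:
    """Planted ground truth, keyed by the site/gene names in the emitted files."""

    sites: pd.DataFrame
    clusters: pd.DataFrame
    genes: pd.DataFrame
    run_id: str
    config: dict


@dataclass
class SimBundle:
    """In-memory result of one simulation; `write_bundle` serialises it."""

    genome: SimulatedGenome
    sites: IntervalSet
    k27_peaks: IntervalSet
    controls: dict[str, IntervalSet]
    genes: list[GeneRecord]
    truth: SimTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# placement bookkeeping
# ---------------------------------------------------------------------------


class _Occupied:
    """Sorted non-overlapping intervals per chromosome with proximity queries."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self.by_chrom[chrom]
        bisect.insort(ivs, (start, end))

    def conflicts(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        """True iff some stored interval is within ``margin`` bp (overlap at margin 0)."""
        ivs = self.by_chrom.get(chrom)
        if not ivs:
            return False
        lo = bisect.bisect_left(ivs, (start - margin - 10**7, 0))
        for os_, oe in ivs[lo:]:
            if os_ >= end + margin:
                break
            if oe > start - margin:
                return True
        return False


class _Forbidden:
    """Merged forbidden zones per chromosome, with subtraction for sampling."""

    def __init__(self) -> None:
        self.by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)

    def add(self, chrom: str, start: int, end: int) -> None:
        zones = self.by_chrom[chrom]
        pos = bisect.bisect_left(zones, (start, end))
        # merge with any neighbors it touches
        lo = pos
        while lo > 0 and zones[lo - 1][1] >= start:
            lo -= 1
        hi = pos
        while hi < len(zones) and zones[hi][0] <= end:
            hi += 1
        if lo < hi:
            start = min(start, zones[lo][0])
            end = max(end, zones[hi - 1][1])
            del zones[lo:hi]
        zones.insert(lo, (start, end))

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        zones = self.by_chrom.get(chrom)
        if not zones:
            return False
        pos = bisect.bisect_left(zones, (start, 0))
        if pos > 0 and zones[pos - 1][1] > start:
            return True
        return pos < len(zones) and zones[pos][0] < end

    def subtract_from(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """Segments of [start, end) not covered by any zone."""
        zones = self.by_chrom.get(chrom, [])
        out: list[tuple[int, int]] = []
        cur = start
        pos = bisect.bisect_left(zones, (start, 0))
        if pos > 0 and zones[pos - 1][1] > start:
            cur = max(cur, zones[pos - 1][1])
        for zs, ze in zones[pos:]:
            if zs >= end:
                break
            if zs > cur:
                out.append((cur, zs))
            cur = max(cur, ze)
        if cur < end:
            out.append((cur, end))
        return out


@dataclass
class _PlannedSite:
    chrom: str
    start: int
    width: int
    full_ere: bool = False
    mismatches: int | None = None
    half_ere: bool = False
    k27: bool = False
    cluster_ref: str | None = None
    name: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.width


def _segments_choice(rng: np.random.Generator, segments: list[tuple[int, int]]) -> int:
    lengths = np.array([e - s for s, e in segments], dtype=float)
    k = int(rng.choice(len(segments), p=lengths / lengths.sum()))
    s, e = segments[k]
    return int(rng.integers(s, e))


# ---------------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------------


def _full_motif(rng: np.random.Generator, model: EreModel, mismatches: int) -> str:
    """A full-ERE instance with a random spacer and exactly ``mismatches``
    substitutions at constrained positions."""
    cons = list(model.full_consensus.upper())
    for i, c in enumerate(cons):
        if c == "N":
            cons[i] = "ACGT"[rng.integers(0, 4)]
    if mismatches:
        positions = rng.choice(model.constrained_positions, size=mismatches, replace=False)
        for p in positions:
            alt = [b for b in "ACGT" if b != cons[p]]
            cons[p] = alt[rng.integers(0, 3)]
    return "".join(cons)


def _site_sequence(rng: np.random.Generator, site: _PlannedSite, model: EreModel) -> str:
    """Draw a site background and plant its motif, rejecting sequences whose
    realized hit set differs from the planted truth."""
    w = site.width
    for _ in range(200):
        seq = _BASES[rng.integers(0, 4, size=w)].tobytes().decode("ascii")
        expected_full: list[tuple[int, int]] = []
        expected_half_offsets: list[int] = []
        if site.full_ere:
            mm = int(site.mismatches or 0)
            motif = _full_motif(rng, model, mm)
            off = int(rng.integers(10, w - model.width - 9))
            seq = seq[:off] + motif + seq[off + model.width :]
            expected_full.append((off, mm))
        elif site.half_ere:
            half = model.half_consensus.upper()
            if rng.random() < 0.5:
                half = reverse_complement(half)
            off = int(rng.integers(10, w - len(half) - 9))
            seq = seq[:off] + half + seq[off + len(half) :]
            expected_half_offsets.append(off)
        got_full = [(h.offset, h.mismatches) for h in scan_full_ere(seq, model)]
        got_half = [h.offset for h in scan_half_ere(seq, model, exclude_full=True)]
        if got_full == expected_full and got_half == expected_half_offsets:
            return seq
    raise RuntimeError("could not draw a clean site sequence after bounded retries")


def _try_plant(
    rng: np.random.Generator,
    cfg: SimConfig,
    segs: list[tuple[int, int]],
    chrom: str,
    is_mmp17: bool,
    min_sep: int,
    planted_occ: "_Occupied",
    sites: list[_PlannedSite],
    cluster_rows: list[dict],
    ref: str,
    gene_id: str,
) -> bool:
    """Place one active cluster for a coupled gene inside the allowed segments.

    Returns False when every sampled anchor collides with already-placed
    planted sites (caller resamples the gene's TSS and tries again).
    """
    w = cfg.site_width
    for _ in range(50):
        anchor = _segments_choice(rng, segs)
        if is_mmp17:
            members = [_PlannedSite(chrom, anchor, w, full_ere=True,
                                    mismatches=int(rng.integers(0, cfg.full_ere_max_planted_mismatch + 1)),
                                    k27=True, cluster_ref=ref)]
            if rng.random() < 0.5:
                gap = int(rng.integers(min_sep, cfg.pair_gap_max + 1))
                members.append(_PlannedSite(chrom, anchor + w + gap, w,
                                            half_ere=True, cluster_ref=ref))
        else:
            gap = int(rng.integers(min_sep, min(cfg.pair_gap_max, cfg.merge_gap) + 1))
            members = [
                _PlannedSite(chrom, anchor, w, full_ere=True,
                             mismatches=int(rng.integers(0, cfg.full_ere_max_planted_mismatch + 1)),
                             cluster_ref=ref),
                _PlannedSite(chrom, anchor + w + gap, w, k27=True,
                             half_ere=bool(rng.random() < cfg.p_half_ere),
                             cluster_ref=ref),
            ]
        if any(planted_occ.conflicts(chrom, m.start, m.end, margin=min_sep)
               for m in members):
            continue
        for m in members:
            planted_occ.add(chrom, m.start, m.end)
        sites.extend(members)
        cluster_rows.append(
            dict(cluster_ref=ref, gene_id=gene_id, chrom=chrom,
                 start=members[0].start, end=members[-1].end,
                 subtype="mmp17" if is_mmp17 else "cish",
                 n_sites=len(members), active=True)
        )
        return True
    return False


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate(cfg: SimConfig) -> SimBundle:
    """Generate a full synthetic input bundle plus its truth record."""
    cfg.validate()
    model = EreModel(max_mismatch=2)
    ss = np.random.SeedSequence(cfg.seed)
    ss_genome, ss_place, ss_seq, ss_expr, ss_ctrl = ss.spawn(5)
    genome_seed = int(ss_genome.generate_state(1)[0])
    rng = np.random.Generator(np.random.Philox(ss_place))
    seq_rng = np.random.Generator(np.random.Philox(ss_seq))
    expr_rng = np.random.Generator(np.random.Philox(ss_expr))
    ctrl_rng = np.random.Generator(np.random.Philox(ss_ctrl))

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    lengths = {c: cfg.chrom_length for c in chroms}
    genome = SimulatedGenome(lengths, genome_seed)

    w = cfg.site_width
    min_sep = cfg.k27_width  # keeps every site clear of its neighbors' K27ac peaks
    extent_max = cfg.pair_gap_max + 2 * w
    dilation = cfg.merge_gap + extent_max

    # -- genes and coupling flags ------------------------------------------
    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    reg_classes = ["up"] * n_up + ["down"] * n_down + ["not"] * (cfg.n_genes - n_up - n_down)
    gene_chrom = [chroms[i] for i in rng.integers(0, cfg.n_chroms, size=cfg.n_genes)]
    gene_tss = [int(p) for p in rng.integers(0, cfg.chrom_length, size=cfg.n_genes)]
    gene_strand = ["+" if b else "-" for b in rng.integers(0, 2, size=cfg.n_genes)]
    coupled = [
        bool(rng.random() < (cfg.pi_active if reg == "up" else cfg.pi_baseline))
        for reg in reg_classes
    ]

    forbidden = _Forbidden()
    r = cfg.coupling_radius
    for i in range(cfg.n_genes):
        if not coupled[i]:
            forbidden.add(
                gene_chrom[i],
                max(0, gene_tss[i] - r - dilation),
                min(cfg.chrom_length, gene_tss[i] + r + dilation),
            )

    # -- planted active clusters for coupled genes --------------------------
    planted_occ = _Occupied()
    sites: list[_PlannedSite] = []
    cluster_rows: list[dict] = []
    n_flipped = 0

    def allowed_segments(chrom: str, tss: int) -> list[tuple[int, int]]:
        lo = max(0, tss - r)
        hi = min(cfg.chrom_length - extent_max, tss + r - extent_max)
        if hi <= lo:
            return []
        return [seg for seg in forbidden.subtract_from(chrom, lo, hi) if seg[1] - seg[0] > 1]

    for i in range(cfg.n_genes):
        if not coupled[i]:
            continue
        ref = f"planted_{len(cluster_rows):05d}"
        is_mmp17 = bool(rng.random() < cfg.subtype_mmp17)
        placed = False
        for outer in range(100):
            if outer > 0:
                # window blocked or crowded: give the gene a fresh TSS
                gene_chrom[i] = chroms[int(rng.integers(0, cfg.n_chroms))]
                gene_tss[i] = int(rng.integers(0, cfg.chrom_length))
            segs = allowed_segments(gene_chrom[i], gene_tss[i])
            if not segs:
                continue
            if _try_plant(rng, cfg, segs, gene_chrom[i], is_mmp17, min_sep,
                          planted_occ, sites, cluster_rows, ref, f"gene_{i:05d}"):
                placed = True
                break
        if not placed:
            coupled[i] = False
            n_flipped += 1
            forbidden.add(
                gene_chrom[i],
                max(0, gene_tss[i] - r - dilation),
                min(cfg.chrom_length, gene_tss[i] + r + dilation),
            )

    # -- background sites ----------------------------------------------------
    n_planted = len(sites)
    n_bg = cfg.n_sites - n_planted
    if n_bg < 0:
        raise ValueError(
            f"coupling demands {n_planted} planted sites but n_sites={cfg.n_sites}"
        )
    n_bg_pairs = int(round(cfg.f_pair * n_bg / 2))
    n_bg_singles = n_bg - 2 * n_bg_pairs

    bg_occ = _Occupied()
    bg_ere = _Occupied()  # background sites carrying a full ERE
    bg_k27 = _Occupied()  # background sites carrying basal K27ac

    def draw_features() -> tuple[bool, int | None, bool, bool]:
        full = bool(rng.random() < cfg.p_full_ere)
        mm = int(rng.integers(0, cfg.full_ere_max_planted_mismatch + 1)) if full else None
        half = (not full) and bool(rng.random() < cfg.p_half_ere)
        k27 = bool(rng.random() < cfg.p_basal_k27ac)
        return full, mm, half, k27

    def place_unit(n_members: int) -> list[_PlannedSite]:
        feats = [draw_features() for _ in range(n_members)]
        gap = int(rng.integers(min_sep, cfg.pair_gap_max + 1)) if n_members == 2 else 0
        extent = n_members * w + gap
        merged = n_members == 2 and gap <= cfg.merge_gap
        if merged:
            unit_active = any(f[0] for f in feats) and any(f[3] for f in feats)
        else:
            unit_active = any(f[0] and f[3] for f in feats)
        has_ere = any(f[0] for f in feats)
        has_k27 = any(f[3] for f in feats)
        for _ in range(2000):
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            pos = int(rng.integers(0, cfg.chrom_length - extent))
            if unit_active and forbidden.intersects(chrom, pos, pos + extent):
                continue
            if planted_occ.conflicts(chrom, pos, pos + extent, margin=cfg.merge_gap):
                continue
            if bg_occ.conflicts(chrom, pos, pos + extent, margin=min_sep):
                continue
            if has_ere and bg_k27.conflicts(chrom, pos, pos + extent, margin=cfg.merge_gap):
                continue
            if has_k27 and bg_ere.conflicts(chrom, pos, pos + extent, margin=cfg.merge_gap):
                continue
            out = []
            for k, (full, mm, half, k27) in enumerate(feats):
                start = pos + k * (w + gap)
                out.append(_PlannedSite(chrom, start, w, full_ere=full, mismatches=mm,
                                        half_ere=half, k27=k27))
                bg_occ.add(chrom, start, start + w)
                if full:
                    bg_ere.add(chrom, start, start + w)
                if k27:
                    bg_k27.add(chrom, start, start + w)
            return out
        raise RuntimeError("infeasible background placement after bounded retries")

    for _ in range(n_bg_pairs):
        sites.extend(place_unit(2))
    for _ in range(n_bg_singles):
        sites.extend(place_unit(1))

    # -- name sites in genomic order, plant sequences ------------------------
    sites.sort(key=lambda s: (s.chrom, s.start))
    for idx, site in enumerate(sites):
        site.name = f"site_{idx:05d}"
    for site in sites:
        genome.add_override(site.chrom, site.start, _site_sequence(seq_rng, site, model))

    site_ivs = IntervalSet(
        [GenomicInterval(s.chrom, s.start, s.end, name=s.name) for s in sites],
        is_sorted=True,
    )

    # -- H3K27ac peaks --------------------------------------------------------
    k27_ivs: list[GenomicInterval] = []
    half_w = cfg.k27_width // 2
    for s in sites:
        if s.k27:
            mid = (s.start + s.end) // 2
            k27_ivs.append(
                GenomicInterval(s.chrom, max(0, mid - half_w),
                                min(cfg.chrom_length, mid + half_w))
            )
    all_sites_occ = _Occupied()
    for s in sites:
        all_sites_occ.add(s.chrom, s.start, s.end)
    n_bg_peaks = 0
    attempts = 0
    while n_bg_peaks < cfg.n_background_k27ac and attempts < 100 * cfg.n_background_k27ac:
        attempts += 1
        chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
        pos = int(rng.integers(0, cfg.chrom_length - cfg.k27_width))
        if all_sites_occ.conflicts(chrom, pos, pos + cfg.k27_width, margin=0):
            continue
        k27_ivs.append(GenomicInterval(chrom, pos, pos + cfg.k27_width))
        n_bg_peaks += 1
    k27_set = IntervalSet(sorted(k27_ivs, key=GenomicInterval.key), is_sorted=True)

    # -- control site sets ----------------------------------------------------
    cw = cfg.control_width or cfg.site_width
    controls: dict[str, IntervalSet] = {}
    for cname in ("dhs_like", "ctcf_like"):
        cc = [chroms[i] for i in ctrl_rng.integers(0, cfg.n_chroms, size=cfg.n_control_sites)]
        cp = ctrl_rng.integers(0, cfg.chrom_length - cw, size=cfg.n_control_sites)
        ivs = sorted(
            (GenomicInterval(c, int(p), int(p) + cw) for c, p in zip(cc, cp)),
            key=GenomicInterval.key,
        )
        controls[cname] = IntervalSet(
            [GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{cname}_{k:05d}")
             for k, iv in enumerate(ivs)],
            is_sorted=True,
        )

    # -- expression ------------------------------------------------------------
    genes: list[GeneRecord] = []
    for i in range(cfg.n_genes):
        reg = reg_classes[i]
        if reg == "up":
            fc = expr_rng.normal(cfg.fc_base_mean, cfg.fc_sd)
            if coupled[i]:
                fc += cfg.fc_shift
        elif reg == "down":
            fc = expr_rng.normal(-cfg.fc_base_mean, cfg.fc_sd)
        else:
            fc = expr_rng.normal(0.0, cfg.fc_not_sd)
        genes.append(
            GeneRecord(f"gene_{i:05d}", gene_chrom[i], gene_tss[i], gene_strand[i],
                       reg, float(fc))
        )

    # -- truth record -----------------------------------------------------------
    if n_flipped:
        warnings.warn(
            f"{n_flipped} coupled genes had fully blocked windows and were flipped "
            "to uncoupled (recorded in truth)",
            stacklevel=2,
        )
    truth_sites = pd.DataFrame(
        dict(
            name=[s.name for s in sites],
            chrom=[s.chrom for s in sites],
            start=[s.start for s in sites],
            end=[s.end for s in sites],
            planted_full=[s.full_ere for s in sites],
            planted_mismatches=pd.array(
                [s.mismatches for s in sites], dtype="Int64"
            ),
            planted_n_half=[int(s.half_ere) for s in sites],
            basal_k27ac=[s.k27 for s in sites],
            cluster_ref=[s.cluster_ref or "" for s in sites],
        )
    )
    truth_clusters = pd.DataFrame(
        cluster_rows,
        columns=["cluster_ref", "gene_id", "chrom", "start", "end", "subtype",
                 "n_sites", "active"],
    )
    truth_genes = pd.DataFrame(
        dict(
            gene_id=[g.gene_id for g in genes],
            chrom=[g.chrom for g in genes],
            tss=[g.tss for g in genes],
            reg_class=[g.reg_class for g in genes],
            coupled=coupled,
            log2fc=[g.log2fc for g in genes],
        )
    )
    truth = SimTruth(
        sites=truth_sites,
        clusters=truth_clusters,
        genes=truth_genes,
        run_id=cfg.run_id,
        config=asdict(cfg),
    )
    return SimBundle(genome, site_ivs, k27_set, controls, genes, truth, cfg)


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict:
    """Serialise a bundle to standard formats; returns the manifest dict.

    Emits genome.fa, sites.bed, k27ac.bed, one control_<name>.bed per control
    set, genes.tsv, the three truth TSVs and manifest.json. Deterministic for
    a fixed config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_bp = sum(bundle.genome.lengths.values())
    if genome_bp > 100_000_000:
        warnings.warn(
            f"materialising {genome_bp / 1e6:.0f} Mb of genome FASTA; consider a "
            "smaller chrom_length for file-based runs",
            stacklevel=2,
        )
    write_fasta(bundle.genome, out / "genome.fa")
    write_bed(bundle.sites, out / "sites.bed")
    write_bed(bundle.k27_peaks, out / "k27ac.bed")
    for name, cset in bundle.controls.items():
        write_bed(cset, out / f"control_{name}.bed")
    write_gene_table(bundle.genes, out / "genes.tsv")
    bundle.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    bundle.truth.clusters.to_csv(out / "truth_clusters.tsv", sep="\t", index=False)
    bundle.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    manifest = dict(
        run_id=bundle.truth.run_id,
        config=asdict(bundle.config),
        counts=dict(
            sites=len(bundle.sites),
            k27_peaks=len(bundle.k27_peaks),
            genes=len(bundle.genes),
            planted_clusters=int(len(bundle.truth.clusters)),
            controls={k: len(v) for k, v in bundle.controls.items()},
        ),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------


@dataclass
class DiscrepancyReport:
    """Per-stage confusion counts between pipeline output and planted truth."""

    full_ere_confusion: dict
    mismatch_disagreements: int
    k27_confusion: dict
    half_count_disagreements: int
    cluster_membership_errors: int
    gene_coupling_confusion: dict

    def is_clean(self) -> bool:
        return (
            self.full_ere_confusion["fp"] == 0
            and self.full_ere_confusion["fn"] == 0
            and self.mismatch_disagreements == 0
            and self.k27_confusion["fp"] == 0
            and self.k27_confusion["fn"] == 0
            and self.half_count_disagreements == 0
            and self.cluster_membership_errors == 0
            and self.gene_coupling_confusion["fp"] == 0
            and self.gene_coupling_confusion["fn"] == 0
        )


def _confusion(pred: Sequence[bool], true: Sequence[bool]) -> dict:
    tp = sum(p and t for p, t in zip(pred, true))
    fp = sum(p and not t for p, t in zip(pred, true))
    fn = sum(t and not p for p, t in zip(pred, true))
    tn = sum(not p and not t for p, t in zip(pred, true))
    return dict(tp=tp, fp=fp, fn=fn, tn=tn)


def truth_compare(result, truth: SimTruth) -> DiscrepancyReport:
    """Compare a :class:`~erbscluster.pipeline.PipelineResult` with the truth.

    Raises when the run identifiers disagree (outputs and truth must come
    from the same seed and config).
    """
    run_id = getattr(result, "run_id", None)
    if run_id is not None and run_id != truth.run_id:
        raise ValueError(f"run_id mismatch: result {run_id} vs truth {truth.run_id}")

    by_name = {r.name: r for r in result.records}
    ts = truth.sites
    pred_full, true_full, pred_k27, true_k27 = [], [], [], []
    mm_dis = 0
    half_dis = 0
    for row in ts.itertuples():
        rec = by_name.get(row.name)
        if rec is None:
            raise ValueError(f"site {row.name} missing from pipeline output")
        pred_full.append(bool(rec.has_full_ere))
        true_full.append(bool(row.planted_full))
        pred_k27.append(bool(rec.basal_k27ac))
        true_k27.append(bool(row.basal_k27ac))
        if rec.has_full_ere and row.planted_full and rec.best_full_mismatches != row.planted_mismatches:
            mm_dis += 1
        if rec.n_half_sites != row.planted_n_half:
            half_dis += 1

    member_of = {
        m.name: c.cluster_id for c in result.clusters for m in c.members
    }
    membership_errors = 0
    for ref, grp in ts[ts.cluster_ref != ""].groupby("cluster_ref"):
        assigned = {member_of.get(n) for n in grp["name"]}
        if len(assigned) != 1 or None in assigned:
            membership_errors += 1

    ann_by_gene = {a.gene_id: a for a in result.annotations}
    pred_c, true_c = [], []
    for row in truth.genes.itertuples():
        a = ann_by_gene.get(row.gene_id)
        if a is None:
            raise ValueError(f"gene {row.gene_id} missing from pipeline output")
        pred_c.append(bool(a.has_active_cluster))
        true_c.append(bool(row.coupled))

    return DiscrepancyReport(
        full_ere_confusion=_confusion(pred_full, true_full),
        mismatch_disagreements=mm_dis,
        k27_confusion=_confusion(pred_k27, true_k27),
        half_count_disagreements=half_dis,
        cluster_membership_errors=membership_errors,
        gene_coupling_confusion=_confusion(pred_c, true_c),
    )
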