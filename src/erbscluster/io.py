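"""Readers and writers for the formats the pipeline touches.

BED3/BED6 and narrowPeak/broadPeak for peak sets, FASTA for genome sequence
(file-backed through pyfaidx or fully in memory), a bespoke tab-separated gene
table (one TSS and one regulation call per gene), and a convenience GTF
importer. Coordinates are converted to 0-based half-open on ingest and back on
output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, runtime_checkable

import numpy as np
from pyfaidx import Fasta

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "Genome",
    "DictGenome",
    "FastaGenome",
    "GeneRecord",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "genes_from_gtf",
    "extract_sequence",
    "extract_tss_points",
]

_ALPHABET = set("ACGTN")
_REG_CLASSES = ("up", "down", "not")


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------


@runtime_checkable
class Genome(Protocol):
    """Anything that can serve nucleotide sequence for interval queries."""

    @property
    def lengths(self) -> Mapping[str, int]: ...

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


def _check_bounds(lengths: Mapping[str, int], chrom: str, start: int, end: int) -> None:
    if chrom not in lengths:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    if start < 0 or end > lengths[chrom]:
        raise ValueError(
            f"request {chrom}:{start}-{end} outside chromosome bounds (length {lengths[chrom]})"
        )
    if start >= end:
        raise ValueError(f"empty sequence request {chrom}:{start}-{end}")


class DictGenome:
    """In-memory genome: chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {chrom!r} contains characters outside ACGTN: {sorted(bad)}"
                )
            self._seqs[chrom] = seq
        self._lengths = {c: len(s) for c, s in self._seqs.items()}

    @property
    def lengths(self) -> Mapping[str, int]:
        return self._lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        _check_bounds(self._lengths, chrom, start, end)
        return self._seqs[chrom][start:end]


class FastaGenome:
    """File-backed genome using a pyfaidx index; validates alphabet per fetch."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True, rebuild=True)
        self._lengths = {name: len(rec) for name, rec in self._fasta.items()}

    @property
    def lengths(self) -> Mapping[str, int]:
        return self._lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        _check_bounds(self._lengths, chrom, start, end)
        seq = str(self._fasta[chrom][start:end])
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"{chrom}:{start}-{end} contains characters outside ACGTN: {sorted(bad)}"
            )
        return seq


def extract_sequence(genome: Genome, iv: GenomicInterval) -> str:
    """Uppercase sequence of ``iv``; length is exactly ``end - start``."""
    return genome.fetch(iv.chrom, iv.start, iv.end)


def write_fasta(
    sequences: Mapping[str, str] | Genome, path: str | Path, line_width: int = 60
) -> None:
    """Write chromosome sequences as FASTA with fixed line width."""
    if isinstance(sequences, Mapping):
        items = sequences.items()
    else:
        items = ((c, sequences.fetch(c, 0, n)) for c, n in sequences.lengths.items())
    with open(path, "w") as fh:
        for chrom, seq in items:
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED family
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6 or narrowPeak/broadPeak; extra columns are preserved."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else None
            extra = tuple(fields[6:])
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand, extra)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(s: IntervalSet | Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; column count is the widest any member needs."""
    ivs = list(s)

    def natural_width(iv: GenomicInterval) -> int:
        if iv.extra:
            return 6 + len(iv.extra)
        if iv.strand is not None:
            return 6
        if iv.score is not None:
            return 5
        if iv.name is not None:
            return 4
        return 3

    ncols = max((natural_width(iv) for iv in ivs), default=3)
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if ncols > 3:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols > 4:
                fields.append(_format_number(iv.score) if iv.score is not None else ".")
            if ncols > 5:
                fields.append(iv.strand if iv.strand is not None else ".")
            fields.extend(iv.extra)
            fields.extend("." for _ in range(ncols - len(fields)))
            fh.write("\t".join(fields) + "\n")


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected name and length")
            sizes[fields[0]] = int(fields[1])
    return sizes


# ---------------------------------------------------------------------------
# gene table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene: a single annotated TSS plus its estrogen-response call."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    reg_class: str  # "up" | "down" | "not"
    log2fc: float

    def __post_init__(self) -> None:
        if self.reg_class not in _REG_CLASSES:
            raise ValueError(f"{self.gene_id}: reg_class must be one of {_REG_CLASSES}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")


_GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand", "reg_class", "log2fc")


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the gene TSV (header: gene_id, chrom, tss, strand, reg_class, log2fc).

    reg_class is case-insensitive and normalized to lower case; duplicate
    gene_ids and malformed fields are rejected with the offending line number.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[: len(_GENE_COLUMNS)]) != _GENE_COLUMNS:
            raise ValueError(
                f"{path}: expected header {list(_GENE_COLUMNS)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, tss_s, strand, reg, fc_s = fields[:6]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            reg = reg.strip().lower()
            if reg not in _REG_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown reg_class {fields[4]!r}")
            try:
                tss = int(tss_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer tss") from exc
            try:
                log2fc = float(fc_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric log2fc") from exc
            try:
                genes.append(GeneRecord(gene_id, chrom, tss, strand, reg, log2fc))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.reg_class}\t{g.log2fc:.6g}\n"
            )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def genes_from_gtf(
    path: str | Path, reg_class: str = "not", log2fc: float = 0.0
) -> list[GeneRecord]:
    """Convenience importer: one TSS per gene from a GTF.

    The TSS is the strand-aware 5'-most transcript start (exons are used when
    no transcript features are present). GTF carries no regulation call, so all
    records get ``reg_class``/``log2fc`` defaults; 1-based GTF starts become
    0-based positions.
    """
    best: dict[str, tuple[str, str, int]] = {}  # gene_id -> (chrom, strand, tss)
    has_transcripts: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("transcript", "exon"):
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                continue
            if f[2] == "transcript":
                has_transcripts.add(gid)
            elif gid in has_transcripts:
                continue  # exons only stand in when transcripts are absent
            chrom, strand = f[0], f[6]
            start, end = int(f[3]) - 1, int(f[4])
            tss = start if strand == "+" else end - 1
            prev = best.get(gid)
            if prev is None:
                best[gid] = (chrom, strand, tss)
            else:
                _, pstrand, ptss = prev
                if (strand == "+" and tss < ptss) or (strand == "-" and tss > ptss):
                    best[gid] = (chrom, strand, tss)
    return [
        GeneRecord(gid, chrom, tss, strand, reg_class, log2fc)
        for gid, (chrom, strand, tss) in sorted(best.items())
    ]


def extract_tss_points(genes: Iterable[GeneRecord]) -> list[tuple[str, int]]:
    """One (chrom, position) point per gene at the stored TSS, order preserved."""
    return [(g.chrom, g.tss) for g in genes]
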