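"""Core domain types and strict readers/writers for on-disk formats.

All coordinates are 0-based half-open (BED convention) internally; any
1-based representation is formatting only.  Parsers validate and reject
malformed records rather than coercing them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SPECIES = ("human", "chimp", "macaque")
VALID_CELL_TYPES = ("fibroblast", "lcl")

#: Windows on these chromosomes are excluded from differential analysis
#: (female samples carry no Y; configurable at the call sites that use it).
DEFAULT_EXCLUDED_CHROMS = frozenset({"chrY"})


class FormatError(ValueError):
    """A file failed validation; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region ``[start, end)`` on a named assembly."""

    assembly: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap between intervals (0 if overlapping, None if trans-chrom)."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    cell_type: str
    individual: str

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.cell_type not in VALID_CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.species == "macaque" and self.cell_type == "lcl":
            # no macaque LCL material exists in this design
            raise ValueError("macaque LCL samples are not a valid design point")


@dataclass
class ScoredPeakSet:
    """Peak calls for one sample, sorted by coordinate, with scores."""

    sample: SampleMeta
    peaks: list[tuple[GenomicInterval, float]]

    def __post_init__(self) -> None:
        keys = [(iv.chrom, iv.start) for iv, _ in self.peaks]
        if keys != sorted(keys):
            self.peaks = sorted(self.peaks, key=lambda p: (p[0].chrom, p[0].start))
        for iv, s in self.peaks:
            if not math.isfinite(s) or s < 0:
                raise ValueError(f"peak score must be finite and >= 0, got {s}")


class CountMatrix:
    """Integer counts for windows/genes (rows) by samples (columns).

    Library sizes default to column sums and may be overridden (e.g. when
    counts are a filtered subset of a larger experiment).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Sequence[float] | None = None,
    ) -> None:
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if arr.size and (counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = counts
        if library_sizes is None:
            self.library_sizes = counts.sum(axis=0).astype(float)
        else:
            ls = pd.Series(
                np.asarray(library_sizes, dtype=float), index=counts.columns
            )
            if (ls < 0).any():
                raise ValueError("library sizes must be nonnegative")
            self.library_sizes = ls

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_rows(self, mask_or_ids) -> "CountMatrix":
        sub = self.counts.loc[mask_or_ids]
        return CountMatrix(sub, self.library_sizes.to_numpy())

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, assembly: str) -> list[tuple]:
    """Read a BED3+ file as validated intervals, preserving input order.

    Returns ``(interval,)`` tuples for BED3, ``(interval, name)`` for
    BED4 and ``(interval, name, score)`` for BED5+ lines (strand taken
    from column 6 when present).
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = GenomicInterval(assembly, fields[0], start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score"
                    ) from exc
                out.append((iv, fields[3], score))
            elif len(fields) == 4:
                out.append((iv, fields[3]))
            else:
                out.append((iv,))
    return out


def write_bed(records: Iterable, path: str | Path) -> None:
    """Write interval records as produced by :func:`read_bed`."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = (rec,)
            iv = rec[0]
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if len(rec) >= 2:
                cols.append(str(rec[1]))
            if len(rec) >= 3:
                cols.append(_fmt_score(rec[2]))
                if iv.strand != ".":
                    cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# BED12 gene models

@dataclass(frozen=True)
class GeneModel:
    """One transcript: span, strand and exon blocks (0-based half-open)."""

    gene_id: str
    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...]  # absolute coordinates, sorted

    def __post_init__(self) -> None:
        for (s, e) in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise ValueError(f"exon ({s},{e}) outside gene span for {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.interval.end - 1 if self.interval.strand == "-" else self.interval.start

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in transcription order (first intron first)."""
        pairs = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]
        return pairs[::-1] if self.interval.strand == "-" else pairs


def read_bed12(path: str | Path, assembly: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 fields")
            try:
                start, end = int(f[1]), int(f[2])
                iv = GenomicInterval(assembly, f[0], start, end, f[5])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s) for o, s in zip(starts, sizes))
            genes.append(GeneModel(f[3], iv, exons))
    return genes


def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offs = ",".join(str(s - iv.start) for s, e in g.exons)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(g.exons)}\t{sizes},\t{offs},\n"
            )


def merge_isoforms(genes: Sequence[GeneModel]) -> dict[str, GeneModel]:
    """Merge transcripts sharing a gene_id into one span with merged exons."""
    by_id: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_id.setdefault(g.gene_id, []).append(g)
    merged = {}
    for gid, models in by_id.items():
        chroms = {m.interval.chrom for m in models}
        if len(chroms) != 1:
            raise ValueError(f"gene {gid} spans multiple chromosomes")
        start = min(m.interval.start for m in models)
        end = max(m.interval.end for m in models)
        strand = models[0].interval.strand
        iv = GenomicInterval(models[0].interval.assembly, chroms.pop(), start, end, strand)
        exon_ivs = merge_intervals(
            [
                GenomicInterval(iv.assembly, iv.chrom, s, e)
                for m in models
                for (s, e) in m.exons
            ]
        )
        merged[gid] = GeneModel(gid, iv, tuple((e.start, e.end) for e in exon_ivs))
    return merged


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: str | Path, assembly: str) -> list[tuple[GenomicInterval, float]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: bedGraph needs 4 fields")
            try:
                iv = GenomicInterval(assembly, fields[0], int(fields[1]), int(fields[2]))
                val = float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            out.append((iv, val))
    return out


def write_bedgraph(records: Iterable[tuple[GenomicInterval, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, val in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val:g}\n")


# ---------------------------------------------------------------------------
# count tables

def read_count_table(path: str | Path) -> CountMatrix:
    """Read a TSV of nonnegative integer counts (rows x samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if arr.size:
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError(f"{path}: non-numeric cells in count table")
        if np.any(arr < 0):
            raise FormatError(f"{path}: negative count")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise FormatError(f"{path}: non-integer count")
    return CountMatrix(df.astype(np.int64))


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# JASPAR-style PFMs

def read_pfm(path: str | Path) -> tuple[str, np.ndarray]:
    """Read a JASPAR-style position frequency matrix.

    Accepts an optional ``>name`` header followed by exactly four rows of
    nonnegative counts (A, C, G, T order), optionally prefixed by the base
    letter and wrapped in brackets, e.g. ``A [ 10  3  0 ]``.

    Returns ``(name, counts)`` with counts shaped (4, L).
    """
    name = Path(path).stem
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else name
                continue
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens and tokens[0].upper() in "ACGT" and len(tokens[0]) == 1:
                tokens = tokens[1:]
            try:
                vals = [float(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-numeric PFM entry") from exc
            if any(v < 0 for v in vals):
                raise FormatError(f"{path}: line {lineno}: negative PFM count")
            rows.append(vals)
    if len(rows) != 4:
        raise FormatError(f"{path}: PFM must have 4 rows (A,C,G,T), got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1 or 0 in lengths:
        raise FormatError(f"{path}: PFM rows differ in length")
    return name, np.array(rows, dtype=float)


def write_pfm(name: str, counts: np.ndarray, path: str | Path) -> None:
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != 4:
        raise ValueError("PFM must have 4 rows")
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", counts):
            fh.write(base + " [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA (simple multi-record; sequences kept as plain strings)

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise FormatError(f"{path}: line {lineno}: duplicate record {current}")
                seqs[current] = []
            else:
                if current is None:
                    raise FormatError(f"{path}: line {lineno}: sequence before header")
                seqs[current].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# sample metadata tables

def read_sample_table(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "species", "cell_type", "individual"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample table needs columns {sorted(required)}")
    metas = [
        SampleMeta(r.sample_id, r.species, r.cell_type, str(r.individual))
        for r in df.itertuples()
    ]
    keys = [(m.species, m.cell_type, m.individual) for m in metas]
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (species, cell_type, individual)")
    return metas


def write_sample_table(metas: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "species": m.species,
                "cell_type": m.cell_type,
                "individual": m.individual,
            }
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interval utilities shared across modules

def merge_intervals(ivs: Iterable[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Merge overlapping (or within ``gap`` bases, book-ended at gap=0) intervals."""
    ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end + gap:
            prev = out.pop()
            out.append(
                GenomicInterval(prev.assembly, prev.chrom, prev.start, max(prev.end, iv.end))
            )
        else:
            out.append(GenomicInterval(iv.assembly, iv.chrom, iv.start, iv.end))
    return out
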