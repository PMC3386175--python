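"""Piecewise 1:1 interval mapping between assemblies.

This is the liftOver abstraction used throughout the pipeline: a map is
a sorted list of equal-length, non-overlapping alignment blocks between
a source and a target assembly.  Lifting an interval succeeds when a
sufficient fraction of its bases (default 80%) land on a single target
chromosome and orientation, with unmapped gaps bridged; reciprocal
lifting detects regions that are not 1:1 between assemblies
(duplications and deletions) and is the basis of the CNV filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from dhsevo.ioformats import FormatError, GenomicInterval

DEFAULT_MIN_MATCH = 0.8


@dataclass(frozen=True)
class Block:
    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValueError("block source and target lengths differ")
        if self.src_end <= self.src_start:
            raise ValueError("block length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("block strand must be + or -")


class OrthologyMap:
    """A set of 1:1 alignment blocks between two assemblies."""

    def __init__(
        self,
        source_assembly: str,
        target_assembly: str,
        blocks: list[Block],
        allow_source_overlap: bool = False,
    ):
        self.source_assembly = source_assembly
        self.target_assembly = target_assembly
        self.blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start))
        if not allow_source_overlap:
            prev_end: dict[str, int] = {}
            for b in self.blocks:
                if b.src_start < prev_end.get(b.src_chrom, 0):
                    raise ValueError("source blocks overlap")
                prev_end[b.src_chrom] = b.src_end
        # per-chromosome arrays for fast interval queries
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Block]]] = {}
        for b in self.blocks:
            self._by_chrom.setdefault(b.src_chrom, ([], [], []))  # type: ignore[arg-type]
        tmp: dict[str, list[Block]] = {}
        for b in self.blocks:
            tmp.setdefault(b.src_chrom, []).append(b)
        for chrom, bl in tmp.items():
            starts = np.array([b.src_start for b in bl])
            ends = np.array([b.src_end for b in bl])
            self._by_chrom[chrom] = (starts, ends, bl)

    def blocks_overlapping(self, iv: GenomicInterval) -> list[Block]:
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return []
        starts, ends, bl = entry
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        return bl[lo:hi]

    def invert(self) -> "OrthologyMap":
        inv = [
            Block(b.tgt_chrom, b.tgt_start, b.tgt_end, b.src_chrom, b.src_start, b.src_end, b.strand)
            for b in self.blocks
        ]
        # the target side may legitimately carry duplications (non-1:1
        # regions); those surface as overlapping source blocks here and
        # are rejected at lift time instead
        return OrthologyMap(
            self.target_assembly, self.source_assembly, inv, allow_source_overlap=True
        )


def read_orthology_map(path: str | Path, source_assembly: str, target_assembly: str) -> OrthologyMap:
    """Read the TSV block format: src_chrom src_start src_end tgt_chrom tgt_start tgt_end strand."""
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 7:
                raise FormatError(f"{path}: line {lineno}: expected 7 fields")
            try:
                blocks.append(
                    Block(f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), f[6])
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return OrthologyMap(source_assembly, target_assembly, blocks)


def write_orthology_map(omap: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in omap.blocks:
            fh.write(
                f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t"
                f"{b.tgt_chrom}\t{b.tgt_start}\t{b.tgt_end}\t{b.strand}\n"
            )


def _mapped_pieces(iv: GenomicInterval, omap: OrthologyMap):
    """Target pieces per covering block, plus the source spans they cover."""
    pieces, src_spans = [], []
    for b in omap.blocks_overlapping(iv):
        s = max(iv.start, b.src_start)
        e = min(iv.end, b.src_end)
        if s >= e:
            continue
        if b.strand == "+":
            ts = b.tgt_start + (s - b.src_start)
            te = ts + (e - s)
        else:
            te = b.tgt_end - (s - b.src_start)
            ts = te - (e - s)
        pieces.append((b.tgt_chrom, ts, te, b.strand))
        src_spans.append((s, e))
    return pieces, src_spans


def lift(
    iv: GenomicInterval,
    omap: OrthologyMap,
    min_match: float = DEFAULT_MIN_MATCH,
) -> GenomicInterval | None:
    """Lift an interval to the target assembly, or return None if unmapped.

    Succeeds iff at least ``min_match`` of the interval's bases map, all
    mapped bases land on one target chromosome with one orientation, and
    the mapped pieces are collinear (internal deletions are bridged).
    """
    if iv.assembly != omap.source_assembly:
        raise ValueError(
            f"interval on {iv.assembly!r} but map source is {omap.source_assembly!r}"
        )
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    pieces, src_spans = _mapped_pieces(iv, omap)
    if not pieces:
        return None
    chroms = {p[0] for p in pieces}
    strands = {p[3] for p in pieces}
    if len(chroms) > 1 or len(strands) > 1:
        return None
    # a source base covered by more than one block maps ambiguously
    src_sorted = sorted(src_spans)
    for prev, nxt in zip(src_sorted, src_sorted[1:]):
        if nxt[0] < prev[1]:
            return None
    mapped = sum(te - ts for _, ts, te, _ in pieces)
    if mapped / len(iv) < min_match:
        return None
    # collinearity: pieces must be disjoint in the target and in
    # consistent order (duplications produce overlapping pieces)
    tgt_sorted = sorted(pieces, key=lambda p: p[1])
    for prev, nxt in zip(tgt_sorted, tgt_sorted[1:]):
        if nxt[1] < prev[2]:
            return None
    strand = strands.pop()
    expected = pieces if strand == "+" else pieces[::-1]
    if tgt_sorted != expected:
        return None
    return GenomicInterval(
        omap.target_assembly,
        tgt_sorted[0][0],
        tgt_sorted[0][1],
        tgt_sorted[-1][2],
        iv.strand,
    )


def reciprocal_ok(
    iv_target: GenomicInterval,
    omap: OrthologyMap,
    min_match: float = DEFAULT_MIN_MATCH,
) -> bool:
    """True iff the target interval maps 1:1 back and forth through the map.

    Lifts the interval back to the source assembly, re-lifts forward and
    requires the round-trip interval to reciprocally overlap at least
    ``min_match`` of the original.  Regions fed by duplicated blocks or
    unmapped regions fail.
    """
    if iv_target.assembly != omap.target_assembly:
        raise ValueError(
            f"interval on {iv_target.assembly!r} but map target is {omap.target_assembly!r}"
        )
    inv = omap.invert()
    # duplications: more target-covering bases than the 1:1 subset allows
    back = lift(iv_target, inv, min_match)
    if back is None:
        return False
    fwd = lift(back, omap, min_match)
    if fwd is None:
        return False
    if fwd.chrom != iv_target.chrom:
        return False
    ov = min(fwd.end, iv_target.end) - max(fwd.start, iv_target.start)
    if ov <= 0:
        return False
    return ov / len(iv_target) >= min_match and ov / len(fwd) >= min_match
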