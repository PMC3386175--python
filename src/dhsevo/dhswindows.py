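"""Analysis windows over union DHS peaks, and count-based artifact filters.

The union of the strongest peaks across all samples is tiled with
fixed-width overlapping windows; per-window DNase cut counts are the
unit of the downstream differential test.  Three filters remove
artifact windows: a zero-count filter (regions absent from a species
are usually alignment dropouts), a sharp-peak filter (PCR/assembly
artifacts concentrate reads in a few bases) and a reciprocal-count
filter (counts must agree between native and lifted coordinates, which
CNVs and liftOver artifacts violate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dhsevo.ioformats import (
    CountMatrix,
    GenomicInterval,
    SampleMeta,
    ScoredPeakSet,
    merge_intervals,
)


@dataclass
class TilingConfig:
    window: int = 300
    default_overlap: int = 100
    edge_threshold: float = 0.10
    top_k_peaks: int = 100_000
    excluded_chroms: frozenset[str] = frozenset({"chrY"})

    def __post_init__(self) -> None:
        if not (0 < self.default_overlap < self.window):
            raise ValueError("need 0 < default_overlap < window")
        if not (0 < self.edge_threshold < 0.5):
            raise ValueError("need 0 < edge_threshold < 0.5")


@dataclass
class FilterConfig:
    sharp_span: int = 30
    sharp_fraction: float = 0.75
    sharp_min_reads: int = 10  # samples with fewer reads in the region cannot trigger
    reciprocal_tolerance: float = 0.10
    blacklist: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 < self.sharp_fraction <= 1):
            raise ValueError("need 0 < sharp_fraction <= 1")


@dataclass
class WindowSet:
    """Fixed-width windows tagged with the id of their source region."""

    windows: list[tuple[GenomicInterval, str]]

    def __len__(self) -> int:
        return len(self.windows)

    def intervals(self) -> list[GenomicInterval]:
        return [w for w, _ in self.windows]

    def ids(self) -> list[str]:
        return [f"{rid}:{w.chrom}:{w.start}-{w.end}" for w, rid in self.windows]


def union_top_peaks(peaksets: list[ScoredPeakSet], k: int) -> list[GenomicInterval]:
    """Union of the top-k peaks (by score) from each sample, merged.

    Score ties are broken by coordinate so the top-k set is
    deterministic.  Output intervals are sorted and disjoint
    (overlapping or book-ended peaks merge).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    selected: list[GenomicInterval] = []
    for ps in peaksets:
        if not ps.peaks:
            raise ValueError(f"peak set for {ps.sample.sample_id} is empty")
        ranked = sorted(ps.peaks, key=lambda p: (-p[1], p[0].chrom, p[0].start))
        selected.extend(iv for iv, _ in ranked[:k])
    return merge_intervals(selected)


def _round_half_even(x: float) -> int:
    # numpy.round implements banker's rounding
    return int(np.round(x))


def tile_region(
    region: GenomicInterval,
    cfg: TilingConfig | None = None,
    chrom_length: int | None = None,
) -> list[GenomicInterval]:
    """Tile one union-peak region with fixed-width overlapping windows.

    Regions no longer than the window width get a single window of the
    full width centered on the region (small peaks are expanded).  For
    longer regions, as many windows as fit with the default overlap are
    laid down; if that would discard at least ``edge_threshold`` of the
    region's bases on an edge, one more window is added and the overlap
    widened so the windows cover the region exactly.
    """
    cfg = cfg or TilingConfig()
    w = cfg.window
    L = len(region)
    if L <= w:
        mid = (region.start + region.end) // 2
        start = mid - w // 2
        if chrom_length is not None:
            start = min(start, chrom_length - w)
        start = max(start, 0)
        return [GenomicInterval(region.assembly, region.chrom, start, start + w)]
    step0 = w - cfg.default_overlap
    n = (L - w) // step0 + 1
    span = w + (n - 1) * step0
    leftover = L - span
    if leftover // 2 < cfg.edge_threshold * L:
        off0 = leftover // 2
        return [
            GenomicInterval(region.assembly, region.chrom, region.start + off0 + i * step0,
                            region.start + off0 + i * step0 + w)
            for i in range(n)
        ]
    # exact cover with n+1 windows and a fractional step
    s = (L - w) / n
    return [
        GenomicInterval(
            region.assembly,
            region.chrom,
            region.start + _round_half_even(i * s),
            region.start + _round_half_even(i * s) + w,
        )
        for i in range(n + 1)
    ]


def tile_regions(
    regions: list[GenomicInterval],
    cfg: TilingConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowSet:
    """Tile every region, excluding configured chromosomes (chrY by default)."""
    cfg = cfg or TilingConfig()
    windows: list[tuple[GenomicInterval, str]] = []
    for i, region in enumerate(regions):
        if region.chrom in cfg.excluded_chroms:
            continue
        clen = chrom_lengths.get(region.chrom) if chrom_lengths else None
        rid = f"region{i}"
        for wiv in tile_region(region, cfg, clen):
            windows.append((wiv, rid))
    return WindowSet(windows)


def count_cuts(
    windows: WindowSet,
    cuts: dict[str, dict[str, np.ndarray]],
) -> CountMatrix:
    """Count DNase cut sites (read 5' positions) per window per sample.

    ``cuts`` maps sample_id -> chrom -> sorted array of cut positions on
    the reference assembly (non-reference samples are lifted upstream).
    A cut at position p is in window [start, end) iff start <= p < end;
    overlapping windows may count the same cut more than once.
    """
    import pandas as pd

    sample_ids = list(cuts)
    sorted_cuts = {
        sid: {c: np.sort(np.asarray(pos)) for c, pos in per.items()}
        for sid, per in cuts.items()
    }
    data = np.zeros((len(windows), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        per = sorted_cuts[sid]
        for i, (iv, _) in enumerate(windows.windows):
            pos = per.get(iv.chrom)
            if pos is None or len(pos) == 0:
                continue
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            data[i, j] = hi - lo
    df = pd.DataFrame(data, index=windows.ids(), columns=sample_ids)
    return CountMatrix(df)


def zero_count_filter(cm: CountMatrix, meta: list[SampleMeta]) -> np.ndarray:
    """Keep a window iff every species has >= 1 cut in >= 1 individual.

    Windows with no signal at all in one species usually reflect
    alignment or reference dropouts rather than biology.
    """
    by_sid = {m.sample_id: m for m in meta}
    species = sorted({m.species for m in meta})
    keep = np.ones(cm.shape[0], dtype=bool)
    arr = cm.values()
    for sp in species:
        cols = [i for i, sid in enumerate(cm.sample_ids) if by_sid[sid].species == sp]
        if not cols:
            raise ValueError(f"no samples for species {sp}")
        keep &= arr[:, cols].max(axis=1) >= 1
    return keep


def sharp_peak_filter(
    region: GenomicInterval,
    cuts_by_sample: dict[str, np.ndarray],
    cfg: FilterConfig | None = None,
) -> bool:
    """Flag a region whose reads pile into a tiny span in any one sample.

    Returns True (flagged) iff in some sample a ``sharp_span``-wide
    sub-window holds at least ``sharp_fraction`` of that sample's reads
    in the region.  A single-sample artifact is enough to flag, but a
    sample must carry ``sharp_min_reads`` reads in the region to count:
    with a handful of basal-digestion reads the fraction is meaningless
    (two coincident background reads would otherwise flag the region).
    """
    cfg = cfg or FilterConfig()
    for pos in cuts_by_sample.values():
        pos = np.sort(np.asarray(pos))
        pos = pos[(pos >= region.start) & (pos < region.end)]
        total = len(pos)
        if total == 0 or total < cfg.sharp_min_reads:
            continue
        # max reads in any [p, p + span) — sliding the window start over
        # read positions attains the same maximum as a 1 bp slide
        hi = np.searchsorted(pos, pos + cfg.sharp_span, side="left")
        in_span = hi - np.arange(total)
        if in_span.max() >= cfg.sharp_fraction * total:
            return True
    return False


def reciprocal_count_filter(
    native_count: int,
    lifted_count: int,
    cfg: FilterConfig | None = None,
) -> bool:
    """Keep (True) iff lifted and native read counts agree within tolerance.

    Lifted counts far above native indicate collapse of several native
    regions onto one reference location; far below indicates spread to
    multiple locations.  Both are CNV/liftOver artifact signatures.
    """
    cfg = cfg or FilterConfig()
    if native_count < 0 or lifted_count < 0:
        raise ValueError("counts must be nonnegative")
    if native_count == 0:
        return lifted_count == 0
    return abs(lifted_count - native_count) <= cfg.reciprocal_tolerance * native_count
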