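"""Linking chromatin calls to genes and to evolutionary constraint.

Two complementary permutation tests connect differential chromatin to
differential expression: forward (are differential DHS regions' nearest
genes enriched for DE genes?) and reverse (do DE genes carry a
differential DHS call within a flanking window?).  Interval-overlap
significance against constrained elements uses a segment-preserving
null: all regions of a genomic compartment are rotated together by one
uniform offset within the compartment's concatenated coordinate space,
which preserves region lengths and spacing (a simplification of block-
randomization genome structure correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from dhsevo.ioformats import GeneModel, GenomicInterval, merge_intervals


@dataclass
class EnrichConfig:
    n_perm_forward: int = 100_000
    n_perm_reverse: int = 1000
    gene_window: int = 20_000
    n_randomizations_gsc: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_perm_forward, self.n_perm_reverse, self.n_randomizations_gsc) < 1:
            raise ValueError("permutation counts must be >= 1")


# ---------------------------------------------------------------------------
# nearest gene

def nearest_gene(region: GenomicInterval, genes: dict[str, GeneModel]) -> str | None:
    """Gene (merged isoform span) closest to the region on its chromosome.

    Distance ties break toward the smaller TSS distance, then the
    lexicographically smaller gene id.  Returns None when the region's
    chromosome carries no gene.
    """
    if not genes:
        raise ValueError("empty gene set")
    best: tuple[int, int, str] | None = None
    mid = (region.start + region.end) // 2
    for gid, g in genes.items():
        if g.interval.chrom != region.chrom:
            continue
        d = region.distance(g.interval)
        assert d is not None
        tss_d = abs(g.tss - mid)
        key = (d, tss_d, gid)
        if best is None or key < best:
            best = key
    return best[2] if best else None


def _subset_counts(
    per_gene_stat: np.ndarray,
    gene_ids: list[str],
    subset_size: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 10_000,
) -> np.ndarray:
    """Null statistic: sum of per-gene contributions over random gene subsets."""
    G = len(gene_ids)
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        keys = rng.random((k, G))
        idx = np.argpartition(keys, subset_size - 1, axis=1)[:, :subset_size]
        out[done : done + k] = per_gene_stat[idx].sum(axis=1)
        done += k
    return out


def forward_enrichment(
    dhs_regions: Sequence[GenomicInterval],
    de_set: set[str],
    all_expressed: list[str],
    genes: dict[str, GeneModel],
    cfg: EnrichConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, float, float]:
    """Do differential DHS regions sit nearest to DE genes more than chance?

    Observed = number of regions whose nearest gene is in ``de_set``.
    Null: redraw ``|de_set|`` genes uniformly without replacement from
    all expressed genes.  Returns (observed, p_enrich, p_deplete) with
    the (1+k)/(n+1) permutation estimator.
    """
    cfg = cfg or EnrichConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not set(de_set).issubset(all_expressed):
        raise ValueError("de_set must be a subset of all_expressed")
    nearest = [nearest_gene(r, genes) for r in dhs_regions]
    nearest = [g for g in nearest if g is not None]
    # regions count individually even when they share a nearest gene
    gene_hits = {g: 0 for g in all_expressed}
    for g in nearest:
        if g in gene_hits:
            gene_hits[g] += 1
    per_gene = np.array([gene_hits[g] for g in all_expressed], dtype=np.int64)
    observed = int(sum(gene_hits[g] for g in de_set))
    null = _subset_counts(per_gene, all_expressed, len(de_set), cfg.n_perm_forward, rng)
    p_enrich = (1 + int((null >= observed).sum())) / (cfg.n_perm_forward + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (cfg.n_perm_forward + 1)
    return observed, p_enrich, p_deplete


def reverse_enrichment(
    de_genes: set[str],
    call_regions: Sequence[GenomicInterval],
    all_expressed: list[str],
    genes: dict[str, GeneModel],
    cfg: EnrichConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, float, float]:
    """Do DE genes carry a differential DHS call within the flanking window?

    A gene matches when >= 1 call of the queried class lies within
    ``gene_window`` bases of its merged span (overlap included).  Null:
    equal-size random gene sets from all expressed genes.
    """
    cfg = cfg or EnrichConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if not set(de_genes).issubset(all_expressed):
        raise ValueError("de_genes must be a subset of all_expressed")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in call_regions:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for v in by_chrom.values():
        v.sort()
    has_call = {}
    for gid in all_expressed:
        g = genes.get(gid)
        if g is None:
            has_call[gid] = 0
            continue
        lo = g.interval.start - cfg.gene_window
        hi = g.interval.end + cfg.gene_window
        hit = 0
        for (s, e) in by_chrom.get(g.interval.chrom, ()):  # few calls; linear scan is fine
            if s < hi and lo < e:
                hit = 1
                break
        has_call[gid] = hit
    per_gene = np.array([has_call[g] for g in all_expressed], dtype=np.int64)
    observed = int(sum(has_call[g] for g in de_genes))
    null = _subset_counts(per_gene, all_expressed, len(de_genes), cfg.n_perm_reverse, rng)
    p_enrich = (1 + int((null >= observed).sum())) / (cfg.n_perm_reverse + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (cfg.n_perm_reverse + 1)
    return observed, p_enrich, p_deplete


# ---------------------------------------------------------------------------
# Fisher overlap

def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def fisher_overlap(
    set_a: Sequence[GenomicInterval],
    set_b: Sequence[GenomicInterval],
    universe: Sequence[GenomicInterval],
) -> tuple[np.ndarray, float]:
    """2x2 Fisher's exact test of co-membership over a region universe.

    Each universe region is classified by >= 1 bp overlap with set A and
    with set B; returns the table [[ab, aB], [Ab, AB']] ordering
    (in A & in B, in A only, in B only, neither) and the two-sided p.
    """
    if not universe:
        raise ValueError("empty universe")
    a = np.array([_overlaps_any(u, set_a) for u in universe])
    b = np.array([_overlaps_any(u, set_b) for u in universe])
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)


# ---------------------------------------------------------------------------
# constrained-element overlap with rotation null

@dataclass
class CompartmentResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    degenerate: bool = False


class _Compartment:
    """Concatenated coordinate space for one genomic compartment."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        ivs = merge_intervals(intervals)
        self.pieces = [(iv.chrom, iv.start, iv.end) for iv in ivs]
        lens = np.array([e - s for _, s, e in self.pieces], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lens)])
        self.total = int(self.offsets[-1])

    def to_concat(self, iv: GenomicInterval) -> list[tuple[int, int]]:
        out = []
        for i, (chrom, s, e) in enumerate(self.pieces):
            if iv.chrom != chrom:
                continue
            lo, hi = max(iv.start, s), min(iv.end, e)
            if lo < hi:
                base = int(self.offsets[i])
                out.append((base + lo - s, base + hi - s))
        return out


def _any_overlap_sorted(seg: tuple[int, int], starts: np.ndarray, ends: np.ndarray) -> bool:
    s, e = seg
    i = int(np.searchsorted(ends, s, side="right"))
    return i < len(starts) and starts[i] < e


def constrained_overlap(
    regions: Sequence[GenomicInterval],
    elements: Sequence[GenomicInterval],
    compartments: dict[str, Sequence[GenomicInterval]],
    cfg: EnrichConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, CompartmentResult]:
    """Observed vs rotation-null overlap fraction with constrained elements.

    Regions are assigned to the compartment holding the majority of
    their bases (ties: promoter > intron > intergenic).  Each
    randomization shifts all of a compartment's regions by one shared
    uniform offset in the compartment's concatenated space (wrapping),
    preserving lengths and spacing, and recomputes the fraction of
    regions overlapping >= 1 element.
    """
    cfg = cfg or EnrichConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    priority = {name: i for i, name in enumerate(("promoter", "intron", "intergenic"))}
    comps = {name: _Compartment(ivs) for name, ivs in compartments.items()}

    assigned: dict[str, list[GenomicInterval]] = {name: [] for name in comps}
    for r in regions:
        best_name, best_key = None, None
        for name, comp in comps.items():
            cov = sum(e - s for s, e in comp.to_concat(r))
            key = (-cov, priority.get(name, 99))
            if cov > 0 and (best_key is None or key < best_key):
                best_name, best_key = name, key
        if best_name is not None:
            assigned[best_name].append(r)

    results: dict[str, CompartmentResult] = {}
    for name, regs in assigned.items():
        if not regs:
            continue
        comp = comps[name]
        elem_segs = []
        for el in elements:
            elem_segs.extend(comp.to_concat(el))
        elem_segs.sort()
        estarts = np.array([s for s, _ in elem_segs], dtype=np.int64)
        eends = np.array([e for _, e in elem_segs], dtype=np.int64)
        region_segs = [comp.to_concat(r) for r in regs]
        total = comp.total
        if total == 0:
            continue

        def frac_overlap(offset: int) -> float:
            hits = 0
            for segs in region_segs:
                hit = False
                for (s, e) in segs:
                    s2 = (s + offset) % total
                    e2 = s2 + (e - s)
                    pieces = [(s2, min(e2, total))]
                    if e2 > total:
                        pieces.append((0, e2 - total))
                    for p in pieces:
                        if p[0] < p[1] and len(estarts) and _any_overlap_sorted(p, estarts, eends):
                            hit = True
                            break
                    if hit:
                        break
                hits += hit
            return hits / len(region_segs)

        observed = frac_overlap(0)
        null = np.array([
            frac_overlap(int(rng.integers(0, max(total, 1))))
            for _ in range(cfg.n_randomizations_gsc)
        ])
        mean, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            results[name] = CompartmentResult(observed, mean, sd, 0.0, degenerate=True)
        else:
            results[name] = CompartmentResult(observed, mean, sd, (observed - mean) / sd)
    return results


# ---------------------------------------------------------------------------
# conservation summaries

def conservation_summary(
    regions: Sequence[GenomicInterval],
    track: Sequence[tuple[GenomicInterval, float]],
) -> pd.DataFrame:
    """Base-weighted mean and max conservation score per region.

    Bases not covered by the track score 0.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int, float]]] = {}
    for iv, val in track:
        tmp.setdefault(iv.chrom, []).append((iv.start, iv.end, val))
    for chrom, rows in tmp.items():
        rows.sort()
        by_chrom[chrom] = (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows]),
        )
    recs = []
    for r in regions:
        entry = by_chrom.get(r.chrom)
        mean, mx, covered = 0.0, 0.0, 0
        if entry is not None:
            starts, ends, vals = entry
            lo = int(np.searchsorted(ends, r.start, side="right"))
            hi = int(np.searchsorted(starts, r.end, side="left"))
            tot = 0.0
            for i in range(lo, hi):
                ov = min(ends[i], r.end) - max(starts[i], r.start)
                if ov > 0:
                    tot += ov * vals[i]
                    covered += ov
                    mx = max(mx, vals[i])
            mean = tot / len(r)
        if covered < len(r):
            mx = max(mx, 0.0)
        recs.append({"chrom": r.chrom, "start": r.start, "end": r.end, "mean": mean, "max": mx})
    return pd.DataFrame(recs)
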