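"""End-to-end orchestration of the chromatin pipeline on in-memory data.

Stages, in dependency order: lift peaks and cuts to the reference
assembly, build union-peak windows, count cuts, apply the zero-count /
mapping / sharp-peak / reciprocal-count filters, fit the NB model, run
pairwise exact tests, polarize calls, and select Common regions.  The
command-line layer and the test-suite recovery checks both run through
these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dhsevo.diffchrom import (
    CommonConfig,
    DiffConfig,
    NBModel,
    RegionCallSet,
    classify_windows,
    fit_nb_model,
    pairwise_window_tests,
    select_common,
)
from dhsevo.dhswindows import (
    FilterConfig,
    TilingConfig,
    WindowSet,
    count_cuts,
    reciprocal_count_filter,
    sharp_peak_filter,
    tile_regions,
    union_top_peaks,
    zero_count_filter,
)
from dhsevo.ioformats import CountMatrix, GenomicInterval, SampleMeta, ScoredPeakSet
from dhsevo.orthomap import OrthologyMap, lift


@dataclass
class PipelineResult:
    windows: WindowSet
    counts: CountMatrix
    kept: np.ndarray  # post-filter window mask
    model: NBModel
    tests: pd.DataFrame
    calls: RegionCallSet
    common: RegionCallSet | None = None
    filter_stats: dict = field(default_factory=dict)


def lift_positions(
    positions: np.ndarray, omap: OrthologyMap, chrom: str
) -> np.ndarray:
    """Map single-base positions through an orthology map; unmapped drop out."""
    bl = [b for b in omap.blocks if b.src_chrom == chrom]
    if not bl:
        return np.array([], dtype=np.int64)
    starts = np.array([b.src_start for b in bl])
    ends = np.array([b.src_end for b in bl])
    tstarts = np.array([b.tgt_start for b in bl])
    tends = np.array([b.tgt_end for b in bl])
    fwd = np.array([b.strand == "+" for b in bl])
    positions = np.asarray(positions, dtype=np.int64)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
    idx = idx[ok]
    pos = positions[ok]
    off = pos - starts[idx]
    out = np.where(fwd[idx], tstarts[idx] + off, tends[idx] - 1 - off)
    return out.astype(np.int64)


def cuts_on_reference(
    cuts: dict[str, dict[str, np.ndarray]],
    meta: list[SampleMeta],
    maps: dict[str, OrthologyMap],
) -> dict[str, dict[str, np.ndarray]]:
    """Lift per-sample native cut positions to the reference assembly.

    Human cuts pass through; other species' positions go through their
    species->reference map (the CNV duplicate blocks intentionally send
    two native locations to one reference window).
    """
    by_sid = {m.sample_id: m for m in meta}
    out: dict[str, dict[str, np.ndarray]] = {}
    for sid, per in cuts.items():
        sp = by_sid[sid].species
        if sp == "human":
            out[sid] = {c: np.sort(p) for c, p in per.items()}
            continue
        omap = maps[sp]
        lifted: dict[str, list[np.ndarray]] = {}
        for chrom, pos in per.items():
            lp = lift_positions(pos, omap, chrom)
            # assume chrom names shared between assemblies in the map
            lifted.setdefault(chrom, []).append(lp)
        out[sid] = {
            c: np.sort(np.concatenate(v)) for c, v in lifted.items()
        }
    return out


def lift_peaks_to_reference(
    peaksets: list[ScoredPeakSet],
    maps: dict[str, OrthologyMap],
    min_match: float = 0.8,
) -> list[ScoredPeakSet]:
    out = []
    for ps in peaksets:
        sp = ps.sample.species
        if sp == "human":
            out.append(ps)
            continue
        omap = maps[sp]
        lifted = []
        for iv, score in ps.peaks:
            tgt = lift(iv, omap, min_match)
            if tgt is not None:
                lifted.append((tgt, score))
        out.append(ScoredPeakSet(ps.sample, lifted))
    return out


def run_chromatin_pipeline(
    peaksets: list[ScoredPeakSet],
    cuts: dict[str, dict[str, np.ndarray]],
    meta: list[SampleMeta],
    maps: dict[str, OrthologyMap],
    tiling: TilingConfig | None = None,
    filters: FilterConfig | None = None,
    diff_cfg: DiffConfig | None = None,
    common_cfg: CommonConfig | None = None,
    min_match: float = 0.8,
    select_common_regions: bool = True,
) -> PipelineResult:
    """Full species-specific DHS calling on reference-space inputs.

    ``peaksets`` and ``cuts`` are in native coordinates; they are lifted
    here.  Windows failing any filter never reach the exact test.
    """
    tiling = tiling or TilingConfig()
    filters = filters or FilterConfig()
    diff_cfg = diff_cfg or DiffConfig()
    stats: dict[str, int] = {}

    ref_peaks = lift_peaks_to_reference(peaksets, maps, min_match)
    regions = union_top_peaks(ref_peaks, tiling.top_k_peaks)
    windows = tile_regions(regions, tiling)
    stats["windows_tiled"] = len(windows)

    # windows must lift to every non-reference species
    inv = {sp: m.invert() for sp, m in maps.items()}
    mappable = []
    for iv, rid in windows.windows:
        ok = all(lift(iv, inv[sp], min_match) is not None for sp in inv)
        mappable.append(ok)
    windows = WindowSet([w for w, ok in zip(windows.windows, mappable) if ok])
    stats["windows_mappable"] = len(windows)

    ref_cuts = cuts_on_reference(cuts, meta, maps)
    cm = count_cuts(windows, ref_cuts)

    keep = zero_count_filter(cm, meta)
    stats["windows_zero_filtered"] = int((~keep).sum())

    # sharp peaks: evaluate per union region on reference-space cuts
    region_flagged: dict[str, bool] = {}
    by_region: dict[str, list[int]] = {}
    for i, (_, rid) in enumerate(windows.windows):
        by_region.setdefault(rid, []).append(i)
    for rid, idxs in by_region.items():
        ivs = [windows.windows[i][0] for i in idxs]
        span = GenomicInterval(
            ivs[0].assembly, ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)
        )
        per_sample = {
            sid: ref_cuts[sid].get(span.chrom, np.array([], dtype=np.int64))
            for sid in ref_cuts
        }
        region_flagged[rid] = sharp_peak_filter(span, per_sample, filters)
    sharp_mask = np.array([not region_flagged[rid] for _, rid in windows.windows])
    stats["windows_sharp_flagged"] = int((~sharp_mask).sum())
    keep &= sharp_mask

    # reciprocal count filter for non-reference species
    by_sid = {m.sample_id: m for m in meta}
    recip = np.ones(len(windows), dtype=bool)
    nonref_samples: dict[str, list[str]] = {}
    for sid in cm.sample_ids:
        sp = by_sid[sid].species
        if sp != "human":
            nonref_samples.setdefault(sp, []).append(sid)
    native_sorted = {
        sid: {c: np.sort(p) for c, p in cuts[sid].items()} for sid in cuts
    }
    for i, (iv, _) in enumerate(windows.windows):
        if not keep[i]:
            continue
        for sp, sids in nonref_samples.items():
            native_iv = lift(iv, inv[sp], min_match)
            if native_iv is None:
                recip[i] = False
                break
            native_n = 0
            lifted_n = 0
            for sid in sids:
                pos = native_sorted[sid].get(native_iv.chrom, np.array([]))
                native_n += int(
                    np.searchsorted(pos, native_iv.end) - np.searchsorted(pos, native_iv.start)
                )
                rp = ref_cuts[sid].get(iv.chrom, np.array([]))
                lifted_n += int(np.searchsorted(rp, iv.end) - np.searchsorted(rp, iv.start))
            if not reciprocal_count_filter(native_n, lifted_n, filters):
                recip[i] = False
                break
    stats["windows_reciprocal_dropped"] = int((keep & ~recip).sum())
    keep &= recip

    kept_windows = WindowSet([w for w, k in zip(windows.windows, keep) if k])
    cm_kept = CountMatrix(cm.counts.loc[kept_windows.ids()], cm.library_sizes.to_numpy())
    groups: dict[str, list[str]] = {}
    for sid in cm_kept.sample_ids:
        groups.setdefault(by_sid[sid].species, []).append(sid)
    model = fit_nb_model(cm_kept, groups, diff_cfg)
    tests = pairwise_window_tests(cm_kept, meta, model)
    calls = classify_windows(tests, kept_windows, diff_cfg)

    common = None
    if select_common_regions and calls.of_class("human_gain") and calls.of_class("chimp_gain"):
        left, right = _flank_counts(kept_windows, ref_cuts)
        common = select_common(
            cm_kept, kept_windows, calls, meta, common_cfg, neighbor_counts=(left, right)
        )
    return PipelineResult(
        windows=kept_windows,
        counts=cm_kept,
        kept=keep,
        model=model,
        tests=tests,
        calls=calls,
        common=common,
        filter_stats=stats,
    )


def _flank_counts(windows: WindowSet, ref_cuts) -> tuple[np.ndarray, np.ndarray]:
    """Pooled cut counts in same-width windows flanking each window."""
    n = len(windows)
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    for i, (iv, _) in enumerate(windows.windows):
        w = len(iv)
        lf = (max(iv.start - w, 0), iv.start)
        rt = (iv.end, iv.end + w)
        for per in ref_cuts.values():
            pos = per.get(iv.chrom)
            if pos is None:
                continue
            left[i] += int(np.searchsorted(pos, lf[1]) - np.searchsorted(pos, lf[0]))
            right[i] += int(np.searchsorted(pos, rt[1]) - np.searchsorted(pos, rt[0]))
    return left, right


# ---------------------------------------------------------------------------
# calibration experiments on planted count matrices

def fdr_calibration_experiment(
    n_windows: int = 20_000,
    effect_fraction: float = 0.05,
    fold: float = 4.0,
    phi: float = 0.2,
    mean: float = 50.0,
    lib_sigma: float = 0.3,
    seed: int = 42,
) -> dict:
    """Realized FDR of the polarized caller on counts with planted shifts.

    A fraction of windows gets a ``fold``-times mean shift in one random
    species.  A call is correct when its window was shifted upward in
    the called species; the realized FDR is false calls over all calls.
    """
    from dhsevo.diffchrom import DiffConfig, classify_windows, fit_nb_model, pairwise_window_tests
    from dhsevo.ioformats import GenomicInterval
    from dhsevo.syndata import simulate_count_experiment

    cm, meta, truth = simulate_count_experiment(
        n_windows, effect_fraction, fold, phi, mean, seed=seed, lib_sigma=lib_sigma
    )
    groups: dict[str, list[str]] = {}
    for m in meta:
        groups.setdefault(m.species, []).append(m.sample_id)
    cfg = DiffConfig(merge_adjacent=False)
    model = fit_nb_model(cm, groups, cfg)
    tests = pairwise_window_tests(cm, meta, model)
    ws = WindowSet(
        [
            (GenomicInterval("hg", "sim", 1000 * i + 1, 1000 * i + 301), rid)
            for i, rid in enumerate(cm.row_ids)
        ]
    )
    calls = classify_windows(tests, ws, cfg)
    false = 0
    for c in calls.calls:
        rid = c.window_rows[0].split(":")[0]
        shifted_in = truth.loc[rid, "shifted_species"]
        if not (c.call_class.endswith("_gain") and shifted_in == c.call_class.split("_")[0]):
            false += 1
    n_calls = len(calls.calls)
    return {
        "n_calls": n_calls,
        "n_false": false,
        "fdr_percent": 100.0 * false / n_calls if n_calls else 0.0,
        "dispersion": model.dispersion,
    }


def replicate_control_experiment(
    n_windows: int = 20_000,
    effect_fraction: float = 0.05,
    fold: float = 4.0,
    phi: float = 0.2,
    mean: float = 50.0,
    lib_sigma: float = 0.3,
    seed: int = 7,
    fdr: float = 0.01,
) -> dict:
    """Same-species replicate split vs a true between-species comparison.

    Two groups of three human-like samples are drawn from identical NB
    means; a chimp-like group carries planted shifts.  Both comparisons
    run through the same exact test and BH threshold; the ratio of
    within-human to human-chimp calls measures specificity.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    from dhsevo.diffchrom import (
        equalize_libraries,
        estimate_common_dispersion,
        nb_exact_test_batch,
        tmm_factors,
    )
    from dhsevo.ioformats import CountMatrix

    rng = np.random.default_rng(seed)
    n_eff = int(round(effect_fraction * n_windows))
    eff = rng.choice(n_windows, size=n_eff, replace=False)
    mu_c = np.full(n_windows, mean)
    mu_c[eff] *= fold
    cols = {}
    for grp, mu in (("h1", np.full(n_windows, mean)), ("h2", np.full(n_windows, mean)),
                    ("c", mu_c)):
        for i in (1, 2, 3):
            lf = float(np.exp(rng.normal(0.0, lib_sigma))) if lib_sigma > 0 else 1.0
            r = 1.0 / phi
            p = r / (r + mu * lf)
            cols[f"{grp}_{i}"] = rng.negative_binomial(r, p)
    cm = CountMatrix(pd.DataFrame(cols, index=[f"w{i}" for i in range(n_windows)]))
    groups = {
        "h1": ["h1_1", "h1_2", "h1_3"],
        "h2": ["h2_1", "h2_2", "h2_3"],
        "c": ["c_1", "c_2", "c_3"],
    }
    factors = tmm_factors(cm)
    eff_lib = cm.library_sizes * factors
    disp = estimate_common_dispersion(cm, groups, effective_lib_sizes=eff_lib)
    eq = equalize_libraries(cm, eff_lib)

    def n_calls(a: list[str], b: list[str]) -> int:
        p = nb_exact_test_batch(eq[a].to_numpy(), eq[b].to_numpy(), disp)
        q = multipletests(p, method="fdr_bh")[1]
        return int((q <= fdr).sum())

    within = n_calls(groups["h1"], groups["h2"])
    between = n_calls(groups["h1"], groups["c"])
    return {
        "within_calls": within,
        "between_calls": between,
        "ratio_percent": 100.0 * within / between if between else float("nan"),
        "dispersion": disp,
    }


# ---------------------------------------------------------------------------
# truth matching helpers (synthetic-data evaluation)

def match_calls_to_truth(
    calls: RegionCallSet,
    truth: pd.DataFrame,
    classes: tuple[str, ...] = ("human_gain", "human_loss", "chimp_gain", "chimp_loss"),
) -> pd.DataFrame:
    """Per planted element: whether a same-class call overlaps it (human coords)."""
    rows = []
    for _, el in truth.iterrows():
        if el["class"] not in classes:
            continue
        hit = False
        for c in calls.of_class(el["class"]):
            if (
                c.region.chrom == el["chrom"]
                and c.region.start < el["human_end"]
                and el["human_start"] < c.region.end
            ):
                hit = True
                break
        rows.append({"element_id": el["element_id"], "class": el["class"], "recovered": hit})
    return pd.DataFrame(rows)
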