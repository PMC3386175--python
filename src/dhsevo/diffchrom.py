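"""Negative-binomial differential accessibility and Common-region selection.

The classic count-based differential test is applied to window cut
counts: TMM library normalization, a single common dispersion estimated
by conditional maximum likelihood, and an exact conditional test on the
split of group sums given their total.  Pairwise species tests are
combined with outgroup polarization: a human gain is a window with
significantly more signal in human than in BOTH chimp and macaque, so
the change is placed on the human branch.  Significant neighboring
windows merge into regions.

Common regions are windows similarly open in all nine samples, selected
through per-sample quantile envelopes derived from the species-specific
gain regions so their intensity matches the differential sets, then
cleansed of "appendages" (shoulders of stronger neighboring sites).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from dhsevo.ioformats import CountMatrix, GenomicInterval, SampleMeta, merge_intervals
from dhsevo.dhswindows import WindowSet

SPECIES_PAIRS = (("human", "chimp"), ("human", "macaque"), ("chimp", "macaque"))


@dataclass
class DiffConfig:
    fdr: float = 0.01
    tmm_trim_M: float = 0.30
    tmm_trim_A: float = 0.05
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0,1)")


@dataclass
class CommonConfig:
    q_lo: float = 0.20
    q_hi: float = 0.80
    target_n: int = 1000
    appendage_fraction: float = 0.80
    narrowing_step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.q_lo < self.q_hi <= 1):
            raise ValueError("need 0 <= q_lo < q_hi <= 1")


@dataclass
class NBModel:
    """Fitted normalization + dispersion for the NB exact test."""

    factors: pd.Series  # TMM factors, geometric mean 1
    dispersion: float
    effective_lib_sizes: pd.Series


@dataclass
class RegionCall:
    region: GenomicInterval
    call_class: str  # human_gain | human_loss | chimp_gain | chimp_loss | common
    window_rows: list[str]
    p: dict[str, float] = field(default_factory=dict)
    q: dict[str, float] = field(default_factory=dict)


@dataclass
class RegionCallSet:
    calls: list[RegionCall]

    def of_class(self, cls: str) -> list[RegionCall]:
        return [c for c in self.calls if c.call_class == cls]

    def classes(self) -> set[str]:
        return {c.call_class for c in self.calls}


# ---------------------------------------------------------------------------
# TMM normalization

def tmm_factors(cm: CountMatrix, cfg: DiffConfig | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the column whose 75th count percentile
    (scaled by library size) is closest to the mean across samples.  M
    (log fold) and A (log abundance) values are computed on rows
    positive in both sample and reference; the extreme ``tmm_trim_M``
    of M and ``tmm_trim_A`` of A are trimmed and the remaining M values
    averaged with inverse-variance (binomial approximation) weights.
    """
    cfg = cfg or DiffConfig()
    if cm.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    y = cm.values().astype(float)
    lib = cm.library_sizes.to_numpy().astype(float)
    safe_lib = np.where(lib > 0, lib, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([
            np.percentile(y[:, j][y[:, j] > 0] / safe_lib[j], 75) if (y[:, j] > 0).any() else 0.0
            for j in range(y.shape[1])
        ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(y.shape[1])
    yr, Nr = y[:, ref], safe_lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yk, Nk = y[:, j], safe_lib[j]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(f"sample {cm.sample_ids[j]} shares no positive rows with reference")
            continue
        pk, pr = yk[ok] / Nk, yr[ok] / Nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        w = 1.0 / ((Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok]))
        keep = _double_trim_mask(M, A, cfg.tmm_trim_M, cfg.tmm_trim_A)
        if not keep.any():
            continue
        factors[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.sample_ids)


def _double_trim_mask(M: np.ndarray, A: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    n = len(M)
    rank_m = np.argsort(np.argsort(M, kind="stable"), kind="stable")
    rank_a = np.argsort(np.argsort(A, kind="stable"), kind="stable")
    lo_m, hi_m = np.floor(n * trim_m), np.ceil(n * (1 - trim_m)) - 1
    lo_a, hi_a = np.floor(n * trim_a), np.ceil(n * (1 - trim_a)) - 1
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


def fit_nb_model(cm: CountMatrix, groups: dict[str, list[str]], cfg: DiffConfig | None = None) -> NBModel:
    """TMM factors plus common dispersion for a grouped count matrix."""
    cfg = cfg or DiffConfig()
    factors = tmm_factors(cm, cfg)
    eff = cm.library_sizes * factors
    phi = estimate_common_dispersion(cm, groups, effective_lib_sizes=eff)
    return NBModel(factors=factors, dispersion=phi, effective_lib_sizes=eff)


# ---------------------------------------------------------------------------
# common dispersion by conditional maximum likelihood

def equalize_libraries(cm: CountMatrix, effective_lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Scale counts to the geometric-mean effective library size, rounded.

    The conditional likelihood and exact test below assume equal library
    sizes; scaling+rounding is the tractable stand-in for pseudocount
    quantile adjustment.
    """
    eff = (effective_lib_sizes if effective_lib_sizes is not None else cm.library_sizes).to_numpy(dtype=float)
    if (eff <= 0).any():
        raise ValueError("effective library sizes must be positive")
    target = np.exp(np.mean(np.log(eff)))
    scaled = cm.values() * (target / eff)[None, :]
    return pd.DataFrame(np.rint(scaled).astype(np.int64), index=cm.row_ids, columns=cm.sample_ids)


def _cond_loglik(phi: float, group_counts: list[np.ndarray]) -> float:
    """Summed NB conditional log-likelihood over windows and groups.

    Each element of ``group_counts`` is a (windows x n_g) array of
    equal-library counts for one group.
    """
    r = 1.0 / phi
    total = 0.0
    for y in group_counts:
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            + len(z) * gammaln(n * r)
            - np.sum(gammaln(z + n * r))
            - len(z) * n * gammaln(r)
        )
    return total


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: dict[str, list[str]],
    effective_lib_sizes: pd.Series | None = None,
    bounds: tuple[float, float] = (1e-4, 10.0),
) -> float:
    """Maximize the conditional NB log-likelihood in phi (golden section on ln phi)."""
    eq = equalize_libraries(cm, effective_lib_sizes)
    arrs = []
    for g, sids in groups.items():
        if len(sids) < 2:
            raise ValueError(f"group {g} needs >= 2 samples for dispersion estimation")
        arrs.append(eq[sids].to_numpy())
    if all((a.sum() == 0) for a in arrs):
        raise ValueError("all counts are zero; cannot estimate dispersion")
    res = minimize_scalar(
        lambda lnphi: -_cond_loglik(float(np.exp(lnphi)), arrs),
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    phi = float(np.exp(np.clip(res.x, np.log(bounds[0]), np.log(bounds[1]))))
    return phi


# ---------------------------------------------------------------------------
# NB exact test

_TIE_EPS = 1e-9  # log-scale tolerance for "as or more extreme" probability ties


def _nb_logpmf(k: np.ndarray, r: float, mu: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    lp = np.log(r / (r + mu))
    lq = np.log(mu / (r + mu)) if mu > 0 else -np.inf
    out = gammaln(k + r) - gammaln(r) - gammaln(k + 1) + r * lp
    return out + np.where(k > 0, k * lq, 0.0)


def nb_exact_test(yA: np.ndarray, yB: np.ndarray, phi: float) -> float:
    """Two-sided exact conditional NB test on group sums.

    Counts must already be equalized to a common library size.  The sum
    of n iid NB(m, phi) variables is NB(n*m, phi/n); conditioning on the
    total t of both group sums, the p-value is the probability of all
    splits (a, t-a) whose conditional probability does not exceed the
    observed split's.
    """
    yA = np.asarray(yA, dtype=float)
    yB = np.asarray(yB, dtype=float)
    nA, nB = len(yA), len(yB)
    if nA < 1 or nB < 1:
        raise ValueError("both groups need >= 1 sample")
    sA, t = float(yA.sum()), float(yA.sum() + yB.sum())
    if t == 0:
        return 1.0
    m = t / (nA + nB)
    a = np.arange(int(t) + 1)
    lpA = _nb_logpmf(a, nA / phi, nA * m)
    lpB = _nb_logpmf(int(t) - a, nB / phi, nB * m)
    logjoint = lpA + lpB
    logZ = _logsumexp(logjoint)
    obs = logjoint[int(round(sA))]
    sel = logjoint <= obs + _TIE_EPS
    return float(min(1.0, np.exp(_logsumexp(logjoint[sel]) - logZ)))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def nb_exact_test_batch(YA: np.ndarray, YB: np.ndarray, phi: float, chunk: int = 2048) -> np.ndarray:
    """Vectorized :func:`nb_exact_test` over many windows (rows)."""
    YA = np.asarray(YA, dtype=np.int64)
    YB = np.asarray(YB, dtype=np.int64)
    nA, nB = YA.shape[1], YB.shape[1]
    sA = YA.sum(axis=1).astype(np.int64)
    t = sA + YB.sum(axis=1).astype(np.int64)
    pvals = np.ones(len(t))
    nz = np.where(t > 0)[0]
    rA, rB = nA / phi, nB / phi
    lg_rA, lg_rB = gammaln(rA), gammaln(rB)
    for start in range(0, len(nz), chunk):
        idx = nz[start : start + chunk]
        tmax = int(t[idx].max())
        a = np.arange(tmax + 1)[None, :].astype(float)
        tt = t[idx][:, None].astype(float)
        m = tt / (nA + nB)
        muA, muB = nA * m, nB * m
        b = tt - a
        valid = a <= tt
        with np.errstate(divide="ignore", invalid="ignore"):
            lpA = gammaln(a + rA) - lg_rA - gammaln(a + 1) + rA * np.log(rA / (rA + muA)) \
                + np.where(a > 0, a * np.log(muA / (rA + muA)), 0.0)
            lpB = gammaln(b + rB) - lg_rB - gammaln(b + 1) + rB * np.log(rB / (rB + muB)) \
                + np.where(b > 0, b * np.log(muB / (rB + muB)), 0.0)
        logjoint = np.where(valid, lpA + lpB, -np.inf)
        mx = logjoint.max(axis=1, keepdims=True)
        w = np.exp(logjoint - mx)
        Z = w.sum(axis=1)
        obs = np.take_along_axis(logjoint, sA[idx][:, None], axis=1)
        sel = logjoint <= obs + _TIE_EPS
        pvals[idx] = np.minimum(1.0, (w * sel).sum(axis=1) / Z)
    return pvals


# ---------------------------------------------------------------------------
# pairwise tests + polarized classification

def pairwise_window_tests(
    cm: CountMatrix,
    meta: list[SampleMeta],
    model: NBModel,
) -> pd.DataFrame:
    """Exact-test p-values and direction for every species pair, per window.

    Returns a frame indexed like ``cm`` with columns ``p_<a>_<b>``,
    ``mean_<species>`` (normalized per-window means).
    """
    by_sid = {m.sample_id: m for m in meta}
    eq = equalize_libraries(cm, model.effective_lib_sizes)
    cols: dict[str, list[str]] = {}
    for sid in cm.sample_ids:
        cols.setdefault(by_sid[sid].species, []).append(sid)
    out = pd.DataFrame(index=cm.counts.index)
    for sp, sids in cols.items():
        out[f"mean_{sp}"] = eq[sids].mean(axis=1)
    for a, b in SPECIES_PAIRS:
        if a in cols and b in cols:
            out[f"p_{a}_{b}"] = nb_exact_test_batch(
                eq[cols[a]].to_numpy(), eq[cols[b]].to_numpy(), model.dispersion
            )
    return out


def classify_windows(
    tests: pd.DataFrame,
    windows: WindowSet,
    cfg: DiffConfig | None = None,
) -> RegionCallSet:
    """Polarize pairwise significance into branch-specific gain/loss calls.

    BH adjustment is applied per pairwise comparison across all windows.
    A window is a human gain iff both human-vs-chimp and human-vs-macaque
    are significant with human higher; losses and the chimp branch are
    symmetric.  Windows matching more than one class (unpolarizable) get
    none.  Same-class overlapping or book-ended windows from the same
    source region merge into one region.
    """
    cfg = cfg or DiffConfig()
    q = {}
    for a, b in SPECIES_PAIRS:
        col = f"p_{a}_{b}"
        if col in tests:
            q[(a, b)] = multipletests(tests[col].to_numpy(), method="fdr_bh")[1]
    mh = tests["mean_human"].to_numpy()
    mc = tests["mean_chimp"].to_numpy()
    mm = tests["mean_macaque"].to_numpy()
    q_hc, q_hm, q_cm = q[("human", "chimp")], q[("human", "macaque")], q[("chimp", "macaque")]
    f = cfg.fdr
    cand = {
        "human_gain": (q_hc <= f) & (q_hm <= f) & (mh > mc) & (mh > mm),
        "human_loss": (q_hc <= f) & (q_hm <= f) & (mh < mc) & (mh < mm),
        "chimp_gain": (q_hc <= f) & (q_cm <= f) & (mc > mh) & (mc > mm),
        "chimp_loss": (q_hc <= f) & (q_cm <= f) & (mc < mh) & (mc < mm),
    }
    stack = np.vstack([cand[k] for k in cand])
    n_match = stack.sum(axis=0)
    labels = np.array(list(cand))
    window_class = np.where(n_match == 1, labels[stack.argmax(axis=0)], "none")

    qframe = pd.DataFrame(
        {"q_human_chimp": q_hc, "q_human_macaque": q_hm, "q_chimp_macaque": q_cm},
        index=tests.index,
    )
    calls: list[RegionCall] = []
    if cfg.merge_adjacent:
        calls = _merge_window_calls(window_class, windows, tests, qframe)
    else:
        for i, (iv, rid) in enumerate(windows.windows):
            if window_class[i] != "none":
                calls.append(
                    RegionCall(iv, str(window_class[i]), [windows.ids()[i]],
                               p=_row_dict(tests, i), q=_row_dict(qframe, i))
                )
    return RegionCallSet(calls)


def _row_dict(df: pd.DataFrame, i: int) -> dict[str, float]:
    return {c: float(df.iloc[i][c]) for c in df.columns if c.startswith(("p_", "q_"))}


def _merge_window_calls(window_class, windows: WindowSet, tests, qframe) -> list:
    ids = windows.ids()
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (_, rid) in enumerate(windows.windows):
        if window_class[i] == "none":
            continue
        groups.setdefault((rid, str(window_class[i])), []).append(i)
    calls = []
    for (rid, cls), idxs in groups.items():
        idxs = sorted(idxs, key=lambda i: windows.windows[i][0].start)
        runs: list[list[int]] = [[idxs[0]]]
        for i in idxs[1:]:
            prev = windows.windows[runs[-1][-1]][0]
            cur = windows.windows[i][0]
            if cur.start <= prev.end:  # overlapping or book-ended
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            ivs = [windows.windows[i][0] for i in run]
            merged = merge_intervals(ivs)[0]
            pvals: dict[str, float] = {}
            qvals: dict[str, float] = {}
            for c in tests.columns:
                if c.startswith("p_"):
                    pvals[c] = float(tests.iloc[run][c].min())
            for c in qframe.columns:
                qvals[c] = float(qframe.iloc[run][c].min())
            calls.append(RegionCall(merged, cls, [ids[i] for i in run], p=pvals, q=qvals))
    calls.sort(key=lambda c: (c.region.chrom, c.region.start))
    return calls


# ---------------------------------------------------------------------------
# Common regions

def select_common(
    cm: CountMatrix,
    windows: WindowSet,
    specific_calls: RegionCallSet,
    meta: list[SampleMeta],
    cfg: CommonConfig | None = None,
    neighbor_counts: tuple[np.ndarray, np.ndarray] | None = None,
) -> RegionCallSet:
    """Intensity-matched Common windows via per-sample quantile envelopes.

    Each sample's envelope is the [q_lo, q_hi] quantile band of its
    counts over its own species' gain regions (macaque, which has no
    specific set, uses the pooled human+chimp gains).  Candidate windows
    must sit inside every sample's envelope; the band narrows
    symmetrically until the candidate list is close to ``target_n``,
    then the appendage filter removes shoulders of stronger sites.

    ``neighbor_counts`` optionally supplies pooled (left, right) flank
    counts per window for the appendage filter; without it the filter
    is skipped.
    """
    cfg = cfg or CommonConfig()
    by_sid = {m.sample_id: m for m in meta}
    gain_rows = {
        "human": _rows_of(specific_calls, "human_gain"),
        "chimp": _rows_of(specific_calls, "chimp_gain"),
    }
    if not gain_rows["human"] or not gain_rows["chimp"]:
        raise ValueError("need gain calls for both human and chimp to build envelopes")
    # macaque has no specific set of its own; its envelope comes from the
    # regions where macaque IS hypersensitive at differential-site intensity:
    # the pooled human+chimp losses (falling back to pooled gains)
    loss_rows = _rows_of(specific_calls, "human_loss") + _rows_of(specific_calls, "chimp_loss")
    gain_rows["macaque"] = loss_rows or (gain_rows["human"] + gain_rows["chimp"])
    arr = cm.counts
    env_rows = {
        sid: arr.loc[gain_rows[by_sid[sid].species], sid].to_numpy()
        for sid in cm.sample_ids
    }
    q_lo, q_hi = cfg.q_lo, cfg.q_hi
    ids = windows.ids()
    vals = cm.counts.loc[ids].to_numpy()
    candidate = np.zeros(len(ids), dtype=bool)
    while True:
        inside = np.ones(len(ids), dtype=bool)
        for j, sid in enumerate(cm.sample_ids):
            lo = np.quantile(env_rows[sid], q_lo)
            hi = np.quantile(env_rows[sid], q_hi)
            inside &= (vals[:, j] >= lo) & (vals[:, j] <= hi)
        candidate = inside
        if candidate.sum() <= cfg.target_n * 1.3:
            break
        q_lo += cfg.narrowing_step
        q_hi -= cfg.narrowing_step
        if q_lo >= q_hi:
            break
    keep = candidate
    if neighbor_counts is not None:
        left, right = neighbor_counts
        pooled_counts = vals.sum(axis=1)
        app = np.array([
            appendage_filter(int(pooled_counts[i]), int(left[i]), int(right[i]), cfg)
            for i in range(len(ids))
        ])
        keep = keep & app
    calls = [
        RegionCall(windows.windows[i][0], "common", [ids[i]])
        for i in np.where(keep)[0]
    ]
    return RegionCallSet(calls)


def _rows_of(calls: RegionCallSet, cls: str) -> list[str]:
    rows: list[str] = []
    for c in calls.of_class(cls):
        rows.extend(c.window_rows)
    return rows


def appendage_filter(
    window_count: int,
    left_count: int,
    right_count: int,
    cfg: CommonConfig | None = None,
) -> bool:
    """Keep (True) iff the window holds >= ``appendage_fraction`` of each flank.

    Counts are pooled over all samples; a chromosome-edge flank counts
    as zero.  A window much weaker than a neighbor is the shoulder of a
    stronger DHS site, not a standalone one.
    """
    cfg = cfg or CommonConfig()
    return (
        window_count >= cfg.appendage_fraction * left_count
        and window_count >= cfg.appendage_fraction * right_count
    )
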