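"""Branch-specific acceleration test on four-primate region alignments.

A neutral HKY85 model (kappa, base frequencies, branch lengths on the
fixed topology ((human,chimp),macaque,orangutan)) is fitted by maximum
likelihood to a local intronic background assumed to evolve neutrally.
For a candidate region, branch rates are rescaled relative to that
background by two multipliers: rho on the non-focal branches and zeta
on the focal (human or chimp) branch.  The null model constrains the
focal branch to neutral-or-slower (zeta <= 1); the alternative frees
zeta, so acceleration (zeta > 1, candidate positive selection) can be
detected by a likelihood-ratio test whose statistic is referred to the
50:50 chi2(0)/chi2(1) boundary mixture.  Uncertainty in the background
is absorbed by bootstrapping its columns and averaging the p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, mannwhitneyu

from dhsevo.ioformats import GeneModel, GenomicInterval

TAXA = ("human", "chimp", "macaque", "orangutan")
#: branch names: four terminal branches plus the internal human-chimp stem
BRANCHES = ("human", "chimp", "hc", "macaque", "orangutan")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


@dataclass
class AlignmentBlock:
    """A 4-taxon alignment; rows ordered human, chimp, macaque, orangutan."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        missing = [t for t in TAXA if t not in self.sequences]
        if missing:
            raise ValueError(f"alignment missing taxa {missing}")
        lens = {len(self.sequences[t]) for t in TAXA}
        if len(lens) != 1:
            raise ValueError("alignment rows differ in length")
        for t in TAXA:
            bad = set(self.sequences[t].upper()) - set("ACGTN-")
            if bad:
                raise ValueError(f"invalid characters {bad} in {t}")

    def __len__(self) -> int:
        return len(self.sequences[TAXA[0]])

    def codes(self) -> np.ndarray:
        """(4, L) integer codes; 4 = N (missing), 5 = gap."""
        return np.array(
            [[_CODE[c] for c in self.sequences[t].upper()] for t in TAXA], dtype=np.int8
        )

    def complete_columns(self) -> np.ndarray:
        """Codes of columns without gaps in any taxon (N retained as missing)."""
        c = self.codes()
        keep = (c != 5).all(axis=0)
        return c[:, keep]

    def concat(self, other: "AlignmentBlock") -> "AlignmentBlock":
        return AlignmentBlock({t: self.sequences[t] + other.sequences[t] for t in TAXA})

    def slice_columns(self, idx: np.ndarray) -> "AlignmentBlock":
        return AlignmentBlock(
            {t: "".join(self.sequences[t][i] for i in idx) for t in TAXA}
        )


@dataclass
class SubstitutionModel:
    """HKY85 with branch lengths (expected substitutions/site)."""

    kappa: float
    pi: np.ndarray
    branch_lengths: dict[str, float]
    flagged: bool = False  # set when the data carried no variation

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi < 0).any():
            raise ValueError("pi must be a distribution")
        for k in BRANCHES:
            if self.branch_lengths.get(k, 0.0) < 0:
                raise ValueError(f"negative branch length on {k}")


@dataclass
class SelectionConfig:
    background_target: int = 2000
    max_window: int = 100_000
    n_bootstrap: int = 50
    splice_trim: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_target <= 0:
            raise ValueError("background_target must be positive")


@dataclass
class SelectionResult:
    region_id: str
    branch: str
    lnl_null: list[float]
    lnl_alt: list[float]
    zeta: float
    rho: float
    p: float
    low_information: bool = False


# ---------------------------------------------------------------------------
# HKY machinery

def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per unit time."""
    pi = np.asarray(pi, dtype=float)
    Q = np.tile(pi, (4, 1)).astype(float)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T transitions
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def _eigen(kappa: float, pi: np.ndarray):
    Q = hky_rate_matrix(kappa, pi)
    sq = np.sqrt(np.maximum(pi, 1e-300))
    S = (Q * sq[:, None]) / sq[None, :]
    S = (S + S.T) / 2
    lam, V = np.linalg.eigh(S)
    U = V / sq[:, None]  # columns scaled: P(t) = D(sq) V e^{lam t} V' D(1/sq)
    Uinv = V.T * sq[None, :]
    return lam, U, Uinv


def transition_matrices(
    kappa: float, pi: np.ndarray, lengths: dict[str, float]
) -> dict[str, np.ndarray]:
    lam, U, Uinv = _eigen(kappa, pi)
    out = {}
    for name, t in lengths.items():
        P = (U * np.exp(lam * max(t, 0.0))[None, :]) @ Uinv
        out[name] = np.clip(P, 0.0, None)
    return out


def _pattern_compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pats, counts = np.unique(codes.T, axis=0, return_counts=True)
    return pats, counts.astype(float)


def _leaf_partial(col: np.ndarray) -> np.ndarray:
    """(n_patterns, 4) partial likelihoods for one taxon's pattern column."""
    n = len(col)
    L = np.zeros((n, 4))
    obs = col < 4
    L[obs, col[obs].astype(int)] = 1.0
    L[~obs, :] = 1.0  # N: missing data
    return L


def pruning_loglik(
    patterns: np.ndarray,
    weights: np.ndarray,
    kappa: float,
    pi: np.ndarray,
    lengths: dict[str, float],
) -> float:
    """Felsenstein pruning on ((human,chimp),macaque,orangutan).

    ``patterns`` is (n_patterns, 4) with taxon columns in TAXA order and
    codes 0-3 (bases) or 4 (missing).
    """
    P = transition_matrices(kappa, pi, lengths)
    Lh = _leaf_partial(patterns[:, 0])
    Lc = _leaf_partial(patterns[:, 1])
    Lm = _leaf_partial(patterns[:, 2])
    Lo = _leaf_partial(patterns[:, 3])
    Lx = (Lh @ P["human"].T) * (Lc @ P["chimp"].T)
    Lroot = (Lx @ P["hc"].T) * (Lm @ P["macaque"].T) * (Lo @ P["orangutan"].T)
    site = Lroot @ pi
    return float(np.dot(weights, np.log(np.maximum(site, 1e-300))))


def alignment_loglik(aln: AlignmentBlock, model: SubstitutionModel) -> float:
    pats, w = _pattern_compress(aln.complete_columns())
    return pruning_loglik(pats, w, model.kappa, model.pi, model.branch_lengths)


# ---------------------------------------------------------------------------
# neutral model fit

def empirical_frequencies(aln: AlignmentBlock) -> np.ndarray:
    c = aln.codes()
    counts = np.array([(c == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def fit_neutral(
    background: AlignmentBlock,
    kappa_bounds: tuple[float, float] = (0.05, 20.0),
    blen_bounds: tuple[float, float] = (0.0, 3.0),
    tol: float = 1e-6,
    max_sweeps: int = 60,
) -> SubstitutionModel:
    """ML fit of kappa and the five branch lengths by coordinate descent.

    Base frequencies are the empirical frequencies of the background.
    Needs >= 200 gap-free columns; invariant alignments return zero
    branch lengths with kappa 1, flagged.
    """
    codes = background.complete_columns()
    if codes.shape[1] < 200:
        raise ValueError(f"background has {codes.shape[1]} gap-free columns; need >= 200")
    pi = empirical_frequencies(background)
    pats, w = _pattern_compress(codes)
    # no variation among observed bases -> nothing to estimate
    base_sets = [set(row[row < 4].tolist()) for row in pats]
    if all(len(s) <= 1 for s in base_sets):
        return SubstitutionModel(1.0, pi, {k: 0.0 for k in BRANCHES}, flagged=True)

    kappa = 2.0
    lengths = {k: 0.05 for k in BRANCHES}

    def lnl() -> float:
        return pruning_loglik(pats, w, kappa, pi, lengths)

    cur = lnl()
    for _ in range(max_sweeps):
        prev = cur
        res = minimize_scalar(
            lambda k: -pruning_loglik(pats, w, float(k), pi, lengths),
            bounds=kappa_bounds, method="bounded", options={"xatol": 1e-7},
        )
        kappa = float(res.x)
        for name in BRANCHES:
            res = minimize_scalar(
                lambda b, nm=name: -pruning_loglik(
                    pats, w, kappa, pi, {**lengths, nm: float(b)}
                ),
                bounds=blen_bounds, method="bounded", options={"xatol": 1e-9},
            )
            lengths[name] = float(res.x)
        cur = lnl()
        if abs(cur - prev) < tol:
            break
    # snap numerically-zero branches
    lengths = {k: (0.0 if v < 1e-7 else v) for k, v in lengths.items()}
    return SubstitutionModel(kappa, pi, lengths)


# ---------------------------------------------------------------------------
# branch LRT

def _scaled_lengths(model: SubstitutionModel, branch: str, rho: float, zeta: float) -> dict[str, float]:
    return {
        k: (zeta if k == branch else rho) * v for k, v in model.branch_lengths.items()
    }


def _profile_lnl(
    pats: np.ndarray,
    w: np.ndarray,
    model: SubstitutionModel,
    branch: str,
    zeta_bounds: tuple[float, float],
    start: tuple[float, float] = (0.5, 0.5),
) -> tuple[float, float, float]:
    """Maximize lnL over rho in [0,1] and zeta in zeta_bounds."""
    rho, zeta = start
    zeta = float(np.clip(zeta, *zeta_bounds))
    cur = pruning_loglik(pats, w, model.kappa, model.pi, _scaled_lengths(model, branch, rho, zeta))
    for _ in range(40):
        prev = cur
        res = minimize_scalar(
            lambda r: -pruning_loglik(
                pats, w, model.kappa, model.pi, _scaled_lengths(model, branch, float(r), zeta)
            ),
            bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8},
        )
        rho = float(res.x)
        res = minimize_scalar(
            lambda z: -pruning_loglik(
                pats, w, model.kappa, model.pi, _scaled_lengths(model, branch, rho, float(z))
            ),
            bounds=zeta_bounds, method="bounded", options={"xatol": 1e-8},
        )
        zeta = float(res.x)
        cur = pruning_loglik(
            pats, w, model.kappa, model.pi, _scaled_lengths(model, branch, rho, zeta)
        )
        if abs(cur - prev) < 1e-7:
            break
    return cur, rho, zeta


def branch_lrt(
    region_aln: AlignmentBlock,
    neutral: SubstitutionModel,
    branch: str,
    zeta_max: float = 50.0,
) -> tuple[float, float, float, float, dict]:
    """LRT for acceleration on one focal branch against a neutral background.

    Null: focal multiplier zeta in [0,1] (conservation/neutrality),
    shared background multiplier rho in [0,1].  Alternative: zeta free
    in [0, zeta_max] (a superset, so the models are nested and the
    statistic is nonnegative).  Returns (lnl_null, lnl_alt, lam,
    p_single, info); p is the 50:50 chi2(0)/chi2(1) boundary mixture.
    """
    if branch not in ("human", "chimp"):
        raise ValueError("focal branch must be human or chimp")
    codes = region_aln.complete_columns()
    low_info = codes.shape[1] < 50
    pats, w = _pattern_compress(codes)
    lnl_null, rho0, zeta0 = _profile_lnl(pats, w, neutral, branch, (0.0, 1.0))
    # start the alternative from the null optimum so nesting holds numerically
    lnl_alt, rho1, zeta1 = _profile_lnl(
        pats, w, neutral, branch, (0.0, zeta_max), start=(rho0, max(zeta0, 1.0))
    )
    if lnl_alt < lnl_null:
        lnl_alt, rho1, zeta1 = lnl_null, rho0, zeta0
    lam = max(0.0, 2.0 * (lnl_alt - lnl_null))
    p = 0.5 * float(chi2.sf(lam, df=1)) if lam > 0 else 0.5
    return lnl_null, lnl_alt, lam, p, {
        "rho": rho1, "zeta": zeta1, "low_information": low_info
    }


def bootstrap_p(
    region_aln: AlignmentBlock,
    background: AlignmentBlock,
    branch: str,
    cfg: SelectionConfig | None = None,
    region_id: str = "",
    rng: np.random.Generator | None = None,
) -> SelectionResult:
    """Average the LRT p over bootstrap replicates of the background.

    Each replicate resamples background columns with replacement to the
    original length, refits the neutral model and reruns the LRT;
    elements under selection that slipped into the background drop out
    of some replicates, making the average p robust to them.
    """
    cfg = cfg or SelectionConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = len(background)
    lnl_null, lnl_alt, ps = [], [], []
    zeta = rho = np.nan
    low_info = False
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n) if cfg.n_bootstrap > 1 else np.arange(n)
        boot = background.slice_columns(idx)
        neutral = fit_neutral(boot)
        l0, l1, _, p, info = branch_lrt(region_aln, neutral, branch)
        lnl_null.append(l0)
        lnl_alt.append(l1)
        ps.append(p)
        zeta, rho = info["zeta"], info["rho"]
        low_info = low_info or info["low_information"]
    return SelectionResult(
        region_id=region_id,
        branch=branch,
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        zeta=float(zeta),
        rho=float(rho),
        p=float(np.mean(ps)),
        low_information=low_info,
    )


# ---------------------------------------------------------------------------
# background collection

def collect_background(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    dhs_union: Sequence[GenomicInterval],
    fetch_alignment: Callable[[GenomicInterval], AlignmentBlock],
    cfg: SelectionConfig | None = None,
) -> AlignmentBlock | None:
    """Assemble a putatively neutral intronic alignment near a region.

    Eligible bases are non-first introns with ``splice_trim`` bases
    removed at each end, minus every DHS interval from any sample.
    Introns are added nearest-center-first within a symmetric window of
    ``max_window`` bases total, until ``background_target`` gap-free
    aligned columns accumulate (the block is truncated there); if the
    window is exhausted first, the region is discarded (None).
    """
    cfg = cfg or SelectionConfig()
    center = (region.start + region.end) // 2
    half = cfg.max_window // 2
    lo, hi = center - half, center + half
    eligible: list[tuple[int, int]] = []
    for g in genes:
        if g.interval.chrom != region.chrom:
            continue
        for (s, e) in g.introns()[1:]:  # drop the first intron
            s2, e2 = s + cfg.splice_trim, e - cfg.splice_trim
            if s2 < e2:
                eligible.append((s2, e2))
    # subtract DHS intervals
    dhs = sorted(
        (d.start, d.end) for d in dhs_union if d.chrom == region.chrom
    )
    pieces: list[tuple[int, int]] = []
    for (s, e) in eligible:
        cur = s
        for (ds, de) in dhs:
            if de <= cur or ds >= e:
                continue
            if ds > cur:
                pieces.append((cur, min(ds, e)))
            cur = max(cur, de)
            if cur >= e:
                break
        if cur < e:
            pieces.append((cur, e))
    pieces = [(s, e) for (s, e) in pieces if e > lo and s < hi]
    pieces = [(max(s, lo), min(e, hi)) for (s, e) in pieces]
    pieces.sort(key=lambda p: (abs((p[0] + p[1]) // 2 - center), p[0]))
    collected: AlignmentBlock | None = None
    n_cols = 0
    for (s, e) in pieces:
        block = fetch_alignment(GenomicInterval(region.assembly, region.chrom, s, e))
        collected = block if collected is None else collected.concat(block)
        n_cols = collected.complete_columns().shape[1]
        if n_cols >= cfg.background_target:
            break
    if collected is None or n_cols < cfg.background_target:
        return None
    codes = collected.codes()
    complete = np.where((codes != 5).all(axis=0))[0]
    # truncate to exactly the target number of gap-free columns
    return collected.slice_columns(complete[: cfg.background_target])


# ---------------------------------------------------------------------------
# simulation + branch comparison

def simulate_alignment(
    model: SubstitutionModel,
    n_columns: int,
    rng: np.random.Generator,
) -> AlignmentBlock:
    """Simulate a gap-free alignment under the model (root at the trifurcation)."""
    P = transition_matrices(model.kappa, model.pi, model.branch_lengths)
    root = rng.choice(4, size=n_columns, p=model.pi / model.pi.sum())

    def evolve(parent: np.ndarray, Pm: np.ndarray) -> np.ndarray:
        u = rng.random(n_columns)
        cum = np.cumsum(Pm, axis=1)
        cum = cum / cum[:, -1][:, None]
        rows = cum[parent]  # (n, 4)
        return (u[:, None] > rows).sum(axis=1).astype(np.int8)

    x = evolve(root, P["hc"])
    seqs = {
        "human": evolve(x, P["human"]),
        "chimp": evolve(x, P["chimp"]),
        "macaque": evolve(root, P["macaque"]),
        "orangutan": evolve(root, P["orangutan"]),
    }
    bases = np.array(list("ACGT"))
    return AlignmentBlock({t: "".join(bases[v]) for t, v in seqs.items()})


def compare_branches(
    p_human: Sequence[float],
    p_chimp: Sequence[float],
) -> float:
    """Two-sided rank-sum test: does one branch have smaller selection p-values?"""
    if len(p_human) < 3 or len(p_chimp) < 3:
        raise ValueError("need >= 3 regions per branch")
    res = mannwhitneyu(p_human, p_chimp, alternative="two-sided", method="auto")
    return float(res.pvalue)
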