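"""Cross-species PWM best-match scoring and motif-change statistics.

Each orthologous region sequence is scored per motif as the best
log-odds match anywhere on either strand (bits).  Between-species
differences of these best scores (equivalently, log2 ratios of
odds-scale scores) quantify the direction of motif improvement; their
joint distribution over two species pairs is summarized by quadrant
counts and, for significance, by projecting onto the y = x diagonal
and rank-sum testing a region class against the Common regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position weight matrix: log-odds in bits, rows A,C,G,T."""

    name: str
    log_odds: np.ndarray  # (4, L)
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[0] != 4 or self.log_odds.shape[1] < 1:
            raise ValueError("log_odds must be 4 x L with L >= 1")

    def __len__(self) -> int:
        return self.log_odds.shape[1]

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        background: Sequence[float] | None = None,
    ) -> "PWM":
        """Counts -> probabilities (pseudocount per cell) -> log2 odds."""
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A,C,G,T)")
        q = np.asarray(background if background is not None else np.full(4, 0.25), dtype=float)
        if not np.isclose(q.sum(), 1.0):
            raise ValueError("background must sum to 1")
        p = counts + pseudocount
        p = p / p.sum(axis=0, keepdims=True)
        return cls(name, np.log2(p / q[:, None]), pseudocount, q)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=0))


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq.upper()), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _strand_best(idx: np.ndarray, lo_ext: np.ndarray) -> float:
    L = lo_ext.shape[1]
    wins = np.lib.stride_tricks.sliding_window_view(idx, L)
    scores = lo_ext[wins, np.arange(L)].sum(axis=1)
    return float(scores.max())


def best_match(seq: str, pwm: PWM) -> float:
    """Best log-odds score (bits) over all offsets and both strands.

    N bases contribute 0 at their positions.
    """
    if len(seq) < len(pwm):
        raise ValueError(f"sequence ({len(seq)} nt) shorter than motif ({len(pwm)} nt)")
    lo_ext = np.vstack([pwm.log_odds, np.zeros(len(pwm))])  # row 4 = N
    fwd = _strand_best(_encode(seq), lo_ext)
    rev = _strand_best(_encode(seq.translate(_COMPLEMENT)[::-1]), lo_ext)
    return max(fwd, rev)


@dataclass
class MotifScoreTable:
    """Best scores per (region, species) and pairwise score differences."""

    scores: pd.DataFrame  # index region id; columns species
    deltas: pd.DataFrame  # columns d_<a>_<b> = score_a - score_b

    def delta(self, a: str, b: str) -> np.ndarray:
        col = f"d_{a}_{b}"
        if col in self.deltas:
            return self.deltas[col].to_numpy()
        return -self.deltas[f"d_{b}_{a}"].to_numpy()


def species_log_ratios(
    region_seqs: dict[str, dict[str, str]],
    pwm: PWM,
    species: tuple[str, str, str] = ("human", "chimp", "macaque"),
) -> MotifScoreTable:
    """Best-match scores per species and pairwise differences, per region.

    ``region_seqs`` maps region id -> {species: sequence}.  Regions
    missing a species (or with sequence shorter than the motif) are
    skipped with a warning.
    """
    import warnings

    rows = {}
    for rid, seqs in region_seqs.items():
        if any(sp not in seqs for sp in species):
            warnings.warn(f"region {rid}: missing species sequence; skipped")
            continue
        if any(len(seqs[sp]) < len(pwm) for sp in species):
            warnings.warn(f"region {rid}: sequence shorter than motif; skipped")
            continue
        rows[rid] = {sp: best_match(seqs[sp], pwm) for sp in species}
    scores = pd.DataFrame.from_dict(rows, orient="index")
    if scores.empty:
        scores = pd.DataFrame(columns=list(species))
    deltas = pd.DataFrame(index=scores.index)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            deltas[f"d_{a}_{b}"] = scores[a] - scores[b]
    return MotifScoreTable(scores, deltas)


def quadrant_counts(
    table: MotifScoreTable,
    axes: tuple[tuple[str, str], tuple[str, str]] = (("human", "chimp"), ("human", "macaque")),
) -> tuple[int, int, int, int]:
    """Counts (upper-right, lower-right x>0 y<0, upper-left, lower-left).

    Points exactly on an axis (a zero difference) belong to no quadrant.
    """
    dx = table.delta(*axes[0])
    dy = table.delta(*axes[1])
    return (
        int(((dx > 0) & (dy > 0)).sum()),
        int(((dx > 0) & (dy < 0)).sum()),
        int(((dx < 0) & (dy > 0)).sum()),
        int(((dx < 0) & (dy < 0)).sum()),
    )


def projections(
    table: MotifScoreTable,
    axes: tuple[tuple[str, str], tuple[str, str]] = (("human", "chimp"), ("human", "macaque")),
) -> np.ndarray:
    """Project (dx, dy) points onto the y = x diagonal: v = (dx + dy) / 2."""
    return (table.delta(*axes[0]) + table.delta(*axes[1])) / 2.0


def projection_test(
    table_class: MotifScoreTable,
    table_common: MotifScoreTable,
    axes: tuple[tuple[str, str], tuple[str, str]] = (("human", "chimp"), ("human", "macaque")),
) -> tuple[float, float]:
    """Rank-sum test of a call class's diagonal projections vs Common's.

    Returns (median projection of the class, two-sided p).
    """
    v_class = projections(table_class, axes)
    v_common = projections(table_common, axes)
    if len(v_class) < 3 or len(v_common) < 3:
        raise ValueError("need >= 3 regions on both sides")
    res = mannwhitneyu(v_class, v_common, alternative="two-sided", method="auto")
    return float(np.median(v_class)), float(res.pvalue)
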