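"""Digital gene expression: correlation structure and polarized DE calls.

Tag counts per gene are compared directly between species on shared
gene ids (exonic homology is high enough that no coordinate lifting is
needed).  Genes below a minimum total tag count are dropped as noise.
Branch-polarized differential expression mirrors the chromatin logic:
a human-upregulated gene is DE in human/chimp AND human/macaque but
not chimp/macaque, with human highest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from dhsevo.diffchrom import nb_exact_test_batch, tmm_factors, estimate_common_dispersion, equalize_libraries
from dhsevo.ioformats import CountMatrix, SampleMeta


@dataclass
class ExprConfig:
    min_total_tags: int = 10
    de_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.de_alpha < 1):
            raise ValueError("de_alpha must be in (0,1)")


DE_CLASSES = ("human_up", "human_down", "chimp_up", "chimp_down", "common_expressed")


@dataclass
class DEGeneSet:
    """Per-gene class labels plus the pairwise p-values they came from."""

    table: pd.DataFrame  # index gene id; columns class, p_*, mean_*

    def genes_of(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])

    @property
    def expressed(self) -> list[str]:
        return list(self.table.index)


def filter_low_expression(cm: CountMatrix, cfg: ExprConfig | None = None) -> CountMatrix:
    """Drop genes with fewer than ``min_total_tags`` combined tags."""
    cfg = cfg or ExprConfig()
    keep = cm.counts.sum(axis=1) >= cfg.min_total_tags
    return CountMatrix(cm.counts.loc[keep], cm.library_sizes.to_numpy())


def correlation_matrix(
    cm: CountMatrix,
    method: str = "spearman",
    log_transform: bool = False,
    cfg: ExprConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """All-vs-all sample correlation on library-normalized counts.

    Returns the symmetric correlation matrix and the sample order given
    by average-linkage hierarchical clustering on 1 - correlation (the
    heatmap leaf order).
    """
    cfg = cfg or ExprConfig()
    cm = filter_low_expression(cm, cfg)
    lib = cm.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive for normalization")
    norm = cm.values() / lib[None, :] * np.exp(np.mean(np.log(lib)))
    if log_transform:
        norm = np.log2(norm + 1.0)
    for j, sid in enumerate(cm.sample_ids):
        if np.allclose(norm[:, j], norm[0, j]):
            raise ValueError(f"sample {sid} has constant counts; correlation undefined")
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 0, norm)
    elif method == "pearson":
        data = norm
    else:
        raise ValueError(f"unknown method {method!r}")
    corr = np.corrcoef(data, rowvar=False)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=cm.sample_ids, columns=cm.sample_ids)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    order = [cm.sample_ids[i] for i in leaves_list(average(dist))]
    return df, order


def classify_de(
    cm: CountMatrix,
    meta: list[SampleMeta],
    cfg: ExprConfig | None = None,
) -> DEGeneSet:
    """Branch-polarized differential expression with macaque as outgroup.

    Pairwise species tests reuse the NB exact test with TMM-normalized,
    library-equalized counts and a common dispersion estimated from the
    species groups.  Unadjusted p-values are compared to ``de_alpha``
    (liberal, but the "not DE in chimp/macaque" arm needs a plain p).
    """
    cfg = cfg or ExprConfig()
    cm = filter_low_expression(cm, cfg)
    by_sid = {m.sample_id: m for m in meta}
    groups: dict[str, list[str]] = {}
    for sid in cm.sample_ids:
        groups.setdefault(by_sid[sid].species, []).append(sid)
    for sp in ("human", "chimp", "macaque"):
        if sp not in groups:
            raise ValueError(f"no samples for {sp}")
    factors = tmm_factors(cm)
    eff = cm.library_sizes * factors
    phi = estimate_common_dispersion(cm, groups, effective_lib_sizes=eff)
    eq = equalize_libraries(cm, eff)

    p = {}
    for a, b in (("human", "chimp"), ("human", "macaque"), ("chimp", "macaque")):
        p[(a, b)] = nb_exact_test_batch(eq[groups[a]].to_numpy(), eq[groups[b]].to_numpy(), phi)
    means = {sp: eq[groups[sp]].mean(axis=1).to_numpy() for sp in groups}
    alpha = cfg.de_alpha
    mh, mc, mm = means["human"], means["chimp"], means["macaque"]
    p_hc, p_hm, p_cm = p[("human", "chimp")], p[("human", "macaque")], p[("chimp", "macaque")]
    cls = np.full(cm.shape[0], "common_expressed", dtype=object)
    hu = (p_hc < alpha) & (p_hm < alpha) & (p_cm >= alpha) & (mh > mc) & (mh > mm)
    hd = (p_hc < alpha) & (p_hm < alpha) & (p_cm >= alpha) & (mh < mc) & (mh < mm)
    cu = (p_hc < alpha) & (p_cm < alpha) & (p_hm >= alpha) & (mc > mh) & (mc > mm)
    cd = (p_hc < alpha) & (p_cm < alpha) & (p_hm >= alpha) & (mc < mh) & (mc < mm)
    cls[hu] = "human_up"
    cls[hd] = "human_down"
    cls[cu] = "chimp_up"
    cls[cd] = "chimp_down"
    table = pd.DataFrame(
        {
            "class": cls,
            "p_human_chimp": p_hc,
            "p_human_macaque": p_hm,
            "p_chimp_macaque": p_cm,
            "mean_human": mh,
            "mean_chimp": mc,
            "mean_macaque": mm,
        },
        index=cm.row_ids,
    )
    return DEGeneSet(table)
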