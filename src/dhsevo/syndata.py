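"""Synthetic three-species regulatory-genomics datasets with known truth.

The generator builds a master multiple alignment per chromosome (human,
chimp, macaque and an orangutan outgroup evolved under HKY along the
fixed tree), carves it into gene "cassettes" (gene model + downstream
DHS element slot), then plants elements of known classes:

* shared DHS sites: open in all nine fibroblast samples;
* branch-specific gains/losses: open (or closed) in exactly one of
  human or chimp, polarized against macaque;
* CNV artifacts: a duplicated chimp copy feeds extra reads into one
  human location, violating reciprocal count consistency;
* sharp-peak artifacts: one sample's reads collapse onto a single
  position.

Species genomes are the master columns present in each species
(lineage-specific deletions create orthology-map indels; planted
elements are protected so they stay mappable).  Cut-site tracks, scored
peak sets, gene models, DGE tag counts (with cell-type structure and DE
genes coupled to nearby chromatin changes), conservation tracks,
constrained elements and JASPAR-style PFMs (with motif improvements
planted into gained sequences) are all derived from this one structure,
so every pipeline stage can be checked against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from dhsevo.ioformats import (
    CountMatrix,
    GeneModel,
    GenomicInterval,
    SampleMeta,
    ScoredPeakSet,
    write_bed,
    write_bed12,
    write_bedgraph,
    write_count_table,
    write_fasta,
    write_pfm,
    write_sample_table,
)
from dhsevo.motifscan import PWM, best_match
from dhsevo.orthomap import Block, OrthologyMap, write_orthology_map
from dhsevo.selection import AlignmentBlock, SubstitutionModel, simulate_alignment

SPECIES = ("human", "chimp", "macaque")
ASSEMBLY = {"human": "hg", "chimp": "pt", "macaque": "rm", "orangutan": "pa"}

# AP1-like PFM (TGACTCA consensus); the motif planted into gained sequences
AP1_COUNTS = np.array(
    [
        [2, 1, 1, 18, 1, 1, 18],   # A
        [1, 1, 17, 1, 1, 18, 1],   # C
        [1, 18, 1, 1, 1, 1, 1],    # G
        [17, 1, 2, 1, 18, 1, 1],   # T
    ],
    dtype=float,
)
GC_COUNTS = np.array(
    [[1, 1, 1, 1, 1, 1], [8, 1, 8, 8, 1, 8], [8, 16, 8, 8, 16, 8], [1, 1, 1, 1, 1, 1]],
    dtype=float,
)

_CASSETTE = 6000
_ELEMENT_W = 300


def _default_gains() -> dict[str, int]:
    return {"human": 12, "chimp": 12}


def _default_losses() -> dict[str, int]:
    return {"human": 8, "chimp": 8}


def _default_subst() -> dict[str, float]:
    # rough primate neutral divergences (substitutions/site)
    return {"human": 0.007, "chimp": 0.007, "hc": 0.012, "macaque": 0.06, "orangutan": 0.035}


@dataclass
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    genome_length: int = 360_000  # master columns per chromosome
    n_shared_dhs: int = 60
    n_gain: dict[str, int] = field(default_factory=_default_gains)
    n_loss: dict[str, int] = field(default_factory=_default_losses)
    nb_dispersion: float = 0.2
    mean_cuts_open: float = 60.0
    mean_cuts_closed: float = 3.0
    fold_change: float = 8.0
    n_cnv_artifacts: int = 2
    n_sharp_artifacts: int = 2
    indel_rate: float = 0.001  # deletion events per base per lineage
    n_genes: int | None = None  # None: one gene per cassette
    de_coupling: float = 0.5
    motif_plant_fraction: float = 0.5
    subst_rates: dict[str, float] = field(default_factory=_default_subst)
    de_fold: float = 6.0
    lib_sigma: float = 0.3
    partial_gain_fraction: float = 0.10  # gains 3-fold reduced (not absent) elsewhere
    strength_sigma: float = 0.8  # per-element intensity spread (log scale)
    strength_clip: tuple[float, float] = (0.4, 2.5)  # keeps weak sites detectable
    dge_mean_tags: float = 80.0
    dge_dispersion: float = 0.05
    species_expr_sd: float = 0.10
    celltype_expr_sd: float = 0.60

    def __post_init__(self) -> None:
        for p in (self.de_coupling, self.motif_plant_fraction, self.indel_rate,
                  self.partial_gain_fraction):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")


@dataclass
class PlantedElement:
    element_id: str
    klass: str  # shared | human_gain | human_loss | chimp_gain | chimp_loss | cnv_artifact | sharp_artifact
    chrom: str
    master_start: int
    master_end: int
    gene_id: str | None
    de_class: str | None = None
    motif_delta: float | None = None
    partial: bool = False  # gain present at reduced level in other species
    strength: float = 1.0  # site intensity multiplier, shared across samples


class SynthDataset:
    """In-memory synthetic dataset; ``write`` serializes every artifact."""

    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        self.master: dict[str, dict[str, np.ndarray]] = {}  # chrom -> species -> base codes
        self.present: dict[str, dict[str, np.ndarray]] = {}  # chrom -> species -> bool mask
        self.elements: list[PlantedElement] = []
        self.genes: list[GeneModel] = []
        self.gene_master: dict[str, tuple[str, int, int]] = {}
        self.maps: dict[str, OrthologyMap] = {}
        self.fib_meta: list[SampleMeta] = []
        self.dge_meta: list[SampleMeta] = []
        self.cuts: dict[str, dict[str, np.ndarray]] = {}  # sample -> chrom -> native positions
        self.peaksets: list[ScoredPeakSet] = []
        self.dge: CountMatrix | None = None
        self.conservation: list[tuple[GenomicInterval, float]] = []
        self.constrained: list[GenomicInterval] = []
        self.pfms: dict[str, np.ndarray] = {}
        self.lib_factors: dict[str, float] = {}

    # -- coordinate helpers -------------------------------------------------

    def native_coord(self, species: str, chrom: str) -> np.ndarray:
        """master column -> native coordinate (of the column's base)."""
        mask = self.present[chrom][species]
        return np.cumsum(mask) - 1

    def native_length(self, species: str, chrom: str) -> int:
        return int(self.present[chrom][species].sum())

    def to_native_interval(self, species: str, iv_master: tuple[str, int, int]) -> GenomicInterval:
        chrom, s, e = iv_master
        coord = self.native_coord(species, chrom)
        mask = self.present[chrom][species]
        cols = np.arange(s, e)[mask[s:e]]
        if len(cols) == 0:
            raise ValueError("interval absent from species")
        return GenomicInterval(
            ASSEMBLY[species], chrom, int(coord[cols[0]]), int(coord[cols[-1]]) + 1
        )

    def genome(self, species: str) -> dict[str, str]:
        bases = np.array(list("ACGT"))
        out = {}
        for chrom in self.master:
            mask = self.present[chrom][species]
            out[chrom] = "".join(bases[self.master[chrom][species][mask]])
        return out

    def fetch_alignment(self, iv: GenomicInterval) -> AlignmentBlock:
        """4-taxon alignment of a human-assembly interval (master columns)."""
        chrom = iv.chrom
        hmask = self.present[chrom]["human"]
        hcols = np.where(hmask)[0]
        cols = hcols[iv.start : iv.end]
        bases = np.array(list("ACGT"))
        seqs = {}
        for sp in ("human", "chimp", "macaque", "orangutan"):
            mask = self.present[chrom][sp][cols]
            chars = np.where(mask, bases[self.master[chrom][sp][cols]], "-")
            seqs[sp] = "".join(chars)
        return AlignmentBlock(seqs)

    # -- truth table ----------------------------------------------------------

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for el in self.elements:
            row = {
                "element_id": el.element_id,
                "class": el.klass,
                "chrom": el.chrom,
                "gene_id": el.gene_id or "",
                "de_class": el.de_class or "",
                "motif_delta": el.motif_delta if el.motif_delta is not None else np.nan,
                "partial": el.partial,
                "strength": el.strength,
            }
            for sp in SPECIES:
                try:
                    iv = self.to_native_interval(sp, (el.chrom, el.master_start, el.master_end))
                    row[f"{sp}_start"], row[f"{sp}_end"] = iv.start, iv.end
                except ValueError:
                    row[f"{sp}_start"], row[f"{sp}_end"] = -1, -1
            rows.append(row)
        return pd.DataFrame(rows)

    # -- serialization ----------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in ("human", "chimp", "macaque", "orangutan"):
            write_fasta(self.genome(sp), out / f"{ASSEMBLY[sp]}.fa")
        for sp, omap in self.maps.items():
            write_orthology_map(omap, out / f"{ASSEMBLY[sp]}_to_hg.map.tsv")
        for ps in self.peaksets:
            recs = [(iv, f"peak{i}", s) for i, (iv, s) in enumerate(ps.peaks)]
            write_bed(recs, out / f"{ps.sample.sample_id}.peaks.bed")
        for sid, per in self.cuts.items():
            sp = sid.split("_")[0]
            recs = []
            for chrom, pos in sorted(per.items()):
                recs.extend(
                    GenomicInterval(ASSEMBLY[sp], chrom, int(p), int(p) + 1)
                    for p in np.sort(pos)
                )
            write_bed(recs, out / f"{sid}.cuts.bed")
        write_bed12(self.genes, out / "genes.bed12")
        assert self.dge is not None
        write_count_table(self.dge, out / "dge_counts.tsv")
        write_sample_table(self.dge_meta, out / "dge_samples.tsv")
        write_sample_table(self.fib_meta, out / "fib_samples.tsv")
        write_bedgraph(self.conservation, out / "conservation.bedGraph")
        write_bed(self.constrained, out / "constrained.bed")
        for name, counts in self.pfms.items():
            write_pfm(name, counts, out / f"{name}.pfm")
        self.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size=None):
    """NB(mean, phi) with var = mean + phi * mean^2."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate the full dataset; identical cfg+seed gives identical output."""
    rng = np.random.default_rng(cfg.seed)
    ds = SynthDataset(cfg)

    n_cass_per_chrom = cfg.genome_length // _CASSETTE
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    total_cass = n_cass_per_chrom * cfg.n_chroms
    n_elements = (
        cfg.n_shared_dhs
        + sum(cfg.n_gain.values())
        + sum(cfg.n_loss.values())
        + cfg.n_cnv_artifacts
        + cfg.n_sharp_artifacts
    )
    if n_elements > total_cass:
        raise ValueError(
            f"{n_elements} planted elements exceed genome capacity ({total_cass} slots)"
        )

    # -- master alignment (substitutions only) --------------------------------
    pi = np.array([0.3, 0.2, 0.2, 0.3])
    model = SubstitutionModel(2.0, pi, dict(cfg.subst_rates))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for chrom in chroms:
        aln = simulate_alignment(model, cfg.genome_length, rng)
        ds.master[chrom] = {
            sp: np.fromiter((base_idx[c] for c in aln.sequences[sp]), dtype=np.int8,
                            count=cfg.genome_length)
            for sp in ("human", "chimp", "macaque", "orangutan")
        }
        ds.present[chrom] = {
            sp: np.ones(cfg.genome_length, dtype=bool)
            for sp in ("human", "chimp", "macaque", "orangutan")
        }

    # -- assign element classes to cassettes -----------------------------------
    classes: list[str] = (
        ["shared"] * cfg.n_shared_dhs
        + ["human_gain"] * cfg.n_gain.get("human", 0)
        + ["chimp_gain"] * cfg.n_gain.get("chimp", 0)
        + ["human_loss"] * cfg.n_loss.get("human", 0)
        + ["chimp_loss"] * cfg.n_loss.get("chimp", 0)
        + ["cnv_artifact"] * cfg.n_cnv_artifacts
        + ["sharp_artifact"] * cfg.n_sharp_artifacts
    )
    slots = rng.permutation(total_cass)[:n_elements]
    slot_class = dict(zip(slots.tolist(), classes))

    n_genes = total_cass if cfg.n_genes is None else min(cfg.n_genes, total_cass)

    # -- build cassettes: genes + element intervals (master coordinates) -------
    protected: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gene_of_slot: dict[int, str] = {}
    for slot in range(total_cass):
        chrom = chroms[slot // n_cass_per_chrom]
        cass_start = (slot % n_cass_per_chrom) * _CASSETTE
        if slot < n_genes:
            gid = f"gene{slot}"
            gstart = cass_start + 500
            # 4 exons of 200 bp, introns of 700 bp; span 2900
            gene_of_slot[slot] = gid
            ds.gene_master[gid] = (chrom, gstart, gstart + 2900)
        if slot in slot_class:
            estart = cass_start + 4200
            protected[chrom].append((estart - 50, estart + _ELEMENT_W + 50))
            el = PlantedElement(
                element_id=f"el{slot}",
                klass=slot_class[slot],
                chrom=chrom,
                master_start=estart,
                master_end=estart + _ELEMENT_W,
                gene_id=gene_of_slot.get(slot),
            )
            if el.klass == "cnv_artifact":
                # donor copy segment lives in the cassette spacer
                protected[chrom].append((cass_start + 5200, cass_start + 5200 + _ELEMENT_W))
            ds.elements.append(el)

    # -- lineage-specific deletions (indels of the orthology maps) -------------
    for chrom in chroms:
        prot = protected[chrom]

        def is_protected(s: int, e: int) -> bool:
            return any(s < pe and ps < e for ps, pe in prot)

        for sp in ("human", "chimp", "macaque"):
            n_events = rng.poisson(cfg.indel_rate * cfg.genome_length)
            starts = rng.integers(0, cfg.genome_length, size=n_events)
            lens = rng.geometric(0.25, size=n_events)  # mean 4 bp
            for s, l in zip(starts, lens):
                e = min(int(s) + int(l), cfg.genome_length)
                if not is_protected(int(s), e):
                    ds.present[chrom][sp][int(s) : e] = False

    # CNV donor: delete the donor segment from human so it is chimp-only
    for el in ds.elements:
        if el.klass == "cnv_artifact":
            cass_start = el.master_start - 4200
            ds.present[el.chrom]["human"][cass_start + 5200 : cass_start + 5200 + _ELEMENT_W] = False

    # -- orthology maps (species -> human), with CNV duplicate blocks ----------
    for sp in ("chimp", "macaque"):
        blocks: list[Block] = []
        for chrom in chroms:
            both = ds.present[chrom][sp] & ds.present[chrom]["human"]
            sp_coord = ds.native_coord(sp, chrom)
            h_coord = ds.native_coord("human", chrom)
            edges = np.flatnonzero(np.diff(np.concatenate([[0], both.view(np.int8), [0]])))
            for s, e in zip(edges[::2], edges[1::2]):
                blocks.append(
                    Block(chrom, int(sp_coord[s]), int(sp_coord[e - 1]) + 1,
                          chrom, int(h_coord[s]), int(h_coord[e - 1]) + 1, "+")
                )
        if sp == "chimp":
            for el in ds.elements:
                if el.klass != "cnv_artifact":
                    continue
                cass_start = el.master_start - 4200
                donor = ds.to_native_interval(
                    "chimp", (el.chrom, cass_start + 5200, cass_start + 5200 + _ELEMENT_W)
                )
                target = ds.to_native_interval(
                    "human", (el.chrom, el.master_start, el.master_end)
                )
                blocks.append(
                    Block(el.chrom, donor.start, donor.end, el.chrom, target.start, target.end, "+")
                )
        ds.maps[sp] = OrthologyMap(ASSEMBLY[sp], ASSEMBLY["human"], blocks)

    # -- sample metadata --------------------------------------------------------
    ds.fib_meta = [
        SampleMeta(f"{sp}_fib_{i}", sp, "fibroblast", f"{sp[0]}{i}")
        for sp in SPECIES
        for i in (1, 2, 3)
    ]
    ds.dge_meta = list(ds.fib_meta) + [
        SampleMeta(f"{sp}_lcl_{i}", sp, "lcl", f"{sp[0]}{i}")
        for sp in ("human", "chimp")
        for i in (1, 2, 3)
    ]

    # -- element openness per species ------------------------------------------
    partial_flags = rng.random(len(ds.elements)) < cfg.partial_gain_fraction
    lo, hi = np.log(cfg.strength_clip[0]), np.log(cfg.strength_clip[1])
    strengths = np.exp(np.clip(rng.normal(0.0, cfg.strength_sigma, len(ds.elements)), lo, hi))
    open_mean: dict[tuple[str, str], float] = {}  # (element_id, species) -> mean cuts
    for el, partial, strength in zip(ds.elements, partial_flags, strengths):
        el.strength = float(strength)
        level = cfg.mean_cuts_open * el.strength
        if el.klass == "shared" or el.klass == "cnv_artifact":
            for sp in SPECIES:
                open_mean[(el.element_id, sp)] = level
        elif el.klass.endswith("_gain"):
            gainer = el.klass.split("_")[0]
            el.partial = bool(partial)
            for sp in SPECIES:
                if sp == gainer:
                    open_mean[(el.element_id, sp)] = level
                elif partial:
                    open_mean[(el.element_id, sp)] = level / 3.0
        elif el.klass.endswith("_loss"):
            loser = el.klass.split("_")[0]
            for sp in SPECIES:
                if sp != loser:
                    open_mean[(el.element_id, sp)] = level
        # sharp artifacts handled separately

    # -- cut-site tracks (native coordinates) -----------------------------------
    bg_rate = cfg.mean_cuts_closed / _ELEMENT_W  # basal digestion per base
    for m in ds.fib_meta:
        ds.lib_factors[m.sample_id] = float(np.exp(rng.normal(0.0, cfg.lib_sigma)))
    sharp_sample = ds.fib_meta[0].sample_id  # artifact lives in one sample

    for m in ds.fib_meta:
        lf = ds.lib_factors[m.sample_id]
        per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        for chrom in chroms:
            L = ds.native_length(m.species, chrom)
            n_bg = rng.poisson(bg_rate * L * lf)
            per_chrom[chrom].append(rng.integers(0, L, size=n_bg))
        coord_cache = {c: ds.native_coord(m.species, c) for c in chroms}
        for el in ds.elements:
            mean = open_mean.get((el.element_id, m.species))
            if el.klass == "sharp_artifact":
                if m.sample_id == sharp_sample:
                    n = int(_nb_draw(rng, cfg.mean_cuts_open * lf, cfg.nb_dispersion))
                    center = coord_cache[el.chrom][(el.master_start + el.master_end) // 2]
                    per_chrom[el.chrom].append(np.full(n, center, dtype=np.int64))
                continue
            if mean is None:
                continue
            n = int(_nb_draw(rng, mean * lf, cfg.nb_dispersion))
            iv = ds.to_native_interval(m.species, (el.chrom, el.master_start, el.master_end))
            pos = np.clip(
                np.round(rng.normal((iv.start + iv.end) / 2, 60, size=n)),
                iv.start, iv.end - 1,
            ).astype(np.int64)
            per_chrom[el.chrom].append(pos)
            if el.klass == "cnv_artifact" and m.species == "chimp":
                cass_start = el.master_start - 4200
                div = ds.to_native_interval(
                    "chimp", (el.chrom, cass_start + 5200, cass_start + 5200 + _ELEMENT_W)
                )
                n2 = int(_nb_draw(rng, mean * lf, cfg.nb_dispersion))
                pos2 = np.clip(
                    np.round(rng.normal((div.start + div.end) / 2, 60, size=n2)),
                    div.start, div.end - 1,
                ).astype(np.int64)
                per_chrom[el.chrom].append(pos2)
        ds.cuts[m.sample_id] = {
            c: np.sort(np.concatenate(v)) if v else np.array([], dtype=np.int64)
            for c, v in per_chrom.items()
        }

    # -- scored peak sets (native coordinates) ----------------------------------
    for m in ds.fib_meta:
        peaks: list[tuple[GenomicInterval, float]] = []
        for el in ds.elements:
            is_open = (el.element_id, m.species) in open_mean
            is_sharp_here = el.klass == "sharp_artifact" and m.sample_id == sharp_sample
            if not (is_open or is_sharp_here):
                continue
            iv = ds.to_native_interval(m.species, (el.chrom, el.master_start, el.master_end))
            pos = ds.cuts[m.sample_id].get(el.chrom, np.array([]))
            score = float(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))
            peaks.append((iv, max(score, 1.0)))
            if el.klass == "cnv_artifact" and m.species == "chimp":
                cass_start = el.master_start - 4200
                div = ds.to_native_interval(
                    "chimp", (el.chrom, cass_start + 5200, cass_start + 5200 + _ELEMENT_W)
                )
                peaks.append((div, max(score, 1.0)))
        ds.peaksets.append(ScoredPeakSet(m, peaks))

    # -- gene models (human assembly coordinates) --------------------------------
    for gid, (chrom, gs, ge) in ds.gene_master.items():
        h_coord = ds.native_coord("human", chrom)
        hmask = ds.present[chrom]["human"]

        def h(col: int) -> int:
            cols = np.arange(col, min(col + 50, cfg.genome_length))
            ok = cols[hmask[cols]]
            return int(h_coord[ok[0]]) if len(ok) else int(h_coord[-1])

        exons = []
        for i in range(4):
            s, e = gs + i * 900, gs + i * 900 + 200
            hs, he = h(s), h(e - 1) + 1
            if he > hs:
                exons.append((hs, he))
        span = GenomicInterval(ASSEMBLY["human"], chrom, exons[0][0], exons[-1][1], "+")
        ds.genes.append(GeneModel(gid, span, tuple(exons)))

    # -- DGE counts with DE coupled to chromatin changes --------------------------
    gene_ids = list(ds.gene_master)
    n_g = len(gene_ids)
    base_log = rng.normal(np.log(cfg.dge_mean_tags), 1.0, size=n_g)
    species_eff = {sp: rng.normal(0.0, cfg.species_expr_sd, size=n_g) for sp in SPECIES}
    ct_eff = {ct: rng.normal(0.0, cfg.celltype_expr_sd, size=n_g) for ct in ("fibroblast", "lcl")}

    de_dir = {"_gain": "up", "_loss": "down"}
    gene_rank = {g: i for i, g in enumerate(gene_ids)}
    for el in ds.elements:
        if el.gene_id is None or el.klass in ("shared", "cnv_artifact", "sharp_artifact"):
            continue
        if rng.random() < cfg.de_coupling:
            sp = el.klass.split("_")[0]
            direction = de_dir["_" + el.klass.split("_")[1]]
            el.de_class = f"{sp}_{direction}"
            gi = gene_rank[el.gene_id]
            shift = np.log(cfg.de_fold) * (1 if direction == "up" else -1)
            species_eff[sp][gi] = shift

    dge_cols = {}
    dge_lib = {m.sample_id: float(np.exp(rng.normal(0.0, cfg.lib_sigma))) for m in ds.dge_meta}
    for m in ds.dge_meta:
        mu = np.exp(base_log + species_eff[m.species] + ct_eff[m.cell_type]) * dge_lib[m.sample_id]
        r = 1.0 / cfg.dge_dispersion
        p = r / (r + mu)
        dge_cols[m.sample_id] = rng.negative_binomial(r, p)
    ds.dge = CountMatrix(pd.DataFrame(dge_cols, index=gene_ids))

    # -- conservation track + constrained elements (human coords) -----------------
    for chrom in chroms:
        L = ds.native_length("human", chrom)
        shared = sorted(
            (
                ds.to_native_interval("human", (el.chrom, el.master_start, el.master_end))
                for el in ds.elements
                if el.klass == "shared" and el.chrom == chrom
            ),
            key=lambda iv: iv.start,
        )
        pos = 0
        for iv in shared:
            if iv.start > pos:
                ds.conservation.append(
                    (GenomicInterval(ASSEMBLY["human"], chrom, pos, iv.start), 0.05)
                )
            ds.conservation.append((iv, 0.8))
            ds.constrained.append(iv)
            pos = iv.end
        if pos < L:
            ds.conservation.append((GenomicInterval(ASSEMBLY["human"], chrom, pos, L), 0.05))

    # -- motif planting in gained sequences ----------------------------------------
    ds.pfms = {"AP1": AP1_COUNTS.copy(), "GCBOX": GC_COUNTS.copy()}
    pwm = PWM.from_counts("AP1", AP1_COUNTS)
    consensus = pwm.consensus
    cons_idx = np.fromiter((("ACGT").index(c) for c in consensus), dtype=np.int8)
    for el in ds.elements:
        if not el.klass.endswith("_gain"):
            continue
        if rng.random() >= cfg.motif_plant_fraction:
            continue
        gainer = el.klass.split("_")[0]
        center = (el.master_start + el.master_end) // 2
        s = center - len(consensus) // 2
        ds.master[el.chrom][gainer][s : s + len(consensus)] = cons_idx
        aln = ds.fetch_alignment(
            ds.to_native_interval("human", (el.chrom, el.master_start, el.master_end))
        )
        scores = {
            sp: best_match(aln.sequences[sp].replace("-", ""), pwm)
            for sp in SPECIES
        }
        others = [scores[sp] for sp in SPECIES if sp != gainer]
        el.motif_delta = float(scores[gainer] - max(others))
    return ds


# ---------------------------------------------------------------------------
# count-matrix simulators for calibration and acceptance runs

def simulate_null_counts(
    n_windows: int,
    groups: dict[str, int],
    phi: float,
    mean: float,
    seed: int,
    lib_sigma: float = 0.0,
) -> tuple[CountMatrix, list[SampleMeta]]:
    """A pure-null NB count matrix: no true differences between groups.

    ``groups`` maps species name -> number of samples.  With
    ``lib_sigma > 0`` the NB mean is scaled per sample by a log-normal
    library factor.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    cols, meta = {}, []
    for sp, n in groups.items():
        for i in range(1, n + 1):
            sid = f"{sp}_fib_{i}"
            lf = float(np.exp(rng.normal(0.0, lib_sigma))) if lib_sigma > 0 else 1.0
            r = 1.0 / phi
            mu = mean * lf
            p = r / (r + mu)
            cols[sid] = rng.negative_binomial(r, p, size=n_windows)
            meta.append(SampleMeta(sid, sp, "fibroblast", f"{sp[0]}{i}"))
    idx = [f"w{i}" for i in range(n_windows)]
    return CountMatrix(pd.DataFrame(cols, index=idx)), meta


def simulate_turnover_counts(
    n_windows: int,
    p_open: float,
    switch_prob: float,
    phi: float,
    mean_open: float,
    mean_closed: float,
    seed: int,
    n_per_group: int = 3,
) -> tuple[CountMatrix, list[SampleMeta], pd.DataFrame]:
    """Counts under symmetric on/off turnover of openness along the tree.

    Each window's open/closed state starts at the root (open with
    probability ``p_open``) and flips with probability ``switch_prob``
    on every branch of ((human,chimp),macaque), in either direction.
    Openness being sparse, single-species-open patterns (detected as
    gains) arise more often than single-species-closed ones (losses),
    even though per-branch turnover is symmetric.
    """
    rng = np.random.default_rng(seed)
    root = rng.random(n_windows) < p_open
    flip = lambda s: s ^ (rng.random(n_windows) < switch_prob)  # noqa: E731
    hc = flip(root)
    states = {"human": flip(hc), "chimp": flip(hc), "macaque": flip(root)}
    cols, meta = {}, []
    for sp in ("human", "chimp", "macaque"):
        mu = np.where(states[sp], mean_open, mean_closed).astype(float)
        for i in range(1, n_per_group + 1):
            sid = f"{sp}_fib_{i}"
            r = 1.0 / phi
            p = r / (r + mu)
            cols[sid] = rng.negative_binomial(r, p)
            meta.append(SampleMeta(sid, sp, "fibroblast", f"{sp[0]}{i}"))
    idx = [f"w{i}" for i in range(n_windows)]
    truth = pd.DataFrame({sp: states[sp] for sp in states}, index=idx)
    return CountMatrix(pd.DataFrame(cols, index=idx)), meta, truth


def simulate_count_experiment(
    n_windows: int,
    effect_fraction: float,
    fold: float,
    phi: float,
    mean: float,
    seed: int,
    lib_sigma: float = 0.3,
    species: tuple[str, ...] = ("human", "chimp", "macaque"),
    n_per_group: int = 3,
) -> tuple[CountMatrix, list[SampleMeta], pd.DataFrame]:
    """NB counts with a fraction of windows shifted ``fold``-x in one species.

    Affected windows and their species are drawn uniformly; the truth
    frame records, per window, the shifted species ('' if none).
    """
    rng = np.random.default_rng(seed)
    n_eff = int(round(effect_fraction * n_windows))
    eff_windows = rng.choice(n_windows, size=n_eff, replace=False)
    eff_species = rng.choice(len(species), size=n_eff)
    shift = {}
    for w, s in zip(eff_windows, eff_species):
        shift[int(w)] = species[int(s)]
    mu_base = np.full(n_windows, mean)
    cols, meta = {}, []
    for sp in species:
        mu_sp = mu_base.copy()
        for w, s in shift.items():
            if s == sp:
                mu_sp[w] *= fold
        for i in range(1, n_per_group + 1):
            sid = f"{sp}_fib_{i}"
            lf = float(np.exp(rng.normal(0.0, lib_sigma))) if lib_sigma > 0 else 1.0
            r = 1.0 / phi
            mu = mu_sp * lf
            p = r / (r + mu)
            cols[sid] = rng.negative_binomial(r, p)
            meta.append(SampleMeta(sid, sp, "fibroblast", f"{sp[0]}{i}"))
    idx = [f"w{i}" for i in range(n_windows)]
    truth = pd.DataFrame(
        {"shifted_species": [shift.get(i, "") for i in range(n_windows)]}, index=idx
    )
    return CountMatrix(pd.DataFrame(cols, index=idx)), meta, truth
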