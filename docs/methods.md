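# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices, and the limitations of `dhsevo`. Everything stated
here is computed by the package's tests or scripts; nothing is quoted from
external results.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); 1-based
output would be formatting only. Chromosome names are taken verbatim from
inputs. Windows on configured excluded chromosomes (default `{chrY}`) are
dropped, since mixed-sex sample sets make Y-linked signal uninterpretable.
Orthology maps are stored as a minimal chain-file analog — one TSV line per
equal-length alignment block (`src_chrom src_start src_end tgt_chrom
tgt_start tgt_end strand`) — which preserves exactly the semantics the
filters need (piecewise 1:1 correspondence, orientation, indels) without
UCSC chain parsing.

## Interval lifting and reciprocal filtering

`lift` maps an interval if at least `min_match` (default 0.8) of its bases
land on a single target chromosome and orientation, with internal deletions
bridged. Two additional failure modes return "unmapped": source bases
covered by more than one block (duplications map ambiguously), and mapped
pieces out of collinear order. Split mappings are treated as unmapped.
`reciprocal_ok` lifts back and re-lifts forward, requiring the round trip
to reciprocally overlap ≥ `min_match` of both intervals; regions fed by
duplicated blocks fail, which is the basis of the CNV filter.

## Window construction

Union peaks are the merged top-k peaks per sample (k defaults to 100,000;
score ties break by coordinate so the set is deterministic). Regions at or
under 300 bp become one 300 bp window centered on the region (clipped at
chromosome bounds). Longer regions are tiled at 300 bp with a 200 bp step;
if the centered layout would discard ≥ 10% of the region's bases per edge,
one extra window is added and the step shrunk to cover the region exactly,
with fractional offsets rounded half-even. The leftover is split
symmetrically (⌊/2⌋ left, remainder right) — the only layout under which a
per-edge threshold is meaningful.

## Artifact filters

* **Zero-count filter**: a window is kept only if every species has ≥ 1 cut
  in ≥ 1 individual; basal DNase digestion makes truly open chromatin never
  fully empty, so empty species indicate alignment/reference dropouts.
* **Sharp-peak filter**: a region is flagged when, in any single sample, a
  30 bp span holds ≥ 75% of that sample's reads in the region. Evaluation
  is per sample (a one-sample PCR artifact should flag the region), but a
  sample must carry at least `sharp_min_reads` (default 10) reads in the
  region to trigger: with a handful of basal reads the fraction is
  meaningless (two coincident background reads are not an artifact), and
  without this guard the filter flags essentially every low-signal region.
* **Reciprocal-count filter**: non-reference windows are kept only when the
  lifted read count is within 10% of the native-assembly count; collapse of
  duplicated regions inflates lifted counts, spreading deflates them.

## Negative-binomial differential test

The classic count-model path is implemented directly: TMM normalization
(doubly trimmed M/A values, 30%/5%, inverse-binomial-variance weights,
factors rescaled to geometric mean 1; reference = sample whose upper
quartile is nearest the mean), followed by common-dispersion estimation by
conditional maximum likelihood on counts scaled and rounded to the
geometric-mean effective library size, optimized on ln φ over [1e−4, 10]
with a bounded scalar search (tolerance 1e−8). The exact test conditions on
the total of the two group sums; equalized-library counts make the group
sums NB(n·m, φ/n), and the two-sided p sums all splits with conditional
probability ≤ observed (a 1e−9 log-scale tie tolerance keeps symmetric
ties stable in floating point). Pseudo-count quantile adjustment is not
implemented; scaling+rounding preserves the structure of the test while
remaining checkable against exact enumeration (the suite verifies agreement
to 1e−12 on random fixtures, and convergence to the conditional binomial
as φ → 0).

Polarization: per pairwise comparison, p-values are BH-adjusted across all
windows; a class requires both of its comparisons at q ≤ FDR (default 1%)
with consistent direction. Windows satisfying more than one class pattern
(unpolarizable double changes) get no call. Same-class overlapping or
book-ended windows from the same source region merge into regions.

## Common regions

Per-sample count envelopes are the [q_lo, q_hi] (default 0.20/0.80)
quantiles of that sample's counts over its own species' gain regions.
Macaque has no specific set of its own; its envelope uses the pooled
human+chimp **loss** regions — the regions where macaque itself is
hypersensitive at differential-site intensity — falling back to pooled
gains if no losses exist. (Using pooled gains directly would build the
macaque envelope from closed-chromatin counts and select nothing.)
Candidates must sit inside every sample's envelope; the band narrows in
0.01 steps until the candidate count is ≤ 1.3 × the target (default 1000),
leaving room for the appendage filter, which removes windows holding < 80%
of either same-width flank's pooled reads. At desk scale the candidate
yield is a few percent of shared sites — the same order as the full-scale
analysis, where ~10³ Common regions emerge from ~10⁶ windows — so test
configurations that need a sizable Common set use more planted shared sites
and/or the wider 0.10/0.90 envelope variant.

## Expression

Genes under 10 total tags are removed as noise. Correlation heatmaps use
library-normalized counts, Spearman by default, with average-linkage
clustering on 1 − r for leaf order. Branch-polarized DE reuses the NB
machinery per species pair; classification uses **unadjusted** p < 0.05 —
deliberately faithful to the original design and liberal, because the
"not DE between chimp and macaque" arm needs a plain p-value, not an
FDR-adjusted one. Counts are compared on shared gene ids without
coordinate lifting (exonic homology across these species is high).

## Enrichment and constraint

Nearest gene = merged-isoform span minimizing region distance (0 when
overlapping), ties broken by TSS distance then gene id. Distinct regions
sharing a nearest gene each count once. Permutation p-values use the
(1+k)/(n+1) estimator. The constrained-element null replaces block
bootstrap genome-structure correction with compartment-wise circular
rotation: all regions of a compartment shift together by one uniform
offset in the compartment's concatenated coordinate space (wrapping),
preserving region lengths and spacings exactly; z = (obs − mean)/sd over
1000 rotations, reported as 0 with a degeneracy flag when sd = 0.
Promoters are TSS ± 1 kb; compartment assignment is by majority base
overlap with ties resolved promoter > intron > intergenic.

## Selection

The acceleration test uses HKY85 with empirical base frequencies and five
branch lengths on ((human,chimp),macaque,orangutan), fitted to the intronic
background by coordinate descent (bounded Brent per parameter, stopping at
1e−6 in lnL) over Felsenstein pruning with site-pattern compression.
Gapped columns are dropped; N is missing data (partial likelihood of 1).
Invariant backgrounds return zero branch lengths, flagged.

Region models scale the neutral branch lengths by a single shared ρ ∈ [0,1]
on non-focal branches and ζ on the focal branch. The null bounds ζ ∈ [0,1]
(conservation through neutrality); the alternative frees ζ ∈ [0, 50] — a
superset of the null rather than the disjoint region ζ ≥ 1, so the models
are nested, the statistic Λ = 2ΔlnL is nonnegative by construction, and
the 50:50 χ²₀/χ²₁ boundary mixture is the appropriate reference (an
identical-sequence region gives Λ = 0, p = 0.5). A single shared ρ (rather
than per-branch scalars) keeps the null one-dimensional and the test
calibratable; simulations in the suite confirm type-I error at or below
nominal and strong power at ζ = 5. Background uncertainty is handled by
resampling background columns with replacement, refitting, and averaging
the 50 per-bootstrap p-values; this also lets constrained elements that
slipped into the background drop out of replicates. Background collection
takes non-first introns, trims 20 bp from each intron end as a fixed-width
splice-junction guard, removes DHS bases from any sample, and adds introns
nearest-first inside a ±50 kb window until 2000 gap-free aligned columns
accumulate (truncating there); otherwise the region is discarded.

## Motif scoring

PFM counts become log₂-odds with pseudocount 1 per cell against a uniform
background; both strands are scanned and N contributes 0. The
between-species statistic is the difference of best log-odds scores in
bits — equal to the log2 ratio of odds-scale best scores, and always
defined, unlike a ratio of (possibly negative) log-odds. Δ = 0 means no
difference. Quadrant counts exclude points exactly on an axis. The
projection test maps (Δx, Δy) to (Δx+Δy)/2 and applies a two-sided
rank-sum test against the Common regions (exact for small tie-free
samples, normal approximation with tie correction otherwise).

## Synthetic data generator

The generator emulates the *data-generating structure the analysis
assumes*, not real chromatin biology. A master alignment per chromosome is
simulated under HKY (κ = 2, π = (0.3, 0.2, 0.2, 0.3)) along the fixed
four-taxon tree with default branch lengths (0.007, 0.007, 0.012, 0.06,
0.035 substitutions/site) in the range of primate neutral divergences.
Chromosomes are partitioned into 6 kb cassettes, each holding a 4-exon gene
model (700 bp introns) and one element slot 800 bp downstream, so each
planted element's nearest gene is unambiguous.

Key default conditions (all configurable in `SynthConfig`):

* NB cut counts, dispersion φ = 0.2; open sites average 60 cuts per 300 bp
  element, basal digestion 3 cuts per 300 bp; library sizes log-normal
  (σ = 0.3).
* 90% of gains are completely absent in non-gaining species; 10% are
  present at one third of the open level.
* Per-element intensity multipliers are log-normal (σ = 0.8, clipped to
  [0.4, 2.5]) and shared across samples — real DHS sites span a wide
  intensity range, and this cross-sample correlation is what makes
  intensity-matched Common selection possible at all; the clip keeps the
  weakest planted effects inside the detectable regime the recovery
  analyses are calibrated to.
* Lineage-specific deletions (rate 0.001 events/base, geometric lengths,
  mean 4 bp) create the orthology-map indels; planted elements are
  protected so truth intervals stay mappable. CNV artifacts add a
  chimp-only donor segment plus a duplicate map block, so donor reads lift
  onto the element and double its lifted count. Sharp artifacts put one
  sample's reads at a single position.
* DGE counts (15 samples: 9 fibroblast + 6 LCL; macaque LCLs do not exist
  as a design point) combine gene baselines (log-normal), species effects
  (log-SD 0.1), cell-type effects (log-SD 0.6, deliberately larger than the
  species effect to reproduce the observed cell-type-dominant correlation
  structure), and NB noise (φ = 0.05). A configurable fraction
  (`de_coupling`, default 0.5) of gains/losses drives 6-fold DE of the
  nearest gene in the matching direction.
* A fraction of gains (default 0.5) carries the AP1 consensus written into
  the gaining species' sequence only; the truth table records the realized
  best-score improvement.
* Conservation tracks are 0.8 over shared sites vs 0.05 background, and
  shared sites double as the constrained-element set.

What the generator does **not** emulate: chromatin domain structure,
mappability and GC biases, diploid genotypes, peak-shape variation,
correlated artifacts, or realistic gene architecture. Passing recovery and
calibration tests therefore demonstrates correctness of the statistical
machinery under the stated model, not performance on real sequencing data.

## Problem sizes and determinism

All simulations are sized for a single CPU: calibration matrices use
20,000 windows, parameter-recovery runs 5,000 windows or 10 kb alignments,
type-I calibration 500 regions of 300 columns, and the end-to-end recovery
dataset ~100 planted elements on a 720 kb genome. Every random process
takes an explicit seed (the CLI derives per-stage seeds from one global
seed by stable hashing), and rerunning any stage with the same
configuration and seed is byte-identical.

## Known limitations

* The DE threshold (raw p < 0.05) is anti-conservative by design; treat DE
  class sizes as liberal.
* The common dispersion is a single shared φ; strongly window-specific
  overdispersion (e.g., CNV-rich regions) is only partially absorbed by
  the artifact filters.
* The selection test's two-parameter rate model cannot distinguish
  acceleration from relaxed constraint plus local mutation-rate change;
  the bootstrap-averaged p is a ranking statistic more than a calibrated
  tail probability when the background is short.
* Circular rotation preserves segment structure but, unlike a full block
  bootstrap, does not resample segment composition; its null is slightly
  narrower for small compartments.
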