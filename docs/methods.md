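# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices that were genuinely open, and what
the synthetic-data generators do and do not emulate.

## Bulk differential expression and the consensus signature

The bulk model is a multi-model, donor-matched senescence study on a
continuous log2-intensity scale (microarray-like). Expression of gene *g*
in sample *s* is

    y_gs = b_g + d_{donor(s)} + effect_gs + e_gs,

with gene baselines b_g ~ N(7, 1.5²) log2 units, a donor intercept
d ~ N(0, donor_sd²) shared by all of a donor's samples, planted condition
effects, and residual noise e ~ N(0, residual_sd²). Defaults: three
models (replicative, xray, etoposide) × three donors × {EP, senescent},
a shared program of 75 up and 209 down genes shifted by ±2.0 log2 in
every senescent arm, 300 model-private genes per model (half up, half
down), residual SD 0.5, donor SD 0.3. An optional interferon arm adds
EP/IFN sample pairs in which 19 of the shared-up and 8 of the shared-down
genes respond to treatment, plus IFN-private genes (150 up / 50 down)
outside the senescence program — interferon induces many genes that
senescence does not.

Per-model differential expression is a Welch two-sample *t*-test per gene
(senescent vs EP), with a donor-paired *t*-test available since donors
are matched. Significance is the compound gate |log2FC| > 1.0 and
*p* < 0.05, both strict, with no multiple-testing correction by default
(a Benjamini–Hochberg option exists behind a flag). Degenerate genes with
zero variance in both arms and zero mean difference get *t* = 0, *p* = 1
by convention.

The consensus signature intersects the per-model significant sets; up
members are ordered by descending mean log2FC across models (down
ascending), ties broken lexicographically by gene id so every ordering,
top-N table and GMT export is deterministic.

**Power under the default conditions.** These defaults are deliberately
noisy. A Welch test at *n* = 3 vs 3 on a 2.0-log2 effect with residual
SD 0.5 and donor SD 0.3 has per-gene power ≈ 0.8, and because the three
donor intercepts are drawn once per dataset and shared by all genes, the
variance-estimate inflation is correlated genome-wide: the realized
consensus recall in a single study fluctuates between roughly 20% and
60% of the planted shared program, while its precision stays near 100%
(three-way null intersections are vanishingly rare at 5000 genes). The
paired *t*-test removes the donor lottery but pays two degrees of
freedom (df = 2, critical *t* = 4.3) and is less powerful still. Tests
that assert near-complete recovery of the planted program under these
conditions fail, and are expected to: an intersection-of-underpowered-
tests design trades sensitivity for specificity. A moderated-variance
test would restore power ≈ 0.99 but is out of scope by design.

## Preranked GSEA

Genes are ranked by the Welch *t*-statistic of the requested contrast
(descending; metric ties broken lexicographically). The enrichment score
is the classical weighted Kolmogorov–Smirnov running sum with weight
exponent *w* (default 1; 0 gives the unweighted KS variant): a hit at
rank *i* adds |m_i|^w / Σ_set |m|^w, a miss subtracts 1/(N − N_hit), and
ES is the running-sum value of maximal |deviation| (first extremum on
ties). If every hit metric is zero the hit increments fall back to
1/N_hit. The leading edge is the set members at or before (ES > 0) /
at or after (ES < 0) the extremum.

The null distribution is **gene-label permutation**: random same-size
gene sets drawn without replacement. Phenotype permutation is
deliberately not offered — benchmark datasets may have three samples per
arm, which cannot support it. NES divides ES by the mean |null ES| over
same-sign nulls; the permutation p is (1 + #{same-sign nulls at least as
extreme}) / (1 + #same-sign), so it is never exactly zero. With +1
smoothing the estimator differs from a raw exhaustive-null ratio by
O(1/#nulls); at desk-scale exhaustive checks (C(8,3) = 56 sets) the
unsmoothed conditional ratio is the correct comparison point.

The interferon signature metric (ISM) summarizes an ISG panel per
sample as the **median of per-gene z-scores** against a reference
condition's mean and SD; panel genes with zero reference SD are dropped
with a warning. The original clinical metric's exact normalization is
not public, so this definition is a documented stand-in.

## Single-cell simulation

The lifespan generator emulates a four-group replicative-senescence
experiment (proliferating EP, quiescent, mid-passage, late-passage; 700
cells each) with planted senescent fractions 1%, 0%, 29%, 77% — the
per-group senescent counts are `round(fraction × n)`, so the planted
fractions are exact. Each cell carries a latent signature activity
a_c = state_c · shift + N(0, activity_sd²) (shift 1.5 natural-log units,
activity SD 0.3) and a SASP activity built from the standardized
signature activity plus an *empirically orthogonalized* noise vector, so
the realized Pearson correlation over the QC-passing cells equals the
target (0.8) exactly rather than only in expectation. Counts are
gamma–Poisson (negative binomial, shape θ = 25) around per-cell rates
∝ baseline_g · exp(a_c) for program genes, scaled to a lognormal library
size (mean 10⁴).

Free parameters were calibrated once, prospectively: program-gene
baselines are kept moderate (log-mean −0.25 vs 0 for background) because
*over*-expressed program genes saturate the top ranks and destroy the
rank score's sensitivity to activity; the binding noise source is rank
competition, not NB overdispersion. With these values the measured
score–score correlation reproduces the planted 0.8 within ≈ 0.03 and
mixture annotation recovers the group fractions within ≈ 1 point.

QC violators are planted by construction: low/high detected-gene cells
have their nonzero gene counts forced below/above the configured window,
high/low mitochondrial cells get fractions outside it, and every other
cell is clamped strictly inside — so a QC filter at the configured window
removes exactly the planted violators, each failing exactly one
criterion. The mitochondrial fraction is simulated directly as per-cell
metadata (no mitochondrial gene subset), since QC operates on the
fraction. Not emulated: doublets, batch effects, pseudotime trajectory
structure — conclusions from these tests say nothing about those
artefacts in real data.

## Single-cell scoring and annotation

QC windows use strict inequalities ("less than / more than"): boundary
cells are retained. Two presets from retinal and ECFC lifespan
experiments ship as `QC_PRESETS` (500–6000 genes with 1–20%
mitochondrial; 2000–9000 genes with 1–10%). Removal is attributed to the
first failing criterion in the order genes-low, genes-high, mito-high,
mito-low.

Normalization is per-cell depth scaling to a common target sum followed
by log1p. The signature score ranks genes within each cell by normalized
expression (average ranks on ties; all-zero genes share the bottom
ranks), clips ranks at r_max + 1 (default 1500), forms the Mann–Whitney
statistic U′ of the signature genes and returns

    score = 1 − U′ / U′_max,   U′_max = n(r_max + 1) − n(n + 1)/2.

Normalizing by the attainable maximum (rather than n·r_max) makes the
score exactly 0 when every signature gene lies beyond the rank cap and
exactly 1 when the signature occupies the top ranks; for n = 1 the two
conventions coincide. Being rank-based, the score is invariant to any
monotone transformation of a cell's profile. Signatures with a down-set
score as score_up − score_down.

Binary senescence annotation fits a two-component 1-D Gaussian mixture
by EM (k-means initialization with the given seed, tolerance 1e-8,
≤ 500 iterations); the higher-mean component is senescent and cells are
labelled by posterior > 0.5. Degenerate fits (component weight < 1e-3,
or constant scores) fall back to a median split — the top half of cells
by score — with a warning. This is a simple, documented annotator
(`method="gmm-2comp"`), not a reimplementation of published
senescence-index tools; with markedly unequal component weights and
variances the posterior boundary sits closer to the smaller component,
which is the main source of the ≈ 1-point fraction bias seen on
simulated data. Group comparison uses per-group mean/median plus
pairwise two-sided Mann–Whitney tests with Benjamini–Hochberg adjustment
across pairs.

## Co-expression network and virtual knockout

The network is principal-component regression ("pcNet" style): for each
gene, the expressions of all other genes are reduced to their top n_pcs
principal components (computed from the Gram matrix of centered
log-normalized values; Lanczos with a fixed start vector; each
component's sign fixed so its largest-|loading| entry is positive), and
the gene is ridge-regressed on the component scores (the PC-space normal
equations are diagonal, so β_k = v_kᵀX ᵀy / (λ_k + ridge)). Coefficients
map back to per-gene weights; row *g* of the adjacency holds the inferred
influence of every other gene on *g*. Entries below the |weight|
sparsity quantile (default 0.95) are zeroed, then the matrix is scaled to
max |weight| = 1. Constant genes keep zero rows/columns. A practical
property of this estimator: a regulator is only visible if its variation
reaches the top PCs, i.e. it must itself vary across cells — an
equal-variance gene buried in noise cannot be recovered at small n_pcs.
The default gene subset is the 500 most variable genes.

Knockout zeroes the target's row and column. Perturbation scores come
from the truncated diffusion S(A) = Σ_{t=0..horizon} (αA)^t (defaults
α = 0.5, horizon = 3): score(g) is the Euclidean distance between row g
of S(intact) and S(knockout), which is nonzero precisely when g has a
directed path of length ≤ horizon from the target. Robust z-scores are
(score − median)/MAD over non-target genes (raw MAD, unscaled); the
target's own score is reported but excluded from ranking. When
α × spectral-radius ≥ 1 the terms are not contracting and a warning is
emitted — with max |weight| normalized to 1 this is common and benign at
a finite horizon. The whole module is tagged `method="pcnet-diffusion"`
and is a simplified stand-in for tensor-decomposition/manifold-alignment
knockout tools; absolute counts of "significantly altered" genes from
such tools are not comparable.

## RIP-qPCR quantification

Percent-input normalization shifts the input Ct down by log2(dilution
factor) (1% input = 100× dilution) to represent the full material:
ΔCt = Ct_fraction − (Ct_input − log2 dilution). Then
ΔΔCt = ΔCt_RIP − ΔCt_NS and fold = 2^−ΔΔCt. Raising the dilution factor
raises ΔCt (the adjusted input Ct falls), and fold enrichment is
invariant to plate-wide Ct shifts and reciprocal under swapping RIP and
NS. Technical replicates are averaged on the Ct scale by default
(`mean_ct`); a per-replicate-fold policy exists for paired replicates.
No amplification-efficiency correction is applied.

## Pipeline determinism

A single global seed deterministically derives per-stage seeds by
hashing the stage name (SHA-256, reduced below 2³¹), so stages can rerun
independently yet reproducibly. Every stage writes its effective
parameters, seed and output SHA-256 hashes into `manifest.json`; no
output embeds timestamps, so reruns with the same configuration are
byte-identical.

## Problem sizes used in the checks

The test suite exercises the full default bulk design (5000 genes,
3 models × 3 donors × 2 arms + IFN arm) and the full default lifespan
design (2800 cells + 40 planted QC violators × 2000 genes); exhaustive
GSEA oracles run on an 8-gene universe (all 56 three-gene sets); the
benchmark discrimination check uses 20 independently seeded studies; the
knockout-recovery check uses five 250-cell, 200-gene simulations with a
planted 10-target driver module. These sizes were chosen as the smallest
that preserve each check's statistical meaning.
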