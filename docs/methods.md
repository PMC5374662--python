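# Methods

This note documents the models behind each stage of the toolkit, the
defaults and why they were chosen, the numerical conventions, and the known
limitations — in particular what the synthetic benchmark does and does not
say about real proteomics data.

## Simulated data

The generator emulates a two-class spectral-count experiment with planted
class and batch effects.

**Base counts.** Each protein receives a mean abundance drawn log-uniformly
from [5, 500]; counts across samples are i.i.d. negative binomial with that
mean and quadratic over-dispersion `var = μ + φμ²`, φ = 0.2. The log-uniform
mean reproduces the orders-of-magnitude abundance spread of shotgun
proteomics; φ = 0.2 (CV ≈ 46% at high abundance) is a moderate,
realistic level of biological-plus-technical noise for spectral counts. All
samples are exchangeable before effects are inserted, so the base matrix is
a genuine null.

**Class effects.** Exactly `round(0.20 · n_proteins)` proteins are chosen
uniformly at random; each gets one multiplicative increase drawn uniformly
from the five-level menu (+20, +50, +80, +100, +200%, i.e. multipliers
1.2–3.0), applied to its values in every `D*` sample. Class-`D` samples are
untouched, so the spike-in direction is a pure increase in the disease
class.

**Batch effects.** Each class is split evenly into batches 1 and 2 (the
default design is 4 samples per class, hence 2 per class per batch). In the
affected batch (batch 2 by default; the choice is symmetric and logged),
*every* protein is multiplied by an independently drawn level from the same
menu. Two properties follow: batch effects touch all variables while class
effects touch 20%, so batch variation dominates total variance; and the
per-protein effect sizes are uneven, so no global normalization (which
applies one correction per sample) can undo them. A second, milder menu
(+10/30/50/70/90%) ships as a preset for two-cohort pooling experiments.

**Defaults.** `n_proteins = 1100` — chosen so the default 20% differential
fraction yields 220 truth proteins, enough to fill the 101 true-positive
pseudo-complexes (which need at least 202). Post-effect values stay
real-valued rather than being re-rounded to integers: downstream methods are
rank- or t-based, and re-rounding would silently erase small effects at low
counts. The clean and noisy matrices of a pair share ids and ground truth;
unaffected-batch columns are bitwise identical between them.

**What the generator does not emulate:** missing values, run-order drift,
correlated (co-regulated) proteins, more than two classes, disease
subpopulations, or batch effects that are non-multiplicative or
sample-rank-preserving. Conclusions about rank-based methods' resistance
therefore apply to multiplicative per-protein batch distortions; a batch
effect that reorders proteins *within* a sample in a class-correlated way
could defeat them.

## Correction methods

**Quantile normalization** maps each sample onto the across-sample mean of
sorted vectors; tied values share the mean of the quantile targets their run
spans (deterministic; note that with ties the post-normalization multisets
are no longer exactly identical across samples). **Linear scaling** equalizes
sample totals at the global mean total.

**Empirical-Bayes location/scale correction (ComBat).** The parametric
variant only. Values are log2(x+1)-transformed by default (the model is
additive; the spike-ins are multiplicative), standardized per protein using
a design with batch indicators and — by default — the class label as a
protected covariate, after which per-batch per-protein location (γ) and
scale (δ²) effects are estimated and shrunk toward batch-level priors
(normal for γ, inverse-gamma for δ²) with method-of-moments hyperpriors and
a fixed-point iteration (elementwise relative-change convergence, tolerance
1e-6, max 500 iterations). The fit refuses designs where class is perfectly
confounded with batch. Back-transformed output is floored at zero; the floor
is cosmetic (counts cannot be negative) and does not affect the modelling
scale.

A behaviour worth knowing: on this benchmark the corrected data can yield
*higher* t-test power than the clean, batch-free matrix. The EB machinery
moderates per-protein variances across the batch dimension, which at 4
samples per class stabilizes the t-statistic denominators — a genuine
alteration of the data's variance structure, not a bug. It is the same
mechanism by which the corrector "introduces" discoveries, and is why
precision on corrected data tends to lag the uncorrected analysis.

## PC-based diagnosis and removal

Proteins are first ranked by across-sample variance (raw scale) and the top
20% retained; this is sufficient for batch detection and avoids dragging a
thousand near-constant variables into the decomposition. PCA is then an SVD
of the per-protein-centered matrix with samples as observations. Values are
log2(x+1)-transformed inside the PCA by default: the planted effects are
multiplicative, so they are additive — and appear as clean per-sample score
shifts — on the log scale. (On the raw scale the batch shift is proportional
to abundance, and the abundance spread smears it across many components; in
100 default replicates the log-scale PCA identifies PC1 as batch-associated
and PC2 as class-associated in 100/100, the raw-scale PCA in ~30/100.) No
unit-variance scaling: the variance ranking is the point of the
preselection. Loading signs are fixed (largest-|loading| positive) for
determinism.

**Association and dominance.** Each component's scores are tested against
class and against batch (two-sample t-test; one-way ANOVA when more than two
batch groups). A factor dominates a component when its p < 0.01 while the
other factor's p ≥ 0.01; both below → "both", neither → "neither". The 0.01
threshold is an explicit stand-in for what is usually judged visually from
per-PC boxplots.

**Removal and clustering.** The batch-removal workflow drops every
batch-dominant component among the first five (at minimum PC1 when it is
batch-dominant) and, when any remaining component is class-associated,
clusters on those components only. The restriction matters: trailing
components that associate with neither factor carry sampling noise whose
summed Euclidean contribution can exceed the class gap at n = 8, and
including them costs ~65 percentage points of perfect-recovery rate. This
mirrors the boxplot-guided practice of choosing informative PCs rather than
using the whole residual spectrum. Ward linkage, k = number of classes,
deterministic.

With two pooled cohorts that share truth but carry different batch menus,
the dominant variation splits into a common "affected batches up" direction
and an inter-cohort contrast; after dropping the batch-dominant components
the class component recovers a perfect 2-cluster split in ~70–80% of
replicates. The failures are replicates where residual batch leakage into
the class component shrinks the between-class gap below the within-class
spread — one sample then lands on the wrong side of Ward's variance cut even
though the classes remain linearly separable on that component.

**Traceback.** A component's proteins are those whose |loading| exceeds
mean + 2·SD of that component's |loadings| (strength) *and* whose largest
|loading| among the first five components is on that component
(exclusivity). Both knobs are configurable; the "−PC1" workflow (remove the
original PC1's proteins, re-run the PCA, trace the new PC1) and the matched
top-n t-statistic ranking are provided for feature-set comparisons. On this
generator the top-variance proteins are already enriched for truth, so
removing the PC1 set tends to *remove* truth — the direction of the
PC1-vs-−PC1 comparison is a property of the dataset, not of the procedure.

## Feature selection

**SP** — per-protein two-sample t-test, pooled-variance Student's t by
default (Welch available). At 4 samples per class on over-dispersed counts
the pooled test is correctly calibrated (measured type-I ≈ 0.044 at nominal
0.05) where Welch is conservative (≈ 0.035). Benjamini-Hochberg adjustment
when an FDR level is set.

**HE** — upper-tail hypergeometric over-representation of a differential
protein set in each complex, BH-adjusted by default. Note that with
2–3-member pseudo-complexes the smallest attainable hypergeometric p is far
above any BH threshold over ~200 complexes, so the benchmark harness runs HE
at raw α following the raw-α t-test set.

**SNET / FSNET** — rank scores per sample (descending abundance, ties share
their run's mean percentile): SNET scores 1 inside the top `alpha_top`
fraction and 0 outside; FSNET ramps linearly from 1 at `alpha_top` to 0 at
`alpha_lo`. Defaults `alpha_top = 0.10`, `alpha_lo = 0.20`, `beta = 0.5`,
1000 permutations, α = 0.05 — the published defaults of this method family.
The per-complex statistic contrasts, between the two classes, the per-sample
difference of the D-referenced and D*-referenced complex scores (Welch t on
the differences); the null is obtained by class-label permutation, enumerated
exhaustively whenever the number of distinct label splits does not exceed
the permutation budget (at 4 vs 4 there are only 70 splits) and sampled
otherwise, with the standard +1 correction in the sampled case.

Calibration notes: at 4 vs 4 the permutation null is discrete and heavily
tied, so null p-values are conservative (selection rate ≤ α) but not
uniform; uniformity (KS) holds at calibration sizes with a rich permutation
group (e.g. 20 vs 20). Complexes with no contributing member in either
class report statistic 0 and p = 1 by convention.

## Pseudo-complexes

True-positive complexes: Euclidean distances between the differential
proteins' sample vectors, Ward linkage, dendrogram leaf order (standard
left-to-right; no optimal-leaf-ordering refinement, keeping the order
deterministic), split into 101 contiguous blocks of near-equal size (larger
blocks first when the remainder is nonzero). True negatives: an equal number
of randomly chosen non-differential proteins, reordered by 1 − Pearson
correlation, split the same way. Purity p replaces `round((1−p)·size)`
members per TP complex with distinct non-differential proteins drawn without
replacement across the whole set, preserving counts and sizes exactly. With
size-2 blocks a 75% purity is not representable per complex (rounding keeps
both members); realized purity equals nominal purity exactly when block
sizes are multiples of 4.

## Evaluation

Precision, recall, harmonic-mean F. Zero selected features reports
precision 1.0 (no false positives) with an explicit `n_selected = 0` flag;
recall and F are then 0. Report tables round to 2 decimals. The benchmark
harness crosses replicates × conditions (clean / noisy / each corrector) ×
methods × purity levels into one tidy table, bitwise reproducible from its
seed.

## Problem sizes

Replicate counts used by the tests and the acceptance script — 100
replicates for PC-dominance and correction orderings, 50 for the pooled
two-cohort experiment, 20 for the RBNA resistance grid (×3 purity levels,
200 permutations), ~10⁴ protein-replicates for the type-I calibration — are
the package's defaults for desk-scale reproduction; all are configurable
upward.

## Known limitations

* The generator's proteins are independent; real co-regulation would make
  pseudo-complexes easier for expression-clustering and harder for
  enrichment than simulated here.
* RBNA resistance is demonstrated against multiplicative per-protein batch
  distortions; the exact-invariance guarantee covers only within-sample
  monotone transforms.
* The EB corrector's variance moderation can overshoot clean-data power at
  very small n (see above), so F-score comparisons against the no-batch
  condition conflate correction quality with test moderation.
* Complex-level recall of the rank-based selectors is bounded by the
  fraction of complexes whose members can reach the top ranks at all; with
  abundances spanning two orders of magnitude most low-abundance complexes
  are untestable by construction.
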