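# Methods

## Design overview

The package models a two-condition (drug-sensitive vs drug-resistant)
multi-platform microarray study. Three layers are processed
independently up to per-feature differential-expression calls and then
integrated: differentially expressed (DE) miRNAs are linked to their
predicted DE targets, genes altered at both the mRNA and protein layer
form a "core", and every predicted (miRNA, gene) pair with all three
layers DE is classified as a regulatory loop by its sign pattern.

## Preprocessing per platform

**Two-color gene arrays.** Features whose foreground falls below the
local background in strictly more than 60% of arrays are removed. The
rule counts arrays, with the denominator restricted to arrays where the
feature is present; on a two-color array a feature counts as "below
background" only when both channels are below their local backgrounds
(i.e. the feature is undetected on that hybridization). Backgrounds are
then subtracted (floored at 0.5 before logging), log-ratios M =
log2(ch2/ch1) are lowess-normalized against the average log-intensity A
(span 0.3, 3 robustness iterations — the usual MA-normalization
defaults; missing pairs pass through), and each array is split back
into two per-channel columns A ± M/2 labelled with the channel's
condition. This puts two-color data in the same two-group layout as
single-channel data, so one fitting routine serves all layers, and
dye-swap orientation is handled by the explicit channel→condition
metadata rather than by sign conventions. For callers who prefer
ratio-space processing, `collapse_replicates` also accepts log-ratio
columns annotated with the dye of the resistant channel (Cy5 =
reference orientation, Cy3 = swapped, sign-flipped before averaging).

**Antibody (protein) arrays.** Foregrounds are normexp
background-corrected: the observed intensity is modelled as
normal background (mu, sigma) plus exponential signal (mean alpha), and
the corrected value is E[signal | observed], the mean of a normal
truncated to (0, ∞) — strictly positive, so log-ratios always exist.
Parameters are estimated per array by method of moments: (mu, sigma)
from the local-background distribution, alpha from mean(fg − bg); a
full maximum-likelihood fit would change the estimates little at panel
sizes of several hundred and is not needed for the downstream ratio
statistics. The offset default (16) is the common practice value for
damping low-intensity ratio variance. Log-ratios are normalized through
a rank-invariant feature subset: features whose within-channel ranks
differ by less than 5% of the subset size, re-selected iteratively
until stable; a lowess curve through that subset is subtracted from all
features. If fewer than 10 rank-invariant features remain (small or
highly regulated panels), the pipeline falls back to plain lowess and
logs it.

**Single-channel miRNA arrays.** After the same low-signal filter, a
variance-stabilizing transform is applied: per-sample affine
calibration matching first/third quartiles to the first sample,
followed by glog2(y) = log2(y + sqrt(y² + c²)) − 1, which equals log2
for y ≫ c and damps the variance of near-background values. The
cofactor c is data-driven: a first guess sqrt(a/b) from the
variance–mean relation var ≈ a + b·mean² (additive variance a from the
lowest-intensity decile, multiplicative coefficient b from the top
decile — the chi-square small-sample bias of the replicate variances
cancels in the ratio), then refined on a log-grid by directly
minimizing the spread of replicate-residual scale across intensity
quartiles, the quantity the transform exists to flatten. This is a
deliberate simplification of full maximum-likelihood variance
stabilization: the pipeline needs stabilized variances, not
bit-compatibility with any particular implementation.

**Technical replicates** are averaged (missing-aware) into one column
per (condition, biological replicate) before model fitting, giving the
3-vs-3 design used everywhere downstream. Modelling technical
replicates inside the linear fit (duplicate-correlation style) is out
of scope; collapse-first is this package's convention.

## Differential expression

`ModeratedTTest(matrix).fit()` computes per-feature two-sample
statistics (complete-case: features with fewer than two finite values
in either condition are excluded from the fit and from the FDR
denominator and can never be selected), estimates the variance prior
(d₀, s₀²) by digamma/trigamma moment matching on log s² (trigamma
inverted by Newton iteration, relative tolerance 1e−8; d₀ = ∞ when the
spread of log s² does not exceed pure sampling noise, with a normal
reference distribution in that limit; d₀ = 0 accepted as an explicit
no-shrinkage override reproducing the ordinary pooled t exactly),
moderates the t-statistics, adjusts p-values by Benjamini–Hochberg, and
applies the layer thresholds. All boundaries are inclusive: FDR exactly
at the cap and |logFC| exactly at the gate are selected. Layer
defaults: mRNA (FDR ≤ 0.01, |logFC| ≥ 1), miRNA (FDR ≤ 0.1), protein
(FDR ≤ 0.1).

The 2^−ΔΔCt fold-change helper implements the standard relative
quantification arithmetic for qRT-PCR validation data; it is pure
arithmetic, no Ct-level modelling.

## Enrichment, clustering, networks

Over-representation of catalog categories in the up- and down-regulated
lists uses the upper-tail hypergeometric probability P(X ≥ overlap)
with all counts restricted to the analysis universe (features surviving
the filter and mapping to a gene; configurable). Categories with zero
overlap are reported with p = 1 rather than dropped so the BH
denominator does not depend on the particular selection. Genomic miRNA
clusters are single-linkage groups per chromosome with consecutive gaps
strictly below 1000 kb (a gap of exactly 1000 kb splits). Networks
carry one node per miRNA/gene with mRNA and protein DE directions as
attributes (the "fill" and "border" colors of the usual figures),
miRNA→gene edges of kind `mirna_target` and pathway edges of kind
`gene_gene` restricted to present nodes; subnetwork extraction keeps a
gene set plus adjacent miRNAs and is idempotent. Export is Cytoscape
SIF plus a node-attribute table; rendering is presentation, not part of
the artifact.

## Integration and loop classification

Pairing defaults to the sign rule — a predicted (miRNA, target) pair is
anti-regulated iff the two log fold changes have opposite signs — since
with three biological replicates per condition, per-pair correlations
are unstable; a correlation mode (Pearson across matched replicate
profiles, |r| ≥ 0.7, at least 4 matched samples) is provided for
completeness. Predicted pairs are those in the target table with score
≤ −0.1 by default (mirSVR-style scores, more negative = stronger; the
cutoff is configurable, and duplicate rows collapse to the most
negative score). Loops require the miRNA, the target mRNA and the
target protein all DE; type A requires the protein concordant with the
mRNA (degradation propagating to protein), and the remaining sign
pattern (mRNA anti, protein co with the miRNA) is reported as
`unclassified` rather than forced into type C, because only three
mechanisms are defined. Protein features map to genes by shared
identifier; one-to-many mappings expand to multiple triplets, but
duplicate (miRNA, gene) triplets are collapsed deterministically (first
protein in id order).

## Synthetic data generator

The generator emulates the study conditions end to end and is the
package's test bed. Defaults: 10,000 genes (two-color), 800 miRNAs
(single-channel), a 725-antibody panel whose features are a subset of
the gene ids; 3 biological × 4 technical replicates per condition with
dye swap on even technical replicates; 400 DE genes, 47 DE miRNAs, 150
DE proteins; 38/34/28 planted loops of types A/B/C at |logFC| = 1.5;
noise sd 0.25 on the log2 scale split evenly between biological
(sd/√2 per replicate) and technical components. Platform sizes,
replicate layout, DE-miRNA count and loop counts echo the emulated
study scenario; the noise model is Gaussian on the log scale, chosen
for analyzability since no noise model is given by the design being
emulated.

Intensities follow intensity = B + S_f · 2^δ with background B ~
N(100, 20²) per spot/channel and per-feature brightness S_f exponential
across features (mean 1000) — the distributional assumption under which
normexp is the right background correction. δ carries the condition
effect (±logFC/2) plus biological and technical noise. Specific
generator choices worth knowing:

* The reported local background equals the true background component,
  so at noise sd → 0 the planted fold changes are recovered exactly —
  a closed-form anchor for tests.
* Planted DE features draw a shifted exponential brightness (≥ the
  exponential mean), so they are always expressed above background:
  recovery rates then measure the pipeline, not whether a planted
  feature happened to be too dim to detect. Null features keep the
  plain exponential.
* Planted low-signal features (default 200, among null genes) fall
  below background in exactly ⌈0.9 · n_arrays⌉ arrays and all other
  features never do, so the filter's ground truth is exact.
* The target table contains every planted (miRNA, gene) loop pair plus
  decoy pairs (default 400) with scores in the same range; decoys never
  coincide with planted pairs and never connect a DE miRNA to a gene DE
  at both the mRNA and protein layers, so the planted loop list is the
  complete set of true triplets and "spurious" is well defined.
* A gene-gene edge list and a toy annotation catalog (one genuinely
  enriched category among random ones) are included so the network and
  enrichment stages run on every fixture.

What the generator does **not** emulate: spatial/print-tip artifacts,
cross-hybridization, antibody cross-reactivity, probe-level multiple
probes per gene, intensity-dependent dye bias (dye swap is pure channel
exchange), or heavy-tailed outlier spots. Passing recovery tests
therefore demonstrate the correctness of the statistical chain under a
clean, known-truth regime — not robustness to every artifact of real
arrays.

## Numerical choices and degenerate inputs

* normexp evaluates the truncated-normal mean through log-space normal
  CDFs, so it is stable arbitrarily deep in the left tail; outputs are
  floored at 1e−12 against underflow.
* Lowess requires ≥ 10 finite (M, A) pairs, rank-invariant
  normalization ≥ 20 features and ≥ 10 invariant ones (with the lowess
  fallback above); a rank-invariant set collapsing to one intensity
  yields a constant (median) correction.
* BH ties are broken by stable sort; adjusted values are capped at 1.
* All tables are tab-separated, floats written with 17 significant
  digits, missing values as `NA`; write→read round trips are exact,
  and pipeline reruns with the same seed are byte-identical (the run
  manifest hashes only analysis-relevant settings, not paths).

## Problem sizes used in checks

The package's own test suite runs the full study at its default scale
(10,000 genes / 800 miRNAs / 725 proteins, three generator seeds) for
loop recovery, a 2000-feature × 200-replicate global-null simulation
for FDR calibration, and scaled-down fixtures (a few hundred features)
for mechanics; these sizes were chosen so the whole suite documents the
defaults while remaining quick to run on a laptop.

## Known limitations

* Two-group designs only; no general linear models, no multi-factor
  contrasts, no duplicate-correlation modelling of technical
  replicates.
* The channel-split representation of two-color data treats the two
  channels of one array as independent samples; with dye-swapped
  technical replicates collapsed first, the residual pairing
  correlation is absorbed into the biological-replicate variance, which
  is slightly conservative.
* Enrichment is a plain hypergeometric over user-supplied catalogs; it
  does not reproduce the modified Fisher/EASE scores of annotation web
  tools, and no annotation databases are bundled.
* Target predictions are consumed as a scored table; no target
  prediction is performed.
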