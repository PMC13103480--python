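# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `orchard` package.

## Genomic relationships and structure

The relationship matrix is VanRaden method 1 with observed-sample allele
frequencies: `G = WW'/(2Σp_k(1−p_k))`, `W = M − 2p` column-centered
dosages. Alternatives (method 2's per-marker scaling, external reference
frequencies) were not implemented: the downstream REML and kernel models
only require a PSD relatedness kernel, and method 1 is the common default
of GCTA-family tools. Missing genotypes are mean-imputed per marker before
the GRM; at the missingness levels the marker filters admit (≤ 20%) the
GRM is insensitive to this choice, and genuine imputation/phasing is
upstream tooling outside this package's scope.

PCA operates on the double-centered GRM; the variance explained by
component k is its eigenvalue over the sum of positive eigenvalues.
Centering makes the "two identical individuals" case degenerate by
construction (no between-individual variance ⇒ zero fraction).

## LD, decay curves and the background threshold

`r²` is the squared correlation of allele indicators across haplotypes when
phase is available ("phased" mode, equal to `D²/(p₁q₁p₂q₂)`), else the
squared dosage correlation (composite LD). The mode is recorded in every
result because the two statistics differ under inbreeding/structure.

Decay curves bin within-chromosome pair distances (defaults: 100 bp bins to
100 kb, both configurable — synthetic genomes at other scales pass wider
bins). Before reading the threshold crossing the binned means are smoothed
by an edge-normalized running mean (window 5 bins) and forced monotone
non-increasing by a cumulative minimum, so a single noisy bin cannot fake a
crossing; a curve that never drops below the threshold reports an infinite
crossing distance rather than a fabricated one. The background threshold is
the 99th percentile of inter-chromosomal pair `r²` from 1000 markers
sampled per chromosome. Physical distance in bp is used throughout.

## Effective number of independent tests

`Me` follows the Li–Ji / Galwey eigenvalue-correction family, the approach
behind GEC-style calculators: markers are processed in consecutive
non-overlapping within-chromosome blocks (default 200), each block
contributes `m_block − Σ(λ−1)⁺` from its marker correlation spectrum, and
blocks sum. This member of the family has the required limits exactly:
orthogonal markers give `Me = m`, duplicated pairs give `m/2`, and the
three-marker `r = 0.5` case gives `λ = {2, ½, ½} ⇒ Me = 2`. The exact
regularization of the original calculator is unpublished detail; the block
size is exposed and logged. Significance thresholds are `α/Me` and `1/Me`.
The reporting helper truncates (rather than rounds) to two significant
figures, matching the printing convention of the upstream calculator
(0.05/5,235,150 = 9.55e−9, printed 9.5e−9).

## GREML

Single-trait: `y = Xb + g + e`, `g ~ N(0, K σ²_G)`. The kernel is
eigendecomposed once; each AI-REML iteration then costs O(n). Updates are
average-information steps with step-halving against the REML
log-likelihood and an EM-REML fallback when the AI proposal is
inadmissible, so the accepted likelihood sequence is monotone
non-decreasing. Variances are floored at `1e−8 · var(y)` (boundary fits are
flagged), convergence is `|Δ logL| < 1e−6`, and standard errors come from
the inverse AI matrix with the delta method for `h²`.

Bivariate: the 2×2 genetic and residual covariance matrices are estimated
by quasi-Newton (L-BFGS-B) maximization of the exact REML log-likelihood
under a log-variance / atanh-correlation parameterization. This was chosen
over a bivariate AI-REML loop because the parameterization enforces PSD
proposals and the `r_g ∈ [−1, 1]` bound *exactly* (no projection step
needed) and converges robustly from univariate starting values; the
univariate fits themselves remain AI-REML. When both traits share one
record set the likelihood reduces to independent 2×2 blocks in the GRM
eigenbasis (O(n) per evaluation); otherwise a dense Cholesky path handles
overlapping or disjoint record sets, estimating a residual covariance only
where records overlap. Standard errors use a finite-difference observed
information matrix and the delta method.

The reliability gate (`SE(h²) ≤ h²`) guards genetic-correlation analyses;
it can be overridden explicitly.

Identifiability note: the sampling SE of `ĥ²` on an unstructured panel
scales like `√(2m)/n`. Recovery and null tests are therefore run in
regimes with `n ≫ √(2m)`; in the opposite regime the likelihood is nearly
flat in `h²` and single-seed estimates are uninformative by nature, not by
implementation.

## Mixed-model GWAS

Per marker: `y = Xb + sβ + g + e` with the GRM eigendecomposed once. The
default is P3D — variance components fitted once under the null and reused
for every marker — which makes each marker a weighted least-squares solve
and the whole scan a few matrix products. An exact mode re-optimizes the
variance ratio per marker by bounded 1-D search on `log(σ²_G/σ²_e)` with
the total variance profiled out; the two modes agree within a few percent
of a standard error under moderate polygenicity, and the mode is recorded
in the result. Wald p-values against χ²₁ match the convention of
GEMMA-style tools. Markers collinear with the covariates get a missing
p-value with a logged count rather than a crash. QTL clustering is purely
positional (markers below the suggestive threshold within a 200 kb window
merge; a cluster is "significant" if any member passes the significant
threshold) — the window is a declared free parameter since no clustering
rule is standard, and positional merging is deterministic where LD-based
merging is not. λ_gc is the median observed χ² over 0.4549.

## Kernel models and the Gibbs sampler

The five prediction models and their kernels are listed in the README. All
kernels live at *record* level (a record is an individual × collection ×
trait cell), so the same machinery covers multi-environment and multi-trait
data and the interaction kernels are literally Hadamard products of the
realized matrices. A model that needs two or more environments or traits
refuses degenerate input by default; `strict=False` builds the degenerate
kernels anyway (single-environment `V_E` is all-ones, so `V_GE ≡ V_G`) for
didactic use.

The sampler eigendecomposes each kernel once (eigenvalues below
`1e−8 · λ_max` dropped) and samples each kernel's effect vector in its
rotated basis, where the full conditional is a set of independent normals.
Variance components get scaled-inverse-chi-square full conditionals with
prior df 5 and scales chosen so each kernel's prior mode is
`var(y)·R²/K` (K kernels, `R² = 0.5`) and the residual's is
`var(y)·(1−R²)` — the convention of the BGLR R package, whose mechanism
this fitter mirrors. The intercept has a flat prior. Missing phenotypes are
imputed each iteration from the current linear predictor plus a residual
draw (data augmentation), which is exactly how masked cross-validation
records acquire GEBVs: GEBV = posterior mean of the sum of
genetic-containing effects (G, plus GE/GT where present). Chains are
deterministic under the seed; an effective-sample-size estimate for
`σ²_G` (initial-positive-sequence estimator) is reported.

Chain lengths: the study-scale default is 25,000 burn-in + 25,000 sampling
(thinning 5). The test suite and examples run 400–2,000 + 800–6,000, which
posterior-mean checks against closed-form BLUP (pinned variances) and
against 2-D numerical integration of the variance posterior show is ample
at those problem sizes.

A caution the test suite encodes: for a boundary-constrained variance the
*posterior mean* is not the REML point estimate. Under the default priors a
pure-noise phenotype yields a posterior mean `σ²_G` around 0.15–0.2 var(y)
even at n = 600 (confirmed by direct numerical integration, and nearly
unchanged as the prior df → 0); the correct null expectation is that GEBVs
are uncorrelated with anything, which holds, not that the posterior mean
collapses to zero.

## Cross-validation and scenario tables

CV1 masks a 20% sample of individuals (all their records); CV2 masks 20%
of records independently within each trait × collection cell, so an
individual can be observed for some traits and masked for others — the
regime where correlated-trait models borrow strength. Masks are
deterministic per (seed, replicate) and *shared across models within a
replicate*; model comparisons are paired t-tests on per-replicate mean
accuracies (pairing on shared masks is the defensible reading of
"t-tests over the replicates"). Accuracy is the Pearson correlation between
raw observed phenotypes and GEBVs, reported per validation group. Kernels
and their eigendecompositions are built once per model and reused across
replicates, since masking changes only `y`.

Inter-collection prediction fits on reference-collection records with
validation records present but masked, then scores each validation
collection separately; reference/validation label overlap is an error
(within-collection accuracy belongs to CV1).

## The synthetic-data generator

Genotypes: a Li–Stephens-style haplotype-copying model. A set of ancestral
pools diverges from common base frequencies by a Balding–Nichols Beta model
(default F_ST 0.15); each pool holds a small number of ancestral haplotypes
(defaults: 3 pools × 4 haplotypes — few ancestors is what creates usable
short-range LD in this model). Each individual draws admixture proportions
from a per-collection Dirichlet; each haplotype is a mosaic of ancestral
haplotypes with per-collection switch rates per bp — a larger rate means
shorter copied segments and faster within-collection LD decay, the single
contrast the diversity analyses need. Mosaic-copying was chosen over
coalescent simulation because it gives direct per-collection control of
decay at trivial cost; it makes no claim to demographic realism, so
site-frequency-spectrum shape, recombination hotspots and mutation are out
of scope. Clone pairs are exact row copies across two collections (applied
after missingness injection, so masks match too); monomorphic markers are
repaired by a single allele flip in a non-clone individual when polymorphism
is requested. `SimGenoConfig.study_default()` reproduces the reference
three-collection layout (225/224/161 individuals, 20 clone pairs between
the first and third collections, faster decay in the second).

Phenotypes: causal effects at a shared marker set are drawn jointly across
traits from a zero-mean Gaussian with the target genetic-correlation
matrix; collection-specific effects are
`√(1−f)·shared + √f·deviation`, which makes the cross-collection genetic
correlation of true breeding values `1−f` — the generative form induced by
a Hadamard GxE kernel. Residual noise is calibrated per collection so the
within-collection `h²` meets its target; environment means are fixed
offsets. Ground truth (breeding values per collection, deviations, causal
effects, realized h²) is returned for recovery tests.

Repeat-measurement protocols: a trait may be recorded as the mean of k or
the max of k per-fruit values, where a per-fruit value is the tree's
genetic value plus tree residual plus within-tree noise with a configurable
coefficient of variation (default 0.15 of the environment mean). The
within-tree CV is a free parameter, not an estimate — within-tree
fruit-weight variance is rarely published for orchard panels. Within-tree
noise is
Gaussian by default; a lognormal option (shape parameter
`within_tree_skew`) models the right-skewed fruit-size distributions of
real canopies. The skew matters quantitatively: with Gaussian noise the
max-of-15 recorder's noise variance is capped at ~3.5× the mean-of-10
recorder's, which attenuates heritability only moderately, whereas skewed
within-tree variation lets the max protocol latch onto erratic tail draws
and realize near-zero heritability while the mean protocol stays highly
heritable — the regime observed when breeding programs record a
"largest fruit" statistic. The protocol-mismatch test scenario therefore
uses shape 1.0.

What passing tests on this generator do **not** show: robustness to real
admixture depth, allele-frequency spectra, assay error, non-additive
architecture, or year/location effects beyond a fixed collection mean.

## Problem sizes and power

Simulation sizes in the test suite (e.g. 2000 × 5000 for heritability
recovery, two collections of 150 for the GxE model comparison, three of
150 for the protocol scenario, 10–20 replicates/seeds) were chosen so each
statistical check is adequately powered: recovery tolerances sit several
standard errors wide at these n, and paired sign-consistency checks use a
GxE fraction (0.65) and heritability (0.7) giving roughly a 90%
per-replicate win probability. Larger runs change none of the qualitative
conclusions; the CLI accepts the study-scale settings.

## Known limitations

- One additive kernel per factor: no dominance/epistasis, no Gaussian
  kernels with bandwidth selection, no multi-chain convergence machinery
  beyond the ESS report.
- The bivariate dense path is O((n₁+n₂)³) per likelihood evaluation; it is
  meant for desk-scale record sets.
- P3D is the scan default; very large single-marker effects shift the
  variance-component null enough that the exact mode is preferable there.
- The pulp trait formula is implemented exactly as its source defines it
  (fruit weight over stone weight); it exceeds 1 and is not a true
  percentage — flagged here rather than silently "corrected".
- The "suggestive = 1/Me" rule is the formula consistent with the printed
  threshold pair; the upstream calculator's exact convention is not
  published.
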