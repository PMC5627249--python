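# Methods

## Model and score

Genotypes for n individuals at m SNPs form a matrix X whose columns are
standardized to mean 0 and variance 1 using the population (divide-by-n)
convention, so that for a standardized trait y the univariate least-squares
coefficient of SNP j is exactly `β_obs,j = x_j'y / n`. A standardized
quantitative trait is modelled additively, `y = Xβ + ε`, with per-SNP
effects `β_j ~ N(0, σ²)` independent across SNPs; the regional genetic
variance is `R²_true = m·σ²` and `ε ~ N(0, 1 − mσ²)`, so Var(y) = 1.

The GraBLD score is `g(x_i) = Σ_j x_ij · w_j / η_j`. The weights come from
two stages applied to external summary coefficients `β_ext` (assumed on the
per-genotype-SD scale; a per-allele → per-SD rescaling by
`sqrt(2·eaf·(1−eaf))` is available for tables carrying allele frequencies):

**Boosted tuning.** The deviation `d_j = (β_obs,j − β_ext,j)·sign(β_ext,j)`
is regressed on SNP annotations — by default the single column `|β_ext|` —
with gradient boosted regression trees under squared-error loss. SNPs are
partitioned into K = 5 contiguous genome-order blocks of near-equal size;
the prediction `d̂_j` for SNPs of a block always comes from a model trained
on the other blocks. Contiguity confines train/held-out LD sharing to two
block edges and guarantees no SNP's observed coefficient touches its own
weight (tested bitwise). Tuned weights are

    ŵ_j = sign(β_ext,j) · (|β_ext,j| + d̂_j).

This composition is the unique one under which a perfect deviation
prediction with agreeing directions returns `sign(β_ext,j)·|β_obs,j|` —
the external direction with the target-population magnitude. A verbatim
alternative composition `(β_ext − d̂)·sign(β_ext)` is retained behind
`convention="literal"` / `--literal-eq4` for comparison; composed with an
exact deviation it amplifies rather than adapts attenuated SNPs, which is
why it is not the default. SNPs with `β_ext = 0` carry no external
direction and receive weight 0 without entering the boosted fit. Tuned
magnitudes that cross zero (`|β_ext| + d̂ < 0`) are kept as sign-crossed
weights rather than truncated.

**LD correction.** `η_j` sums the squared Pearson correlation between SNP j
and every scored SNP within a window of 100 SNPs on either side (the self
term r² = 1 included, so η ≥ 1 and an isolated SNP is untouched), computed
from the calibration-cohort genotypes, truncated at chromosome ends and
never crossing a chromosome boundary (inter-chromosomal r² is sampling
noise). c duplicate SNPs each get η = c, so their corrected contributions
sum to one uncorrected SNP — the correction must therefore follow, not
precede, the boosted tuning, or the per-SNP association strength the trees
need would already be diluted.

## Boosting hyperparameters

Defaults: 2,000 trees, interaction depth 5 (interpreted as splits per tree,
implemented as best-first trees with depth+1 leaves), shrinkage 0.001, bag
fraction 0.5, five folds. The effective tree count is chosen per fold from
the maximum of the cumulative out-of-bag improvement curve (available
because bagging leaves half the SNPs out of each stage); `inner-cv`
(stagewise 5-fold cross-validation inside the training folds) and `fixed`
are alternatives. All randomness derives from a single integer seed through
`numpy.random.SeedSequence`, making refits bitwise reproducible. Additional
annotation columns can be appended to the boosting input.

## Evaluation and calibration

Prediction R² is the squared Pearson correlation between score and trait
(reported on the covariate-residualized trait when covariates are supplied;
the joint-model R² of `trait ~ score + covariates` is reported separately).
Binary discrimination is the ROC AUC (Mann–Whitney convention, ties counted
half). Calibration: a linear recalibration `trait ~ score (+ covariates)`
fitted in a training set disjoint from evaluation; the mean absolute
difference between calibrated prediction and trait in SD units; per-decile
tables (stable sort by prediction, equal-count bins, normal-approximation
95% CIs on the observed−predicted difference); and for binary traits the
Hosmer–Lemeshow statistic `Σ_g (O_g − E_g)²/(E_g(1 − E_g/n_g))` on G−2
degrees of freedom, with degenerate bins (expected events 0 or n_g) merged
into a neighbour.

## Synthetic data generator

The generator stands in for genotype panels, cohorts and consortium files
so every pipeline stage is testable offline.

*Haplotype pool.* A pool of H binary haplotypes (default 30,000) over one
contiguous region. The default block-LD model repeats a 9-SNP unit — blocks
of 3, 3, 2 and 1 SNPs at within-block r² of 0.8, 0.5, 0.2 and 0 — mixing
strong, moderate and weak LD with isolated sites as a stand-in for the
partial LD of a genotyped region. Block alleles are thresholded
equicorrelated Gaussians; the latent correlation is calibrated through the
bivariate-normal orthant probability so the realized binary correlation
hits the requested r². Each block shares one allele frequency drawn from
U[0.05, 0.95]: with heterogeneous frequencies the attainable correlation
between binary variants is capped below 1 (checked explicitly), so a
common frequency is what makes the whole r² range reachable. A mosaic
model (founder copying with geometric switch points, giving
distance-decaying LD) and a no-LD model are also provided. The pool size
matters: the pool is the population shared by the target and external
samples, and a small pool carries noise LD of order 1/H between all SNP
pairs — beyond the η window this inflates Var(g) and depresses the
recovery ratio, which is why the default is large.

*Cohorts and external study.* Individuals are two haplotypes drawn with
replacement. Effects are `β_j ~ N(0, h2/m)`; the realized regional variance
`Σβ_j²` is recorded per replicate as R²_true. The external study is an
independent draw of N individuals (default 50,000) from the same pool whose
standardized univariate coefficients `b*_j = x_j'y*/N` play the role of the
published summary statistics.

What the generator does **not** emulate: realistic allele-frequency spectra
and frequency–LD coupling, distance-decaying LD within blocks (except in
the mosaic model), population stratification, non-additive effects,
genotyping error and missingness patterns of real arrays. Passing tests
certify the algebra and the statistical behaviour of the method under the
stated generative model, not its field performance on cohort data.

## Theory experiments

`run_theory_experiment` builds, per replicate, the LD-corrected score from
the raw external coefficients (weights `b*/η`, no boosting — the
correction is what is under test) and records R²_true, Cov(g,y), Var(g) and
the prediction R². Three properties are verified over the h2 grid
(default 0.05–0.5, 1,000 replicates per set-point; tests and the
acceptance script use 200):

- unbiasedness: mean Cov(g,y) equals mean R²_true within Monte-Carlo error;
- variance excess: mean Var(g) ≥ mean R²_true;
- information loss: the ratio mean(prediction R²)/mean(R²_true) falls
  short of 1 under partial LD — ≈0.87 under the default block mixture
  (the block structure was chosen a priori from the trace identity
  ratio ≈ m/tr(RCRCR) evaluated on the design correlation matrix, which
  gives 0.90 in the ideal limit; finite external samples account for the
  rest) — and equals 1 up to sampling error when LD is absent or perfect.

η in these experiments is computed from the pool's population LD by
default (`eta_source="pool"`). The unbiasedness identity is a
population-LD statement: estimating η from a finite calibration sample
adds ≈(window pairs)/n of null-pair noise to every η_j, deflating Cov(g,y)
by 2–3% at n = 5,000 — a real (and documented) small-sample property of
the windowed estimator, reproducible via `eta_source="target"`, but not
the claim under test. The data-analysis pipeline (the `GraBLD` model
class) always uses calibration-set genotypes, as a practitioner must.

Numerical choices: correlations and scores use float32 matrices with BLAS
Gram products (full Gram per chromosome below 1,500 SNPs, a shifted
elementwise accumulation above); η windows truncate at chromosome ends;
replicate seeds spawn from one root seed.

## End-to-end recovery experiment

`run_end_to_end_recovery` exercises the full boosted pipeline against a
deliberately miscalibrated external study. Target effects follow a
two-level architecture — half the SNPs "strong" with 5× the per-SNP
magnitude of the weak half, random signs — and the external study
under-reports the strong stratum three-fold. The two strata then occupy
separated `|β_ext|` ranges, the deviation target is a learnable step
function of the boosting input, and repairing it restores the strong
stratum's share of the score; the boosted score beats the raw
external-weight score in ≥90% of replicates, and the oracle score `Xβ`
(η-corrected) bounds both.

The design is deliberate. With Gaussian effects, *inflating* the
information-rich top-|β| stratum is nearly cost-free for a
correlation-based metric and — counterintuitively — undoing it is
counterproductive: the inflated stratum's relative estimation noise is
suppressed by the inflation, and an ideal conditional-mean correction
(verified with a pooled-replicate oracle) re-weights the score toward the
noisy weak stratum and loses. *Deflating* Gaussian strata is not
learnable: the attenuated stratum's |β_ext| range collapses onto the
untouched one. A two-level architecture with an under-reported strong
stratum is the configuration in which magnitude miscalibration is both
costly and identifiable from `|β_ext|`, which is the property the boosted
tuning exists to exploit.

## Problem sizes

The reference simulation is 5,000 target individuals at 450 contiguous
SNPs with an external study of 50,000 and a 30,000-haplotype pool. The
theory property suites run at reduced sizes chosen as the smallest at
which Monte-Carlo error, not finite-sample bias, dominates each
comparison: unbiasedness/variance at m = 90, n = 2,000, N = 30,000 with
500 replicates per set-point; the no-LD limit at m = 50, N = 100,000, 200
replicates (ratio tolerance 0.02, the sampling/concavity scale of a
50-SNP region — with few SNPs the realized Σβ² varies ±20% between
replicates and the saturating map R² = v/(v+1−v) is concave, biasing the
mean ratio ~1% low); the end-to-end experiment at m = 150, n = 3,000,
N = 100,000, 50 replicates.

## Known limitations

- The windowed η is an SNP-count heuristic: in regions where LD extends
  past 100 scored SNPs (or in scores built on very dense panels) the
  window underestimates η; the window is a flag.
- Boosted tuning assumes the external-vs-target miscalibration is a
  function of the supplied annotations; miscalibration orthogonal to
  |β_ext| (e.g. random sign heterogeneity) is invisible to it.
- Binary traits use the linear-probability convention for β_obs
  (0/1 labels, standardized genotypes) to keep the deviation algebra on
  one scale; no liability-scale conversion is attempted.
- Palindromic (A/T, C/G) SNPs are dropped by default; frequency-based
  resolution requires both sources' frequencies to sit clearly off 0.5.
- Multi-allelic variants, genotype imputation and genome-build liftover
  are out of scope.
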