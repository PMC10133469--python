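# Methods

This note documents the models, the numerical choices behind them, and
what the synthetic-data tests do and do not establish.

## Compositional preprocessing

Genus-level 16S counts carry only relative information, so all modelling
happens on the simplex or in log-ratio coordinates.

**Prevalence filtering.** A genus is kept when its fraction of samples
with count > 0 is ≥ the threshold (boundary inclusive). The default 20 %
can be replaced by `scan_prevalence`, which scores each candidate
threshold by the repeated-CV misclassification of a one-component
discriminant PLS on the filtered/imputed/clr table and picks the minimum
(ties to the smallest threshold). This uses the downstream classifier
itself as the discrimination score, which keeps the pipeline
self-contained; a random-forest out-of-bag score would be an equally
valid plug-in.

**Zero replacement.** The Geometric Bayesian-multiplicative (GBM)
scheme: for sample i with depth N_i, a zero cell of genus j is imputed by
the posterior-expected proportion under a Dirichlet prior with location
t_j (the geometric mean of genus j's proportions over its non-zero
samples) and per-sample strength s_i = √N_i, giving
r_ij = s_i·t_j/(N_i + s_i). Non-zero cells are multiplied by
(1 − Σ_zeros r_ij), so every ratio among observed parts is preserved
exactly and rows close to 1. The prior parameters had to be fixed for
reproducibility; the √N strength makes imputed mass shrink as depth
grows, and the scheme is pluggable (`method="multiplicative"` imputes
δ = 0.65 × the smallest observed proportion instead). A genus with no
non-zero sample has no defined prior location and is rejected; the
prevalence filter guarantees this precondition at any threshold > 0.

**clr transform.** clr_ij = ln p_ij − mean_k ln p_ik. Rows sum to zero
(checked to 1e−10) and the transform is invariant to per-sample count
scaling. Note that after *subsetting* genera the clr reference (the
per-sample geometric mean) changes; all downstream models use the clr of
the filtered table consistently.

**A:B log-ratio.** ln(Σ archaeal counts / Σ bacterial counts) per
sample, computed on the full unfiltered table (filtering is a
discrimination device, not a statement about the community). Genera
whose domain contains "Archaea"/"Bacteria" (including "unclassified
Archaea") count toward their domain; genera with no resolvable domain
are excluded from both sums. A sample with zero archaeal or bacterial
total raises a named error rather than returning ±inf.

## PLS models

NIPALS PLS1 with X-deflation; predictors are centred and scaled to unit
variance (constant columns get scale 1), the response centred. Two-class
discrimination is PLS1 on a ±1 dummy with class assignment by prediction
sign — equivalent to two-class PLS-DA with one response. Coefficients
are reported both in autoscaled space and back-transformed.

**Dimension choice.** RSS_h is the residual sum of squares of the
full-data fit at h components (RSS_0 = total centred SS); PRESS_h sums
squared test-fold residuals within a replicate and averages over
replicates; Q²_h = 1 − PRESS_h/RSS_{h−1}. Components are added while
Q²_h > 0.0975, with a floor of one component so a final model always
exists. When RSS_{h−1} is numerically zero (< 1e−12 × RSS_0, e.g. exact
low-rank data) Q²_h is −∞: no further component can help. Folds are
seeded and stratified by class in discriminant mode; fold assignment
depends only on (seed, replicate, n, strata).

**VIP.** VIP_j = √(p · Σ_h SSY_h w_jh² / Σ_h SSY_h) with
SSY_h = q_h² t_hᵀt_h and unit-norm weights, so Σ_j VIP_j² = p exactly.

**Jack-knife intervals.** Within each CV replicate the k delete-a-fold
refits give the standard jack-knife variance
(k−1)/k · Σ_f (b_f − b̄)²; variances are averaged over replicates and
the interval is the overall mean coefficient ± t_{0.975,m−1} × SE with
m = k × replicates. Pooling all m refits into a single jack-knife sum
instead would inflate the SE by roughly √(m−1) and no variable would
ever exclude zero, which would disable selection entirely.

**Iterative selection.** Each round: pick h by Q², fit, drop every
variable failing VIP > 0.8 or whose jack-knife interval contains zero,
re-evaluate the repeated-CV criterion on the same fold seeds (so
iterations are compared net of fold noise), stop when the criterion
stops strictly improving or nothing fails. The best-criterion iteration
is returned, with ties resolved toward the smaller variable set —
without that tie-break a full model already at 0 % misclassification
could never be trimmed. If a round would empty the variable set the
previous set is returned with a warning flag.

**Validation.** Misclassification % (discriminant) or predictive
ability (squared Pearson correlation of test-fold predictions and
observations, per fold, regression) averaged folds-then-replicates, SD
across replicates. The permutation analogue shuffles only the held-out
labels before scoring (`permute="test_labels"`); with small test folds
its null mean is near 1/(n_test − 1) for predictive ability, i.e. ~1/3
for 3-fold CV of 12 samples, not zero. A `permute="full_labels"` mode
shuffles before splitting. Because the iterative selection optimises
the CV criterion, the reported CV ability of the *selected* model is
optimistically biased — the selected variables were chosen using all
samples. The honest null reference for the whole procedure is selection
re-run on permuted responses; the test-label analogue is the right
reference for a *fixed* final model.

## Bayesian linear models

y = Xβ + e with e ~ N(0, σ²I); flat priors on β bounded at ±1e6 and on
σ² on (0, 1e6]. Single-site Gibbs: each β_j from its full-conditional
normal (rejection against the bounds, which are effectively never
active), σ² from its full conditional — with a flat prior on σ² that is
a scaled inverse-χ² with n−2 degrees of freedom. Sampling uses the
sufficient statistics XᵀX, Xᵀy, so a sweep is O(p²) regardless of n.
Default chain: 60,000 iterations, 10,000 burn-in, keep every 10th →
exactly 5,000 saved samples. The test suite and the acceptance script
run reduced chains (6,000–20,000 iterations) whose Monte-Carlo error is
well below reporting resolution; this is a problem-size choice, and the
chain settings are always printed in the run log.

**Design.** Intercept + reference-coded factors (first level zero) +
centred covariates. With 26 animals crossed over 6 chambers and 6 weeks
some columns are aliased; they are dropped greedily (first come, first
kept) with a warning, as any fit on such a design implicitly must. The
diet contrast is the `diet[TMR]` coefficient, i.e. TMR − GRASS.

**Summaries.** Posterior mean/median; HPD95 as the shortest interval
containing ⌈0.95 n⌉ sorted samples; P₀ = posterior probability the
contrast exceeds 0 in the direction of its mean; P_r the same against
the relevant threshold r (default ⅓ of the phenotypic SD), so P_r ≤ P₀
by construction; the effect size is the per-sample contrast divided by
the residual SD, summarised by its median — a difference in SD units
(the natural scale for the magnitudes involved). Geweke's Z compares
the first 10 % and last 50 % of a chain with Bartlett lag-window
spectral variances (window = 4 % of the segment length); the
Monte-Carlo standard error uses the same estimator with a √n lag window
(the 4 % rule is too noisy on long chains), with batch means (√n
batches) as an alternative.

**Pre-correction.** Traits are "pre-corrected" for breed and body
weight by subtracting the centred posterior-mean contributions of those
terms, preserving the trait mean; Pearson correlations on pre-corrected
data are reported with the dispersion (1 − ρ²)/√(n − 1), a first-order
standard error matching the ± presentation convention. The within-diet
A:B regressions report both the posterior-mean-fit R² and the
least-squares R² on pre-corrected data, which need not coincide.

## Synthetic data

The generator emulates the study conditions: 26 animals (13 per diet,
breeds balanced, paired chamber/week assignment in a Latin-square-style
crossing with zero effects), 203 genera, sequencing depth ~5.06 × 10⁵
reads/sample with 30 % CV, and a target of 78 % zero counts per cell.
Per-genus baseline log-abundances are Gaussian with spread σ solved by
bisection so the expected multinomial zero fraction matches the target
(σ ≈ 7 at the defaults — a handful of genera dominate, as in real 16S
genus tables); the two most abundant genera are labelled archaeal so the
A:B ratio is defined in every sample even at extreme sparsity (dominant
rumen methanogens are likewise never absent), with further archaea drawn
at random; per-sample log-noise (SD 1) individualises communities;
counts are multinomial at the sampled depth (Dirichlet-multinomial
optionally). Diet shifts 22 genera by ±2 (default) log units; methane
yield is intercept (25 g/kg DMI for GRASS) + diet difference (−10.6 for
TMR) + breed and body-weight terms (zero by default) + Σ_j c_j · clr_j
over diet-specific driver genera + Gaussian noise (SD 1.5 default).
Driver contributions are centred within diet so the configured diet
difference is exactly the ground-truth contrast, and they use the *true*
clr (before zero handling), making truth unambiguous. One driver genus
is shared between diets with opposite-sign coefficients (a cross-over
association). Effect genera are drawn from genera whose predicted zero
probability at the mean depth is < 0.2: an effect planted in a genus
that is unobserved in half the samples lives in imputed cells and is
unrecoverable by construction, which would defeat the generator's
purpose as a ground-truth test bed.

What the generator does **not** emulate: phylogenetic or ecological
correlation between genera (baselines are independent), longitudinal
dynamics, PCR/chimera artifacts, taxonomic mis-assignment, or genuine
chamber/week effects. Passing recovery tests therefore show that the
pipeline recovers effects of the modelled kind at the study's sample
size and sparsity — not that real rumen data satisfy these assumptions.

## Numerical conventions and degenerate inputs

Same seed ⇒ bit-identical datasets, folds, chains and reports; stage
seeds derive from the master seed by CRC32 of a stage tag (< 2³¹).
Constant predictor columns are scaled by 1; a constant response, a
single-class labelling, h > min(n−1, p), all-zero samples, zero archaeal
or bacterial totals, rank-deficient designs and too-short chains all
raise named errors. Per-fold predictive ability is 0 when a test fold
has fewer than 2 samples or zero variance in either vector.

## Known limitations

* Univariate per-genus regressions estimate marginal, not conditional,
  associations: with several simultaneous drivers and n ≈ 13 per diet,
  chance clr cross-correlations can flip the sign of weak coefficients
  even with a perfect pipeline. Ground-truth sign recovery is therefore
  assessed with the joint within-diet model in the acceptance tests.
* The GBM-imputed clr of low-prevalence genera is dominated by the
  prior; its variance is inflated several-fold relative to the true clr,
  which attenuates any signal carried by such genera.
* CV ability of a model selected by CV on the same samples is
  optimistically biased (see Validation above); the pipeline reports the
  permutation analogue alongside every such number.
* The Gibbs sampler covers fixed-effects models only; no random effects
  or model comparison.
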