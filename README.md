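# rumenpls

Statistical pipeline linking rumen microbial genus abundances to enteric
methane yield under contrasting cattle diets (fresh-cut grass vs. a
high-concentrate total mixed ration), built for quantitative
microbiologists and animal scientists working with genus-level 16S count
tables and respiration-chamber phenotypes.

The data are compositional (only relative abundances are meaningful) and
extremely sparse (~78 % zero counts per sample), and the designs are small
(tens of animals). The package implements the analysis chain suited to
that regime, plus a synthetic-data generator with known ground truth so
every stage can be verified by recovery tests.

## What it computes

**Compositional preprocessing.** Genera observed in fewer than a
prevalence threshold of samples (default 20 %, selectable by a
discrimination scan) are removed; remaining zeros are imputed by a
Geometric Bayesian-multiplicative scheme (Dirichlet prior with location
t_j = the genus's geometric-mean non-zero proportion and strength
s_i = √N_i, so a zero cell becomes s_i·t_j/(N_i + s_i) and non-zero cells
are multiplicatively shrunk, preserving their ratios exactly); abundances
are then mapped to centred log-ratio coordinates
clr_ij = ln p_ij − (1/p)·Σ_k ln p_ik. The archaea:bacteria balance is
summarised per sample as A:B = ln(Σ archaeal counts / Σ bacterial counts).

**PLS modelling.** NIPALS PLS1 regression and two-class discriminant PLS
(a ±1 dummy response, class by prediction sign), with

* dimension choice by Q²_h = 1 − PRESS_h / RSS_{h−1}, adding components
  while Q²_h > 0.0975 (repeated k-fold CV supplies PRESS);
* variable selection keeping genera with VIP > 0.8 **and** a jack-knife
  coefficient interval excluding zero, iterated while the cross-validated
  criterion improves;
* validation by repeated CV (4-fold × 20 for diet discrimination,
  3-fold × 20 for within-diet prediction) reporting misclassification %
  or predictive ability (squared predicted–observed correlation), plus a
  permutation analogue that shuffles held-out labels.

**Bayesian linear models.** Gibbs sampling with bounded flat priors
(60,000 iterations, 10,000 burn-in, thinning 10 by default); contrasts
are summarised by the posterior mean, the 95 % highest-posterior-density
interval, P₀ (probability the contrast exceeds 0 in the direction of its
mean) and P_r (same for the relevant threshold r = ⅓ of the phenotypic
SD), with Geweke Z and time-series Monte-Carlo errors as diagnostics.

**Synthetic data.** `SimConfig`/`generate_dataset` emulate the study
conditions — 26 animals (13 per diet), 203 genera, ~78 % zeros at
~5 × 10⁵ reads/sample, 22 diet-shifted genera, 5 methane-driver genera
per diet including one cross-over genus whose association flips sign
between diets — and record every injected effect in a `truth` block.

## Worked example

```python
from rumenpls import (AnalysisConfig, ChainSpec, SimConfig,
                      generate_dataset, preprocess, run_da_pls)

dataset = generate_dataset(SimConfig(seed=1, diet_effect_size=3.0,
                                     methane_noise_sd=1.0))
config = AnalysisConfig(seed=1, chain=ChainSpec(iterations=20_000,
                                                burn_in=4_000, thin=4))
clr, phen = preprocess(dataset.counts, dataset.taxonomy,
                       dataset.phenotypes, config)
result = run_da_pls(clr, phen, config)
```

This prints (via `examples/03_diet_discrimination.py`):

```
retained 23 genera in a 1-component model
misclassification: 0.0% (permuted labels: 50.4%)
truly diet-shifted genera recovered: 21/22
genera with a relevant diet difference (Pr >= 0.90): 22
```

The discriminant model separates the two diets perfectly under repeated
cross-validation while the permutation analogue stays at chance level;
21 of the 22 genera the generator actually shifted are among the
retained set, and the per-genus Bayesian models flag 22 genera whose
TMR − GRASS clr difference exceeds a third of its SD with probability
≥ 0.90. `examples/04_methane_prediction.py` continues with the
within-diet methane models (predictive ability 83.7 ± 6.6 % for GRASS
and 41.8 ± 9.3 % for TMR against permutation analogues near 32/27 %),
and `examples/05_diet_effects_bayes.py` prints the trait table, e.g. a
posterior TMR − GRASS methane-yield difference of −10.58 g/kg DMI with
95 % HPD [−14.5, −6.5] against a simulated truth of −10.6.

A thin CLI wraps the same functions:

```bash
rumenpls simulate --seed 1 --outdir data/
rumenpls full-run --indir data/ --outdir out/ --seed 1
```

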