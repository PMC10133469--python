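"""Bayesian diet contrasts for intake and methane traits.

Each trait (dry matter intake, methane production, methane yield, A:B) is
modelled with diet, breed, chamber and week as fixed effects and body
weight as a covariate, using a Gibbs sampler with bounded flat priors.
The TMR - GRASS difference is summarised by its posterior mean, 95% HPD
interval, P0 (probability the difference has the sign of its mean) and Pr
(probability it exceeds the relevant threshold r = SD/3).
"""

from rumenpls import (
    AnalysisConfig,
    ChainSpec,
    SimConfig,
    generate_dataset,
    preprocess,
    run_diet_effects,
)

dataset = generate_dataset(SimConfig(seed=1))
config = AnalysisConfig(seed=1, chain=ChainSpec(iterations=20_000, burn_in=4_000, thin=4))

clr, phen = preprocess(dataset.counts, dataset.taxonomy, dataset.phenotypes, config)
table = run_diet_effects(phen, config)
cols = ["trait", "mean", "hpd_low", "hpd_high", "p0", "r", "pr", "geweke_z", "mc_se"]
print(table[cols].round(3).to_string(index=False))
# The simulated TMR - GRASS methane-yield difference is -10.6 g/kg DMI;
# its posterior mean should sit near that value with the HPD covering it,
# |Geweke Z| < 2 indicates the chain converged, and mc_se shows the
# Monte-Carlo precision of the posterior mean.
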