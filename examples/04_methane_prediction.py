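"""Within-diet PLS prediction of methane yield from clr genus abundances.

Each diet gets its own PLS regression of methane yield (g CH4 per kg dry
matter intake) with the same Q2 / VIP / jack-knife selection machinery,
validated by 3-fold CV repeated 20 times and a permutation analogue.
Retained genera are then quantified one at a time with a Bayesian
regression (breed + body weight adjusted) and a Pearson correlation on
pre-corrected data.
"""

from rumenpls import (
    AnalysisConfig,
    ChainSpec,
    SimConfig,
    generate_dataset,
    preprocess,
    run_methane_pls,
)

dataset = generate_dataset(SimConfig(seed=1, diet_effect_size=3.0, methane_noise_sd=1.0))
config = AnalysisConfig(seed=1, chain=ChainSpec(iterations=20_000, burn_in=4_000, thin=4))
clr, phen = preprocess(dataset.counts, dataset.taxonomy, dataset.phenotypes, config)

for diet in ("GRASS", "TMR"):
    res = run_methane_pls(clr, phen, diet, config)
    pa, perm = res["predictive_ability"], res["permuted"]
    print(f"\n{diet}: {len(res['selection'].retained)} genera, "
          f"predictive ability {100 * pa.mean:.1f} +/- {100 * pa.sd:.1f}% "
          f"(permuted: {100 * perm.mean:.1f}%)")
    print(res["univariate"][["genus", "mean", "p0", "pearson", "pearson_se"]]
          .round(2).to_string(index=False))
# "mean" is the Bayesian regression coefficient of methane yield on the
# genus's clr abundance (g/kg DMI per clr unit); a predictive ability far
# above its permutation analogue indicates genuine microbiome signal.
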