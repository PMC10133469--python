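"""DA-PLS diet discrimination with iterative variable selection.

A discriminant PLS on the clr genus abundances separates the two diets;
genera are retained when their VIP exceeds 0.8 AND their jack-knife
coefficient interval excludes zero, iterating while the cross-validated
misclassification improves.  The final model is validated by 4-fold CV
repeated 20 times, plus a permutation analogue that shuffles the held-out
labels (which should sit near 50%).
"""

from rumenpls import (
    AnalysisConfig,
    ChainSpec,
    SimConfig,
    generate_dataset,
    preprocess,
    run_da_pls,
)

dataset = generate_dataset(SimConfig(seed=1, diet_effect_size=3.0, methane_noise_sd=1.0))
config = AnalysisConfig(seed=1, chain=ChainSpec(iterations=20_000, burn_in=4_000, thin=4))

clr, phen = preprocess(dataset.counts, dataset.taxonomy, dataset.phenotypes, config)
result = run_da_pls(clr, phen, config)

sel = result["selection"]
print(f"retained {len(sel.retained)} genera in a {sel.n_components}-component model")
print(f"misclassification: {result['misclassification'].mean:.1f}%"
      f" (permuted labels: {result['permuted'].mean:.1f}%)")

truth = {d["genus"] for d in dataset.truth["diet_affected"]}
print(f"truly diet-shifted genera recovered: {len(truth & set(sel.retained))}/{len(truth)}")

uni = result["univariate"]
flagged = uni[uni["pr"] >= 0.90]
print(f"genera with a relevant diet difference (Pr >= 0.90): {len(flagged)}")
print(flagged[["genus", "mean", "hpd_low", "hpd_high", "p0", "effect_size"]]
      .head(8).round(2).to_string(index=False))
# "mean" is the TMR - GRASS difference in clr abundance; effect_size is
# that difference in residual-SD units.
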