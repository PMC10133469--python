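"""End-to-end analyses linking diet, rumen microbiota and methane yield.

Three analyses are orchestrated on a genus count table + phenotype table:

1. diet effects on intake and methane traits (Bayesian linear models with
   diet, breed, chamber and week as fixed effects and body weight as a
   covariate; differences reported as TMR - GRASS);
2. diet discrimination from clr genus abundances (DA-PLS with iterative
   VIP/jack-knife selection, repeated-CV misclassification and its
   test-label-permutation analogue, then per-genus Bayesian
   quantification of the diet difference);
3. within-diet prediction of methane yield from clr abundances (PLS
   regression per diet with 3-fold x 20 CV predictive ability, permutation
   analogue, and per-genus Bayesian regressions plus Pearson correlations
   on breed/body-weight pre-corrected data), and the A:B log-ratio
   regression per diet.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .bayes import (
    ChainSpec,
    build_design,
    gibbs_lm,
    relevant_threshold,
    summarize,
)
from .compositional import (
    archaea_bacteria_logratio,
    clr_transform,
    prevalence_filter,
    replace_zeros,
)
from .errors import ValidationError
from .pls import (
    CvSpec,
    SelectionResult,
    cross_validate,
    iterative_variable_selection,
)

__all__ = [
    "AnalysisConfig",
    "validate_phenotypes",
    "preprocess",
    "run_diet_effects",
    "run_da_pls",
    "run_methane_pls",
    "run_ab_regression",
    "precorrect",
    "full_run",
]

logger = logging.getLogger("rumenpls")

TRAITS = ["dmi_kg_d", "ch4_g_d", "ch4_yield_g_kg_dmi", "ab_logratio"]
DIET_MODEL_FACTORS = ("diet", "breed", "chamber", "week")


@dataclass(frozen=True)
class AnalysisConfig:
    """All thresholds and CV settings of the pipeline.

    Defaults are the study settings: 20 % prevalence, 4-fold x 20 CV for
    diet discrimination, 3-fold x 20 for within-diet prediction, Q2
    threshold 0.0975, VIP threshold 0.8, 60,000/10,000/10 chains and
    r = one-third of the phenotypic SD.
    """

    prevalence_threshold: float = 0.20
    prevalence_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    da_cv_k: int = 4
    da_cv_replicates: int = 20
    reg_cv_k: int = 3
    reg_cv_replicates: int = 20
    q2_threshold: float = 0.0975
    vip_threshold: float = 0.8
    h_max: int = 5
    r_fraction: float = 1.0 / 3.0
    chain: ChainSpec = field(default_factory=ChainSpec)
    seed: int = 0
    outdir: str | None = None

    def child_seed(self, tag: str) -> int:
        """Stable sub-seed for one stage, derived from the master seed."""
        return zlib.crc32(f"{self.seed}:{tag}".encode()) % (2**31)

    def chain_for(self, tag: str) -> ChainSpec:
        return dataclasses.replace(self.chain, seed=self.child_seed(tag))

    def da_cv(self, tag: str = "da", permute: str = "none") -> CvSpec:
        return CvSpec(
            k=self.da_cv_k,
            replicates=self.da_cv_replicates,
            seed=self.child_seed(tag),
            permute=permute,
        )

    def reg_cv(self, tag: str = "reg", permute: str = "none") -> CvSpec:
        return CvSpec(
            k=self.reg_cv_k,
            replicates=self.reg_cv_replicates,
            seed=self.child_seed(tag),
            permute=permute,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        chain = ChainSpec(**raw.pop("chain", {}))
        if "prevalence_grid" in raw:
            raw["prevalence_grid"] = tuple(raw["prevalence_grid"])
        return cls(chain=chain, **raw)


def validate_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Check internal consistency of the phenotype table."""
    phen = phen.copy()
    if {"ch4_g_d", "dmi_kg_d", "ch4_yield_g_kg_dmi"} <= set(phen.columns):
        implied = phen["ch4_g_d"] / phen["dmi_kg_d"]
        if not np.allclose(implied, phen["ch4_yield_g_kg_dmi"], atol=1e-6):
            raise ValidationError("ch4_yield_g_kg_dmi != ch4_g_d / dmi_kg_d")
    counts = phen["diet"].value_counts()
    if len(counts) != 2:
        raise ValidationError(f"expected two diets, got {list(counts.index)}")
    if abs(counts.iloc[0] - counts.iloc[1]) > 1:
        logger.warning("diet groups unbalanced: %s", counts.to_dict())
    return phen


def preprocess(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts -> (clr matrix, phenotypes with the A:B column appended).

    The A:B log-ratio is computed on the full, unfiltered table; the clr
    matrix on the prevalence-filtered, zero-replaced one.
    """
    phen = validate_phenotypes(phenotypes)
    phen = phen.set_index("sample_id") if "sample_id" in phen.columns else phen
    counts = counts.loc[phen.index]
    ab = archaea_bacteria_logratio(counts, taxonomy)
    phen = phen.assign(ab_logratio=ab)
    filtered = prevalence_filter(counts, config.prevalence_threshold)
    clr = clr_transform(replace_zeros(filtered))
    logger.info(
        "preprocess: %d genera retained at prevalence >= %.0f%%",
        filtered.shape[1],
        100 * config.prevalence_threshold,
    )
    return clr, phen


def run_diet_effects(
    phenotypes: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Diet contrasts (TMR - GRASS) for DMI, methane production, methane
    yield and A:B, from the full fixed-effects Bayesian model."""
    rows = []
    for trait in TRAITS:
        if trait not in phenotypes.columns:
            raise ValidationError(f"phenotypes lack the column {trait!r}")
        chain = gibbs_lm(
            phenotypes,
            response=trait,
            factors=DIET_MODEL_FACTORS,
            covariates=("body_weight_kg",),
            chain=config.chain_for(f"diet_effects:{trait}"),
        )
        r = config.r_fraction * 3.0 * relevant_threshold(phenotypes[trait])
        summ = summarize(chain, "diet[TMR]", r=r)
        row = {"trait": trait, **summ.as_dict()}
        row.pop("term")
        rows.append(row)
    return pd.DataFrame(rows)


def run_da_pls(
    clr: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Diet discrimination from clr abundances.

    Runs iterative DA-PLS variable selection, validates the final model by
    repeated CV and its test-label permutation analogue, then fits one
    Bayesian model per retained genus (diet + breed fixed, body weight
    covariate) quantifying the TMR - GRASS clr difference.
    """
    phen = phenotypes.loc[clr.index]
    diet = phen["diet"].values
    cv = config.da_cv("da_pls")
    selection = iterative_variable_selection(
        clr,
        diet,
        cv=cv,
        vip_threshold=config.vip_threshold,
        q2_threshold=config.q2_threshold,
        h_max=config.h_max,
    )
    permuted = cross_validate(
        clr[selection.retained],
        diet,
        h=selection.n_components,
        cv=config.da_cv("da_pls", permute="test_labels"),
    )

    rows = []
    for genus in selection.retained:
        data = phen.assign(_clr=clr[genus].values)
        chain = gibbs_lm(
            data,
            response="_clr",
            factors=("diet", "breed"),
            covariates=("body_weight_kg",),
            chain=config.chain_for(f"da_univariate:{genus}"),
        )
        r = config.r_fraction * 3.0 * relevant_threshold(clr[genus])
        summ = summarize(chain, "diet[TMR]", r=r)
        row = {"genus": genus, **summ.as_dict()}
        row.pop("term")
        row["vip"] = float(selection.vip[genus])
        rows.append(row)
    univariate = pd.DataFrame(rows)
    return {
        "selection": selection,
        "misclassification": selection.cv_final,
        "permuted": permuted,
        "univariate": univariate,
    }


def precorrect(
    trait,
    phenotypes: pd.DataFrame,
    factors: tuple[str, ...] = ("breed",),
    covariates: tuple[str, ...] = ("body_weight_kg",),
    chain: ChainSpec | None = None,
) -> np.ndarray:
    """Remove posterior-mean nuisance contributions from a trait.

    Subtracts the centred breed and body-weight contributions estimated by
    the Bayesian model, keeping the trait's overall mean and all remaining
    variation.  Deterministic given the chain seed.
    """
    chain = chain or ChainSpec(iterations=12_000, burn_in=2_000, thin=2)
    data = phenotypes.assign(_trait=np.asarray(trait, dtype=float))
    fit = gibbs_lm(
        data, response="_trait", factors=factors, covariates=covariates, chain=chain
    )
    X, names, _ = build_design(data, factors, covariates)
    beta = fit.samples[names].mean(axis=0).values
    nuisance = [i for i, nm in enumerate(names) if nm != "intercept"]
    contrib = X[:, nuisance] @ beta[nuisance]
    return np.asarray(trait, dtype=float) - (contrib - contrib.mean())


def _pearson_with_se(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the (1 - rho^2)/sqrt(n - 1) dispersion used
    alongside it in reporting."""
    rho = float(np.corrcoef(a, b)[0, 1])
    se = (1.0 - rho**2) / np.sqrt(len(a) - 1)
    return rho, se


def run_methane_pls(
    clr: pd.DataFrame,
    phenotypes: pd.DataFrame,
    diet: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Within-diet PLS of methane yield on clr abundances.

    Iterative selection in regression mode with 3-fold x 20 CV; reports
    predictive ability +/- SD and its permutation analogue, then per
    retained genus the Bayesian regression coefficient of methane yield on
    clr abundance (breed + body weight adjusted) and the Pearson
    correlation on pre-corrected data.
    """
    phen = phenotypes.loc[clr.index]
    mask = (phen["diet"] == diet).values
    if mask.sum() < 6:
        raise ValidationError(f"only {mask.sum()} samples in diet {diet!r}")
    phen_d = phen.loc[mask]
    clr_d = clr.loc[mask]
    y = phen_d["ch4_yield_g_kg_dmi"].values

    cv = config.reg_cv(f"methane:{diet}")
    selection = iterative_variable_selection(
        clr_d,
        y,
        cv=cv,
        vip_threshold=config.vip_threshold,
        q2_threshold=config.q2_threshold,
        h_max=config.h_max,
    )
    permuted = cross_validate(
        clr_d[selection.retained],
        y,
        h=selection.n_components,
        cv=config.reg_cv(f"methane:{diet}", permute="test_labels"),
    )

    pre_chain = ChainSpec(
        iterations=12_000, burn_in=2_000, thin=2,
        seed=config.child_seed(f"precorrect:{diet}"),
    )
    y_corr = precorrect(y, phen_d, chain=pre_chain)
    rows = []
    for genus in selection.retained:
        data = phen_d.assign(_clr=clr_d[genus].values)
        chain = gibbs_lm(
            data,
            response="ch4_yield_g_kg_dmi",
            factors=("breed",),
            covariates=("body_weight_kg", "_clr"),
            chain=config.chain_for(f"methane_univariate:{diet}:{genus}"),
        )
        summ = summarize(chain, "_clr", r=0.0)
        g_corr = precorrect(clr_d[genus].values, phen_d, chain=pre_chain)
        rho, se = _pearson_with_se(g_corr, y_corr)
        row = {"genus": genus, **summ.as_dict()}
        row.pop("term")
        row["pearson"] = rho
        row["pearson_se"] = se
        row["vip"] = float(selection.vip[genus])
        rows.append(row)
    return {
        "diet": diet,
        "selection": selection,
        "predictive_ability": selection.cv_final,
        "permuted": permuted,
        "univariate": pd.DataFrame(rows),
    }


def run_ab_regression(
    phenotypes: pd.DataFrame,
    diet: str,
    response: str = "ch4_yield_g_kg_dmi",
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Within-diet Bayesian slope of a methane trait on the A:B log-ratio
    (breed + body weight adjusted), with R2 and the Pearson correlation on
    pre-corrected data."""
    mask = (phenotypes["diet"] == diet).values
    if mask.sum() < 6:
        raise ValidationError(f"only {mask.sum()} samples in diet {diet!r}")
    phen_d = phenotypes.loc[mask]
    chain = gibbs_lm(
        phen_d,
        response=response,
        factors=("breed",),
        covariates=("body_weight_kg", "ab_logratio"),
        chain=config.chain_for(f"ab:{diet}:{response}"),
    )
    summ = summarize(chain, "ab_logratio", r=0.0)

    # posterior-mean fit R2
    X, names, _ = build_design(phen_d, ("breed",), ("body_weight_kg", "ab_logratio"))
    beta = chain.samples[names].mean(axis=0).values
    y = phen_d[response].astype(float).values
    fitted = X @ beta
    r2_bayes = 1.0 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)

    pre_chain = ChainSpec(
        iterations=12_000, burn_in=2_000, thin=2,
        seed=config.child_seed(f"ab_precorrect:{diet}:{response}"),
    )
    y_corr = precorrect(y, phen_d, chain=pre_chain)
    ab_corr = precorrect(phen_d["ab_logratio"].values, phen_d, chain=pre_chain)
    rho, se = _pearson_with_se(ab_corr, y_corr)
    slope_ls, icept_ls = np.polyfit(ab_corr, y_corr, 1)
    resid = y_corr - (slope_ls * ab_corr + icept_ls)
    r2_ls = 1.0 - np.sum(resid**2) / np.sum((y_corr - y_corr.mean()) ** 2)
    return {
        "diet": diet,
        "response": response,
        "summary": summ,
        "r2_bayes": float(r2_bayes),
        "r2_ls": float(r2_ls),
        "pearson": rho,
        "pearson_se": se,
    }


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def _cv_block(res) -> dict:
    return {"mean": res.mean, "sd": res.sd, "k": res.cv.k, "replicates": res.cv.replicates}


def _selection_block(sel: SelectionResult) -> dict:
    return {
        "retained": list(sel.retained),
        "n_components": sel.n_components,
        "iterations": [
            {k: v for k, v in it.items()} for it in sel.iterations
        ],
        "emptied": sel.emptied,
    }


def full_run(
    input_dir: str | Path | None = None,
    config: AnalysisConfig = AnalysisConfig(),
    dataset=None,
) -> dict:
    """Preprocess -> diet effects -> DA-PLS -> within-diet PLS -> A:B
    regressions; returns the report dict and, if ``config.outdir`` is set,
    writes report.json, tidy CSV tables and a log."""
    if dataset is not None:
        counts, taxonomy, phenotypes = dataset.counts, dataset.taxonomy, dataset.phenotypes
    elif input_dir is not None:
        input_dir = Path(input_dir)
        counts = rio.read_counts(input_dir / "counts.tsv")
        taxonomy = rio.read_taxonomy(input_dir / "taxonomy.tsv")
        phenotypes = rio.read_phenotypes(input_dir / "phenotypes.csv")
    else:
        raise ValidationError("provide input_dir or dataset")

    clr, phen = preprocess(counts, taxonomy, phenotypes, config)
    diet_effects = run_diet_effects(phen, config)
    da = run_da_pls(clr, phen, config)
    diets = sorted(phen["diet"].unique())
    methane = {d: run_methane_pls(clr, phen, d, config) for d in diets}
    ab = {
        d: {
            resp: run_ab_regression(phen, d, resp, config)
            for resp in ("ch4_g_d", "ch4_yield_g_kg_dmi")
        }
        for d in diets
    }

    report = {
        "settings": {
            "config": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(config).items()
                    if k not in ("chain", "outdir")
                },
                "chain": dataclasses.asdict(config.chain),
            },
            "versions": {
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
        "preprocess": {
            "n_samples": int(clr.shape[0]),
            "n_genera_retained": int(clr.shape[1]),
            "zero_fraction": float((counts.values == 0).mean()),
        },
        "diet_effects": diet_effects.to_dict(orient="records"),
        "da_pls": {
            "selection": _selection_block(da["selection"]),
            "misclassification_pct": _cv_block(da["misclassification"]),
            "permuted_misclassification_pct": _cv_block(da["permuted"]),
            "n_p0_95": int((da["univariate"]["p0"] >= 0.95).sum()),
            "n_pr_90": int((da["univariate"]["pr"] >= 0.90).sum()),
            "univariate": da["univariate"].to_dict(orient="records"),
        },
        "methane_pls": {
            d: {
                "selection": _selection_block(m["selection"]),
                "predictive_ability": _cv_block(m["predictive_ability"]),
                "permuted_predictive_ability": _cv_block(m["permuted"]),
                "univariate": m["univariate"].to_dict(orient="records"),
            }
            for d, m in methane.items()
        },
        "ab_regression": {
            d: {
                resp: {
                    **blk["summary"].as_dict(),
                    "r2_bayes": blk["r2_bayes"],
                    "r2_ls": blk["r2_ls"],
                    "pearson": blk["pearson"],
                    "pearson_se": blk["pearson_se"],
                }
                for resp, blk in by_resp.items()
            }
            for d, by_resp in ab.items()
        },
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=float)
        diet_effects.to_csv(outdir / "diet_effects.csv", index=False)
        da["univariate"].to_csv(outdir / "da_pls_univariate.csv", index=False)
        for d, m in methane.items():
            m["univariate"].to_csv(
                outdir / f"methane_pls_univariate_{d}.csv", index=False
            )
        with open(outdir / "run.log", "w") as fh:
            fh.write(
                f"seed={config.seed}\n"
                f"prevalence_threshold={config.prevalence_threshold}\n"
                f"q2_threshold={config.q2_threshold}\n"
                f"vip_threshold={config.vip_threshold}\n"
                f"da_cv={config.da_cv_k}x{config.da_cv_replicates}\n"
                f"reg_cv={config.reg_cv_k}x{config.reg_cv_replicates}\n"
                f"chain={dataclasses.asdict(config.chain)}\n"
            )
    return report
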