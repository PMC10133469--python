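"""Synthetic rumen-microbiome datasets with known ground truth.

Emulates a two-diet (fresh-cut GRASS vs. high-concentrate TMR) cattle
experiment: a sparse genus-level 16S count table, a taxonomy map, and a
phenotype table in which methane yield (g CH4 / kg dry-matter intake)
depends linearly on the *true* underlying clr abundances of a small set of
"driver" genera, plus diet, breed and body-weight terms and Gaussian noise.

The generator is the test bed for the whole pipeline: every effect it
injects is recorded in a ``truth`` block so that recovery can be scored.

Mechanism
---------
Per-genus baseline log-abundances are Gaussian with a spread ``sigma``
solved numerically so that the expected per-sample zero fraction of the
multinomial counts matches ``target_zero_fraction`` (16S genus tables are
dominated by a few taxa; a heavy-tailed log-normal baseline reproduces that
sparsity without modelling ecology).  Diet shifts a chosen subset of
prevalent genera on the log scale; counts are multinomial draws at a depth
sampled around ``sequencing_depth_mean`` (Dirichlet-multinomial when
``overdispersion`` > 0).  Methane yield is built from the true composition
*before* any zero handling, so ground truth is unambiguous.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SimulationConfigError, ValidationError

__all__ = ["SimConfig", "SyntheticDataset", "generate_dataset", "write_fixture"]

_BACTERIAL_PHYLA = (
    "Firmicutes",
    "Bacteroidetes",
    "Proteobacteria",
    "Actinobacteria",
    "Fibrobacteres",
    "Spirochaetes",
)

# GRASS-group baseline methane yield (g/kg DMI) and the DMI split between
# diets follow the magnitudes reported for contrasting grass/concentrate
# finishing diets: yield ~25 on grass, ~3.2 kg/day more intake on TMR.
_GRASS_YIELD_INTERCEPT = 25.0
_GRASS_DMI_MEAN = 7.0
_TMR_DMI_MEAN = 10.25
_DMI_SD = 0.8


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults reproduce the scale of the emulated study: 26 animals (13 per
    diet), 203 genera, ~78 % zero counts per sample, ~5.1e5 reads per
    sample, 22 diet-affected genera and 5 methane-driver genera per diet
    with a cross-over genus whose association flips sign between diets.
    """

    n_per_diet: int = 13
    n_genera: int = 203
    n_diet_affected: int = 22
    diet_effect_size: float = 2.0
    n_methane_drivers_per_diet: int = 5
    methane_coefficients: tuple[float, ...] = (2.5, -2.0, 1.5, -1.2, 1.0)
    methane_noise_sd: float = 1.5
    target_zero_fraction: float = 0.78
    sequencing_depth_mean: int = 506_000
    breed_effect: float = 0.0
    bodyweight_slope: float = 0.0
    seed: int = 0
    # TMR - GRASS shift in methane yield, g/kg DMI
    diet_yield_difference: float = -10.6
    # SD of per-sample log-abundance noise around the genus baseline
    sample_log_sd: float = 1.0
    # relative SD of sequencing depth across samples
    depth_cv: float = 0.3
    # 0 = multinomial counts; >0 = Dirichlet-multinomial with this
    # overdispersion (variance inflation grows with the value)
    overdispersion: float = 0.0
    # share the first driver genus between diets with opposite-sign
    # coefficients (a diet-dependent association)
    crossover_driver: bool = True

    def validate(self) -> None:
        if self.n_per_diet < 1:
            raise SimulationConfigError("n_per_diet must be >= 1")
        if self.n_genera < 2:
            raise SimulationConfigError("n_genera must be >= 2")
        if self.n_diet_affected > self.n_genera:
            raise SimulationConfigError(
                f"n_diet_affected ({self.n_diet_affected}) exceeds "
                f"n_genera ({self.n_genera})"
            )
        if self.n_methane_drivers_per_diet > self.n_genera:
            raise SimulationConfigError(
                f"n_methane_drivers_per_diet ({self.n_methane_drivers_per_diet}) "
                f"exceeds n_genera ({self.n_genera})"
            )
        if len(self.methane_coefficients) != self.n_methane_drivers_per_diet:
            raise SimulationConfigError(
                "methane_coefficients must have length n_methane_drivers_per_diet"
            )
        if not 0.0 < self.target_zero_fraction < 1.0:
            raise SimulationConfigError("target_zero_fraction must lie in (0, 1)")
        if self.sequencing_depth_mean <= 0:
            raise SimulationConfigError("sequencing_depth_mean must be positive")
        if self.methane_noise_sd < 0:
            raise SimulationConfigError("methane_noise_sd must be non-negative")
        if self.sample_log_sd < 0 or self.depth_cv < 0 or self.overdispersion < 0:
            raise SimulationConfigError("dispersion parameters must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated experiment: counts, taxonomy, phenotypes and truth."""

    counts: pd.DataFrame  # samples x genera, integer
    taxonomy: pd.DataFrame  # genus, domain, phylum
    phenotypes: pd.DataFrame  # per-sample covariates and methane traits
    truth: dict
    config: SimConfig = field(repr=False)

    # true clr matrix (before zero handling); used by recovery tests
    true_clr: pd.DataFrame | None = field(default=None, repr=False)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _solve_sigma(
    u: np.ndarray,
    noise: np.ndarray,
    depth: float,
    target: float,
) -> float:
    """Bisect the baseline log-abundance spread so the expected zero
    fraction of a multinomial draw at ``depth`` reads matches ``target``.

    ``u`` are the fixed standard-normal genus effects, ``noise`` a fixed
    pseudo-sample noise matrix; the zero probability of genus j is
    approximated by exp(-depth * p_j).
    """

    def predicted(sigma: float) -> float:
        p = _softmax_rows(sigma * u[None, :] + noise)
        return float(np.mean(np.exp(-depth * p)))

    lo, hi = 0.05, 40.0
    if predicted(hi) < target:  # pragma: no cover - pathological targets
        return hi
    if predicted(lo) > target:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if predicted(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Draw one complete synthetic dataset; same config (incl. seed) gives
    bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_g = config.n_genera
    n = 2 * config.n_per_diet

    genus_ids = [f"Genus{j + 1:03d}" for j in range(n_g)]
    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    diet = np.array(["GRASS"] * config.n_per_diet + ["TMR"] * config.n_per_diet)

    # --- baseline abundances, calibrated to the target sparsity ---
    u = rng.normal(size=n_g)
    calib_noise = rng.normal(scale=config.sample_log_sd, size=(8, n_g))
    sigma = _solve_sigma(
        u, calib_noise, float(config.sequencing_depth_mean), config.target_zero_fraction
    )
    alpha = sigma * u  # per-genus baseline log-abundance

    # --- pick effect genera among genera that are reliably observed, so
    # the injected ground truth is recoverable after zero handling: a
    # genus whose counts are zero in half the samples carries its effect
    # in cells the analysis must impute ---
    order = np.argsort(alpha)[::-1]
    need = config.n_diet_affected + 2 * config.n_methane_drivers_per_diet
    if need > n_g:
        raise SimulationConfigError(
            "too many effect genera for the number of genera available"
        )
    p_base = _softmax_rows(alpha[None, :])[0]
    zero_prob = np.exp(-float(config.sequencing_depth_mean) * p_base)
    reliable = order[zero_prob[order] < 0.2]
    prevalent = reliable if len(reliable) >= need else order[: max(need, len(reliable))]
    perm = rng.permutation(prevalent)
    diet_affected = np.sort(perm[: config.n_diet_affected])
    pool = perm[config.n_diet_affected :]
    n_drv = config.n_methane_drivers_per_diet
    if config.crossover_driver and n_drv >= 1:
        shared = pool[0]
        grass_drivers = np.concatenate([[shared], pool[1:n_drv]])
        tmr_drivers = np.concatenate([[shared], pool[n_drv : 2 * n_drv - 1]])
    else:
        grass_drivers = pool[:n_drv]
        tmr_drivers = pool[n_drv : 2 * n_drv]
    coeffs = np.asarray(config.methane_coefficients, dtype=float)
    grass_coeffs = coeffs.copy()
    tmr_coeffs = coeffs.copy()
    if config.crossover_driver and n_drv >= 1:
        tmr_coeffs[0] = -coeffs[0]  # the cross-over association flips sign

    # alternating-sign GRASS-minus-TMR log-scale shifts
    effects = np.array(
        [config.diet_effect_size * (1 if k % 2 == 0 else -1) for k in range(config.n_diet_affected)]
    )

    # --- per-sample composition and counts ---
    logit = np.tile(alpha, (n, 1))
    grass_rows = diet == "GRASS"
    for gid, eff in zip(diet_affected, effects):
        logit[grass_rows, gid] += eff
    logit += rng.normal(scale=config.sample_log_sd, size=(n, n_g))
    p_true = _softmax_rows(logit)

    depths = rng.normal(
        loc=config.sequencing_depth_mean,
        scale=config.depth_cv * config.sequencing_depth_mean,
        size=n,
    )
    depths = np.maximum(np.rint(depths).astype(np.int64), 1000)

    counts = np.empty((n, n_g), dtype=np.int64)
    for i in range(n):
        p_i = p_true[i]
        if config.overdispersion > 0:
            conc = (1.0 - config.overdispersion) / config.overdispersion
            p_i = rng.dirichlet(np.maximum(p_i * conc, 1e-12))
        counts[i] = rng.multinomial(depths[i], p_i)

    # --- taxonomy: a handful of archaea (some prevalent, as rumen
    # methanogens are), a couple of domain-unclassified genera ---
    n_arch = max(3, n_g // 25)
    # pin the two most abundant genera as archaea so the archaeal total is
    # positive in every sample even at extreme sparsity (the A:B log-ratio
    # needs both domains observed everywhere; in real rumen profiles the
    # dominant methanogens are likewise never absent); the rest are random
    arch_pick = list(order[: min(2, n_g)])
    remaining = np.setdiff1d(np.arange(n_g), arch_pick)
    arch_pick += list(rng.choice(remaining, size=n_arch - len(arch_pick), replace=False))
    archaea = np.zeros(n_g, dtype=bool)
    archaea[np.asarray(arch_pick)] = True
    unclassified = rng.choice(np.flatnonzero(~archaea), size=2, replace=False)
    domain = np.where(archaea, "Archaea", "Bacteria").astype(object)
    domain[unclassified] = "unclassified"
    phylum = np.where(
        archaea,
        "Euryarchaeota",
        rng.choice(_BACTERIAL_PHYLA, size=n_g),
    ).astype(object)
    phylum[unclassified] = "unclassified"

    # --- phenotypes ---
    breed = np.array(
        [("AAx" if i % 2 == 0 else "LIMx") for i in range(config.n_per_diet)] * 2
    )
    # paired animals (one per diet) share chamber and week; a Latin-square-
    # style crossing avoids exact chamber/week aliasing
    pair = np.concatenate([np.arange(config.n_per_diet)] * 2)
    chamber = (pair + pair // 6) % 6 + 1
    week = pair % 6 + 1
    body_weight = np.clip(rng.normal(505.0, 35.0, size=n), 438.0, 656.0)

    log_p = np.log(p_true)
    true_clr = log_p - log_p.mean(axis=1, keepdims=True)

    # driver contributions are centred within diet so the configured diet
    # yield difference is exactly the between-diet contrast in expectation
    yield_signal = np.zeros(n)
    for gid, c in zip(grass_drivers, grass_coeffs):
        v = true_clr[grass_rows, gid]
        yield_signal[grass_rows] += c * (v - v.mean())
    for gid, c in zip(tmr_drivers, tmr_coeffs):
        v = true_clr[~grass_rows, gid]
        yield_signal[~grass_rows] += c * (v - v.mean())

    ch4_yield = (
        _GRASS_YIELD_INTERCEPT
        + np.where(grass_rows, 0.0, config.diet_yield_difference)
        + config.breed_effect * (breed == "LIMx")
        + config.bodyweight_slope * (body_weight - body_weight.mean())
        + yield_signal
        + (rng.normal(scale=config.methane_noise_sd, size=n) if config.methane_noise_sd > 0 else 0.0)
    )
    dmi = np.where(grass_rows, _GRASS_DMI_MEAN, _TMR_DMI_MEAN) + rng.normal(
        scale=_DMI_SD, size=n
    )
    dmi = np.maximum(dmi, 2.0)
    ch4_g_d = ch4_yield * dmi

    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=genus_ids)
    taxonomy_df = pd.DataFrame(
        {"genus": genus_ids, "domain": domain, "phylum": phylum}
    )
    phenotypes_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "diet": diet,
            "breed": breed,
            "chamber": chamber,
            "week": week,
            "body_weight_kg": body_weight,
            "dmi_kg_d": dmi,
            "ch4_g_d": ch4_g_d,
            "ch4_yield_g_kg_dmi": ch4_yield,
        }
    )

    truth = {
        "diet_affected": [
            {"genus": genus_ids[g], "grass_minus_tmr_log_effect": float(e)}
            for g, e in zip(diet_affected, effects)
        ],
        "methane_drivers": {
            "GRASS": [
                {"genus": genus_ids[g], "coefficient": float(c)}
                for g, c in zip(grass_drivers, grass_coeffs)
            ],
            "TMR": [
                {"genus": genus_ids[g], "coefficient": float(c)}
                for g, c in zip(tmr_drivers, tmr_coeffs)
            ],
        },
        "diet_yield_difference_tmr_minus_grass": config.diet_yield_difference,
        "breed_effect": config.breed_effect,
        "bodyweight_slope": config.bodyweight_slope,
        "baseline_log_sd": float(sigma),
    }

    true_clr_df = pd.DataFrame(
        true_clr, index=counts_df.index.copy(), columns=genus_ids
    )
    return SyntheticDataset(
        counts=counts_df,
        taxonomy=taxonomy_df,
        phenotypes=phenotypes_df,
        truth=truth,
        config=config,
        true_clr=true_clr_df,
    )


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write ``counts.tsv``, ``taxonomy.tsv``, ``phenotypes.csv`` and
    ``truth.json`` under ``directory``; returns the paths written."""
    if dataset.counts.shape[0] == 0:
        raise ValidationError("dataset has no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "phenotypes": directory / "phenotypes.csv",
        "truth": directory / "truth.json",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    dataset.phenotypes.to_csv(paths["phenotypes"], index=False)
    truth = dict(dataset.truth)
    truth["config"] = dataclasses.asdict(dataset.config)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
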