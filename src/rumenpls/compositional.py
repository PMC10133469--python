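"""Compositional preprocessing of genus count tables.

Raw 16S genus counts are compositional: only relative information is
meaningful, and the tables are extremely sparse.  The preprocessing chain is

    prevalence filter -> Bayesian-multiplicative zero replacement
                      -> centred log-ratio (clr) transform

plus the per-sample natural log ratio of total archaeal to total bacterial
counts (A:B), a one-number summary of the methanogen share of the community.

Zero replacement follows the Geometric Bayesian-multiplicative (GBM) scheme:
for sample i with depth N_i, a zero cell of genus j is imputed by the
posterior-expected proportion under a Dirichlet prior whose location t_j is
the geometric mean of genus j's proportions over its non-zero samples and
whose per-sample strength is s_i = sqrt(N_i):

    replaced_ij = s_i * t_j / (N_i + s_i)

Non-zero cells are multiplicatively shrunk by (1 - sum of replacements in
the row), which preserves every pairwise ratio among observed parts exactly
and keeps each row closed to 1.  A simpler multiplicative delta replacement
(delta = 0.65 x the smallest observed proportion) is available as an
alternative scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    AllZeroSampleError,
    DomainTotalError,
    EmptyFilterError,
    NonPositiveEntryError,
    ValidationError,
)

__all__ = [
    "prevalence_filter",
    "replace_zeros",
    "clr_transform",
    "archaea_bacteria_logratio",
    "scan_prevalence",
    "PrevalenceScanResult",
]


def prevalence_filter(counts: pd.DataFrame, min_prevalence: float) -> pd.DataFrame:
    """Keep the genera present (count > 0) in at least ``min_prevalence``
    of samples; the boundary is inclusive (prevalence == threshold is kept).
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValidationError("min_prevalence must lie in [0, 1]")
    prevalence = (counts.values > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise EmptyFilterError(
            f"prevalence threshold {min_prevalence:.2f} removes every genus; "
            "lower the threshold"
        )
    return counts.loc[:, keep]


def replace_zeros(counts: pd.DataFrame, method: str = "gbm") -> pd.DataFrame:
    """Turn counts into strictly positive proportions closed to 1.

    ``method='gbm'`` applies the Geometric Bayesian-multiplicative scheme
    described in the module docstring; ``method='multiplicative'`` imputes a
    single delta = 0.65 x min observed proportion.  Ratios among originally
    non-zero parts within a sample are preserved exactly by both schemes.
    """
    x = counts.values.astype(float)
    depths = x.sum(axis=1)
    if (depths <= 0).any():
        bad = counts.index[depths <= 0].tolist()
        raise AllZeroSampleError(f"all-zero sample(s): {bad}")
    props = x / depths[:, None]
    zeros = x == 0

    if not zeros.any():
        out = props
    elif method == "gbm":
        if (x.sum(axis=0) == 0).any():
            bad = counts.columns[x.sum(axis=0) == 0].tolist()
            raise ValidationError(f"genera with no non-zero sample: {bad}")
        with np.errstate(divide="ignore"):
            logp = np.where(zeros, 0.0, np.log(np.where(zeros, 1.0, props)))
        nonzero_per_genus = (~zeros).sum(axis=0)
        t = np.exp(logp.sum(axis=0) / nonzero_per_genus)  # geometric-mean proportion
        s = np.sqrt(depths)
        replaced = (s[:, None] * t[None, :]) / (depths + s)[:, None]
        repl_mass = np.where(zeros, replaced, 0.0).sum(axis=1)
        if (repl_mass >= 1.0).any():  # pragma: no cover - degenerate tables
            raise ValidationError("zero-replacement mass reached the whole row")
        out = np.where(zeros, replaced, props * (1.0 - repl_mass)[:, None])
    elif method == "multiplicative":
        delta = 0.65 * props[~zeros].min()
        repl_mass = zeros.sum(axis=1) * delta
        if (repl_mass >= 1.0).any():
            raise ValidationError("zero-replacement mass reached the whole row")
        out = np.where(zeros, delta, props * (1.0 - repl_mass)[:, None])
    else:
        raise ValidationError(f"unknown zero-replacement method {method!r}")

    out = out / out.sum(axis=1, keepdims=True)  # close exactly
    return pd.DataFrame(out, index=counts.index.copy(), columns=counts.columns.copy())


def clr_transform(comp: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio: ln(p_ij) minus the row mean of ln(p_i.); rows of
    the result sum to zero."""
    x = comp.values.astype(float)
    if (x <= 0).any():
        raise NonPositiveEntryError(
            "composition contains non-positive entries; replace zeros first"
        )
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=comp.index.copy(), columns=comp.columns.copy())


def archaea_bacteria_logratio(
    counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.Series:
    """Per-sample ln(total archaeal counts / total bacterial counts).

    Genera labelled "unclassified Archaea/Bacteria" count toward their
    domain; genera with no resolvable domain are excluded from both sums.
    """
    domain = taxonomy.set_index("genus")["domain"].reindex(counts.columns)
    is_arch = domain.str.contains("Archaea", case=False, na=False).values
    is_bact = domain.str.contains("Bacteria", case=False, na=False).values
    arch_tot = counts.values[:, is_arch].sum(axis=1).astype(float)
    bact_tot = counts.values[:, is_bact].sum(axis=1).astype(float)
    bad = (arch_tot <= 0) | (bact_tot <= 0)
    if bad.any():
        raise DomainTotalError(
            f"zero archaeal or bacterial total in sample(s): {counts.index[bad].tolist()}"
        )
    return pd.Series(np.log(arch_tot / bact_tot), index=counts.index, name="ab_logratio")


@dataclass
class PrevalenceScanResult:
    """Outcome of a prevalence-threshold scan."""

    thresholds: list[float]
    retained: list[int]  # genera kept at each threshold (-1 if inapplicable)
    misclassification: list[float]  # CV % at each threshold (nan if inapplicable)
    misclassification_sd: list[float]  # spread across CV replicates
    selected: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "retained_genera": self.retained,
                "misclassification_pct": self.misclassification,
                "misclassification_sd": self.misclassification_sd,
            }
        )


def scan_prevalence(
    counts: pd.DataFrame,
    labels,
    grid,
    cv=None,
    seed: int = 0,
) -> PrevalenceScanResult:
    """Choose the prevalence threshold that maximises diet discrimination.

    For each threshold in ``grid`` the table is filtered, zero-replaced and
    clr-transformed, and a one-component discriminant PLS is scored by
    repeated cross-validated misclassification.  The threshold with the
    lowest misclassification wins; ties go to the smallest threshold.  This
    plays the role of a prevalence-interval scan with the downstream
    classifier itself as the discrimination score.
    """
    from .pls import CvSpec, cross_validate

    grid = sorted(set(float(g) for g in grid))
    if not grid:
        raise ValidationError("threshold grid is empty")
    labels = np.asarray(labels)
    classes, counts_per = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts_per.min() < 2:
        raise ValidationError("need two classes with >= 2 samples each")
    if cv is None:
        cv = CvSpec(k=4, replicates=20, seed=seed)

    retained: list[int] = []
    miscl: list[float] = []
    miscl_sd: list[float] = []
    for thr in grid:
        try:
            filtered = prevalence_filter(counts, thr)
        except EmptyFilterError:
            retained.append(-1)
            miscl.append(float("nan"))
            miscl_sd.append(float("nan"))
            continue
        # genera never observed carry no information and break the GBM
        # prior; score on the observed ones
        observed = filtered.loc[:, filtered.sum(axis=0) > 0]
        clr = clr_transform(replace_zeros(observed))
        res = cross_validate(clr.values, labels, h=1, cv=cv)
        retained.append(filtered.shape[1])
        miscl.append(res.mean)
        miscl_sd.append(res.sd)

    finite = [(m, t) for m, t in zip(miscl, grid) if np.isfinite(m)]
    if not finite:
        raise ValidationError("no applicable threshold in the grid")
    best = min(finite)  # ties resolve to the smallest threshold
    return PrevalenceScanResult(
        thresholds=grid,
        retained=retained,
        misclassification=miscl,
        misclassification_sd=miscl_sd,
        selected=best[1],
    )
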