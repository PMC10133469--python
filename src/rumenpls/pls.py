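"""NIPALS partial least squares (PLS1) and two-class discriminant PLS.

The model chain mirrors common chemometric practice for small-n problems:

* dimension choice by the Q2 criterion,
      Q2_h = 1 - PRESS_h / RSS_{h-1},
  adding components while Q2_h > 0.0975, with repeated k-fold
  cross-validation supplying PRESS;
* variable selection by the VIP criterion (> 0.8) combined with
  jack-knife coefficient intervals from the leave-fold-out refits, applied
  iteratively until the cross-validated criterion stops improving;
* validation by repeated cross-validation (misclassification % for the
  discriminant case, squared predicted-observed correlation for
  regression) with a permutation analogue that shuffles the test-set
  labels before scoring.

Two-class discrimination is PLS1 on a +/-1 dummy response with class
assignment by the sign of the prediction.  Predictors are autoscaled
(centred, unit variance) inside every fit; fold assignment is seeded and
stratified so that results are reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ColumnMismatchError, SingleClassError, ValidationError

__all__ = [
    "PlsModel",
    "CvSpec",
    "CvResult",
    "Q2Series",
    "SelectionResult",
    "fit_pls",
    "predict",
    "q2_sequence",
    "select_n_components",
    "vip_scores",
    "jackknife_coefficients",
    "cross_validate",
    "iterative_variable_selection",
]

Q2_DEFAULT_THRESHOLD = 0.0975
VIP_DEFAULT_THRESHOLD = 0.8


# --------------------------------------------------------------------------
# model container and fitting
# --------------------------------------------------------------------------


@dataclass
class PlsModel:
    """A fitted PLS1 / discriminant-PLS model.

    Weights ``W`` (unit norm per column), X-loadings ``P``, scores ``T`` and
    scalar y-loadings ``q`` are stored per component; ``coef_scaled`` acts on
    autoscaled predictors, ``coef_`` on the original scale.
    """

    mode: str  # "regression" | "discriminant"
    n_components: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    q: np.ndarray
    coef_scaled: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    columns: list | None = None
    classes_: np.ndarray | None = None

    @property
    def coef_(self) -> np.ndarray:
        """Regression coefficients on the original predictor scale."""
        return self.coef_scaled / self.x_scale

    @property
    def intercept_(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef_)


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.values.astype(float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _encode_response(y):
    """Return (numeric y, mode, classes).  Two-level non-numeric input (or
    explicit labels) becomes a +/-1 dummy."""
    arr = np.asarray(y)
    if arr.dtype.kind in "OUSb":
        classes = np.unique(arr)
        if len(classes) != 2:
            raise SingleClassError(
                f"discriminant mode needs exactly 2 classes, got {list(classes)}"
            )
        ynum = np.where(arr == classes[1], 1.0, -1.0)
        return ynum, "discriminant", classes
    return arr.astype(float), "regression", None


def fit_pls(X, y, h: int, mode: str | None = None) -> PlsModel:
    """Fit an h-component PLS1 model by NIPALS with X-deflation.

    Predictors are centred and unit-variance scaled (constant columns get
    scale 1); the response is centred.  ``h=0`` yields the null model whose
    prediction is the response mean.
    """
    Xm, columns = _as_matrix(X)
    ynum, inferred_mode, classes = _encode_response(y)
    mode = mode or inferred_mode
    if mode == "discriminant" and classes is None:
        classes = np.array([-1.0, 1.0])
    n, p = Xm.shape
    if len(ynum) != n:
        raise ValidationError("X and y have different lengths")
    if np.isnan(Xm).any() or np.isnan(ynum).any():
        raise ValidationError("missing values are not supported")
    if h > min(n - 1, p):
        raise ValidationError(f"h={h} exceeds min(n-1, p)={min(n - 1, p)}")
    if h < 0:
        raise ValidationError("h must be >= 0")
    if np.ptp(ynum) == 0:
        raise ValidationError("constant response")

    x_mean = Xm.mean(axis=0)
    x_scale = Xm.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(ynum.mean())
    Xc = (Xm - x_mean) / x_scale
    yc = ynum - y_mean

    W = np.zeros((p, h))
    P = np.zeros((p, h))
    T = np.zeros((n, h))
    q = np.zeros(h)
    Xd = Xc.copy()
    yd = yc.copy()
    for a in range(h):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            # residual X carries no covariance with y; stop early
            W, P, T, q = W[:, :a], P[:, :a], T[:, :a], q[:a]
            h = a
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        qa = (t @ yd) / tt
        pa = (Xd.T @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa

    if h == 0:
        coef_scaled = np.zeros(p)
    else:
        # B = W (P'W)^-1 q maps scaled X to the centred response
        coef_scaled = W @ np.linalg.solve(P.T @ W, q)

    return PlsModel(
        mode=mode,
        n_components=h,
        W=W,
        P=P,
        T=T,
        q=q,
        coef_scaled=coef_scaled,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        columns=columns,
        classes_=classes,
    )


def predict(model: PlsModel, Xnew, return_labels: bool | None = None):
    """Linear predictor for new samples; in discriminant mode hard labels
    are assigned by the sign of the score."""
    Xm, columns = _as_matrix(Xnew)
    if model.columns is not None and columns is not None and columns != model.columns:
        missing = [c for c in model.columns if c not in columns]
        extra = [c for c in columns if c not in model.columns]
        raise ColumnMismatchError(f"missing columns {missing}; unexpected {extra}")
    if Xm.shape[1] != len(model.x_mean):
        raise ColumnMismatchError(
            f"expected {len(model.x_mean)} columns, got {Xm.shape[1]}"
        )
    scores = ((Xm - model.x_mean) / model.x_scale) @ model.coef_scaled + model.y_mean
    if return_labels is None:
        return_labels = model.mode == "discriminant"
    if return_labels and model.mode == "discriminant":
        labels = np.where(scores >= 0, model.classes_[1], model.classes_[0])
        return scores, labels
    return scores


# --------------------------------------------------------------------------
# cross-validation machinery
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CvSpec:
    """Repeated k-fold cross-validation settings.

    ``permute='test_labels'`` shuffles only the held-out labels/responses
    before scoring (the permutation analogue used throughout);
    ``permute='full_labels'`` shuffles the response before splitting.
    """

    k: int = 4
    replicates: int = 20
    stratified: bool = True
    seed: int = 0
    permute: str = "none"  # none | test_labels | full_labels

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.permute not in ("none", "test_labels", "full_labels"):
            raise ValidationError(f"unknown permute mode {self.permute!r}")


def _fold_indices(n: int, cv: CvSpec, replicate: int, strata=None) -> list[np.ndarray]:
    """Deterministic fold assignment from (seed, replicate, n, strata).

    Stratified assignment shuffles each stratum and deals its members
    round-robin across folds, rotating the starting fold per stratum so
    fold sizes stay balanced.
    """
    rng = np.random.default_rng([cv.seed, replicate, n])
    folds: list[list[int]] = [[] for _ in range(cv.k)]
    if strata is not None and cv.stratified:
        offset = 0
        for cls in np.unique(strata):
            idx = np.flatnonzero(np.asarray(strata) == cls)
            idx = idx[rng.permutation(len(idx))]
            for j, i in enumerate(idx):
                folds[(j + offset) % cv.k].append(int(i))
            offset += len(idx) % cv.k
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            folds[j % cv.k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f) > 0]


@dataclass
class CvResult:
    """Averaged repeated-CV outcome.

    ``mean`` is misclassification % (discriminant) or predictive ability
    (squared predicted-observed correlation, regression), averaged over
    folds within replicate and then over replicates; ``sd`` is the spread
    across replicates.
    """

    mode: str
    per_replicate: np.ndarray
    mean: float
    sd: float
    cv: CvSpec
    h: int

    @property
    def criterion(self) -> float:
        return self.mean


def _replicate_score(Xm, ynum, labels, h, cv, rep, mode, rng_perm) -> float:
    strata = labels if mode == "discriminant" else None
    folds = _fold_indices(len(ynum), cv, rep, strata)
    fold_scores = []
    for test in folds:
        train = np.setdiff1d(np.arange(len(ynum)), test)
        if mode == "discriminant" and len(np.unique(labels[train])) < 2:
            raise SingleClassError("a training fold lost one class")
        y_train = labels[train] if mode == "discriminant" else ynum[train]
        if cv.permute == "full_labels":
            y_train = y_train  # response already shuffled by caller
        model = fit_pls(Xm[train], y_train, h=min(h, min(len(train) - 1, Xm.shape[1])))
        if mode == "discriminant":
            _, pred = predict(model, Xm[test])
            truth = labels[test]
            if cv.permute == "test_labels":
                truth = truth[rng_perm.permutation(len(truth))]
            fold_scores.append(100.0 * np.mean(pred != truth))
        else:
            pred = predict(model, Xm[test])
            obs = ynum[test]
            if cv.permute == "test_labels":
                obs = obs[rng_perm.permutation(len(obs))]
            if len(obs) < 2 or np.ptp(obs) == 0 or np.ptp(pred) == 0:
                fold_scores.append(0.0)
            else:
                r = np.corrcoef(pred, obs)[0, 1]
                fold_scores.append(r * r)
    return float(np.mean(fold_scores))


def cross_validate(X, y, h: int, cv: CvSpec, variables=None) -> CvResult:
    """Repeated k-fold CV of an h-component model on a fixed variable set.

    Misclassification % (discriminant) or predictive ability (regression)
    is averaged folds-then-replicates, with the SD taken across replicates.
    """
    Xm, columns = _as_matrix(X)
    if variables is not None:
        if columns is None:
            idx = np.asarray(variables, dtype=int)
        else:
            idx = np.array([columns.index(v) for v in variables])
        Xm = Xm[:, idx]
    ynum, mode, classes = _encode_response(y)
    labels = np.asarray(y) if mode == "discriminant" else None

    per_rep = np.empty(cv.replicates)
    for rep in range(cv.replicates):
        rng_perm = np.random.default_rng([cv.seed, rep, 7919])
        yr, labr = ynum, labels
        if cv.permute == "full_labels":
            perm = rng_perm.permutation(len(ynum))
            yr = ynum[perm]
            labr = labels[perm] if labels is not None else None
        cv_inner = cv if cv.permute != "full_labels" else CvSpec(
            k=cv.k, replicates=cv.replicates, stratified=cv.stratified,
            seed=cv.seed, permute="none",
        )
        per_rep[rep] = _replicate_score(Xm, yr, labr, h, cv_inner, rep, mode, rng_perm)
    return CvResult(
        mode=mode,
        per_replicate=per_rep,
        mean=float(per_rep.mean()),
        sd=float(per_rep.std(ddof=1)) if cv.replicates > 1 else 0.0,
        cv=cv,
        h=h,
    )


# --------------------------------------------------------------------------
# dimension selection
# --------------------------------------------------------------------------


@dataclass
class Q2Series:
    """RSS/PRESS/Q2 per dimension.  RSS_0 is the total (centred) sum of
    squares of the response; Q2_h = 1 - PRESS_h / RSS_{h-1}."""

    rss: np.ndarray  # rss[0] = RSS_0, rss[h] = RSS at h components
    press: np.ndarray  # press[h-1] = averaged PRESS at h components
    q2: np.ndarray  # q2[h-1] = Q2_h
    cv: CvSpec
    threshold: float = Q2_DEFAULT_THRESHOLD


def q2_sequence(X, y, cv: CvSpec, h_max: int) -> Q2Series:
    """Compute RSS_h, replicate-averaged PRESS_h and Q2_h for h = 1..h_max.

    RSS_h comes from the full-data fit with h components; PRESS_h sums the
    squared test-fold residuals within each replicate and averages across
    replicates.  Folds are stratified by class in discriminant mode.
    """
    if h_max < 1:
        raise ValidationError("h_max must be >= 1")
    Xm, _ = _as_matrix(X)
    ynum, mode, classes = _encode_response(y)
    labels = np.asarray(y) if mode == "discriminant" else None
    n, p = Xm.shape
    h_max = min(h_max, n - 1, p)

    rss = np.empty(h_max + 1)
    rss[0] = float(np.sum((ynum - ynum.mean()) ** 2))
    full_models = [fit_pls(Xm, y, h=h) for h in range(1, h_max + 1)]
    for h, m in enumerate(full_models, start=1):
        fitted = predict(m, Xm, return_labels=False)
        rss[h] = float(np.sum((ynum - fitted) ** 2))

    press = np.zeros(h_max)
    for rep in range(cv.replicates):
        folds = _fold_indices(n, cv, rep, labels)
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            if mode == "discriminant" and len(np.unique(labels[train])) < 2:
                raise SingleClassError("a training fold lost one class")
            y_train = labels[train] if mode == "discriminant" else ynum[train]
            for h in range(1, h_max + 1):
                m = fit_pls(Xm[train], y_train, h=min(h, len(train) - 1, p))
                pred = predict(m, Xm[test], return_labels=False)
                press[h - 1] += float(np.sum((ynum[test] - pred) ** 2))
    press /= cv.replicates

    q2 = np.empty(h_max)
    tiny = 1e-12 * max(rss[0], 1.0)
    for h in range(1, h_max + 1):
        denom = rss[h - 1]
        q2[h - 1] = -np.inf if denom <= tiny else 1.0 - press[h - 1] / denom
    return Q2Series(rss=rss, press=press, q2=q2, cv=cv)


def select_n_components(
    q2: Q2Series, threshold: float = Q2_DEFAULT_THRESHOLD
) -> int:
    """Largest h* with Q2_h > threshold for every h <= h*; at least one
    component is always retained (boundary Q2 == threshold stops)."""
    h = 0
    for value in q2.q2:
        if value > threshold:
            h += 1
        else:
            break
    return max(h, 1)


# --------------------------------------------------------------------------
# variable importance and selection
# --------------------------------------------------------------------------


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_h SSY_h w_jh^2 / sum_h SSY_h ) with
    SSY_h = q_h^2 t_h' t_h; the scores satisfy sum_j VIP_j^2 = p.
    """
    if model.n_components < 1:
        raise ValidationError("model has no components")
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)
    weights = model.W**2  # columns already unit norm
    return np.sqrt(p * (weights @ ssy) / ssy.sum())


@dataclass
class JackknifeResult:
    """Per-variable jack-knife coefficient intervals over the m = k x
    replicates leave-fold-out refits (original predictor scale)."""

    mean: np.ndarray
    se: np.ndarray
    low: np.ndarray
    high: np.ndarray
    excludes_zero: np.ndarray
    m: int

    def as_frame(self, columns=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coefficient": self.mean,
                "jk_se": self.se,
                "low": self.low,
                "high": self.high,
                "excludes_zero": self.excludes_zero,
            }
        )
        if columns is not None:
            df.index = pd.Index(columns, name="variable")
        return df


def jackknife_coefficients(X, y, h: int, cv: CvSpec) -> JackknifeResult:
    """Leave-fold-out jack-knife intervals for the PLS coefficients.

    Within each CV replicate the k delete-a-fold refits give a jack-knife
    variance (k-1)/k x sum (b_fold - b_bar_rep)^2; variances are averaged
    across replicates for stability and the interval is the overall mean
    coefficient +/- t_{0.975, m-1} x SE with m = k x replicates refits.
    """
    Xm, _ = _as_matrix(X)
    ynum, mode, classes = _encode_response(y)
    labels = np.asarray(y) if mode == "discriminant" else None
    n, p = Xm.shape
    rep_vars = []
    coefs = []
    for rep in range(cv.replicates):
        folds = _fold_indices(n, cv, rep, labels)
        rep_coefs = []
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            if mode == "discriminant" and len(np.unique(labels[train])) < 2:
                raise SingleClassError("a training fold lost one class")
            y_train = labels[train] if mode == "discriminant" else ynum[train]
            m = fit_pls(Xm[train], y_train, h=min(h, len(train) - 1, p))
            rep_coefs.append(m.coef_)
        R = np.asarray(rep_coefs)
        k_eff = R.shape[0]
        rep_vars.append(
            (k_eff - 1) / k_eff * np.sum((R - R.mean(axis=0)) ** 2, axis=0)
        )
        coefs.extend(rep_coefs)
    B = np.asarray(coefs)
    m = B.shape[0]
    mean = B.mean(axis=0)
    se = np.sqrt(np.mean(rep_vars, axis=0))
    tcrit = stats.t.ppf(0.975, m - 1)
    low, high = mean - tcrit * se, mean + tcrit * se
    return JackknifeResult(
        mean=mean,
        se=se,
        low=low,
        high=high,
        excludes_zero=(low > 0) | (high < 0),
        m=m,
    )


@dataclass
class SelectionResult:
    """Outcome of iterative VIP/jack-knife variable selection."""

    retained: list
    vip: pd.Series
    jackknife: pd.DataFrame
    n_components: int
    cv_final: CvResult
    iterations: list = field(default_factory=list)
    emptied: bool = False  # selection would have removed every variable


def _better(current: float, previous: float, mode: str) -> bool:
    if mode == "discriminant":  # lower misclassification is better
        return current < previous
    return current > previous


def iterative_variable_selection(
    X,
    y,
    cv: CvSpec,
    vip_threshold: float = VIP_DEFAULT_THRESHOLD,
    q2_threshold: float = Q2_DEFAULT_THRESHOLD,
    h_max: int = 5,
    max_iterations: int = 50,
) -> SelectionResult:
    """Iteratively drop variables failing VIP > threshold or whose
    jack-knife interval contains zero, re-selecting the number of
    components each round, until the cross-validated criterion stops
    strictly improving or nothing fails; the best-criterion iteration's
    variable set is returned.  The same fold seeds are reused throughout so
    iterations are compared net of CV noise.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    if Xdf.shape[1] < 2:
        raise ValidationError("need at least 2 variables")
    _, mode, _ = _encode_response(y)

    variables = list(Xdf.columns)
    trace: list[dict] = []
    records: list[dict] = []
    emptied = False
    prev_criterion = None
    for it in range(max_iterations):
        Xs = Xdf[variables]
        q2 = q2_sequence(Xs, y, cv, h_max=min(h_max, len(variables)))
        h = select_n_components(q2, q2_threshold)
        model = fit_pls(Xs, y, h=h)
        vip = vip_scores(model)
        jk = jackknife_coefficients(Xs, y, h, cv)
        result = cross_validate(Xs, y, h=h, cv=cv)
        records.append(
            {"variables": list(variables), "h": h, "vip": vip, "jk": jk, "cv": result}
        )
        passing = [
            v
            for v, ok in zip(
                variables, (vip > vip_threshold) & jk.excludes_zero
            )
            if ok
        ]
        removed = [v for v in variables if v not in passing]
        trace.append(
            {
                "iteration": it,
                "n_variables": len(variables),
                "h": h,
                "criterion": result.mean,
                "removed": removed,
            }
        )
        if it > 0 and not _better(result.mean, prev_criterion, mode):
            break
        prev_criterion = result.mean
        if not removed:
            break
        if not passing:
            emptied = True
            warnings.warn(
                "variable selection would remove every variable; "
                "keeping the previous iteration",
                stacklevel=2,
            )
            break
        variables = passing

    # best criterion wins; ties go to the smaller (more parsimonious) set
    best = records[0]
    for rec in records[1:]:
        if _better(rec["cv"].mean, best["cv"].mean, mode) or (
            rec["cv"].mean == best["cv"].mean
            and len(rec["variables"]) < len(best["variables"])
        ):
            best = rec
    return SelectionResult(
        retained=best["variables"],
        vip=pd.Series(best["vip"], index=best["variables"], name="vip"),
        jackknife=best["jk"].as_frame(best["variables"]),
        n_components=best["h"],
        cv_final=best["cv"],
        iterations=trace,
        emptied=emptied,
    )
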