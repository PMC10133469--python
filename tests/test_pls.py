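"""NIPALS PLS1 / DA-PLS: oracles, Q2 selection, VIP, jack-knife, CV."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumenpls.errors import ColumnMismatchError, ValidationError
from rumenpls.pls import (
    CvSpec,
    cross_validate,
    fit_pls,
    iterative_variable_selection,
    jackknife_coefficients,
    predict,
    q2_sequence,
    Q2Series,
    select_n_components,
    vip_scores,
)


# ------------------------------------------------------------- oracles


def svd_pls1_coefficients(X, y, h):
    """Independent PLS1 reference: weights from the SVD of the
    cross-covariance X'y, scores by projection, X-deflation, and the
    coefficient map B = W (P'W)^-1 q, assembled with lstsq.  Returns
    coefficients on the original predictor scale plus the intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xm, xs = X.mean(0), X.std(0, ddof=1)
    xs[xs == 0] = 1.0
    ym = y.mean()
    Xc = (X - xm) / xs
    yc = y - ym
    W, P, Q = [], [], []
    Xd = Xc.copy()
    yd = yc.copy()
    for _ in range(h):
        U, s, Vt = np.linalg.svd(Xd.T @ yd.reshape(-1, 1), full_matrices=False)
        w = U[:, 0] * np.sign(Vt[0, 0]) if s[0] > 0 else U[:, 0]
        t = Xd @ w
        p_ = np.linalg.lstsq(t.reshape(-1, 1), Xd, rcond=None)[0][0]
        q_ = np.linalg.lstsq(t.reshape(-1, 1), yd.reshape(-1, 1), rcond=None)[0][0, 0]
        Xd = Xd - np.outer(t, p_)
        yd = yd - q_ * t
        W.append(w)
        P.append(p_)
        Q.append(q_)
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    B = W @ np.linalg.solve(P.T @ W, Q)
    coef = B / xs
    return coef, ym - xm @ coef


@pytest.mark.parametrize("seed", range(10))
def test_coefficients_match_svd_oracle_and_sklearn(seed):
    r = np.random.default_rng(seed)
    n, p, h = r.integers(10, 31), r.integers(3, 21), r.integers(1, 6)
    h = int(min(h, p, n - 1))
    X = r.normal(size=(n, p))
    y = r.normal(size=n)
    model = fit_pls(X, y, h=h)

    coef, icept = svd_pls1_coefficients(X, y, h)
    np.testing.assert_allclose(model.coef_, coef, atol=1e-8)
    np.testing.assert_allclose(model.intercept_, icept, atol=1e-8)

    from sklearn.cross_decomposition import PLSRegression

    sk = PLSRegression(n_components=h, scale=True).fit(X, y.reshape(-1, 1))
    np.testing.assert_allclose(
        predict(model, X), sk.predict(X).ravel(), atol=1e-8
    )


# ---------------------------------------------------------- fit/predict


def test_perfectly_collinear_predictor_gives_r2_one(rng):
    # orthogonal zero-mean predictors: the first weight vector points
    # exactly at the informative column, so one component fits perfectly
    Z = rng.normal(size=(15, 4))
    X, _ = np.linalg.qr(Z - Z.mean(axis=0))
    y = 3.0 * X[:, 2]
    model = fit_pls(X, y, h=1)
    fitted = predict(model, X)
    ss = np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
    assert ss < 1e-10


def test_zero_components_predicts_the_mean(rng):
    X = rng.normal(size=(10, 3))
    y = rng.normal(size=10)
    model = fit_pls(X, y, h=0)
    np.testing.assert_allclose(predict(model, X), y.mean(), atol=1e-12)


def test_scores_orthogonal_and_weights_unit_norm(rng):
    X = rng.normal(size=(25, 12))
    y = X @ rng.normal(size=12) + rng.normal(size=25)
    m = fit_pls(X, y, h=4)
    G = m.T.T @ m.T
    np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
    np.testing.assert_allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-12)


def test_prediction_consistency_and_column_checks(rng):
    X = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
    y = rng.normal(size=12)
    m = fit_pls(X, y, h=2)
    fitted = predict(m, X)
    # duplicated training sample predicts identically
    assert predict(m, X.iloc[[3]])[0] == pytest.approx(fitted[3], abs=1e-12)
    with pytest.raises(ColumnMismatchError):
        predict(m, X.rename(columns={"a": "z"}))


def test_separable_discriminant_classifies_training_data(rng):
    X = np.vstack([rng.normal(-3, 0.5, (8, 4)), rng.normal(3, 0.5, (8, 4))])
    labels = np.array(["A"] * 8 + ["B"] * 8)
    m = fit_pls(X, labels, h=1)
    _, pred = predict(m, X)
    assert (pred == labels).all()


def test_degenerate_inputs_raise():
    X = np.random.default_rng(0).normal(size=(8, 3))
    with pytest.raises(ValidationError):
        fit_pls(X, np.ones(8), h=1)  # constant response
    with pytest.raises(ValidationError):
        fit_pls(X, np.arange(8.0), h=5)  # h > p
    with pytest.raises(ValidationError):
        fit_pls(X, np.array(["a"] * 8), h=1)  # single class


# ------------------------------------------------------------------- Q2


def test_rss0_is_total_sum_of_squares(rng):
    X = rng.normal(size=(20, 6))
    y = rng.normal(size=20)
    series = q2_sequence(X, y, CvSpec(k=4, replicates=2, seed=0), h_max=2)
    assert series.rss[0] == pytest.approx((len(y) - 1) * np.var(y, ddof=1))
    assert (np.diff(series.rss) <= 1e-9).all()  # RSS non-increasing


def test_select_n_components_rules():
    def series(vals):
        return Q2Series(
            rss=np.zeros(len(vals) + 1),
            press=np.zeros(len(vals)),
            q2=np.array(vals),
            cv=CvSpec(k=4, replicates=1),
        )

    assert select_n_components(series([0.41, 0.12, 0.03])) == 2
    assert select_n_components(series([0.02, 0.5])) == 1  # floor rule
    assert select_n_components(series([0.0975])) == 1  # boundary stops


def test_one_factor_data_selects_one_component(rng):
    t = rng.normal(size=24)
    X = np.outer(t, rng.normal(size=10)) + 0.05 * rng.normal(size=(24, 10))
    series = q2_sequence(X, t, CvSpec(k=4, replicates=5, seed=1), h_max=3)
    assert series.q2[0] > 0.9
    assert select_n_components(series) == 1


# ------------------------------------------------------------------ VIP


def test_vip_hand_case_and_identity(rng):
    # h=1 and w = (1/sqrt2, 1/sqrt2, 0): VIP = sqrt(3 w_j^2)
    X = np.random.default_rng(5).normal(size=(40, 3))
    X[:, 2] = np.random.default_rng(6).normal(size=40)
    y = X[:, 0] + X[:, 1]
    m = fit_pls(X, y, h=1)
    vip = vip_scores(m)
    np.testing.assert_allclose(vip[:2], np.sqrt(1.5), atol=0.05)
    assert vip[2] < 0.5
    for h in (1, 2, 3):
        model = fit_pls(rng.normal(size=(20, 7)), rng.normal(size=20), h=h)
        assert np.sum(vip_scores(model) ** 2) == pytest.approx(7.0, abs=1e-8)


# ------------------------------------------------------------ jack-knife


def test_jackknife_matches_brute_force_loop(rng):
    X = rng.normal(size=(16, 5))
    y = X @ np.array([2.0, 0, 0, 0, 0]) + 0.1 * rng.normal(size=16)
    cv = CvSpec(k=4, replicates=3, seed=9)
    jk = jackknife_coefficients(X, y, h=1, cv=cv)

    # brute force: same folds, explicit per-replicate jackknife variance
    from rumenpls.pls import _fold_indices

    all_coefs, variances = [], []
    for rep in range(cv.replicates):
        folds = _fold_indices(16, cv, rep, None)
        B = []
        for test in folds:
            train = np.setdiff1d(np.arange(16), test)
            B.append(fit_pls(X[train], y[train], h=1).coef_)
        B = np.asarray(B)
        variances.append((len(B) - 1) / len(B) * ((B - B.mean(0)) ** 2).sum(0))
        all_coefs.extend(B)
    mean = np.mean(all_coefs, axis=0)
    se = np.sqrt(np.mean(variances, axis=0))
    tcrit = stats.t.ppf(0.975, len(all_coefs) - 1)
    np.testing.assert_allclose(jk.mean, mean, atol=1e-10)
    np.testing.assert_allclose(jk.se, se, atol=1e-10)
    np.testing.assert_allclose(jk.low, mean - tcrit * se, atol=1e-10)


def test_jackknife_signal_excludes_zero_noise_contains_it():
    hits_signal, hits_noise = 0, 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.normal(size=(20, 6))
        y = 3.0 * X[:, 0] + 0.05 * r.normal(size=20)
        jk = jackknife_coefficients(X, y, h=1, cv=CvSpec(k=4, replicates=5, seed=seed))
        hits_signal += jk.excludes_zero[0]
        hits_noise += not jk.excludes_zero[5]
    assert hits_signal == 10
    assert hits_noise >= 9


# ------------------------------------------------------------------- CV


def test_separable_classes_cv_misclassification_zero(rng):
    X = np.vstack([rng.normal(-4, 0.5, (12, 5)), rng.normal(4, 0.5, (12, 5))])
    labels = np.array(["G"] * 12 + ["T"] * 12)
    res = cross_validate(X, labels, h=1, cv=CvSpec(k=4, replicates=20, seed=0))
    assert res.mean == 0.0


def test_noiseless_regression_predictive_ability(rng):
    X = rng.normal(size=(30, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    res = cross_validate(X, y, h=5, cv=CvSpec(k=3, replicates=5, seed=1))
    assert res.mode == "regression"
    assert res.mean > 0.99


def test_fold_assignment_is_deterministic_and_stratified():
    from rumenpls.pls import _fold_indices

    labels = np.array(["A"] * 13 + ["B"] * 13)
    cv = CvSpec(k=4, replicates=2, seed=5)
    f1 = _fold_indices(26, cv, 0, labels)
    f2 = _fold_indices(26, cv, 0, labels)
    assert all((a == b).all() for a, b in zip(f1, f2))
    for fold in f1:
        classes = set(labels[fold])
        assert classes == {"A", "B"}
    assert sorted(len(f) for f in f1) in ([6, 6, 7, 7], [5, 7, 7, 7])


# -------------------------------------------------------------- selection


def test_iterative_selection_recovers_planted_signal():
    """5 of 50 variables carry all the signal (a shared latent factor);
    selection keeps them and improves or preserves the CV criterion."""
    hits = 0
    for seed in range(5):
        r = np.random.default_rng(100 + seed)
        n, p = 26, 50
        t = r.normal(size=n)
        X = r.normal(size=(n, p))
        X[:, :5] = np.outer(t, [1.0, -1.0, 0.8, -0.8, 0.6]) + 0.2 * X[:, :5]
        y = t + 0.1 * r.normal(size=n)
        sel = iterative_variable_selection(
            pd.DataFrame(X), y, cv=CvSpec(k=3, replicates=10, seed=seed)
        )
        full_cv = cross_validate(X, y, h=1, cv=CvSpec(k=3, replicates=10, seed=seed))
        if set(range(5)) <= set(sel.retained) and sel.cv_final.mean >= full_cv.mean:
            hits += 1
    assert hits >= 4


def test_selection_keeps_everything_when_all_variables_matter(rng):
    X, _ = np.linalg.qr(rng.normal(size=(24, 3)))
    y = X @ np.array([2.0, 2.0, 2.0]) + 0.02 * rng.normal(size=24)
    sel = iterative_variable_selection(
        pd.DataFrame(X, columns=list("abc")), y, cv=CvSpec(k=4, replicates=5, seed=0)
    )
    assert sel.retained == list("abc")
    assert len(sel.iterations) == 1
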