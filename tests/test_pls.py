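"""PLS matrices, fitting, prediction, cross-sample validation, and
covariate tests — checked against an independently coded deflation oracle."""

import numpy as np
import pandas as pd
import pytest

from hemiasym.containers import SCORED_EPOCHS, SchemaError
from hemiasym.coupling import InsufficientDataError  # noqa: F401  (API surface)
from hemiasym.networks import aggregate_by_network
from hemiasym.pls import (
    PLSModel,
    build_accuracy_matrix,
    build_predictor_matrix,
    component_covariate_tests,
    cross_sample_validate,
    evaluate_prediction,
)
from hemiasym.simulate import SimulationConfig, generate_cohort
from hemiasym.asymmetry import compute_asymmetry


def _summary(n_subjects=30, seed=2, n_vertices=120):
    config = SimulationConfig(n_subjects=n_subjects, n_vertices=n_vertices,
                              seed=seed)
    dataset, table, truth = generate_cohort(config)
    result = compute_asymmetry(dataset)
    return aggregate_by_network(result, truth.partition()), table


# -- NIPALS deflation oracle ------------------------------------------------

def nipals_oracle(X, Y, n_components, tol=1e-12, max_iter=2000):
    """Single-component-at-a-time PLS2 with X deflation, coded directly
    from the algorithm definition: iterate w <- X'u/|X'u|, t <- Xw,
    q <- Y't/t't, u <- Yq/q'q to convergence, then deflate X by t p'."""
    X = np.asarray(X, float).copy()
    Y = np.asarray(Y, float).copy()
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    Yc = Y.copy()
    T, Q = [], []
    for _ in range(n_components):
        u = Y[:, [np.argmax(Y.var(0))]].copy()
        for _ in range(max_iter):
            w = X.T @ u
            w /= np.linalg.norm(w)
            t = X @ w
            q = Y.T @ t / (t.T @ t)
            u_new = Y @ q / (q.T @ q)
            if np.linalg.norm(u_new - u) < tol * np.linalg.norm(u):
                u = u_new
                break
            u = u_new
        t = X @ w
        p = X.T @ t / (t.T @ t)
        X = X - t @ p.T
        Y = Y - t @ q.T
        T.append(t.ravel())
        Q.append(q.ravel())
    T = np.column_stack(T)
    Q = np.column_stack(Q)
    tss = float(np.sum(Yc ** 2))
    evar = []
    for k in range(1, n_components + 1):
        resid = Yc - T[:, :k] @ Q[:, :k].T
        evar.append(1.0 - float(np.sum(resid ** 2)) / tss)
    return np.asarray(evar), T


def test_explained_variance_matches_deflation_oracle(rng):
    """Fixed 30x8 -> 30x3 problem: cumulative explained variance agrees
    with the independently coded deflation oracle to 1e-6."""
    X = rng.standard_normal((30, 8))
    B = rng.standard_normal((8, 3))
    Y = X @ B + 0.5 * rng.standard_normal((30, 3))
    res = PLSModel(X, Y, n_components=5).fit(cv_folds=0)
    evar_oracle, T_oracle = nipals_oracle(X, Y, 5)
    np.testing.assert_allclose(res.cumulative_explained_variance,
                               evar_oracle, atol=1e-6)
    # scores span the same sequence of 1-D subspaces
    for k in range(5):
        c = np.corrcoef(res.x_scores[:, k], T_oracle[:, k])[0, 1]
        assert abs(c) > 1 - 1e-6


def test_exact_linear_map_explained_at_one_component(rng):
    """A noiseless rank-1 map on uncorrelated equal-variance predictors
    is captured fully by a single component (the first weight vector is
    then exactly proportional to the true map)."""
    raw = rng.standard_normal((40, 6))
    U, _, _ = np.linalg.svd(raw - raw.mean(0), full_matrices=False)
    X = U  # zero-mean, orthonormal, equal-variance columns
    w = rng.standard_normal(6)
    Y = np.outer(X @ w, [1.0, 2.0, -0.5])  # rank-1 exact map
    res = PLSModel(X, Y, n_components=1).fit(cv_folds=0)
    assert res.cumulative_explained_variance[0] == pytest.approx(1.0,
                                                                 abs=1e-8)


def test_score_orthogonality_and_nesting(rng):
    X = rng.standard_normal((50, 20))
    Y = X[:, :4] @ rng.standard_normal((4, 5)) + rng.standard_normal((50, 5))
    res = PLSModel(X, Y, n_components=8).fit(cv_folds=0)
    gram = res.x_scores.T @ res.x_scores
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8
    assert np.all(np.diff(res.cumulative_explained_variance) >= -1e-12)


def test_null_data_low_cv_explained_variance():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((200, 30))
    Y = rng.standard_normal((200, 4))
    res = PLSModel(X, Y, n_components=8).fit(cv_folds=10, seed=5)
    assert (res.cv_table["cv_explained_variance"] <= 0.05).all()


def test_predict_reproduces_fitted_and_rows(rng):
    X = pd.DataFrame(rng.standard_normal((30, 6)))
    Y = pd.DataFrame(rng.standard_normal((30, 2)))
    res = PLSModel(X, Y, n_components=3).fit(cv_folds=0)
    fitted = res.fittedvalues()
    np.testing.assert_allclose(res.predict(X).to_numpy(),
                               fitted.to_numpy(), atol=1e-10)
    row = X.iloc[[4]]
    np.testing.assert_allclose(res.predict(row).to_numpy(),
                               fitted.iloc[[4]].to_numpy(), atol=1e-10)


def test_predict_label_mismatch_raises(rng):
    X = pd.DataFrame(rng.standard_normal((20, 4)), columns=list("abcd"))
    Y = rng.standard_normal((20, 2))
    res = PLSModel(X, Y, n_components=2).fit(cv_folds=0)
    bad = X.rename(columns={"d": "e"})
    with pytest.raises(SchemaError, match="columns"):
        res.predict(bad)


def test_fold_assignment_deterministic(rng):
    X = rng.standard_normal((40, 10))
    Y = rng.standard_normal((40, 3))
    r1 = PLSModel(X, Y, n_components=4).fit(cv_folds=5, seed=11)
    r2 = PLSModel(X, Y, n_components=4).fit(cv_folds=5, seed=11)
    pd.testing.assert_frame_equal(r1.cv_table, r2.cv_table)
    np.testing.assert_array_equal(r1.coef, r2.coef)


def test_n_components_bounds(rng):
    X = rng.standard_normal((10, 5))
    Y = rng.standard_normal((10, 2))
    with pytest.raises(ValueError, match="n_components"):
        PLSModel(X, Y, n_components=10)


# -- matrix construction ----------------------------------------------------

def test_predictor_matrix_153_columns():
    summary, _ = _summary()
    X = build_predictor_matrix(summary, "amplitude")
    assert X.n_columns == 153  # 9 networks x 17 epochs
    # epoch-major order, canonical networks within each epoch
    assert X.values.columns[0] == ("faces", "VIS1")
    assert X.values.columns[9] == ("shapes", "VIS1")


def test_predictor_matrix_small_order():
    summary, _ = _summary()
    X = build_predictor_matrix(summary, "delta",
                               networks=["LAN", "FPN"],
                               epochs=["story", "math", "2bk"])
    assert [tuple(c) for c in X.values.columns] == [
        ("story", "LAN"), ("story", "FPN"), ("math", "LAN"),
        ("math", "FPN"), ("2bk", "LAN"), ("2bk", "FPN")]


def test_excluded_networks_rejected():
    summary, _ = _summary()
    with pytest.raises(SchemaError, match="ORA"):
        build_predictor_matrix(summary, "amplitude",
                               networks=["LAN", "ORA"])
    X = build_predictor_matrix(summary, "amplitude",
                               networks=["LAN", "ORA"], allow_excluded=True)
    assert X.n_columns == 34


def test_accuracy_matrix_order_and_imputation():
    summary, table = _summary()
    acc, mask = build_accuracy_matrix(table)
    assert list(acc.columns) == list(SCORED_EPOCHS)
    assert acc.shape == (30, 12)
    assert not mask.any().any()

    table2 = table.copy()
    table2.iloc[0, table2.columns.get_loc("acc_story")] = np.nan
    acc2, mask2 = build_accuracy_matrix(table2)
    assert mask2.iloc[0][acc2.columns.get_loc("story")
                         if False else "story"]
    col_mean = table2["acc_story"].iloc[1:].mean()
    assert acc2["story"].iloc[0] == pytest.approx(col_mean)

    table3 = table.copy()
    table3["acc_story"] = np.nan
    with pytest.raises(SchemaError, match="story"):
        build_accuracy_matrix(table3)


# -- evaluation -------------------------------------------------------------

def test_perfect_prediction_all_r_one(rng):
    Y = pd.DataFrame(rng.standard_normal((20, 4)))
    ev = evaluate_prediction(Y, Y.copy())
    np.testing.assert_allclose(ev.r, 1.0)
    assert ev.significant.all()


def test_permuted_prediction_near_zero():
    rng = np.random.default_rng(2)
    Y = pd.DataFrame(rng.standard_normal((500, 6)))
    perm = rng.permutation(500)
    ev = evaluate_prediction(Y, Y.iloc[perm].to_numpy())
    assert (ev.r.abs() < 0.15).all()


def test_bonferroni_threshold_over_12_responses(rng):
    n = 40
    Y = pd.DataFrame(rng.standard_normal((n, 12)))
    pred = Y + rng.standard_normal((n, 12))
    ev = evaluate_prediction(Y, pred, alpha=0.05, control="bonferroni")
    expected = ev.p < 0.05 / 12
    pd.testing.assert_series_equal(ev.significant, expected,
                                   check_names=False)


def test_held_out_prediction_of_planted_map(rng):
    """Planted rank-3 linear map: held-out correlation approaches the
    analytic signal fraction sqrt(s2/(s2 + sigma2))."""
    n, p, q = 1000, 20, 6
    rng = np.random.default_rng(8)
    X = rng.standard_normal((n, p))
    B = rng.standard_normal((p, 3)) @ rng.standard_normal((3, q))
    B /= np.linalg.norm(B, axis=0, keepdims=True)
    sigma = 1.0
    signal = X @ B                       # unit variance per column approx
    Y = signal + sigma * rng.standard_normal((n, q))
    res = PLSModel(X[:500], Y[:500], n_components=6).fit(cv_folds=0)
    pred = res.predict(pd.DataFrame(X[500:]))
    ev = evaluate_prediction(pd.DataFrame(Y[500:]), pred)
    expected = np.sqrt(signal.var(0) / (signal.var(0) + sigma ** 2))
    np.testing.assert_allclose(ev.r.to_numpy(), expected, atol=0.06)


def test_cross_sample_identical_cohorts_agree(rng):
    X = rng.standard_normal((60, 10))
    Y = X[:, :3] @ rng.standard_normal((3, 4)) + \
        0.3 * rng.standard_normal((60, 4))
    out = cross_sample_validate(X, Y, X.copy(), Y.copy(), n_components=5,
                                cv_folds=0)
    a = out["a_to_b"]
    np.testing.assert_allclose(a["within"].r, a["out_of_sample"].r,
                               atol=1e-10)


def test_component_covariate_tests_recover_age(rng):
    """With the age signal planted in the predictors and the response,
    the first component's scores track age almost exactly, and the
    Bonferroni flags follow p < alpha / n_components."""
    _, table = _summary(n_subjects=60, seed=9)
    age = table["age"].to_numpy()
    z = (age - age.mean()) / age.std()
    X = np.column_stack([z, 1e-3 * rng.standard_normal((60, 4))])
    res = PLSModel(pd.DataFrame(X, index=table.index),
                   z[:, None], n_components=3).fit(cv_folds=0)
    stats_df = component_covariate_tests(res, table, alpha=0.05)
    assert stats_df.shape[0] == 3
    # columns are re-standardized inside the model, so the noise columns
    # contribute O(1/sqrt(n)) each; component 1 still tracks age closely
    assert abs(stats_df["age_r"].iloc[0]) > 0.9
    expected_sig = stats_df["age_p"] < 0.05 / 3
    assert (stats_df["age_significant"] == expected_sig).all()
    assert np.isfinite(stats_df["sex_p"]).all()  # two sexes present


def test_pls_summary_prints_key_fields(rng):
    X = rng.standard_normal((30, 8))
    Y = rng.standard_normal((30, 2))
    res = PLSModel(X, Y, n_components=3).fit(cv_folds=3, seed=0)
    text = res.summary()
    assert "PLS Regression Results" in text
    assert "Components:          3" in text
    assert "cv_evar" in text
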