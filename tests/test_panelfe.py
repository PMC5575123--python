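"""Within-FE estimator and CR1 cluster sandwich against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pestnatal.panelfe import (
    ModelSpec,
    build_design,
    cluster_se,
    fit_model,
    fit_within,
    full_battery,
    run_model_battery,
    table2_specs,
)


def _instance(rng, n=300, n_groups=5, n_clusters=15, k=4):
    X = rng.normal(size=(n, k))
    groups = rng.integers(0, n_groups, n)
    clusters = rng.integers(0, n_clusters, n)
    y = X @ rng.normal(size=k) + rng.normal(size=n_groups)[groups] \
        + 0.6 * rng.normal(size=n_clusters)[clusters] + rng.normal(size=n)
    return y, X, groups, clusters


def _frame(y, X, groups, clusters):
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    df["y"], df["g"], df["c"] = y, groups, clusters
    return df


def _fit(y, X, groups, clusters):
    Xf = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    return fit_within(y, Xf, groups, clusters)


def test_within_estimator_matches_dummy_ols_oracle():
    """Demeaning reproduces explicit-dummy OLS coefficients to 1e-8 on 20
    random small instances."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        n = int(rng.integers(150, 501))
        y, X, groups, clusters = _instance(rng, n=n,
                                           n_groups=int(rng.integers(2, 9)),
                                           n_clusters=int(rng.integers(5, 20)),
                                           k=int(rng.integers(2, 6)))
        fit = _fit(y, X, groups, clusters)
        D = pd.get_dummies(groups, dtype=float).to_numpy()
        oracle = sm.OLS(y, np.column_stack([X, D])).fit()
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   oracle.params[: X.shape[1]],
                                   rtol=1e-8, atol=1e-10)


def test_cr1_matches_brute_force_cluster_loop():
    rng = np.random.default_rng(7)
    y, X, groups, clusters = _instance(rng)
    fit = _fit(y, X, groups, clusters)

    # brute force on the explicit-dummy regression
    D = pd.get_dummies(groups, dtype=float).to_numpy()
    Z = np.column_stack([X, D])
    ols = sm.OLS(y, Z).fit()
    e = y - Z @ ols.params
    K, G, n = Z.shape[1], clusters.max() + 1, len(y)
    meat = np.zeros((K, K))
    for g in range(G):
        s = Z[clusters == g].T @ e[clusters == g]
        meat += np.outer(s, s)
    bread = np.linalg.inv(Z.T @ Z)
    V = (G / (G - 1)) * ((n - 1) / (n - K)) * bread @ meat @ bread
    se_oracle = np.sqrt(np.diag(V))[: X.shape[1]]
    np.testing.assert_allclose(fit.se.to_numpy(), se_oracle, rtol=1e-10)


def test_cr1_singleton_clusters_reduce_to_hc1():
    rng = np.random.default_rng(3)
    y, X, groups, _ = _instance(rng, n=200, n_clusters=200)
    clusters = np.arange(200)
    fit = _fit(y, X, groups, clusters)

    D = pd.get_dummies(groups, dtype=float).to_numpy()
    hc1 = sm.OLS(y, np.column_stack([X, D])).fit(cov_type="HC1")
    np.testing.assert_allclose(fit.se.to_numpy(), hc1.bse[: X.shape[1]], rtol=1e-8)


def test_cluster_se_requires_two_clusters():
    rng = np.random.default_rng(0)
    y, X, groups, _ = _instance(rng, n=100)
    with pytest.raises(ValueError, match="clusters"):
        _fit(y, X, groups, np.zeros(100, dtype=int))


def test_duplicating_clusters_keeps_coefs_and_cluster_ses():
    rng = np.random.default_rng(11)
    y, X, groups, clusters = _instance(rng, n=250, n_clusters=20)
    fit1 = _fit(y, X, groups, clusters)
    y2 = np.concatenate([y, y])
    X2 = np.vstack([X, X])
    g2 = np.concatenate([groups, groups])
    c2 = np.concatenate([clusters, clusters])
    fit2 = _fit(y2, X2, g2, c2)
    np.testing.assert_allclose(fit1.params.to_numpy(), fit2.params.to_numpy(),
                               rtol=1e-8)
    # cluster SEs are approximately invariant to duplication...
    ratio = fit2.se.to_numpy() / fit1.se.to_numpy()
    assert np.all((ratio > 0.9) & (ratio < 1.1))
    # ...while the naive (classical) SE would shrink by ~sqrt(2)
    s1 = np.sqrt((fit1.resid**2).sum() / (fit1.n_obs - fit1.k_params))
    s2 = np.sqrt((fit2.resid**2).sum() / (fit2.n_obs - fit2.k_params))
    assert s2 / s1 < 1.01  # same residual scale, but doubled n halves var(beta)


def test_single_group_equals_global_demeaning():
    rng = np.random.default_rng(5)
    y, X, _, clusters = _instance(rng, n=150, n_groups=1)
    groups = np.zeros(150, dtype=int)
    fit = _fit(y, X, groups, clusters)
    ols = sm.OLS(y - y.mean(), X - X.mean(axis=0)).fit()
    np.testing.assert_allclose(fit.params.to_numpy(), ols.params, rtol=1e-8)


def test_outcome_level_shift_absorbed():
    rng = np.random.default_rng(9)
    y, X, groups, clusters = _instance(rng)
    fit1 = _fit(y, X, groups, clusters)
    fit2 = _fit(y + 100.0, X, groups, clusters)
    np.testing.assert_allclose(fit1.params.to_numpy(), fit2.params.to_numpy(),
                               rtol=1e-8, atol=1e-10)


def test_cluster_ses_near_classical_under_iid_errors():
    rng = np.random.default_rng(21)
    n, k = 4000, 3
    X = rng.normal(size=(n, k))
    y = X @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=n)
    groups = rng.integers(0, 4, n)
    clusters = rng.integers(0, 400, n)  # many clusters, no within correlation
    fit = _fit(y, X, groups, clusters)
    D = pd.get_dummies(groups, dtype=float).to_numpy()
    classical = sm.OLS(y, np.column_stack([X, D])).fit().bse[:k]
    assert np.all(np.abs(fit.se.to_numpy() / classical - 1) < 0.15)


# ---------------------------------------------------------------------------
# design construction and battery on the simulated study

def test_build_design_reference_coding(study):
    f = study["frame"]
    sub = f[f["full_estimation"]]
    y, X, fe, cl = build_design(sub, ModelSpec("preterm", ("high_total",)))
    age_cols = [c for c in X.columns if c.startswith("mother_age_")]
    assert len(age_cols) == 4      # 5 levels incl. missing -> 4 dummies
    month_cols = [c for c in X.columns if c.startswith("month_")]
    assert len(month_cols) == 11
    assert fe.max() + 1 == sub.groupby(["township_id", "year"]).ngroups
    assert cl.max() + 1 == sub["zipcode"].nunique()


def test_build_design_two_fe_structures_share_covariates(study):
    f = study["frame"]
    sub = f[f["focal"]]
    _, X1, fe1, _ = build_design(sub, ModelSpec("preterm", ("high_total",)))
    _, X2, fe2, _ = build_design(sub, ModelSpec("preterm", ("high_total",),
                                                fe="zipcode_year"))
    assert list(X1.columns) == list(X2.columns)
    assert fe1.max() != fe2.max() or not np.array_equal(fe1, fe2)


def test_constant_exposure_rejected(study):
    f = study["frame"].copy()
    f["flat"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        build_design(f[f["focal"]], ModelSpec("preterm", ("flat",)))


def test_exposure_constant_within_fe_groups_flagged(study):
    """An exposure varying only between Township-years is absorbed by the FE
    and must be reported as dropped, never silently estimated."""
    f = study["frame"]
    sub = f[f["full_estimation"]].copy()
    ty = sub["township_id"].astype(str) + ":" + sub["year"].astype(str)
    sub["ty_level"] = ty.map(ty.value_counts()).astype(float)  # constant within group
    with pytest.warns(UserWarning, match="collinear"):
        fit = fit_model(sub, ModelSpec("preterm", ("high_total", "ty_level")))
    assert "ty_level" in fit.dropped_collinear
    assert "high_total" in fit.params.index


def test_empty_sample_rejected(study):
    f = study["frame"]
    with pytest.raises(ValueError, match="empty"):
        build_design(f[0:0], ModelSpec("preterm", ("high_total",)))


def test_lpm_reports_out_of_unit_fitted_values(study):
    f = study["frame"]
    fit = fit_model(f[f["full_estimation"]], ModelSpec("preterm", ("high_total",)))
    assert fit.n_fitted_outside_unit is not None
    assert 0 <= fit.n_fitted_outside_unit < fit.n_obs


def test_battery_structure_and_robustness_counts(study):
    f = study["frame"]
    t2 = run_model_battery(f, table2_specs())
    per_panel = t2.groupby("sample").size()
    assert (per_panel == 30).all()          # 5 outcomes x (1 + 2 + 3) terms
    full = run_model_battery(f, full_battery())
    assert len(full) >= 100
    placebo = full[full["model_id"].str.contains("trimester04")]
    assert placebo.groupby("outcome").size().eq(5).all()  # tri1-3 + tri0 + tri4


def test_battery_survives_per_model_failure(study):
    f = study["frame"].copy()
    specs = [ModelSpec("preterm", ("no_such_column",), model_id="bad"),
             ModelSpec("preterm", ("high_total",), model_id="good")]
    out = run_model_battery(f, specs)
    assert (out.loc[out["model_id"] == "bad", "status"].str.startswith("error")).all()
    assert (out.loc[out["model_id"] == "good", "status"] == "ok").all()


def test_log_outcome_percent_first_order_consistency(study):
    f = study["frame"]
    fit = fit_model(f[f["focal"]], ModelSpec("log_bw", ("high_total",)))
    th = fit.params["high_total"]
    assert abs(100 * th - 100 * (np.exp(th) - 1)) < 0.05  # small-theta agreement
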