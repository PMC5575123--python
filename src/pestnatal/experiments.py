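"""End-to-end study builds and Monte Carlo experiments.

These routines wire the generator, exposure, cohort and estimation stages
together for the validation studies the package ships with: parameter
recovery of an injected preterm effect, the post-birth ("4th trimester")
placebo, oracle-equivalence checks of the within-FE estimator and CR1
sandwich against explicit-dummy OLS, and generator calibration summaries.

Replicate sizes follow the package's validation design: 10 000 births over
two years on a 3x3-Township grid per replicate, 200 replicates for the
recovery and placebo studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import build_samples
from .exposure import attach_exposures, binarize_exposures
from .panelfe import ModelSpec, fit_model, full_battery, run_model_battery, table2_specs
from .synth import GridSpec, SimConfig, build_panel, generate_applications, generate_births

__all__ = [
    "build_study_frame",
    "recovery_experiment",
    "placebo_experiment",
    "fe_oracle_check",
    "generator_calibration",
    "battery_counts",
    "REPLICATE_GRID",
    "replicate_config",
]

REPLICATE_GRID = GridSpec(3, 3)


def replicate_config(seed: int, true_effects: dict | None = None,
                     n_births: int = 10_000) -> SimConfig:
    """Per-replicate study conditions: two birth years, 10 000 births."""
    return SimConfig(seed=seed, years=(2000, 2001), n_births_per_year=n_births // 2,
                     true_effects=true_effects or {}, missing_tobacco_year=None)


def build_study_frame(grid: GridSpec, cfg: SimConfig,
                      require_pesticides_every_year: bool = False,
                      buffer_m: float = 200.0):
    """Simulate, expose, filter and binarize: the analysis-ready frame.

    Returns ``(frame, cutoffs, log, applications)`` where ``frame`` holds the
    all-births rows with exposure columns, high-exposure indicators and one
    boolean membership column per sample label.
    """
    apps = generate_applications(grid, cfg)
    panel = build_panel(apps, grid, cfg)
    births = generate_births(grid, cfg, panel)
    if len(births) == 0:
        raise ValueError("empty sample: the generator produced no births")
    births = pd.concat([births, attach_exposures(births, panel)], axis=1)

    dropped = (cfg.missing_tobacco_year
               if cfg.missing_tobacco_year is not None
               and cfg.years[0] <= cfg.missing_tobacco_year <= cfg.years[1] else None)
    frame, log = build_samples(births, apps, grid, dropped_year=dropped,
                               buffer_m=buffer_m,
                               require_pesticides_every_year=require_pesticides_every_year)
    high, cutoffs = binarize_exposures(frame, reference_mask=frame["all_births"])
    frame = pd.concat([frame, high], axis=1)
    return frame, cutoffs, log, apps


def _fit_replicate(seed: int, true_effects: dict, spec_terms: tuple[str, ...],
                   outcome: str = "preterm", sample: str = "full_estimation"):
    cfg = replicate_config(seed, true_effects)
    frame, _, _, _ = build_study_frame(REPLICATE_GRID, cfg)
    spec = ModelSpec(outcome=outcome, exposure_terms=spec_terms, sample=sample)
    return fit_model(frame[frame[sample]], spec)


def recovery_experiment(n_reps: int = 200, base_seed: int = 1,
                        effect: float = 0.0075) -> pd.DataFrame:
    """Recover an injected preterm effect on the gestational high-exposure
    indicator across replicates.

    Returns one row per replicate with the estimate, CR1 standard error and
    whether the t(G-1) 95% confidence interval covers the truth.
    """
    rows = []
    for r in range(n_reps):
        fit = _fit_replicate(base_seed * 100_000 + r, {"preterm": effect},
                             ("high_total",))
        th, se = fit.params["high_total"], fit.se["high_total"]
        crit = stats.t.ppf(0.975, fit.df_t)
        rows.append({"theta": th, "se": se,
                     "covered": abs(th - effect) <= crit * se})
    out = pd.DataFrame(rows)
    out.attrs["true_effect"] = effect
    return out


def recovery_summary(reps: pd.DataFrame) -> dict[str, float]:
    effect = reps.attrs.get("true_effect", 0.0)
    mc_se = reps["theta"].std(ddof=1) / np.sqrt(len(reps))
    return {
        "true_effect": effect,
        "mean_theta": float(reps["theta"].mean()),
        "bias": float(reps["theta"].mean() - effect),
        "mc_se": float(mc_se),
        "coverage": float(reps["covered"].mean()),
        "n_reps": int(len(reps)),
    }


def placebo_experiment(n_reps: int = 200, base_seed: int = 2,
                       effect: float = 0.0075, alpha: float = 0.05) -> pd.DataFrame:
    """Post-birth placebo under a DGP where only gestational exposure matters.

    The preterm effect is injected on the gestational-total indicator; the
    fitted model is the trimester 0-4 battery row, and the quantity of
    interest is how often the trimester-4 (post-birth) coefficient rejects.
    """
    terms = ("high_tri1", "high_tri2", "high_tri3", "high_tri0", "high_tri4")
    rows = []
    for r in range(n_reps):
        fit = _fit_replicate(base_seed * 100_000 + r, {"preterm": effect}, terms)
        rows.append({"coef_tri4": fit.params.get("high_tri4", np.nan),
                     "p_tri4": fit.pvalues.get("high_tri4", np.nan),
                     "reject": bool(fit.pvalues.get("high_tri4", 1.0) < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# oracle equivalence on small random instances

def _random_instance(rng: np.random.Generator):
    n = int(rng.integers(120, 501))
    n_groups = int(rng.integers(3, 9))
    n_clusters = int(rng.integers(8, 25))
    k = int(rng.integers(2, 6))
    X = rng.normal(size=(n, k))
    groups = rng.integers(0, n_groups, n)
    clusters = rng.integers(0, n_clusters, n)
    beta = rng.normal(size=k)
    y = X @ beta + rng.normal(size=n_groups)[groups] + rng.normal(size=n) \
        + 0.5 * rng.normal(size=n_clusters)[clusters]
    return y, X, groups, clusters


def fe_oracle_check(n_instances: int = 20, seed: int = 3) -> dict[str, float]:
    """Within-FE estimator vs explicit-dummy OLS, and CR1 vs a brute-force
    loop over clusters, on random small instances.

    The oracle fits OLS with one dummy per FE group (statsmodels) and forms
    the CR1 sandwich by looping over clusters on the full dummy design.
    Returns the worst absolute coefficient deviation and worst relative SE
    deviation across instances.
    """
    import statsmodels.api as sm

    from .panelfe import _demean, cluster_se  # the implementation under test

    rng = np.random.default_rng(seed)
    worst_coef, worst_se = 0.0, 0.0
    for _ in range(n_instances):
        y, X, groups, clusters = _random_instance(rng)
        n, k = X.shape
        n_groups = groups.max() + 1

        # implementation path
        Xd = _demean(X, groups, n_groups)
        yd = _demean(y, groups, n_groups)
        beta_w, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        resid = yd - Xd @ beta_w
        se_w, G = cluster_se(Xd, resid, clusters, k + n_groups)

        # oracle: explicit dummies, no intercept
        D = np.zeros((n, n_groups))
        D[np.arange(n), groups] = 1.0
        Z = np.column_stack([X, D])
        ols = sm.OLS(y, Z).fit()
        beta_o = ols.params[:k]
        e = y - Z @ ols.params
        meat = np.zeros((Z.shape[1], Z.shape[1]))
        for g in range(clusters.max() + 1):
            s = Z[clusters == g].T @ e[clusters == g]
            meat += np.outer(s, s)
        bread = np.linalg.pinv(Z.T @ Z)
        c = (G / (G - 1.0)) * ((n - 1.0) / (n - Z.shape[1]))
        se_o = np.sqrt(np.diag(c * bread @ meat @ bread))[:k]

        worst_coef = max(worst_coef, float(np.max(np.abs(beta_w - beta_o))))
        worst_se = max(worst_se, float(np.max(np.abs(se_w - se_o) / se_o)))
    return {"max_abs_coef_dev": worst_coef, "max_rel_se_dev": worst_se,
            "n_instances": n_instances}


def generator_calibration(seed: int = 0, n_births: int = 10_000) -> dict[str, float]:
    """Distributional facts of the default generator at a fixed seed batch."""
    cfg = replicate_config(seed, n_births=n_births)
    frame, cutoffs, log, _ = build_study_frame(REPLICATE_GRID, cfg)
    tot = frame.loc[frame["all_births"], "total_kg"].to_numpy()
    q75, q95, q99 = np.quantile(tot, [0.75, 0.95, 0.99], method="inverted_cdf")
    full = frame[frame["full_estimation"]]
    return {
        "zero_exposure_fraction": float((tot == 0).mean()),
        "mean_kg": float(tot.mean()),
        "q75_kg": float(q75), "q95_kg": float(q95), "q99_kg": float(q99),
        "q99_over_q75": float(q99 / q75) if q75 > 0 else float("inf"),
        "focal_fraction": log["n"]["focal"] / max(log["n"]["full_estimation"], 1),
        "rate_low_bw": float(full["low_bw"].mean()),
        "rate_preterm": float(full["preterm"].mean()),
        "rate_abnormality": float(full["abnormality"].mean()),
    }


def battery_counts(seed: int = 5) -> dict[str, int]:
    """Coefficient accounting of the full model battery on one simulated
    study: exposure coefficients per headline panel and in total."""
    cfg = replicate_config(seed)
    frame, _, _, _ = build_study_frame(REPLICATE_GRID, cfg)
    t2 = run_model_battery(frame, table2_specs())
    full = run_model_battery(frame, full_battery())
    per_panel = t2.groupby("sample").size().to_dict()
    return {
        "per_panel_full_estimation": int(per_panel.get("full_estimation", 0)),
        "per_panel_focal": int(per_panel.get("focal", 0)),
        "total_coefficients": int(len(full)),
        "total_ok": int((full["status"] == "ok").sum()),
    }
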