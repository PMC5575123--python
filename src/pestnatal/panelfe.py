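"""Two-way fixed-effects estimation with cluster-robust standard errors.

The estimating equation regresses a birth outcome B on exposure terms AI,
individual covariate dummies X, Township-by-year fixed effects and
birth-month fixed effects:

    B = delta0 + AI * theta + X * beta + alpha_ty + gamma_m + eps

The Township-year effects are absorbed by within-group demeaning (the
Frisch-Waugh partialling that makes the demeaned OLS coefficients equal the
explicit-dummy OLS coefficients); month and covariate dummies are few and
kept explicit.  Standard errors are the CR1 cluster sandwich

    V = c * (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1,
    c = G/(G-1) * (N-1)/(N-K),

with K counting the absorbed group effects, clustered at the zipcode by
default.  p-values use a t distribution with G-1 degrees of freedom (a
conservative convention).  Collinear columns are dropped deterministically
in column order and reported, never silently.

Linear probability model fits are not clipped; the count of fitted values
outside [0, 1] is reported as a diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "build_design",
    "fit_within",
    "cluster_se",
    "fit_model",
    "run_model_battery",
    "table2_specs",
    "robustness_specs",
    "full_battery",
    "OUTCOMES",
    "COVARIATE_LEVELS",
]

OUTCOMES = ("log_bw", "low_bw", "log_gest", "preterm", "abnormality")

#: categorical covariates with the reference level first
COVARIATE_LEVELS = {
    "mother_age": ("25_35", "lt19", "19_24", "36plus", "missing"),
    "education": ("hs", "lt_hs", "some_college", "college_plus", "missing"),
    "race_ethnicity": ("nh_white", "nh_black", "hispanic", "missing"),
    "tobacco": ("no", "yes", "missing"),
    "prenatal_visits": ("9_14", "lt5", "5_8", "15plus", "missing"),
    "infant_sex": ("M", "F", "missing"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One regression in the battery."""

    outcome: str
    exposure_terms: tuple[str, ...]
    sample: str = "full_estimation"
    fe: str = "township_year"          # or "zipcode_year"
    cluster: str = "zipcode"           # or "township"
    covariates: tuple[str, ...] = tuple(COVARIATE_LEVELS)
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.exposure_terms:
            raise ValueError("exposure_terms must be nonempty")
        if self.fe not in ("township_year", "zipcode_year"):
            raise ValueError(f"unknown fe structure {self.fe!r}")
        if self.cluster not in ("zipcode", "township"):
            raise ValueError(f"unknown cluster variable {self.cluster!r}")


@dataclass
class FitResult:
    """Coefficients, CR1 standard errors and fit diagnostics."""

    params: pd.Series
    se: pd.Series
    tstats: pd.Series
    pvalues: pd.Series
    resid: np.ndarray
    n_obs: int
    n_fe_groups: int
    n_clusters: int
    k_params: int                      # identified params incl. absorbed FE
    r_squared: float
    dropped_collinear: list[str] = field(default_factory=list)
    n_fitted_outside_unit: int | None = None   # LPM diagnostic

    @property
    def df_t(self) -> int:
        return self.n_clusters - 1


def _outcome_values(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome == "log_bw":
        return np.log(df["birth_weight_g"].to_numpy(float))
    if outcome == "log_gest":
        return np.log(df["gestation_days"].to_numpy(float))
    return df[outcome].to_numpy(float)


def build_design(records: pd.DataFrame, spec: ModelSpec,
                 ) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    """Outcome vector, explicit design matrix, FE group codes, cluster codes.

    The design holds the exposure terms, reference-coded covariate dummies
    and 11 birth-month dummies; the FE groups (Township-year or
    zipcode-year) are returned as integer codes for absorption.  Exposure
    terms constant within every FE group are not identified; they are
    reported here and dropped during fitting.
    """
    if len(records) == 0:
        raise ValueError("empty sample: no observations to fit")
    y = _outcome_values(records, spec.outcome)
    if np.isnan(y).any():
        raise ValueError(f"outcome {spec.outcome} contains missing values")

    X = pd.DataFrame(index=records.index)
    for term in spec.exposure_terms:
        if term not in records:
            raise ValueError(f"exposure term {term!r} missing from records")
        v = records[term].to_numpy(float)
        if np.ptp(v) == 0:
            raise ValueError(f"exposure term {term!r} is constant in this sample")
        X[term] = v

    for cov in spec.covariates:
        levels = COVARIATE_LEVELS[cov]
        cat = pd.Categorical(records[cov], categories=levels)
        d = pd.get_dummies(cat, prefix=cov, drop_first=True, dtype=float)
        X = pd.concat([X, d.set_axis(records.index)], axis=1)
    X["first_born"] = records["first_born"].to_numpy(float)

    mon = pd.Categorical(records["month"], categories=range(1, 13))
    X = pd.concat([X, pd.get_dummies(mon, prefix="month", drop_first=True,
                                     dtype=float).set_axis(records.index)], axis=1)

    fe_key = (records["township_id"] if spec.fe == "township_year"
              else records["zipcode"]).astype(str) + ":" + records["year"].astype(str)
    fe_codes = pd.factorize(fe_key)[0]
    cl_codes = pd.factorize(records["zipcode" if spec.cluster == "zipcode"
                                    else "township_id"])[0]
    return y, X, fe_codes, cl_codes


def _demean(a: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if a.ndim == 1:
        means = np.bincount(codes, weights=a, minlength=n_groups) / counts
        return a - means[codes]
    out = np.empty_like(a)
    for j in range(a.shape[1]):
        means = np.bincount(codes, weights=a[:, j], minlength=n_groups) / counts
        out[:, j] = a[:, j] - means[codes]
    return out


def _select_independent(Xd: np.ndarray, names: list[str], tol: float = 1e-8,
                        ) -> tuple[list[int], list[str]]:
    """Greedy Gram-Schmidt column selection, keeping earlier columns."""
    kept: list[int] = []
    dropped: list[str] = []
    Q = np.empty((Xd.shape[0], 0))
    for j in range(Xd.shape[1]):
        col = Xd[:, j]
        norm0 = np.linalg.norm(col)
        if norm0 == 0:
            dropped.append(names[j])
            continue
        r = col - Q @ (Q.T @ col)
        # re-orthogonalize once for numerical safety
        r = r - Q @ (Q.T @ r)
        if np.linalg.norm(r) <= tol * norm0:
            dropped.append(names[j])
            continue
        kept.append(j)
        Q = np.column_stack([Q, r / np.linalg.norm(r)])
    return kept, dropped


def fit_within(y: np.ndarray, X: pd.DataFrame, fe_codes: np.ndarray,
               cluster_codes: np.ndarray, lpm: bool = False) -> FitResult:
    """Absorb the FE groups by demeaning and fit OLS on the residualized data.

    Coefficients equal the explicit-dummy OLS fit; the degrees of freedom
    account for the absorbed group effects.
    """
    n = y.shape[0]
    n_groups = int(fe_codes.max()) + 1
    names = list(X.columns)
    Xd = _demean(X.to_numpy(float), fe_codes, n_groups)
    yd = _demean(y.astype(float), fe_codes, n_groups)

    kept, dropped = _select_independent(Xd, names)
    if dropped:
        warnings.warn(f"dropped collinear columns: {dropped}", stacklevel=2)
    Xk = Xd[:, kept]
    k_explicit = Xk.shape[1]
    k_total = k_explicit + n_groups
    if n <= k_total:
        raise ValueError(f"n_obs={n} insufficient for {k_total} identified parameters")

    beta, *_ = np.linalg.lstsq(Xk, yd, rcond=None)
    resid = yd - Xk @ beta

    se, n_clusters = cluster_se(Xk, resid, cluster_codes, k_total)
    tvals = beta / se
    df_t = n_clusters - 1
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_t)

    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else np.nan

    kept_names = [names[j] for j in kept]
    outside = None
    if lpm:
        fitted = y - resid
        outside = int(((fitted < 0) | (fitted > 1)).sum())
    return FitResult(
        params=pd.Series(beta, index=kept_names),
        se=pd.Series(se, index=kept_names),
        tstats=pd.Series(tvals, index=kept_names),
        pvalues=pd.Series(pvals, index=kept_names),
        resid=resid, n_obs=n, n_fe_groups=n_groups, n_clusters=n_clusters,
        k_params=k_total, r_squared=r2, dropped_collinear=dropped,
        n_fitted_outside_unit=outside,
    )


def cluster_se(X: np.ndarray, resid: np.ndarray, cluster_codes: np.ndarray,
               k_params: int) -> tuple[np.ndarray, int]:
    """CR1 cluster-robust standard errors.

    meat = sum_g (X_g' e_g)(X_g' e_g)', scaled by G/(G-1) * (N-1)/(N-K).
    With every observation its own cluster this reduces to HC1.  Raises with
    fewer than two clusters.
    """
    n, k = X.shape
    codes = np.asarray(cluster_codes)
    G = int(codes.max()) + 1
    if G < 2:
        raise ValueError("cluster-robust errors require at least 2 clusters")
    scores = np.zeros((G, k))
    Xe = X * resid[:, None]
    for j in range(k):
        scores[:, j] = np.bincount(codes, weights=Xe[:, j], minlength=G)
    meat = scores.T @ scores
    bread = np.linalg.pinv(X.T @ X)
    c = (G / (G - 1.0)) * ((n - 1.0) / (n - k_params))
    V = c * bread @ meat @ bread
    return np.sqrt(np.clip(np.diag(V), 0.0, None)), G


def fit_model(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Build the design for ``spec`` and fit it."""
    y, X, fe_codes, cl_codes = build_design(records, spec)
    lpm = spec.outcome in ("low_bw", "preterm", "abnormality")
    return fit_within(y, X, fe_codes, cl_codes, lpm=lpm)


# ---------------------------------------------------------------------------
# model batteries

_EXPOSURE_SETS = {
    "sum_ai": ("high_total",),
    "toxicity": ("high_tox12", "high_tox34"),
    "trimester": ("high_tri1", "high_tri2", "high_tri3"),
}
_ROBUSTNESS_SETS = {
    "method": ("high_aerial", "high_ground"),
    "trimester04": ("high_tri1", "high_tri2", "high_tri3", "high_tri0", "high_tri4"),
}


def table2_specs(samples=("full_estimation", "focal")) -> list[ModelSpec]:
    """The headline battery: 3 exposure parameterizations x 5 outcomes per
    sample panel (30 exposure coefficients per panel)."""
    specs = []
    for sample in samples:
        for pname, terms in _EXPOSURE_SETS.items():
            for outcome in OUTCOMES:
                specs.append(ModelSpec(outcome=outcome, exposure_terms=terms,
                                       sample=sample,
                                       model_id=f"{sample}:{pname}:{outcome}"))
    return specs


def robustness_specs() -> list[ModelSpec]:
    """Robustness battery on the focal sample: aerial/ground split,
    pre-conception and post-birth placebo trimesters, and the interior-buffer
    re-estimation of the headline parameterizations."""
    specs = []
    for pname, terms in _ROBUSTNESS_SETS.items():
        for outcome in OUTCOMES:
            specs.append(ModelSpec(outcome=outcome, exposure_terms=terms,
                                   sample="focal",
                                   model_id=f"focal:{pname}:{outcome}"))
    specs.extend(table2_specs(samples=("interior_buffer",)))
    return specs


def full_battery() -> list[ModelSpec]:
    return table2_specs() + robustness_specs()


def run_model_battery(records: pd.DataFrame, specs: list[ModelSpec],
                      ) -> pd.DataFrame:
    """Fit every spec; one row per exposure term.

    ``records`` must carry the sample membership columns and the binary
    exposure indicators.  Per-model failures are recorded (status column)
    and the battery continues.
    """
    rows = []
    for spec in specs:
        sub = records[records[spec.sample]] if spec.sample in records else records
        try:
            fit = fit_model(sub, spec)
            for term in spec.exposure_terms:
                if term in fit.params.index:
                    rows.append({
                        "model_id": spec.model_id, "outcome": spec.outcome,
                        "term": term, "coef": fit.params[term], "se": fit.se[term],
                        "p": fit.pvalues[term], "n": fit.n_obs,
                        "n_clusters": fit.n_clusters, "r2": fit.r_squared,
                        "sample": spec.sample, "fe": spec.fe,
                        "cluster": spec.cluster, "status": "ok",
                    })
                else:
                    rows.append({"model_id": spec.model_id, "outcome": spec.outcome,
                                 "term": term, "coef": np.nan, "se": np.nan,
                                 "p": np.nan, "n": fit.n_obs,
                                 "n_clusters": fit.n_clusters, "r2": fit.r_squared,
                                 "sample": spec.sample, "fe": spec.fe,
                                 "cluster": spec.cluster, "status": "dropped_collinear"})
        except Exception as exc:  # per-model failure, battery continues
            for term in spec.exposure_terms:
                rows.append({"model_id": spec.model_id, "outcome": spec.outcome,
                             "term": term, "coef": np.nan, "se": np.nan, "p": np.nan,
                             "n": 0, "n_clusters": 0, "r2": np.nan,
                             "sample": spec.sample, "fe": spec.fe,
                             "cluster": spec.cluster, "status": f"error: {exc}"})
    return pd.DataFrame(rows)
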