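"""Post-estimation interpretation: percent/unit conversions, Bonferroni
thresholds, significance tabulation.

A linear-probability coefficient theta on a binary outcome with sample rate
r converts to a percent change of 100*theta/r.  A coefficient on a log
outcome converts to a percent change of 100*theta (first-order; the exact
100*(e^theta - 1) is available) and to physical units via the sample mean:
theta * mean * unit_scale (unit_scale 24 turns days into hours).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "pct_change_binary",
    "pct_change_log",
    "unit_change_continuous",
    "bonferroni_alpha",
    "summarize_effects",
]


def pct_change_binary(coef: float, outcome_rate: float) -> float:
    """Percent change implied by an LPM coefficient, relative to the sample
    rate of the outcome: 100 * coef / rate."""
    if not (0.0 < outcome_rate < 1.0):
        raise ValueError(f"outcome rate must be in (0, 1), got {outcome_rate!r}")
    return 100.0 * coef / outcome_rate


def pct_change_log(coef: float, exact: bool = False) -> float:
    """Percent change for a log-outcome coefficient: 100*theta, or the exact
    100*(e^theta - 1)."""
    return 100.0 * (np.expm1(coef) if exact else coef)


def unit_change_continuous(coef_log_outcome: float, sample_mean: float,
                           unit_scale: float = 1.0) -> float:
    """Physical-unit change implied by a log-outcome coefficient.

    coef * mean * unit_scale; e.g. a log-gestation coefficient with the mean
    in days and unit_scale=24 gives hours.
    """
    if sample_mean <= 0:
        raise ValueError(f"sample mean must be positive, got {sample_mean!r}")
    return coef_log_outcome * sample_mean * unit_scale


def bonferroni_alpha(alpha: float, n_outcomes: int, n_exposure_terms: int) -> float:
    """Family-wise corrected significance level: alpha / (outcomes * terms)."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha!r}")
    if n_outcomes <= 0 or n_exposure_terms <= 0:
        raise ValueError("comparison counts must be positive")
    return alpha / (n_outcomes * n_exposure_terms)


_BINARY = {"low_bw", "preterm", "abnormality"}
_UNIT_SCALE = {"log_bw": 1.0, "log_gest": 24.0}  # grams; days -> hours


def summarize_effects(results: pd.DataFrame, rates: dict[str, float],
                      means: dict[str, float], alpha: float = 0.05,
                      n_comparisons: int = 25) -> pd.DataFrame:
    """Join battery results with sample rates/means into an effects table.

    ``rates``: outcome -> sample rate for binary outcomes; ``means``:
    outcome -> sample mean of the underlying quantity (grams for log_bw,
    days for log_gest).  Adds percent change, unit change where applicable,
    significance stars at 0.05/0.01 and a Bonferroni flag at
    alpha/n_comparisons.
    """
    a_bonf = alpha / n_comparisons
    out = results.copy()
    pct, unit = [], []
    for _, r in out.iterrows():
        if pd.isna(r["coef"]):
            pct.append(np.nan)
            unit.append(np.nan)
        elif r["outcome"] in _BINARY:
            pct.append(pct_change_binary(r["coef"], rates[r["outcome"]]))
            unit.append(np.nan)
        else:
            pct.append(pct_change_log(r["coef"]))
            unit.append(unit_change_continuous(r["coef"], means[r["outcome"]],
                                               _UNIT_SCALE[r["outcome"]]))
    out["pct_change"] = np.round(pct, 1)
    out["unit_change"] = np.round(unit, 0)
    out["stars"] = ["**" if p < 0.01 else "*" if p < alpha else ""
                    for p in out["p"].fillna(1.0)]
    out["bonferroni_significant"] = out["p"].fillna(1.0) < a_bonf
    out.attrs["alpha_nominal"] = alpha
    out.attrs["alpha_bonferroni"] = a_bonf
    return out
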