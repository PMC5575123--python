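"""Study-sample construction: base restrictions, year drop, focal sample,
interior-buffer subsample.

All printed inequalities are applied exactly as stated: gestation kept when
182 d (26 weeks) <= gestation <= 350 d (50 weeks), birth weight kept when
250 g <= weight <= 5500 g (so 250 g exactly is retained), total births to the
same mother kept when <= 15, and geocoding match scores kept only when
strictly greater than 85.  Missing covariates are explicit category levels
and never cause a row to be dropped; missing outcomes do.

Sample nesting: interior_buffer <= focal <= full_estimation <= all_births.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synth import GridSpec

__all__ = [
    "apply_base_restrictions",
    "drop_year",
    "focal_sample",
    "interior_buffer",
    "build_samples",
    "SAMPLE_LABELS",
]

SAMPLE_LABELS = ("all_births", "full_estimation", "focal", "interior_buffer")

MIN_GESTATION_D = 26 * 7   # < 26 weeks excluded
MAX_GESTATION_D = 50 * 7   # > 50 weeks excluded
MIN_WEIGHT_G = 250         # < 250 g excluded (250 exactly retained)
MAX_WEIGHT_G = 5500        # > 5500 g excluded
MAX_TOTAL_BIRTHS = 15      # > 15 excluded
MIN_MATCH_SCORE = 85       # kept only when strictly > 85


def apply_base_restrictions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the base sample restrictions in order, tallying exclusions.

    Order: gestational-age rule, then birth-weight / parity rule, then
    geocoding match-score rule.  Returns the retained records and a per-rule
    exclusion count; counts sum to input minus output.
    """
    tally: dict[str, int] = {}
    df = records

    g = df["gestation_days"]
    keep = g.notna() & (g >= MIN_GESTATION_D) & (g <= MAX_GESTATION_D)
    tally["gestation_out_of_range_or_missing"] = int((~keep).sum())
    df = df[keep]

    w = df["birth_weight_g"]
    keep = (w.notna() & (w >= MIN_WEIGHT_G) & (w <= MAX_WEIGHT_G)
            & (df["total_births_to_mother"] <= MAX_TOTAL_BIRTHS))
    tally["weight_out_of_range_or_parity"] = int((~keep).sum())
    df = df[keep]

    keep = df["match_score"] > MIN_MATCH_SCORE
    tally["match_score_le_85"] = int((~keep).sum())
    df = df[keep]

    if len(df) == 0:
        warnings.warn("base restrictions removed every record", stacklevel=2)
    return df, tally


def drop_year(records: pd.DataFrame, year: int) -> pd.DataFrame:
    """Drop an entire birth year (e.g. a year with no tobacco field)."""
    return records[records["year"] != year]


def focal_sample(records: pd.DataFrame, applications: pd.DataFrame,
                 years=None, require_pesticides_every_year: bool = False) -> pd.DataFrame:
    """Births in Sections with pesticides and with births in every study year.

    A Section qualifies when it has at least one mass-reporting application
    (in every study year when ``require_pesticides_every_year``, the stricter
    reading; otherwise in any year) and at least one birth in every study
    year.  ``years`` defaults to the years present in ``records``.
    """
    years = sorted(set(records["year"])) if years is None else sorted(years)
    if not years or len(records) == 0:
        warnings.warn("focal sample requested on an empty cohort", stacklevel=2)
        return records.iloc[0:0]

    apps = applications[applications["kg_ai"] > 0]
    if require_pesticides_every_year:
        app_years = pd.to_datetime(apps["date"]).dt.year
        per_sec = apps.groupby("section_id").apply(
            lambda s: set(app_years.loc[s.index]), include_groups=False)
        pest_secs = {s for s, ys in per_sec.items() if set(years) <= ys}
    else:
        pest_secs = set(apps["section_id"])

    birth_years = records.groupby("section_id")["year"].agg(lambda s: len(set(s)))
    full_secs = set(birth_years.index[birth_years == len(years)])

    keep_secs = pest_secs & full_secs
    if not keep_secs:
        warnings.warn("no Section qualifies for the focal sample", stacklevel=2)
    return records[records["section_id"].isin(keep_secs)]


def interior_buffer(records: pd.DataFrame, grid: GridSpec,
                    buffer_m: float = 200.0) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep births at least ``buffer_m`` from the nearest Section boundary.

    Distance to the boundary of the square Section is the Chebyshev distance
    to the nearest edge.  A 200 m buffer on a 1609.344 m Section removes
    about 43.5% of the Section's area.  Records with missing coordinates are
    excluded and tallied.
    """
    side = grid.section_side_m
    x, y = records["x_m"], records["y_m"]
    has_xy = x.notna() & y.notna()
    dx = np.minimum(x % side, side - x % side)
    dy = np.minimum(y % side, side - y % side)
    keep = has_xy & (np.minimum(dx, dy) >= buffer_m)
    tally = {"missing_coordinates": int((~has_xy).sum()),
             "within_buffer": int((has_xy & ~keep).sum())}
    return records[keep], tally


def build_samples(records: pd.DataFrame, applications: pd.DataFrame, grid: GridSpec,
                  dropped_year: int | None = 2006, buffer_m: float = 200.0,
                  require_pesticides_every_year: bool = False,
                  ) -> tuple[pd.DataFrame, dict]:
    """Attach one boolean membership column per sample label.

    ``all_births``: base restrictions only (the reference sample for exposure
    cutoffs).  ``full_estimation``: all_births minus the dropped year.
    ``focal``: Sections with pesticides and births in every estimation year.
    ``interior_buffer``: focal births at least ``buffer_m`` inside their
    Section.  Returns the all_births records with membership columns plus a
    log of exclusion tallies.
    """
    base, tally = apply_base_restrictions(records)
    out = base.copy()
    out["all_births"] = True

    full = drop_year(base, dropped_year) if dropped_year is not None else base
    out["full_estimation"] = out["birth_id"].isin(full["birth_id"])

    years = sorted(set(full["year"]))
    focal = focal_sample(full, applications, years=years,
                         require_pesticides_every_year=require_pesticides_every_year)
    out["focal"] = out["birth_id"].isin(focal["birth_id"])

    interior, buf_tally = interior_buffer(focal, grid, buffer_m)
    out["interior_buffer"] = out["birth_id"].isin(interior["birth_id"])

    log = {"base_restrictions": tally,
           "dropped_year": dropped_year,
           "interior_buffer": buf_tally,
           "n": {lbl: int(out[lbl].sum()) for lbl in SAMPLE_LABELS}}
    return out, log
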