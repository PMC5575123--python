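"""Synthetic PLS grid, pesticide-application panel, and birth cohort.

The generator emulates the data structure of a Central-Valley-style birth
cohort linked to pesticide use reports: a rectangular grid of ~1 mi^2 PLS
Sections nested 36-to-a-Township, a zero-inflated and heavily right-skewed
Section-month application process, and births with categorical maternal
covariates, Township-year and birth-month effects, and known injected
exposure effects, so every downstream stage (exposure windows, cohort
filters, fixed-effects estimation, placebo battery) is testable without the
restricted vital-statistics file.

Key emulated facts, frozen in the defaults: a majority of births with zero
gestational exposure, mean gestational exposure of roughly 750 kg of active
ingredients, and an extreme right tail (75th/95th/99th percentiles near
250 / 4200 / 11000 kg).  A minority of Sections are agricultural; births are
spread uniformly so about a third fall where pesticides are applied.

Binary outcomes follow a linear-probability data-generating process
(probabilities clipped to [0.001, 0.999]) so the estimand matches the
linear-probability estimator; gestation length and birth weight are drawn
conditionally on the binary flags so that preterm (<259 d) and low birth
weight (<2500 g) stay exactly consistent with the continuous values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import SectionMonthPanel, attach_exposures, ym_index

__all__ = [
    "GridSpec",
    "SimConfig",
    "generate_applications",
    "build_panel",
    "generate_births",
    "township_of",
]

_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

# categorical covariate tables (level, probability); probabilities emulate a
# Central-Valley birth cohort and always include an explicit "missing" level
_COVARIATE_TABLES = {
    "mother_age": (("lt19", 0.09), ("19_24", 0.34), ("25_35", 0.48),
                   ("36plus", 0.08), ("missing", 0.01)),
    "education": (("lt_hs", 0.33), ("hs", 0.31), ("some_college", 0.22),
                  ("college_plus", 0.11), ("missing", 0.03)),
    "race_ethnicity": (("hispanic", 0.58), ("nh_white", 0.29), ("nh_black", 0.04),
                       ("missing", 0.09)),
    "tobacco": (("no", 0.97), ("yes", 0.02), ("missing", 0.01)),
    "prenatal_visits": (("lt5", 0.03), ("5_8", 0.13), ("9_14", 0.59),
                        ("15plus", 0.21), ("missing", 0.04)),
    "infant_sex": (("M", 0.510), ("F", 0.485), ("missing", 0.005)),
}

# baseline adverse-outcome probabilities before covariate and regional shifts
_BASE_RATES = {"preterm": 0.092, "low_bw": 0.040, "abnormality": 0.052}

# small fractions of deliberately out-of-range or missing values so the
# cohort filters have work to do
_P_BAD_GESTATION = 0.003
_P_BAD_WEIGHT = 0.002
_P_MANY_BIRTHS = 0.0005


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid of PLS Townships, each a square block of Sections."""

    n_townships_x: int = 3
    n_townships_y: int = 3
    sections_per_township_side: int = 6
    section_side_m: float = 1609.344  # one mile

    def __post_init__(self) -> None:
        for name in ("n_townships_x", "n_townships_y", "sections_per_township_side"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.section_side_m <= 0:
            raise ValueError(f"section_side_m must be positive, got {self.section_side_m!r}")

    @property
    def n_cols(self) -> int:
        return self.n_townships_x * self.sections_per_township_side

    @property
    def n_rows(self) -> int:
        return self.n_townships_y * self.sections_per_township_side

    @property
    def n_sections(self) -> int:
        return self.n_cols * self.n_rows

    def section_ids(self) -> list[str]:
        """Section IDs in row-major order; the Township is embedded in the ID."""
        k = self.sections_per_township_side
        ids = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                i = (r % k) * k + (c % k)
                ids.append(f"T{c // k:02d}{r // k:02d}S{i:02d}")
        return ids


def township_of(section_id: str) -> str:
    """Recover the Township ID from a Section ID."""
    return section_id.split("S")[0]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.  Defaults are the calibrated study conditions."""

    seed: int = 0
    years: tuple[int, int] = (1997, 2011)
    n_births_per_year: int = 2000
    p_section_agricultural: float = 0.36
    p_zero_section_month: float = 0.45
    lognormal_mu: float = 5.0
    lognormal_sigma: float = 1.0
    section_intensity_sigma: float = 1.25
    seasonal_amplitude: float = 0.6
    frac_aerial: float = 0.40
    frac_high_tox: float = 0.33
    township_year_sd: float = 0.010
    month_effect_sd: float = 0.005
    confounding: float = 0.5
    true_effects: dict = field(default_factory=dict)
    covariate_effect_sizes: dict = field(default_factory=lambda: {
        "tobacco:yes": 0.030, "mother_age:lt19": 0.010, "mother_age:36plus": 0.010,
        "education:lt_hs": 0.008, "prenatal_visits:lt5": 0.020, "first_born": 0.003,
    })
    missing_tobacco_year: int | None = 2006

    def __post_init__(self) -> None:
        probs = ("p_section_agricultural", "p_zero_section_month", "frac_aerial",
                 "frac_high_tox")
        for name in probs:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("lognormal_sigma", "section_intensity_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not (0.0 <= self.seasonal_amplitude < 1.0):
            raise ValueError(
                f"seasonal_amplitude must be in [0, 1), got {self.seasonal_amplitude!r}")
        if not (0.0 <= self.confounding <= 1.0):
            raise ValueError(f"confounding must be in [0, 1], got {self.confounding!r}")
        if self.years[0] > self.years[1]:
            raise ValueError(f"years range is empty: {self.years!r}")
        if self.n_births_per_year < 0:
            raise ValueError(f"n_births_per_year must be >= 0, got {self.n_births_per_year!r}")
        for k, v in self.true_effects.items():
            if not np.isfinite(v):
                raise ValueError(f"true_effects[{k!r}] must be finite, got {v!r}")

    @property
    def app_years(self) -> tuple[int, int]:
        """Applications span one extra year on each side of the birth years,
        covering pre-conception and post-birth placebo windows."""
        return (self.years[0] - 1, self.years[1] + 1)


def _children(cfg: SimConfig) -> list[np.random.SeedSequence]:
    # fixed spawn order: sections, applications, births, zipcodes
    return np.random.SeedSequence(cfg.seed).spawn(4)


def _section_attributes(grid: GridSpec, cfg: SimConfig) -> pd.DataFrame:
    """Per-Section agricultural flag and latent intensity (shared across the
    application and birth generators through a dedicated seed stream)."""
    rng = np.random.default_rng(_children(cfg)[0])
    n = grid.n_sections
    # fixed agricultural share of land: exactly round(p * n) Sections are
    # agricultural, their placement random — keeps the exposed-birth share
    # stable across seeds the way a fixed landscape would
    is_ag = np.zeros(n, dtype=bool)
    is_ag[rng.permutation(n)[: round(cfg.p_section_agricultural * n)]] = True
    intensity = np.exp(rng.normal(0.0, cfg.section_intensity_sigma, n))
    return pd.DataFrame({"section_id": grid.section_ids(),
                         "is_ag": is_ag, "intensity": intensity})


def _seasonal_factor(month: np.ndarray, amplitude: float) -> np.ndarray:
    # multiplicative month effect peaking mid-summer
    return 1.0 + amplitude * np.cos(2 * np.pi * (month - 7) / 12.0)


def generate_applications(grid: GridSpec, cfg: SimConfig) -> pd.DataFrame:
    """Simulate the application-record table.

    Per agricultural Section-month the total applied mass is zero with
    probability ``p_zero_section_month`` and otherwise lognormal, scaled by
    the Section's latent intensity and a seasonal factor, then split into
    1-5 records with dates uniform within the month.  Deterministic given
    the config seed.
    """
    sec = _section_attributes(grid, cfg)
    rng = np.random.default_rng(_children(cfg)[1])
    y0, y1 = cfg.app_years
    months = np.arange(ym_index(y0, 1), ym_index(y1, 12) + 1)
    ag_idx = np.flatnonzero(sec["is_ag"].to_numpy())

    cells_sec = np.repeat(ag_idx, months.size)
    cells_mon = np.tile(months, ag_idx.size)
    active = rng.random(cells_sec.size) >= cfg.p_zero_section_month
    cells_sec, cells_mon = cells_sec[active], cells_mon[active]

    cal_month = cells_mon % 12 + 1
    totals = (sec["intensity"].to_numpy()[cells_sec]
              * _seasonal_factor(cal_month, cfg.seasonal_amplitude)
              * rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, cells_sec.size))

    n_rec = rng.integers(1, 6, cells_sec.size)
    cell_of_rec = np.repeat(np.arange(cells_sec.size), n_rec)
    w = rng.gamma(1.0, 1.0, cell_of_rec.size)
    wsum = np.zeros(cells_sec.size)
    np.add.at(wsum, cell_of_rec, w)
    kg = totals[cell_of_rec] * w / wsum[cell_of_rec]

    rec_mon = cells_mon[cell_of_rec]
    year, month = rec_mon // 12, rec_mon % 12 + 1
    day = rng.integers(1, 29, rec_mon.size)
    hi = rng.random(rec_mon.size) < cfg.frac_high_tox
    word = np.where(hi, rng.integers(1, 3, rec_mon.size), rng.integers(3, 5, rec_mon.size))
    method = np.where(rng.random(rec_mon.size) < cfg.frac_aerial, "A", "G")

    apps = pd.DataFrame({
        "section_id": sec["section_id"].to_numpy()[cells_sec[cell_of_rec]],
        "date": [f"{y}-{m:02d}-{d:02d}" for y, m, d in zip(year, month, day)],
        "kg_ai": kg,
        "signal_word": word.astype(int),
        "method": method,
    })
    return apps.sort_values(["section_id", "date", "kg_ai"], kind="mergesort",
                            ignore_index=True)


def build_panel(applications: pd.DataFrame, grid: GridSpec, cfg: SimConfig) -> SectionMonthPanel:
    """Section-month exposure surface covering the full simulated range."""
    y0, y1 = cfg.app_years
    return SectionMonthPanel(applications, grid.section_ids(),
                             ym_index(y0, 1), ym_index(y1, 12))


def _assign_zipcodes(grid: GridSpec, cfg: SimConfig) -> np.ndarray:
    """Partition the Section grid into contiguous zipcodes of 4-9 Sections.

    Column strips two Sections wide (three for an odd last strip) are chunked
    into runs of 2-4 rows, so zipcodes cut across both Section and Township
    boundaries and differ from every other grouping level.
    """
    rng = np.random.default_rng(_children(cfg)[3])
    zip_of = np.empty((grid.n_rows, grid.n_cols), dtype=int)
    zid = 0
    col = 0
    while col < grid.n_cols:
        width = 2 if grid.n_cols - col != 3 else 3
        heights = (2, 3, 4) if width == 2 else (2, 3)
        row = 0
        while row < grid.n_rows:
            h = int(rng.choice(heights))
            h = min(h, grid.n_rows - row)
            if grid.n_rows - (row + h) == 1:  # avoid a dangling 1-row chunk
                h += 1
            zip_of[row:row + h, col:col + width] = zid
            zid += 1
            row += h
        col += width
    return zip_of.reshape(-1)  # row-major, aligned with GridSpec.section_ids()


def _draw_categorical(rng, table, n: int) -> np.ndarray:
    levels = np.array([lv for lv, _ in table])
    probs = np.array([p for _, p in table])
    return levels[rng.choice(len(levels), size=n, p=probs / probs.sum())]


def _covariate_shift(births: pd.DataFrame, sizes: dict) -> np.ndarray:
    shift = np.zeros(len(births))
    for key, eff in sizes.items():
        if key == "first_born":
            shift += eff * births["first_born"].to_numpy()
        else:
            fld, level = key.split(":")
            shift += eff * (births[fld].to_numpy() == level)
    return shift


def generate_births(grid: GridSpec, cfg: SimConfig,
                    panel: SectionMonthPanel) -> pd.DataFrame:
    """Simulate the birth-record table on a precomputed exposure surface.

    Each birth gets uniform coordinates within a uniformly chosen Section, a
    geocoding match score, categorical covariates, and outcomes generated
    from a linear-probability process with Township-year effects (partially
    correlated with local pesticide use), birth-month effects, covariate
    effects, and ``cfg.true_effects`` applied to the indicator of being at
    or above the 95th percentile of gestational exposure.
    """
    y0, y1 = cfg.years
    lo_needed, hi_needed = ym_index(y0, 1) - 12, ym_index(y1, 12) + 3
    if panel.start > lo_needed or panel.end < hi_needed:
        raise ValueError(
            "exposure surface does not cover the birth cohort: needs months "
            f"{lo_needed}..{hi_needed}, panel has {panel.start}..{panel.end}"
        )
    rng = np.random.default_rng(_children(cfg)[2])
    n_years = y1 - y0 + 1
    n = cfg.n_births_per_year * n_years
    if n == 0:
        return _empty_births()

    year = np.repeat(np.arange(y0, y1 + 1), cfg.n_births_per_year)
    month = rng.integers(1, 13, n)
    day = 1 + (rng.random(n) * _MONTH_DAYS[month - 1]).astype(int)

    sec_ids = np.asarray(grid.section_ids())
    sec_idx = rng.integers(0, grid.n_sections, n)
    row, colm = sec_idx // grid.n_cols, sec_idx % grid.n_cols
    side = grid.section_side_m
    x_m = (colm + rng.random(n)) * side
    y_m = (row + rng.random(n)) * side
    zip_of = _assign_zipcodes(grid, cfg)

    births = pd.DataFrame({
        "birth_id": [f"B{i:07d}" for i in range(n)],
        "year": year, "month": month, "day": day,
        "section_id": sec_ids[sec_idx],
        "x_m": x_m, "y_m": y_m,
        "zipcode": [f"Z{z:04d}" for z in zip_of[sec_idx]],
    })
    births["township_id"] = [township_of(s) for s in births["section_id"]]
    births["birth_date"] = [f"{y}-{m:02d}-{d:02d}" for y, m, d in zip(year, month, day)]
    births["match_score"] = np.round(np.clip(100.0 - rng.exponential(4.0, n), 0, 100), 1)

    for fld, table in _COVARIATE_TABLES.items():
        births[fld] = _draw_categorical(rng, table, n)
    births["first_born"] = (rng.random(n) < 0.40).astype(int)
    births["total_births_to_mother"] = 1 + rng.poisson(1.2, n)
    many = rng.random(n) < _P_MANY_BIRTHS
    births.loc[many, "total_births_to_mother"] = rng.integers(16, 20, int(many.sum()))
    if cfg.missing_tobacco_year is not None:
        births.loc[births["year"] == cfg.missing_tobacco_year, "tobacco"] = "missing"

    # gestational exposure and the high-exposure indicator driving the DGP
    total_kg = attach_exposures(births, panel)["total_kg"].to_numpy()
    cutoff = np.quantile(total_kg, 0.95, method="inverted_cdf")
    high = (total_kg >= cutoff).astype(float) if cutoff > 0 else np.zeros(n)

    # Township-year effects, partially loaded on local pesticide use so the
    # fixed effects genuinely matter; month effects for seasonality
    ty_key = pd.factorize(births["township_id"] + ":" + births["year"].astype(str))[0]
    n_ty = ty_key.max() + 1
    ty_pest = np.zeros(n_ty)
    np.add.at(ty_pest, ty_key, np.log1p(total_kg))
    cnt = np.bincount(ty_key, minlength=n_ty).astype(float)
    ty_pest /= np.maximum(cnt, 1.0)
    ty_pest = (ty_pest - ty_pest.mean()) / (ty_pest.std() + 1e-12)
    c = cfg.confounding
    alpha = cfg.township_year_sd * (np.sqrt(1 - c * c) * rng.normal(size=n_ty)
                                    + c * ty_pest)
    gamma = rng.normal(0.0, cfg.month_effect_sd, 12)
    regional = alpha[ty_key] + gamma[month - 1]
    cov_shift = _covariate_shift(births, cfg.covariate_effect_sizes)

    for outcome, base in _BASE_RATES.items():
        p = base + cov_shift + regional + cfg.true_effects.get(outcome, 0.0) * high
        births[outcome] = (rng.random(n) < np.clip(p, 0.001, 0.999)).astype(int)

    # continuous outcomes drawn conditionally on the flags, log-linear shifts
    log_shift = -0.5 * (cov_shift + regional)
    gest = np.where(
        births["preterm"].to_numpy() == 1,
        258.0 - rng.exponential(13.0, n),
        np.clip(rng.normal(281.0, 8.5, n), 259, 315),
    )
    gest = gest * np.exp(log_shift + cfg.true_effects.get("log_gest", 0.0) * high)
    gest = np.where(births["preterm"] == 1, np.clip(gest, 120, 258), np.clip(gest, 259, 350))
    births["gestation_days"] = np.round(gest, 0)

    bw = np.where(
        births["low_bw"].to_numpy() == 1,
        np.clip(rng.normal(2100.0, 320.0, n), 500, 2499),
        np.clip(rng.normal(3445.0, 410.0, n), 2500, 5450),
    )
    bw = bw * np.exp(log_shift + cfg.true_effects.get("log_bw", 0.0) * high)
    bw = np.where(births["low_bw"] == 1, np.clip(bw, 400, 2499), np.clip(bw, 2500, 5500))
    births["birth_weight_g"] = np.round(bw, 0)

    # sprinkle out-of-range / missing values for the cohort filters
    bad_g = rng.random(n) < _P_BAD_GESTATION
    births.loc[bad_g, "gestation_days"] = rng.choice(
        [150.0, 170.0, 360.0, 400.0, np.nan], int(bad_g.sum()))
    bad_w = rng.random(n) < _P_BAD_WEIGHT
    births.loc[bad_w, "birth_weight_g"] = rng.choice(
        [100.0, 200.0, 5600.0, np.nan], int(bad_w.sum()))

    return births


def _empty_births() -> pd.DataFrame:
    cols = ["birth_id", "year", "month", "day", "section_id", "x_m", "y_m",
            "zipcode", "township_id", "birth_date", "match_score",
            *_COVARIATE_TABLES, "first_born", "total_births_to_mother",
            "preterm", "low_bw", "abnormality", "gestation_days", "birth_weight_g"]
    return pd.DataFrame(columns=cols)
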