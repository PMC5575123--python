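"""Per-birth pesticide exposure measures from application records.

Exposure is the mass of pesticide active ingredients (kg AI) applied in the
~2.6 km^2 Public Land Survey (PLS) Section containing the mother's residence,
aggregated over whole calendar months.  The gestational window is counted
backwards from the birth month (birth month plus the 8 previous months when
the birth falls on or after the 15th of the month, otherwise the 9 months
preceding the birth month), which avoids anchoring trimesters on the last
menstrual period.  Trimesters partition that window into three 3-month
blocks; trimester 0 (pre-conception) and trimester 4 (post-birth placebo)
extend it on either side.

All aggregation is at Section-month resolution: an application contributes
entirely to the calendar month of its date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MonthWindow",
    "CutoffSet",
    "ym_index",
    "index_ym",
    "gestation_window",
    "trimester_windows",
    "SectionMonthPanel",
    "attach_exposures",
    "aggregate_exposure",
    "compute_cutoffs",
    "binarize",
    "binarize_exposures",
    "spline_basis",
    "EXPOSURE_COLUMNS",
]

#: exposure columns produced by :func:`attach_exposures`
EXPOSURE_COLUMNS = (
    "total_kg", "tox12_kg", "tox34_kg", "aerial_kg", "ground_kg",
    "tri1_kg", "tri2_kg", "tri3_kg", "tri0_kg", "tri4_kg",
)

_COMPONENTS = ("total", "tox12", "tox34", "aerial", "ground")


def ym_index(year: int, month: int) -> int:
    """Serial month number: January of year 0 is 0."""
    return int(year) * 12 + int(month) - 1


def index_ym(idx: int) -> tuple[int, int]:
    """Inverse of :func:`ym_index`."""
    return idx // 12, idx % 12 + 1


@dataclass(frozen=True)
class MonthWindow:
    """Inclusive range of calendar months, stored as serial month indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} after end {self.end}")

    @classmethod
    def from_ym(cls, start: tuple[int, int], end: tuple[int, int]) -> "MonthWindow":
        return cls(ym_index(*start), ym_index(*end))

    @property
    def start_ym(self) -> tuple[int, int]:
        return index_ym(self.start)

    @property
    def end_ym(self) -> tuple[int, int]:
        return index_ym(self.end)

    @property
    def n_months(self) -> int:
        return self.end - self.start + 1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s, e = self.start_ym, self.end_ym
        return f"MonthWindow({s[0]}-{s[1]:02d} .. {e[0]}-{e[1]:02d})"


def gestation_window(birth_date) -> MonthWindow:
    """Nine-month gestational exposure window for a birth date.

    Births on or after the 15th of the month: the birth month and the 8
    previous months.  Births before the 15th: the 9 months preceding the
    birth month.
    """
    d = pd.Timestamp(birth_date)
    m = ym_index(d.year, d.month)
    if d.day >= 15:
        return MonthWindow(m - 8, m)
    return MonthWindow(m - 9, m - 1)


def trimester_windows(window: MonthWindow) -> dict[str, MonthWindow]:
    """Split a 9-month gestational window into trimesters 1-3 plus the
    pre-conception (0) and post-birth placebo (4) windows.

    Trimester 1 is the earliest three months of gestation.
    """
    if window.n_months != 9:
        raise ValueError(f"gestation window must span 9 months, got {window.n_months}")
    s = window.start
    return {
        "tri1": MonthWindow(s, s + 2),
        "tri2": MonthWindow(s + 3, s + 5),
        "tri3": MonthWindow(s + 6, s + 8),
        "tri0": MonthWindow(s - 3, s - 1),
        "tri4": MonthWindow(s + 9, s + 11),
    }


class SectionMonthPanel:
    """Dense Section x month totals of applied kg AI, by component.

    Components: total, tox12 (signal words I-II), tox34 (III-IV), aerial,
    ground.  Cumulative sums along the month axis give O(1) window sums.
    """

    def __init__(self, applications: pd.DataFrame, sections, start: int, end: int):
        if end < start:
            raise ValueError("panel month range is empty")
        self.sections = pd.Index(sections)
        self.start = int(start)
        self.end = int(end)
        n_sec, n_mon = len(self.sections), self.end - self.start + 1

        mats = {c: np.zeros((n_sec, n_mon)) for c in _COMPONENTS}
        if len(applications):
            apps = applications
            dates = pd.to_datetime(apps["date"])
            midx = dates.dt.year.to_numpy() * 12 + dates.dt.month.to_numpy() - 1
            if midx.min() < start or midx.max() > end:
                raise ValueError(
                    "application dates fall outside the panel month range "
                    f"[{index_ym(start)} .. {index_ym(end)}]"
                )
            row = self.sections.get_indexer(apps["section_id"])
            if (row < 0).any():
                missing = sorted(set(apps.loc[row < 0, "section_id"]))[:5]
                raise KeyError(f"applications reference unknown Sections, e.g. {missing}")
            col = midx - start
            kg = apps["kg_ai"].to_numpy(float)
            sw = apps["signal_word"].to_numpy()
            meth = apps["method"].to_numpy()
            np.add.at(mats["total"], (row, col), kg)
            hi = np.isin(sw, (1, 2))
            np.add.at(mats["tox12"], (row[hi], col[hi]), kg[hi])
            np.add.at(mats["tox34"], (row[~hi], col[~hi]), kg[~hi])
            air = meth == "A"
            np.add.at(mats["aerial"], (row[air], col[air]), kg[air])
            np.add.at(mats["ground"], (row[~air], col[~air]), kg[~air])

        # cumulative along months with a leading zero column
        self._cum = {
            c: np.concatenate([np.zeros((n_sec, 1)), np.cumsum(m, axis=1)], axis=1)
            for c, m in mats.items()
        }

    def window_sum(self, rows: np.ndarray, start: np.ndarray, end: np.ndarray,
                   component: str = "total") -> np.ndarray:
        """Sum of ``component`` over inclusive month windows, per row."""
        lo, hi = np.asarray(start) - self.start, np.asarray(end) - self.start + 1
        if (lo < 0).any() or (hi > self.end - self.start + 1).any():
            bad = int(np.asarray(start)[lo < 0][0]) if (lo < 0).any() \
                else int(np.asarray(end)[hi > self.end - self.start + 1][0])
            raise ValueError(
                f"exposure surface does not cover month {index_ym(bad)}; panel spans "
                f"{index_ym(self.start)} .. {index_ym(self.end)}"
            )
        cum = self._cum[component]
        return cum[rows, hi] - cum[rows, lo]


def _birth_window_bounds(births: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gestational window (start, end) month indices per birth."""
    m = births["year"].to_numpy(int) * 12 + births["month"].to_numpy(int) - 1
    late = births["day"].to_numpy(int) >= 15
    end = np.where(late, m, m - 1)
    return end - 8, end


def attach_exposures(births: pd.DataFrame, panel: SectionMonthPanel) -> pd.DataFrame:
    """Compute the full exposure vector for every birth.

    Requires resolved ``section_id`` on every birth (raises otherwise; a
    missing Section is never treated as zero exposure) and a panel covering
    trimester 0 through trimester 4 for every birth.
    """
    if births["section_id"].isna().any():
        n = int(births["section_id"].isna().sum())
        raise ValueError(f"{n} births have unresolved Section IDs")
    rows = panel.sections.get_indexer(births["section_id"])
    if (rows < 0).any():
        missing = sorted(set(births.loc[rows < 0, "section_id"]))[:5]
        raise KeyError(f"births reference Sections absent from the panel, e.g. {missing}")

    start, end = _birth_window_bounds(births)
    out = pd.DataFrame(index=births.index)
    out["total_kg"] = panel.window_sum(rows, start, end, "total")
    for comp, name in [("tox12", "tox12_kg"), ("tox34", "tox34_kg"),
                       ("aerial", "aerial_kg"), ("ground", "ground_kg")]:
        out[name] = panel.window_sum(rows, start, end, comp)
    out["tri1_kg"] = panel.window_sum(rows, start, start + 2)
    out["tri2_kg"] = panel.window_sum(rows, start + 3, start + 5)
    out["tri3_kg"] = panel.window_sum(rows, start + 6, start + 8)
    out["tri0_kg"] = panel.window_sum(rows, start - 3, start - 1)
    out["tri4_kg"] = panel.window_sum(rows, end + 1, end + 3)
    return out


def aggregate_exposure(birth, applications: pd.DataFrame) -> pd.Series:
    """Exposure vector for a single birth record (Series or mapping).

    Convenience wrapper over the vectorized path; ``birth`` needs
    ``section_id``, ``year``, ``month``, ``day``.
    """
    b = pd.DataFrame([dict(birth)])
    if pd.isna(b.at[0, "section_id"]):
        raise ValueError("birth has an unresolved Section ID")
    m = ym_index(int(b.at[0, "year"]), int(b.at[0, "month"]))
    apps = applications[applications["section_id"] == b.at[0, "section_id"]]
    panel = SectionMonthPanel(apps, [b.at[0, "section_id"]], m - 13, m + 4)
    return attach_exposures(b, panel).iloc[0]


@dataclass(frozen=True)
class CutoffSet:
    """Exposure mass cutoffs (kg AI) at the 75th/95th/99th percentiles of a
    reference sample."""

    q75_kg: float
    q95_kg: float
    q99_kg: float

    def __post_init__(self) -> None:
        if not (self.q75_kg <= self.q95_kg <= self.q99_kg):
            raise ValueError("cutoffs must be monotone: q75 <= q95 <= q99")

    def as_knots(self) -> tuple[float, float, float]:
        return (self.q75_kg, self.q95_kg, self.q99_kg)


def compute_cutoffs(values, probs=(0.75, 0.95, 0.99)) -> CutoffSet:
    """Empirical exposure cutoffs on the all-births reference sample.

    Uses the inverted-CDF (lower empirical) quantile, which is well defined
    under the majority-zero exposure distribution.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot compute cutoffs on an empty reference sample")
    q = np.quantile(v, probs, method="inverted_cdf")
    return CutoffSet(float(q[0]), float(q[1]), float(q[2]))


def binarize(values, cutoff: float):
    """High-exposure indicator: 1 when exposure is at or above the cutoff.

    "Top 95th percentile or above" makes the indicator inclusive at the
    cutoff; ties at positive cutoffs are rare given the continuous mass
    distribution.
    """
    v = np.asarray(values, float)
    if (v < 0).any():
        raise ValueError("exposure values must be non-negative")
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    out = (v >= cutoff).astype(np.int8)
    return out if out.ndim else int(out)


def binarize_exposures(expo: pd.DataFrame, reference_mask=None, prob: float = 0.95,
                       columns=EXPOSURE_COLUMNS) -> tuple[pd.DataFrame, dict[str, float]]:
    """High-exposure indicators for every exposure column.

    Each measure gets its own cutoff, computed at ``prob`` on the reference
    (all-births) rows.  Returns the indicator frame (columns ``high_<name>``
    with the ``_kg`` suffix stripped) and the cutoffs used.
    """
    ref = expo if reference_mask is None else expo.loc[reference_mask]
    if len(ref) == 0:
        raise ValueError("empty reference sample for exposure cutoffs")
    cutoffs: dict[str, float] = {}
    out = pd.DataFrame(index=expo.index)
    for col in columns:
        c = float(np.quantile(ref[col].to_numpy(float), prob, method="inverted_cdf"))
        cutoffs[col] = c
        out["high_" + col.removesuffix("_kg")] = binarize(expo[col].to_numpy(), c)
    return out, cutoffs


def spline_basis(values, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis for continuous exposure.

    With knots t1 < t2 < t3 the basis has two columns: the linear term and
    one restricted cubic term, linear beyond the boundary knots (zero second
    derivative at and outside t1 and t3).  Tied knots — which happen when the
    75th percentile sits on the zero mass point — are refused rather than
    silently merged; choose knots on the positive part of the distribution
    instead.
    """
    t = np.asarray(knots.as_knots() if isinstance(knots, CutoffSet) else knots, float)
    if t.shape != (3,):
        raise ValueError("exactly 3 knots required")
    if not (t[0] < t[1] < t[2]):
        raise ValueError(
            f"knots must be strictly increasing, got {tuple(t)}; with a mass "
            "point at zero exposure the 75th-percentile knot can collide — "
            "adjust the knot probabilities or use the binary coding"
        )
    x = np.asarray(values, float)
    p3 = lambda u: np.clip(u, 0.0, None) ** 3
    t1, t2, t3 = t
    cub = (p3(x - t1)
           - p3(x - t2) * (t3 - t1) / (t3 - t2)
           + p3(x - t3) * (t2 - t1) / (t3 - t2))
    return np.column_stack([x, cub])
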