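"""Gestational windows, exposure aggregation, cutoffs and spline basis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestnatal.exposure import (
    CutoffSet,
    MonthWindow,
    aggregate_exposure,
    binarize,
    compute_cutoffs,
    gestation_window,
    spline_basis,
    trimester_windows,
    ym_index,
)


@pytest.mark.parametrize(
    "birth_date, start, end",
    [
        ("2000-06-20", (1999, 10), (2000, 6)),   # day >= 15: birth month + 8 previous
        ("2000-06-10", (1999, 9), (2000, 5)),    # day < 15: 9 preceding months
        ("2000-01-15", (1999, 5), (2000, 1)),    # boundary day 15, crosses year
        ("2000-01-14", (1999, 4), (1999, 12)),   # day 14 excludes the birth month
    ],
)
def test_gestation_window_rule(birth_date, start, end):
    w = gestation_window(birth_date)
    assert w.start_ym == start
    assert w.end_ym == end
    assert w.n_months == 9


@given(st.dates(min_value=pd.Timestamp("1950-01-01").date(),
                max_value=pd.Timestamp("2049-12-01").date()))
@settings(max_examples=200, deadline=None)
def test_gestation_window_properties(date):
    w = gestation_window(date)
    assert w.n_months == 9
    birth_m = ym_index(date.year, date.month)
    if date.day >= 15:
        assert w.end == birth_m
    else:
        assert w.end == birth_m - 1


def test_trimester_partition_example():
    w = MonthWindow.from_ym((1999, 10), (2000, 6))
    t = trimester_windows(w)
    assert t["tri1"].start_ym == (1999, 10) and t["tri1"].end_ym == (1999, 12)
    assert t["tri2"].start_ym == (2000, 1) and t["tri2"].end_ym == (2000, 3)
    assert t["tri3"].start_ym == (2000, 4) and t["tri3"].end_ym == (2000, 6)
    assert t["tri0"].start_ym == (1999, 7) and t["tri0"].end_ym == (1999, 9)
    assert t["tri4"].start_ym == (2000, 7) and t["tri4"].end_ym == (2000, 9)


@given(st.integers(min_value=1950 * 12, max_value=2049 * 12))
@settings(max_examples=100, deadline=None)
def test_trimester_partition_properties(start):
    w = MonthWindow(start, start + 8)
    t = trimester_windows(w)
    months = [m for k in ("tri1", "tri2", "tri3")
              for m in range(t[k].start, t[k].end + 1)]
    assert months == list(range(w.start, w.end + 1))  # exact disjoint partition
    assert t["tri4"].start > w.end                    # placebo never overlaps gestation
    assert t["tri0"].end < w.start


def test_trimester_rejects_non_nine_month_window():
    with pytest.raises(ValueError, match="9 months"):
        trimester_windows(MonthWindow(0, 5))


def _birth(section="S1", date="2000-06-20"):
    d = pd.Timestamp(date)
    return {"section_id": section, "year": d.year, "month": d.month, "day": d.day}


def test_aggregate_exposure_hand_example():
    # two applications inside trimester 2 of a window ending 2000-06
    apps = pd.DataFrame({
        "section_id": ["S1", "S1"],
        "date": ["2000-02-10", "2000-03-05"],
        "kg_ai": [100.0, 50.0],
        "signal_word": [1, 3],
        "method": ["G", "A"],
    })
    v = aggregate_exposure(_birth(), apps)
    assert v["total_kg"] == 150.0
    assert v["tox12_kg"] == 100.0 and v["tox34_kg"] == 50.0
    assert v["tri2_kg"] == 150.0 and v["tri1_kg"] == 0.0 and v["tri3_kg"] == 0.0
    assert v["aerial_kg"] == 50.0 and v["ground_kg"] == 100.0


def test_aggregate_exposure_window_boundaries():
    # 1999-09 is the month before the window start: excluded from total, in tri0
    apps = pd.DataFrame({
        "section_id": ["S1", "S1"],
        "date": ["1999-09-28", "2000-07-02"],
        "kg_ai": [40.0, 70.0],
        "signal_word": [2, 4],
        "method": ["G", "G"],
    })
    v = aggregate_exposure(_birth(), apps)
    assert v["total_kg"] == 0.0
    assert v["tri0_kg"] == 40.0
    assert v["tri4_kg"] == 70.0


def test_aggregate_exposure_no_applications_is_exact_zero():
    apps = pd.DataFrame(columns=["section_id", "date", "kg_ai", "signal_word", "method"])
    v = aggregate_exposure(_birth(), apps)
    assert (v == 0).all()


def test_aggregate_exposure_rejects_unresolved_section():
    apps = pd.DataFrame(columns=["section_id", "date", "kg_ai", "signal_word", "method"])
    with pytest.raises(ValueError, match="[Ss]ection"):
        aggregate_exposure({"section_id": np.nan, "year": 2000, "month": 6, "day": 20},
                           apps)


def test_additivity_on_simulated_cohort(study):
    f = study["frame"]
    kw = dict(rtol=1e-12, atol=1e-9)  # sums of the same records, machine precision
    np.testing.assert_allclose(
        f["tri1_kg"] + f["tri2_kg"] + f["tri3_kg"], f["total_kg"], **kw)
    np.testing.assert_allclose(f["tox12_kg"] + f["tox34_kg"], f["total_kg"], **kw)
    np.testing.assert_allclose(f["aerial_kg"] + f["ground_kg"], f["total_kg"], **kw)


def test_translation_invariance_by_whole_months():
    apps = pd.DataFrame({
        "section_id": ["S1", "S1", "S1"],
        "date": ["1999-11-03", "2000-02-21", "2000-08-09"],
        "kg_ai": [10.0, 20.0, 30.0],
        "signal_word": [1, 3, 2],
        "method": ["A", "G", "G"],
    })
    shifted = apps.copy()
    shifted["date"] = (pd.to_datetime(apps["date"])
                       + pd.DateOffset(months=7)).dt.strftime("%Y-%m-%d")
    v0 = aggregate_exposure(_birth(date="2000-06-20"), apps)
    v1 = aggregate_exposure(_birth(date="2001-01-20"), shifted)
    pd.testing.assert_series_equal(v0, v1)


# ---------------------------------------------------------------------------
# cutoffs, binarization, spline

def test_cutoffs_majority_zero_sample():
    cs = compute_cutoffs([0, 0, 0, 0, 0, 0, 0, 0, 0, 100])
    assert cs.q75_kg == 0.0
    assert cs.q95_kg == 100.0 and cs.q99_kg == 100.0


def test_cutoffs_constant_sample():
    cs = compute_cutoffs([7.0] * 20)
    assert cs.q75_kg == cs.q95_kg == cs.q99_kg == 7.0


def test_cutoffs_empty_sample_rejected():
    with pytest.raises(ValueError, match="empty"):
        compute_cutoffs([])


def test_cutoffs_half_sample_stability(study):
    tot = study["frame"]["total_kg"].to_numpy()
    full = compute_cutoffs(tot)
    half = compute_cutoffs(tot[::2])
    assert abs(half.q95_kg - full.q95_kg) / full.q95_kg < 0.25


@pytest.mark.parametrize("value, cutoff, expected", [
    (5000.0, 4178.0, 1),   # above the 95th-percentile cutoff
    (0.0, 4178.0, 0),
    (4178.0, 4178.0, 1),   # tie at the cutoff counts as high ("or above")
])
def test_binarize_tie_rule(value, cutoff, expected):
    assert binarize(value, cutoff) == expected


def test_binarize_rejects_negative_exposure():
    with pytest.raises(ValueError, match="non-negative"):
        binarize(-1.0, 100.0)


def test_spline_linear_below_first_knot():
    basis = spline_basis([0.0, 50.0, 100.0], (249.0, 4178.0, 11134.0))
    np.testing.assert_allclose(basis[:, 0], [0.0, 50.0, 100.0])
    np.testing.assert_allclose(basis[:, 1], 0.0)


def test_spline_natural_beyond_boundary_knots():
    # second differences vanish outside the boundary knots (linearity)
    knots = (1.0, 3.0, 8.0)
    for x0 in (-5.0, 0.5, 9.0, 50.0):
        h = 1e-3
        b = spline_basis([x0 - h, x0, x0 + h], knots)[:, 1]
        second = (b[0] - 2 * b[1] + b[2]) / h**2
        assert abs(second) < 1e-4


def test_spline_matches_truncated_power_oracle():
    knots = (2.0, 5.0, 11.0)
    x = np.linspace(-1, 20, 301)
    basis = spline_basis(x, knots)

    def tp(u, t):  # independent truncated-power construction
        return np.maximum(u - t, 0.0) ** 3

    t1, t2, t3 = knots
    oracle = tp(x, t1) - tp(x, t2) * (t3 - t1) / (t3 - t2) \
        + tp(x, t3) * (t2 - t1) / (t3 - t2)
    np.testing.assert_allclose(basis[:, 1], oracle, rtol=1e-12, atol=1e-12)
    np.testing.assert_allclose(basis[:, 0], x)


def test_spline_refuses_tied_knots():
    with pytest.raises(ValueError, match="strictly increasing"):
        spline_basis([1.0], (0.0, 0.0, 11134.0))
    with pytest.raises(ValueError):
        spline_basis([1.0], CutoffSet(0.0, 0.0, 5.0))
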