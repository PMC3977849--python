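"""Growth-record extraction and population statistics."""

import numpy as np
import pandas as pd
import pytest

from pombetrack import (
    GrowthConfig,
    SimulationParams,
    align_to_shift,
    birth_division_regression,
    detect_plateau,
    extract_record,
    sample_cycle_records,
    summarize,
    sister_table,
)
from pombetrack.growth import IncompleteCycle, PARAMETERS

from test_lineage import build_tree


def piecewise_series(n=140, rate=0.05, break_at=100, level_from=7.3, noise=0.0,
                     seed=0):
    rng = np.random.default_rng(seed)
    L = np.where(np.arange(n) < break_at,
                 level_from + rate * np.arange(n),
                 level_from + rate * break_at)
    return L + rng.normal(0, noise, n)


# ---------------------------------------------------------------------------
# plateau detection
# ---------------------------------------------------------------------------

def test_plateau_breakpoint_recovered():
    L = piecewise_series(noise=0.05, seed=1)
    b, div_len = detect_plateau(L)
    assert abs(b - 100) <= 2
    assert div_len == pytest.approx(7.3 + 0.05 * 100, abs=0.05)


def test_noiseless_plateau_level_exact():
    L = piecewise_series(break_at=80, noise=0.0)
    _b, div_len = detect_plateau(L)
    assert div_len == pytest.approx(7.3 + 0.05 * 80, abs=1e-9)


def test_monotone_series_is_incomplete():
    L = 7.0 + 0.05 * np.arange(120)
    with pytest.raises(IncompleteCycle):
        detect_plateau(L)


def test_too_short_series_is_incomplete():
    with pytest.raises(IncompleteCycle):
        detect_plateau(np.linspace(7, 8, 10))


# ---------------------------------------------------------------------------
# record extraction
# ---------------------------------------------------------------------------

def test_extract_record_piecewise():
    """100 min growth at 0.05 um/min then a 30-min plateau."""
    n = 130
    L = piecewise_series(n=n, rate=0.05, break_at=100, noise=0.0)
    frames = np.arange(n)
    rec = extract_record(L, frames, birth_frame=0, division_frame=130)
    assert rec.elongation_time == pytest.approx(100, abs=2)
    assert rec.septation_time == pytest.approx(30, abs=2)
    assert rec.doubling_time == rec.elongation_time + rec.septation_time
    assert rec.elongation_rate == pytest.approx(0.05, rel=0.02)
    assert rec.birth_length == pytest.approx(7.3, abs=1e-9)


def test_records_recover_zero_cv_configuration(small_sim):
    """Zero-CV simulation: the record reproduces configured lengths within
    one pixel equivalent (0.23 um)."""
    from pombetrack import (SegmentationConfig, TrackerConfig, DivisionConfig,
                            build_forest, detect_divisions, extract_records,
                            segment_movie, simulate_colony, track_movie)

    p = SimulationParams(n_lanes=1, lane_length=600, initial_cells_per_lane=3,
                         n_frames=220, cv_lengths=0.0, cv_times=0.0,
                         noise_sd=0.0, seed=17,
                         mean_birth_length=7.1, mean_division_length=12.9,
                         mean_fission_length=14.2)
    stack, truth = simulate_colony(p)
    frames = segment_movie(stack, lanes_geometry=p.lane_rows,
                           config=SegmentationConfig())
    mat = track_movie(frames, TrackerConfig(lane_length_px=p.lane_length))
    events = detect_divisions(mat, DivisionConfig())
    forest = build_forest(mat, events)
    records = extract_records(mat, events, forest, GrowthConfig())
    assert len(records) >= 1
    assert records["birth_length"].mean() == pytest.approx(14.2 / 2, abs=0.23)
    assert records["division_length"].mean() == pytest.approx(12.9, abs=0.23)
    assert records["fission_length"].mean() == pytest.approx(14.2, abs=0.23)


def test_every_record_satisfies_time_identity(small_analysis):
    rec = small_analysis["records"]
    assert len(rec) > 0
    assert np.allclose(rec["doubling_time"],
                       rec["elongation_time"] + rec["septation_time"])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_identical_records_zero_sd():
    rec = sample_cycle_records(SimulationParams(cv_lengths=0.0, cv_times=0.0),
                               20, seed=1)
    s = summarize(rec).set_index("parameter")
    assert s.loc["doubling_time", "sd"] == pytest.approx(0.0, abs=1e-9)
    assert s.loc["doubling_time", "cv"] == pytest.approx(0.0, abs=1e-12)


def test_doubling_cv_recovered():
    """cv_times 0.18 per phase: doubling-time CV recovered within 0.03."""
    p = SimulationParams(cv_times=0.18)
    rec = sample_cycle_records(p, 500, seed=3)
    s = summarize(rec).set_index("parameter")
    te, ts = p.mean_elongation_time, p.mean_septation_time
    expected_cv = 0.18 * np.hypot(te, ts) / (te + ts)
    assert s.loc["doubling_time", "cv"] == pytest.approx(expected_cv, abs=0.03)


def test_two_condition_summary():
    rec = pd.concat([sample_cycle_records(SimulationParams(), 50, seed=4),
                     sample_cycle_records(SimulationParams(), 50, seed=5)],
                    ignore_index=True)
    cond = pd.Series(["pre"] * 50 + ["post"] * 50)
    s = summarize(rec, cond)
    for par in PARAMETERS:
        assert len(s[s["parameter"] == par]) == 2


def test_summary_permutation_invariant():
    rec = sample_cycle_records(SimulationParams(), 100, seed=6)
    shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = summarize(rec).set_index("parameter")["mean"]
    b = summarize(shuffled).set_index("parameter")["mean"]
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# shift alignment
# ---------------------------------------------------------------------------

def _records_for_shift():
    return pd.DataFrame({
        "division_time_abs": [100.0, 400.0, 260.0],
        "doubling_time": [120.0, 130.0, 100.0],
        **{p: [1.0, 1.0, 1.0] for p in PARAMETERS if p != "doubling_time"},
    })


def test_shift_fractions():
    rec = _records_for_shift()
    out = align_to_shift(rec, t_shift=200.0)
    frac = out["fraction_of_cycle_after_shift"].to_numpy()
    assert frac[0] == 0.0          # divided before the shift
    assert frac[1] == 1.0          # born after the shift
    assert frac[2] == pytest.approx(0.6)  # 60 of 100 minutes after


def test_shift_fractions_bounded_and_monotone():
    times = np.linspace(0, 500, 40)
    rec = pd.DataFrame({
        "division_time_abs": times, "doubling_time": np.full(40, 100.0),
        **{p: np.ones(40) for p in PARAMETERS if p != "doubling_time"},
    })
    out = align_to_shift(rec, t_shift=250.0)
    f = out["fraction_of_cycle_after_shift"].to_numpy()
    assert ((0 <= f) & (f <= 1)).all()
    assert (np.diff(f) >= -1e-12).all()


# ---------------------------------------------------------------------------
# birth-division regression
# ---------------------------------------------------------------------------

def test_regression_exact_on_collinear_data():
    birth = np.linspace(6.2, 9.8, 60)
    rec = pd.DataFrame({"birth_length": birth,
                        "division_length": 0.61 * birth + 9.0})
    slope, intercept, _table = birth_division_regression(rec)
    assert slope == pytest.approx(0.61, abs=1e-9)
    assert intercept == pytest.approx(9.0, abs=1e-9)


def test_regression_zero_slope_on_constant_division():
    birth = np.linspace(6.2, 9.8, 60)
    rec = pd.DataFrame({"birth_length": birth,
                        "division_length": np.full(60, 12.9)})
    slope, _i, _t = birth_division_regression(rec)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_regression_needs_enough_records():
    rec = pd.DataFrame({"birth_length": [7.0] * 5, "division_length": [12.0] * 5})
    with pytest.raises(ValueError):
        birth_division_regression(rec)


def test_sizer_slope_near_zero():
    rec = sample_cycle_records(SimulationParams(), 500, seed=0)
    slope, _i, _t = birth_division_regression(rec)
    assert abs(slope) < 0.1


# ---------------------------------------------------------------------------
# sister pairs
# ---------------------------------------------------------------------------

def _forest_and_records(doubling_b=None, n_pairs=5):
    edges = []
    rows = []
    tid = 1
    for k in range(n_pairs):
        parent, a, b = tid, tid + 1, tid + 2
        tid += 3
        edges.append((parent, a))
        edges.append((parent, b))
        da = 120.0 + k
        db = da if doubling_b is None else doubling_b[k]
        for t, d in ((parent, 115.0), (a, da), (b, db)):
            rows.append({"track_id": t, "doubling_time": d,
                         "elongation_rate": 0.06, "division_length": 12.9,
                         **{p: 1.0 for p in PARAMETERS
                            if p not in ("doubling_time", "elongation_rate")}})
    # separate trees, one per (parent, sister, sister) triple
    trees = []
    for k in range(n_pairs):
        p, a, b = 3 * k + 1, 3 * k + 2, 3 * k + 3
        trees.append(build_tree([(p, a), (p, b)], root=p))
    return trees, pd.DataFrame(rows)


def test_perfectly_heritable_sisters_correlate():
    forest, records = _forest_and_records()
    table = sister_table(forest, records)
    assert len(table) == 5
    assert table.attrs["correlations"]["doubling_time"] == pytest.approx(1.0)
    assert (table["sister_a"] < table["sister_b"]).all()


def test_no_complete_pairs_empty_table():
    forest, records = _forest_and_records()
    table = sister_table(forest, records.iloc[0:0])
    assert len(table) == 0


def test_independent_sisters_uncorrelated():
    rng = np.random.default_rng(8)
    n = 300
    trees = []
    rows = []
    for k in range(n):
        p, a, b = 3 * k + 1, 3 * k + 2, 3 * k + 3
        from test_lineage import build_tree as bt
        trees.append(bt([(p, a), (p, b)], root=p))
        for t in (p, a, b):
            rows.append({"track_id": t,
                         "doubling_time": float(rng.normal(129, 17)),
                         "elongation_rate": float(rng.normal(0.06, 0.006)),
                         "division_length": 12.9,
                         **{q: 1.0 for q in PARAMETERS
                            if q not in ("doubling_time", "elongation_rate")}})
    table = sister_table(trees, pd.DataFrame(rows))
    assert len(table) == n
    assert abs(table.attrs["correlations"]["doubling_time"]) < 0.15


# ---------------------------------------------------------------------------
# figure output
# ---------------------------------------------------------------------------

def test_plot_outputs(tmp_path):
    from pombetrack.plots import plot_histograms, plot_shift_scatter, \
        plot_sister_scatter

    rec = sample_cycle_records(SimulationParams(), 80, seed=9)
    rec["division_time_abs"] = np.linspace(50, 350, 80)
    assert plot_histograms(rec, tmp_path / "hist.png").stat().st_size > 0
    assert plot_shift_scatter(rec, 200.0, tmp_path / "shift.png").stat().st_size > 0
    forest, records = _forest_and_records()
    table = sister_table(forest, records)
    assert plot_sister_scatter(table, tmp_path / "sisters.png").stat().st_size > 0
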