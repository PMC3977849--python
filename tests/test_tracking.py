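"""Tracking: score functions, gates, local/global matching, track building."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pombetrack import (
    SegmentationConfig,
    SimulationParams,
    TrackerConfig,
    global_score,
    local_score,
    match_global,
    match_local,
    needs_global_fallback,
    segment_movie,
    simulate_colony,
    track_movie,
)
from pombetrack.segmentation import CellObservation
from pombetrack.tracking import PairingResult, brute_force_assignment
from pombetrack.validate import match_observations


def make_obs(obs_id=1, frame=0, x=50.0, y=30.0, area=600.0, length=10.0,
             width=3.5, angle=0.0, mask_size=20):
    """Minimal synthetic observation with a square mask centered on (x, y)."""
    half = mask_size // 2
    mask = np.ones((mask_size, mask_size), dtype=bool)
    bbox = (int(y) - half, int(x) - half, int(y) + half, int(x) + half)
    return CellObservation(
        id=obs_id, frame=frame, lane=0, centroid=(x, y), area=area,
        length_um=length, width_um=width, orientation_deg=angle,
        mean_intensity=140.0, profile=np.full(40, 140.0),
        contour=np.zeros((0, 2)), mask=mask, bbox=bbox,
    )


CFG = TrackerConfig()


# ---------------------------------------------------------------------------
# score functions
# ---------------------------------------------------------------------------

def test_local_score_zero_at_identity():
    a = make_obs(1)
    b = make_obs(2)
    assert local_score(a, b, CFG) == 0.0
    assert global_score(a, b, CFG) == 0.0


def test_local_score_infinite_beyond_displacement_gate():
    a = make_obs(1, x=50.0)
    b = make_obs(2, x=101.0)  # 51 px away
    assert math.isinf(local_score(a, b, CFG))
    c = make_obs(3, x=99.0)   # 49 px away
    assert math.isfinite(local_score(a, c, CFG))


def test_local_score_monotone_in_distance():
    a = make_obs(1, x=100.0)
    scores = [local_score(a, make_obs(2, x=100.0 + d), CFG)
              for d in np.linspace(0, 45, 12)]
    assert all(s2 > s1 for s1, s2 in zip(scores, scores[1:]))


def test_global_score_area_normalization():
    """Areas 300 vs 600: normalized area term is |dA|/max = 0.5."""
    cfg = TrackerConfig(global_weights=(0.0, 1.0, 0.0))
    a = make_obs(1, area=300.0)
    b = make_obs(2, area=600.0)
    assert global_score(a, b, cfg) == pytest.approx(0.5)


@given(st.floats(0, 89), st.floats(-89, 89))
@settings(max_examples=50, deadline=None)
def test_score_symmetry_and_nonnegativity(angle_a, angle_b):
    a = make_obs(1, angle=angle_a)
    b = make_obs(2, angle=angle_b)
    sa = local_score(a, b, CFG)
    sb = local_score(b, a, CFG)
    assert sa == pytest.approx(sb)
    assert sa >= 0
    assert global_score(a, b, CFG) == pytest.approx(global_score(b, a, CFG))


# ---------------------------------------------------------------------------
# gates (printed thresholds)
# ---------------------------------------------------------------------------

def test_area_change_gate():
    a = make_obs(1, area=1000.0)
    b = make_obs(2, area=550.0)   # 45% change
    res = match_local([a], [b], CFG)
    assert res.pairs == []
    assert res.unpaired_n == [1] and res.unpaired_n1 == [2]
    c = make_obs(3, area=700.0)   # 30% change
    res2 = match_local([a], [c], CFG)
    assert len(res2.pairs) == 1


def test_score_threshold_gate():
    cfg = TrackerConfig(local_weights=(10.0, 0.0, 0.0, 0.0, 0.0))
    a = make_obs(1, x=50.0)
    b = make_obs(2, x=56.5)   # score = 65 -> rejected (strict <)
    assert match_local([a], [b], cfg).pairs == []
    c = make_obs(3, x=56.4)   # score = 64 -> accepted
    assert len(match_local([a], [c], cfg).pairs) == 1


def test_overlap_gate():
    a = make_obs(1, x=50.0, mask_size=10)
    b = make_obs(2, x=70.0, mask_size=10)  # disjoint masks, 20 px apart
    assert match_local([a], [b], CFG).pairs == []


def test_stationary_cell_pairs_trivially():
    a = make_obs(1)
    b = make_obs(2, frame=1)
    res = match_local([a], [b], CFG)
    assert res.pairs == [(1, 2, 0.0)]
    assert res.unpaired_n == [] and res.unpaired_n1 == []


def test_fallback_unpaired_threshold():
    def res_with(n_unpaired, disp=1.0):
        return PairingResult(pairs=[(0, 0, 0.0)], unpaired_n=list(range(n_unpaired)),
                             unpaired_n1=[], tracker="local", mean_displacement=disp)
    assert needs_global_fallback(res_with(31), CFG) is True
    assert needs_global_fallback(res_with(30), CFG) is False
    assert needs_global_fallback(res_with(0, disp=9.0), CFG) is True   # disjunction


# ---------------------------------------------------------------------------
# global tracker
# ---------------------------------------------------------------------------

def test_match_global_equals_brute_force():
    """LAP solution equals exhaustive enumeration on 200 random instances."""
    rng = np.random.default_rng(42)
    cfg = TrackerConfig(global_no_match_cost=25.0)
    for _ in range(200):
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        obs_n = [make_obs(i + 1, x=float(rng.uniform(0, 120)),
                          y=float(rng.uniform(10, 50)),
                          area=float(rng.uniform(300, 900)),
                          length=float(rng.uniform(6, 14))) for i in range(n)]
        obs_m = [make_obs(100 + j, frame=1, x=float(rng.uniform(0, 120)),
                          y=float(rng.uniform(10, 50)),
                          area=float(rng.uniform(300, 900)),
                          length=float(rng.uniform(6, 14))) for j in range(m)]
        res = match_global(obs_n, obs_m, cfg)
        _pairs, best_cost = brute_force_assignment(obs_n, obs_m, cfg)
        got = sum(s for _a, _b, s in res.pairs) + cfg.global_no_match_cost * (
            len(res.unpaired_n) + len(res.unpaired_n1))
        assert got == pytest.approx(best_cost, abs=1e-9)


def test_global_handles_bulk_advection():
    """A 12-px bulk shift defeats the local mean-displacement gate but the
    global tracker recovers the ground-truth pairing."""
    rng = np.random.default_rng(3)
    xs = np.arange(40, 260, 55, dtype=float)
    obs_n = [make_obs(i + 1, x=x, area=600 + 30 * i, length=8 + 0.5 * i)
             for i, x in enumerate(xs)]
    obs_m = [make_obs(100 + i, frame=1, x=x + 12.0, area=600 + 30 * i,
                      length=8 + 0.5 * i) for i, x in enumerate(xs)]
    res_local = match_local(obs_n, obs_m, CFG)
    assert needs_global_fallback(res_local, CFG)  # mean displacement 12 > 8
    res = match_global(obs_n, obs_m, CFG)
    assert sorted(res.pairs) == [(i + 1, 100 + i, pytest.approx(12.0))
                                 for i in range(len(xs))]


def test_global_rerun_on_poor_pairing():
    """Mean displacement above 8 px with poor pairing triggers one re-run."""
    cfg = TrackerConfig(min_displacement_ramp_max=30.0, lane_length_px=100.0,
                        rerun_min_paired_fraction=0.9,
                        global_no_match_cost=1000.0)
    # cells near the outlet (x ~ 90) must move >= ~27 px; they move 9 px,
    # so their pairs are forbidden on the first pass
    obs_n = [make_obs(1, x=90.0), make_obs(2, x=30.0)]
    obs_m = [make_obs(101, frame=1, x=99.0), make_obs(102, frame=1, x=39.0)]
    res = match_global(obs_n, obs_m, cfg)
    assert res.reruns == 1


def test_empty_frames():
    res = match_global([], [make_obs(1)], CFG)
    assert res.pairs == [] and res.unpaired_n1 == [1]
    assert match_local([], [], CFG).pairs == []


# ---------------------------------------------------------------------------
# track building
# ---------------------------------------------------------------------------

def test_single_drifting_cell_single_track():
    frames = [[make_obs(i + 1, frame=i, x=50.0 + 0.5 * i)] for i in range(100)]
    mat = track_movie(frames, TrackerConfig())
    assert mat.n_tracks == 1
    assert len(next(iter(mat.tracks.values()))) == 100


def test_lost_cell_reseeds_as_new_track():
    frames = [[make_obs(i + 1, frame=i)] if i < 20 or i >= 80 else []
              for i in range(120)]
    mat = track_movie(frames, TrackerConfig())
    assert mat.n_tracks == 2
    spans = sorted((mat.start_frame(t), mat.end_frame(t)) for t in mat.tracks)
    assert spans == [(0, 19), (80, 119)]


def test_no_observation_in_two_tracks(small_analysis):
    mat = small_analysis["matrix"]
    seen = {}
    for tid, obs_ids in mat.tracks.items():
        for oid in obs_ids:
            assert oid not in seen, f"observation {oid} in two tracks"
            seen[oid] = tid


def test_synthetic_links_recovered(small_analysis):
    """>= 95% of ground-truth frame links recovered, <= 1% false links."""
    mat = small_analysis["matrix"]
    truth = small_analysis["truth"]
    frames = small_analysis["frames"]
    obs2cell = match_observations(frames, truth)
    traj = truth.trajectories_frame()
    per_frame = traj.groupby("cell_id")["frame"].agg(["min", "max"])
    n_truth_links = int((per_frame["max"] - per_frame["min"]).sum())
    good = sum(1 for a, b in mat.links
               if obs2cell.get(a) is not None and obs2cell.get(a) == obs2cell.get(b))
    assert good / n_truth_links >= 0.95
    assert (len(mat.links) - good) / len(mat.links) <= 0.01


def test_local_global_agree_on_easy_movies():
    """Low density, small displacement, no noise: both trackers give the
    same pairing."""
    p = SimulationParams(n_lanes=1, lane_length=400, initial_cells_per_lane=3,
                         n_frames=25, noise_sd=0.0, advection_vmax=0.2, seed=21)
    stack, _truth = simulate_colony(p)
    frames = segment_movie(stack, lanes_geometry=p.lane_rows,
                           config=SegmentationConfig())
    cfg = TrackerConfig(lane_length_px=p.lane_length)
    for f in range(len(frames) - 1):
        loc = match_local(frames[f], frames[f + 1], cfg)
        glo = match_global(frames[f], frames[f + 1], cfg)
        assert sorted((a, b) for a, b, _ in loc.pairs) == \
            sorted((a, b) for a, b, _ in glo.pairs)
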