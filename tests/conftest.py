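import numpy as np
import pytest

from pombetrack import (
    DivisionConfig,
    GrowthConfig,
    SegmentationConfig,
    SimulationParams,
    TrackerConfig,
    build_forest,
    detect_divisions,
    extract_records,
    segment_movie,
    simulate_colony,
    track_movie,
)


@pytest.fixture(scope="session")
def small_sim():
    """One-lane movie with a handful of cells and divisions (fast)."""
    params = SimulationParams(n_lanes=1, lane_length=400, initial_cells_per_lane=4,
                              n_frames=150, seed=1)
    stack, truth = simulate_colony(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def small_analysis(small_sim):
    """Segmented + tracked + divided small movie, shared across tests."""
    params, stack, truth = small_sim
    frames = segment_movie(stack, lanes_geometry=params.lane_rows,
                           config=SegmentationConfig())
    matrix = track_movie(frames, TrackerConfig(lane_length_px=params.lane_length))
    events = detect_divisions(matrix, DivisionConfig())
    forest = build_forest(matrix, events)
    records = extract_records(matrix, events, forest, GrowthConfig())
    return dict(params=params, stack=stack, truth=truth, frames=frames,
                matrix=matrix, events=events, forest=forest, records=records)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_rod_frame(length_um=10.0, width_um=3.5, angle_deg=0.0, septum=0.0,
                   noise_sd=0.0, lane_width=60, lane_length=200, x=None, y=None,
                   seed=0):
    """Render a single rod in a one-lane frame; returns (frame, params, state)."""
    from pombetrack.synthetic import CellState, render_frame

    params = SimulationParams(n_lanes=1, lane_width=lane_width,
                              lane_length=lane_length, noise_sd=noise_sd,
                              seed=seed)
    state = CellState(cell_id=1, lane=0,
                      x=lane_length / 2 if x is None else x,
                      y=lane_width / 2 if y is None else y,
                      length_um=length_um, width_um=width_um,
                      angle_deg=angle_deg, septum=septum)
    frame = render_frame([state], params, np.random.default_rng(seed))
    return frame, params, state
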