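"""Synthetic microchemostat movies with ground truth.

Generates bright-field-like image stacks of a highway-structured growth
chamber populated by rod-shaped fission-yeast cells.  Cells follow a
three-phase cycle: linear elongation from birth length to division length,
a length plateau during septation, and a terminal snap to fission length
followed by (near-)symmetric division.  Imaging slightly out of focus is
emulated by dark cell contours on a mid-gray background with a transient
bright transverse septum band whose intensity rises toward a peak and then
collapses to background within a few minutes before the cell splits.

Cells advect lane-wise toward the chamber outlet: a position-dependent
drift (slow near the sieve, fast near the outlet) plus hard-core packing
that transmits growth pressure downstream.  Cells reaching the outlet are
eluted.  Every frame is rendered from an explicit per-cell state, so the
emitted ground truth (trajectories, division records, lineage forest,
per-cycle parameters) is consistent with the images by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "CellState",
    "CellRecord",
    "GroundTruth",
    "steady_state_params",
    "simulate_colony",
    "render_frame",
    "label_frame",
    "sample_cycle_records",
    "write_truth",
    "read_truth",
]


# Steady-state cell-cycle means (minutes) at the two culture temperatures.
# Doubling time = elongation + septation exactly; the 30 C pair sums to
# 129.3 min and the 25 C pair to 182.5 min, with the ~73%/26% phase split
# preserved across the shift.
CONDITION_PRESETS = {
    "30C": {"mean_elongation_time": 95.0, "mean_septation_time": 34.3},
    "25C": {"mean_elongation_time": 134.2, "mean_septation_time": 48.3},
}


@dataclass
class SimulationParams:
    """Configuration of the synthetic colony and its rendering.

    Lengths are in micrometers, times in minutes, positions/extents in
    pixels unless suffixed otherwise.  ``pixel_size`` defaults to
    0.2304 um/px (50 px = 11.52 um).
    """

    # chamber geometry
    n_lanes: int = 5
    lane_width: int = 60            # px (rows per lane)
    lane_length: int = 1500         # px (sieve at x=0, outlet at x=lane_length)
    wall_px: int = 2                # thickness of highway walls
    # imaging
    n_frames: int = 360
    frame_interval: float = 1.0     # minutes per frame
    pixel_size: float = 0.2304      # um per pixel
    # cell-cycle parameters (population means)
    mean_birth_length: float = 7.1
    mean_division_length: float = 12.9
    mean_fission_length: float = 14.2
    mean_elongation_time: float = 95.0
    mean_septation_time: float = 34.3
    cv_lengths: float = 0.10
    cv_times: float = 0.18
    division_asymmetry_sd: float = 0.0   # SD of the daughter length fraction
    cell_width_um: float = 3.5
    # septum dynamics (minutes)
    septum_appear_frac: float = 0.5      # fraction of the plateau elapsed at appearance
    septum_peak_delay: float = 30.0      # max rise time from appearance to peak
    septum_fall_time: float = 4.0        # peak -> complete disappearance
    fission_snap_time: float = 2.0       # terminal window rendered at fission length
    # rendering
    background: float = 128.0
    interior: float = 150.0
    border: float = 60.0
    border_px: float = 1.5
    wall_intensity: float = 50.0
    septum_contrast: float = 90.0
    septum_sigma_px: float = 1.5
    noise_sd: float = 5.0
    orientation_jitter_deg: float = 0.0  # static per-cell tilt SD, capped at 10 deg
    # motion
    advection_vmax: float = 1.0          # px/frame drift at the outlet (0 at sieve)
    cell_gap_px: float = 2.0             # enforced hard-core gap between cells
    # population
    initial_cells_per_lane: int = 27
    seed: int = 0

    def validate(self) -> None:
        positive = [
            ("lane_width", self.lane_width),
            ("lane_length", self.lane_length),
            ("frame_interval", self.frame_interval),
            ("pixel_size", self.pixel_size),
            ("mean_birth_length", self.mean_birth_length),
            ("mean_division_length", self.mean_division_length),
            ("mean_fission_length", self.mean_fission_length),
            ("mean_elongation_time", self.mean_elongation_time),
            ("mean_septation_time", self.mean_septation_time),
            ("cell_width_um", self.cell_width_um),
        ]
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_lanes < 1 or self.n_frames < 1:
            raise ValueError("need at least one lane and one frame")
        if not (0 <= self.cv_lengths < 1 and 0 <= self.cv_times < 1):
            raise ValueError("coefficients of variation must be in [0, 1)")
        if self.mean_fission_length < self.mean_division_length:
            raise ValueError("fission length must be >= division length")

    # -- derived helpers -------------------------------------------------
    @property
    def mean_doubling_time(self) -> float:
        return self.mean_elongation_time + self.mean_septation_time

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.n_lanes * self.lane_width, self.lane_length)

    @property
    def lane_rows(self) -> list[tuple[int, int]]:
        """Half-open row ranges of the lanes (equal partition)."""
        return [
            (i * self.lane_width, (i + 1) * self.lane_width)
            for i in range(self.n_lanes)
        ]

    def px(self, um: float) -> float:
        return um / self.pixel_size

    def um(self, px: float) -> float:
        return px * self.pixel_size


def steady_state_params(temperature: str = "30C", **overrides) -> SimulationParams:
    """Parameter preset for a steady-state culture at 30C or 25C."""
    if temperature not in CONDITION_PRESETS:
        raise ValueError(f"unknown condition {temperature!r}; use one of {sorted(CONDITION_PRESETS)}")
    kwargs = dict(CONDITION_PRESETS[temperature])
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


@dataclass
class CellState:
    """Render state of one cell in one frame."""

    cell_id: int
    lane: int
    x: float                 # centroid column, px
    y: float                 # centroid row, px (absolute in the frame)
    length_um: float
    width_um: float
    angle_deg: float = 0.0
    septum: float = 0.0      # septum band envelope in [0, 1]
    septum_pos: float = 0.5  # axial position of the band (fraction of length)


@dataclass
class CellRecord:
    """Ground-truth cycle parameters of one simulated cell."""

    cell_id: int
    parent_id: int | None
    lane: int
    birth_time: float            # minutes; negative for founders born pre-movie
    birth_length: float          # um
    division_length: float       # um (plateau length)
    fission_length: float        # um (length at separation)
    elongation_time: float       # minutes
    septation_time: float        # minutes
    fission_frame: int | None = None
    fate: str = "growing"        # growing | divided | eluted | end

    @property
    def doubling_time(self) -> float:
        return self.elongation_time + self.septation_time

    @property
    def elongation_rate(self) -> float:
        return (self.division_length - self.birth_length) / self.elongation_time


@dataclass
class GroundTruth:
    """Everything the simulator knows about a rendered movie."""

    params: SimulationParams
    cells: dict[int, CellRecord] = field(default_factory=dict)
    trajectories: list[tuple] = field(default_factory=list)
    divisions: list[tuple[int, int, int, int]] = field(default_factory=list)
    frame_states: list[list[CellState]] = field(default_factory=list)

    def trajectories_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.trajectories,
            columns=["frame", "cell_id", "lane", "x", "y", "length_um", "width_um", "septum"],
        )

    def divisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.divisions, columns=["parent_id", "frame", "daughter_a", "daughter_b"]
        )

    def cells_frame(self) -> pd.DataFrame:
        cols = ["cell_id", "parent_id", "lane", "birth_time", "birth_length",
                "division_length", "fission_length", "elongation_time",
                "septation_time", "fission_frame", "fate",
                "doubling_time", "elongation_rate"]
        rows = []
        for rec in self.cells.values():
            d = asdict(rec)
            d["doubling_time"] = rec.doubling_time
            d["elongation_rate"] = rec.elongation_rate
            rows.append(d)
        return pd.DataFrame(rows, columns=cols)

    def label_mask(self, frame: int) -> np.ndarray:
        """Labeled (cell_id) mask of a frame, rendered on demand."""
        return label_frame(self.frame_states[frame], self.params)

    # -- lineage forest ---------------------------------------------------
    def children(self) -> dict[int, tuple[int, int]]:
        return {p: (a, b) for p, _f, a, b in self.divisions}

    def roots(self) -> list[int]:
        kids = {c for _p, _f, a, b in self.divisions for c in (a, b)}
        return [cid for cid in self.cells if cid not in kids]

    def forest_edges(self) -> set[tuple[int, int]]:
        return {(p, c) for p, _f, a, b in self.divisions for c in (a, b)}

    @property
    def n_divisions(self) -> int:
        return len(self.divisions)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _paint_cell(img: np.ndarray, s: CellState, p: SimulationParams) -> None:
    l_px = p.px(s.length_um)
    w_px = p.px(s.width_um)
    r = w_px / 2.0
    half = l_px / 2.0
    seg = max(half - r, 0.0)

    pad = r + 2.0
    c0 = max(int(math.floor(s.x - half - pad)), 0)
    c1 = min(int(math.ceil(s.x + half + pad)) + 1, img.shape[1])
    r0 = max(int(math.floor(s.y - half - pad)), 0)
    r1 = min(int(math.ceil(s.y + half + pad)) + 1, img.shape[0])
    if c1 <= c0 or r1 <= r0:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    dx = xx - s.x
    dy = yy - s.y
    if s.angle_deg:
        th = math.radians(s.angle_deg)
        dxr = dx * math.cos(th) + dy * math.sin(th)
        dyr = -dx * math.sin(th) + dy * math.cos(th)
    else:
        dxr, dyr = dx, dy
    ax = np.abs(dxr) - seg
    np.clip(ax, 0.0, None, out=ax)
    d = np.hypot(ax, dyr)

    cov_out = np.clip(r + 0.5 - d, 0.0, 1.0)       # inside the capsule
    cov_in = np.clip(r - p.border_px + 0.5 - d, 0.0, 1.0)  # interior zone
    patch = img[r0:r1, c0:c1]
    cell_val = p.border * cov_out + (p.interior - p.border) * cov_in
    patch *= 1.0 - cov_out
    patch += cell_val
    if s.septum > 0:
        t = dxr - (s.septum_pos - 0.5) * l_px
        band = s.septum * p.septum_contrast * np.exp(
            -(t ** 2) / (2.0 * p.septum_sigma_px ** 2)
        )
        patch += band * cov_in


def render_frame(states: list[CellState], params: SimulationParams,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one frame (uint8) from explicit cell states.

    Deterministic for ``noise_sd == 0``; otherwise ``rng`` supplies the
    additive Gaussian noise (a fresh seeded generator is used if omitted).
    """
    p = params
    H, W = p.frame_shape
    img = np.full((H, W), p.background, dtype=np.float64)
    # highway walls: chamber edges and internal lane boundaries
    wall_rows: list[int] = list(range(p.wall_px)) + list(range(H - p.wall_px, H))
    for b in range(1, p.n_lanes):
        rb = b * p.lane_width
        wall_rows.extend(range(rb - p.wall_px // 2 - 1, rb + (p.wall_px + 1) // 2))
    img[sorted(set(wall_rows)), :] = p.wall_intensity
    for s in states:
        _paint_cell(img, s, p)
    if p.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(p.seed)
        img += rng.normal(0.0, p.noise_sd, size=img.shape)
    np.clip(img, 0, 255, out=img)
    return img.astype(np.uint8)


def label_frame(states: list[CellState], params: SimulationParams) -> np.ndarray:
    """Ground-truth labeled mask (cell_id per pixel) for one frame."""
    p = params
    H, W = p.frame_shape
    lab = np.zeros((H, W), dtype=np.uint32)
    for s in states:
        l_px = p.px(s.length_um)
        w_px = p.px(s.width_um)
        r = w_px / 2.0
        seg = max(l_px / 2.0 - r, 0.0)
        pad = r + 1.0
        c0 = max(int(math.floor(s.x - l_px / 2 - pad)), 0)
        c1 = min(int(math.ceil(s.x + l_px / 2 + pad)) + 1, W)
        r0 = max(int(math.floor(s.y - l_px / 2 - pad)), 0)
        r1 = min(int(math.ceil(s.y + l_px / 2 + pad)) + 1, H)
        yy, xx = np.mgrid[r0:r1, c0:c1].astype(np.float64)
        dx = xx - s.x
        dy = yy - s.y
        if s.angle_deg:
            th = math.radians(s.angle_deg)
            dxr = dx * math.cos(th) + dy * math.sin(th)
            dyr = -dx * math.sin(th) + dy * math.cos(th)
        else:
            dxr, dyr = dx, dy
        ax = np.clip(np.abs(dxr) - seg, 0.0, None)
        inside = np.hypot(ax, dyr) < r
        lab[r0:r1, c0:c1][inside] = s.cell_id
    return lab


# ---------------------------------------------------------------------------
# colony simulation
# ---------------------------------------------------------------------------

class _Cell:
    """Mutable simulation state of a live cell."""

    __slots__ = ("rec", "x", "y", "angle", "width_um")

    def __init__(self, rec: CellRecord, x: float, y: float, angle: float, width_um: float):
        self.rec = rec
        self.x = x
        self.y = y
        self.angle = angle
        self.width_um = width_um

    def age(self, t_min: float) -> float:
        return t_min - self.rec.birth_time

    def length_at(self, t_min: float, p: SimulationParams) -> float:
        r = self.rec
        a = self.age(t_min)
        T = r.doubling_time
        if a >= T - p.fission_snap_time:
            return r.fission_length
        if a >= r.elongation_time:
            return r.division_length
        return r.birth_length + r.elongation_rate * max(a, 0.0)

    def septum_env(self, t_min: float, p: SimulationParams) -> float:
        r = self.rec
        a = self.age(t_min)
        T = r.doubling_time
        appear = r.elongation_time + p.septum_appear_frac * r.septation_time
        peak = T - p.septum_fall_time
        if a < appear or a >= T:
            return 0.0
        if a >= peak:
            return max((T - a) / max(p.septum_fall_time, 1e-9), 0.0)
        rise = min(p.septum_peak_delay, peak - appear)
        start = peak - rise
        if a < start:
            return 0.0
        return min((a - start) / max(rise, 1e-9), 1.0)


def _draw_cycle(p: SimulationParams, rng: np.random.Generator,
                birth_length: float) -> tuple[float, float, float, float]:
    """Draw (division_length, fission_length, elongation_time, septation_time)."""
    ratio = p.mean_fission_length / p.mean_division_length
    ld = rng.normal(p.mean_division_length, p.cv_lengths * p.mean_division_length)
    ld = max(ld, birth_length * 1.25, 2.0)
    lf = ld * ratio
    te = max(rng.normal(p.mean_elongation_time, p.cv_times * p.mean_elongation_time), 5.0)
    ts = max(rng.normal(p.mean_septation_time, p.cv_times * p.mean_septation_time), 6.0)
    return ld, lf, te, ts


def _lane_center_row(lane: int, p: SimulationParams) -> float:
    return lane * p.lane_width + p.lane_width / 2.0


def _new_cell(p: SimulationParams, rng, cell_id: int, parent: int | None, lane: int,
              birth_time: float, birth_length: float, x: float) -> _Cell:
    ld, lf, te, ts = _draw_cycle(p, rng, birth_length)
    rec = CellRecord(
        cell_id=cell_id, parent_id=parent, lane=lane, birth_time=birth_time,
        birth_length=birth_length, division_length=ld, fission_length=lf,
        elongation_time=te, septation_time=ts,
    )
    width = max(p.cell_width_um * (1.0 + 0.03 * rng.standard_normal()), 1.5)
    y_jit = float(np.clip(rng.normal(0.0, 1.5), -3.0, 3.0))
    angle = 0.0
    if p.orientation_jitter_deg > 0:
        angle = float(np.clip(rng.normal(0.0, p.orientation_jitter_deg), -10.0, 10.0))
    return _Cell(rec, x, _lane_center_row(lane, p) + y_jit, angle, width)


def simulate_colony(params: SimulationParams) -> tuple[np.ndarray, GroundTruth]:
    """Simulate a steady-state colony and render the full movie.

    Returns the image stack (frames, H, W; uint8) and the ground truth.
    Identical ``params`` (including ``seed``) give bit-identical output.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)
    truth = GroundTruth(params=p)
    next_id = 1
    lanes: list[list[_Cell]] = [[] for _ in range(p.n_lanes)]

    # founders: packed from the sieve end, random cycle phase
    for lane in range(p.n_lanes):
        x_cursor = 4.0
        for _ in range(p.initial_cells_per_lane):
            lb = max(rng.normal(p.mean_birth_length, p.cv_lengths * p.mean_birth_length), 2.0)
            cell = _new_cell(p, rng, next_id, None, lane, 0.0, lb, 0.0)
            next_id += 1
            phase = rng.uniform(0.0, 0.97)
            cell.rec.birth_time = -phase * cell.rec.doubling_time
            length = cell.length_at(0.0, p)
            half_px = p.px(length) / 2.0
            cell.x = x_cursor + half_px
            x_cursor = cell.x + half_px + p.cell_gap_px
            if cell.x + half_px > p.lane_length - 4:
                break
            lanes[lane].append(cell)
            truth.cells[cell.rec.cell_id] = cell.rec

    stack = np.empty((p.n_frames,) + p.frame_shape, dtype=np.uint8)

    for f in range(p.n_frames):
        t_min = f * p.frame_interval
        # 1. divisions
        for lane in range(p.n_lanes):
            newlane: list[_Cell] = []
            for cell in lanes[lane]:
                if cell.age(t_min) >= cell.rec.doubling_time:
                    r = cell.rec
                    r.fate = "divided"
                    r.fission_frame = f
                    frac = 0.5
                    if p.division_asymmetry_sd > 0:
                        frac = float(np.clip(rng.normal(0.5, p.division_asymmetry_sd), 0.35, 0.65))
                    la = frac * r.fission_length
                    lb = r.fission_length - la
                    lf_px = p.px(r.fission_length)
                    da = _new_cell(p, rng, next_id, r.cell_id, lane, t_min, la,
                                   cell.x - lf_px / 2.0 + p.px(la) / 2.0)
                    db = _new_cell(p, rng, next_id + 1, r.cell_id, lane, t_min, lb,
                                   cell.x + lf_px / 2.0 - p.px(lb) / 2.0)
                    next_id += 2
                    truth.cells[da.rec.cell_id] = da.rec
                    truth.cells[db.rec.cell_id] = db.rec
                    truth.divisions.append((r.cell_id, f, da.rec.cell_id, db.rec.cell_id))
                    newlane.extend([da, db])
                else:
                    newlane.append(cell)
            lanes[lane] = newlane

        # 2. advection + hard-core packing + elution
        for lane in range(p.n_lanes):
            cells = sorted(lanes[lane], key=lambda c: c.x)
            cursor = 2.0
            survivors: list[_Cell] = []
            for cell in cells:
                cell.x += p.advection_vmax * max(cell.x, 0.0) / p.lane_length
                half_px = p.px(cell.length_at(t_min, p)) / 2.0
                min_x = cursor + half_px
                if cell.x < min_x:
                    cell.x = min_x
                cursor = cell.x + half_px + p.cell_gap_px
                if cell.x + half_px > p.lane_length - 3:
                    cell.rec.fate = "eluted"
                    continue
                survivors.append(cell)
            lanes[lane] = survivors

        # 3. record truth + render
        states: list[CellState] = []
        for lane in range(p.n_lanes):
            for cell in lanes[lane]:
                length = cell.length_at(t_min, p)
                env = cell.septum_env(t_min, p)
                states.append(CellState(
                    cell_id=cell.rec.cell_id, lane=lane, x=cell.x, y=cell.y,
                    length_um=length, width_um=cell.width_um,
                    angle_deg=cell.angle, septum=env,
                ))
                truth.trajectories.append(
                    (f, cell.rec.cell_id, lane, cell.x, cell.y, length, cell.width_um, env)
                )
        truth.frame_states.append(states)
        stack[f] = render_frame(states, p, rng)

    for lane_cells in lanes:
        for cell in lane_cells:
            if cell.rec.fate == "growing":
                cell.rec.fate = "end"
    return stack, truth


# ---------------------------------------------------------------------------
# cycle-parameter sampler (no imaging)
# ---------------------------------------------------------------------------

def sample_cycle_records(params: SimulationParams, n: int, seed: int | None = None,
                         birth_division_slope: float | None = None) -> pd.DataFrame:
    """Draw ``n`` per-cycle growth records straight from the generative model.

    With ``birth_division_slope=None`` the division length is drawn
    independently of birth length (the generator's default, i.e. a pure
    sizer with no birth-length memory).  A float installs a linear
    dependence ``division = mean_div + slope*(birth - mean_birth) + noise``
    with the same residual scatter, for testing regression recovery.
    """
    p = params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    birth = rng.normal(p.mean_birth_length, p.cv_lengths * p.mean_birth_length, n)
    resid = rng.normal(0.0, p.cv_lengths * p.mean_division_length, n)
    if birth_division_slope is None:
        division = p.mean_division_length + resid
    else:
        division = (p.mean_division_length
                    + birth_division_slope * (birth - p.mean_birth_length) + resid)
    division = np.maximum(division, birth * 1.1)
    fission = division * (p.mean_fission_length / p.mean_division_length)
    te = np.maximum(rng.normal(p.mean_elongation_time, p.cv_times * p.mean_elongation_time, n), 5.0)
    ts = np.maximum(rng.normal(p.mean_septation_time, p.cv_times * p.mean_septation_time, n), 6.0)
    return pd.DataFrame({
        "birth_length": birth,
        "division_length": division,
        "fission_length": fission,
        "elongation_time": te,
        "septation_time": ts,
        "doubling_time": te + ts,
        "elongation_rate": (division - birth) / te,
    })


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def _newick_of(root: int, children: dict[int, tuple[int, int]]) -> str:
    a_b = children.get(root)
    if a_b is None:
        return str(root)
    a, b = a_b
    return f"({_newick_of(a, children)},{_newick_of(b, children)}){root}"


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write trajectories/divisions/cells CSVs, a Newick lineage forest and
    a flat key=value parameter echo under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.trajectories_frame().to_csv(path / "trajectories.csv", index=False)
    truth.divisions_frame().to_csv(path / "divisions.csv", index=False)
    truth.cells_frame().to_csv(path / "cells.csv", index=False)
    children = truth.children()
    with open(path / "lineage.nwk", "w") as fh:
        for root in sorted(truth.roots()):
            fh.write(_newick_of(root, children) + ";\n")
    with open(path / "params.txt", "w") as fh:
        for key, value in asdict(truth.params).items():
            fh.write(f"{key}={value}\n")


def read_truth(path: str | Path) -> dict:
    """Read back truth tables and lineage topology written by write_truth."""
    import dendropy

    path = Path(path)
    out = {
        "trajectories": pd.read_csv(path / "trajectories.csv"),
        "divisions": pd.read_csv(path / "divisions.csv"),
        "cells": pd.read_csv(path / "cells.csv"),
    }
    edges: set[tuple[int, int]] = set()
    text = (path / "lineage.nwk").read_text().strip()
    if text:
        trees = dendropy.TreeList.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=False)
        def _label(nd):
            return nd.taxon.label if nd.taxon is not None else nd.label

        for tree in trees:
            for node in tree.preorder_node_iter():
                if node.parent_node is not None:
                    edges.add((int(_label(node.parent_node)), int(_label(node))))
    out["forest_edges"] = edges
    params = {}
    for line in (path / "params.txt").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            params[k] = v
    out["params"] = params
    return out
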