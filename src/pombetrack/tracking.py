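"""Two-tier frame-to-frame cell tracking.

Cells are matched frame ``n`` to ``n+1`` with a fast greedy local scorer
(weighted sum of centroid distance, |dx|, |dy|, normalized area difference
and angular difference).  A candidate pair is accepted only if its score is
below a threshold (65), the contours overlap, and the areas differ by at
most 40%; cells beyond a single cell length (50 px) score infinite.  If a
transition leaves too many cells unpaired (>30) or the mean displacement
exceeds a threshold, the transition is redone with a global
linear-assignment tracker (length difference, max-normalized area
difference and displacement terms), with position-dependent minimal
displacement constraints and a single re-run with enlarged constraints
when pairing is poor and the mean displacement exceeds 8 px.

Observations failing every gate are deliberately left unpaired: a missed
link is cheaper than a propagated wrong identity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .segmentation import CellObservation

__all__ = [
    "TrackerConfig",
    "PairingResult",
    "TrackMatrix",
    "local_score",
    "match_local",
    "needs_global_fallback",
    "global_score",
    "match_global",
    "brute_force_assignment",
    "track_movie",
]

_BIG = 1e12  # forbidden-pair cost (linear_sum_assignment rejects inf)


@dataclass
class TrackerConfig:
    # local scorer weights: (distance, |dx|, |dy|, normalized area diff, angle diff)
    local_weights: tuple = (1.0, 0.5, 0.5, 20.0, 0.5)
    local_score_threshold: float = 65.0
    max_displacement: float = 50.0        # px; one cell length
    max_area_change: float = 0.40         # relative, |dA| / max(A)
    fallback_unpaired_threshold: int = 30
    fallback_mean_displacement: float = 8.0   # px
    # global scorer weights: (length diff px, normalized area diff, displacement px)
    global_weights: tuple = (1.0, 20.0, 1.0)
    min_displacement_ramp_max: float = 0.0    # px at the outlet; 0 disables
    lane_length_px: float | None = None       # needed for the position ramp
    global_no_match_cost: float | None = None # None: auto from cost percentile
    global_rerun_mean_displacement: float = 8.0
    rerun_min_paired_fraction: float = 0.5
    rerun_ramp_scale: float = 2.0
    reseed_interval: int = 50
    pixel_size: float = 0.2304

    def validate(self) -> None:
        if not 0 < self.max_area_change < 1:
            raise ValueError("max_area_change must be in (0, 1)")
        for name in ("local_score_threshold", "max_displacement",
                     "fallback_mean_displacement", "reseed_interval"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if any(w < 0 for w in self.local_weights + self.global_weights):
            raise ValueError("score weights must be non-negative")


@dataclass
class PairingResult:
    pairs: list[tuple[int, int, float]]      # (obs id in n, obs id in n+1, score)
    unpaired_n: list[int]
    unpaired_n1: list[int]
    tracker: str                             # "local" | "global"
    mean_displacement: float                 # px, over matched pairs
    reruns: int = 0


def _angle_diff(a: float, b: float) -> float:
    """Acute angle between two orientations, in [0, 90] degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def _rel_area_diff(a: CellObservation, b: CellObservation) -> float:
    return abs(a.area - b.area) / max(a.area, b.area)


def local_score(a: CellObservation, b: CellObservation, cfg: TrackerConfig) -> float:
    """Local pairing score; infinite beyond the displacement gate, 0 at identity."""
    dx = b.centroid[0] - a.centroid[0]
    dy = b.centroid[1] - a.centroid[1]
    dist = math.hypot(dx, dy)
    if dist > cfg.max_displacement:
        return math.inf
    w = cfg.local_weights
    return (w[0] * dist + w[1] * abs(dx) + w[2] * abs(dy)
            + w[3] * _rel_area_diff(a, b)
            + w[4] * _angle_diff(a.orientation_deg, b.orientation_deg))


def match_local(frame_n: list[CellObservation], frame_n1: list[CellObservation],
                cfg: TrackerConfig) -> PairingResult:
    """Greedy ascending-score local matching with the three acceptance gates."""
    candidates: list[tuple[float, float, int, int]] = []
    if frame_n and frame_n1:
        pts1 = np.array([o.centroid for o in frame_n1])
        tree = cKDTree(pts1)
        for i, a in enumerate(frame_n):
            for j in tree.query_ball_point(a.centroid, cfg.max_displacement + 1e-9):
                b = frame_n1[j]
                s = local_score(a, b, cfg)
                if math.isfinite(s):
                    d = math.hypot(b.centroid[0] - a.centroid[0],
                                   b.centroid[1] - a.centroid[1])
                    candidates.append((s, d, i, j))
    candidates.sort(key=lambda t: (t[0], t[1], frame_n[t[2]].id, frame_n1[t[3]].id))
    used_n: set[int] = set()
    used_n1: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    disps: list[float] = []
    for s, d, i, j in candidates:
        if i in used_n or j in used_n1:
            continue
        if s >= cfg.local_score_threshold:
            continue
        a, b = frame_n[i], frame_n1[j]
        if _rel_area_diff(a, b) > cfg.max_area_change:
            continue
        if not a.overlaps(b):
            continue
        used_n.add(i)
        used_n1.add(j)
        pairs.append((a.id, b.id, s))
        disps.append(d)
    return PairingResult(
        pairs=pairs,
        unpaired_n=[o.id for i, o in enumerate(frame_n) if i not in used_n],
        unpaired_n1=[o.id for j, o in enumerate(frame_n1) if j not in used_n1],
        tracker="local",
        mean_displacement=float(np.mean(disps)) if disps else 0.0,
    )


def needs_global_fallback(res: PairingResult, cfg: TrackerConfig) -> bool:
    """True iff too many cells were left unpaired (>30) or the mean
    displacement exceeded the fallback threshold."""
    return (len(res.unpaired_n) > cfg.fallback_unpaired_threshold
            or res.mean_displacement > cfg.fallback_mean_displacement)


def global_score(a: CellObservation, b: CellObservation, cfg: TrackerConfig) -> float:
    """Global-assignment pair score: length difference (px), max-normalized
    area difference and displacement; 0 for identical observations."""
    w = cfg.global_weights
    dlen = abs(a.length_um - b.length_um) / cfg.pixel_size
    dist = math.hypot(b.centroid[0] - a.centroid[0], b.centroid[1] - a.centroid[1])
    return w[0] * dlen + w[1] * _rel_area_diff(a, b) + w[2] * dist


def _min_displacement(x: float, cfg: TrackerConfig, scale: float) -> float:
    if cfg.min_displacement_ramp_max <= 0 or not cfg.lane_length_px:
        return 0.0
    return scale * cfg.min_displacement_ramp_max * max(x, 0.0) / cfg.lane_length_px


def _global_cost_matrix(frame_n, frame_n1, cfg, ramp_scale):
    n, m = len(frame_n), len(frame_n1)
    cost = np.full((n, m), _BIG)
    for i, a in enumerate(frame_n):
        for j, b in enumerate(frame_n1):
            dist = math.hypot(b.centroid[0] - a.centroid[0],
                              b.centroid[1] - a.centroid[1])
            if dist > cfg.max_displacement:
                continue
            if dist < _min_displacement(a.centroid[0], cfg, ramp_scale):
                continue
            cost[i, j] = global_score(a, b, cfg)
    return cost


def _no_match_cost(cost: np.ndarray, cfg: TrackerConfig) -> float:
    if cfg.global_no_match_cost is not None:
        return cfg.global_no_match_cost
    finite = cost[cost < _BIG / 2]
    if finite.size == 0:
        return 1.0
    return 1.05 * float(np.percentile(finite, 90)) + 1e-9


def _solve_lap(cost: np.ndarray, b: float) -> list[tuple[int, int]]:
    """Minimize sum of matched costs + b per unmatched cell (either frame)."""
    n, m = cost.shape
    aug = np.zeros((n + m, n + m))
    aug[:n, :m] = cost
    aug[:n, m:] = _BIG
    aug[n:, :m] = _BIG
    np.fill_diagonal(aug[:n, m:], b)   # cell in n left unmatched
    np.fill_diagonal(aug[n:, :m], b)   # cell in n+1 left unmatched
    aug[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(aug)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and cost[r, c] < _BIG / 2:
            out.append((r, c))
    return out


def match_global(frame_n: list[CellObservation], frame_n1: list[CellObservation],
                 cfg: TrackerConfig) -> PairingResult:
    """Linear-assignment matching minimizing the total global score.

    Each cell may instead stay unmatched at a fixed alternative cost.
    Pairs violating the displacement gates are forbidden.  If the paired
    fraction is poor and the mean displacement of paired cells exceeds
    ``global_rerun_mean_displacement`` (8 px), the tracker is re-run once
    with enlarged minimal-displacement constraints.
    """
    if not frame_n or not frame_n1:
        return PairingResult([], [o.id for o in frame_n], [o.id for o in frame_n1],
                             "global", 0.0)

    def run(scale: float):
        cost = _global_cost_matrix(frame_n, frame_n1, cfg, scale)
        b = _no_match_cost(cost, cfg)
        idx_pairs = _solve_lap(cost, b)
        disps = [math.hypot(frame_n1[j].centroid[0] - frame_n[i].centroid[0],
                            frame_n1[j].centroid[1] - frame_n[i].centroid[1])
                 for i, j in idx_pairs]
        return cost, idx_pairs, (float(np.mean(disps)) if disps else 0.0)

    cost, idx_pairs, mean_disp = run(1.0)
    reruns = 0
    frac = len(idx_pairs) / max(min(len(frame_n), len(frame_n1)), 1)
    if (frac < cfg.rerun_min_paired_fraction
            and mean_disp > cfg.global_rerun_mean_displacement):
        cost, idx_pairs, mean_disp = run(cfg.rerun_ramp_scale)
        reruns = 1

    used_n = {i for i, _ in idx_pairs}
    used_n1 = {j for _, j in idx_pairs}
    return PairingResult(
        pairs=[(frame_n[i].id, frame_n1[j].id, float(cost[i, j])) for i, j in idx_pairs],
        unpaired_n=[o.id for i, o in enumerate(frame_n) if i not in used_n],
        unpaired_n1=[o.id for j, o in enumerate(frame_n1) if j not in used_n1],
        tracker="global",
        mean_displacement=mean_disp,
        reruns=reruns,
    )


def brute_force_assignment(frame_n, frame_n1, cfg) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive minimal-total-score assignment (oracle for small frames).

    Enumerates every one-to-one partial pairing; the objective is the sum
    of pair scores plus the no-match alternative for every unmatched cell,
    exactly as in :func:`match_global`.  Only feasible for tiny frames.
    """
    cost = _global_cost_matrix(frame_n, frame_n1, cfg, 1.0)
    b = _no_match_cost(cost, cfg)
    n, m = cost.shape
    best: tuple[float, list[tuple[int, int]]] = (b * (n + m), [])
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                total = 0.0
                ok = True
                for r, c in zip(rows, cols):
                    if cost[r, c] >= _BIG / 2:
                        ok = False
                        break
                    total += cost[r, c]
                if not ok:
                    continue
                total += b * ((n - k) + (m - k))
                if total < best[0] - 1e-12:
                    best = (total, list(zip(rows, cols)))
    return best[1], best[0]


# ---------------------------------------------------------------------------
# track matrix
# ---------------------------------------------------------------------------

@dataclass
class TrackMatrix:
    """Observations linked into temporally contiguous tracks."""

    observations: dict[int, CellObservation] = field(default_factory=dict)
    tracks: dict[int, list[int]] = field(default_factory=dict)   # tid -> obs ids
    obs_track: dict[int, int] = field(default_factory=dict)      # obs id -> tid
    reseed_events: list[tuple[int, list[int]]] = field(default_factory=list)
    transitions: list[dict] = field(default_factory=list)
    links: list[tuple[int, int]] = field(default_factory=list)   # accepted pairs

    def track_frames(self, tid: int) -> np.ndarray:
        return np.array([self.observations[o].frame for o in self.tracks[tid]])

    def track_lengths(self, tid: int) -> np.ndarray:
        return np.array([self.observations[o].length_um for o in self.tracks[tid]])

    def track_profiles(self, tid: int) -> list[np.ndarray]:
        return [self.observations[o].profile for o in self.tracks[tid]]

    def start_frame(self, tid: int) -> int:
        return self.observations[self.tracks[tid][0]].frame

    def end_frame(self, tid: int) -> int:
        return self.observations[self.tracks[tid][-1]].frame

    def first_obs(self, tid: int) -> CellObservation:
        return self.observations[self.tracks[tid][0]]

    def last_obs(self, tid: int) -> CellObservation:
        return self.observations[self.tracks[tid][-1]]

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


def track_movie(frames: list[list[CellObservation]], cfg: TrackerConfig | None = None,
                force_global: bool = False) -> TrackMatrix:
    """Link per-frame observations into tracks.

    Local matching first; the global tracker replaces a transition when
    :func:`needs_global_fallback` fires (or always, with ``force_global``).
    Global pairs are post-gated on relative area change so that division
    splits terminate the parent track.  Observations with no accepted
    predecessor start new tracks; new tracks born on a reseed boundary
    (every ``reseed_interval`` frames) are recorded as reseed events.
    """
    cfg = cfg or TrackerConfig()
    cfg.validate()
    mat = TrackMatrix()
    if not frames:
        return mat
    next_tid = 1

    def start_track(obs: CellObservation) -> int:
        nonlocal next_tid
        tid = next_tid
        next_tid += 1
        mat.tracks[tid] = [obs.id]
        mat.obs_track[obs.id] = tid
        return tid

    for obs in frames[0]:
        mat.observations[obs.id] = obs
    new0 = [start_track(o) for o in frames[0]]
    if new0:
        mat.reseed_events.append((0, new0))

    for f in range(len(frames) - 1):
        cur, nxt = frames[f], frames[f + 1]
        for obs in nxt:
            mat.observations[obs.id] = obs
        res = match_local(cur, nxt, cfg)
        if force_global or needs_global_fallback(res, cfg):
            gres = match_global(cur, nxt, cfg)
            by_id = {o.id: o for o in cur + nxt}
            kept = [(a, b, s) for a, b, s in gres.pairs
                    if _rel_area_diff(by_id[a], by_id[b]) <= cfg.max_area_change]
            dropped_a = {a for a, b, s in gres.pairs} - {a for a, b, s in kept}
            dropped_b = {b for a, b, s in gres.pairs} - {b for a, b, s in kept}
            res = PairingResult(
                pairs=kept,
                unpaired_n=gres.unpaired_n + sorted(dropped_a),
                unpaired_n1=gres.unpaired_n1 + sorted(dropped_b),
                tracker="global",
                mean_displacement=gres.mean_displacement,
                reruns=gres.reruns,
            )
        paired_next = set()
        for a_id, b_id, _s in res.pairs:
            tid = mat.obs_track[a_id]
            mat.tracks[tid].append(b_id)
            mat.obs_track[b_id] = tid
            mat.links.append((a_id, b_id))
            paired_next.add(b_id)
        new_tids = [start_track(o) for o in nxt if o.id not in paired_next]
        if new_tids and (f + 1) % cfg.reseed_interval == 0:
            mat.reseed_events.append((f + 1, new_tids))
        mat.transitions.append({
            "frame": f,
            "tracker": res.tracker,
            "mean_displacement": res.mean_displacement,
            "n_pairs": len(res.pairs),
            "n_unpaired_n": len(res.unpaired_n),
            "n_unpaired_n1": len(res.unpaired_n1),
            "reruns": res.reruns,
        })
    return mat
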