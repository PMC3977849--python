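"""Pipeline validation against simulator ground truth.

Observations are matched to ground-truth cells by nearest same-frame
centroid; tracking links, division calls, lineage edges and per-cycle
parameter estimates are then scored against the truth tables, playing the
role of the manual annotation used to benchmark the original platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .divisions import DivisionEvent
from .growth import PARAMETERS
from .lineage import LineageTree
from .synthetic import GroundTruth
from .tracking import TrackMatrix

__all__ = ["ValidationReport", "match_observations", "validate_against_truth"]

TRUTH_PARAM_COLS = {
    "birth_length": "birth_length",
    "division_length": "division_length",
    "fission_length": "fission_length",
    "elongation_time": "elongation_time",
    "septation_time": "septation_time",
    "doubling_time": "doubling_time",
    "elongation_rate": "elongation_rate",
}


@dataclass
class ValidationReport:
    n_truth_divisions: int
    n_called_divisions: int
    division_recall: float
    division_precision: float
    n_links: int
    n_false_links: int
    false_link_rate: float
    lineage_edge_agreement: float
    parameter_means_measured: dict
    parameter_means_truth: dict
    parameter_mean_rel_error: dict
    n_records: int

    def as_dict(self) -> dict:
        return {
            "n_truth_divisions": self.n_truth_divisions,
            "n_called_divisions": self.n_called_divisions,
            "division_recall": self.division_recall,
            "division_precision": self.division_precision,
            "n_links": self.n_links,
            "n_false_links": self.n_false_links,
            "false_link_rate": self.false_link_rate,
            "lineage_edge_agreement": self.lineage_edge_agreement,
            "parameter_means_measured": self.parameter_means_measured,
            "parameter_means_truth": self.parameter_means_truth,
            "parameter_mean_rel_error": self.parameter_mean_rel_error,
            "n_records": self.n_records,
        }


def match_observations(frames_obs, truth: GroundTruth,
                       max_dist: float = 8.0) -> dict[int, int]:
    """Map observation id -> ground-truth cell id by same-frame nearest
    centroid (within ``max_dist`` px)."""
    traj = truth.trajectories_frame()
    mapping: dict[int, int] = {}
    for f, group in traj.groupby("frame"):
        f = int(f)
        if f >= len(frames_obs) or not frames_obs[f]:
            continue
        pts = group[["x", "y"]].to_numpy(dtype=float)
        ids = group["cell_id"].to_numpy()
        tree = cKDTree(pts)
        for obs in frames_obs[f]:
            d, i = tree.query(obs.centroid)
            if d <= max_dist:
                mapping[obs.id] = int(ids[i])
    return mapping


def _track_truth_id(matrix: TrackMatrix, tid: int, obs2cell: dict[int, int]) -> int | None:
    """Majority ground-truth cell over a track's observations."""
    votes: dict[int, int] = {}
    for oid in matrix.tracks[tid]:
        c = obs2cell.get(oid)
        if c is not None:
            votes[c] = votes.get(c, 0) + 1
    if not votes:
        return None
    return max(votes.items(), key=lambda kv: kv[1])[0]


def validate_against_truth(matrix: TrackMatrix, events: list[DivisionEvent],
                           forest: list[LineageTree], records: pd.DataFrame,
                           frames_obs, truth: GroundTruth,
                           division_frame_tol: int = 2,
                           edge_margin: int = 2) -> ValidationReport:
    """Score a full analysis against the simulator's ground truth.

    Division recall/precision use a parent-identity + frame-tolerance
    match, excluding truth divisions within ``edge_margin`` frames of the
    movie end (their daughters are not observable).  The false-link rate
    is the fraction of accepted frame-to-frame links whose two
    observations belong to different ground-truth cells.  Parameter
    errors compare the mean of each measured growth parameter with the
    ground-truth mean over the same matched cycles.
    """
    obs2cell = match_observations(frames_obs, truth)
    n_frames = truth.params.n_frames

    # --- links ---------------------------------------------------------
    n_links = len(matrix.links)
    n_false = 0
    for a_id, b_id in matrix.links:
        ca, cb = obs2cell.get(a_id), obs2cell.get(b_id)
        if ca is None or cb is None or ca != cb:
            n_false += 1

    # --- divisions -----------------------------------------------------
    truth_divs = [(p, f) for p, f, _a, _b in truth.divisions
                  if f <= n_frames - 1 - edge_margin]
    track2cell = {tid: _track_truth_id(matrix, tid, obs2cell)
                  for tid in matrix.tracks}
    # the pipeline's emitted division set: calls whose daughters were
    # linked; unlinked calls are filtered downstream.  Calls inside the
    # movie-end margin are excluded symmetrically with the truth side.
    called = [(track2cell.get(ev.parent_track), ev.frame) for ev in events
              if ev.daughters and ev.frame <= n_frames - 1 - edge_margin]
    truth_by_parent: dict[int, list[int]] = {}
    for p, f in truth_divs:
        truth_by_parent.setdefault(p, []).append(f)
    matched_truth = set()
    n_correct_calls = 0
    for cell, f in called:
        ok = False
        if cell is not None:
            for tf in truth_by_parent.get(cell, ()):
                if abs(tf - f) <= division_frame_tol and (cell, tf) not in matched_truth:
                    matched_truth.add((cell, tf))
                    ok = True
                    break
        n_correct_calls += int(ok)
    recall = len(matched_truth) / len(truth_divs) if truth_divs else 1.0
    precision = n_correct_calls / len(called) if called else 1.0

    # --- lineage edges -------------------------------------------------
    truth_edges = truth.forest_edges()
    pred_edges = set()
    for tree in forest:
        for node in tree.root.walk():
            for ch in node.children:
                pc = track2cell.get(node.track_id)
                cc = track2cell.get(ch.track_id)
                if pc is not None and cc is not None:
                    pred_edges.add((pc, cc))
    edge_agree = (len(pred_edges & truth_edges) / len(pred_edges)
                  if pred_edges else 1.0)

    # --- parameters ----------------------------------------------------
    cells_df = truth.cells_frame()
    meas_means: dict[str, float] = {}
    truth_means: dict[str, float] = {}
    rel_err: dict[str, float] = {}
    n_rec = len(records)
    if n_rec:
        cell_ids = records["track_id"].map(track2cell)
        merged = records.assign(cell_id=cell_ids).dropna(subset=["cell_id"])
        merged = merged.merge(cells_df, left_on="cell_id", right_on="cell_id",
                              suffixes=("", "_truth"))
        for par in PARAMETERS:
            tvals = merged[par + "_truth"] if par + "_truth" in merged.columns \
                else merged[par]
            mvals = merged[par]
            meas_means[par] = float(mvals.mean())
            truth_means[par] = float(tvals.mean())
            rel_err[par] = abs(meas_means[par] - truth_means[par]) / abs(truth_means[par])

    return ValidationReport(
        n_truth_divisions=len(truth_divs),
        n_called_divisions=len(called),
        division_recall=recall,
        division_precision=precision,
        n_links=n_links,
        n_false_links=n_false,
        false_link_rate=n_false / n_links if n_links else 0.0,
        lineage_edge_agreement=edge_agree,
        parameter_means_measured=meas_means,
        parameter_means_truth=truth_means,
        parameter_mean_rel_error=rel_err,
        n_records=n_rec,
    )
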