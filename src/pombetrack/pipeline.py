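"""End-to-end analysis pipeline with run manifests.

Orchestrates simulate -> segment -> track -> divide -> lineage -> stats,
writing every intermediate table as CSV under a run directory together
with a JSON manifest (config echo, package version, per-stage counts and
timings).  Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as pio
from .divisions import DivisionConfig, detect_divisions
from .growth import GrowthConfig, extract_records, summarize, align_to_shift
from .lineage import build_forest, census, forest_to_newick
from .segmentation import SegmentationConfig, segment_movie, detect_lane_geometry
from .synthetic import SimulationParams, simulate_colony, write_truth
from .tracking import TrackerConfig, track_movie
from .validate import validate_against_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    output_dir: str = "run"
    input_stack: str | None = None        # TIFF path; None = simulate
    simulate: bool = True
    lane_geometry: list[tuple[int, int]] | None = None
    n_lanes: int = 5
    t_shift: float | None = None          # minutes; shift-alignment output
    seed: int = 0
    log_level: str = "INFO"
    params: SimulationParams = field(default_factory=SimulationParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    division: DivisionConfig = field(default_factory=DivisionConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def __post_init__(self):
        if not self.simulate and self.input_stack is None:
            raise ValueError("either simulate=True or an input stack is required")


@dataclass
class PipelineResult:
    stack: np.ndarray
    truth: object | None
    frames_obs: list
    matrix: object
    events: list
    forest: list
    records: pd.DataFrame
    summary: pd.DataFrame
    census: pd.DataFrame
    report: object | None
    manifest: dict


def run_pipeline(cfg: RunConfig, write_frames: bool = True) -> PipelineResult:
    """Execute all pipeline stages; returns the in-memory result bundle."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "lineages").mkdir(exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    t_all = time.time()

    def stage(name):
        manifest["stages"][name] = {"t_start": time.time() - t_all}

    def done(name, **counts):
        manifest["stages"][name]["seconds"] = round(
            time.time() - t_all - manifest["stages"][name]["t_start"], 3)
        manifest["stages"][name].update(counts)

    # --- acquire stack -------------------------------------------------
    truth = None
    if cfg.simulate:
        stage("simulate")
        cfg.params.seed = cfg.seed
        stack, truth = simulate_colony(cfg.params)
        if write_frames:
            (out / "frames").mkdir(exist_ok=True)
            pio.write_stack(stack, out / "frames" / "movie.tif")
        write_truth(truth, out / "truth")
        done("simulate", frames=int(stack.shape[0]), cells=len(truth.cells),
             divisions=truth.n_divisions)
        cfg.segmentation.pixel_size = cfg.params.pixel_size
        geometry = cfg.lane_geometry or cfg.params.lane_rows
    else:
        p = Path(cfg.input_stack)
        if not p.exists():
            raise FileNotFoundError(f"input stack not found: {p}")
        stage("load")
        stack = pio.read_stack(p)
        done("load", frames=int(stack.shape[0]))
        geometry = cfg.lane_geometry or detect_lane_geometry(stack[0], cfg.n_lanes)

    # --- segment -------------------------------------------------------
    stage("segment")
    frames_obs = segment_movie(stack, geometry, cfg.segmentation)
    pio.write_observations(frames_obs, out / "tables" / "observations.csv")
    done("segment", observations=sum(len(f) for f in frames_obs))

    # --- track ---------------------------------------------------------
    stage("track")
    cfg.tracker.lane_length_px = stack.shape[2]
    matrix = track_movie(frames_obs, cfg.tracker)
    pio.write_tracks(matrix, out / "tables" / "tracks.csv")
    pio.write_diagnostics(matrix, out / "tables" / "tracking_diagnostics.csv")
    done("track", tracks=matrix.n_tracks)

    # --- divisions + lineage -------------------------------------------
    stage("divide")
    cfg.division.frame_interval = cfg.growth.frame_interval
    events = detect_divisions(matrix, cfg.division)
    forest = build_forest(matrix, events, cfg.division.max_daughter_gap)
    events_linked = [ev for ev in events if ev.daughters]
    pio.write_divisions(events, out / "tables" / "divisions.csv")
    (out / "lineages" / "forest.nwk").write_text(forest_to_newick(forest) + "\n")
    cens = census(forest)
    cens.to_csv(out / "tables" / "census.csv", index=False)
    done("divide", divisions=len(events), linked=len(events_linked),
         trees=len(forest))

    # --- growth stats --------------------------------------------------
    stage("stats")
    records = extract_records(matrix, events, forest, cfg.growth)
    if cfg.t_shift is not None and len(records):
        records = align_to_shift(records, cfg.t_shift)
        records.attrs["moving"].to_csv(out / "tables" / "shift_moving_stats.csv",
                                       index=False)
    records.to_csv(out / "tables" / "records.csv", index=False)
    summary = summarize(records) if len(records) >= 2 else pd.DataFrame()
    summary.to_csv(out / "tables" / "summary.csv", index=False)
    done("stats", records=len(records))

    # --- validation (simulated runs only) ------------------------------
    report = None
    if truth is not None:
        stage("validate")
        report = validate_against_truth(matrix, events, forest, records,
                                        frames_obs, truth)
        with open(out / "tables" / "validation.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        done("validate")

    manifest["config"] = {
        "params": asdict(cfg.params) if cfg.simulate else None,
        "segmentation": asdict(cfg.segmentation),
        "tracker": asdict(cfg.tracker),
        "division": {k: v for k, v in asdict(cfg.division).items()},
        "growth": asdict(cfg.growth),
        "t_shift": cfg.t_shift,
        "lane_geometry": [list(g) for g in geometry],
    }
    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(stack=stack, truth=truth, frames_obs=frames_obs,
                          matrix=matrix, events=events, forest=forest,
                          records=records, summary=summary, census=cens,
                          report=report, manifest=manifest)
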