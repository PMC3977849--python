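"""Tabular and image I/O for pipeline artifacts.

All intermediate products are plain text (CSV, Newick, key=value config)
except the image stacks themselves, which are multi-page grayscale TIFF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .divisions import DivisionEvent
from .segmentation import CellObservation
from .tracking import TrackMatrix

OBSERVATION_COLUMNS = [
    "id", "frame", "lane", "x", "y", "area_px", "length_um", "width_um",
    "orientation_deg", "mean_intensity", "flags",
]


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def observations_to_frame(frames_obs: list[list[CellObservation]]) -> pd.DataFrame:
    rows = []
    for obs_list in frames_obs:
        for o in obs_list:
            rows.append({
                "id": o.id, "frame": o.frame, "lane": o.lane,
                "x": o.centroid[0], "y": o.centroid[1], "area_px": o.area,
                "length_um": o.length_um, "width_um": o.width_um,
                "orientation_deg": o.orientation_deg,
                "mean_intensity": o.mean_intensity,
                "flags": ";".join(sorted(o.flags)),
            })
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def write_observations(frames_obs, path: str | Path) -> None:
    observations_to_frame(frames_obs).to_csv(path, index=False)


def tracks_to_frame(matrix: TrackMatrix) -> pd.DataFrame:
    rows = []
    for tid, obs_ids in matrix.tracks.items():
        for oid in obs_ids:
            rows.append({"frame": matrix.observations[oid].frame,
                         "observation_id": oid, "track_id": tid})
    return pd.DataFrame(rows, columns=["frame", "observation_id", "track_id"])


def write_tracks(matrix: TrackMatrix, path: str | Path) -> None:
    tracks_to_frame(matrix).sort_values(["frame", "track_id"]).to_csv(path, index=False)


def write_diagnostics(matrix: TrackMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.transitions).to_csv(path, index=False)


def divisions_to_frame(events: list[DivisionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        da, db = ev.daughters if ev.daughters else (-1, -1)
        rows.append({
            "parent_track": ev.parent_track, "frame": ev.frame,
            "daughter_a": da, "daughter_b": db,
            "septum_peak_frame": ev.septum_peak_frame,
            "septum_peak_response": ev.septum_peak_response,
            "septum_position": ev.septum_position,
        })
    return pd.DataFrame(rows, columns=[
        "parent_track", "frame", "daughter_a", "daughter_b",
        "septum_peak_frame", "septum_peak_response", "septum_position"])


def write_divisions(events, path: str | Path) -> None:
    divisions_to_frame(events).to_csv(path, index=False)


def read_flat_config(path: str | Path) -> dict[str, str]:
    """Read a flat key=value config file (blank lines and # comments ok)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_flat_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k}={v}\n")
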