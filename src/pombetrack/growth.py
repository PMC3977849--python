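"""Per-cycle growth parameters and population statistics.

A complete cell cycle runs from birth (the parent's fission) to the cell's
own fission.  Six parameters describe it: birth length, division length
(the plateau where elongation ceases), fission length (the sharp terminal
length peak just before separation), elongation time, septation time
(plateau onset to fission) and elongation rate (slope of the linear
growth phase).  Doubling time is elongation + septation by definition.

Population summaries, temperature-shift alignment (fraction of the cycle
elapsed after the shift), birth-vs-division regression (size-homeostasis
slope) and sister-pair tables mirror the analyses a steady-state
microchemostat experiment supports.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .divisions import DivisionEvent
from .lineage import LineageTree
from .tracking import TrackMatrix

__all__ = [
    "GrowthConfig",
    "GrowthRecord",
    "detect_plateau",
    "extract_record",
    "extract_records",
    "summarize",
    "align_to_shift",
    "birth_division_regression",
    "sister_table",
    "PARAMETERS",
]

PARAMETERS = [
    "birth_length", "division_length", "fission_length",
    "elongation_time", "septation_time", "doubling_time", "elongation_rate",
]


@dataclass
class GrowthConfig:
    frame_interval: float = 1.0      # minutes
    plateau_window: int = 10         # frames, sliding slope window
    plateau_slope_frac: float = 0.2  # of the early-cycle elongation rate
    fission_window: int = 10         # frames before division for the peak
    skip_birth_frames: int = 3       # excluded from the elongation fit
    fission_peak_frames: int = 3     # terminal frames excluded from the plateau


@dataclass
class GrowthRecord:
    track_id: int
    generation: int
    birth_time: float            # minutes, absolute
    division_time_abs: float     # minutes, absolute (fission)
    birth_length: float          # um
    division_length: float       # um
    fission_length: float        # um
    elongation_time: float       # minutes
    septation_time: float        # minutes
    doubling_time: float         # minutes (= elongation + septation)
    elongation_rate: float       # um / minute
    fraction_of_cycle_after_shift: float = float("nan")


class IncompleteCycle(Exception):
    """Raised when a track does not span a measurable full cycle."""


def detect_plateau(lengths: np.ndarray, cfg: GrowthConfig | None = None
                   ) -> tuple[int, float]:
    """Locate the growth plateau of a birth-to-fission length series.

    A coarse sliding-window slope test finds where growth ceases; the
    breakpoint is then refined by a two-segment (line + constant) least
    squares fit, excluding the first frames after birth and the terminal
    fission peak.  Returns ``(plateau start index, division length)``;
    raises :class:`IncompleteCycle` when no plateau exists.
    """
    cfg = cfg or GrowthConfig()
    L = np.asarray(lengths, dtype=float)
    n = L.size
    w = cfg.plateau_window
    s0 = cfg.skip_birth_frames
    tail = cfg.fission_peak_frames
    if n < s0 + w + tail + 4:
        raise IncompleteCycle("track too short for plateau detection")
    body = L[: n - tail]

    early_end = min(s0 + max(w, 8), body.size - 2)
    early_slope = np.polyfit(np.arange(s0, early_end), body[s0:early_end], 1)[0]
    if early_slope <= 0:
        raise IncompleteCycle("no measurable elongation phase")

    coarse = None
    for f in range(s0, body.size - w + 1):
        slope = np.polyfit(np.arange(w), body[f:f + w], 1)[0]
        if slope < cfg.plateau_slope_frac * early_slope:
            coarse = f
            break
    if coarse is None:
        raise IncompleteCycle("no plateau: growth never ceases")

    lo = max(s0 + 2, coarse - 6)
    hi = min(body.size - 2, coarse + 7)
    best = (np.inf, coarse)
    x = np.arange(body.size)
    for b in range(lo, hi):
        seg1 = body[s0:b]
        if seg1.size >= 2:
            fit = np.polyfit(x[s0:b], seg1, 1)
            sse1 = float(np.sum((seg1 - np.polyval(fit, x[s0:b])) ** 2))
        else:
            sse1 = 0.0
        seg2 = body[b:]
        sse2 = float(np.sum((seg2 - seg2.mean()) ** 2))
        if sse1 + sse2 < best[0]:
            best = (sse1 + sse2, b)
    b = best[1]
    division_length = float(np.median(body[b:]))
    return b, division_length


def extract_record(lengths: np.ndarray, frames: np.ndarray, birth_frame: int,
                   division_frame: int, cfg: GrowthConfig | None = None,
                   track_id: int = -1, generation: int = 1) -> GrowthRecord:
    """Measure the six growth parameters of one complete cycle.

    ``lengths``/``frames`` span the daughter track from birth to its last
    observation; ``division_frame`` is the fission frame of the cell's own
    division (first frame of its daughters).
    """
    cfg = cfg or GrowthConfig()
    L = np.asarray(lengths, dtype=float)
    dt = cfg.frame_interval
    plateau_idx, division_length = detect_plateau(L, cfg)

    birth_length = float(L[0])
    fission_length = float(L[-cfg.fission_window:].max())
    elongation_time = (float(frames[plateau_idx]) - birth_frame) * dt
    septation_time = (division_frame - float(frames[plateau_idx])) * dt
    if elongation_time <= 0 or septation_time <= 0:
        raise IncompleteCycle("non-positive phase duration")

    s0 = cfg.skip_birth_frames
    xe = np.arange(s0, plateau_idx) * dt
    if xe.size < 3:
        raise IncompleteCycle("elongation phase too short for a rate fit")
    rate = float(np.polyfit(xe, L[s0:plateau_idx], 1)[0])

    return GrowthRecord(
        track_id=track_id, generation=generation,
        birth_time=birth_frame * dt, division_time_abs=division_frame * dt,
        birth_length=birth_length, division_length=division_length,
        fission_length=fission_length,
        elongation_time=elongation_time, septation_time=septation_time,
        doubling_time=elongation_time + septation_time,
        elongation_rate=rate,
    )


def extract_records(matrix: TrackMatrix, events: list[DivisionEvent],
                    forest: list[LineageTree] | None = None,
                    cfg: GrowthConfig | None = None) -> pd.DataFrame:
    """Growth records for every complete cycle (birth and division observed).

    A track yields a record when it starts as the daughter of a detected
    division and itself ends in a detected division.  Incomplete cycles
    (founders, eluted or end-of-movie cells, failed plateau detection) are
    excluded.  Generations are depths in the lineage forest when given.
    """
    cfg = cfg or GrowthConfig()
    born: dict[int, DivisionEvent] = {}
    divides: dict[int, DivisionEvent] = {}
    for ev in events:
        if ev.daughters:
            for d in ev.daughters:
                born[d] = ev
        divides[ev.parent_track] = ev

    generation: dict[int, int] = {}
    if forest:
        for tree in forest:
            def rec(node, depth):
                generation[node.track_id] = depth
                for ch in node.children:
                    rec(ch, depth + 1)
            rec(tree.root, 1)

    rows = []
    for tid, ev_in in born.items():
        ev_out = divides.get(tid)
        if ev_out is None:
            continue
        frames = matrix.track_frames(tid)
        lengths = matrix.track_lengths(tid)
        try:
            r = extract_record(lengths, frames, birth_frame=ev_in.frame,
                               division_frame=ev_out.frame, cfg=cfg,
                               track_id=tid,
                               generation=generation.get(tid, 1))
        except IncompleteCycle:
            continue
        rows.append(asdict(r))
    df = pd.DataFrame(rows, columns=[f.name for f in
                                     GrowthRecord.__dataclass_fields__.values()])
    return df


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def summarize(records: pd.DataFrame, condition: pd.Series | None = None
              ) -> pd.DataFrame:
    """Mean / SD / CV / n per growth parameter, optionally per condition."""
    if condition is None:
        groups = [("all", records)]
    else:
        groups = list(records.groupby(condition.values))
    rows = []
    for label, df in groups:
        if len(df) < 2:
            continue
        for par in PARAMETERS:
            vals = df[par].to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            rows.append({
                "condition": label, "parameter": par, "mean": mean,
                "sd": sd, "cv": sd / mean if mean else float("nan"),
                "n": len(vals),
            })
    return pd.DataFrame(rows)


def histogram_table(records: pd.DataFrame, parameter: str,
                    bin_width: float) -> pd.DataFrame:
    vals = records[parameter].to_numpy(dtype=float)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def align_to_shift(records: pd.DataFrame, t_shift: float,
                   window: float = 30.0) -> pd.DataFrame:
    """Annotate records with the fraction of the cycle after a shift.

    ``fraction_of_cycle_after_shift`` is ``(division time - t_shift) /
    doubling time`` clipped to [0, 1]: 0 for cycles entirely before the
    shift, 1 for cycles entirely after.  Also returns a moving average and
    SD of each parameter versus absolute division time in windows of
    ``window`` minutes (attached as ``.attrs["moving"]``).
    """
    out = records.copy()
    frac = (out["division_time_abs"] - t_shift) / out["doubling_time"]
    out["fraction_of_cycle_after_shift"] = frac.clip(0.0, 1.0)

    moving_rows = []
    t = out["division_time_abs"].to_numpy(dtype=float)
    if t.size:
        centers = np.arange(t.min(), t.max() + window / 2, window / 2)
        for c in centers:
            sel = np.abs(t - c) <= window / 2
            if sel.sum() < 2:
                continue
            row = {"t_center": c, "n": int(sel.sum())}
            for par in PARAMETERS:
                vals = out.loc[sel, par]
                row[f"{par}_mean"] = float(vals.mean())
                row[f"{par}_sd"] = float(vals.std(ddof=1))
            moving_rows.append(row)
    out.attrs["moving"] = pd.DataFrame(moving_rows)
    return out


def birth_division_regression(records: pd.DataFrame,
                              birth_range: tuple[float, float] = (6.0, 10.0),
                              bin_width: float = 0.5):
    """OLS of division length on birth length within a birth-length range.

    Returns ``(slope, intercept, table)`` where the table gives per-bin
    division-length distributions (median and quartiles) for box-plot
    style output.  Raises ``ValueError`` with fewer than 10 records in
    range.
    """
    sel = records[(records["birth_length"] >= birth_range[0])
                  & (records["birth_length"] <= birth_range[1])]
    if len(sel) < 10:
        raise ValueError(f"only {len(sel)} records in birth range {birth_range}")
    fit = sstats.linregress(sel["birth_length"], sel["division_length"])
    edges = np.arange(birth_range[0], birth_range[1] + bin_width, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        b = sel[(sel["birth_length"] >= lo) & (sel["birth_length"] < hi)]
        if len(b) == 0:
            continue
        q = b["division_length"].quantile([0.25, 0.5, 0.75])
        rows.append({"bin_left": lo, "bin_right": hi, "n": len(b),
                     "q25": q[0.25], "median": q[0.5], "q75": q[0.75]})
    return float(fit.slope), float(fit.intercept), pd.DataFrame(rows)


def sister_table(forest: list[LineageTree], records: pd.DataFrame) -> pd.DataFrame:
    """Paired sister-cell rows with the mother's division length.

    One row per division whose both daughters completed a cycle; sisters
    ordered by track id.  Pearson correlations for doubling time and
    elongation rate are attached as ``.attrs["correlations"]``.
    """
    by_track = records.set_index("track_id") if len(records) else pd.DataFrame()
    rows = []
    for tree in forest:
        for node in tree.root.walk():
            if len(node.children) != 2:
                continue
            a, b = sorted(c.track_id for c in node.children)
            if len(by_track) == 0 or a not in by_track.index or b not in by_track.index:
                continue
            mother_dl = (float(by_track.loc[node.track_id, "division_length"])
                         if node.track_id in getattr(by_track, "index", [])
                         else float("nan"))
            rows.append({
                "sister_a": a, "sister_b": b,
                "mother_division_length": mother_dl,
                "doubling_time_a": float(by_track.loc[a, "doubling_time"]),
                "doubling_time_b": float(by_track.loc[b, "doubling_time"]),
                "elongation_rate_a": float(by_track.loc[a, "elongation_rate"]),
                "elongation_rate_b": float(by_track.loc[b, "elongation_rate"]),
            })
    table = pd.DataFrame(rows, columns=[
        "sister_a", "sister_b", "mother_division_length",
        "doubling_time_a", "doubling_time_b",
        "elongation_rate_a", "elongation_rate_b"])
    corr = {}
    if len(table) >= 3:
        for par in ("doubling_time", "elongation_rate"):
            a = table[f"{par}_a"].to_numpy(dtype=float)
            b = table[f"{par}_b"].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                corr[par] = float("nan")  # undefined for constant input
                continue
            r, _p = sstats.pearsonr(a, b)
            corr[par] = float(r)
    table.attrs["correlations"] = corr
    return table
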