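"""Septum detection and division calling via Mexican-hat filtering.

The division septum of a fission-yeast cell imaged slightly out of focus
is a bright transverse band at mid-cell.  Convolving the lengthwise
intensity profile with a zero-mean Mexican-hat (Ricker) kernel gives a
response that peaks sharply at the band; tracking the position and value
of the response maximum over a cell's track traces the septum's rise to
peak intensity and its rapid collapse (within ~4 min) at fission.  A
division is called when the response, having risen above an appearance
threshold near mid-cell during a length plateau, falls back to baseline —
or when the track terminates while the septum is collapsing (the tracker
splits the contour at separation, so parent tracks end at fission).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tracking import TrackMatrix

__all__ = [
    "DivisionConfig",
    "SeptumTrace",
    "DivisionEvent",
    "ricker_kernel",
    "ricker_response",
    "septum_trace",
    "call_division",
    "detect_divisions",
]

logger = logging.getLogger(__name__)


@dataclass
class DivisionConfig:
    kernel_width_px: float = 4.0        # Ricker scale ~ septum band width
    k_appear: float = 5.0               # appearance threshold: baseline + k*MAD
    k_clear: float = 2.0                # return-to-baseline threshold
    min_appear_response: float = 20.0   # absolute floor on the peak response
    mid_band: tuple[float, float] = (0.30, 0.70)  # allowed peak position
    smooth_frames: int = 3              # median smoothing of the trace
    min_track_frames: int = 5
    end_fall_fraction: float = 0.5      # required fall from peak at track end
    end_window: int = 6                 # frames; peak this close to track end
                                        # may resolve as an end-of-track fission
    max_daughter_gap: int = 2           # frames between division and daughter start
    plateau_slope_max: float = 0.05     # um/min near the peak
    frame_interval: float = 1.0


@dataclass
class SeptumTrace:
    """Per-frame septum evidence along one track."""

    frames: np.ndarray        # frame indices
    position: np.ndarray      # argmax position as fraction of cell length, [0, 1]
    response: np.ndarray      # convolved response maximum


@dataclass
class DivisionEvent:
    parent_track: int
    frame: int                     # first frame of the daughters (fission frame)
    daughters: tuple[int, int] | None = None
    septum_peak_frame: int = -1
    septum_peak_response: float = 0.0
    septum_position: float = 0.5   # fraction of parent length at the peak


# ---------------------------------------------------------------------------
# Ricker filtering
# ---------------------------------------------------------------------------

def ricker_kernel(width: float, support: int | None = None) -> np.ndarray:
    """Discrete Mexican-hat (Ricker) kernel of scale ``width`` pixels.

    The sampled kernel is mean-subtracted so it sums exactly to zero: a
    flat profile then yields an identically zero response.
    """
    if width <= 0:
        raise ValueError("kernel width must be > 0")
    if support is None:
        support = max(int(np.ceil(4.0 * width)), 3)
    x = np.arange(-support, support + 1, dtype=float)
    a = float(width)
    norm = 2.0 / (np.sqrt(3.0 * a) * np.pi ** 0.25)
    psi = norm * (1.0 - (x / a) ** 2) * np.exp(-(x ** 2) / (2.0 * a ** 2))
    return psi - psi.mean()


def ricker_response(profile: np.ndarray, width: float = 4.0,
                    kernel: np.ndarray | None = None) -> tuple[np.ndarray, int, float]:
    """Convolve a lengthwise profile with the Mexican-hat kernel.

    Returns ``(response, argmax index, max value)``.  The profile is
    reflect-padded so the response has the same length.  Raises
    ``ValueError`` when the profile is shorter than the kernel support.
    """
    prof = np.asarray(profile, dtype=float)
    k = ricker_kernel(width) if kernel is None else kernel
    if prof.size < k.size:
        raise ValueError(
            f"profile of length {prof.size} shorter than kernel support {k.size}")
    half = k.size // 2
    padded = np.pad(prof, half, mode="reflect")
    resp = np.convolve(padded, k[::-1], mode="valid")
    idx = int(np.argmax(resp))
    return resp, idx, float(resp[idx])


# ---------------------------------------------------------------------------
# traces and calls
# ---------------------------------------------------------------------------

def septum_trace(frames: np.ndarray, profiles: list[np.ndarray],
                 cfg: DivisionConfig | None = None) -> SeptumTrace:
    """Per-frame (position, response) of the filtered-profile maximum.

    The response and position series are median-smoothed over
    ``smooth_frames`` to suppress single-frame glitches (at 1 frame/min
    the ~4-min septum collapse spans several frames, so a 3-frame median
    keeps the dynamics intact).
    """
    cfg = cfg or DivisionConfig()
    kernel = ricker_kernel(cfg.kernel_width_px)
    pos = np.empty(len(profiles))
    resp = np.empty(len(profiles))
    for i, prof in enumerate(profiles):
        if prof.size < kernel.size:
            pos[i] = 0.5
            resp[i] = 0.0
            continue
        _r, idx, mx = ricker_response(prof, kernel=kernel)
        pos[i] = idx / max(prof.size - 1, 1)
        resp[i] = mx
    if cfg.smooth_frames > 1 and len(profiles) >= cfg.smooth_frames:
        resp = ndimage.median_filter(resp, size=cfg.smooth_frames, mode="nearest")
        pos = ndimage.median_filter(pos, size=cfg.smooth_frames, mode="nearest")
    return SeptumTrace(frames=np.asarray(frames), position=pos, response=resp)


def call_division(trace: SeptumTrace, lengths: np.ndarray,
                  cfg: DivisionConfig | None = None,
                  track_id: int = -1,
                  baseline: float | None = None, mad: float | None = None,
                  movie_end: int | None = None) -> DivisionEvent | None:
    """Call a division from one track's septum trace.

    The septum must rise above ``baseline + k_appear*MAD`` (and an absolute
    floor) near mid-cell while the length series is non-elongating, then
    fall back toward baseline.  The division frame is the first frame after
    the response returns to baseline; if the track ends while the response
    is still collapsing (the usual case: the contour splits at fission and
    the tracker rejects the parent-to-half links), the frame after the
    last track frame is used — but only when the response actually fell
    from its peak and the movie itself did not end (a cell eluted or
    truncated mid-septation is not a division).  An ambiguous double peak
    yields no call.

    ``baseline``/``mad`` default to per-track robust statistics; the
    movie-wide values computed by :func:`detect_divisions` are preferred
    since most frames movie-wide carry no septum.
    """
    cfg = cfg or DivisionConfig()
    resp = trace.response
    n = resp.size
    if n < cfg.min_track_frames:
        return None
    if baseline is None:
        baseline = float(np.median(resp))
    if mad is None:
        mad = float(np.median(np.abs(resp - baseline)))
    appear_thr = max(baseline + cfg.k_appear * mad, cfg.min_appear_response)
    clear_thr = baseline + cfg.k_clear * mad

    peak = int(np.argmax(resp))
    if resp[peak] < appear_thr:
        return None
    lo, hi = cfg.mid_band
    if not (lo <= trace.position[peak] <= hi):
        return None

    # double-peak guard: two excursions above the appearance threshold with
    # a cleared valley between them are ambiguous (re-crossings whose valley
    # never returns to baseline count as one peak)
    idxs = np.flatnonzero(resp >= appear_thr)
    runs = np.split(idxs, np.flatnonzero(np.diff(idxs) > 1) + 1)
    merged = 1
    for prev, cur in zip(runs, runs[1:]):
        if resp[prev[-1]:cur[0] + 1].min() <= clear_thr:
            merged += 1
    if merged > 1:
        logger.info("track %s: ambiguous multi-peak septum trace, no call", track_id)
        return None

    # concurrent length plateau around the peak
    w0 = max(peak - 5, 0)
    if peak - w0 >= 3:
        seg = lengths[w0:peak + 1]
        slope = np.polyfit(np.arange(seg.size) * cfg.frame_interval, seg, 1)[0]
        if slope > cfg.plateau_slope_max * 3:
            return None

    after = resp[peak:]
    below = np.flatnonzero(after <= clear_thr)
    if below.size:
        division_frame = int(trace.frames[peak + below[0]])
    elif (peak >= n - cfg.end_window
          and resp[-1] <= cfg.end_fall_fraction * resp[peak]
          and (movie_end is None or trace.frames[-1] < movie_end)):
        division_frame = int(trace.frames[-1]) + 1
    else:
        return None

    return DivisionEvent(
        parent_track=track_id,
        frame=division_frame,
        septum_peak_frame=int(trace.frames[peak]),
        septum_peak_response=float(resp[peak]),
        septum_position=float(trace.position[peak]),
    )


def detect_divisions(matrix: TrackMatrix,
                     cfg: DivisionConfig | None = None) -> list[DivisionEvent]:
    """Run septum tracing and division calling over every track.

    The response baseline and its MAD are estimated movie-wide (cells
    carry no septum most of the time, so the pooled median is the
    no-septum response level); this keeps thresholds meaningful for short
    tracks that are born or lost mid-septation.
    """
    cfg = cfg or DivisionConfig()
    traces: dict[int, SeptumTrace] = {}
    for tid in matrix.tracks:
        frames = matrix.track_frames(tid)
        if frames.size < cfg.min_track_frames:
            continue
        traces[tid] = septum_trace(frames, matrix.track_profiles(tid), cfg)
    if not traces:
        return []
    pooled = np.concatenate([t.response for t in traces.values()])
    baseline = float(np.median(pooled))
    mad = float(np.median(np.abs(pooled - baseline)))
    movie_end = max(int(t.frames[-1]) for t in traces.values())
    events: list[DivisionEvent] = []
    for tid, trace in traces.items():
        ev = call_division(trace, matrix.track_lengths(tid), cfg, track_id=tid,
                           baseline=baseline, mad=mad, movie_end=movie_end)
        if ev is not None:
            events.append(ev)
    return events
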