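"""Lane splitting, cell segmentation, contour measurement and triage.

Frames are imaged slightly out of focus so cell contours are dark and the
septum bright.  Each chamber frame is split into lanes along the highway
walls; each lane is thresholded for dark contour pixels, contours are
filled and labeled, non-cell features (walls, specks) are filtered out by
area/width/solidity, and each remaining object is measured into a
:class:`CellObservation`.  Objects are triaged into single / too-large /
too-long; the latter two are refined by cutting at dark internal valleys
of the lengthwise intensity profile (double cell walls between abutting
cells) until pieces meet the single-cell criteria.

Coordinates are 0-based pixels, ``(x=column, y=row)``; row ranges are
half-open.  Lengths and widths are reported in micrometers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure as skmeasure

__all__ = [
    "SegmentationConfig",
    "Lane",
    "ContourCategory",
    "CellObservation",
    "split_lanes",
    "detect_lane_geometry",
    "auto_threshold",
    "segment_lane",
    "measure_contour",
    "triage_contour",
    "refine_contour",
    "segment_frame",
    "segment_movie",
]


@dataclass
class SegmentationConfig:
    pixel_size: float = 0.2304       # um / px
    threshold: float | None = None   # fixed dark threshold; None = per-lane auto
    smooth_sigma: float = 0.0        # optional Gaussian blur before thresholding
    min_area_px: int = 40            # below: rejected as non-cell (specks)
    min_width_px: float = 3.5        # below: rejected (highway walls, debris)
    min_solidity: float = 0.5
    max_width_um: float = 4.6        # triage: too-large above (20 px)
    max_length_um: float = 13.0      # triage: too-long above
    min_piece_length_um: float = 2.0 # refinement never cuts smaller pieces
    profile_halfwidth: int = 1       # transverse averaging of the profile


class ContourCategory(enum.Enum):
    SINGLE = "single"
    TOO_LARGE = "too_large"
    TOO_LONG = "too_long"
    REJECTED_NON_CELL = "rejected_non_cell"


@dataclass
class Lane:
    """A horizontal slice of the chamber between highway walls."""

    index: int
    row_start: int
    row_stop: int  # half-open
    image: np.ndarray | None = None

    @property
    def rows(self) -> tuple[int, int]:
        return (self.row_start, self.row_stop)


@dataclass
class CellObservation:
    """One segmented cell in one frame."""

    id: int
    frame: int
    lane: int
    centroid: tuple[float, float]          # (x, y) px, frame coordinates
    area: float                            # px^2 (filled)
    length_um: float
    width_um: float
    orientation_deg: float                 # [-90, 90) from the x axis
    mean_intensity: float
    profile: np.ndarray                    # lengthwise intensity, 1-px steps
    contour: np.ndarray                    # closed polygon, (N, 2) of (x, y)
    mask: np.ndarray                       # filled boolean mask (bbox-local)
    bbox: tuple[int, int, int, int]        # (row0, col0, row1, col1), half-open
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    flags: set = field(default_factory=set)

    def overlaps(self, other: "CellObservation") -> bool:
        r0 = max(self.bbox[0], other.bbox[0])
        c0 = max(self.bbox[1], other.bbox[1])
        r1 = min(self.bbox[2], other.bbox[2])
        c1 = min(self.bbox[3], other.bbox[3])
        if r1 <= r0 or c1 <= c0:
            return False
        a = self.mask[r0 - self.bbox[0]:r1 - self.bbox[0],
                      c0 - self.bbox[1]:c1 - self.bbox[1]]
        b = other.mask[r0 - other.bbox[0]:r1 - other.bbox[0],
                       c0 - other.bbox[1]:c1 - other.bbox[1]]
        return bool(np.any(a & b))


# ---------------------------------------------------------------------------
# lanes
# ---------------------------------------------------------------------------

def split_lanes(frame: np.ndarray, geometry: list[tuple[int, int]] | None = None,
                n_lanes: int = 5) -> list[Lane]:
    """Split a chamber frame into disjoint lanes.

    ``geometry`` gives explicit half-open row ranges; otherwise the chamber
    rows are partitioned into ``n_lanes`` equal lanes.
    """
    H = frame.shape[0]
    if geometry is None:
        if H % n_lanes:
            bounds = np.linspace(0, H, n_lanes + 1).round().astype(int)
            geometry = [(int(bounds[i]), int(bounds[i + 1])) for i in range(n_lanes)]
        else:
            w = H // n_lanes
            geometry = [(i * w, (i + 1) * w) for i in range(n_lanes)]
    lanes = []
    prev_stop = None
    for i, (r0, r1) in enumerate(geometry):
        if not (0 <= r0 < r1 <= H):
            raise ValueError(f"lane {i} rows [{r0}, {r1}) outside frame of height {H}")
        if prev_stop is not None and r0 < prev_stop:
            raise ValueError("lane row ranges must be disjoint and ordered")
        prev_stop = r1
        lanes.append(Lane(index=i, row_start=r0, row_stop=r1, image=frame[r0:r1]))
    return lanes


def detect_lane_geometry(frame: np.ndarray, n_lanes: int = 5) -> list[tuple[int, int]]:
    """Detect lane row ranges from the dark highway-wall rows.

    Wall rows are found as row-mean intensity minima well below the chamber
    median; lanes are the runs between consecutive wall bands.
    """
    rowmean = np.asarray(frame, dtype=float).mean(axis=1)
    med = np.median(rowmean)
    lo = rowmean.min()
    if med - lo < 1.0:
        raise ValueError("no dark wall rows detected")
    wall = rowmean < (med + lo) / 2.0
    # runs of non-wall rows = lanes
    lanes = []
    in_lane = False
    start = 0
    for r, is_wall in enumerate(wall):
        if not is_wall and not in_lane:
            start, in_lane = r, True
        elif is_wall and in_lane:
            lanes.append((start, r))
            in_lane = False
    if in_lane:
        lanes.append((start, len(wall)))
    lanes = [(a, b) for a, b in lanes if b - a >= 5]
    if len(lanes) != n_lanes:
        raise ValueError(f"detected {len(lanes)} lanes, expected {n_lanes}")
    return lanes


# ---------------------------------------------------------------------------
# thresholding and labeling
# ---------------------------------------------------------------------------

def auto_threshold(img: np.ndarray) -> float | None:
    """Dark-contour threshold for one lane; None if no dark class exists."""
    x = np.asarray(img, dtype=float).ravel()
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    sigma = 1.4826 * mad
    dark = x[x < med - max(4.0 * sigma, 4.0)]
    if dark.size < 20:
        return None
    return 0.5 * (float(np.median(dark)) + float(med))


def segment_lane(lane_img: np.ndarray, config: SegmentationConfig | None = None):
    """Segment dark-contour objects in one lane image.

    Returns a list of ``skimage`` region proxies (filled, labeled, with
    non-cell features removed).  A blank or degenerate lane yields an
    empty list.
    """
    config = config or SegmentationConfig()
    if lane_img.size == 0 or min(lane_img.shape) < 3:
        return []
    work = lane_img.astype(float)
    if config.smooth_sigma > 0:
        work = ndimage.gaussian_filter(work, config.smooth_sigma)
    thr = config.threshold if config.threshold is not None else auto_threshold(work)
    if thr is None:
        return []
    binary = work < thr
    filled = ndimage.binary_fill_holes(binary)
    labels = skmeasure.label(filled, connectivity=2)
    regions = []
    for reg in skmeasure.regionprops(labels):
        if reg.area < max(config.min_area_px, 4):
            continue
        # transverse extent: reject thin lines (highway walls, scratches)
        if reg.axis_minor_length < config.min_width_px:
            continue
        if reg.solidity < config.min_solidity:
            # a noise-broken contour ring fails to fill; repair it in
            # isolation (per component, so neighbors can never merge)
            repaired = _repair_ring(reg)
            if repaired is not None and repaired.solidity >= config.min_solidity:
                regions.append(repaired)
            continue
        regions.append(reg)
    return regions


class _Region:
    """Minimal region proxy (mask + bbox) mirroring skimage regionprops."""

    def __init__(self, image: np.ndarray, bbox: tuple[int, int, int, int]):
        self.image = image
        self.bbox = bbox
        self.area = float(image.sum())
        props = skmeasure.regionprops(image.astype(np.uint8))
        self.solidity = props[0].solidity if props else 0.0
        self.axis_minor_length = props[0].axis_minor_length if props else 0.0


def _repair_ring(reg) -> "_Region | None":
    mask = np.pad(reg.image, 2)
    closed = ndimage.binary_closing(mask, structure=np.ones((3, 3), bool))
    fixed = ndimage.binary_fill_holes(closed)[2:-2, 2:-2]
    if not fixed.any():
        return None
    return _Region(fixed | reg.image, reg.bbox)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axes of a boolean mask (x, y order)."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    c = pts.mean(axis=0)
    d = pts - c
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    n = np.array([-u[1], u[0]])
    return c, u, n


def measure_contour(region, image: np.ndarray, config: SegmentationConfig | None = None,
                    frame_index: int = 0, lane_index: int = 0,
                    row_offset: int = 0, obs_id: int = 0) -> CellObservation:
    """Measure a filled region into a :class:`CellObservation`.

    ``region`` is a labeled-region proxy (from :func:`segment_lane`) or a
    boolean mask; ``image`` is the full frame (or lane image with
    ``row_offset`` mapping lane rows to frame rows).  Length and width are
    extents of the mask projected on the principal axes, converted with
    ``pixel_size``; the lengthwise profile is sampled at 1-px steps along
    the major axis, averaged over a short transverse stencil.
    """
    config = config or SegmentationConfig()
    if hasattr(region, "image"):
        mask = region.image
        r0, c0, r1, c1 = region.bbox
    else:
        mask = np.asarray(region, dtype=bool)
        ys, xs = np.nonzero(mask)
        r0, c0, r1, c1 = ys.min(), xs.min(), ys.max() + 1, xs.max() + 1
        mask = mask[r0:r1, c0:c1]
    area = float(mask.sum())
    if area < 4:
        raise ValueError("contour area below 4 px^2: rejected as non-cell")

    c_local, u, n = _principal_axes(mask)
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float) - c_local
    proj_u = pts @ u
    proj_n = pts @ n
    length_px = float(proj_u.max() - proj_u.min() + 1.0)
    width_px = float(proj_n.max() - proj_n.min() + 1.0)
    if width_px > length_px:
        length_px, width_px = width_px, length_px
        u, n = n, u
        proj_u, proj_n = proj_n, proj_u

    angle = math.degrees(math.atan2(u[1], u[0]))
    if angle >= 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0

    centroid = (c_local[0] + c0, c_local[1] + r0 + row_offset)

    # lengthwise intensity profile through the centroid along the major axis
    s = np.arange(-length_px / 2.0, length_px / 2.0 + 0.5, 1.0)
    offsets = range(-config.profile_halfwidth, config.profile_halfwidth + 1)
    acc = np.zeros_like(s)
    for t in offsets:
        px = centroid[0] + s * u[0] + t * n[0]
        py = centroid[1] + s * u[1] + t * n[1]
        acc += ndimage.map_coordinates(image.astype(float), [py, px],
                                       order=1, mode="nearest")
    profile = acc / len(list(offsets))

    mean_int = float(image[r0 + row_offset:r1 + row_offset, c0:c1][mask].mean())

    padded = np.pad(mask, 1).astype(float)
    contours = skmeasure.find_contours(padded, 0.5)
    poly = max(contours, key=len) if contours else np.zeros((0, 2))
    poly = np.column_stack([poly[:, 1] - 1 + c0, poly[:, 0] - 1 + r0 + row_offset])

    obs = CellObservation(
        id=obs_id, frame=frame_index, lane=lane_index, centroid=centroid,
        area=area, length_um=length_px * config.pixel_size,
        width_um=width_px * config.pixel_size, orientation_deg=angle,
        mean_intensity=mean_int, profile=profile, contour=poly,
        mask=mask, bbox=(r0 + row_offset, c0, r1 + row_offset, c1), axis=u,
    )
    return obs


def triage_contour(obs: CellObservation,
                   config: SegmentationConfig | None = None) -> ContourCategory:
    """Sort a measured contour into single / too-large / too-long.

    Pure function of (length, width); too-large (transverse extent over
    20 px / 4.6 um) takes precedence over too-long (over 13 um).
    """
    config = config or SegmentationConfig()
    if obs.width_um > config.max_width_um:
        return ContourCategory.TOO_LARGE
    if obs.length_um > config.max_length_um:
        return ContourCategory.TOO_LONG
    return ContourCategory.SINGLE


def refine_contour(obs: CellObservation, image: np.ndarray,
                   config: SegmentationConfig | None = None,
                   threshold: float | None = None) -> list[CellObservation]:
    """Split a too-large/too-long object at dark internal valleys.

    Abutting cells segmented as one object share a dark double wall that
    shows up as a deep valley of the lengthwise intensity profile; the mask
    is cut perpendicular to the major axis at each such valley.  Pieces
    below the single-cell criteria are re-measured and returned; an object
    with no internal valley is returned unsplit with its category flag
    retained.  Pieces shorter than ``min_piece_length_um`` are never
    produced.
    """
    config = config or SegmentationConfig()
    category = triage_contour(obs, config)
    if category is ContourCategory.SINGLE:
        return [obs]

    profile = ndimage.gaussian_filter1d(obs.profile.astype(float), 1.0)
    if threshold is None:
        lo, hi = float(profile.min()), float(np.median(profile))
        threshold = 0.5 * (lo + hi) if hi - lo > 10 else lo - 1.0
    idx, _ = find_peaks(-profile, prominence=max(10.0, 0.2 * np.ptp(profile)))
    min_piece_px = config.min_piece_length_um / config.pixel_size
    length_px = obs.length_um / config.pixel_size
    cuts: list[float] = []
    left_edge = -length_px / 2.0
    for i in idx:
        if profile[i] >= threshold:
            continue
        s_cut = i - (len(profile) - 1) / 2.0  # axial px rel. centroid
        if s_cut - left_edge < min_piece_px or (length_px / 2.0 - s_cut) < min_piece_px:
            continue
        cuts.append(s_cut)
        left_edge = s_cut
    if not cuts:
        obs.flags.add(f"unsplit_{category.value}")
        return [obs]

    r0, c0 = obs.bbox[0], obs.bbox[1]
    ys, xs = np.nonzero(obs.mask)
    pts = np.column_stack([xs + c0, ys + r0]).astype(float)
    s_all = (pts - np.array(obs.centroid)) @ obs.axis
    bounds = [-np.inf] + sorted(cuts) + [np.inf]
    pieces: list[CellObservation] = []
    for k in range(len(bounds) - 1):
        sel = (s_all > bounds[k] + 1.0) & (s_all < bounds[k + 1] - 1.0)
        if sel.sum() < max(config.min_area_px, 4):
            continue
        sub = np.zeros(image.shape, dtype=bool)
        sub[ys[sel] + r0, xs[sel] + c0] = True
        piece = measure_contour(sub, image, config, frame_index=obs.frame,
                                lane_index=obs.lane, row_offset=0, obs_id=obs.id)
        if piece.length_um < config.min_piece_length_um:
            continue
        sub_cat = triage_contour(piece, config)
        if sub_cat is not ContourCategory.SINGLE:
            piece.flags.add(f"unsplit_{sub_cat.value}")
        pieces.append(piece)
    if not pieces:
        obs.flags.add(f"unsplit_{category.value}")
        return [obs]
    return pieces


# ---------------------------------------------------------------------------
# frame / movie drivers
# ---------------------------------------------------------------------------

def segment_frame(frame: np.ndarray, lanes_geometry: list[tuple[int, int]],
                  config: SegmentationConfig, frame_index: int,
                  next_id: int) -> tuple[list[CellObservation], int]:
    """Segment one frame into observations with globally unique ids."""
    observations: list[CellObservation] = []
    lanes = split_lanes(frame, geometry=lanes_geometry)
    for lane in lanes:
        regions = segment_lane(lane.image, config)
        thr = config.threshold if config.threshold is not None else auto_threshold(lane.image)
        for reg in regions:
            obs = measure_contour(reg, frame, config, frame_index=frame_index,
                                  lane_index=lane.index, row_offset=lane.row_start,
                                  obs_id=next_id)
            next_id += 1
            if triage_contour(obs, config) is ContourCategory.SINGLE:
                observations.append(obs)
            else:
                for piece in refine_contour(obs, frame, config, threshold=thr):
                    piece.id = next_id
                    next_id += 1
                    observations.append(piece)
    return observations, next_id


def segment_movie(stack: np.ndarray, lanes_geometry: list[tuple[int, int]] | None = None,
                  config: SegmentationConfig | None = None,
                  n_lanes: int = 5) -> list[list[CellObservation]]:
    """Segment every frame of a stack; returns per-frame observation lists."""
    config = config or SegmentationConfig()
    if lanes_geometry is None:
        lanes_geometry = detect_lane_geometry(stack[0], n_lanes=n_lanes)
    frames: list[list[CellObservation]] = []
    next_id = 1
    for f in range(stack.shape[0]):
        obs, next_id = segment_frame(stack[f], lanes_geometry, config, f, next_id)
        frames.append(obs)
    return frames
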