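"""Lineage forests from tracks and division events.

Each detected division links a parent track to the two daughter tracks
that start where the parent's final contour split.  Daughters are
identified by maximal pixel overlap of their first contour with the two
halves of the parent's last contour (split transversely at the septum
position).  Tracks with no detected parent are forest roots.

Census metrics follow the platform-performance definitions: a lineage of
``g`` generations is a root-anchored path with ``g`` observed division
cycles; a tree is complete at ``g`` when all ``2**g`` expected leaves are
observed; tree completeness at ``g`` is the observed fraction of those
leaves (root = generation 1, so the leaves of a ``g``-generation tree sit
at depth ``g + 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .divisions import DivisionEvent
from .tracking import TrackMatrix
from .segmentation import CellObservation

__all__ = [
    "LineageNode",
    "LineageTree",
    "build_forest",
    "census",
    "completeness",
    "mean_completeness",
    "forest_to_newick",
]

logger = logging.getLogger(__name__)


@dataclass
class LineageNode:
    track_id: int
    children: list["LineageNode"] = field(default_factory=list)
    parent: "LineageNode | None" = None
    record: object | None = None     # GrowthRecord, attached by growth stats

    def add_child(self, node: "LineageNode") -> None:
        if len(self.children) >= 2:
            raise ValueError("lineage nodes are binary")
        node.parent = self
        self.children.append(node)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


@dataclass
class LineageTree:
    root: LineageNode

    def nodes_at_depth(self, depth: int) -> list[LineageNode]:
        """Nodes at a given depth; the root is depth 1."""
        out = []

        def rec(node: LineageNode, d: int) -> None:
            if d == depth:
                out.append(node)
                return
            for ch in node.children:
                rec(ch, d + 1)

        rec(self.root, 1)
        return out

    @property
    def depth(self) -> int:
        def rec(node: LineageNode) -> int:
            if not node.children:
                return 1
            return 1 + max(rec(c) for c in node.children)

        return rec(self.root)

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.root.walk())


def completeness(tree: LineageTree, g: int) -> float:
    """Observed leaves of a ``g``-generation tree divided by ``2**g``.

    The expected leaves of a ``g``-generation tree sit at depth ``g + 1``
    (the root is generation 1 and each generation is one division cycle).
    """
    if g < 1:
        raise ValueError("completeness is defined for g >= 1")
    return len(tree.nodes_at_depth(g + 1)) / float(2 ** g)


def mean_completeness(forest: list[LineageTree], g: int) -> float:
    """Average completeness at ``g`` over trees that reach at least one
    leaf of a ``g``-generation tree."""
    vals = [completeness(t, g) for t in forest]
    vals = [v for v in vals if v > 0]
    return float(np.mean(vals)) if vals else 0.0


def census(forest: list[LineageTree], max_generations: int = 10) -> pd.DataFrame:
    """Per-generation lineage and complete-tree counts.

    ``n_lineages``: root-anchored paths with ``g`` observed division
    cycles (equivalently, nodes at depth ``g + 1``, summed over trees).
    ``n_complete_trees``: trees where all ``2**g`` expected leaves are
    observed.  ``mean_completeness``: average observed-leaf fraction over
    trees with at least one leaf at that depth.
    """
    rows = []
    for g in range(1, max_generations + 1):
        n_lineages = sum(len(t.nodes_at_depth(g + 1)) for t in forest)
        n_complete = sum(
            1 for t in forest if len(t.nodes_at_depth(g + 1)) == 2 ** g
        )
        rows.append({
            "generation": g,
            "n_lineages": n_lineages,
            "n_complete_trees": n_complete,
            "mean_completeness": mean_completeness(forest, g),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forest construction
# ---------------------------------------------------------------------------

def _half_masks(obs: CellObservation, split_frac: float):
    """Split an observation's mask transversely at an axial fraction."""
    r0, c0 = obs.bbox[0], obs.bbox[1]
    ys, xs = np.nonzero(obs.mask)
    pts = np.column_stack([xs + c0, ys + r0]).astype(float)
    s = (pts - np.array(obs.centroid)) @ obs.axis
    length_px = s.max() - s.min() + 1.0
    cut = s.min() + split_frac * length_px
    left = set(map(tuple, pts[s < cut].astype(int)))
    right = set(map(tuple, pts[s >= cut].astype(int)))
    return left, right


def _obs_pixels(obs: CellObservation) -> set[tuple[int, int]]:
    r0, c0 = obs.bbox[0], obs.bbox[1]
    ys, xs = np.nonzero(obs.mask)
    return set(zip((xs + c0).tolist(), (ys + r0).tolist()))


def build_forest(matrix: TrackMatrix, events: list[DivisionEvent],
                 max_daughter_gap: int = 2) -> list[LineageTree]:
    """Assemble tracks and division events into a lineage forest.

    For each division the daughter tracks are the (at most two) tracks
    starting within ``max_daughter_gap`` frames of the division whose
    first contour overlaps the parent's final contour; each is assigned to
    the parent half (split at the septum position) it overlaps most.
    Events for which two daughters cannot be found are dropped; extra
    candidates stay roots.
    """
    starts: dict[int, list[int]] = {}
    for tid in matrix.tracks:
        starts.setdefault(matrix.start_frame(tid), []).append(tid)

    nodes: dict[int, LineageNode] = {tid: LineageNode(tid) for tid in matrix.tracks}
    child_of: dict[int, int] = {}

    for ev in events:
        parent_obs = matrix.last_obs(ev.parent_track)
        cands = []
        for df in range(0, max_daughter_gap + 1):
            for tid in starts.get(ev.frame + df, ()):
                if tid == ev.parent_track or tid in child_of:
                    continue
                first = matrix.first_obs(tid)
                if first.overlaps(parent_obs):
                    cands.append(tid)
        if len(cands) < 2:
            logger.info("division of track %s at frame %s: %d daughter candidate(s), dropped",
                        ev.parent_track, ev.frame, len(cands))
            ev.daughters = None
            continue
        left, right = _half_masks(parent_obs, ev.septum_position)
        scored = []
        for tid in cands:
            px = _obs_pixels(matrix.first_obs(tid))
            scored.append((tid, len(px & left), len(px & right)))
        best_left = max(scored, key=lambda t: t[1])
        best_right = max((s for s in scored if s[0] != best_left[0]),
                         key=lambda t: t[2])
        da, db = sorted((best_left[0], best_right[0]))
        ev.daughters = (da, db)
        for d in (da, db):
            child_of[d] = ev.parent_track
            nodes[ev.parent_track].add_child(nodes[d])

    forest = [LineageTree(nodes[tid]) for tid in sorted(matrix.tracks)
              if tid not in child_of]
    return forest


def forest_to_newick(forest: list[LineageTree]) -> str:
    """Newick serialization (track ids as labels), one tree per line."""

    def rec(node: LineageNode) -> str:
        if not node.children:
            return str(node.track_id)
        inner = ",".join(rec(c) for c in node.children)
        return f"({inner}){node.track_id}"

    return "\n".join(rec(t.root) + ";" for t in forest)
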