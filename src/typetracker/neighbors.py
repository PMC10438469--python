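"""Neighbor detection and separation-rate analysis.

Epithelial adjacency is decided per frame by the *neighbor score*: for a
candidate pair A, B and any third cell S, the score is
``(d_AS + d_BS) / d_AB``.  It is 1 when S sits exactly between A and B and
grows as S moves away from the segment; the pair's score is the minimum over
all other cells in the frame, and the pair are neighbors when that minimum
exceeds the cutoff (default 2), i.e. when no other nucleus lies between
them.  Only the ``k_candidates`` (default 20) nearest cells of a focal cell
are considered as potential partners; blocking cells S are unrestricted.

The cutoff comparison admits scores equal to the cutoff up to a small
numerical tolerance: in an ideal hexagonally packed epithelium the blocking
cells of an adjacent pair form equilateral triangles with score exactly 2,
and those pairs are adjacent (interior cells have six neighbors, as expected
on the basal side of a curved epithelium).

Separation rates follow pairs over time: partners of a newly born cell are
selected one hour after its birth (when nuclei have returned to the basal
side) from its neighbor-graph edges; if a followed cell divides, one of its
daughters (chosen by the run's seeded RNG) substitutes for it, and the pair
counts as "still neighbors" at a horizon iff it is a graph edge at the frame
nearest that horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .model import CellType, LineageForest, TypedForest

__all__ = [
    "neighbor_score",
    "pair_min_score",
    "pair_is_neighbor",
    "NeighborGraph",
    "neighbor_graph",
    "GraphProvider",
    "SeparationResult",
    "follow_pairs",
    "sister_separation",
]

logger = logging.getLogger(__name__)

#: Scores within this tolerance of the cutoff count as above it.
CUTOFF_TOL = 1e-9


def neighbor_score(a, b, s) -> float:
    """``(d_AS + d_BS) / d_AB`` for one blocking cell S; >= 1 always."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    s = np.asarray(s, float)
    d_ab = float(np.linalg.norm(a - b))
    if d_ab == 0.0:
        raise ValueError("neighbor score undefined for coincident pair (d_AB = 0)")
    return float((np.linalg.norm(a - s) + np.linalg.norm(b - s)) / d_ab)


def _min_scores_for_focal(
    i: int, candidates: np.ndarray, dist: np.ndarray
) -> np.ndarray:
    """Min-over-S neighbor score of pairs (i, j) for each candidate j.

    ``dist`` is the full per-frame distance matrix.  The blocking set for a
    pair is every other cell in the frame; with no third cell the score is
    +inf (an isolated pair is trivially adjacent).
    """
    n = dist.shape[0]
    out = np.empty(len(candidates))
    for k, j in enumerate(candidates):
        d_ab = dist[i, j]
        if d_ab == 0.0:
            out[k] = np.inf
            continue
        ssum = dist[i] + dist[j]
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        out[k] = ssum[mask].min() / d_ab if mask.any() else np.inf
    return out


def pair_min_score(
    a_idx: int, b_idx: int, positions: np.ndarray
) -> float:
    """Min-over-S score for one pair given all frame positions."""
    dist = cdist(positions, positions)
    return float(_min_scores_for_focal(a_idx, np.array([b_idx]), dist)[0])


def pair_is_neighbor(
    a_id: int,
    b_id: int,
    frame_positions: dict[int, np.ndarray],
    k_candidates: int = 20,
    cutoff: float = 2.0,
) -> bool:
    """Are A and B neighbors in this frame?

    B must be among A's ``k_candidates`` nearest cells; the pair's min-over-S
    score must exceed ``cutoff`` (boundary inclusive up to numerical
    tolerance, see module docstring).
    """
    ids = sorted(frame_positions)
    if a_id not in frame_positions or b_id not in frame_positions:
        raise KeyError("both cells must be present in the frame")
    pos = np.stack([np.asarray(frame_positions[t], float) for t in ids])
    i, j = ids.index(a_id), ids.index(b_id)
    dist = cdist(pos, pos)
    order = np.argsort(dist[i], kind="stable")
    nearest = [k for k in order if k != i][:k_candidates]
    if j not in nearest:
        return False
    score = _min_scores_for_focal(i, np.array([j]), dist)[0]
    return bool(score > cutoff - CUTOFF_TOL)


@dataclass
class NeighborGraph:
    """Per-frame undirected adjacency between tracked cells."""

    frame: int
    nodes: list[int]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def neighbors_of(self, a: int) -> list[int]:
        out = [v if u == a else u for u, v in self.edges if a in (u, v)]
        return sorted(out)

    def degree(self, a: int) -> int:
        return sum(1 for e in self.edges if a in e)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def neighbor_graph(
    ids: list[int],
    positions: np.ndarray,
    frame: int = 0,
    k_candidates: int = 20,
    cutoff: float = 2.0,
) -> NeighborGraph:
    """Neighbor graph of one frame.

    Edges are the union of pairs passing the neighbor test from either
    endpoint, which makes the graph symmetric by construction.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(ids)
    graph = NeighborGraph(frame=frame, nodes=sorted(ids))
    if n < 2:
        return graph
    dist = cdist(positions, positions)
    order = np.argsort(dist, axis=1, kind="stable")
    for i in range(n):
        nearest = order[i][order[i] != i][:k_candidates]
        scores = _min_scores_for_focal(i, nearest, dist)
        for j, sc in zip(nearest, scores):
            if sc > cutoff - CUTOFF_TOL:
                a, b = ids[i], ids[int(j)]
                graph.edges.add((min(a, b), max(a, b)))
    return graph


class GraphProvider:
    """Lazily computed, cached per-frame neighbor graphs for a forest."""

    def __init__(
        self,
        forest: LineageForest,
        k_candidates: int = 20,
        cutoff: float = 2.0,
    ) -> None:
        self.forest = forest
        self.k_candidates = k_candidates
        self.cutoff = cutoff
        self._cache: dict[int, NeighborGraph] = {}

    def graph_at(self, frame: int) -> NeighborGraph:
        if frame not in self._cache:
            ids, pos = self.forest.positions_at_frame(frame)
            self._cache[frame] = neighbor_graph(
                ids, pos, frame, self.k_candidates, self.cutoff
            )
        return self._cache[frame]


@dataclass
class SeparationResult:
    """Fraction of followed pairs still adjacent at each horizon."""

    horizons_h: tuple[float, ...]
    fractions: dict[float, float]
    n_followed: dict[float, int]
    n_excluded: dict[float, int]


def _resolve_member(
    forest: LineageForest, track_id: int, target_frame: int, rng: np.random.Generator
) -> int | None:
    """Follow a track to ``target_frame``, substituting a random daughter at
    each division; ``None`` if the lineage dies out or is lost first."""
    tid = track_id
    while forest.tracks[tid].last_frame < target_frame:
        tr = forest.tracks[tid]
        if tr.daughters is None:
            return None  # death / lost / movie end before target
        tid = tr.daughters[int(rng.integers(2))]
    return tid


def _follow(
    forest: LineageForest,
    graphs: GraphProvider,
    pairs: list[tuple[int, int, int]],  # (member_a, member_b, selection_frame)
    horizons_h: tuple[float, ...],
    rng: np.random.Generator,
) -> SeparationResult:
    fractions: dict[float, float] = {}
    n_followed: dict[float, int] = {}
    n_excluded: dict[float, int] = {}
    for h in horizons_h:
        dh = int(round(h / forest.frame_interval_h))
        still = 0
        followed = 0
        excluded = 0
        for a, b, sel_frame in pairs:
            target = sel_frame + dh
            if target > forest.movie_end_frame:
                excluded += 1
                continue
            ra = _resolve_member(forest, a, target, rng)
            rb = _resolve_member(forest, b, target, rng)
            if ra is None or rb is None:
                excluded += 1
                continue
            followed += 1
            if graphs.graph_at(target).has_edge(ra, rb):
                still += 1
        fractions[h] = still / followed if followed else float("nan")
        n_followed[h] = followed
        n_excluded[h] = excluded
        if excluded:
            logger.info(
                "horizon %.1f h: %d pair(s) excluded (window beyond movie or "
                "lineage ended)", h, excluded,
            )
    return SeparationResult(tuple(horizons_h), fractions, n_followed, n_excluded)


def follow_pairs(
    forest: LineageForest,
    graphs: GraphProvider,
    horizons_h: tuple[float, ...] = (2.0, 10.0),
    selection_delay_h: float = 1.0,
    rng_seed: int = 0,
) -> SeparationResult:
    """Neighbor persistence of newly born cells' neighbor pairs.

    For every track born at a fork, partners are its neighbor-graph edges at
    ``selection_delay_h`` after birth; each (focal, partner) pair is then
    followed to each horizon (measured from selection), with random-daughter
    substitution when a member divides.
    """
    rng = np.random.default_rng(rng_seed)
    delay = int(round(selection_delay_h / forest.frame_interval_h))
    pairs: list[tuple[int, int, int]] = []
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        if tr.parent is None:
            continue
        sel_frame = tr.first_frame + delay
        if sel_frame > tr.last_frame or sel_frame > forest.movie_end_frame:
            continue  # focal divided/died before selection
        for partner in graphs.graph_at(sel_frame).neighbors_of(tid):
            pairs.append((tid, partner, sel_frame))
    return _follow(forest, graphs, pairs, horizons_h, rng)


def sister_separation(
    typed: TypedForest,
    graphs: GraphProvider,
    horizons_h: tuple[float, ...] = (2.0, 10.0),
    selection_delay_h: float = 1.0,
    rng_seed: int = 0,
) -> dict[CellType, SeparationResult]:
    """Separation of same-type sister pairs, stratified by inferred type.

    Applies the follow protocol of :func:`follow_pairs` to every sister pair
    sharing the same (non-UNKNOWN) inferred type.  Returns an empty mapping
    (with a logged warning) when the forest has no eligible sister pairs.
    """
    forest = typed.forest
    rng = np.random.default_rng(rng_seed)
    delay = int(round(selection_delay_h / forest.frame_interval_h))
    by_type: dict[CellType, list[tuple[int, int, int]]] = {}
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        if tr.daughters is None:
            continue
        d1, d2 = tr.daughters
        t1, t2 = typed.type_of(d1), typed.type_of(d2)
        if t1 is not t2 or t1 is CellType.UNKNOWN:
            continue
        sel_frame = forest.tracks[d1].first_frame + delay
        if sel_frame > forest.movie_end_frame:
            continue
        if (
            sel_frame > forest.tracks[d1].last_frame
            or sel_frame > forest.tracks[d2].last_frame
        ):
            continue  # a sister divided or ended before selection
        by_type.setdefault(t1, []).append((d1, d2, sel_frame))
    if not by_type:
        logger.warning("no same-type sister pairs to follow")
        return {}
    return {
        ct: _follow(forest, graphs, prs, horizons_h, rng)
        for ct, prs in sorted(by_type.items(), key=lambda kv: kv[0].value)
    }
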