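"""End-point cell typing: marker gating, the type decision table, and
matching of stained cells to tracked end-point cells.

After the last movie frame the organoid is fixed and stained in several
rounds, producing one table of stained cells (post-fixation positions plus a
six-marker panel: Olfm4, Cga, Aldo-beta, KRT20, WGA, Lyz).  Each stained cell
must be linked back to a tracked cell at the movie end point.  Fixation and
washing deform the tissue slightly, so the link is found by a globally
optimal one-to-one point-set matching that minimises the summed Euclidean
distance, with a hard gate ``max_match_distance`` (default 10 um, about one
nucleus) replacing manual curation: pairs farther apart stay unmatched and
are reported for audit.

The decision table maps a boolean marker panel to a type:

========== ===============================================
type       panel
========== ===============================================
stem       Olfm4+ only
EEC        Cga+ only
enterocyte Aldo-beta+ (KRT20 may be + or -), rest -
Paneth     WGA+ and Lyz+ (KRT20 free), Olfm4/Cga/Aldo -
goblet     WGA+ and KRT20+, Lyz-, rest -
IMPC       WGA+ only
TA         all six negative
========== ===============================================

Any other combination is a conflict and maps to ``UNKNOWN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu

from .model import CellType, LineageForest, MARKERS

__all__ = [
    "call_positivity",
    "call_type",
    "otsu_thresholds",
    "Assignment",
    "match_stained_to_tracked",
    "TypingReport",
    "assign_endpoint_types",
]

logger = logging.getLogger(__name__)


def call_positivity(
    intensities: dict[str, float], thresholds: dict[str, float]
) -> dict[str, bool]:
    """Convert marker intensities to boolean positivity.

    A marker is positive iff its intensity is *strictly* greater than its
    threshold.  All six markers must be present in both mappings.
    """
    calls = {}
    for m in MARKERS:
        if m not in intensities:
            raise KeyError(f"missing marker intensity: {m}")
        if m not in thresholds:
            raise KeyError(f"missing marker threshold: {m}")
        calls[m] = bool(intensities[m] > thresholds[m])
    return calls


def call_type(markers: dict[str, bool]) -> CellType:
    """Apply the decision table to one boolean marker panel.

    Total over all 2^6 combinations; combinations outside the table return
    ``UNKNOWN`` (the caller decides how to log the conflict).
    """
    olfm4 = bool(markers["olfm4"])
    cga = bool(markers["cga"])
    aldob = bool(markers["aldob"])
    krt20 = bool(markers["krt20"])
    wga = bool(markers["wga"])
    lyz = bool(markers["lyz"])

    if olfm4 and not (cga or aldob or krt20 or wga or lyz):
        return CellType.STEM
    if cga and not (olfm4 or aldob or krt20 or wga or lyz):
        return CellType.EEC
    if aldob and not (olfm4 or cga or wga or lyz):  # KRT20 free
        return CellType.ENTEROCYTE
    if wga and lyz and not (olfm4 or cga or aldob):  # KRT20 free
        return CellType.PANETH
    if wga and krt20 and not (olfm4 or cga or aldob or lyz):
        return CellType.GOBLET
    if wga and not (olfm4 or cga or aldob or krt20 or lyz):
        return CellType.IMPC
    if not (olfm4 or cga or aldob or krt20 or wga or lyz):
        return CellType.TA
    return CellType.UNKNOWN


def otsu_thresholds(
    stain_table: pd.DataFrame, min_effectiveness: float = 0.85
) -> dict[str, float]:
    """Per-marker intensity thresholds from the staining table itself.

    Each marker is thresholded by Otsu's method, refined by two-class mean
    iteration (binned Otsu can cut through the edge of the negative cluster),
    with the final threshold midway between the two classes' boundary values.
    A marker with no positive population at all must not be split: if the
    split's effectiveness (between-class variance over total variance, Otsu's
    eta) falls below ``min_effectiveness``, or the intensities are constant,
    the threshold is set to the maximum intensity so every cell is negative.
    """
    out = {}
    for m in MARKERS:
        vals = stain_table[m].to_numpy(dtype=float)
        if len(vals) == 0:
            out[m] = 0.0
            continue
        if np.ptp(vals) == 0:
            out[m] = float(vals[0])
            continue
        t = float(threshold_otsu(vals))
        for _ in range(100):
            lo, hi = vals[vals <= t], vals[vals > t]
            if len(lo) == 0 or len(hi) == 0:
                break
            t_new = (lo.mean() + hi.mean()) / 2.0
            if t_new == t:
                break
            t = t_new
        lo, hi = vals[vals <= t], vals[vals > t]
        if len(lo) == 0 or len(hi) == 0:
            out[m] = float(vals.max())
            continue
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        eta = w0 * w1 * (lo.mean() - hi.mean()) ** 2 / vals.var()
        if eta < min_effectiveness:
            out[m] = float(vals.max())  # unimodal: no positive population
        else:
            out[m] = float((lo.max() + hi.min()) / 2.0)
    return out


@dataclass
class Assignment:
    """Result of one-to-one point-set matching.

    ``pairs`` holds ``(endpoint_id, stain_id, distance_um)`` triples; ids that
    could not be matched within the gate are listed on their own side.
    """

    pairs: list[tuple[int, int, float]]
    unmatched_endpoints: list[int]
    unmatched_stains: list[int]

    @property
    def total_cost(self) -> float:
        return float(sum(d for _, _, d in self.pairs))


def match_stained_to_tracked(
    endpoint_ids: list[int],
    endpoint_points: np.ndarray,
    stain_ids: list[int],
    stain_points: np.ndarray,
    max_match_distance: float = 10.0,
    prealign: bool = False,
) -> Assignment:
    """Optimal one-to-one matching of stained cells to end-point cells.

    Finds the assignment of maximal cardinality among those whose every pair
    is within ``max_match_distance``, minimising total Euclidean distance,
    via the Hungarian algorithm on a gate-padded cost matrix.  Inputs are
    processed in id-sorted order and cost ties are biased toward low
    (endpoint_id, stain_id) pairs, so the result is deterministic and
    independent of input ordering.

    ``prealign=True`` removes the centroid offset between the two clouds
    before matching (rigid translation pre-registration); reported distances
    refer to the aligned coordinates.
    """
    if max_match_distance <= 0:
        raise ValueError("max_match_distance must be positive")
    endpoint_points = np.asarray(endpoint_points, dtype=float).reshape(-1, 3)
    stain_points = np.asarray(stain_points, dtype=float).reshape(-1, 3)
    n, m = len(endpoint_ids), len(stain_ids)
    if n != len(endpoint_points) or m != len(stain_points):
        raise ValueError("ids and points disagree in length")
    if n == 0 or m == 0:
        return Assignment([], sorted(endpoint_ids), sorted(stain_ids))

    e_order = np.argsort(endpoint_ids)
    s_order = np.argsort(stain_ids)
    e_ids = [endpoint_ids[i] for i in e_order]
    s_ids = [stain_ids[j] for j in s_order]
    epts = endpoint_points[e_order]
    spts = stain_points[s_order]
    if prealign:
        spts = spts - spts.mean(axis=0) + epts.mean(axis=0)

    dist = cdist(epts, spts)
    feasible = dist <= max_match_distance
    # pad to a square matrix so every point may remain unmatched: leaving one
    # point out costs PENALTY, so cardinality is maximised first, cost second
    penalty = max_match_distance * (n + m) + 1.0
    forbidden = 3.0 * penalty
    size = n + m
    cost = np.full((size, size), 0.0)
    cost[:n, m:] = penalty  # endpoint unmatched
    cost[n:, :m] = penalty  # stain unmatched
    block = np.where(feasible, dist, forbidden)
    # deterministic tie-break: negligible bias toward low-index pairs
    eps = 1e-12 * max(1.0, max_match_distance)
    bias = eps * (np.arange(n)[:, None] * (m + 1) + np.arange(m)[None, :])
    cost[:n, :m] = block + bias

    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_e, matched_s = set(), set()
    for r, c in zip(rows, cols):
        if r < n and c < m and feasible[r, c]:
            pairs.append((e_ids[r], s_ids[c], float(dist[r, c])))
            matched_e.add(e_ids[r])
            matched_s.add(s_ids[c])
    pairs.sort()
    return Assignment(
        pairs=pairs,
        unmatched_endpoints=sorted(set(e_ids) - matched_e),
        unmatched_stains=sorted(set(s_ids) - matched_s),
    )


@dataclass
class TypingReport:
    """Audit record of one end-point typing run."""

    n_endpoints: int
    n_stained: int
    n_matched: int
    thresholds: dict[str, float] = field(default_factory=dict)
    conflicts: list[tuple[int, int, dict[str, bool]]] = field(default_factory=list)
    unmatched_endpoints: list[int] = field(default_factory=list)
    unmatched_stains: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_endpoints if self.n_endpoints else 0.0


def _marker_calls(stain_table: pd.DataFrame, thresholds: dict[str, float] | None):
    """Per-row boolean panels; ``<marker>_pos`` columns win over intensities."""
    has_bool = all(f"{m}_pos" in stain_table.columns for m in MARKERS)
    if has_bool:
        used_thresholds: dict[str, float] = {}
        panels = {
            int(r["stain_cell_id"]): {m: bool(r[f"{m}_pos"]) for m in MARKERS}
            for _, r in stain_table.iterrows()
        }
        return panels, used_thresholds
    if thresholds is None:
        thresholds = otsu_thresholds(stain_table)
    panels = {}
    for _, r in stain_table.iterrows():
        intensities = {m: float(r[m]) for m in MARKERS}
        panels[int(r["stain_cell_id"])] = call_positivity(intensities, thresholds)
    return panels, thresholds


def assign_endpoint_types(
    forest: LineageForest,
    stain_table: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    max_match_distance: float = 10.0,
    prealign: bool = False,
) -> tuple[dict[int, CellType], TypingReport]:
    """Type every end-point track of ``forest`` from a staining table.

    Tracks alive at the movie end are matched against the stained cells;
    matched tracks receive the decision-table type of their stain panel,
    unmatched / dead / lost terminal tracks receive ``UNKNOWN``.

    Returns the per-track end-point types (for every track without
    daughters) plus a :class:`TypingReport` with the match rate, conflicting
    panels and unmatched ids.
    """
    endpoint_ids = forest.endpoint_track_ids()
    types: dict[int, CellType] = {
        t: CellType.UNKNOWN
        for t, tr in forest.tracks.items()
        if tr.daughters is None
    }
    report = TypingReport(
        n_endpoints=len(endpoint_ids), n_stained=len(stain_table), n_matched=0
    )
    if len(stain_table) == 0:
        report.warnings.append("empty stain table: all end points UNKNOWN")
        logger.warning("empty stain table: all end points UNKNOWN")
        report.unmatched_endpoints = list(endpoint_ids)
        return types, report

    panels, used_thresholds = _marker_calls(stain_table, thresholds)
    report.thresholds = dict(used_thresholds)

    epts = (
        np.stack(
            [forest.tracks[t].position_at(forest.movie_end_frame) for t in endpoint_ids]
        )
        if endpoint_ids
        else np.empty((0, 3))
    )
    s_ids = [int(i) for i in stain_table["stain_cell_id"]]
    spts = stain_table[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    assignment = match_stained_to_tracked(
        endpoint_ids, epts, s_ids, spts, max_match_distance, prealign=prealign
    )
    for tid, sid, _dist in assignment.pairs:
        ct = call_type(panels[sid])
        if ct is CellType.UNKNOWN:
            report.conflicts.append((tid, sid, panels[sid]))
            logger.info(
                "conflicting marker panel for stain cell %d (track %d): %s",
                sid, tid, panels[sid],
            )
        types[tid] = ct
    report.n_matched = len(assignment.pairs)
    report.unmatched_endpoints = assignment.unmatched_endpoints
    report.unmatched_stains = assignment.unmatched_stains
    if report.n_matched == 0:
        report.warnings.append("no stained cell matched any end-point cell")
        logger.warning("no stained cell matched any end-point cell")
    return types, report
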