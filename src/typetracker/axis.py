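"""Crypt-villus axis geometry: spline fitting, arc-length projection,
per-frame normalisation and migration speed.

The axis of a crypt is annotated per frame by 3-6 ordered control points
(crypt bottom first) plus a neck point where the crypt meets the villus.  A
natural cubic spline is interpolated through the control points and
reparameterised to arc length by dense sampling; each cell is projected onto
the curve by minimising its distance to it, yielding an arc-length
coordinate ``r`` (um) and a residual distance ``d`` (um).

Per frame, ``r`` is zeroed at the bottom-most cell of that frame and
normalised by the zeroed arc length of the neck, so the crypt bottom sits at
``r_norm = 0`` and the neck at ``r_norm = 1`` in every frame regardless of
crypt size.  Migration speed is the first-to-last displacement in zeroed
``r`` divided by the time the cell was present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .model import AxisAnnotation, LineageForest

__all__ = [
    "CryptAxis",
    "fit_axis",
    "project",
    "zero_and_normalize",
    "compute_axis_positions",
    "migration_speed",
]


@dataclass
class CryptAxis:
    """A fitted, arc-length-sampled crypt-villus axis for one frame.

    ``samples``/``arclen`` hold a dense polyline (spacing <= ``spacing`` um)
    along the interpolating spline; ``r_neck`` is the arc length of the
    projected neck annotation (before per-frame zeroing).
    """

    frame: int
    samples: np.ndarray          # (M, 3)
    arclen: np.ndarray           # (M,), arclen[0] == 0, non-decreasing
    r_neck: float
    spacing: float

    @property
    def length(self) -> float:
        return float(self.arclen[-1])


def fit_axis(annotation: AxisAnnotation, spacing: float = 0.25) -> CryptAxis:
    """Interpolate a natural cubic spline through the control points and
    reparameterise it to arc length by dense sampling at ``spacing`` um."""
    pts = annotation.control_points
    # chordal parameterisation
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(u, pts, bc_type="natural", axis=0)
    # sample densely enough that polyline spacing stays below `spacing`
    n_dense = max(int(np.ceil(u[-1] / (spacing / 4))) + 1, 2)
    samples = spline(np.linspace(0.0, u[-1], n_dense))
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    r_neck, _ = _project_polyline(
        np.asarray(annotation.neck_point, float)[None, :], samples, arclen
    )
    return CryptAxis(
        frame=annotation.frame,
        samples=samples,
        arclen=arclen,
        r_neck=float(r_neck[0]),
        spacing=spacing,
    )


def _project_polyline(
    points: np.ndarray, samples: np.ndarray, arclen: np.ndarray, mode: str = "3d"
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest point on the sampled polyline for each query point.

    Finds the nearest vertex, then refines on the two segments flanking it.
    Returns (r, d) arrays.  ``mode='2d'`` measures distances in the xy plane
    only (for axes annotated at the crypt's central z plane).
    """
    q = points[:, :2] if mode == "2d" else points
    s = samples[:, :2] if mode == "2d" else samples
    # nearest vertex (chunked to bound memory)
    n = len(q)
    idx = np.empty(n, dtype=int)
    step = max(1, int(4e6 // max(len(s), 1)))
    for start in range(0, n, step):
        d2 = ((q[start:start + step, None, :] - s[None, :, :]) ** 2).sum(-1)
        idx[start:start + step] = np.argmin(d2, axis=1)
    r = np.empty(n)
    d = np.empty(n)
    for i in range(n):
        best_d2 = np.inf
        best_r = arclen[idx[i]]
        for j in (idx[i] - 1, idx[i]):
            if j < 0 or j + 1 >= len(s):
                continue
            a, b = s[j], s[j + 1]
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0.0:
                continue
            t = float(np.clip((q[i] - a) @ ab / denom, 0.0, 1.0))
            p = a + t * ab
            d2 = float(((q[i] - p) ** 2).sum())
            if d2 < best_d2:
                best_d2 = d2
                best_r = arclen[j] + t * (arclen[j + 1] - arclen[j])
        if not np.isfinite(best_d2):  # single-vertex degenerate polyline
            best_d2 = float(((q[i] - s[idx[i]]) ** 2).sum())
        r[i] = best_r
        d[i] = np.sqrt(best_d2)
    return r, d


def project(
    position: np.ndarray, axis: CryptAxis, mode: str = "3d"
) -> tuple[float, float]:
    """Arc-length coordinate and residual distance of one point (pre-zeroing)."""
    r, d = _project_polyline(
        np.asarray(position, float).reshape(1, 3), axis.samples, axis.arclen, mode
    )
    return float(r[0]), float(d[0])


def zero_and_normalize(
    r: np.ndarray, axis: CryptAxis
) -> tuple[np.ndarray, np.ndarray, float]:
    """Zero arc-length positions at the bottom-most cell of the frame and
    normalise by the neck distance.

    Returns ``(r_zeroed, r_norm, r_offset)``; requires at least one cell and
    a neck strictly above the bottom-most cell.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("no cells in frame")
    r_offset = float(r.min())
    denom = axis.r_neck - r_offset
    if denom <= 0:
        raise ValueError(
            f"frame {axis.frame}: neck arc length {axis.r_neck:.3f} um is at or "
            f"below the bottom-most cell ({r_offset:.3f} um)"
        )
    rz = r - r_offset
    return rz, rz / denom, r_offset


def _annotation_for_frame(
    annotations: dict[int, AxisAnnotation], frame: int, max_gap: int = 5
) -> AxisAnnotation:
    if frame in annotations:
        return annotations[frame]
    if annotations:
        nearest = min(annotations, key=lambda f: (abs(f - frame), f))
        if abs(nearest - frame) <= max_gap:
            return annotations[nearest]
    raise KeyError(
        f"no axis annotation at frame {frame} (none within +-{max_gap} frames)"
    )


def compute_axis_positions(
    forest: LineageForest,
    annotations: dict[int, AxisAnnotation],
    mode: str = "3d",
    frames: list[int] | None = None,
    max_gap: int = 5,
    spacing: float = 0.25,
) -> pd.DataFrame:
    """Project every cell of every (requested) frame onto that frame's axis.

    Returns a DataFrame with columns ``track_id, frame, r_raw, r, d, r_norm``
    where ``r_raw`` is the arc length before zeroing, ``r`` the per-frame
    zeroed arc length and ``r_norm`` the neck-normalised position.  Frames
    missing an annotation reuse the nearest one within ``max_gap`` frames,
    else raise.
    """
    if frames is None:
        frames = list(range(0, forest.movie_end_frame + 1))
    axis_cache: dict[int, CryptAxis] = {}
    out: list[tuple[int, int, float, float, float, float]] = []
    for frame in frames:
        ids, pos = forest.positions_at_frame(frame)
        if not ids:
            continue
        ann = _annotation_for_frame(annotations, frame, max_gap)
        if ann.frame not in axis_cache:
            axis_cache[ann.frame] = fit_axis(ann, spacing=spacing)
        axis = axis_cache[ann.frame]
        r_raw, d = _project_polyline(pos, axis.samples, axis.arclen, mode)
        rz, rn, _ = zero_and_normalize(r_raw, axis)
        for i, tid in enumerate(ids):
            out.append((tid, frame, r_raw[i], rz[i], d[i], rn[i]))
    return pd.DataFrame(
        out, columns=["track_id", "frame", "r_raw", "r", "d", "r_norm"]
    )


def migration_speed(
    track_id: int,
    axis_positions: pd.DataFrame,
    frame_interval_h: float,
    method: str = "endpoints",
) -> float:
    """Signed migration speed (um/h, positive toward the villus) of a track.

    ``endpoints`` (default) divides the zeroed-``r`` displacement between the
    track's first and last observed frames by the elapsed time; ``regression``
    instead fits a least-squares line to r(t) over the whole track (more
    robust, non-default).
    """
    rows = axis_positions[axis_positions["track_id"] == track_id].sort_values("frame")
    if len(rows) < 2:
        raise ValueError(
            f"track {track_id}: need >=2 frames with axis positions, got {len(rows)}"
        )
    t = rows["frame"].to_numpy(dtype=float) * frame_interval_h
    r = rows["r"].to_numpy(dtype=float)
    if method == "endpoints":
        return float((r[-1] - r[0]) / (t[-1] - t[0]))
    if method == "regression":
        return float(np.polyfit(t, r, 1)[0])
    raise ValueError(f"unknown method {method!r}")
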