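"""Readers and writers for lineage forests, staining tables, axis annotations
and typed forests.

Two on-disk dialects are supported for forests:

* **tabular** — a directory of plain CSV files designed for diff-ability and
  spreadsheet inspection:

  - ``points.csv``: ``track_id, frame, x_um, y_um, z_um`` (one row per
    observation; frames within a track must be consecutive),
  - ``links.csv``: ``child_id, parent_id`` (one row per daughter),
  - ``meta.csv``: ``key, value`` rows for ``movie_end_frame`` and
    ``frame_interval_h``,
  - ``end_reasons.csv`` (optional): ``track_id, end_reason`` for tracks that
    end in ``death`` or ``lost``.  Tracks that end early without an entry
    default to ``lost`` (conservative: lost cells cannot anchor types).

* **tracker-json** — a single JSON file in the style of nucleus-tracking
  tools: a flat list of per-frame points plus point-to-point links, from
  which tracks are assembled (a point with two successors is a division).
  Unknown keys are tolerated.  See ``docs/tracker_json_schema.json``.

Staining tables and axis annotations are single CSV files (see
:func:`load_stain_table` and :func:`load_axis_annotations`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AxisAnnotation,
    CellType,
    EndReason,
    ForestError,
    LineageForest,
    MARKERS,
    Track,
    TransitionEvent,
    TypedForest,
)

__all__ = [
    "load_forest",
    "save_forest",
    "load_stain_table",
    "save_stain_table",
    "load_axis_annotations",
    "save_axis_annotations",
    "save_typed_forest",
    "load_typed_forest",
]


# ---------------------------------------------------------------------------
# forest: tabular dialect
# ---------------------------------------------------------------------------

def _build_forest(
    points: pd.DataFrame,
    links: dict[int, int],
    movie_end_frame: int,
    frame_interval_h: float,
    end_reasons: dict[int, EndReason],
) -> LineageForest:
    """Assemble and validate a forest from long-format points + child->parent
    links."""
    tracks: dict[int, Track] = {}
    daughters: dict[int, list[int]] = {}
    for child, parent in links.items():
        daughters.setdefault(parent, []).append(child)
    for parent, ds in daughters.items():
        if len(ds) != 2:
            raise ForestError(
                f"track {parent} has {len(ds)} daughter(s) in links; "
                f"divisions are binary"
            )
    for tid, grp in points.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if len(frames) > 1 and not np.array_equal(
            frames, np.arange(frames[0], frames[0] + len(frames))
        ):
            raise ForestError(f"track {tid}: frames are not consecutive")
        if len(np.unique(frames)) != len(frames):
            raise ForestError(f"track {tid}: duplicate frame entries")
        tid = int(tid)
        ds = daughters.get(tid)
        if ds is not None:
            reason = EndReason.DIVISION
        elif int(frames[-1]) == movie_end_frame:
            reason = EndReason.MOVIE_END
        else:
            reason = end_reasons.get(tid, EndReason.LOST)
        tracks[tid] = Track(
            track_id=tid,
            first_frame=int(frames[0]),
            positions=grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            parent=links.get(tid),
            daughters=tuple(sorted(ds)) if ds is not None else None,
            end_reason=reason,
        )
    for child, parent in links.items():
        if child not in tracks:
            raise ForestError(f"links mention unknown child track {child}")
        if parent not in tracks:
            raise ForestError(f"track {child} lists missing parent {parent}")
    return LineageForest(
        tracks=tracks,
        movie_end_frame=movie_end_frame,
        frame_interval_h=frame_interval_h,
    )


def _load_tabular(path: Path) -> LineageForest:
    pts_file = path / "points.csv"
    if not pts_file.exists():
        raise ForestError(f"{pts_file} not found")
    points = pd.read_csv(pts_file)
    required = {"track_id", "frame", "x_um", "y_um", "z_um"}
    missing = required - set(points.columns)
    if missing:
        raise ForestError(f"{pts_file}: missing column(s) {sorted(missing)}")

    links: dict[int, int] = {}
    links_file = path / "links.csv"
    if links_file.exists():
        ldf = pd.read_csv(links_file)
        for _, row in ldf.iterrows():
            child = int(row["child_id"])
            if child in links:
                raise ForestError(f"{links_file}: child {child} listed twice")
            links[child] = int(row["parent_id"])

    meta = pd.read_csv(path / "meta.csv").set_index("key")["value"]
    movie_end_frame = int(float(meta["movie_end_frame"]))
    frame_interval_h = float(meta["frame_interval_h"])

    end_reasons: dict[int, EndReason] = {}
    er_file = path / "end_reasons.csv"
    if er_file.exists():
        edf = pd.read_csv(er_file)
        for _, row in edf.iterrows():
            end_reasons[int(row["track_id"])] = EndReason(str(row["end_reason"]))

    return _build_forest(points, links, movie_end_frame, frame_interval_h, end_reasons)


def _save_tabular(forest: LineageForest, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        for i, f in enumerate(tr.frames):
            x, y, z = tr.positions[i]
            rows.append((tid, int(f), x, y, z))
    pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um", "z_um"]
    ).to_csv(path / "points.csv", index=False)
    links = [
        (tid, tr.parent)
        for tid, tr in sorted(forest.tracks.items())
        if tr.parent is not None
    ]
    pd.DataFrame(links, columns=["child_id", "parent_id"]).to_csv(
        path / "links.csv", index=False
    )
    pd.DataFrame(
        {
            "key": ["movie_end_frame", "frame_interval_h"],
            "value": [forest.movie_end_frame, forest.frame_interval_h],
        }
    ).to_csv(path / "meta.csv", index=False)
    reasons = [
        (tid, tr.end_reason.value)
        for tid, tr in sorted(forest.tracks.items())
        if tr.end_reason in (EndReason.DEATH, EndReason.LOST)
    ]
    pd.DataFrame(reasons, columns=["track_id", "end_reason"]).to_csv(
        path / "end_reasons.csv", index=False
    )


# ---------------------------------------------------------------------------
# forest: tracker-JSON dialect
# ---------------------------------------------------------------------------

def _load_tracker_json(path: Path) -> LineageForest:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:  # pragma: no cover - message detail
            raise ForestError(f"{path}: malformed JSON at line {e.lineno}") from e
    for key in ("positions", "links"):
        if key not in doc:
            raise ForestError(f"{path}: missing required key '{key}'")

    pts: dict[int, dict] = {}
    for rec in doc["positions"]:
        try:
            pid = int(rec["id"])
            pts[pid] = {
                "frame": int(rec["frame"]),
                "xyz": (float(rec["x"]), float(rec["y"]), float(rec["z"])),
                "track": rec.get("track"),
            }
        except (KeyError, TypeError, ValueError) as e:
            raise ForestError(f"{path}: malformed position record {rec!r}") from e

    succ: dict[int, list[int]] = {}
    pred: dict[int, int] = {}
    for pair in doc["links"]:
        a, b = int(pair[0]), int(pair[1])
        if a not in pts or b not in pts:
            raise ForestError(f"{path}: link ({a}, {b}) references unknown point")
        # orient the link by frame order
        if pts[a]["frame"] + 1 == pts[b]["frame"]:
            src, dst = a, b
        elif pts[b]["frame"] + 1 == pts[a]["frame"]:
            src, dst = b, a
        else:
            raise ForestError(
                f"{path}: link ({a}, {b}) does not join consecutive frames"
            )
        succ.setdefault(src, []).append(dst)
        if dst in pred:
            raise ForestError(f"{path}: point {dst} has two predecessors")
        pred[dst] = src

    deaths = {int(p) for p in doc.get("deaths", [])}

    movie_end_frame = doc.get("movie_end_frame")
    if movie_end_frame is None:
        movie_end_frame = max(p["frame"] for p in pts.values()) if pts else 0
    frame_interval_h = float(doc.get("frame_interval_h", 0.2))

    # walk chains: a track starts at a point with no predecessor or whose
    # predecessor divided (two successors)
    starts = []
    for pid, rec in pts.items():
        p = pred.get(pid)
        if p is None or len(succ.get(p, [])) == 2:
            starts.append(pid)
    # deterministic track ids: honour an explicit "track" key when present,
    # else number chains in (first frame, point id) order
    explicit = all(pts[s]["track"] is not None for s in starts) and starts
    starts.sort(key=lambda s: (pts[s]["frame"], s))
    chain_id: dict[int, int] = {}
    for i, s in enumerate(starts):
        chain_id[s] = int(pts[s]["track"]) if explicit else i + 1

    tracks: dict[int, Track] = {}
    parent_of: dict[int, int] = {}
    daughters_of: dict[int, list[int]] = {}
    for s in starts:
        tid = chain_id[s]
        chain = [s]
        cur = s
        while len(succ.get(cur, [])) == 1:
            cur = succ[cur][0]
            chain.append(cur)
        nxt = succ.get(cur, [])
        if len(nxt) == 2:
            reason = EndReason.DIVISION
            for d in nxt:
                parent_of[chain_id[d]] = tid
                daughters_of.setdefault(tid, []).append(chain_id[d])
        elif len(nxt) > 2:
            raise ForestError(f"{path}: point {cur} has {len(nxt)} successors")
        elif cur in deaths:
            reason = EndReason.DEATH
        elif pts[cur]["frame"] == int(movie_end_frame):
            reason = EndReason.MOVIE_END
        else:
            reason = EndReason.LOST
        frames = [pts[p]["frame"] for p in chain]
        if frames != list(range(frames[0], frames[0] + len(frames))):
            raise ForestError(f"{path}: track through point {s} skips frames")
        tracks[tid] = Track(
            track_id=tid,
            first_frame=frames[0],
            positions=np.array([pts[p]["xyz"] for p in chain]),
            end_reason=reason,
        )
    for tid, tr in tracks.items():
        tr.parent = parent_of.get(tid)
        ds = daughters_of.get(tid)
        tr.daughters = tuple(sorted(ds)) if ds else None
    return LineageForest(
        tracks=tracks,
        movie_end_frame=int(movie_end_frame),
        frame_interval_h=frame_interval_h,
    )


def _save_tracker_json(forest: LineageForest, path: Path) -> None:
    positions = []
    links = []
    deaths = []
    pid_of: dict[tuple[int, int], int] = {}
    nxt = 1
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        for i, f in enumerate(tr.frames):
            pid_of[(tid, int(f))] = nxt
            x, y, z = tr.positions[i]
            positions.append(
                {"id": nxt, "frame": int(f), "x": x, "y": y, "z": z, "track": tid}
            )
            nxt += 1
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        for f in range(tr.first_frame, tr.last_frame):
            links.append([pid_of[(tid, f)], pid_of[(tid, f + 1)]])
        if tr.daughters is not None:
            for d in tr.daughters:
                links.append(
                    [pid_of[(tid, tr.last_frame)], pid_of[(d, tr.last_frame + 1)]]
                )
        if tr.end_reason is EndReason.DEATH:
            deaths.append(pid_of[(tid, tr.last_frame)])
    doc = {
        "format": "typetracker tracker-json",
        "movie_end_frame": forest.movie_end_frame,
        "frame_interval_h": forest.frame_interval_h,
        "positions": positions,
        "links": links,
        "deaths": deaths,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_forest(path: str | Path, format: str = "auto") -> LineageForest:
    """Load a lineage forest from disk.

    Parameters
    ----------
    path
        Directory (tabular dialect) or ``.json`` file (tracker-json dialect).
    format
        ``"tabular"``, ``"tracker-json"``, or ``"auto"`` (by path type).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "tabular" if path.is_dir() else "tracker-json"
    if format == "tabular":
        return _load_tabular(path)
    if format == "tracker-json":
        return _load_tracker_json(path)
    raise ValueError(f"unknown forest format {format!r}")


def save_forest(forest: LineageForest, path: str | Path, format: str = "tabular") -> None:
    """Write a forest in the requested dialect (see :func:`load_forest`)."""
    path = Path(path)
    if format == "tabular":
        _save_tabular(forest, path)
    elif format == "tracker-json":
        _save_tracker_json(forest, path)
    else:
        raise ValueError(f"unknown forest format {format!r}")


# ---------------------------------------------------------------------------
# staining tables and axis annotations
# ---------------------------------------------------------------------------

def load_stain_table(path: str | Path) -> pd.DataFrame:
    """Load an end-point staining table.

    Required columns: ``stain_cell_id, x_um, y_um, z_um`` plus, per marker,
    either an intensity column named after the marker (``olfm4`` ...) or a
    boolean positivity column ``<marker>_pos``.
    """
    df = pd.read_csv(path)
    required = {"stain_cell_id", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for m in MARKERS:
        if m not in df.columns and f"{m}_pos" not in df.columns:
            raise ValueError(f"{path}: no intensity or positivity column for {m}")
        if m in df.columns and (df[m] < 0).any():
            raise ValueError(f"{path}: negative intensities for {m}")
    return df


def save_stain_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_axis_annotations(path: str | Path) -> dict[int, AxisAnnotation]:
    """Load per-frame axis annotations.

    CSV columns: ``frame, point_index, x_um, y_um, z_um, is_neck``; the neck
    row has ``is_neck=1`` and its ``point_index`` is ignored; control points
    are ordered by ``point_index``, crypt bottom first.
    """
    df = pd.read_csv(path)
    out: dict[int, AxisAnnotation] = {}
    for frame, grp in df.groupby("frame"):
        neck = grp[grp["is_neck"] == 1]
        ctrl = grp[grp["is_neck"] != 1].sort_values("point_index")
        if len(neck) != 1:
            raise ValueError(f"frame {frame}: expected exactly one neck point")
        out[int(frame)] = AxisAnnotation(
            frame=int(frame),
            control_points=ctrl[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            neck_point=neck[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)[0],
        )
    return out


def save_axis_annotations(annotations: dict[int, AxisAnnotation], path: str | Path) -> None:
    rows = []
    for frame in sorted(annotations):
        ann = annotations[frame]
        for i, (x, y, z) in enumerate(ann.control_points):
            rows.append((frame, i, x, y, z, 0))
        nx, ny, nz = ann.neck_point
        rows.append((frame, -1, nx, ny, nz, 1))
    pd.DataFrame(
        rows, columns=["frame", "point_index", "x_um", "y_um", "z_um", "is_neck"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# typed forests
# ---------------------------------------------------------------------------

def save_typed_forest(typed: TypedForest, path: str | Path) -> None:
    """Write a typed forest as a directory: the tabular forest files plus
    ``track_types.csv``, ``transitions.csv`` and ``flags.csv``.

    Every track must carry a type (``UNKNOWN`` is allowed).
    """
    missing = [t for t in typed.forest.tracks if t not in typed.track_types]
    if missing:
        raise ValueError(f"untyped track(s): {sorted(missing)}")
    path = Path(path)
    _save_tabular(typed.forest, path)
    pd.DataFrame(
        [(t, typed.track_types[t].value) for t in sorted(typed.track_types)],
        columns=["track_id", "type"],
    ).to_csv(path / "track_types.csv", index=False)
    pd.DataFrame(
        [
            (ev.track_id, ev.from_type.value, ev.to_type.value, ev.frame,
             ev.position[0], ev.position[1], ev.position[2])
            for ev in typed.transitions
        ],
        columns=["track_id", "from_type", "to_type", "frame", "x_um", "y_um", "z_um"],
    ).to_csv(path / "transitions.csv", index=False)
    pd.DataFrame(
        [(t, "low_confidence") for t in sorted(typed.low_confidence)]
        + [
            (t, f"conflict:{a.value}|{b.value}")
            for t, a, b in typed.conflicts
        ],
        columns=["track_id", "flag"],
    ).to_csv(path / "flags.csv", index=False)


def load_typed_forest(path: str | Path) -> TypedForest:
    path = Path(path)
    forest = _load_tabular(path)
    tdf = pd.read_csv(path / "track_types.csv")
    track_types = {
        int(r["track_id"]): CellType(str(r["type"])) for _, r in tdf.iterrows()
    }
    transitions = []
    xdf = pd.read_csv(path / "transitions.csv")
    for _, r in xdf.iterrows():
        transitions.append(
            TransitionEvent(
                track_id=int(r["track_id"]),
                from_type=CellType(str(r["from_type"])),
                to_type=CellType(str(r["to_type"])),
                frame=int(r["frame"]),
                position=(float(r["x_um"]), float(r["y_um"]), float(r["z_um"])),
            )
        )
    low_confidence: set[int] = set()
    conflicts: list[tuple[int, CellType, CellType]] = []
    fdf = pd.read_csv(path / "flags.csv")
    for _, r in fdf.iterrows():
        flag = str(r["flag"])
        if flag == "low_confidence":
            low_confidence.add(int(r["track_id"]))
        elif flag.startswith("conflict:"):
            a, b = flag.split(":", 1)[1].split("|")
            conflicts.append((int(r["track_id"]), CellType(a), CellType(b)))
    return TypedForest(
        forest=forest,
        track_types=track_types,
        transitions=transitions,
        conflicts=conflicts,
        low_confidence=low_confidence,
    )
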