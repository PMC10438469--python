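"""Core data model for tracked organoid cell lineages.

The central container is the :class:`LineageForest`: a set of tracks, each a
contiguous run of per-frame 3D nuclear positions, connected by parent/daughter
links at division forks.  A *track* is the life of one cell between two
divisions (or between a division and the movie end / the cell's death / the
loss of the track).  Divisions are always binary: a dividing track has exactly
two daughter tracks whose first frame follows the mother's last frame.

Coordinates are micrometres, with any axial (z) anisotropy already corrected
upstream by the tracker.  Time is stored as integer frame indices; wall-clock
hours are derived through ``frame_interval_h`` (default 0.2 h, i.e. one frame
every 12 minutes).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellType",
    "EndReason",
    "ForestError",
    "Track",
    "LineageForest",
    "AxisAnnotation",
    "TypeInterval",
    "TransitionEvent",
    "TypedForest",
    "MARKERS",
    "CANONICAL_TYPES",
]

#: The six end-point staining markers, in canonical column order.
MARKERS = ("olfm4", "cga", "aldob", "krt20", "wga", "lyz")


class CellType(enum.Enum):
    """Intestinal cell-type labels used throughout the package.

    ``UNKNOWN`` is a system-assigned sink state (unmatched, dead or lost
    end points, or conflicting marker panels); it is never read from a
    typing table.
    """

    STEM = "stem"
    TA = "ta"
    ENTEROCYTE = "enterocyte"
    EEC = "eec"
    PANETH = "paneth"
    GOBLET = "goblet"
    IMPC = "impc"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # compact CSV/CLI rendering
        return self.value


#: The eight real labels (everything except UNKNOWN), canonical display order.
CANONICAL_TYPES = (
    CellType.STEM,
    CellType.TA,
    CellType.ENTEROCYTE,
    CellType.EEC,
    CellType.PANETH,
    CellType.GOBLET,
    CellType.IMPC,
)


class EndReason(enum.Enum):
    """Why a track ends."""

    DIVISION = "division"
    DEATH = "death"
    MOVIE_END = "movie_end"
    LOST = "lost"

    def __str__(self) -> str:
        return self.value


class ForestError(ValueError):
    """Structural violation in a lineage forest or one of its files."""


@dataclass
class Track:
    """One cell's life between forks.

    Parameters
    ----------
    track_id
        Unique integer identifier.
    first_frame
        Frame index of the first observation.
    positions
        ``(n_frames, 3)`` float array of x, y, z in micrometres; row ``i``
        is the position at frame ``first_frame + i``.
    parent
        ``track_id`` of the mother track, or ``None`` for roots.
    daughters
        Pair of daughter ``track_id`` values for dividing tracks, else ``None``.
    end_reason
        Why the track ends; ``DIVISION`` iff ``daughters`` is set.
    """

    track_id: int
    first_frame: int
    positions: np.ndarray
    parent: int | None = None
    daughters: tuple[int, int] | None = None
    end_reason: EndReason = EndReason.MOVIE_END

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ForestError(
                f"track {self.track_id}: positions must be (n, 3), "
                f"got {self.positions.shape}"
            )
        if len(self.positions) == 0:
            raise ForestError(f"track {self.track_id}: empty track")
        if self.daughters is not None:
            # canonical order so saved/loaded forests compare equal
            self.daughters = tuple(sorted(self.daughters))  # type: ignore[assignment]

    @property
    def last_frame(self) -> int:
        return self.first_frame + len(self.positions) - 1

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.last_frame + 1)

    def position_at(self, frame: int) -> np.ndarray:
        if not self.first_frame <= frame <= self.last_frame:
            raise KeyError(
                f"track {self.track_id} not present at frame {frame} "
                f"(span {self.first_frame}..{self.last_frame})"
            )
        return self.positions[frame - self.first_frame]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        return (
            self.track_id == other.track_id
            and self.first_frame == other.first_frame
            and self.parent == other.parent
            and self.daughters == other.daughters
            and self.end_reason == other.end_reason
            and np.array_equal(self.positions, other.positions)
        )


@dataclass
class LineageForest:
    """A validated collection of tracks forming binary lineage trees."""

    tracks: dict[int, Track]
    movie_end_frame: int
    frame_interval_h: float = 0.2

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise :class:`ForestError` naming
        the offending track(s) otherwise."""
        for tid, tr in self.tracks.items():
            if tid != tr.track_id:
                raise ForestError(f"track keyed {tid} carries id {tr.track_id}")
            if tr.last_frame > self.movie_end_frame:
                raise ForestError(
                    f"track {tid} extends to frame {tr.last_frame} beyond "
                    f"movie end frame {self.movie_end_frame}"
                )
            if tr.parent is not None:
                if tr.parent not in self.tracks:
                    raise ForestError(f"track {tid} lists missing parent {tr.parent}")
                mother = self.tracks[tr.parent]
                if mother.daughters is None or tid not in mother.daughters:
                    raise ForestError(
                        f"track {tid} lists parent {tr.parent}, which does not "
                        f"list it as a daughter"
                    )
                if tr.first_frame != mother.last_frame + 1:
                    raise ForestError(
                        f"track {tid} starts at frame {tr.first_frame}, expected "
                        f"{mother.last_frame + 1} (parent {tr.parent} ends at "
                        f"{mother.last_frame})"
                    )
            if tr.daughters is not None:
                if len(set(tr.daughters)) != 2:
                    raise ForestError(
                        f"track {tid} has {len(tr.daughters)} daughter(s); "
                        f"divisions are binary"
                    )
                for d in tr.daughters:
                    if d not in self.tracks:
                        raise ForestError(f"track {tid} lists missing daughter {d}")
                    if self.tracks[d].parent != tid:
                        raise ForestError(
                            f"daughter {d} of track {tid} does not point back"
                        )
                if tr.end_reason is not EndReason.DIVISION:
                    raise ForestError(
                        f"track {tid} has daughters but end_reason="
                        f"{tr.end_reason}"
                    )
            elif tr.end_reason is EndReason.DIVISION:
                raise ForestError(f"track {tid}: end_reason=division without daughters")
            if tr.end_reason is EndReason.MOVIE_END and tr.last_frame != self.movie_end_frame:
                raise ForestError(
                    f"track {tid} claims movie_end but ends at frame {tr.last_frame}"
                )
        # acyclicity: walk each parent chain with a visited set
        for tid in self.tracks:
            seen = set()
            cur: int | None = tid
            while cur is not None:
                if cur in seen:
                    raise ForestError(f"cycle in parent chain through track {tid}")
                seen.add(cur)
                cur = self.tracks[cur].parent

    # -- convenience -------------------------------------------------------

    @property
    def roots(self) -> list[int]:
        return sorted(t for t, tr in self.tracks.items() if tr.parent is None)

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def time_h(self, frame: int) -> float:
        return frame * self.frame_interval_h

    @property
    def movie_length_h(self) -> float:
        return self.movie_end_frame * self.frame_interval_h

    def endpoint_track_ids(self) -> list[int]:
        """Tracks alive at the movie end (candidates for staining)."""
        return sorted(
            t
            for t, tr in self.tracks.items()
            if tr.end_reason is EndReason.MOVIE_END
        )

    def sister_of(self, track_id: int) -> int | None:
        tr = self.tracks[track_id]
        if tr.parent is None:
            return None
        d = self.tracks[tr.parent].daughters
        assert d is not None
        return d[0] if d[1] == track_id else d[1]

    def positions_at_frame(self, frame: int) -> tuple[list[int], np.ndarray]:
        """All (track_id, position) pairs present at ``frame``, id-sorted."""
        ids = sorted(
            t
            for t, tr in self.tracks.items()
            if tr.first_frame <= frame <= tr.last_frame
        )
        if not ids:
            return [], np.empty((0, 3))
        pos = np.stack([self.tracks[t].position_at(frame) for t in ids])
        return ids, pos

    def reverse_topological(self) -> list[int]:
        """Track ids ordered daughters-before-mothers (deterministic)."""
        # a daughter always starts after its mother starts, so sorting by
        # descending first_frame (ties by id) puts children first
        return sorted(
            self.tracks, key=lambda t: (-self.tracks[t].first_frame, t)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineageForest):
            return NotImplemented
        return (
            self.movie_end_frame == other.movie_end_frame
            and self.frame_interval_h == other.frame_interval_h
            and self.tracks == other.tracks
        )


@dataclass
class AxisAnnotation:
    """Manually placed crypt-villus axis control points for one frame.

    ``control_points`` is an ordered ``(k, 3)`` array, crypt bottom first,
    with 3 <= k <= 6; ``neck_point`` marks the crypt/villus transition.
    """

    frame: int
    control_points: np.ndarray
    neck_point: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        self.neck_point = np.asarray(self.neck_point, dtype=float)
        k = len(self.control_points)
        if k < 3:
            raise ValueError(
                f"frame {self.frame}: need >=3 axis control points, got {k}"
            )
        steps = np.linalg.norm(np.diff(self.control_points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError(
                f"frame {self.frame}: consecutive control points coincide"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AxisAnnotation):
            return NotImplemented
        return (
            self.frame == other.frame
            and np.array_equal(self.control_points, other.control_points)
            and np.array_equal(self.neck_point, other.neck_point)
        )


@dataclass(frozen=True)
class TypeInterval:
    """Piecewise-constant type assignment over a span of frames of a track."""

    track_id: int
    start_frame: int
    end_frame: int
    type: CellType


@dataclass(frozen=True)
class TransitionEvent:
    """An inferred type commitment, placed halfway through the daughter
    track whose type differs from its mother's."""

    track_id: int
    from_type: CellType
    to_type: CellType
    frame: int
    position: tuple[float, float, float]


@dataclass
class TypedForest:
    """A lineage forest with one inferred type per track plus the transition
    events produced by the backpropagation rules.

    ``track_types[t]`` is the type of track ``t`` over (the latter part of)
    its life; if ``t`` carries a transition event, the type before the event
    frame is the mother's.
    """

    forest: LineageForest
    track_types: dict[int, CellType]
    transitions: list[TransitionEvent] = field(default_factory=list)
    conflicts: list[tuple[int, CellType, CellType]] = field(default_factory=list)
    low_confidence: set[int] = field(default_factory=set)

    def type_of(self, track_id: int) -> CellType:
        return self.track_types.get(track_id, CellType.UNKNOWN)

    def _transition_in(self, track_id: int) -> TransitionEvent | None:
        for ev in self.transitions:
            if ev.track_id == track_id:
                return ev
        return None

    def intervals(self, track_id: int) -> list[TypeInterval]:
        """Contiguous, non-overlapping intervals covering the track."""
        tr = self.forest.tracks[track_id]
        own = self.type_of(track_id)
        ev = self._transition_in(track_id)
        if ev is None or ev.frame <= tr.first_frame:
            return [TypeInterval(track_id, tr.first_frame, tr.last_frame, own)]
        return [
            TypeInterval(track_id, tr.first_frame, ev.frame - 1, ev.from_type),
            TypeInterval(track_id, ev.frame, tr.last_frame, ev.to_type),
        ]

    def all_intervals(self) -> list[TypeInterval]:
        out: list[TypeInterval] = []
        for tid in sorted(self.forest.tracks):
            out.extend(self.intervals(tid))
        return out

    def type_at(self, track_id: int, frame: int) -> CellType:
        for iv in self.intervals(track_id):
            if iv.start_frame <= frame <= iv.end_frame:
                return iv.type
        raise KeyError(f"track {track_id} not present at frame {frame}")
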