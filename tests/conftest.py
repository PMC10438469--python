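"""Shared fixtures and forest-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from typetracker.model import (
    CellType,
    EndReason,
    LineageForest,
    Track,
)

# leaf labels understood by build_forest besides cell-type names
DEAD = "dead"
LOST = "lost"


def _positions(tid: int, first: int, n: int) -> np.ndarray:
    frames = np.arange(first, first + n, dtype=float)
    return np.c_[np.full(n, float(tid)), frames * 0.5, np.zeros(n)]


def build_forest(
    tree,
    frames_per_track: int = 4,
    frame_interval_h: float = 0.2,
):
    """Build a one-tree forest from a nested topology.

    ``tree`` is either a leaf label (a :class:`CellType`, its string value,
    ``'dead'`` or ``'lost'``) or a pair ``(left, right)`` for a division.
    Internal tracks last ``frames_per_track`` frames; leaves run to the movie
    end except dead/lost leaves, which stop one frame early.

    Returns ``(forest, endpoint_types)`` where ``endpoint_types`` maps each
    alive leaf to its label.
    """

    def depth(node) -> int:
        if isinstance(node, tuple):
            return 1 + max(depth(node[0]), depth(node[1]))
        return 0

    movie_end = (depth(tree) + 1) * frames_per_track - 1
    tracks: dict[int, Track] = {}
    endpoint_types: dict[int, CellType] = {}
    counter = [0]

    def build(node, first: int, parent: int | None) -> int:
        counter[0] += 1
        tid = counter[0]
        if isinstance(node, tuple):
            last = first + frames_per_track - 1
            left = build(node[0], last + 1, tid)
            right = build(node[1], last + 1, tid)
            tracks[tid] = Track(
                track_id=tid,
                first_frame=first,
                positions=_positions(tid, first, frames_per_track),
                parent=parent,
                daughters=(left, right),
                end_reason=EndReason.DIVISION,
            )
            return tid
        label = node.value if isinstance(node, CellType) else str(node)
        if label in (DEAD, LOST):
            n = max(movie_end - first, 1)  # ends one frame before movie end
            reason = EndReason.DEATH if label == DEAD else EndReason.LOST
        else:
            n = movie_end - first + 1
            reason = EndReason.MOVIE_END
            endpoint_types[tid] = CellType(label)
        tracks[tid] = Track(
            track_id=tid,
            first_frame=first,
            positions=_positions(tid, first, n),
            parent=parent,
            end_reason=reason,
        )
        return tid

    build(tree, 0, None)
    forest = LineageForest(
        tracks=tracks, movie_end_frame=movie_end, frame_interval_h=frame_interval_h
    )
    return forest, endpoint_types


def random_topology(rng: np.random.Generator, max_depth: int, p_split: float = 0.6):
    """Random binary topology with leaf labels drawn from all nine states."""
    labels = [t.value for t in CellType] + [DEAD, LOST]
    if max_depth > 0 and rng.uniform() < p_split:
        return (
            random_topology(rng, max_depth - 1, p_split),
            random_topology(rng, max_depth - 1, p_split),
        )
    return labels[int(rng.integers(len(labels)))]


@pytest.fixture(scope="session")
def sim_result():
    """One default-condition synthetic organoid, shared across tests."""
    from typetracker.simulate import simulate

    return simulate(seed=1)


@pytest.fixture(scope="session")
def typed_sim(sim_result):
    from typetracker.simulate import run_typing

    typed, report = run_typing(sim_result)
    return typed, report
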