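"""Lineage-level summaries of a typed forest.

Implements the end-point sister-type histogram (same-type pairs counted
twice, columns normalised to 1), end-point cell ages, per-type division
counts over maximal same-type lineage segments, complete cell-cycle
durations, and the census of maximal two-type subtrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CANONICAL_TYPES,
    CellType,
    EndReason,
    TypedForest,
)

__all__ = [
    "SisterTypeHistogram",
    "sister_type_histogram",
    "endpoint_sisters",
    "endpoint_ages",
    "divisions_per_type",
    "cycle_durations",
    "SubtreeCensus",
    "two_type_subtrees",
]

logger = logging.getLogger(__name__)

_TYPE_INDEX = [t.value for t in CANONICAL_TYPES]


@dataclass
class SisterTypeHistogram:
    """Raw and column-normalised counts of end-point sister type pairs.

    ``counts[a, b]`` is the number of sister pairs with one member of type
    ``b`` (the column) and the other of type ``a``; a same-type pair
    contributes 2 to its diagonal cell, so each column ``b`` sums to the
    number of pairs containing at least one ``b`` cell, same-type pairs
    counted twice.  ``frequencies`` divides each occupied column by its sum.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    n_pairs: int
    n_excluded: int  # pairs dropped (dead/lost sister or UNKNOWN member)


def endpoint_sisters(typed: TypedForest) -> list[tuple[int, int]]:
    """Sister pairs with both members alive at the movie end."""
    forest = typed.forest
    out = []
    for tid in sorted(forest.tracks):
        ds = forest.tracks[tid].daughters
        if ds is None:
            continue
        if all(
            forest.tracks[d].end_reason is EndReason.MOVIE_END for d in ds
        ):
            out.append(ds)
    return out


def sister_type_histogram(typed: TypedForest) -> SisterTypeHistogram:
    """End-point sister-type histogram under the double-count rule."""
    forest = typed.forest
    counts = pd.DataFrame(
        np.zeros((len(_TYPE_INDEX), len(_TYPE_INDEX))),
        index=_TYPE_INDEX,
        columns=_TYPE_INDEX,
    )
    n_pairs = 0
    n_excluded = 0
    # pairs with a dead/lost sister are not end-point pairs; count them too
    for tid in sorted(forest.tracks):
        ds = forest.tracks[tid].daughters
        if ds is None:
            continue
        if not all(forest.tracks[d].end_reason is EndReason.MOVIE_END for d in ds):
            n_excluded += 1
            continue
        a, b = (typed.type_of(d) for d in ds)
        if CellType.UNKNOWN in (a, b):
            n_excluded += 1
            continue
        counts.loc[a.value, b.value] += 1
        counts.loc[b.value, a.value] += 1
        n_pairs += 1
    if n_pairs == 0:
        logger.warning("no typed end-point sister pairs; histogram is empty")
    col_sums = counts.sum(axis=0)
    freq = counts.copy()
    for c in freq.columns:
        if col_sums[c] > 0:
            freq[c] = freq[c] / col_sums[c]
    return SisterTypeHistogram(
        counts=counts, frequencies=freq, n_pairs=n_pairs, n_excluded=n_excluded
    )


def endpoint_ages(
    typed: TypedForest, movie_length_h: float | None = None
) -> dict[CellType, list[float]]:
    """Per-type ages of cells alive at the movie end.

    Age is the time since the cell's birth (its track's first frame); cells
    present since the movie start without a recorded division get the full
    movie length.
    """
    forest = typed.forest
    if movie_length_h is None:
        movie_length_h = forest.movie_length_h
    ages: dict[CellType, list[float]] = {}
    for tid in forest.endpoint_track_ids():
        tr = forest.tracks[tid]
        if tr.parent is None:
            age = movie_length_h
        else:
            age = (forest.movie_end_frame - tr.first_frame) * forest.frame_interval_h
        ages.setdefault(typed.type_of(tid), []).append(age)
    return ages


def _segments(typed: TypedForest) -> list[tuple[CellType, list[int]]]:
    """Maximal connected lineage segments of tracks sharing one type.

    Segment membership uses each track's own inferred type; UNKNOWN tracks
    form no segments.
    """
    forest = typed.forest
    seen: set[int] = set()
    segments = []
    for tid in sorted(forest.tracks):
        if tid in seen:
            continue
        ct = typed.type_of(tid)
        if ct is CellType.UNKNOWN:
            seen.add(tid)
            continue
        parent = forest.tracks[tid].parent
        if parent is not None and typed.type_of(parent) is ct:
            continue  # not the segment's top track
        # flood down through same-type daughters
        members = []
        stack = [tid]
        while stack:
            t = stack.pop()
            members.append(t)
            seen.add(t)
            ds = forest.tracks[t].daughters or ()
            stack.extend(d for d in ds if typed.type_of(d) is ct)
        segments.append((ct, sorted(members)))
    return segments


def divisions_per_type(typed: TypedForest) -> dict[CellType, list[int]]:
    """Observed division counts per maximal same-type lineage segment.

    For each segment, the number of forks whose mother belongs to the
    segment (hence carries its type).  Returns the per-segment distribution
    for each type; undivided segments contribute 0.
    """
    forest = typed.forest
    out: dict[CellType, list[int]] = {}
    for ct, members in _segments(typed):
        forks = sum(1 for t in members if forest.tracks[t].daughters is not None)
        out.setdefault(ct, []).append(forks)
    return out


def cycle_durations(typed: TypedForest) -> dict[CellType, list[float]]:
    """Complete fork-to-fork cell-cycle durations (hours), by the dividing
    track's inferred type.

    Only tracks that begin at a fork (have a parent) and end in a division
    are complete cycles; tracks present at the movie start are excluded.
    """
    forest = typed.forest
    out: dict[CellType, list[float]] = {}
    for tid in sorted(forest.tracks):
        tr = forest.tracks[tid]
        if tr.parent is None or tr.daughters is None:
            continue
        dur = (tr.last_frame - tr.first_frame) * forest.frame_interval_h
        out.setdefault(typed.type_of(tid), []).append(dur)
    return out


@dataclass
class SubtreeCensus:
    """Counts of maximal two-type subtrees per unordered type pair."""

    counts: dict[frozenset[CellType], int] = field(default_factory=dict)
    n_excluded: int = 0  # maximal two-type subtrees dropped (>50% dead/lost)

    def count(self, a: CellType, b: CellType) -> int:
        return self.counts.get(frozenset((a, b)), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def two_type_subtrees(
    typed: TypedForest, max_dead_fraction: float = 0.5
) -> SubtreeCensus:
    """Census of maximal subtrees containing exactly two distinct types.

    A subtree rooted at track ``t`` qualifies when the set of (non-UNKNOWN)
    types among its tracks has exactly two members and the subtree is
    maximal: ``t`` is a root, or the subtree rooted at ``t``'s parent
    contains a third type.  Subtrees in which more than
    ``max_dead_fraction`` of the tracks died or were lost are excluded from
    the census (their number is reported).
    """
    forest = typed.forest
    typeset: dict[int, frozenset[CellType]] = {}
    n_tracks: dict[int, int] = {}
    n_deadlost: dict[int, int] = {}
    for tid in forest.reverse_topological():
        tr = forest.tracks[tid]
        own = typed.type_of(tid)
        ts = set() if own is CellType.UNKNOWN else {own}
        cnt, dl = 1, int(tr.end_reason in (EndReason.DEATH, EndReason.LOST))
        for d in tr.daughters or ():
            ts |= typeset[d]
            cnt += n_tracks[d]
            dl += n_deadlost[d]
        typeset[tid] = frozenset(ts)
        n_tracks[tid] = cnt
        n_deadlost[tid] = dl

    census = SubtreeCensus()
    for tid in sorted(forest.tracks):
        if len(typeset[tid]) != 2:
            continue
        parent = forest.tracks[tid].parent
        if parent is not None and len(typeset[parent]) <= 2:
            continue  # parent subtree holds the same (or a smaller) type set
        if n_deadlost[tid] > max_dead_fraction * n_tracks[tid]:
            census.n_excluded += 1
            continue
        key = typeset[tid]
        census.counts[key] = census.counts.get(key, 0) + 1
    return census
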