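"""Backpropagation of end-point cell types along lineage trees.

Once every terminal track carries an end-point type (``UNKNOWN`` allowed),
types are propagated from the leaves toward the roots.  Within a track the
type is carried backward unchanged; at each division fork the mother's type
is inferred from its two daughters' (inferred) types by, in order:

R2. both daughters the same type            -> mother gets that type;
R3. exactly one daughter a stem cell        -> mother is a stem cell;
R4. one daughter TA, the other not stem     -> mother is a TA cell.

A daughter that is dead, lost or untypeable (``UNKNOWN``) cannot constrain
the fork: the mother inherits the other daughter's type and is flagged
low-confidence.  Two daughters with distinct types that none of the rules
covers (two different terminally differentiated types — never observed in
real recordings) leave the mother ``UNKNOWN`` and are recorded as a
conflict.

Whenever a daughter's inferred type differs from its mother's, a commitment
(type transition) is inferred inside that daughter and placed halfway
through the daughter's observed lifetime (``floor`` of the mid frame); for
tracks only partially observed the midpoint of the observed span is used.
"""

from __future__ import annotations

from .model import (
    CellType,
    LineageForest,
    TransitionEvent,
    TypedForest,
)

__all__ = ["fork_rule", "backpropagate", "collect_transitions"]


def fork_rule(
    a: CellType, b: CellType
) -> tuple[CellType, bool, bool]:
    """Infer a mother's type from its two daughters' inferred types.

    Returns ``(mother_type, conflict, low_confidence)``.  Rules are checked
    in the order R2 (same type), R3 (one stem), R4 (one TA, other not stem);
    UNKNOWN daughters are treated like dead ones (the mother inherits the
    other daughter's type, flagged low-confidence), and two UNKNOWN
    daughters leave the mother UNKNOWN.
    """
    U = CellType.UNKNOWN
    if a is U and b is U:
        return U, False, False
    if a is U or b is U:
        return (b if a is U else a), False, True
    if a is b:  # R2
        return a, False, False
    if (a is CellType.STEM) != (b is CellType.STEM):  # R3
        return CellType.STEM, False, False
    if CellType.TA in (a, b):  # R4 (the other is not STEM here)
        return CellType.TA, False, False
    return U, True, False


def backpropagate(
    forest: LineageForest, endpoint_types: dict[int, CellType]
) -> TypedForest:
    """Propagate end-point types to every track of ``forest``.

    ``endpoint_types`` maps terminal (non-dividing) track ids to their
    end-point type; missing terminals default to ``UNKNOWN``.  The result is
    independent of track iteration order.
    """
    for tid in endpoint_types:
        if tid not in forest.tracks:
            raise KeyError(f"endpoint type for unknown track {tid}")
        if forest.tracks[tid].daughters is not None:
            raise ValueError(f"track {tid} divides; it cannot carry an end-point type")

    track_types: dict[int, CellType] = {}
    conflicts: list[tuple[int, CellType, CellType]] = []
    low_confidence: set[int] = set()
    for tid in forest.reverse_topological():  # daughters before mothers
        tr = forest.tracks[tid]
        if tr.daughters is None:
            track_types[tid] = endpoint_types.get(tid, CellType.UNKNOWN)
            continue
        d1, d2 = tr.daughters
        mother, conflict, low = fork_rule(track_types[d1], track_types[d2])
        track_types[tid] = mother
        if conflict:
            conflicts.append((tid, track_types[d1], track_types[d2]))
        if low:
            low_confidence.add(tid)

    typed = TypedForest(
        forest=forest,
        track_types=track_types,
        conflicts=conflicts,
        low_confidence=low_confidence,
    )
    typed.transitions = collect_transitions(typed)
    return typed


def collect_transitions(typed: TypedForest) -> list[TransitionEvent]:
    """One event per mother/daughter type mismatch (both types known).

    The event sits at the floor midpoint of the daughter's observed span and
    carries the daughter's position at that frame.
    """
    events: list[TransitionEvent] = []
    for tid in sorted(typed.forest.tracks):
        tr = typed.forest.tracks[tid]
        if tr.parent is None:
            continue
        own = typed.type_of(tid)
        mother = typed.type_of(tr.parent)
        if CellType.UNKNOWN in (own, mother) or own is mother:
            continue
        mid = (tr.first_frame + tr.last_frame) // 2
        pos = tr.position_at(mid)
        events.append(
            TransitionEvent(
                track_id=tid,
                from_type=mother,
                to_type=own,
                frame=mid,
                position=(float(pos[0]), float(pos[1]), float(pos[2])),
            )
        )
    return events
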