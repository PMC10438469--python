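"""Synthetic crypt-villus tracking datasets with ground truth.

The generator emulates the statistical structure the typing/backpropagation
pipeline assumes, under an explicit commit-then-sort model:

* cells live on the surface of a tube (crypt below the neck, villus above)
  and are tracked every frame as nuclear positions in micrometres;
* stem and TA cells proliferate with lognormal cycle times; a proliferating
  cell may *commit* to a new type during its life (stem -> TA or a secretory
  type; TA -> enterocyte, goblet or EEC), after which it still divides and
  all its offspring inherit the committed type — commitment precedes the
  terminal division, so end-point sisters always share a type;
* sisters never commit to independent fates within their own lifetimes
  (Notch-style lateral inhibition between sisters): each fork separates a
  committed lineage from one that keeps the mother type;
* committed lineages of terminal types divide a bounded number of further
  generations (more for absorptive than secretory lineages) and then arrest;
* antibody markers mature slowly: a committed cell stains for its new type
  only once the commitment is older than ``maturation_delay_h`` (20 h by
  default), staining all-negative (TA-like) before that;
* cells advect toward the villus at a speed proportional to the number of
  proliferating cells below them, scaled by a per-type motility, with
  isotropic positional jitter, soft nuclear exclusion and, for designated
  secretory types, an extra tangential drift that scatters sister pairs;
* at the movie end every surviving cell is "stained": a table of end
  positions (optionally jittered) with per-marker intensities drawn from
  well-separated positive/negative distributions.

Ground truth (per-track type intervals, planted commitment events with an
observability flag, sister-scatter flags) is returned alongside the tracks,
staining table and per-frame axis annotations, so recovery can be scored
exactly.

A planted commitment is *observable* when (i) the committed track has a
mother (commitments in cells already present at the movie start leave no
fork context to infer them from), (ii) some descendant of the committed cell
is alive at the movie end, and (iii) the commitment is old enough at the end
point for its markers to have matured (always true for TA, which stains
all-negative).  Only observable events can be recovered by any end-point
staining method; recovery is reported against that denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .backprop import backpropagate
from .endpoint_typing import assign_endpoint_types
from .model import (
    AxisAnnotation,
    CellType,
    EndReason,
    LineageForest,
    MARKERS,
    Track,
    TypedForest,
)

__all__ = [
    "SimConfig",
    "PlantedCommitment",
    "GroundTruth",
    "SimResult",
    "simulate",
    "degrade",
    "RecoveryReport",
    "commitment_recovery",
]

#: Positive markers per cell type (see the typing decision table).
MARKER_PATTERNS: dict[CellType, frozenset[str]] = {
    CellType.STEM: frozenset({"olfm4"}),
    CellType.EEC: frozenset({"cga"}),
    CellType.ENTEROCYTE: frozenset({"aldob", "krt20"}),
    CellType.PANETH: frozenset({"wga", "lyz"}),
    CellType.GOBLET: frozenset({"wga", "krt20"}),
    CellType.IMPC: frozenset({"wga"}),
    CellType.TA: frozenset(),
}


def _default_cycle_means() -> dict[CellType, float]:
    # proliferative and secretory cycle times are similar; enterocytes cycle
    # slightly faster
    return {
        CellType.STEM: 15.5,
        CellType.TA: 14.1,
        CellType.ENTEROCYTE: 12.5,
        CellType.EEC: 15.0,
        CellType.PANETH: 15.0,
        CellType.GOBLET: 15.0,
        CellType.IMPC: 15.0,
    }


def _default_commitment_rates() -> dict[tuple[CellType, CellType], float]:
    # per-hour hazards for the allowed transitions
    return {
        (CellType.STEM, CellType.TA): 0.030,
        (CellType.STEM, CellType.PANETH): 0.005,
        (CellType.STEM, CellType.IMPC): 0.005,
        (CellType.STEM, CellType.EEC): 0.003,
        (CellType.TA, CellType.ENTEROCYTE): 0.035,
        (CellType.TA, CellType.GOBLET): 0.008,
        (CellType.TA, CellType.EEC): 0.004,
    }


def _default_post_commitment_divisions() -> dict[CellType, dict[int, float]]:
    # generations of further division after commitment (>=1: commitment
    # always precedes at least one division); absorptive lineages expand more
    return {
        CellType.ENTEROCYTE: {1: 0.2, 2: 0.35, 3: 0.3, 4: 0.1, 5: 0.05},
        CellType.GOBLET: {1: 0.7, 2: 0.3},
        CellType.PANETH: {1: 0.75, 2: 0.25},
        CellType.IMPC: {1: 0.7, 2: 0.3},
        CellType.EEC: {1: 0.8, 2: 0.2},
    }


def _default_motility() -> dict[CellType, float]:
    # multiplier on the proliferation-driven advection; the planted ordering
    # of migration speeds (enterocyte/goblet fast, Paneth/IMPC slow)
    return {
        CellType.ENTEROCYTE: 1.3,
        CellType.GOBLET: 1.3,
        CellType.TA: 1.0,
        CellType.EEC: 0.5,
        CellType.STEM: 0.25,
        CellType.IMPC: 0.1,
        CellType.PANETH: 0.0,
    }


def _default_sister_scatter() -> dict[CellType, float]:
    # tangential drift (rad/h) applied with opposite sign to the two sisters
    return {CellType.PANETH: 0.35, CellType.IMPC: 0.35}


@dataclass
class SimConfig:
    """All knobs of the synthetic organoid, with study-scale defaults."""

    tube_radius_um: float = 12.0
    crypt_length_um: float = 40.0
    villus_length_um: float = 80.0
    frame_interval_h: float = 0.2
    movie_length_h: float = 60.0
    n_initial_cells: int = 12
    cycle_time_mean_h: dict[CellType, float] = field(default_factory=_default_cycle_means)
    cycle_time_cv: float = 0.15
    commitment_rates: dict[tuple[CellType, CellType], float] = field(
        default_factory=_default_commitment_rates
    )
    post_commitment_divisions: dict[CellType, dict[int, float]] = field(
        default_factory=_default_post_commitment_divisions
    )
    maturation_delay_h: float = 20.0
    advection_um_per_cell_h: float = 0.02
    motility: dict[CellType, float] = field(default_factory=_default_motility)
    sister_scatter_rad_h: dict[CellType, float] = field(
        default_factory=_default_sister_scatter
    )
    positional_jitter_um: float = 0.35   # per-frame isotropic SD
    exclusion_radius_um: float = 6.0     # soft nuclear exclusion distance
    stain_jitter_sd_um: float = 0.0
    label_noise_rate: float = 0.0
    death_rate_per_h: float = 0.0
    max_cells: int = 100_000

    def validate(self) -> None:
        if any(r < 0 for r in self.commitment_rates.values()):
            raise ValueError("commitment rates must be >= 0")
        for ct, dist in self.post_commitment_divisions.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"division-count distribution for {ct} must sum to 1")
        for p in (self.label_noise_rate, self.death_rate_per_h):
            if p < 0:
                raise ValueError("rates must be >= 0")
        if self.label_noise_rate > 1:
            raise ValueError("label_noise_rate must be <= 1")


@dataclass(frozen=True)
class PlantedCommitment:
    """A ground-truth type commitment planted by the generator."""

    track_id: int
    from_type: CellType
    to_type: CellType
    time_h: float
    frame: int
    observable: bool


@dataclass
class GroundTruth:
    """True per-track type intervals and planted events."""

    events: list[PlantedCommitment]
    track_intervals: dict[int, list[tuple[int, int, CellType]]]
    endpoint_types: dict[int, CellType]     # true type of cells alive at end
    scatter_tracks: set[int]
    seed: int

    def true_type_at(self, track_id: int, frame: int) -> CellType:
        for s, e, ct in self.track_intervals[track_id]:
            if s <= frame <= e:
                return ct
        raise KeyError(f"track {track_id} not present at frame {frame}")


@dataclass
class SimResult:
    forest: LineageForest
    stain_table: pd.DataFrame
    axis_annotations: dict[int, AxisAnnotation]
    ground_truth: GroundTruth
    config: SimConfig
    seed: int


class _Cell:
    __slots__ = (
        "track_id", "theta", "y", "type", "birth_time", "first_frame",
        "committed_time", "committed_this_track", "gens_left",
        "division_time", "commit_candidate", "death_time", "theta_drift",
        "rows", "parent", "sister",
    )

    def __init__(self, **kw):
        for k in self.__slots__:
            setattr(self, k, kw.get(k))
        if self.rows is None:
            self.rows = []


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _draw_from(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def simulate(config: SimConfig | None = None, seed: int = 0) -> SimResult:
    """Run the generator and return tracks, staining, axes and ground truth.

    Deterministic given ``(config, seed)``.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    dt = cfg.frame_interval_h
    n_frames = int(round(cfg.movie_length_h / dt))
    t_end = n_frames * dt
    tube_len = cfg.crypt_length_um + cfg.villus_length_um
    radius = cfg.tube_radius_um

    hazards: dict[CellType, list[tuple[CellType, float]]] = {}
    for (src, dst), rate in sorted(
        cfg.commitment_rates.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        if rate > 0:
            hazards.setdefault(src, []).append((dst, rate))

    committed_tracks: set[int] = set()
    cells: list[_Cell] = []
    closed: list[_Cell] = []
    end_reason: dict[int, EndReason] = {}
    parent_of: dict[int, int] = {}
    daughters_of: dict[int, tuple[int, int]] = {}
    events: list[PlantedCommitment] = []
    commit_frame: dict[int, int] = {}   # track -> frame at which type switched
    birth_type: dict[int, CellType] = {}
    final_type: dict[int, CellType] = {}
    next_id = 1

    def schedule(cell: _Cell, now: float) -> None:
        """(Re)draw division/commitment/death clocks for a fresh track."""
        nonlocal rng
        ct = cell.type
        proliferative = cell.gens_left is None or cell.gens_left > 0
        if proliferative:
            cycle = _lognormal(rng, cfg.cycle_time_mean_h[ct], cfg.cycle_time_cv)
            cell.division_time = now + cycle
        else:
            cell.division_time = None
        cell.commit_candidate = None
        if ct in hazards and not cell.committed_this_track:
            total = sum(r for _, r in hazards[ct])
            cell.commit_candidate = now + float(rng.exponential(1.0 / total))
        cell.death_time = (
            now + float(rng.exponential(1.0 / cfg.death_rate_per_h))
            if cfg.death_rate_per_h > 0
            else None
        )

    # ---- initial stem cells near the crypt bottom -------------------------
    for _ in range(cfg.n_initial_cells):
        c = _Cell(
            track_id=next_id,
            theta=float(rng.uniform(0, 2 * math.pi)),
            y=float(rng.uniform(2.0, 0.6 * cfg.crypt_length_um)),
            type=CellType.STEM,
            birth_time=0.0,
            first_frame=0,
            committed_time=None,
            committed_this_track=False,
            gens_left=None,
            theta_drift=0.0,
            parent=None,
            sister=None,
        )
        next_id += 1
        birth_type[c.track_id] = CellType.STEM
        schedule(c, 0.0)
        # stagger the first divisions: cells are mid-cycle at movie start
        if c.division_time is not None:
            c.division_time = float(rng.uniform(0.3, 1.0)) * c.division_time
        cells.append(c)

    def record_frame(frame: int) -> None:
        for c in cells:
            x = radius * math.sin(c.theta)
            z = radius * math.cos(c.theta)
            c.rows.append((x, c.y, z))

    def try_commit(cell: _Cell, now_frame: int) -> None:
        """Execute a pending commitment if its conditions hold."""
        nonlocal events
        t_c = cell.commit_candidate
        cell.commit_candidate = None
        if cell.committed_this_track:
            return
        if cell.sister is not None and cell.sister in committed_tracks:
            return  # lateral inhibition: sister already committed
        if cell.division_time is None or cell.division_time > t_end:
            return  # commitment must precede a division inside the movie
        if t_c >= cell.division_time:
            return
        options = hazards[cell.type]
        rates = np.array([r for _, r in options])
        dst = options[int(rng.choice(len(options), p=rates / rates.sum()))][0]
        src = cell.type
        cell.type = dst
        cell.committed_time = t_c
        cell.committed_this_track = True
        committed_tracks.add(cell.track_id)
        commit_frame[cell.track_id] = now_frame
        if dst in cfg.post_commitment_divisions:
            cell.gens_left = _draw_from(rng, cfg.post_commitment_divisions[dst])
        events.append(
            PlantedCommitment(
                track_id=cell.track_id,
                from_type=src,
                to_type=dst,
                time_h=t_c,
                frame=now_frame,
                observable=False,  # filled in at the end
            )
        )

    def close(cell: _Cell, reason: EndReason) -> None:
        end_reason[cell.track_id] = reason
        final_type[cell.track_id] = cell.type
        closed.append(cell)

    record_frame(0)
    for frame in range(1, n_frames + 1):
        now = frame * dt
        if len(closed) + len(cells) > cfg.max_cells:
            raise RuntimeError(
                f"simulation exceeded {cfg.max_cells} cells; shorten the movie "
                f"or lower the proliferation parameters"
            )

        # --- continuous-time events that fell inside this frame step -------
        newborn: list[_Cell] = []
        survivors: list[_Cell] = []
        for c in cells:
            if c.commit_candidate is not None and c.commit_candidate <= now:
                try_commit(c, frame)
            if c.death_time is not None and c.death_time <= now and (
                c.division_time is None or c.death_time < c.division_time
            ):
                close(c, EndReason.DEATH)
                continue
            if c.division_time is not None and c.division_time <= now:
                close(c, EndReason.DIVISION)
                kids = []
                for sgn in (-1.0, 1.0):
                    kid = _Cell(
                        track_id=None,
                        theta=c.theta + sgn * float(rng.uniform(2.0, 4.0)) / radius,
                        y=min(max(c.y + sgn * float(rng.uniform(0.5, 2.0)), 0.5), tube_len),
                        type=c.type,
                        birth_time=now,
                        first_frame=frame,
                        committed_time=c.committed_time,
                        committed_this_track=False,
                        gens_left=None if c.gens_left is None else c.gens_left - 1,
                        theta_drift=0.0,
                        parent=c.track_id,
                        sister=None,
                    )
                    kids.append(kid)
                scatter = cfg.sister_scatter_rad_h.get(c.type, 0.0)
                kids[0].theta_drift = -scatter
                kids[1].theta_drift = +scatter
                ids = []
                for kid in kids:
                    kid.track_id = next_id
                    next_id += 1
                    ids.append(kid.track_id)
                    birth_type[kid.track_id] = kid.type
                    parent_of[kid.track_id] = c.track_id
                    schedule(kid, now)
                kids[0].sister = ids[1]
                kids[1].sister = ids[0]
                daughters_of[c.track_id] = (ids[0], ids[1])
                newborn.extend(kids)
                continue
            survivors.append(c)
        cells = survivors + newborn

        # --- motion ---------------------------------------------------------
        if cells:
            ys = np.array([c.y for c in cells])
            prolif = np.array(
                [c.division_time is not None for c in cells], dtype=bool
            )
            # number of proliferating cells strictly below each cell
            below = np.searchsorted(np.sort(ys[prolif]), ys, side="left").astype(float)
            jit = rng.normal(0.0, cfg.positional_jitter_um, size=(len(cells), 2))
            for i, c in enumerate(cells):
                v = cfg.advection_um_per_cell_h * below[i] * cfg.motility.get(c.type, 1.0)
                c.y = min(max(c.y + v * dt + jit[i, 0], 0.5), tube_len)
                c.theta += jit[i, 1] / radius + c.theta_drift * dt
            # soft nuclear exclusion
            pos = np.array(
                [
                    (radius * math.sin(c.theta), c.y, radius * math.cos(c.theta))
                    for c in cells
                ]
            )
            tree = cKDTree(pos)
            for i, j in sorted(tree.query_pairs(cfg.exclusion_radius_um)):
                ci, cj = cells[i], cells[j]
                d = float(np.linalg.norm(pos[i] - pos[j]))
                push = 0.25 * (cfg.exclusion_radius_um - d)
                dy = ci.y - cj.y
                dth = math.remainder(ci.theta - cj.theta, 2 * math.pi)
                norm = math.hypot(dy, dth * radius)
                if norm == 0.0:
                    dy, norm = 1.0, 1.0
                ci.y = min(max(ci.y + push * dy / norm, 0.5), tube_len)
                cj.y = min(max(cj.y - push * dy / norm, 0.5), tube_len)
                ci.theta += push * dth / norm / radius
                cj.theta -= push * dth / norm / radius

        record_frame(frame)

    for c in cells:
        close(c, EndReason.MOVIE_END)

    # ---- assemble the forest ----------------------------------------------
    tracks: dict[int, Track] = {}
    for c in closed:
        tracks[c.track_id] = Track(
            track_id=c.track_id,
            first_frame=c.first_frame,
            positions=np.array(c.rows),
            parent=parent_of.get(c.track_id),
            daughters=daughters_of.get(c.track_id),
            end_reason=end_reason[c.track_id],
        )
    forest = LineageForest(
        tracks=tracks, movie_end_frame=n_frames, frame_interval_h=dt
    )

    # ---- ground truth -------------------------------------------------------
    track_intervals: dict[int, list[tuple[int, int, CellType]]] = {}
    for tid, tr in tracks.items():
        fc = commit_frame.get(tid)
        if fc is not None:
            # a commitment immediately followed by division in the same frame
            # step is only ever observed at the mother's final frame
            fc = min(fc, tr.last_frame)
        if fc is None or fc <= tr.first_frame:
            track_intervals[tid] = [(tr.first_frame, tr.last_frame, final_type[tid])]
        else:
            track_intervals[tid] = [
                (tr.first_frame, fc - 1, birth_type[tid]),
                (fc, tr.last_frame, final_type[tid]),
            ]

    def clone_survives(tid: int) -> bool:
        stack = [tid]
        while stack:
            t = stack.pop()
            if end_reason[t] is EndReason.MOVIE_END:
                return True
            stack.extend(daughters_of.get(t, ()))
        return False

    resolved = []
    for ev in events:
        mature = (
            ev.to_type is CellType.TA
            or (t_end - ev.time_h) >= cfg.maturation_delay_h
        )
        obs = (
            parent_of.get(ev.track_id) is not None
            and clone_survives(ev.track_id)
            and mature
        )
        resolved.append(replace(ev, observable=obs))

    endpoint_true = {
        tid: final_type[tid]
        for tid, r in end_reason.items()
        if r is EndReason.MOVIE_END
    }
    ground_truth = GroundTruth(
        events=resolved,
        track_intervals=track_intervals,
        endpoint_types=endpoint_true,
        scatter_tracks={
            tid
            for tid in tracks
            if cfg.sister_scatter_rad_h.get(birth_type[tid], 0.0) > 0
            and parent_of.get(tid) is not None
        },
        seed=seed,
    )

    # ---- staining table -----------------------------------------------------
    stain_rng = np.random.default_rng(rng.integers(2**31))
    stain_table = _make_stain_table(
        forest, closed, cfg, t_end, stain_rng,
        jitter_sd=cfg.stain_jitter_sd_um, label_noise=cfg.label_noise_rate,
    )

    # ---- axis annotations ---------------------------------------------------
    ctrl = np.array(
        [[0.0, f * tube_len, 0.0] for f in (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)]
    )
    neck = np.array([0.0, cfg.crypt_length_um, 0.0])
    annotations = {
        f: AxisAnnotation(frame=f, control_points=ctrl.copy(), neck_point=neck.copy())
        for f in range(0, n_frames + 1)
    }

    return SimResult(
        forest=forest,
        stain_table=stain_table,
        axis_annotations=annotations,
        ground_truth=ground_truth,
        config=cfg,
        seed=seed,
    )


def _stained_type(cell_type: CellType, committed_time, t_end: float, delay: float) -> CellType:
    """The type a cell's markers express at fixation (maturation delay)."""
    if cell_type in (CellType.STEM, CellType.TA):
        return cell_type
    if committed_time is None or (t_end - committed_time) >= delay:
        return cell_type
    return CellType.TA  # committed too recently: markers not yet detectable


def _pattern_intensities(
    pattern: frozenset[str], rng: np.random.Generator
) -> dict[str, float]:
    return {
        m: float(rng.uniform(80.0, 120.0)) if m in pattern else float(rng.uniform(0.0, 5.0))
        for m in MARKERS
    }


def _make_stain_table(
    forest: LineageForest,
    closed: list[_Cell],
    cfg: SimConfig,
    t_end: float,
    rng: np.random.Generator,
    jitter_sd: float,
    label_noise: float,
) -> pd.DataFrame:
    alive = [c for c in closed if c.track_id in set(forest.endpoint_track_ids())]
    alive.sort(key=lambda c: c.track_id)
    rows = []
    order = rng.permutation(len(alive))
    types = list(MARKER_PATTERNS)
    for rank, i in enumerate(order):
        c = alive[i]
        st = _stained_type(c.type, c.committed_time, t_end, cfg.maturation_delay_h)
        # noise draws are consumed for every cell regardless of the rate, so
        # for one seed the flipped sets are nested across noise rates
        u = float(rng.uniform())
        pick = int(rng.integers(len(types) - 1))
        if u < label_noise:
            st = [t for t in types if t is not st][pick]
        x, y, z = forest.tracks[c.track_id].position_at(forest.movie_end_frame)
        jx, jy, jz = rng.normal(0.0, 1.0, size=3) * jitter_sd
        inten = _pattern_intensities(MARKER_PATTERNS[st], rng)
        rows.append(
            {
                "stain_cell_id": 1000 + rank,
                "x_um": x + jx,
                "y_um": y + jy,
                "z_um": z + jz,
                **inten,
            }
        )
    cols = ["stain_cell_id", "x_um", "y_um", "z_um", *MARKERS]
    return pd.DataFrame(rows, columns=cols)


def degrade(
    result: SimResult,
    stain_jitter_sd: float = 0.0,
    label_noise: float = 0.0,
    track_loss_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Return a noisier copy of a simulated dataset.

    Adds Gaussian jitter to stain positions, flips each stained cell's marker
    panel to a random other type with probability ``label_noise`` (flips are
    nested across rates for a fixed seed), and truncates random non-root
    tracks (``end_reason=lost``, descendants dropped).  All rates must lie in
    [0, 1] where they are probabilities; rates of zero leave that aspect
    untouched.
    """
    for name, p in (("label_noise", label_noise), ("track_loss_rate", track_loss_rate)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if stain_jitter_sd < 0:
        raise ValueError("stain_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    cfg = result.config
    t_end = result.forest.movie_end_frame * result.forest.frame_interval_h

    # staining noise, coupled across rates by consuming draws for every cell
    stain = result.stain_table.copy().reset_index(drop=True)
    types = list(MARKER_PATTERNS)
    inverse = {pattern: ct for ct, pattern in MARKER_PATTERNS.items()}
    for idx in range(len(stain)):
        jit = rng.normal(0.0, 1.0, size=3) * stain_jitter_sd
        stain.loc[idx, ["x_um", "y_um", "z_um"]] += jit
        u = float(rng.uniform())
        pick = int(rng.integers(len(types) - 1))
        inten_draw = np.random.default_rng(int(rng.integers(2**31)))
        if u < label_noise:
            cur = inverse.get(
                frozenset(m for m in MARKERS if float(stain.loc[idx, m]) > 40.0),
                CellType.TA,
            )
            new = [t for t in types if t is not cur][pick]
            for m, v in _pattern_intensities(MARKER_PATTERNS[new], inten_draw).items():
                stain.loc[idx, m] = v

    forest = result.forest
    if track_loss_rate > 0:
        tracks = {t: tr for t, tr in forest.tracks.items()}
        dropped: set[int] = set()
        truncated: dict[int, int] = {}
        for tid in sorted(tracks):
            u = float(rng.uniform())
            cut = int(rng.integers(tracks[tid].first_frame, tracks[tid].last_frame + 1))
            if tracks[tid].parent is None or tid in dropped:
                continue
            if u < track_loss_rate:
                truncated[tid] = cut
                stack = list(tracks[tid].daughters or ())
                while stack:
                    d = stack.pop()
                    dropped.add(d)
                    stack.extend(tracks[d].daughters or ())
        new_tracks: dict[int, Track] = {}
        for tid, tr in tracks.items():
            if tid in dropped:
                continue
            if tid in truncated:
                cut = truncated[tid]
                new_tracks[tid] = Track(
                    track_id=tid,
                    first_frame=tr.first_frame,
                    positions=tr.positions[: cut - tr.first_frame + 1],
                    parent=tr.parent if tr.parent not in dropped else None,
                    daughters=None,
                    end_reason=EndReason.LOST,
                )
            else:
                new_tracks[tid] = Track(
                    track_id=tid,
                    first_frame=tr.first_frame,
                    positions=tr.positions.copy(),
                    parent=tr.parent,
                    daughters=tr.daughters,
                    end_reason=tr.end_reason,
                )
        forest = LineageForest(
            tracks=new_tracks,
            movie_end_frame=result.forest.movie_end_frame,
            frame_interval_h=result.forest.frame_interval_h,
        )

    return SimResult(
        forest=forest,
        stain_table=stain,
        axis_annotations=result.axis_annotations,
        ground_truth=result.ground_truth,
        config=cfg,
        seed=result.seed,
    )


@dataclass
class RecoveryReport:
    """How many planted, observable commitments the pipeline recovered."""

    n_planted: int
    n_observable: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_observable if self.n_observable else float("nan")


def commitment_recovery(ground_truth: GroundTruth, typed: TypedForest) -> RecoveryReport:
    """Score inferred transitions against the planted, observable events.

    An event is recovered when an inferred transition exists in the same
    track with the same from/to types.
    """
    inferred = {
        (ev.track_id, ev.from_type, ev.to_type) for ev in typed.transitions
    }
    observable = [e for e in ground_truth.events if e.observable]
    hits = sum(
        1
        for e in observable
        if (e.track_id, e.from_type, e.to_type) in inferred
    )
    return RecoveryReport(
        n_planted=len(ground_truth.events),
        n_observable=len(observable),
        n_recovered=hits,
    )


def run_typing(
    result: SimResult, max_match_distance: float = 10.0
):
    """Convenience: end-point typing + backpropagation of a simulated dataset."""
    types, report = assign_endpoint_types(
        result.forest, result.stain_table, max_match_distance=max_match_distance
    )
    typed = backpropagate(result.forest, types)
    return typed, report
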