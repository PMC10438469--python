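"""Axis fitting, projection, normalisation and migration speed."""

import numpy as np
import pytest

from typetracker.axis import (
    _project_polyline,
    compute_axis_positions,
    fit_axis,
    migration_speed,
    project,
    zero_and_normalize,
)
from typetracker.model import AxisAnnotation, EndReason, LineageForest, Track


def straight_axis(length=60.0, n_ctrl=4, neck=40.0):
    pts = np.c_[
        np.zeros(n_ctrl), np.linspace(0, length, n_ctrl), np.zeros(n_ctrl)
    ]
    ann = AxisAnnotation(frame=0, control_points=pts, neck_point=np.array([0.0, neck, 0.0]))
    return fit_axis(ann)


class TestFitAxis:
    def test_collinear_points_give_straight_segment(self):
        pts = np.array([[0, 0, 0], [3, 4, 0], [6, 8, 0]], float)
        ann = AxisAnnotation(frame=0, control_points=pts, neck_point=pts[-1])
        ax = fit_axis(ann)
        assert ax.length == pytest.approx(10.0, rel=1e-6)

    def test_quarter_circle_arc_length(self):
        th = np.linspace(0, np.pi / 2, 5)
        pts = np.c_[10 * np.cos(th), 10 * np.sin(th), np.zeros(5)]
        ann = AxisAnnotation(frame=0, control_points=pts, neck_point=pts[-1])
        ax = fit_axis(ann)
        assert ax.length == pytest.approx(5 * np.pi, rel=0.01)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            AxisAnnotation(
                frame=0,
                control_points=np.array([[0, 0, 0], [1, 0, 0]], float),
                neck_point=np.array([1.0, 0, 0]),
            )

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            AxisAnnotation(
                frame=0,
                control_points=np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float),
                neck_point=np.array([1.0, 0, 0]),
            )


class TestProject:
    def test_point_on_straight_axis(self):
        ax = straight_axis()
        r, d = project(np.array([0.0, 30.0, 0.0]), ax)
        assert r == pytest.approx(30.0, abs=1e-6)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_perpendicular_offset(self):
        ax = straight_axis()
        r, d = project(np.array([5.0, 30.0, 0.0]), ax)
        assert r == pytest.approx(30.0, abs=1e-6)
        assert d == pytest.approx(5.0, abs=1e-6)

    def test_matches_fine_grid_oracle_on_random_points(self):
        rng = np.random.default_rng(0)
        th = np.linspace(0, np.pi / 2, 5)
        pts = np.c_[30 * np.cos(th), 30 * np.sin(th), np.linspace(0, 10, 5)]
        ann = AxisAnnotation(frame=0, control_points=pts, neck_point=pts[-1])
        coarse = fit_axis(ann, spacing=0.25)
        fine = fit_axis(ann, spacing=0.01)
        q = rng.uniform(-5, 40, size=(100, 3))
        r_c, d_c = _project_polyline(q, coarse.samples, coarse.arclen)
        r_f, d_f = _project_polyline(q, fine.samples, fine.arclen)
        assert np.abs(r_c - r_f).max() < 0.1
        assert np.abs(d_c - d_f).max() < 0.01

    def test_rigid_transform_leaves_residual_invariant(self):
        rng = np.random.default_rng(1)
        th = np.linspace(0, 1.2, 4)
        pts = np.c_[20 * np.cos(th), 20 * np.sin(th), th * 3]
        neck = pts[-1]
        q = rng.uniform(0, 25, size=(20, 3))
        # random rotation + translation
        a, b, c = rng.uniform(0, 2 * np.pi, 3)

        def rot(axis_i, ang):
            m = np.eye(3)
            i, j = [(1, 2), (0, 2), (0, 1)][axis_i]
            m[i, i] = m[j, j] = np.cos(ang)
            m[i, j], m[j, i] = -np.sin(ang), np.sin(ang)
            return m

        R = rot(0, a) @ rot(1, b) @ rot(2, c)
        t = rng.uniform(-50, 50, 3)
        ax1 = fit_axis(AxisAnnotation(frame=0, control_points=pts, neck_point=neck))
        ax2 = fit_axis(
            AxisAnnotation(frame=0, control_points=pts @ R.T + t, neck_point=neck @ R.T + t)
        )
        _, d1 = _project_polyline(q, ax1.samples, ax1.arclen)
        _, d2 = _project_polyline(q @ R.T + t, ax2.samples, ax2.arclen)
        np.testing.assert_allclose(d1, d2, atol=1e-6)


class TestZeroAndNormalize:
    def test_bottom_cell_is_zero_and_neck_is_one(self):
        ax = straight_axis(neck=40.0)
        r = np.array([10.0, 25.0, 40.0])
        rz, rn, off = zero_and_normalize(r, ax)
        assert off == 10.0
        assert rz[0] == 0.0 and rn[0] == 0.0
        assert rn[2] == pytest.approx(1.0)  # cell exactly at the neck

    def test_scale_invariance_of_r_norm(self):
        for scale in (1.0, 2.0):
            pts = scale * np.c_[np.zeros(4), np.linspace(0, 60, 4), np.zeros(4)]
            ann = AxisAnnotation(
                frame=0, control_points=pts, neck_point=scale * np.array([0.0, 40.0, 0.0])
            )
            ax = fit_axis(ann)
            r = scale * np.array([10.0, 25.0])
            _, rn, _ = zero_and_normalize(r, ax)
            if scale == 1.0:
                ref = rn
        np.testing.assert_allclose(rn, ref, rtol=1e-9)

    def test_neck_below_bottom_cell_rejected(self):
        ax = straight_axis(neck=5.0)
        with pytest.raises(ValueError, match="neck"):
            zero_and_normalize(np.array([10.0, 20.0]), ax)

    def test_empty_frame_rejected(self):
        ax = straight_axis()
        with pytest.raises(ValueError, match="no cells"):
            zero_and_normalize(np.array([]), ax)


def _forest_with_moving_cell(r0=10.0, v_um_h=4.0, hours=5.0, interval=0.2):
    n = int(hours / interval) + 1
    t = np.arange(n) * interval
    moving = Track(
        track_id=1,
        first_frame=0,
        positions=np.c_[np.zeros(n), r0 + v_um_h * t, np.zeros(n)],
        end_reason=EndReason.MOVIE_END,
    )
    anchor = Track(  # pins the per-frame zero so r equals raw arc length
        track_id=2,
        first_frame=0,
        positions=np.c_[np.zeros(n), np.zeros(n), np.zeros(n)],
        end_reason=EndReason.MOVIE_END,
    )
    forest = LineageForest(
        tracks={1: moving, 2: anchor}, movie_end_frame=n - 1, frame_interval_h=interval
    )
    pts = np.c_[np.zeros(4), np.linspace(0, 80, 4), np.zeros(4)]
    ann = {
        f: AxisAnnotation(frame=f, control_points=pts, neck_point=np.array([0.0, 60.0, 0.0]))
        for f in range(n)
    }
    return forest, ann


class TestMigrationSpeed:
    def test_stationary_cell_speed_zero(self):
        forest, ann = _forest_with_moving_cell(v_um_h=0.0)
        table = compute_axis_positions(forest, ann)
        assert migration_speed(1, table, 0.2) == pytest.approx(0.0, abs=1e-9)

    def test_linear_motion_arithmetic(self):
        # r from 10 to 30 um over 5 h -> 4 um/h
        forest, ann = _forest_with_moving_cell(r0=10.0, v_um_h=4.0, hours=5.0)
        table = compute_axis_positions(forest, ann)
        assert migration_speed(1, table, 0.2) == pytest.approx(4.0, rel=1e-6)
        assert migration_speed(1, table, 0.2, method="regression") == pytest.approx(
            4.0, rel=1e-6
        )

    def test_planted_advection_recovered(self, sim_result):
        # the generator's tube runs along y, so the realised speed along the
        # axis is the per-track y displacement over time; the estimator must
        # agree within 5% for long, clearly moving tracks
        forest = sim_result.forest
        candidates = {}
        for tid, tr in forest.tracks.items():
            if tr.n_frames < 100:
                continue
            dy = tr.positions[-1, 1] - tr.positions[0, 1]
            dt = (tr.n_frames - 1) * forest.frame_interval_h
            if abs(dy / dt) >= 0.5:
                candidates[tid] = dy / dt
        assert candidates
        frames = sorted(
            {forest.tracks[t].first_frame for t in candidates}
            | {forest.tracks[t].last_frame for t in candidates}
        )
        table = compute_axis_positions(
            forest, sim_result.axis_annotations, frames=frames
        )
        for tid, planted in candidates.items():
            tr = forest.tracks[tid]
            rows = table[
                (table.track_id == tid)
                & table.frame.isin([tr.first_frame, tr.last_frame])
            ]
            got = migration_speed(tid, rows, forest.frame_interval_h)
            assert got == pytest.approx(planted, rel=0.05)

    def test_missing_annotation_named_in_error(self):
        forest, ann = _forest_with_moving_cell()
        sparse = {0: ann[0]}  # only the first frame is annotated
        with pytest.raises(KeyError, match="frame 25"):
            compute_axis_positions(forest, sparse, frames=[25])

    def test_nearby_annotation_reused_within_gap(self):
        forest, ann = _forest_with_moving_cell()
        sparse = {0: ann[0], 24: ann[24]}
        table = compute_axis_positions(forest, sparse, frames=[3, 22])
        assert set(table.frame) == {3, 22}


class TestAxisPositionsTable:
    def test_r_norm_bounds_on_simulated_crypt(self, sim_result):
        forest = sim_result.forest
        table = compute_axis_positions(
            forest, sim_result.axis_annotations, frames=[forest.movie_end_frame]
        )
        assert (table.r >= 0).all()
        assert (table.d >= 0).all()
        assert table.r_norm.min() == 0.0
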