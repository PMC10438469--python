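"""Marker gating, the type decision table, and stain-to-track matching."""

import itertools

import numpy as np
import pandas as pd
import pytest

from typetracker.endpoint_typing import (
    assign_endpoint_types,
    call_positivity,
    call_type,
    match_stained_to_tracked,
    otsu_thresholds,
)
from typetracker.model import CellType, MARKERS

from conftest import build_forest


def panel(**positives):
    p = {m: False for m in MARKERS}
    p.update(positives)
    return p


class TestPositivity:
    def test_all_zero_intensities_are_negative(self):
        calls = call_positivity({m: 0.0 for m in MARKERS}, {m: 1.0 for m in MARKERS})
        assert not any(calls.values())

    def test_intensity_at_threshold_is_negative(self):
        thr = {m: 10.0 for m in MARKERS}
        inten = {m: 0.0 for m in MARKERS}
        inten["olfm4"] = 10.0  # exactly at threshold: strict >
        assert call_positivity(inten, thr)["olfm4"] is False

    def test_single_marker_above_threshold(self):
        inten = {m: 0.0 for m in MARKERS}
        inten["wga"] = 100.0
        calls = call_positivity(inten, {m: 10.0 for m in MARKERS})
        assert calls == panel(wga=True)

    def test_missing_marker_named(self):
        inten = {m: 0.0 for m in MARKERS if m != "lyz"}
        with pytest.raises(KeyError, match="lyz"):
            call_positivity(inten, {m: 1.0 for m in MARKERS})


class TestDecisionTable:
    @pytest.mark.parametrize(
        "positives,expected",
        [
            (dict(olfm4=True), CellType.STEM),
            (dict(cga=True), CellType.EEC),
            (dict(aldob=True), CellType.ENTEROCYTE),
            (dict(aldob=True, krt20=True), CellType.ENTEROCYTE),
            (dict(wga=True, lyz=True), CellType.PANETH),
            (dict(wga=True, krt20=True), CellType.GOBLET),
            (dict(wga=True), CellType.IMPC),
            (dict(), CellType.TA),
            # outside the table
            (dict(olfm4=True, aldob=True), CellType.UNKNOWN),
            (dict(olfm4=True, cga=True), CellType.UNKNOWN),
            (dict(krt20=True), CellType.UNKNOWN),
        ],
    )
    def test_table_rows(self, positives, expected):
        assert call_type(panel(**positives)) is expected

    def test_total_and_single_valued_over_all_panels(self):
        # every one of the 2^6 combinations maps to exactly one label
        seen = {}
        for bits in itertools.product([False, True], repeat=6):
            p = dict(zip(MARKERS, bits))
            ct = call_type(p)
            assert isinstance(ct, CellType)
            seen[bits] = ct
        assert len(seen) == 64
        # the seven real types are all reachable
        assert set(seen.values()) >= set(
            ct for ct in CellType if ct is not CellType.UNKNOWN
        )


def brute_force_assignment(epts, spts, max_dist):
    """Exhaustive maximal-cardinality min-cost matching for tiny instances."""
    n, m = len(epts), len(spts)
    dist = np.linalg.norm(epts[:, None, :] - spts[None, :, :], axis=-1)
    best = (0, 0.0)  # (-cardinality, cost)
    found = False
    for k in range(min(n, m), -1, -1):
        best_cost = None
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                d = dist[list(rows), list(cols)]
                if np.all(d <= max_dist):
                    c = float(d.sum())
                    if best_cost is None or c < best_cost:
                        best_cost = c
        if best_cost is not None:
            return k, best_cost
    return 0, 0.0


class TestMatching:
    def test_identical_point_sets_identity(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [0, 7, 0]], float)
        a = match_stained_to_tracked([1, 2, 3], pts, [10, 20, 30], pts, 5.0)
        assert [(e, s) for e, s, _ in a.pairs] == [(1, 10), (2, 20), (3, 30)]
        assert a.total_cost == 0.0

    def test_small_jitter_preserves_identity(self):
        # six points jittered by less than half the minimum spacing must map
        # onto themselves; verified against exhaustive permutations
        rng = np.random.default_rng(3)
        pts = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0], [5, 20, 0], [20, 5, 0]],
            float,
        )
        min_spacing = min(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(6)
            for j in range(i + 1, 6)
        )
        jittered = pts + rng.uniform(-1, 1, pts.shape) * (min_spacing / 5)
        ids = list(range(6))
        a = match_stained_to_tracked(ids, pts, ids, jittered, 100.0)
        assert [(e, s) for e, s, _ in a.pairs] == [(i, i) for i in range(6)]
        best = min(
            sum(np.linalg.norm(pts[i] - jittered[p[i]]) for i in range(6))
            for p in itertools.permutations(range(6))
        )
        assert a.total_cost == pytest.approx(best, rel=1e-9)

    def test_far_point_left_unmatched(self):
        epts = np.array([[0, 0, 0], [5, 0, 0]], float)
        spts = np.array([[0, 0.1, 0], [500, 0, 0]], float)
        a = match_stained_to_tracked([1, 2], epts, [10, 20], spts, 10.0)
        assert [(e, s) for e, s, _ in a.pairs] == [(1, 10)]
        assert a.unmatched_stains == [20]
        assert a.unmatched_endpoints == [2]

    def test_empty_inputs_allowed(self):
        a = match_stained_to_tracked([], np.empty((0, 3)), [1], np.zeros((1, 3)), 5.0)
        assert a.pairs == [] and a.unmatched_stains == [1]

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 50, (7, 3))
        spts = pts + rng.normal(0, 1, pts.shape)
        ids = [30, 10, 20, 70, 50, 60, 40]
        a1 = match_stained_to_tracked(ids, pts, ids, spts, 15.0)
        perm = [3, 0, 6, 1, 4, 5, 2]
        a2 = match_stained_to_tracked(
            [ids[i] for i in perm], pts[perm], ids, spts, 15.0
        )
        assert a1.pairs == a2.pairs

    @pytest.mark.parametrize("seed", range(12))
    def test_optimality_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        m = int(rng.integers(2, 7))
        epts = rng.uniform(0, 30, (n, 3))
        spts = rng.uniform(0, 30, (m, 3))
        maxd = float(rng.uniform(5, 40))
        a = match_stained_to_tracked(list(range(n)), epts, list(range(m)), spts, maxd)
        k, cost = brute_force_assignment(epts, spts, maxd)
        assert len(a.pairs) == k
        assert a.total_cost == pytest.approx(cost, rel=1e-6, abs=1e-9)


class TestAssignEndpointTypes:
    def _stain_row(self, sid, xyz, ct):
        from typetracker.simulate import MARKER_PATTERNS

        row = {"stain_cell_id": sid, "x_um": xyz[0], "y_um": xyz[1], "z_um": xyz[2]}
        for m in MARKERS:
            row[m] = 100.0 if m in MARKER_PATTERNS[ct] else 1.0
        return row

    def _forest_and_exact_stains(self):
        forest, leaf_types = build_forest(
            ((CellType.STEM, CellType.TA), (CellType.PANETH, CellType.PANETH))
        )
        rows = [
            self._stain_row(
                100 + tid,
                forest.tracks[tid].position_at(forest.movie_end_frame),
                ct,
            )
            for tid, ct in leaf_types.items()
        ]
        return forest, leaf_types, pd.DataFrame(rows)

    def test_exact_positions_recover_ground_truth(self):
        forest, leaf_types, stains = self._forest_and_exact_stains()
        thresholds = {m: 40.0 for m in MARKERS}
        types, report = assign_endpoint_types(forest, stains, thresholds)
        assert report.match_rate == 1.0
        assert {t: types[t] for t in leaf_types} == leaf_types

    def test_missing_stain_gives_unknown(self):
        forest, leaf_types, stains = self._forest_and_exact_stains()
        drop = min(leaf_types)
        stains = stains[stains.stain_cell_id != 100 + drop]
        types, report = assign_endpoint_types(
            forest, stains, {m: 40.0 for m in MARKERS}
        )
        assert types[drop] is CellType.UNKNOWN
        assert report.unmatched_endpoints == [drop]

    def test_global_shift_beyond_gate_matches_nothing(self):
        forest, _, stains = self._forest_and_exact_stains()
        stains = stains.copy()
        stains[["x_um", "y_um", "z_um"]] += 1000.0
        types, report = assign_endpoint_types(
            forest, stains, {m: 40.0 for m in MARKERS}, max_match_distance=10.0
        )
        assert report.n_matched == 0
        assert report.warnings
        assert all(ct is CellType.UNKNOWN for ct in types.values())

    def test_empty_stain_table_warns(self):
        forest, _, stains = self._forest_and_exact_stains()
        types, report = assign_endpoint_types(forest, stains.iloc[:0], None)
        assert all(ct is CellType.UNKNOWN for ct in types.values())
        assert any("empty" in w for w in report.warnings)

    def test_boolean_columns_bypass_thresholds(self):
        forest, leaf_types, stains = self._forest_and_exact_stains()
        for m in MARKERS:
            stains[f"{m}_pos"] = stains[m] > 40.0
            stains = stains.drop(columns=[m])
        types, _ = assign_endpoint_types(forest, stains)
        assert {t: types[t] for t in leaf_types} == leaf_types


class TestOtsuThresholds:
    def test_separates_clear_bimodal_columns(self):
        rng = np.random.default_rng(0)
        n = 60
        df = pd.DataFrame({
            "stain_cell_id": range(n),
            "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
        })
        for m in MARKERS:
            neg = rng.uniform(0, 5, n - 12)
            pos = rng.uniform(80, 120, 12)
            df[m] = np.concatenate([neg, pos])
        thr = otsu_thresholds(df)
        for m in MARKERS:
            assert 5.0 < thr[m] < 80.0

    def test_marker_without_positives_stays_all_negative(self):
        rng = np.random.default_rng(1)
        n = 80
        df = pd.DataFrame({
            "stain_cell_id": range(n),
            "x_um": 0.0, "y_um": 0.0, "z_um": 0.0,
        })
        for m in MARKERS:
            df[m] = rng.uniform(0, 5, n)  # background only
        thr = otsu_thresholds(df)
        for m in MARKERS:
            assert not (df[m] > thr[m]).any()
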