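"""Eq.-1-style pose scoring, normalization, ranking, hit selection."""

import numpy as np
import pytest

import peptogrid as pg
from peptogrid.rescore import (
    nearest_vertex,
    rescore_set,
    score_histogram,
    score_pose,
    select_top_percentile,
)


def _atom(coords, styp="C.3"):
    return pg.AtomRecord(atom_name="X", element="C", coords=coords,
                         sybyl_type=styp, vdw_radius=1.7)


def _pose(atoms, pid="p", seq="G", native=None):
    return pg.Pose(pose_id=pid, sequence=seq, source="synthetic", atoms=atoms,
                   native_score=native)


def _grid_from_arrays(box, arrays):
    return pg.FrequencyGrid(box=box, type_axis=pg.supported_alphabet(),
                            counts={k: v.astype(np.float32)
                                    for k, v in arrays.items()})


def naive_score(pose, grid):
    """Independent straight-line oracle: exhaustive nearest-vertex search
    plus per-atom lookup and plain averaging."""
    nx, ny, nz = grid.box.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    vertices = grid.box.origin + np.stack([ii, jj, kk], axis=-1) * grid.box.step
    total = 0.0
    for atom in pose.atoms:
        d2 = np.sum((vertices - atom.coords) ** 2, axis=-1)
        flat = int(np.argmin(d2))
        idx = np.unravel_index(flat, (nx, ny, nz))
        pos = grid.box.origin + np.array(idx) * grid.box.step
        # the atom is "in box" iff its nearest lattice vertex is within half a
        # step on every axis; otherwise the true nearest vertex of the
        # infinite lattice falls outside and the atom contributes zero
        if np.all(np.abs(pos - atom.coords) <= grid.box.step / 2 + 1e-12):
            arr = grid.counts.get(atom.sybyl_type)
            if arr is not None:
                total += float(arr[idx])
    return total / len(pose.atoms)


class TestNearestVertex:
    def test_coordinate_on_vertex_is_identity(self, small_box):
        for k in ([0, 0, 0], [7, 3, 20], [20, 20, 20]):
            coord = small_box.vertex_position(k)
            idx, in_box = nearest_vertex(coord, small_box)
            assert idx == tuple(k) and in_box

    def test_halfway_tie_rounds_to_even(self):
        box = pg.DockingBox(center=np.full(3, 0.5), edges=np.full(3, 1.0),
                            step=0.1)
        coord = box.origin + 0.05  # exactly between vertices 0 and 1
        idx, _ = nearest_vertex(coord, box)
        assert idx == (0, 0, 0)

    def test_out_of_box_is_flagged_and_clamped(self, small_box):
        idx, in_box = nearest_vertex(small_box.origin - 1.0, small_box)
        assert not in_box and idx == (0, 0, 0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        box = pg.DockingBox(center=rng.uniform(-2, 2, 3),
                            edges=np.full(3, 4.0), step=0.4)
        nx, ny, nz = box.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        verts = box.origin + np.stack([ii, jj, kk], axis=-1) * box.step
        for _ in range(50):
            coord = box.center + rng.uniform(-1.9, 1.9, 3)
            idx, in_box = nearest_vertex(coord, box)
            assert in_box
            d2 = np.sum((verts - coord) ** 2, axis=-1)
            best = np.unravel_index(int(np.argmin(d2)), (nx, ny, nz))
            assert d2[idx] == pytest.approx(d2[best], abs=1e-12)


class TestScorePose:
    def test_constant_grid_scores_constant(self, small_box):
        arrays = {t: np.full(small_box.shape, 3.5) for t in ("C.3", "N.am")}
        grid = _grid_from_arrays(small_box, arrays)
        pose = _pose([_atom(small_box.center, "C.3"),
                      _atom(small_box.center + 0.3, "N.am")])
        assert score_pose(pose, grid) == pytest.approx(3.5)

    def test_three_atom_mean(self, small_box):
        arr = np.zeros(small_box.shape)
        arr[2, 2, 2], arr[4, 4, 4], arr[6, 6, 6] = 1.0, 2.0, 3.0
        grid = _grid_from_arrays(small_box, {"C.3": arr})
        pose = _pose([
            _atom(small_box.vertex_position([2, 2, 2])),
            _atom(small_box.vertex_position([4, 4, 4])),
            _atom(small_box.vertex_position([6, 6, 6])),
        ])
        assert score_pose(pose, grid) == pytest.approx(2.0)

    def test_out_of_box_atom_scores_zero_but_counts(self, small_box):
        arr = np.full(small_box.shape, 4.0)
        grid = _grid_from_arrays(small_box, {"C.3": arr})
        pose = _pose([_atom(small_box.center),
                      _atom(small_box.origin - 5.0)])
        assert score_pose(pose, grid) == pytest.approx(2.0)

    def test_unknown_type_is_error(self, small_box):
        grid = pg.FrequencyGrid(box=small_box, type_axis=("C.3",))
        pose = _pose([_atom(small_box.center, "N.am")])
        with pytest.raises(ValueError, match="N.am"):
            score_pose(pose, grid)

    def test_atom_order_invariance(self, small_box):
        rng = np.random.default_rng(4)
        arr = rng.random(small_box.shape)
        grid = _grid_from_arrays(small_box, {"C.3": arr})
        atoms = [_atom(rng.uniform(-4, 4, 3)) for _ in range(8)]
        fwd = score_pose(_pose(atoms), grid)
        rev = score_pose(_pose(list(reversed(atoms))), grid)
        assert fwd == pytest.approx(rev, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        box = pg.DockingBox(center=rng.uniform(-1, 1, 3),
                            edges=np.full(3, 5.0), step=float(rng.uniform(0.3, 0.6)))
        arrays = {
            t: rng.integers(0, 20, box.shape).astype(float)
            for t in ("C.3", "C.ar", "N.am")
        }
        grid = _grid_from_arrays(box, arrays)
        for _ in range(5):
            atoms = [
                _atom(box.center + rng.uniform(-3.5, 3.5, 3),
                      str(rng.choice(["C.3", "C.ar", "N.am"])))
                for _ in range(rng.integers(3, 12))
            ]
            pose = _pose(atoms)
            assert score_pose(pose, grid) == pytest.approx(
                naive_score(pose, grid), abs=1e-12
            )


class TestRescoreSet:
    def _grid_with_values(self, box, values):
        """Grid + poses arranged so raw scores equal the given values."""
        arr = np.zeros(box.shape)
        poses = []
        for i, v in enumerate(values):
            arr[2 * i + 1, 1, 1] = v
            poses.append(_pose([_atom(box.vertex_position([2 * i + 1, 1, 1]))],
                               pid=f"p{i}"))
        return _grid_from_arrays(box, {"C.3": arr}), poses

    def test_normalization_and_ranks(self, small_box):
        grid, poses = self._grid_with_values(small_box, [2.0, 4.0, 8.0])
        results = rescore_set(poses, grid)
        by_id = {r.pose_id: r for r in results}
        assert by_id["p0"].normalized_score == pytest.approx(0.25)
        assert by_id["p1"].normalized_score == pytest.approx(0.5)
        assert by_id["p2"].normalized_score == pytest.approx(1.0)
        assert (by_id["p0"].rank, by_id["p1"].rank, by_id["p2"].rank) == (3, 2, 1)

    def test_single_pose(self, small_box):
        grid, poses = self._grid_with_values(small_box, [5.0])
        (r,) = rescore_set(poses, grid)
        assert r.normalized_score == 1.0 and r.rank == 1

    def test_all_equal_scores_tie_break_by_pose_id(self, small_box):
        grid, poses = self._grid_with_values(small_box, [3.0, 3.0, 3.0])
        # same vertex value everywhere relevant -> identical raw scores
        arr = np.full(small_box.shape, 3.0)
        grid = _grid_from_arrays(small_box, {"C.3": arr})
        results = rescore_set(poses, grid)
        assert all(r.normalized_score == 1.0 for r in results)
        assert [r.pose_id for r in results] == ["p0", "p1", "p2"]
        assert [r.rank for r in results] == [1, 2, 3]

    def test_all_zero_scores_warns_and_keeps_input_order(self, small_box):
        grid = _grid_from_arrays(small_box, {})
        poses = [_pose([_atom(small_box.center)], pid=f"p{i}") for i in range(3)]
        with pytest.warns(UserWarning, match="all raw scores are zero"):
            results = rescore_set(poses, grid)
        assert [r.rank for r in results] == [1, 2, 3]
        assert all(r.normalized_score == 0.0 for r in results)

    def test_ranking_invariant_under_grid_scaling(self, typed_ensemble, small_grid):
        typed, _ = typed_ensemble
        base = rescore_set(typed, small_grid)
        # occurrence counts are integers, so these products are exact in
        # float64 and ties are preserved bit-for-bit; the invariance itself
        # holds for any positive factor in exact arithmetic
        for lam in (0.5, 3.0, 1024.0):
            scaled = pg.FrequencyGrid(
                box=small_grid.box, type_axis=small_grid.type_axis,
                counts={k: lam * v.astype(np.float64)
                        for k, v in small_grid.counts.items()},
                n_poses=small_grid.n_poses,
            )
            rs = rescore_set(typed, scaled)
            assert [r.pose_id for r in rs] == [r.pose_id for r in base]
            for a, b in zip(rs, base):
                assert a.normalized_score == pytest.approx(b.normalized_score,
                                                           rel=1e-5)

    def test_bounds_after_normalization(self, typed_ensemble, small_grid):
        typed, _ = typed_ensemble
        results = rescore_set(typed, small_grid)
        scores = [r.normalized_score for r in results]
        assert max(scores) == 1.0
        assert min(scores) >= 0.0
        assert sorted(r.rank for r in results) == list(range(1, len(results) + 1))
        # normalized score is non-increasing with rank
        ordered = sorted(results, key=lambda r: r.rank)
        assert all(a.normalized_score >= b.normalized_score
                   for a, b in zip(ordered, ordered[1:]))

    def test_duplicated_pose_dominates_its_own_grid(self, table, small_box):
        """Density dominance: a pose duplicated many times plus scattered
        singletons ranks first when self-rescoring."""
        rng = np.random.default_rng(9)
        template = [_atom(small_box.center + rng.uniform(-1, 1, 3))
                    for _ in range(6)]
        poses = [
            _pose([_atom(a.coords) for a in template], pid=f"dup{i}")
            for i in range(20)
        ]
        for i in range(10):
            atoms = [_atom(rng.uniform(-4.5, 4.5, 3)) for _ in range(6)]
            poses.append(_pose(atoms, pid=f"lone{i}"))
        grid = pg.build_frequency_grid(poses, box=small_box)
        results = rescore_set(poses, grid)
        assert results[0].pose_id.startswith("dup")


class TestSelection:
    def test_hundred_distinct_scores_percentile_95_gives_5(self):
        results = [
            pg.RescoredPose(f"p{i:03d}", "GGG", "vina", float(i),
                            (i + 1) / 100.0, 100 - i)
            for i in range(100)
        ]
        sel = select_top_percentile(results, 95.0)
        assert len(sel) == 5
        assert all(r.rank <= 5 for r in sel.poses)

    def test_percentile_zero_selects_everything(self):
        results = [pg.RescoredPose(f"p{i}", "GGG", "vina", 1.0, 0.5, i + 1)
                   for i in range(10)]
        sel = select_top_percentile(results, 0.0)
        assert len(sel) == 10

    def test_planted_cluster_is_recovered_with_sequence_tally(self):
        low = [pg.RescoredPose(f"low{i}", "AAA", "vina", 1.0, 0.1 + i * 1e-3,
                               i + 8) for i in range(92)]
        high = [pg.RescoredPose(f"hit{i}", "PSYG" if i < 5 else "PYYA",
                                "vina", 9.0, 0.95 + i * 1e-3, 7 - i)
                for i in range(7)]
        sel = select_top_percentile(low + high, 95.0)
        assert {r.pose_id for r in sel.poses} <= {r.pose_id for r in high}
        assert sel.sequence_counts["PSYG"] + sel.sequence_counts["PYYA"] == len(sel)


def test_histogram_conserves_counts_and_range(typed_ensemble, small_grid):
    typed, _ = typed_ensemble
    results = rescore_set(typed, small_grid)
    counts, edges = score_histogram(results, bins=10)
    assert counts.sum() == len(results)
    assert edges[0] == 0.0 and edges[-1] == 1.0
    constant = [pg.RescoredPose(f"c{i}", "G", "vina", 1.0, 0.55, i + 1)
                for i in range(9)]
    counts2, _ = score_histogram(constant, bins=10)
    assert (counts2 > 0).sum() == 1
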