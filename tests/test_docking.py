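"""Grid maps, interpolation, stochastic search, RMSD and clustering."""

import numpy as np
import pytest

from hingedock.docking import (
    Box,
    SearchConfig,
    _batch_totals,
    _interpolate,
    build_grids,
    cluster_poses,
    dock,
    grid_energy,
    pose_rmsd,
)
from hingedock.geometry import Pose, realize_pose
from hingedock.mol_model import AtomRecord, Molecule, assign_atom_types
from hingedock.scoring import binding_free_energy


@pytest.fixture(scope="module")
def binder_grids(toy_binder, params):
    types = sorted({a.type_code for a in toy_binder.ligand.atoms})
    box = Box.from_center_extent(toy_binder.site_center, 11.0, 0.25)
    return build_grids(toy_binder.receptor, box, params, ligand_types=types)


# make session fixtures visible at module scope
@pytest.fixture(scope="module")
def toy_binder(params):
    from hingedock.fixtures import make_toy_complex

    return make_toy_complex(1, "binder", params)


@pytest.fixture(scope="module")
def params():
    from hingedock.params import ParameterSet

    return ParameterSet.default()


fast_cfg = SearchConfig(population=40, generations=40)


class TestBoxGeometry:
    def test_doubling_spacing_halves_node_counts(self):
        fine = Box.from_center_extent([0, 0, 0], 10.0, 0.5)
        coarse = Box.from_center_extent([0, 0, 0], 10.0, 1.0)
        for n_f, n_c in zip(fine.dims, coarse.dims):
            assert n_c == -(-(n_f + 1) // 2)

    def test_contains(self):
        box = Box((0.0, 0.0, 0.0), (11, 11, 11), 1.0)
        assert box.contains(np.array([5.0, 5.0, 5.0]))
        assert not box.contains(np.array([10.5, 5.0, 5.0]))

    def test_degenerate_boxes_rejected(self):
        with pytest.raises(ValueError):
            Box((0, 0, 0), (1, 5, 5), 1.0)
        with pytest.raises(ValueError):
            Box((0, 0, 0), (5, 5, 5), 0.0)


class TestInterpolation:
    def test_identity_on_nodes(self, rng):
        grid = rng.normal(size=(5, 6, 7))
        idx = np.array([[2.0, 3.0, 4.0], [0.0, 0.0, 0.0], [4.0, 5.0, 6.0]])
        vals = _interpolate(grid, idx)
        assert vals == pytest.approx(
            [grid[2, 3, 4], grid[0, 0, 0], grid[4, 5, 6]], abs=1e-12
        )

    def test_exact_for_linear_fields(self, rng):
        # trilinear interpolation reproduces any affine function exactly
        ii, jj, kk = np.meshgrid(
            np.arange(6), np.arange(6), np.arange(6), indexing="ij"
        )
        grid = 1.5 * ii - 2.0 * jj + 0.25 * kk + 3.0
        pts = rng.uniform(0, 5, size=(20, 3))
        expected = 1.5 * pts[:, 0] - 2.0 * pts[:, 1] + 0.25 * pts[:, 2] + 3.0
        assert _interpolate(grid, pts) == pytest.approx(expected, abs=1e-9)

    def test_edge_midpoint_is_mean_of_nodes(self, rng):
        grid = rng.normal(size=(4, 4, 4))
        mid = _interpolate(grid, np.array([[1.5, 2.0, 2.0]]))[0]
        assert mid == pytest.approx((grid[1, 2, 2] + grid[2, 2, 2]) / 2, abs=1e-12)


class TestGridMaps:
    def test_probe_at_node_equals_direct_pair_sum(self, toy_binder, params):
        box = Box.from_center_extent(toy_binder.site_center, 6.0, 1.0)
        grids = build_grids(
            toy_binder.receptor, box, params, ligand_types=["C.3"]
        )
        node = np.asarray(box.origin) + np.array([3, 3, 3]) * box.spacing
        expected = 0.0
        for a in toy_binder.receptor.atoms:
            r = float(np.linalg.norm(a.coords - node))
            if r > params.cutoff:
                continue
            aij, bij = params.vdw_pair("C.3", a.type_code)
            expected += aij / r**12 - bij / r**6
        assert grids.vdw_maps[("C.3", "")][3, 3, 3] == pytest.approx(
            expected, rel=1e-9
        )

    def test_electrostatic_map_linear_in_probe_charge(
        self, toy_binder, binder_grids, params
    ):
        mol = toy_binder.ligand.copy()
        e1 = grid_energy(binder_grids, mol, toy_binder.planted_pose, params).elec
        for a in mol.atoms:
            a.partial_charge *= 2.0
        mol._score_cache = None
        e2 = grid_energy(binder_grids, mol, toy_binder.planted_pose, params).elec
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_grid_error_shrinks_with_spacing(self, toy_binder, params):
        direct = binding_free_energy(
            toy_binder.receptor, toy_binder.ligand, toy_binder.planted_pose, params
        ).total
        types = sorted({a.type_code for a in toy_binder.ligand.atoms})
        errors = []
        for spacing in (1.0, 0.5, 0.25):
            box = Box.from_center_extent(toy_binder.site_center, 10.0, spacing)
            grids = build_grids(
                toy_binder.receptor, box, params, ligand_types=types
            )
            approx = grid_energy(
                grids, toy_binder.ligand, toy_binder.planted_pose, params
            ).total
            errors.append(abs(approx - direct))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] <= 0.10

    def test_out_of_box_pose_rejected_or_raises(
        self, toy_binder, binder_grids, params
    ):
        far = Pose(np.asarray(binder_grids.box.upper) + 50.0)
        e = grid_energy(binder_grids, toy_binder.ligand, far, params)
        assert np.isinf(e.total)
        with pytest.raises(ValueError):
            grid_energy(
                binder_grids, toy_binder.ligand, far, params, out_of_box="raise"
            )

    def test_batch_totals_match_single_pose_path(
        self, toy_binder, binder_grids, params, rng
    ):
        poses = [
            Pose(toy_binder.site_center + rng.normal(0, 1.5, 3),
                 rng.normal(size=4))
            for _ in range(12)
        ]
        batch = _batch_totals(binder_grids, toy_binder.ligand, poses, params)
        single = np.array(
            [
                grid_energy(binder_grids, toy_binder.ligand, p, params).total
                for p in poses
            ]
        )
        finite = np.isfinite(single)
        assert np.array_equal(np.isfinite(batch), finite)
        assert batch[finite] == pytest.approx(single[finite], abs=1e-9)


class TestDock:
    def test_seed_determinism_bit_identical(self, toy_binder, binder_grids, params):
        kw = dict(n_runs=2, seed=11, search_cfg=fast_cfg)
        r1 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params, **kw)
        r2 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params, **kw)
        for a, b in zip(r1.poses, r2.poses):
            assert np.array_equal(a.translation, b.translation)
            assert np.array_equal(a.orientation, b.orientation)
            assert a.score.total == b.score.total

    def test_runs_independent_of_execution_order(
        self, toy_binder, binder_grids, params
    ):
        r4 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                  n_runs=4, seed=7, search_cfg=fast_cfg)
        r2 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                  n_runs=2, seed=7, search_cfg=fast_cfg)
        # first two runs of the 4-run result replicate the 2-run result
        for a, b in zip(r2.poses, r4.poses[:2]):
            assert np.array_equal(a.translation, b.translation)
            assert a.score.total == b.score.total

    def test_best_never_worsens_with_more_runs(
        self, toy_binder, binder_grids, params
    ):
        r2 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                  n_runs=2, seed=5, search_cfg=fast_cfg)
        r5 = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                  n_runs=5, seed=5, search_cfg=fast_cfg)
        assert r5.best.score.total <= r2.best.score.total

    def test_elitism_trace_monotone(self, toy_binder, binder_grids, params):
        res = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                   n_runs=2, seed=3, search_cfg=fast_cfg)
        for trace in res.history:
            finite = trace[np.isfinite(trace)]
            assert np.all(np.diff(finite) <= 1e-12)

    def test_zero_runs_rejected(self, toy_binder, binder_grids, params):
        with pytest.raises(ValueError):
            dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                 n_runs=0, seed=0)

    def test_clusters_partition_poses(self, toy_binder, binder_grids, params):
        res = dock(toy_binder.ligand, binder_grids, toy_binder.receptor, params,
                   n_runs=4, seed=2, search_cfg=fast_cfg)
        flat = sorted(i for c in res.clusters for i in c)
        assert flat == list(range(len(res.poses)))
        assert res.best.score.total <= min(p.score.total for p in res.poses)


class TestPoseRmsd:
    def test_identical_poses_zero(self, toy_binder):
        p = toy_binder.planted_pose
        assert pose_rmsd(toy_binder.ligand, p, p) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self, toy_binder):
        p = toy_binder.planted_pose
        q = Pose(p.translation + np.array([1.0, 0, 0]), p.orientation, p.torsions)
        assert pose_rmsd(toy_binder.ligand, p, q) == pytest.approx(1.0, abs=1e-9)

    def test_benzene_flip_is_symmetry_equivalent(self, params):
        benzene = assign_atom_types(Molecule.from_smiles("c1ccccc1"), params)
        heavy = benzene.coords[benzene.heavy_indices]
        # ring normal via SVD of the centered ring coordinates
        centered = heavy - heavy.mean(axis=0)
        normal = np.linalg.svd(centered)[2][2]
        half = np.deg2rad(60.0) / 2
        q_rot = np.concatenate([[np.cos(half)], np.sin(half) * normal])
        a = Pose(np.zeros(3), torsions=np.zeros(benzene.n_tor))
        b = Pose(np.zeros(3), q_rot, np.zeros(benzene.n_tor))
        assert pose_rmsd(benzene, a, b) < 0.05

    def test_torsion_count_mismatch_rejected(self, params):
        mol = assign_atom_types(Molecule.from_smiles("CCCC"), params)
        bad = Pose(np.zeros(3), torsions=np.zeros(mol.n_tor + 2))
        with pytest.raises(ValueError, match="torsions"):
            realize_pose(mol, bad)

    def test_cluster_poses_greedy_by_energy(self, toy_binder):
        p = toy_binder.planted_pose.copy()
        from hingedock.scoring import EnergyBreakdown

        def with_total(t, shift):
            q = Pose(p.translation + shift, p.orientation, p.torsions)
            q.score = EnergyBreakdown.from_terms(t, 0, 0, 0, 0)
            return q

        poses = [
            with_total(-1.0, np.zeros(3)),
            with_total(-0.5, np.array([0.5, 0, 0])),   # same basin
            with_total(-0.2, np.array([8.0, 0, 0])),   # distinct
        ]
        clusters = cluster_poses(toy_binder.ligand, poses, cutoff=2.0)
        assert sorted(map(len, clusters)) == [1, 2]
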