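"""The five-term binding free energy function and its invariants."""

import math

import numpy as np
import pytest

from hingedock.fixtures import brute_force_energy, make_toy_complex
from hingedock.geometry import Pose
from hingedock.mol_model import AtomRecord
from hingedock.params import AngularParams, DielectricParams, ParameterSet, Weights
from hingedock.receptor_prep import Receptor
from hingedock.scoring import (
    angular_weight,
    binding_free_energy,
    desolvation_term,
    elec_term,
    hbond_term,
    torsion_penalty,
    vdw_term,
)


class TestPairTerms:
    def test_vdw_direct_substitution(self):
        assert vdw_term(1.0, (2.0, 2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_vdw_minimum_depth(self):
        a, b = 5.0e5, 1.2e3
        r_eq = (2 * a / b) ** (1 / 6)
        assert vdw_term(r_eq, (a, b)) == pytest.approx(-b * b / (4 * a), rel=1e-12)

    def test_vdw_decays_beyond_three_equilibria(self):
        a, b = 5.0e5, 1.2e3
        r_eq = (2 * a / b) ** (1 / 6)
        depth = b * b / (4 * a)
        assert abs(vdw_term(3 * r_eq, (a, b))) < 0.01 * depth

    @pytest.mark.parametrize("bad_r", [0.0, -1.0])
    def test_nonpositive_distance_rejected(self, bad_r):
        with pytest.raises(ValueError):
            vdw_term(bad_r, (1.0, 1.0))
        with pytest.raises(ValueError):
            hbond_term(bad_r, 180.0, (1.0, 1.0), AngularParams())
        with pytest.raises(ValueError):
            elec_term(bad_r, 0.1, 0.1, DielectricParams())

    def test_hbond_direct_substitution_at_ideal_angle(self):
        assert hbond_term(1.0, 180.0, (5.0, 6.0), AngularParams()) == pytest.approx(
            -1.0, abs=1e-12
        )

    def test_hbond_angular_node_at_90_degrees_off(self):
        assert hbond_term(2.9, 90.0, (5.0, 6.0), AngularParams()) == pytest.approx(
            0.0, abs=1e-30
        )

    def test_angular_weight_monotone_from_ideal(self):
        ang = AngularParams()
        ws = [angular_weight(t, ang) for t in (180, 160, 140, 120, 100, 90)]
        assert ws[0] == 1.0
        assert all(x > y for x, y in zip(ws, ws[1:]))

    def test_elec_zero_charge(self):
        assert elec_term(3.0, 0.0, 0.5, DielectricParams()) == 0.0

    def test_elec_sign_rule(self):
        d = DielectricParams()
        for r in (1.0, 3.0, 10.0):
            assert elec_term(r, 0.3, 0.3, d) > 0
            assert elec_term(r, 0.3, -0.3, d) < 0

    def test_sigmoidal_dielectric_reaches_bulk(self):
        d = DielectricParams()
        assert float(d.epsilon(50.0)) == pytest.approx(78.4, rel=0.01)

    def test_dielectric_strictly_increasing(self):
        d = DielectricParams()
        r = np.linspace(0.5, 40, 200)
        eps = np.asarray(d.epsilon(r))
        assert np.all(np.diff(eps) > 0)

    def test_torsion_penalty_values(self):
        assert torsion_penalty(0, 0.3113) == 0.0
        assert torsion_penalty(3, 0.3113) == pytest.approx(0.9339, abs=1e-9)
        assert torsion_penalty(6, 0.3113) == pytest.approx(
            2 * torsion_penalty(3, 0.3113), abs=1e-12
        )
        with pytest.raises(ValueError):
            torsion_penalty(-1, 0.3113)


def _atom(xyz, s, v, occ):
    a = AtomRecord("C", xyz, type_code="C.3")
    a.solvation = (s, v, occ)
    return a


class TestDesolvation:
    def test_isolated_atom_keeps_full_deficit(self):
        a = _atom([0, 0, 0], 0.01, 10.0, 20.0)
        assert desolvation_term([a], [a], 3.5, 1.0) == pytest.approx(
            0.01 * 20.0, abs=1e-12
        )

    def test_single_neighbor_hand_value(self):
        a = _atom([0, 0, 0], 0.01, 10.0, 20.0)
        b = _atom([3.5, 0, 0], 0.0, 10.0, 20.0)
        expected = 0.01 * (20.0 - 10.0 * math.exp(-0.5))
        assert desolvation_term([a], [a, b], 3.5, 1.0) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(0.1394, abs=5e-4)

    def test_full_burial_clamps_to_zero(self):
        a = _atom([0, 0, 0], 0.01, 10.0, 20.0)
        nbrs = [a] + [_atom([0.1 * k, 0, 0], 0.0, 50.0, 20.0) for k in range(1, 5)]
        assert desolvation_term([a], nbrs, 3.5, 1.0) == 0.0

    def test_adding_neighbor_never_increases_deficit(self, rng):
        a = _atom([0, 0, 0], 0.01, 10.0, 200.0)
        nbrs = [a]
        prev = desolvation_term([a], nbrs, 3.5, 1.0)
        for _ in range(10):
            nbrs.append(_atom(rng.uniform(-5, 5, 3), 0.0, 12.0, 200.0))
            cur = desolvation_term([a], nbrs, 3.5, 1.0)
            assert cur <= prev + 1e-12
            prev = cur

    def test_missing_parameters_named(self):
        a = AtomRecord("C", [0, 0, 0], type_code="C.3", name="C7")
        with pytest.raises(ValueError, match="C7"):
            desolvation_term([a], [a], 3.5, 1.0)


class TestBindingFreeEnergy:
    def test_breakdown_additivity(self, toy_binder, params):
        e = binding_free_energy(
            toy_binder.receptor, toy_binder.ligand, toy_binder.planted_pose, params
        )
        assert e.total == pytest.approx(
            e.vdw + e.hbond + e.elec + e.torsion + e.desolvation, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("kind", ["binder", "nonbinder", "clash"])
    def test_oracle_equivalence(self, seed, kind, params):
        tc = make_toy_complex(seed, kind, params)
        mine = binding_free_energy(tc.receptor, tc.ligand, tc.planted_pose, params)
        ref = brute_force_energy(tc.receptor, tc.ligand, tc.planted_pose, params)
        for field in ("vdw", "hbond", "elec", "torsion", "desolvation", "total"):
            assert getattr(mine, field) == pytest.approx(
                getattr(ref, field), abs=1e-9
            ), field
        assert mine.clash == ref.clash

    def test_rigid_motion_invariance(self, toy_binder, params, rng):
        from hingedock.geometry import quaternion_matrix, realize_pose
        from hingedock.mol_model import Molecule

        tc = toy_binder
        e0 = binding_free_energy(tc.receptor, tc.ligand, tc.planted_pose, params)
        q = rng.normal(size=4)
        R = quaternion_matrix(q / np.linalg.norm(q))
        t = rng.uniform(-20, 20, 3)

        rec2 = Receptor.from_atoms(
            [
                AtomRecord(
                    a.element, R @ a.coords + t, type_code=a.type_code,
                    partial_charge=a.partial_charge, roles=a.roles,
                    name=a.name, resname=a.resname, resnum=a.resnum,
                    chain=a.chain,
                )
                for a in tc.receptor.atoms
            ]
        )
        for a, b in zip(rec2.atoms, tc.receptor.atoms):
            a.solvation = b.solvation
        lig_xyz = realize_pose(tc.ligand, tc.planted_pose)
        lig2 = tc.ligand.copy()
        lig2.set_coords(lig_xyz @ R.T + t)
        e1 = binding_free_energy(rec2, lig2, None, params)
        for field in ("vdw", "hbond", "elec", "torsion", "desolvation", "total"):
            assert getattr(e1, field) == pytest.approx(
                getattr(e0, field), abs=1e-9
            ), field

    def test_beyond_cutoff_leaves_only_ligand_intrinsic_terms(
        self, toy_binder, params
    ):
        tc = toy_binder
        far = Pose(
            tc.planted_pose.translation + np.array([500.0, 0.0, 0.0]),
            tc.planted_pose.orientation,
            tc.planted_pose.torsions,
        )
        e = binding_free_energy(tc.receptor, tc.ligand, far, params)
        assert e.vdw == 0.0 and e.hbond == 0.0 and e.elec == 0.0
        # the dehydration term keeps its ligand-only self-occupancy value
        iso = desolvation_term(
            tc.ligand.atoms, tc.ligand.atoms, params.sigma, params.weights.sol
        )
        assert e.desolvation == pytest.approx(iso, abs=1e-9)
        assert e.total == pytest.approx(e.torsion + e.desolvation, abs=1e-9)

    def test_single_pair_equilibrium_reproduces_well_depth(self, params):
        a, b = params.vdw_pair("C.3", "C.3")
        r_eq = (2 * a / b) ** (1 / 6)
        rec = Receptor.from_atoms(
            [AtomRecord("C", [0, 0, 0], type_code="C.3", name="C1")]
        )
        rec.atoms[0].solvation = params.solvation("C.3")
        from hingedock.mol_model import Molecule

        probe = Molecule.from_atoms(
            [AtomRecord("C", [r_eq, 0, 0], type_code="C.3")]
        )
        psz = params.with_weights(sol=0.0)
        probe.atoms[0].solvation = params.solvation("C.3")
        e = binding_free_energy(rec, probe, None, psz)
        depth = b * b / (4 * a)
        assert e.total == pytest.approx(-psz.weights.vdw * depth, abs=1e-9)

    def test_zero_solvation_weight_reproduces_four_term_score(
        self, toy_binder, params
    ):
        tc = toy_binder
        full = binding_free_energy(tc.receptor, tc.ligand, tc.planted_pose, params)
        p4 = params.with_weights(sol=0.0)
        four = binding_free_energy(tc.receptor, tc.ligand, tc.planted_pose, p4)
        assert four.desolvation == 0.0
        for field in ("vdw", "hbond", "elec", "torsion"):
            assert getattr(four, field) == pytest.approx(
                getattr(full, field), abs=1e-12
            )
        assert four.total == pytest.approx(
            full.total - full.desolvation, abs=1e-9
        )

    def test_clash_flagged_but_energy_returned(self, params):
        tc = make_toy_complex(3, "clash", params)
        e = binding_free_energy(tc.receptor, tc.ligand, tc.planted_pose, params)
        assert e.clash
        assert np.isfinite(e.total)

    def test_empty_ligand_scores_zero(self, toy_binder, params):
        from hingedock.mol_model import Molecule

        empty = Molecule.from_atoms([])
        e = binding_free_energy(toy_binder.receptor, empty, None, params)
        assert e.total == 0.0


class TestParameterSet:
    def test_pair_symmetry(self, params):
        for ti, tj in [("C.3", "O.2"), ("N.am", "C.ar"), ("O.3", "N.ar")]:
            assert params.vdw_pair(ti, tj) == params.vdw_pair(tj, ti)
            assert params.hbond_eligible(ti, tj) == params.hbond_eligible(tj, ti)

    def test_hbond_pair_requires_complementary_roles(self, params):
        assert params.hbond_eligible("N.am", "O.2")   # donor vs acceptor
        assert not params.hbond_eligible("C.3", "O.2")
        with pytest.raises(ValueError):
            params.hbond_pair("C.3", "C.3")

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            Weights(vdw=-0.1)

    def test_unknown_type_code_named_in_error(self, params):
        with pytest.raises(KeyError, match="Z.9"):
            params.type_params("Z.9")

    def test_roundtrip_through_text_table(self, tmp_path, params):
        # the shipped table is self-describing text; re-reading it must
        # reproduce identical pair parameters
        import importlib.resources as resources

        src = resources.files("hingedock.data").joinpath("atom_types.txt")
        dst = tmp_path / "copy.txt"
        dst.write_text(src.read_text())
        again = ParameterSet.from_file(dst)
        assert set(again.atom_types) == set(params.atom_types)
        assert again.vdw_pair("C.3", "O.2") == params.vdw_pair("C.3", "O.2")
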