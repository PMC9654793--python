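"""Receptor loading, rule-based protonation, hydrogen placement, hinge."""

import numpy as np
import pytest

from hingedock.fixtures import make_tripeptide_pdb
from hingedock.mol_model import AtomRecord
from hingedock.receptor_prep import (
    Receptor,
    _hydrogen_directions,
    _residue_h_template,
    Residue,
    add_hydrogens,
    assign_protonation_states,
    assign_receptor_types,
    designate_hinge_residue,
    load_receptor,
    write_receptor,
)


@pytest.fixture(scope="module")
def tripeptide(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "tripeptide.pdb"
    make_tripeptide_pdb(path)
    return load_receptor(path)


def _res_atom(name, resname, resnum, xyz, chain="A"):
    elem = name[0] if name[0] not in "0123456789" else name[1]
    return AtomRecord(
        elem, xyz, name=name, resname=resname, resnum=resnum, chain=chain
    )


def _asp_with_partner(partner_dist):
    """Minimal ASP sidechain plus a serine OG acceptor at a set distance."""
    atoms = [
        _res_atom("N", "ASP", 1, [0.0, 3.0, 0.0]),
        _res_atom("CA", "ASP", 1, [0.0, 1.6, 0.0]),
        _res_atom("C", "ASP", 1, [1.4, 1.1, 0.0]),
        _res_atom("O", "ASP", 1, [2.4, 1.8, 0.0]),
        _res_atom("CB", "ASP", 1, [-1.1, 0.7, 0.0]),
        _res_atom("CG", "ASP", 1, [-1.1, -0.8, 0.0]),
        _res_atom("OD1", "ASP", 1, [-0.1, -1.5, 0.0]),
        _res_atom("OD2", "ASP", 1, [-2.2, -1.4, 0.0]),
        _res_atom("OG", "SER", 2, [-0.1, -1.5 - partner_dist, 0.0]),
    ]
    return Receptor.from_atoms(atoms)


def _lys_with_donor(partner_dist):
    atoms = [
        _res_atom("N", "LYS", 1, [0.0, 6.0, 0.0]),
        _res_atom("CA", "LYS", 1, [0.0, 4.6, 0.0]),
        _res_atom("C", "LYS", 1, [1.4, 4.1, 0.0]),
        _res_atom("O", "LYS", 1, [2.4, 4.8, 0.0]),
        _res_atom("CB", "LYS", 1, [-1.2, 3.8, 0.0]),
        _res_atom("CG", "LYS", 1, [-1.2, 2.3, 0.0]),
        _res_atom("CD", "LYS", 1, [-2.4, 1.5, 0.0]),
        _res_atom("CE", "LYS", 1, [-2.4, 0.0, 0.0]),
        _res_atom("NZ", "LYS", 1, [-3.6, -0.8, 0.0]),
    ]
    if np.isfinite(partner_dist):
        atoms.append(
            _res_atom("NE2", "GLN", 2, [-3.6, -0.8 - partner_dist, 0.0])
        )
    return Receptor.from_atoms(atoms)


class TestLoadReceptor:
    def test_tripeptide_has_three_residues(self, tripeptide):
        assert len(tripeptide.residues) == 3
        assert all(r.name == "ALA" for r in tripeptide.residues.values())
        assert len(tripeptide) == 15

    def test_backbone_geometry_sane(self, tripeptide):
        r1 = tripeptide.residues[("A", 1)]
        n = r1.atom_index(tripeptide, "N")
        ca = r1.atom_index(tripeptide, "CA")
        d = np.linalg.norm(tripeptide.atoms[n].coords - tripeptide.atoms[ca].coords)
        assert d == pytest.approx(1.458, abs=0.01)

    def test_altloc_highest_occupancy_retained(self, tmp_path):
        pdb = tmp_path / "altloc.pdb"
        pdb.write_text(
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N\n"
            "ATOM      2  N  BALA A   1       5.000   0.000   0.000  0.40  0.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        rec = load_receptor(pdb)
        n = [a for a in rec.atoms if a.name == "N"]
        assert len(n) == 1
        assert np.allclose(n[0].coords, [0.0, 0.0, 0.0])

    def test_empty_file_is_fatal(self, tmp_path):
        pdb = tmp_path / "empty.pdb"
        pdb.write_text("END\n")
        with pytest.raises(ValueError):
            load_receptor(pdb)

    def test_waters_dropped(self, tmp_path):
        pdb = tmp_path / "wat.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "HETATM    2  O   HOH A   2       9.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        rec = load_receptor(pdb)
        assert len(rec) == 1


class TestProtonationRules:
    def test_asp_neutral_when_acceptor_within_limit(self):
        rec = assign_protonation_states(_asp_with_partner(3.4))
        assert rec.protonation_states[("A", 1)] == "neutral"

    def test_asp_charged_at_boundary_violation(self):
        rec = assign_protonation_states(_asp_with_partner(3.6))
        assert rec.protonation_states[("A", 1)] == "charged"

    def test_lys_charged_without_donor_neighbor(self):
        rec = assign_protonation_states(_lys_with_donor(np.inf))
        assert rec.protonation_states[("A", 1)] == "charged"

    def test_lys_neutral_near_donor(self):
        rec = assign_protonation_states(_lys_with_donor(3.2))
        assert rec.protonation_states[("A", 1)] == "neutral"

    def test_assignment_is_idempotent(self):
        rec = assign_protonation_states(_asp_with_partner(3.4))
        first = dict(rec.protonation_states)
        assign_protonation_states(rec)
        assert rec.protonation_states == first

    def test_invariant_under_rigid_motion(self, rng):
        from hingedock.geometry import quaternion_matrix

        q = rng.normal(size=4)
        R = quaternion_matrix(q / np.linalg.norm(q))
        t = rng.uniform(-30, 30, 3)
        rec = _asp_with_partner(3.4)
        moved = Receptor.from_atoms(
            [
                AtomRecord(a.element, R @ a.coords + t, name=a.name,
                           resname=a.resname, resnum=a.resnum, chain=a.chain)
                for a in rec.atoms
            ]
        )
        assert (
            assign_protonation_states(rec).protonation_states
            == assign_protonation_states(moved).protonation_states
        )

    def test_formal_charge_tracks_states(self):
        charged = assign_protonation_states(_lys_with_donor(np.inf))
        assert charged.formal_charge == 1
        neutral = assign_protonation_states(_asp_with_partner(3.4))
        assert neutral.formal_charge == 0
        anionic = assign_protonation_states(_asp_with_partner(3.6))
        assert anionic.formal_charge == -1


class TestHydrogenPlacement:
    def test_tripeptide_gains_five_hydrogens_per_alanine(self, tripeptide):
        rec = add_hydrogens(assign_protonation_states(tripeptide))
        # ALA: 1 backbone NH + 1 HA + 3 HB
        assert len(rec) == 15 + 3 * 5

    def test_hydrogen_bond_lengths(self, tripeptide):
        rec = add_hydrogens(assign_protonation_states(tripeptide))
        coords = rec.coords
        for i, a in enumerate(rec.atoms):
            if a.element != "H":
                continue
            d = np.linalg.norm(coords - a.coords, axis=1)
            nearest = np.sort(d)[1]
            assert 0.9 < nearest < 1.15

    def test_polar_hydrogens_flagged(self, tripeptide):
        rec = add_hydrogens(assign_protonation_states(tripeptide))
        hn = [a for a in rec.atoms if a.name == "HN"]
        assert len(hn) == 3 and all(a.type_code == "H.p" for a in hn)

    def test_neutral_asp_template_gains_carboxyl_hydrogen(self):
        res = Residue("ASP", "A", 1)
        neutral = _residue_h_template(res, "neutral")
        charged = _residue_h_template(res, "charged")
        assert neutral.get("OD2") == (1, True)
        assert "OD2" not in charged

    def test_lysine_amine_hydrogen_count_follows_state(self):
        res = Residue("LYS", "A", 1)
        assert _residue_h_template(res, "charged")["NZ"] == (3, True)
        assert _residue_h_template(res, "neutral")["NZ"] == (2, True)

    def test_glycine_gains_two_alpha_hydrogens(self):
        res = Residue("GLY", "A", 1)
        assert _residue_h_template(res, None)["CA"] == (2, False)

    def test_direction_geometry_tetrahedral(self):
        u = np.array([0.0, 0.0, 1.0])
        dirs = _hydrogen_directions([u], 3)
        assert len(dirs) == 3
        for d in dirs:
            assert np.degrees(np.arccos(d @ u)) == pytest.approx(109.47, abs=0.5)

    def test_incomplete_residue_skipped_with_warning(self, caplog):
        rec = Receptor.from_atoms(
            [
                _res_atom("N", "ALA", 1, [0, 0, 0]),
                _res_atom("CA", "ALA", 1, [1.46, 0, 0]),
                # no C, O, CB
            ]
        )
        import logging

        with caplog.at_level(logging.WARNING):
            out = add_hydrogens(rec)
        assert len(out) == 2  # unchanged
        assert "incomplete" in caplog.text


class TestHingeDesignation:
    def test_designation_caches_backbone_handles(self, tripeptide):
        rec = designate_hinge_residue(tripeptide, "A", 2)
        idx = rec.hinge_atom_indices
        assert rec.atoms[idx["N"]].name == "N"
        assert rec.atoms[idx["O"]].name == "O"
        assert rec.atoms[idx["N"]].resnum == 2

    def test_missing_residue_lists_available_range(self, tripeptide):
        with pytest.raises(ValueError, match="1..3"):
            designate_hinge_residue(tripeptide, "A", 99)

    def test_residue_lacking_backbone_oxygen_errors(self):
        rec = Receptor.from_atoms(
            [
                _res_atom("N", "ALA", 1, [0, 0, 0]),
                _res_atom("CA", "ALA", 1, [1.46, 0, 0]),
                _res_atom("C", "ALA", 1, [2.0, 1.3, 0]),
            ]
        )
        with pytest.raises(ValueError, match="backbone O"):
            designate_hinge_residue(rec, "A", 1)


class TestWriter:
    def test_roundtrip_with_remarks(self, tmp_path, tripeptide):
        rec = assign_protonation_states(tripeptide)
        params_out = tmp_path / "out.pdb"
        write_receptor(rec, params_out)
        text = params_out.read_text()
        assert text.startswith("REMARK") or "ATOM" in text
        again = load_receptor(params_out)
        assert len(again.residues) == 3

    def test_receptor_typing_resolves_all_atoms(self, tripeptide, params):
        rec = add_hydrogens(assign_protonation_states(tripeptide))
        assign_receptor_types(rec, params)
        assert all(a.type_code for a in rec.atoms)
        assert all(a.solvation is not None for a in rec.atoms)
        # backbone N donates, backbone O accepts
        r2 = rec.residues[("A", 2)]
        n = r2.atom_index(rec, "N")
        o = r2.atom_index(rec, "O")
        assert rec.atoms[n].is_donor
        assert rec.atoms[o].is_acceptor
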