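"""Synthetic test systems and an independent brute-force energy oracle.

Toy receptors are abstract atom arrangements, not proteins: a concave
shell of carbon atoms around a binding site plus a minimal backbone
amide motif (carbonyl C=O and amide N flanked by CA carbons, registered
as residue HNG A:1) so hinge logic can be exercised without any PDB
input.  Toy atoms carry no explicit hydrogens, so the directional
hydrogen-bond weight evaluates to 1 on these systems by construction.

``brute_force_energy`` re-derives the five-term score as plain nested
loops straight from the published functional form.  It shares only the
parameter tables and the pair conventions with the production scorer,
none of its code paths, and serves as the equivalence oracle in tests.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    Pose,
    normalize_quaternion,
    quaternion_multiply,
    rotvec_to_quaternion,
    realize_pose,
)
from .mol_model import (
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    AtomRecord,
    Molecule,
    assign_atom_types,
)
from .params import COULOMB_CONSTANT, HARD_CLASH_DISTANCE, ParameterSet
from .receptor_prep import Receptor
from .scoring import EnergyBreakdown

__all__ = [
    "ToyComplex",
    "make_toy_pocket",
    "make_toy_complex",
    "make_library",
    "brute_force_energy",
    "make_tripeptide_pdb",
]

BINDER_SMILES = [
    "O=C1CCC1", "O=C1CCCC1", "O=C1CCCCC1",
    "C1COC1", "C1CCOC1", "c1ccoc1", "c1ccncc1",
]
NONBINDER_SMILES = [
    "C1CCCCC1", "C1CCCC1", "c1ccccc1", "Cc1ccccc1",
    "CC1CCCCC1", "C1CCCCCC1",
]
RO5_FAIL_SMILES = [
    # C40 alkane: MW > 500 and logP > 5 (two violations)
    "C" * 40,
    # undecaol: 11 donors and 11 acceptors (two violations)
    "OCC(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)C(O)CO",
]


@dataclass
class ToyComplex:
    """A synthetic pocket + ligand + planted pose with its oracle energy."""

    receptor: Receptor
    ligand: Molecule
    planted_pose: Pose
    expected: EnergyBreakdown
    kind: str
    site_center: np.ndarray


# ----------------------------------------------------------------------
# pocket construction


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_toy_pocket(
    seed: int, params: ParameterSet | None = None
) -> tuple[Receptor, np.ndarray]:
    """A ~30-atom pocket: carbon shell around a site next to an amide.

    Returns the typed, charged receptor and the site center (the point
    2.9 A from the amide nitrogen where an acceptor would sit).
    """
    params = params or ParameterSet.default()
    rng = np.random.default_rng([int(seed), 7])
    u = np.array([1.0, -0.6, 0.0])
    u /= np.linalg.norm(u)

    def rec_atom(name, element, type_code, xyz, q, roles=frozenset()):
        return AtomRecord(
            element=element, coords=np.asarray(xyz, float), name=name,
            resname="HNG", resnum=1, chain="A", type_code=type_code,
            partial_charge=q, roles=roles,
        )

    n_pos = np.zeros(3)
    atoms = [
        rec_atom("CA", "C", "C.3", [-2.40, 1.20, 0.0], 0.05),
        rec_atom("C", "C", "C.2", [-1.33, 0.00, 0.0], 0.45),
        rec_atom("O", "O", "O.2", [-1.90, -1.15, 0.0], -0.45),
        rec_atom("N", "N", "N.am", n_pos, 0.30),
        rec_atom("CA2", "C", "C.3", [0.70, 1.20, 0.0], 0.05),
    ]
    site = n_pos + 2.9 * u
    amide = list(atoms)

    # mold the carbon shell to the binder template: each shell atom sits
    # at the C-C van der Waals equilibrium distance from the nearest
    # template atom, so the planted placement enjoys full shape
    # complementarity and is the deepest basin by construction
    template = _binder_template_coords(seed)
    centroid = template.mean(axis=0)
    # the amide sits in the pocket wall (as a hinge does); the solvent
    # opening points perpendicular (+z), so burying deeper can never
    # carry a ligand out of hydrogen-bonding reach of the backbone
    opening = np.array([0.0, 0.0, 1.0])
    count = 0
    for d in _fibonacci_sphere(60):
        if d @ opening > 0.55:
            continue  # leave the solvent approach open
        pos = None
        for t in np.arange(1.0, 14.0, 0.05):
            p_try = centroid + t * d
            if np.min(np.linalg.norm(template - p_try, axis=1)) >= 4.2:
                pos = p_try
                break
        if pos is None:
            continue
        pos = pos + rng.normal(0.0, 0.05, 3)
        if min(np.linalg.norm(pos - a.coords) for a in amide) < 3.2:
            continue
        if any(np.linalg.norm(pos - a.coords) < 3.2 for a in atoms[5:]):
            continue
        count += 1
        atoms.append(rec_atom(f"CS{count}", "C", "C.3", pos, 0.0))

    rec = Receptor.from_atoms(atoms)
    # resolve table roles/solvation for the pre-typed synthetic atoms
    for a in rec.atoms:
        tp = params.type_params(a.type_code)
        roles = set()
        if tp.is_acceptor:
            roles.add(ROLE_ACCEPTOR)
        if tp.is_donor:
            roles.add(ROLE_DONOR)
        a.roles = frozenset(roles)
        a.solvation = (tp.s, tp.v, tp.occ_max)
    from .receptor_prep import designate_hinge_residue

    designate_hinge_residue(rec, "A", 1)
    return rec, site


def _binder_template_coords(seed: int) -> np.ndarray:
    """Reference coordinates of the binder ligand (the cavity template)."""
    rng = np.random.default_rng([int(seed), 13])
    jit = lambda: rng.normal(0.0, 0.04, 3)
    return np.array(
        [
            [2.49, -1.49, 0.0],
            np.array([1.60, -2.35, 0.0]) + jit(),
            np.array([0.55, -3.10, 0.0]) + jit(),
            np.array([2.70, -3.35, 0.30]) + jit(),
            np.array([4.00, -3.90, 0.60]) + jit(),
        ]
    )


def _toy_ligand(kind: str, seed: int, params: ParameterSet) -> Molecule:
    """Toy ligands defined directly in the pocket frame.

    The binder is a rigid bidentate anchor mimicking a hinge-binding
    chemotype: an acceptor positioned for the backbone N, a donor
    positioned for the backbone O, and a short hydrophobic tail filling
    the shell.  The flip and spin degeneracies of a monodentate anchor
    are broken by the second hydrogen bond, so the planted pose is the
    unique optimum basin.
    """
    rng = np.random.default_rng([int(seed), 13])
    jit = lambda: rng.normal(0.0, 0.04, 3)
    if kind in ("binder", "clash"):
        xyz = _binder_template_coords(seed)
        atoms = [
            AtomRecord("O", xyz[0], type_code="O.2", name="O1",
                       partial_charge=-0.40),
            AtomRecord("C", xyz[1], type_code="C.2", name="C1",
                       partial_charge=0.45),
            AtomRecord("N", xyz[2], type_code="N.am", name="N1",
                       partial_charge=0.25),
            AtomRecord("C", xyz[3], type_code="C.3", name="C2",
                       partial_charge=0.15),
            AtomRecord("C", xyz[4], type_code="C.3", name="C3",
                       partial_charge=0.0),
        ]
        # the N1-C2 edge closes a ring so the toy is rigid (n_tor = 0);
        # toy bond lengths are schematic, not chemical
        bonds = [(0, 1, 2.0), (1, 2, 1.0), (1, 3, 1.0), (3, 4, 1.0),
                 (2, 3, 1.0)]
    else:  # nonbinder: pure hydrocarbon, no polar atoms at all
        atoms = [
            AtomRecord("C", [2.49, -1.49, 0.0], type_code="C.3", name="C1"),
            AtomRecord("C", np.array([3.40, -2.60, 0.30]) + jit(),
                       type_code="C.3", name="C2"),
            AtomRecord("C", np.array([2.80, -3.90, 0.60]) + jit(),
                       type_code="C.3", name="C3"),
        ]
        bonds = [(0, 1, 1.0), (1, 2, 1.0)]
    mol = Molecule.from_atoms(atoms, bonds, name=f"toy-{kind}-{seed}")
    assign_atom_types(mol, params)
    return mol


def _minimize_rigid(
    rec: Receptor, mol: Molecule, pose: Pose, params: ParameterSet
) -> Pose:
    """Deterministic local 6-dof minimization of the complex energy."""
    from .scoring import binding_free_energy

    def apply(x):
        dq = rotvec_to_quaternion(x[3:6])
        return Pose(
            pose.translation + x[:3],
            normalize_quaternion(quaternion_multiply(dq, pose.orientation)),
            pose.torsions,
        )

    def objective(x):
        return binding_free_energy(rec, mol, apply(x), params).total

    res = minimize(
        objective, np.zeros(6), method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-7},
    )
    return apply(res.x)


def make_toy_complex(
    seed: int, kind: str = "binder", params: ParameterSet | None = None
) -> ToyComplex:
    """Deterministic toy complex of the requested kind.

    binder     plants the ligand acceptor within 3.4 A of the amide N at
               a local optimum of the energy;
    nonbinder  plants an apolar ligand in the site (nearest polar
               contact is vacuously beyond any limit);
    clash      starts from the binder pose and drives one atom below the
               hard-clash distance.
    """
    if kind not in ("binder", "nonbinder", "clash"):
        raise ValueError(f"unknown toy-complex kind {kind!r}")
    params = params or ParameterSet.default()
    rec, site = make_toy_pocket(seed, params)
    mol = _toy_ligand(kind, seed, params)

    n_xyz = rec.atoms[rec.hinge_atom_indices["N"]].coords
    # ligand reference coordinates already sit in the pocket frame, so
    # the starting pose is the identity placement at the centroid
    pose = Pose(mol.coords.mean(axis=0), np.array([1.0, 0.0, 0.0, 0.0]),
                np.zeros(mol.n_tor))
    pose = _minimize_rigid(rec, mol, pose, params)

    if kind == "binder":
        xyz = realize_pose(mol, pose)
        d = float(np.linalg.norm(xyz[0] - n_xyz))
        if d > 3.4:
            raise AssertionError(
                f"binder construction failed: acceptor {d:.2f} A from amide N"
            )
    if kind == "clash":
        xyz = realize_pose(mol, pose)
        dists = np.linalg.norm(
            rec.coords[:, None, :] - xyz[None, :, :], axis=2
        )
        ri, li = np.unravel_index(np.argmin(dists), dists.shape)
        # overlap at 1.3 A: below the hard-clash limit, but shy of the
        # r -> 0 singularity where float precision degrades
        shift = (rec.coords[ri] - xyz[li])
        shift *= (1.0 - 1.3 / np.linalg.norm(shift))
        pose = Pose(pose.translation + shift, pose.orientation, pose.torsions)

    expected = brute_force_energy(rec, mol, pose, params)
    return ToyComplex(
        receptor=rec, ligand=mol, planted_pose=pose,
        expected=expected, kind=kind, site_center=site,
    )


# ----------------------------------------------------------------------
# synthetic screening library


def make_library(
    seed: int,
    n: int,
    frac_binders: float = 0.1,
    params: ParameterSet | None = None,
) -> tuple[list[Molecule], dict[str, dict]]:
    """``n`` small molecules with ground-truth labels for pipeline tests.

    Binders carry a hydrogen-bond acceptor and are drawn from small
    rigid scaffolds; non-binders are hydrocarbons; a slice of the
    non-binder budget is druggability failures (two Rule-of-Five
    violations) that must fall out at the first stage.
    """
    if n < 0 or not 0.0 <= frac_binders <= 1.0:
        raise ValueError("need n >= 0 and frac_binders in [0, 1]")
    params = params or ParameterSet.default()
    rng = np.random.default_rng([int(seed), 23])
    n_bind = int(round(n * frac_binders))
    n_rest = n - n_bind
    n_fail = min(n_rest, max(1, n_rest // 10) if n_rest else 0)
    n_non = n_rest - n_fail

    specs = (
        [("binder", s) for s in _cycle(BINDER_SMILES, n_bind)]
        + [("nonbinder", s) for s in _cycle(NONBINDER_SMILES, n_non)]
        + [("ro5fail", s) for s in _cycle(RO5_FAIL_SMILES, n_fail)]
    )
    rng.shuffle(specs)

    mols: list[Molecule] = []
    labels: dict[str, dict] = {}
    for i, (label, smiles) in enumerate(specs):
        name = f"lib_{i:04d}"
        mol = Molecule.from_smiles(smiles, name=name)
        assign_atom_types(mol, params)
        from .mol_model import gasteiger_charges

        gasteiger_charges(mol)
        mols.append(mol)
        labels[name] = {
            "binder": label == "binder",
            "ro5_expected": label != "ro5fail",
            "smiles": smiles,
        }
    return mols, labels


def _cycle(pool: list[str], n: int) -> list[str]:
    return [pool[i % len(pool)] for i in range(n)]


# ----------------------------------------------------------------------
# independent oracle


def brute_force_energy(
    rec: Receptor, mol: Molecule, pose: Pose | None, params: ParameterSet
) -> EnergyBreakdown:
    """Direct double-loop evaluation of the five-term score.

    No grids, no vectorization; the nonbonded cutoff and pair
    conventions match the production scorer's documented contract so
    the two must agree to numerical precision.
    """
    if len(mol.atoms) == 0:
        return EnergyBreakdown.zero()
    lig_xyz = realize_pose(mol, pose)
    rec_atoms = rec.atoms
    cutoff = params.cutoff
    sigma = params.sigma
    ang = params.angular
    well = params.hbond

    # polar hydrogens attached to each donor (receptor side)
    rec_donor_h: dict[int, list[int]] = {}
    for i, a in enumerate(rec_atoms):
        if a.is_donor:
            rec_donor_h[i] = [
                j for j, b in enumerate(rec_atoms)
                if b.is_polar_h
                and float(np.linalg.norm(b.coords - a.coords)) < 1.3
            ]
    lig_donor_h = {
        i: mol.attached_polar_hydrogens(i)
        for i in range(len(mol.atoms))
        if mol.atoms[i].is_donor
    }

    def e_of_t(dxyz, hxyz, axyz):
        v1 = dxyz - hxyz
        v2 = axyz - hxyz
        n1 = math.sqrt(float(v1 @ v1))
        n2 = math.sqrt(float(v2 @ v2))
        if n1 == 0 or n2 == 0:
            return 0.0
        t = math.degrees(math.acos(max(-1.0, min(1.0, float(v1 @ v2) / (n1 * n2)))))
        dev = math.radians(t - ang.ideal_deg)
        return max(0.0, math.cos(dev)) ** ang.exponent

    vdw = 0.0
    hb = 0.0
    elec = 0.0
    clash = False
    for i, ra in enumerate(rec_atoms):
        for j, la in enumerate(mol.atoms):
            r = float(np.linalg.norm(ra.coords - lig_xyz[j]))
            if r < HARD_CLASH_DISTANCE:
                clash = True
            if r > cutoff or r == 0.0:
                continue
            eligible = (ra.is_donor and la.is_acceptor) or (
                ra.is_acceptor and la.is_donor
            )
            if eligible:
                radial = well.c / r ** 12 - well.d / r ** 10
                candidates = []
                if ra.is_donor and la.is_acceptor:
                    hs = rec_donor_h.get(i, [])
                    if hs:
                        e = max(
                            e_of_t(ra.coords, rec_atoms[h].coords, lig_xyz[j])
                            for h in hs
                        )
                        candidates.append(e * radial)
                    else:
                        candidates.append(radial)
                if ra.is_acceptor and la.is_donor:
                    hs = lig_donor_h.get(j, [])
                    if hs:
                        e = max(
                            e_of_t(lig_xyz[j], lig_xyz[h], ra.coords)
                            for h in hs
                        )
                        candidates.append(e * radial)
                    else:
                        candidates.append(radial)
                hb += min(candidates)
            else:
                a_ij, b_ij = params.vdw_pair(ra.type_code, la.type_code)
                vdw += a_ij / r ** 12 - b_ij / r ** 6
            elec += (
                COULOMB_CONSTANT
                * ra.partial_charge
                * la.partial_charge
                / (float(params.epsilon(r)) * r)
            )

    # dehydration of each ligand atom
    desolv = 0.0
    for i, la in enumerate(mol.atoms):
        s_i, _, occ_max = params.solvation(la.type_code)
        occ = 0.0
        for ra in rec_atoms:
            r = float(np.linalg.norm(ra.coords - lig_xyz[i]))
            if r <= cutoff:
                occ += params.solvation(ra.type_code)[1] * math.exp(
                    -(r ** 2) / (2 * sigma ** 2)
                )
        for j, lb in enumerate(mol.atoms):
            if j == i:
                continue
            r = float(np.linalg.norm(lig_xyz[j] - lig_xyz[i]))
            if r <= cutoff:
                occ += params.solvation(lb.type_code)[1] * math.exp(
                    -(r ** 2) / (2 * sigma ** 2)
                )
        desolv += s_i * max(0.0, occ_max - occ)

    # intra-ligand pairs: >= 4 bonds apart, in different rigid fragments
    n = len(mol.atoms)
    adj = mol.adjacency()
    rot_bonds = (
        {frozenset(b.bond) for b in mol.torsion_tree.branches}
        if mol.torsion_tree
        else set()
    )
    # rigid fragment labels by flood fill over non-rotatable bonds
    frag = [-1] * n
    fid = 0
    for s in range(n):
        if frag[s] >= 0:
            continue
        stack = [s]
        frag[s] = fid
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if frag[y] < 0 and frozenset((x, y)) not in rot_bonds:
                    frag[y] = fid
                    stack.append(y)
        fid += 1

    def bond_distance(src: int) -> list[int]:
        dist = [-1] * n
        dist[src] = 0
        queue = [src]
        while queue:
            x = queue.pop(0)
            for y in adj[x]:
                if dist[y] < 0:
                    dist[y] = dist[x] + 1
                    queue.append(y)
        return dist

    ivdw = 0.0
    ielec = 0.0
    for i in range(n):
        dist_i = bond_distance(i)
        for j in range(i + 1, n):
            if frag[i] == frag[j]:
                continue
            if 0 <= dist_i[j] < 4:
                continue
            r = float(np.linalg.norm(lig_xyz[i] - lig_xyz[j]))
            if r > cutoff or r == 0.0:
                continue
            a_ij, b_ij = params.vdw_pair(
                mol.atoms[i].type_code, mol.atoms[j].type_code
            )
            ivdw += a_ij / r ** 12 - b_ij / r ** 6
            ielec += (
                COULOMB_CONSTANT
                * mol.atoms[i].partial_charge
                * mol.atoms[j].partial_charge
                / (float(params.epsilon(r)) * r)
            )

    w = params.weights
    return EnergyBreakdown.from_terms(
        vdw=w.vdw * (vdw + ivdw),
        hbond=w.hbond * hb,
        elec=w.elec * (elec + ielec),
        torsion=w.tor * mol.n_tor,
        desolvation=w.sol * desolv,
        clash=clash,
    )


# ----------------------------------------------------------------------
# tiny real-format PDB fixture


def _nerf(a, b, c, r, theta_deg, phi_deg):
    """Place the next atom from three predecessors by internal coordinates."""
    theta = math.radians(theta_deg)
    phi = math.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -r * math.cos(theta),
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def make_tripeptide_pdb(path, n_res: int = 3) -> None:
    """Write a small ideal-geometry polyalanine PDB file (reader fixture)."""
    phi, psi, omega = -120.0, 120.0, 180.0
    atoms = []  # (name, resnum, xyz)
    anchor = np.array([-1.0, 0.8, 0.0])
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = _nerf(anchor, n, ca, 1.525, 111.0, phi)
    for i in range(1, n_res + 1):
        o = _nerf(n, ca, c, 1.231, 120.8, psi + 180.0)
        cb = _nerf(c, n, ca, 1.530, 110.5, 240.0 + phi)
        atoms += [
            ("N", i, n), ("CA", i, ca), ("C", i, c), ("O", i, o), ("CB", i, cb)
        ]
        if i == n_res:
            break
        n_next = _nerf(n, ca, c, 1.329, 116.2, psi)
        ca_next = _nerf(ca, c, n_next, 1.458, 121.7, omega)
        c_next = _nerf(c, n_next, ca_next, 1.525, 111.0, phi)
        n, ca, c = n_next, ca_next, c_next
    lines = []
    for k, (name, resnum, xyz) in enumerate(atoms, 1):
        lines.append(
            f"ATOM  {k:5d}  {name:<3s} ALA A{resnum:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
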