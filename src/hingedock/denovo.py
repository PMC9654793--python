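"""Core-fixed derivative growth.

Starting from a docked scaffold with marked substitution points
(hydrogens on the core that may be replaced), enumerate the Cartesian
product of a fragment library over the sites, place each substituent at
ideal bond geometry along the replaced hydrogen's direction, relax only
the substituent's rotation about the new bond, and score with the full
binding free energy function while every core heavy atom stays frozen
at its docked coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .geometry import Pose, realize_pose, rotate_about_axis
from .mol_model import Molecule, assign_atom_types, gasteiger_charges, rule_of_five
from .params import ParameterSet
from .scoring import EnergyBreakdown, binding_free_energy

log = logging.getLogger(__name__)

__all__ = [
    "CoreTemplate", "Fragment", "FragmentLibrary", "Derivative",
    "default_fragment_library", "enumerate_derivatives",
    "grow_and_score", "select_candidates",
]

#: New-bond lengths by (core element, fragment attach element), Angstrom.
_BOND_LENGTHS = {
    ("C", "C"): 1.51, ("C", "O"): 1.43, ("C", "N"): 1.41,
    ("C", "F"): 1.35, ("C", "Cl"): 1.73, ("C", "Br"): 1.90,
    ("C", "I"): 2.10, ("C", "S"): 1.77,
}


@dataclass(frozen=True)
class Fragment:
    """A substituent with one attachment point, written as SMILES with ``*``."""

    name: str
    smiles: str  # contains exactly one dummy atom marking the attachment

    @property
    def is_hydrogen(self) -> bool:
        return self.smiles in ("*[H]", "[H]*", "*")


@dataclass(frozen=True)
class FragmentLibrary:
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        for f in self.fragments:
            if f.smiles.count("*") != 1:
                raise ValueError(
                    f"fragment {f.name}: exactly one attachment atom required"
                )
        if not any(f.is_hydrogen for f in self.fragments):
            raise ValueError("library must include the null (H) substitution")

    def __iter__(self):
        return iter(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)


def default_fragment_library() -> FragmentLibrary:
    """Small substituents typical of kinase-inhibitor SAR series."""
    return FragmentLibrary(
        (
            Fragment("H", "*[H]"),
            Fragment("methyl", "*C"),
            Fragment("ethyl", "*CC"),
            Fragment("propyl", "*CCC"),
            Fragment("isopropyl", "*C(C)C"),
            Fragment("methoxy", "*OC"),
            Fragment("hydroxy", "*O"),
            Fragment("amino", "*N"),
            Fragment("fluoro", "*F"),
            Fragment("chloro", "*Cl"),
            Fragment("bromo", "*Br"),
            Fragment("phenyl", "*c1ccccc1"),
        )
    )


@dataclass
class CoreTemplate:
    """A docked scaffold plus its marked substitution points.

    ``attachment_points`` are (heavy atom index, replaced hydrogen
    index) pairs into ``molecule``; the hydrogen must be terminal and
    bonded to the heavy atom.
    """

    molecule: Molecule
    attachment_points: list[tuple[int, int]]
    core_pose: Pose | None

    def __post_init__(self) -> None:
        seen = set()
        for heavy, h in self.attachment_points:
            if (heavy, h) in seen:
                raise ValueError("attachment points must be distinct")
            seen.add((heavy, h))
            if self.molecule.atoms[h].element != "H":
                raise ValueError(f"atom {h} is not a hydrogen")
            nbrs = self.molecule.neighbors(h)
            if nbrs != [heavy]:
                raise ValueError(
                    f"replaced hydrogen {h} must be terminal on atom {heavy}"
                )


@dataclass
class Derivative:
    molecule: Molecule
    assignment: dict[int, str]          # site index -> fragment name
    core_atom_sources: list[int]        # kept atom indices into the core
    core_atom_map: list[int]            # their indices in the derivative
    substituent_atoms: list[list[int]]  # new-atom indices per site
    clash: bool = False


# ----------------------------------------------------------------------


def _fragment_rdmol(frag: Fragment) -> tuple[Chem.Mol, int]:
    """Embedded fragment with explicit Hs; returns (mol, dummy index)."""
    m = Chem.MolFromSmiles(frag.smiles)
    if m is None:
        raise ValueError(f"unparseable fragment SMILES {frag.smiles!r}")
    m = Chem.AddHs(m)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = 0xF7A6
    if AllChem.EmbedMolecule(m, ps) != 0:
        ps.useRandomCoords = True
        AllChem.EmbedMolecule(m, ps)
    dummy = next(
        a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() == 0
    )
    return m, dummy


def enumerate_derivatives(
    core: CoreTemplate, frags: FragmentLibrary
) -> list[Derivative]:
    """Cartesian product of fragments over the attachment points.

    Duplicate structures (by canonical SMILES) and valence violations
    are dropped with a log entry; the all-H assignment (the core
    itself) is always present.
    """
    if not core.attachment_points:
        raise ValueError("core has no attachment points")
    if core.molecule.rdmol is None:
        raise ValueError("de novo growth needs an RDKit-backed core")

    out: list[Derivative] = []
    seen: set[str] = set()
    n_dropped = 0
    for combo in itertools.product(list(frags), repeat=len(core.attachment_points)):
        try:
            deriv = _build_derivative(core, combo)
        except ValueError as exc:
            n_dropped += 1
            log.info("derivative dropped (%s)", exc)
            continue
        smi = Chem.MolToSmiles(Chem.RemoveHs(deriv.molecule.rdmol))
        if smi in seen:
            n_dropped += 1
            continue
        seen.add(smi)
        out.append(deriv)
    if n_dropped:
        log.info("enumeration dropped %d duplicates/invalid candidates", n_dropped)
    return out


def _build_derivative(
    core: CoreTemplate, combo: tuple[Fragment, ...]
) -> Derivative:
    """Attach one fragment per site; geometry is resolved later in growth."""
    base = core.molecule
    if all(f.is_hydrogen for f in combo):
        mol = base.copy()
        mol.name = f"{base.name}:" + ",".join(f.name for f in combo)
        return Derivative(
            molecule=mol,
            assignment={i: f.name for i, f in enumerate(combo)},
            core_atom_sources=list(range(len(base.atoms))),
            core_atom_map=list(range(len(base.atoms))),
            substituent_atoms=[[] for _ in combo],
        )

    rw = Chem.RWMol(base.rdmol)
    conf = rw.GetConformer()
    site_attach: list[tuple[int, int] | None] = []  # (core heavy, frag attach)
    removed: list[int] = []
    for (heavy, h), frag in zip(core.attachment_points, combo):
        if frag.is_hydrogen:
            site_attach.append(None)
            continue
        fmol, dummy = _fragment_rdmol(frag)
        attach = next(
            b.GetOtherAtomIdx(dummy)
            for b in fmol.GetAtomWithIdx(dummy).GetBonds()
        )
        offset = rw.GetNumAtoms()
        combined = Chem.CombineMols(rw, fmol)
        rw = Chem.RWMol(combined)
        rw.AddBond(heavy, offset + attach, Chem.BondType.SINGLE)
        rw.RemoveAtom(offset + dummy)
        removed.append(h)
        site_attach.append((heavy, offset + attach if offset + attach < offset + dummy
                            else offset + attach - 1))
    # drop the replaced hydrogens last (descending) so indices stay valid
    index_map = list(range(rw.GetNumAtoms()))
    for h in sorted(removed, reverse=True):
        rw.RemoveAtom(h)
    try:
        newmol = rw.GetMol()
        Chem.SanitizeMol(newmol)
    except Exception as exc:
        raise ValueError(f"valence violation on attachment: {exc}") from None

    # map original indices to post-deletion indices
    shift = np.zeros(len(index_map), dtype=int)
    for h in removed:
        shift[h + 1:] += 1
    remap = {old: old - int(shift[old]) for old in index_map if old not in removed}

    mol = Molecule.from_rdkit(newmol, add_hs=False, embed=False,
                              name=f"{base.name}:" + ",".join(f.name for f in combo))
    core_sources = [i for i in range(len(base.atoms)) if i not in removed]
    core_atom_map = [remap[i] for i in core_sources]
    # carry core coordinates over (fragment atoms keep embedded positions
    # for now; growth re-places them)
    xyz = mol.coords
    for src, dst in zip(core_sources, core_atom_map):
        xyz[dst] = base.atoms[src].coords
    mol.set_coords(xyz)
    # substituent atoms: everything not mapped from the core, grouped by
    # connectivity to each site's attach atom
    core_set = set(core_atom_map)
    extra_set = {i for i in range(len(mol.atoms)) if i not in core_set}
    subst: list[list[int]] = []
    adj = mol.adjacency()
    for k, site in enumerate(site_attach):
        if site is None:
            subst.append([])
            continue
        heavy, attach_old = site
        attach_new = attach_old - int(shift[attach_old])
        group = {attach_new}
        stack = [attach_new]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y in extra_set and y not in group:
                    group.add(y)
                    stack.append(y)
        subst.append(sorted(group))
    return Derivative(
        molecule=mol,
        assignment={i: f.name for i, f in enumerate(combo)},
        core_atom_sources=core_sources,
        core_atom_map=core_atom_map,
        substituent_atoms=subst,
    )


# ----------------------------------------------------------------------
# growth and scoring


def _place_substituent(
    mol: Molecule,
    heavy_new: int,
    attach_new: int,
    group: list[int],
    direction: np.ndarray,
) -> None:
    """Rigidly move a substituent so its attach atom sits at ideal bond
    geometry along ``direction`` from the core heavy atom."""
    xyz = mol.coords
    pair = (mol.atoms[heavy_new].element, mol.atoms[attach_new].element)
    blen = _BOND_LENGTHS.get(pair, 1.50)
    target = xyz[heavy_new] + blen * direction

    # align the fragment's internal attach->centroid axis opposite to the bond
    group_arr = np.array(group)
    local = xyz[group_arr] - xyz[attach_new]
    if len(group) > 1:
        axis_from = local.sum(axis=0)
        nrm = np.linalg.norm(axis_from)
        axis_from = axis_from / nrm if nrm > 1e-8 else direction
        rot = _rotation_between(axis_from, direction)
        local = local @ rot.T
    xyz[group_arr] = target + local
    mol.set_coords(xyz)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        p = np.array([1.0, 0.0, 0.0])
        if abs(a @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, p)
        v /= np.linalg.norm(v)
        return 2 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def grow_and_score(
    core: CoreTemplate,
    derivatives: list[Derivative],
    rec,
    params: ParameterSet,
    grids=None,
    seed: int = 0,
    scan_step_deg: float = 15.0,
) -> list[tuple[Derivative, EnergyBreakdown]]:
    """Place and score every derivative with the core frozen.

    Substituents are placed along the replaced hydrogen's direction at
    ideal bond length, then rotated about the new bond on a grid of
    ``scan_step_deg`` steps to the lowest-energy torsion.  Core heavy
    atoms never move (their RMSD to the docked core pose is exactly 0).
    Hard clashes are flagged, never dropped.  Returns (derivative,
    breakdown) sorted by total energy, ties broken by name.
    """
    base = core.molecule
    core_xyz = realize_pose(base, core.core_pose)

    results: list[tuple[Derivative, EnergyBreakdown]] = []
    for deriv in derivatives:
        mol = deriv.molecule
        xyz = mol.coords
        # freeze core atoms at the docked coordinates
        for src, dst in zip(deriv.core_atom_sources, deriv.core_atom_map):
            xyz[dst] = core_xyz[src]
        mol.set_coords(xyz)

        for site_idx, group in enumerate(deriv.substituent_atoms):
            if not group:
                continue
            heavy_old, h_old = core.attachment_points[site_idx]
            heavy_new = deriv.core_atom_map[
                deriv.core_atom_sources.index(heavy_old)
            ]
            direction = core_xyz[h_old] - core_xyz[heavy_old]
            direction = direction / np.linalg.norm(direction)
            attach_new = group[0]
            # attach atom is the group member bonded to the core heavy atom
            for g in group:
                if heavy_new in mol.neighbors(g):
                    attach_new = g
                    break
            _place_substituent(mol, heavy_new, attach_new, group, direction)
            _scan_torsion(mol, heavy_new, attach_new, group, rec, params,
                          scan_step_deg)

        assign_atom_types(mol, params)
        if mol.rdmol is not None:
            gasteiger_charges(mol)
        mol._score_cache = None
        e = binding_free_energy(rec, mol, None, params)
        deriv.clash = e.clash
        results.append((deriv, e))

    results.sort(key=lambda t: (t[1].total, t[0].molecule.name))
    return results


def _scan_torsion(
    mol: Molecule,
    heavy: int,
    attach: int,
    group: list[int],
    rec,
    params: ParameterSet,
    step_deg: float,
) -> None:
    """Rotate the substituent about the core-substituent bond to the
    lowest-energy angle (core atoms untouched)."""
    rotating = [g for g in group if g != attach]
    if not rotating:
        return
    assign_atom_types(mol, params)
    mol._score_cache = None
    base_xyz = mol.coords
    best_xyz, best_e = base_xyz.copy(), np.inf
    axis = base_xyz[attach] - base_xyz[heavy]
    angles = np.arange(0.0, 360.0, step_deg)
    for ang in angles:
        xyz = base_xyz.copy()
        xyz[rotating] = rotate_about_axis(
            xyz[rotating], base_xyz[attach], axis, ang
        )
        mol.set_coords(xyz)
        e = binding_free_energy(rec, mol, None, params).total
        if e < best_e:
            best_e, best_xyz = e, xyz
    mol.set_coords(best_xyz)


def select_candidates(
    ranked: list[tuple[Derivative, EnergyBreakdown]],
    k: int,
    druggability_filter: bool = True,
) -> list[tuple[Derivative, EnergyBreakdown]]:
    """Apply the Rule-of-Five filter, then truncate to the top ``k``.

    Ties were already broken by (energy, name) in the ranking.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    kept = []
    for deriv, e in ranked:
        if druggability_filter and not rule_of_five(deriv.molecule).passed:
            continue
        kept.append((deriv, e))
    return kept[:k]
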