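"""Ligand data model: parsing, atom typing, charges, descriptors, filtering.

A :class:`Molecule` is a plain container of :class:`AtomRecord` objects
plus a bond list and a torsion tree.  Molecules parsed from SMILES/SDF
keep a reference to their RDKit mol, through which standard chemistry
(Gasteiger charging, logP, canonicalization) is delegated; synthetic toy
molecules built directly from atom records work everywhere except the
RDKit-backed descriptor operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen
from rdkit.Chem import rdPartialCharges

from .params import ParameterSet

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: IUPAC standard average atomic masses, amu (to one-thousandth).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06,
    "Cl": 35.453, "K": 39.098, "Ca": 40.078, "Br": 79.904, "I": 126.904,
}

#: Fixed seed for conformer embedding so parsing is reproducible.
_EMBED_SEED = 0xD0C5

ROLE_DONOR = "donor-heavy"
ROLE_ACCEPTOR = "acceptor"
ROLE_POLAR_H = "polar-hydrogen"


@dataclass
class AtomRecord:
    """One atom: element, force-field type, position, charge and roles.

    ``roles`` is a frozenset drawn from {donor-heavy, acceptor,
    polar-hydrogen}; an atom such as a hydroxyl oxygen is legitimately
    both donor-heavy and acceptor, so a single label would be lossy.
    ``solvation`` holds (S_i, V_i, Occ_max_i) of the dehydration term.
    """

    element: str
    coords: np.ndarray
    type_code: str = ""
    partial_charge: float = 0.0
    roles: frozenset = frozenset()
    solvation: tuple[float, float, float] | None = None
    name: str = ""
    resname: str = ""
    resnum: int = 0
    chain: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name or self.element}: bad coordinates")

    @property
    def is_donor(self) -> bool:
        return ROLE_DONOR in self.roles

    @property
    def is_acceptor(self) -> bool:
        return ROLE_ACCEPTOR in self.roles

    @property
    def is_polar_h(self) -> bool:
        return ROLE_POLAR_H in self.roles

    @property
    def hbond_role(self) -> str:
        """Primary role as a single label ('none' when no role applies)."""
        if self.is_polar_h:
            return ROLE_POLAR_H
        if self.is_donor:
            return ROLE_DONOR
        if self.is_acceptor:
            return ROLE_ACCEPTOR
        return "none"


@dataclass(frozen=True)
class TorsionBranch:
    """A rotatable bond (axis a->b) and the atoms it moves."""

    bond: tuple[int, int]
    atoms: tuple[int, ...]
    polar_h_rotor: bool = False


@dataclass(frozen=True)
class TorsionTree:
    root: tuple[int, ...]
    branches: tuple[TorsionBranch, ...]


class Molecule:
    """Atoms + bonds + torsion tree; the ligand side of every energy term."""

    def __init__(
        self,
        atoms: list[AtomRecord],
        bonds: list[tuple[int, int, float]],
        name: str = "",
        formal_charge: int = 0,
        rdmol: Chem.Mol | None = None,
    ) -> None:
        self.atoms = list(atoms)
        self.bonds = [(int(i), int(j), float(o)) for i, j, o in bonds]
        self.name = name
        self.formal_charge = int(formal_charge)
        self.rdmol = rdmol
        self.torsion_tree: TorsionTree | None = None
        self.n_tor: int = 0

    # ------------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.coords = p.copy()

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for a, b, _ in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def attached_polar_hydrogens(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.atoms[j].is_polar_h]

    def copy(self) -> "Molecule":
        m = Molecule(
            [replace(a, coords=a.coords.copy(), roles=frozenset(a.roles))
             for a in self.atoms],
            list(self.bonds),
            name=self.name,
            formal_charge=self.formal_charge,
            rdmol=Chem.Mol(self.rdmol) if self.rdmol is not None else None,
        )
        m.torsion_tree = self.torsion_tree
        m.n_tor = self.n_tor
        return m

    # ------------------------------------------------------------------
    # construction

    @classmethod
    def from_rdkit(
        cls,
        rdmol: Chem.Mol,
        name: str = "",
        embed: bool = True,
        add_hs: bool = True,
    ) -> "Molecule":
        """Build a Molecule from an RDKit mol (adds Hs, embeds 3D if needed)."""
        mol = Chem.Mol(rdmol)
        if add_hs:
            mol = Chem.AddHs(mol)
        if mol.GetNumConformers() == 0:
            if not embed:
                raise ValueError("molecule has no conformer and embed=False")
            ps = AllChem.ETKDGv3()
            ps.randomSeed = _EMBED_SEED
            if AllChem.EmbedMolecule(mol, ps) != 0:
                # fall back to random coords for pathological inputs
                ps.useRandomCoords = True
                if AllChem.EmbedMolecule(mol, ps) != 0:
                    raise ValueError(f"3D embedding failed for {name!r}")
            AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
        conf = mol.GetConformer()
        atoms = [
            AtomRecord(
                element=a.GetSymbol(),
                coords=np.array(conf.GetAtomPosition(a.GetIdx())),
                name=f"{a.GetSymbol()}{a.GetIdx()}",
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
            for b in mol.GetBonds()
        ]
        out = cls(
            atoms, bonds,
            name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
            formal_charge=Chem.GetFormalCharge(mol),
            rdmol=mol,
        )
        build_torsion_tree(out)
        return out

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "Molecule":
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls.from_rdkit(rdmol, name=name)

    @classmethod
    def from_atoms(
        cls,
        atoms: list[AtomRecord],
        bonds: list[tuple[int, int, float]] | None = None,
        name: str = "",
        formal_charge: int = 0,
    ) -> "Molecule":
        """Synthetic molecule from explicit atom records (no RDKit backing)."""
        m = cls(atoms, bonds or [], name=name, formal_charge=formal_charge)
        build_torsion_tree(m)
        return m


@dataclass
class FilterVerdict:
    """Outcome of the Rule-of-Five druggability screen.

    ``passed`` follows the common at-most-one-violation convention.
    """

    passed: bool
    violations: list[str]
    descriptor_values: dict[str, float]


class LibraryLoadResult(list):
    """List of molecules with a count of skipped (unparseable) records."""

    n_skipped: int = 0


# ----------------------------------------------------------------------
# operations


def load_library(path: str | Path, format: str | None = None) -> LibraryLoadResult:
    """Read a ligand library (SMILES: one record per line, or SDF V2000).

    Invalid records are skipped; the count is logged and available as
    ``result.n_skipped``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"smi": "smiles", "smiles": "smiles", "ism": "smiles",
                  "sdf": "sdf", "mol": "sdf"}.get(suffix.lstrip("."), None)
        if format is None:
            raise ValueError(f"cannot infer format from extension {suffix!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    out = LibraryLoadResult()
    skipped = 0
    if format == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{lineno}"
            try:
                out.append(Molecule.from_smiles(smiles, name=name))
            except ValueError:
                skipped += 1
                log.warning("skipping unparseable SMILES record at line %d", lineno)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for idx, rdmol in enumerate(supplier):
            if rdmol is None:
                skipped += 1
                log.warning("skipping unparseable SDF record %d", idx)
                continue
            out.append(Molecule.from_rdkit(rdmol))
    else:
        raise ValueError(f"unknown library format {format!r}")
    if skipped:
        log.info("loaded %d molecules, skipped %d invalid records", len(out), skipped)
    if not out:
        log.warning("no valid records in %s", path)
    out.n_skipped = skipped
    return out


def molecular_weight(mol: Molecule) -> float:
    """Molecular mass in amu: sum of standard average atomic masses."""
    total = 0.0
    for i, a in enumerate(mol.atoms):
        try:
            total += ATOMIC_MASSES[a.element]
        except KeyError:
            raise ValueError(
                f"unknown element {a.element!r} at atom index {i}"
            ) from None
    return total


def gasteiger_charges(mol: Molecule, n_iter: int = 8) -> Molecule:
    """Assign Gasteiger-Marsilli (PEOE) partial charges in place.

    Iterative partial equalization of orbital electronegativity with the
    canonical halved-damping schedule, run for ``n_iter`` rounds.  Total
    charge is conserved.
    """
    if mol.rdmol is None:
        raise ValueError(
            "Gasteiger charging requires an RDKit-backed molecule; "
            "synthetic molecules carry explicit charges instead"
        )
    try:
        rdPartialCharges.ComputeGasteigerCharges(
            mol.rdmol, nIter=n_iter, throwOnParamFailure=True
        )
    except Exception as exc:  # element outside the electronegativity table
        raise ValueError(f"Gasteiger parameters unavailable: {exc}") from exc
    for rec, atom in zip(mol.atoms, mol.rdmol.GetAtoms()):
        rec.partial_charge = float(atom.GetDoubleProp("_GasteigerCharge"))
    return mol


def _is_amide_bond(mol: Molecule, a: int, b: int) -> bool:
    """C-N single bond where the C carries a double-bonded O."""
    for c, n in ((a, b), (b, a)):
        if mol.atoms[c].element == "C" and mol.atoms[n].element == "N":
            for x, y, order in mol.bonds:
                if order == 2.0 and (
                    (x == c and mol.atoms[y].element == "O")
                    or (y == c and mol.atoms[x].element == "O")
                ):
                    return True
    return False


def _ring_bonds(mol: Molecule) -> set[frozenset[int]]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from([(a, b) for a, b, _ in mol.bonds])
    rings: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for i in range(len(cycle)):
            rings.add(frozenset((cycle[i], cycle[(i + 1) % len(cycle)])))
    return rings


def rotatable_bonds(
    mol: Molecule, include_polar_h: bool = True
) -> list[tuple[int, int, bool]]:
    """Rotatable bonds under the docking-tool dialect.

    A heavy-heavy acyclic single bond rotates when each end bears at
    least one further heavy neighbor (terminal methyls therefore do not
    rotate) and the bond is not an amide.  Terminal hydroxyl/amine
    rotors (heavy-heavy bond whose far end carries only hydrogens
    besides the bond, at least one of them polar) are counted when
    ``include_polar_h`` — they move no heavy atoms but freeze a rotor on
    binding, so they enter N_tor by default.

    Returns (a, b, polar_h_rotor) triples.
    """
    ring = _ring_bonds(mol)
    out = []
    for a, b, order in mol.bonds:
        if order != 1.0 or frozenset((a, b)) in ring:
            continue
        ea, eb = mol.atoms[a].element, mol.atoms[b].element
        if ea == "H" or eb == "H":
            continue
        if _is_amide_bond(mol, a, b):
            continue
        heavy_a = [n for n in mol.neighbors(a) if mol.atoms[n].element != "H" and n != b]
        heavy_b = [n for n in mol.neighbors(b) if mol.atoms[n].element != "H" and n != a]
        if heavy_a and heavy_b:
            out.append((a, b, False))
            continue
        if not include_polar_h:
            continue
        # one end terminal: polar rotor if the terminal end is N/O/S with H
        for end, other_heavy in ((a, heavy_b), (b, heavy_a)):
            h_nbrs = [n for n in mol.neighbors(end) if mol.atoms[n].element == "H"]
            heavy_end = [n for n in mol.neighbors(end)
                         if mol.atoms[n].element != "H"]
            if (
                mol.atoms[end].element in ("N", "O", "S")
                and len(heavy_end) == 1
                and h_nbrs
                and other_heavy
            ):
                out.append((a, b, True))
                break
    return out


def count_rotatable_bonds(mol: Molecule, include_polar_h: bool = True) -> int:
    """Count rotatable bonds (N_tor) and store the result on the molecule."""
    n = len(rotatable_bonds(mol, include_polar_h=include_polar_h))
    mol.n_tor = n
    return n


def build_torsion_tree(mol: Molecule, include_polar_h: bool = True) -> TorsionTree:
    """Partition the molecule into a rigid root plus rotatable branches.

    The root is the largest rigid fragment (lowest atom index breaks
    ties); each branch stores its bond axis oriented root-outward and
    the set of atoms it moves.
    """
    rots = rotatable_bonds(mol, include_polar_h=include_polar_h)
    rot_set = {frozenset((a, b)) for a, b, _ in rots}
    polar = {frozenset((a, b)): p for a, b, p in rots}
    adj = mol.adjacency()

    # rigid fragments: connected components after cutting rotatable bonds
    seen: set[int] = set()
    fragments: list[set[int]] = []
    for start in range(len(mol.atoms)):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp and frozenset((u, v)) not in rot_set:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        fragments.append(comp)
    root = max(fragments, key=lambda c: (len(c), -min(c))) if fragments else set()

    # BFS from the root across rotatable bonds; moving set = far side
    branches: list[TorsionBranch] = []
    placed = set(root)
    frontier = list(root)
    while frontier:
        nxt: list[int] = []
        for u in frontier:
            for v in adj[u]:
                if v in placed or frozenset((u, v)) not in rot_set:
                    continue
                # far-side atoms: component of v with bond (u, v) cut
                moving = {v}
                queue = [v]
                while queue:
                    x = queue.pop()
                    for y in adj[x]:
                        if y not in moving and frozenset((x, y)) != frozenset((u, v)):
                            moving.add(y)
                            queue.append(y)
                branches.append(
                    TorsionBranch(
                        bond=(u, v),
                        atoms=tuple(sorted(moving)),
                        polar_h_rotor=polar[frozenset((u, v))],
                    )
                )
                placed |= moving
                nxt.extend(moving)
        frontier = nxt

    tree = TorsionTree(root=tuple(sorted(root)), branches=tuple(branches))
    mol.torsion_tree = tree
    mol.n_tor = len(branches)
    return tree


def hbond_donor_count(mol: Molecule) -> int:
    """Lipinski donors: number of O-H and N-H hydrogens."""
    n = 0
    for a, b, _ in mol.bonds:
        ea, eb = mol.atoms[a].element, mol.atoms[b].element
        if (ea == "H" and eb in ("N", "O")) or (eb == "H" and ea in ("N", "O")):
            n += 1
    return n


def hbond_acceptor_count(mol: Molecule) -> int:
    """Lipinski acceptors: N + O count."""
    return sum(1 for a in mol.atoms if a.element in ("N", "O"))


def logp(mol: Molecule) -> float:
    """Octanol-water logP via the Wildman-Crippen atomic-contribution method."""
    if mol.rdmol is None:
        raise ValueError("logP requires an RDKit-backed molecule")
    return float(Crippen.MolLogP(mol.rdmol))


#: Rule-of-Five limits and the estimator choice recorded for audit.
RULE_OF_FIVE_CONFIG = {
    "MW": 500.0,
    "HBD": 5,
    "HBA": 10,
    "logP": 5.0,
    "logp_estimator": "wildman-crippen",
    "pass_convention": "at most one violation",
}


def rule_of_five(mol: Molecule) -> FilterVerdict:
    """Lipinski druggability screen; passes with at most one violation."""
    values = {
        "MW": molecular_weight(mol),
        "HBD": float(hbond_donor_count(mol)),
        "HBA": float(hbond_acceptor_count(mol)),
        "logP": logp(mol),
    }
    violations = [
        rule for rule in ("MW", "HBD", "HBA", "logP")
        if values[rule] > RULE_OF_FIVE_CONFIG[rule]
    ]
    return FilterVerdict(
        passed=len(violations) <= 1,
        violations=violations,
        descriptor_values=values,
    )


# ----------------------------------------------------------------------
# atom typing


def _rdkit_type_code(atom: Chem.Atom) -> str:
    elem = atom.GetSymbol()
    if elem == "C":
        if atom.GetIsAromatic():
            return "C.ar"
        if atom.GetHybridization() in (
            Chem.HybridizationType.SP2, Chem.HybridizationType.SP
        ):
            return "C.2"
        return "C.3"
    if elem == "N":
        if atom.GetFormalCharge() > 0:
            return "N.4"
        if atom.GetIsAromatic():
            # pyrrole-type NH donates; pyridine-type accepts
            return "N.pl" if atom.GetTotalNumHs(includeNeighbors=True) else "N.ar"
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() == "C":
                for b in nbr.GetBonds():
                    other = b.GetOtherAtom(nbr)
                    if (
                        b.GetBondType() == Chem.BondType.DOUBLE
                        and other.GetSymbol() == "O"
                    ):
                        return "N.am"
        if atom.GetHybridization() == Chem.HybridizationType.SP2:
            return "N.pl"
        return "N.3"
    if elem == "O":
        if atom.GetFormalCharge() < 0:
            return "O.co2"
        for b in atom.GetBonds():
            if b.GetBondType() == Chem.BondType.DOUBLE:
                return "O.2"
        if atom.GetIsAromatic():
            return "O.2"
        return "O.3"
    if elem == "S":
        return "S.3"
    if elem == "P":
        return "P.3"
    if elem == "H":
        nbr = atom.GetNeighbors()
        if nbr and nbr[0].GetSymbol() in ("N", "O", "S"):
            return "H.p"
        return "H"
    if elem in ("F", "Cl", "Br", "I"):
        return elem
    raise ValueError(f"no atom type for element {elem!r}")


def assign_atom_types(mol: Molecule, params: ParameterSet) -> Molecule:
    """Resolve type codes, hydrogen-bond roles and solvation parameters.

    RDKit-backed molecules are typed from hybridization/aromaticity; a
    synthetic molecule must arrive with type codes already set, and this
    call then validates them against the table and fills in roles and
    solvation.  Donor status additionally requires an attached hydrogen
    when hydrogens are explicit.
    """
    if mol.rdmol is not None:
        for i, (rec, atom) in enumerate(zip(mol.atoms, mol.rdmol.GetAtoms())):
            try:
                rec.type_code = _rdkit_type_code(atom)
            except ValueError as exc:
                raise ValueError(f"atom {i} ({rec.element}): {exc}") from exc

    for i, rec in enumerate(mol.atoms):
        if not rec.type_code:
            raise ValueError(
                f"atom {i} ({rec.element}) has no type code; synthetic "
                "molecules must be pre-typed"
            )
        tp = params.type_params(rec.type_code)
        roles = set()
        if tp.is_polar_h:
            roles.add(ROLE_POLAR_H)
        if tp.is_acceptor:
            roles.add(ROLE_ACCEPTOR)
        if tp.is_donor:
            if mol.rdmol is not None:
                # with explicit hydrogens, donating needs an attached H
                if any(mol.atoms[j].element == "H" for j in mol.neighbors(i)):
                    roles.add(ROLE_DONOR)
            else:
                roles.add(ROLE_DONOR)
        rec.roles = frozenset(roles)
        rec.solvation = (tp.s, tp.v, tp.occ_max)
    return mol


def descriptor_table(mols: list[Molecule]) -> "pd.DataFrame":
    """Descriptor summary (id, MW, HBD, HBA, logP, n_tor, verdict) as a frame."""
    import pandas as pd

    rows = []
    for m in mols:
        v = rule_of_five(m)
        rows.append(
            {
                "id": m.name,
                "MW": round(v.descriptor_values["MW"], 3),
                "HBD": int(v.descriptor_values["HBD"]),
                "HBA": int(v.descriptor_values["HBA"]),
                "logP": round(v.descriptor_values["logP"], 3),
                "n_tor": count_rotatable_bonds(m),
                "verdict": "pass" if v.passed else "fail",
            }
        )
    return pd.DataFrame(rows)
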