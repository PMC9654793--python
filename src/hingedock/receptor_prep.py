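"""Receptor preparation: load, protonate by rule, add hydrogens, hinge.

The protonation rules are geometric, not pKa-based: a titratable
sidechain takes the state implied by its hydrogen-bonding neighborhood
within a 3.5 A heavy-atom distance limit.  Asp/Glu go neutral when a
carboxylate oxygen can donate to a nearby acceptor; Lys stays
protonated unless its amine sits near a donor (which would force the
amine into the acceptor role); His follows the same neighborhood logic
for both its protonation and its tautomer.  Every decision is recorded
per residue for audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .mol_model import ROLE_ACCEPTOR, ROLE_DONOR, ROLE_POLAR_H, AtomRecord
from .params import ParameterSet

log = logging.getLogger(__name__)

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Heavy atoms that can accept a hydrogen bond, per residue (plus backbone O).
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
#: Heavy atoms that can donate, per residue (plus backbone N).
SIDECHAIN_DONORS = {
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "TRP": ("NE1",),
    "ASN": ("ND2",), "GLN": ("NE2",), "SER": ("OG",), "THR": ("OG1",),
    "TYR": ("OH",), "HIS": ("ND1", "NE2"), "CYS": ("SG",),
}

#: Hydrogens per heavy atom: residue -> {atom: (count, polar)}.
_BB = {"N": (1, True), "CA": (1, False)}
_H_TEMPLATE: dict[str, dict[str, tuple[int, bool]]] = {
    "GLY": {"N": (1, True), "CA": (2, False)},
    "ALA": {**_BB, "CB": (3, False)},
    "VAL": {**_BB, "CB": (1, False), "CG1": (3, False), "CG2": (3, False)},
    "LEU": {**_BB, "CB": (2, False), "CG": (1, False),
            "CD1": (3, False), "CD2": (3, False)},
    "ILE": {**_BB, "CB": (1, False), "CG1": (2, False),
            "CG2": (3, False), "CD1": (3, False)},
    "PRO": {"CA": (1, False), "CB": (2, False), "CG": (2, False),
            "CD": (2, False)},
    "SER": {**_BB, "CB": (2, False), "OG": (1, True)},
    "THR": {**_BB, "CB": (1, False), "OG1": (1, True), "CG2": (3, False)},
    "CYS": {**_BB, "CB": (2, False), "SG": (1, True)},
    "MET": {**_BB, "CB": (2, False), "CG": (2, False), "CE": (3, False)},
    "PHE": {**_BB, "CB": (2, False), "CD1": (1, False), "CD2": (1, False),
            "CE1": (1, False), "CE2": (1, False), "CZ": (1, False)},
    "TYR": {**_BB, "CB": (2, False), "CD1": (1, False), "CD2": (1, False),
            "CE1": (1, False), "CE2": (1, False), "OH": (1, True)},
    "TRP": {**_BB, "CB": (2, False), "CD1": (1, False), "NE1": (1, True),
            "CE3": (1, False), "CZ2": (1, False), "CZ3": (1, False),
            "CH2": (1, False)},
    "ASP": {**_BB, "CB": (2, False)},
    "GLU": {**_BB, "CB": (2, False), "CG": (2, False)},
    "ASN": {**_BB, "CB": (2, False), "ND2": (2, True)},
    "GLN": {**_BB, "CB": (2, False), "CG": (2, False), "NE2": (2, True)},
    "LYS": {**_BB, "CB": (2, False), "CG": (2, False), "CD": (2, False),
            "CE": (2, False)},
    "ARG": {**_BB, "CB": (2, False), "CG": (2, False), "CD": (2, False),
            "NE": (1, True), "NH1": (2, True), "NH2": (2, True)},
    "HIS": {**_BB, "CB": (2, False), "CD2": (1, False), "CE1": (1, False)},
}

_BOND_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

#: PDB atom name -> force-field type code for protein heavy atoms.
def _protein_type_code(resname: str, atom_name: str, element: str) -> str:
    if element == "H":
        return "H"
    if atom_name == "N":
        return "N.am"
    if atom_name in ("O", "OXT"):
        return "O.2" if atom_name == "O" else "O.co2"
    if atom_name == "C":
        return "C.2"
    if element == "C":
        aromatic = {
            "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
            "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
            "TRP": ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
            "HIS": ("CG", "CD2", "CE1"),
        }.get(resname, ())
        if atom_name in aromatic:
            return "C.ar"
        if (resname, atom_name) in {
            ("ASP", "CG"), ("GLU", "CD"), ("ASN", "CG"),
            ("GLN", "CD"), ("ARG", "CZ"),
        }:
            return "C.2"
        return "C.3"
    if element == "N":
        if resname == "LYS" and atom_name == "NZ":
            return "N.4"
        if resname == "HIS":
            return "N.ar"
        return "N.am" if resname in ("ASN", "GLN", "ARG", "TRP") else "N.3"
    if element == "O":
        if (resname, atom_name) in {
            ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
        }:
            return "O.co2"
        if atom_name in ("OD1", "OE1"):
            return "O.2"
        return "O.3"
    if element == "S":
        return "S.3"
    return element


@dataclass
class Residue:
    name: str
    chain: str
    number: int
    atom_indices: list[int] = field(default_factory=list)
    incomplete: bool = False

    def atom_index(self, rec: "Receptor", atom_name: str) -> int | None:
        for i in self.atom_indices:
            if rec.atoms[i].name == atom_name:
                return i
        return None


class Receptor:
    """Typed protein atoms with residue bookkeeping and a hinge anchor."""

    def __init__(self, atoms: list[AtomRecord]) -> None:
        self.atoms = list(atoms)
        self.residues: dict[tuple[str, int], Residue] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.resnum)
            if key not in self.residues:
                self.residues[key] = Residue(a.resname, a.chain, a.resnum)
            self.residues[key].atom_indices.append(i)
        for res in self.residues.values():
            if res.name in STANDARD_RESIDUES:
                have = {self.atoms[i].name for i in res.atom_indices}
                missing = set(BACKBONE_ATOMS) - have
                if res.name == "PRO":
                    missing.discard("H")
                if missing:
                    res.incomplete = True
        self.protonation_states: dict[tuple[str, int], str] = {}
        self.hinge_residue: tuple[str, int] | None = None
        self._hinge_atoms: dict[str, int] = {}
        self._cache: dict | None = None

    # ------------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def formal_charge(self) -> int:
        charge = 0
        for key, state in self.protonation_states.items():
            name = self.residues[key].name
            if name in ("ASP", "GLU"):
                charge += 0 if state == "neutral" else -1
            elif name == "LYS":
                charge += 1 if state == "charged" else 0
            elif name == "HIS":
                charge += 1 if state == "charged" else 0
        for key, res in self.residues.items():
            if res.name == "ARG":
                charge += 1
        return charge

    def invalidate(self) -> None:
        self._cache = None

    def neighbors_within(self, idx: int, radius: float) -> list[int]:
        d = np.linalg.norm(self.coords - self.atoms[idx].coords, axis=1)
        return [i for i in np.nonzero(d <= radius)[0] if i != idx]

    @property
    def hinge_atom_indices(self) -> dict[str, int]:
        if self.hinge_residue is None:
            raise ValueError("no hinge residue designated")
        return self._hinge_atoms

    def score_arrays(self, params: ParameterSet) -> dict:
        """Per-atom numeric arrays for the vectorized scorer (cached)."""
        if self._cache is not None and self._cache.get("params") is params:
            return self._cache
        ti = params.type_indices([a.type_code for a in self.atoms])
        donor_h: dict[int, list[int]] = {}
        h_idx = [i for i, a in enumerate(self.atoms) if a.is_polar_h]
        if h_idx:
            hx = np.array([self.atoms[i].coords for i in h_idx])
            for i, a in enumerate(self.atoms):
                if a.is_donor:
                    d = np.linalg.norm(hx - a.coords, axis=1)
                    donor_h[i] = [h_idx[k] for k in np.nonzero(d < 1.3)[0]]
        else:
            donor_h = {i: [] for i, a in enumerate(self.atoms) if a.is_donor}
        self._cache = {
            "params": params,
            "types": ti,
            "q": np.array([a.partial_charge for a in self.atoms]),
            "donor": np.array([a.is_donor for a in self.atoms]),
            "acceptor": np.array([a.is_acceptor for a in self.atoms]),
            "v": params.v_array[ti],
            "donor_h": donor_h,
        }
        return self._cache

    @classmethod
    def from_atoms(cls, atoms: list[AtomRecord]) -> "Receptor":
        """Build a receptor directly from atom records (synthetic pockets)."""
        return cls(atoms)


# ----------------------------------------------------------------------
# operations


def load_receptor(path: str | Path, keep_hetero: bool = False) -> Receptor:
    """Read a one-model PDB file into a Receptor.

    Altlocs resolve to the highest occupancy; waters and hetero groups
    are dropped unless ``keep_hetero``.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no model found in {path}")
    atoms: list[AtomRecord] = []
    for chain in models[0]:
        for residue in chain:
            hetflag = residue.id[0].strip()
            if hetflag and (hetflag == "W" or not keep_hetero):
                continue
            resname = residue.get_resname().strip()
            resnum = residue.id[1]
            for atom in residue:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0, a.get_altloc()),
                    )
                element = (atom.element or "").strip().capitalize() or atom.get_name()[0]
                atoms.append(
                    AtomRecord(
                        element=element,
                        coords=np.array(atom.get_coord(), dtype=float),
                        name=atom.get_name().strip(),
                        resname=resname,
                        resnum=resnum,
                        chain=chain.id.strip() or "A",
                    )
                )
    if not atoms:
        raise ValueError(f"no protein atoms found in {path}")
    return Receptor(atoms)


def _acceptor_indices(rec: Receptor) -> list[int]:
    out = []
    for key, res in rec.residues.items():
        names = ("O", "OXT") + SIDECHAIN_ACCEPTORS.get(res.name, ())
        for i in res.atom_indices:
            if rec.atoms[i].name in names:
                out.append(i)
    return out


def _donor_indices(rec: Receptor) -> list[int]:
    out = []
    for key, res in rec.residues.items():
        names = SIDECHAIN_DONORS.get(res.name, ())
        if res.name != "PRO":
            names = ("N",) + names
        for i in res.atom_indices:
            if rec.atoms[i].name in names:
                out.append(i)
    return out


def _min_dist_to(rec: Receptor, own: list[int], partner: list[int]) -> float:
    partner = [p for p in partner if p not in own]
    if not own or not partner:
        return np.inf
    a = np.array([rec.atoms[i].coords for i in own])
    b = np.array([rec.atoms[i].coords for i in partner])
    return float(cdist(a, b).min())


def assign_protonation_states(rec: Receptor, dmax: float = 3.5) -> Receptor:
    """Set titratable-residue states from hydrogen-bonding neighborhoods.

    Asp/Glu: neutral iff a carboxylate oxygen lies within ``dmax`` of an
    acceptor atom.  Lys: +1 unless the amine nitrogen lies within
    ``dmax`` of a donor atom.  His: the same neighborhood criterion sets
    protonation and tautomer — a donor near exactly one imidazole
    nitrogen forces that nitrogen into the acceptor role (H on the
    other); acceptors near both nitrogens mark the ring protonated; the
    ambiguous default is the neutral N-epsilon-H tautomer.  Arg is
    always charged.  The pass is idempotent (a pure function of heavy-
    atom geometry).
    """
    acceptors = _acceptor_indices(rec)
    donors = _donor_indices(rec)
    own_res = lambda res: list(res.atom_indices)

    for key, res in rec.residues.items():
        if res.name in ("ASP", "GLU"):
            ox = ("OD1", "OD2") if res.name == "ASP" else ("OE1", "OE2")
            own = [i for i in res.atom_indices if rec.atoms[i].name in ox]
            d = _min_dist_to(rec, own, [a for a in acceptors
                                        if a not in res.atom_indices])
            state = "neutral" if d <= dmax else "charged"
        elif res.name == "LYS":
            own = [i for i in res.atom_indices if rec.atoms[i].name == "NZ"]
            d = _min_dist_to(rec, own, [a for a in donors
                                        if a not in res.atom_indices])
            state = "neutral" if d <= dmax else "charged"
        elif res.name == "HIS":
            nd1 = [i for i in res.atom_indices if rec.atoms[i].name == "ND1"]
            ne2 = [i for i in res.atom_indices if rec.atoms[i].name == "NE2"]
            other_don = [a for a in donors if a not in res.atom_indices]
            other_acc = [a for a in acceptors if a not in res.atom_indices]
            don_nd1 = _min_dist_to(rec, nd1, other_don) <= dmax
            don_ne2 = _min_dist_to(rec, ne2, other_don) <= dmax
            acc_nd1 = _min_dist_to(rec, nd1, other_acc) <= dmax
            acc_ne2 = _min_dist_to(rec, ne2, other_acc) <= dmax
            if don_nd1 and not don_ne2:
                state = "neutral-NE2H"
            elif don_ne2 and not don_nd1:
                state = "neutral-ND1H"
            elif acc_nd1 and acc_ne2 and not (don_nd1 or don_ne2):
                state = "charged"
            else:
                state = "neutral-NE2H"  # ambiguous default
        else:
            continue
        rec.protonation_states[key] = state
        log.debug("protonation %s %s%d -> %s", res.name, key[0], key[1], state)
    rec.invalidate()
    return rec


def _orthonormal_perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def _hydrogen_directions(units: list[np.ndarray], n: int) -> list[np.ndarray]:
    """Ideal-geometry unit vectors for ``n`` new hydrogens given the
    unit vectors toward existing bonded neighbors."""
    k = len(units)
    if k == 0:
        raise ValueError("cannot place hydrogens on an unbonded atom")
    if n == 1 and k >= 2:
        d = -np.sum(units, axis=0)
        nrm = np.linalg.norm(d)
        if nrm < 1e-6:
            d = _orthonormal_perp(units[0])
            nrm = 1.0
        return [d / nrm]
    if k == 1:
        u = units[0]
        p = _orthonormal_perp(u)
        q = np.cross(u, p)
        if n == 1:  # 109.5 deg off the single neighbor
            ang = np.deg2rad(180.0 - 109.47)
            return [-u * np.cos(ang) + p * np.sin(ang)]
        if n == 2:  # trigonal in the (u, p) plane
            ang = np.deg2rad(60.0)
            return [
                -u * np.cos(ang) + p * np.sin(ang),
                -u * np.cos(ang) - p * np.sin(ang),
            ]
        if n == 3:  # tetrahedral cone about -u
            ang = np.deg2rad(180.0 - 109.47)
            out = []
            for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
                out.append(
                    -u * np.cos(ang)
                    + (p * np.cos(phi) + q * np.sin(phi)) * np.sin(ang)
                )
            return out
    if k == 2 and n == 2:  # tetrahedral pair perpendicular to the bisector plane
        u1, u2 = units
        d = -(u1 + u2)
        d /= np.linalg.norm(d)
        wv = np.cross(u1, u2)
        wv /= np.linalg.norm(wv)
        half = np.deg2rad(109.47 / 2)
        return [d * np.cos(half) + wv * np.sin(half),
                d * np.cos(half) - wv * np.sin(half)]
    raise ValueError(f"unsupported hydrogen geometry (k={k}, n={n})")


def _residue_h_template(res: Residue, state: str | None) -> dict[str, tuple[int, bool]]:
    t = dict(_H_TEMPLATE.get(res.name, {}))
    if res.name == "ASP" and state == "neutral":
        t["OD2"] = (1, True)
    if res.name == "GLU" and state == "neutral":
        t["OE2"] = (1, True)
    if res.name == "LYS":
        t["NZ"] = (3, True) if state != "neutral" else (2, True)
    if res.name == "HIS":
        if state == "charged":
            t["ND1"] = (1, True)
            t["NE2"] = (1, True)
        elif state == "neutral-ND1H":
            t["ND1"] = (1, True)
        else:  # neutral-NE2H (default)
            t["NE2"] = (1, True)
    return t


def add_hydrogens(rec: Receptor) -> Receptor:
    """Place hydrogens at ideal internal coordinates for assigned states.

    Residues with missing template atoms are skipped with a warning.
    Returns a new Receptor (heavy atoms first ordering is not kept;
    hydrogens follow their residue's heavy atoms).
    """
    new_atoms: list[AtomRecord] = []
    coords = rec.coords
    # intra-residue heavy-atom bonds by distance
    for key in sorted(rec.residues):
        res = rec.residues[key]
        state = rec.protonation_states.get(key)
        template = _residue_h_template(res, state)
        idx = res.atom_indices
        name_to_i = {rec.atoms[i].name: i for i in idx}
        if res.name in STANDARD_RESIDUES and any(
            nm not in name_to_i for nm in template
        ):
            log.warning(
                "residue %s %s%d incomplete; hydrogens skipped",
                res.name, key[0], key[1],
            )
            for i in idx:
                new_atoms.append(rec.atoms[i])
            continue
        # neighbor lookup: heavy atoms within covalent range, incl. peptide C-N
        for i in idx:
            a = rec.atoms[i]
            new_atoms.append(a)
            n_h, polar = template.get(a.name, (0, False))
            if n_h == 0:
                continue
            maxlen = 1.95 if a.element == "S" else 1.75
            d = np.linalg.norm(coords - a.coords, axis=1)
            nbr = [j for j in np.nonzero((d > 0.1) & (d <= maxlen))[0]
                   if rec.atoms[j].element != "H"]
            units = []
            for j in nbr:
                v = rec.atoms[j].coords - a.coords
                units.append(v / np.linalg.norm(v))
            try:
                dirs = _hydrogen_directions(units, n_h)
            except ValueError:
                log.warning("cannot place H on %s of %s %s%d",
                            a.name, res.name, key[0], key[1])
                continue
            blen = _BOND_LENGTH.get(a.element, 1.0)
            for m, u in enumerate(dirs, 1):
                new_atoms.append(
                    AtomRecord(
                        element="H",
                        coords=a.coords + blen * u,
                        name=f"H{a.name}{m}" if n_h > 1 else f"H{a.name}",
                        resname=a.resname,
                        resnum=a.resnum,
                        chain=a.chain,
                        type_code="H.p" if polar else "H",
                        roles=frozenset({ROLE_POLAR_H}) if polar else frozenset(),
                    )
                )
    out = Receptor(new_atoms)
    out.protonation_states = dict(rec.protonation_states)
    if rec.hinge_residue is not None:
        designate_hinge_residue(out, *rec.hinge_residue)
    return out


def assign_receptor_types(rec: Receptor, params: ParameterSet) -> Receptor:
    """Resolve type codes, roles and solvation for every receptor atom."""
    for i, a in enumerate(rec.atoms):
        if not a.type_code:
            a.type_code = _protein_type_code(a.resname, a.name, a.element)
        tp = params.type_params(a.type_code)
        roles = set(a.roles)
        if tp.is_polar_h:
            roles.add(ROLE_POLAR_H)
        if tp.is_acceptor:
            roles.add(ROLE_ACCEPTOR)
        if tp.is_donor:
            roles.add(ROLE_DONOR)
        a.roles = frozenset(roles)
        a.solvation = (tp.s, tp.v, tp.occ_max)
    rec.invalidate()
    return rec


def designate_hinge_residue(rec: Receptor, chain: str, resnum: int) -> Receptor:
    """Mark the hinge anchor residue and cache its backbone amide handles."""
    key = (chain, resnum)
    if key not in rec.residues:
        nums = sorted(r for c, r in rec.residues if c == chain)
        raise ValueError(
            f"residue {chain}:{resnum} not found (available: "
            f"{nums[0]}..{nums[-1]})" if nums else f"chain {chain!r} not found"
        )
    res = rec.residues[key]
    n_idx = res.atom_index(rec, "N")
    o_idx = res.atom_index(rec, "O")
    if n_idx is None:
        raise ValueError(f"hinge residue {chain}:{resnum} lacks backbone N")
    if o_idx is None:
        raise ValueError(f"hinge residue {chain}:{resnum} lacks backbone O")
    rec.hinge_residue = key
    rec._hinge_atoms = {"N": n_idx, "O": o_idx}
    hn = res.atom_index(rec, "HN")
    if hn is not None:
        rec._hinge_atoms["HN"] = hn
    return rec


def write_receptor(rec: Receptor, path: str | Path) -> None:
    """Write the (possibly protonated) model as PDB with decision REMARKs."""
    lines = []
    for key in sorted(rec.protonation_states):
        res = rec.residues.get(key)
        nm = res.name if res else "?"
        lines.append(
            f"REMARK 999 PROTONATION {nm} {key[0]}:{key[1]} "
            f"{rec.protonation_states[key]}"
        )
    if rec.hinge_residue is not None:
        lines.append(
            f"REMARK 999 HINGE {rec.hinge_residue[0]}:{rec.hinge_residue[1]}"
        )
    for i, a in enumerate(rec.atoms, 1):
        name = a.name if len(a.name) >= 4 else f" {a.name}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{a.resname:>4s} {a.chain:1s}"
            f"{a.resnum:4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}"
            f"{a.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
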