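"""The modified protein-ligand binding free energy function.

The score is a sum of five weighted terms over receptor-ligand atom
pairs:

    dG_b = W_vdw  * sum_ij (A_ij/r^12 - B_ij/r^6)
         + W_hb   * sum_ij E(t) (C_ij/r^12 - D_ij/r^10)
         + W_elec * sum_ij q_i q_j / (eps(r_ij) r_ij)
         + W_tor  * N_tor
         + W_sol  * sum_i S_i (Occ_max_i - sum_{j!=i} V_j exp(-r_ij^2/(2 sigma^2)))

with eps(r) the sigmoidal distance-dependent dielectric and the
dehydration sum running over every ligand atom i with receptor atoms
and the ligand's own other atoms as neighbors j.  The occupancy deficit
is clamped at zero: full burial removes the dehydration penalty but
cannot flip its sign.

Conventions shared with the independent brute-force oracle:

* a receptor-ligand pair is hydrogen-bond eligible when one atom is a
  donor heavy atom and the other an acceptor; eligible pairs take the
  12-10 well and are excluded from the van der Waals sum;
* the directionality weight E(t) uses the donor-H...acceptor angle of
  the donor's best-aligned polar hydrogen, and falls back to E = 1 when
  the donor carries no explicit hydrogen;
* every pair sum applies the nonbonded cutoff (params.cutoff, 12 A);
* intra-ligand van der Waals/electrostatics are evaluated for atom
  pairs at least four bonds apart whose path crosses a rotatable bond
  (pairs inside one rigid fragment contribute a pose-independent
  constant and are skipped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import Pose, realize_pose
from .mol_model import Molecule
from .params import (
    COULOMB_CONSTANT,
    HARD_CLASH_DISTANCE,
    AngularParams,
    DielectricParams,
    ParameterSet,
)

__all__ = [
    "EnergyBreakdown",
    "vdw_term",
    "hbond_term",
    "angular_weight",
    "elec_term",
    "torsion_penalty",
    "desolvation_term",
    "binding_free_energy",
    "intra_ligand_energy",
    "ligand_arrays",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Five-term decomposition (weight-multiplied, kcal/mol) plus total."""

    vdw: float
    hbond: float
    elec: float
    torsion: float
    desolvation: float
    total: float
    clash: bool = False

    @classmethod
    def from_terms(
        cls, vdw: float, hbond: float, elec: float,
        torsion: float, desolvation: float, clash: bool = False,
    ) -> "EnergyBreakdown":
        return cls(
            vdw=vdw, hbond=hbond, elec=elec, torsion=torsion,
            desolvation=desolvation,
            total=vdw + hbond + elec + torsion + desolvation,
            clash=clash,
        )

    @classmethod
    def zero(cls) -> "EnergyBreakdown":
        return cls.from_terms(0.0, 0.0, 0.0, 0.0, 0.0)

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown.from_terms(
            self.vdw + other.vdw,
            self.hbond + other.hbond,
            self.elec + other.elec,
            self.torsion + other.torsion,
            self.desolvation + other.desolvation,
            clash=self.clash or other.clash,
        )


# ----------------------------------------------------------------------
# single-pair terms


def vdw_term(r: float, pair: tuple[float, float]) -> float:
    """12-6 van der Waals pair energy: A/r^12 - B/r^6 (unweighted)."""
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    a, b = pair
    return a / r ** 12 - b / r ** 6


def angular_weight(t_deg: float, angular: AngularParams) -> float:
    """Directionality factor E(t); 1 at the ideal angle, 0 at 90 deg off."""
    dev = math.radians(t_deg - angular.ideal_deg)
    c = math.cos(dev)
    return max(0.0, c) ** angular.exponent


def hbond_term(
    r: float, t_deg: float, pair: tuple[float, float], angular: AngularParams
) -> float:
    """Directional 12-10 hydrogen-bond pair energy: E(t)(C/r^12 - D/r^10)."""
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    if not 0.0 <= t_deg <= 180.0:
        raise ValueError("angle must lie in [0, 180] degrees")
    c, d = pair
    return angular_weight(t_deg, angular) * (c / r ** 12 - d / r ** 10)


def elec_term(
    r: float, q_i: float, q_j: float, dielectric: DielectricParams
) -> float:
    """Screened Coulomb pair energy with the sigmoidal dielectric."""
    if r <= 0:
        raise ValueError("pair distance must be > 0")
    return COULOMB_CONSTANT * q_i * q_j / (float(dielectric.epsilon(r)) * r)


def torsion_penalty(n_tor: int, w_tor: float) -> float:
    """Conformational entropy penalty W_tor * N_tor (pose independent)."""
    if n_tor < 0:
        raise ValueError("n_tor must be >= 0")
    return w_tor * n_tor


def desolvation_term(
    ligand_atoms,
    neighbor_atoms,
    sigma: float,
    w_sol: float,
) -> float:
    """Dehydration energy of a set of ligand atoms.

    ``ligand_atoms``/``neighbor_atoms`` are sequences of AtomRecord with
    ``solvation`` resolved; the neighbor list should contain receptor
    atoms plus the ligand's own other atoms.  Atoms present in both
    sequences are excluded from their own occupancy (j != i).
    """
    total = 0.0
    for ai in ligand_atoms:
        if ai.solvation is None:
            raise ValueError(f"atom {ai.name or ai.element} lacks solvation parameters")
        s_i, _, occ_max = ai.solvation
        occ = 0.0
        for aj in neighbor_atoms:
            if aj is ai:
                continue
            if aj.solvation is None:
                raise ValueError(
                    f"atom {aj.name or aj.element} lacks solvation parameters"
                )
            r2 = float(np.sum((ai.coords - aj.coords) ** 2))
            occ += aj.solvation[1] * math.exp(-r2 / (2.0 * sigma ** 2))
        total += s_i * max(0.0, occ_max - occ)
    return w_sol * total


# ----------------------------------------------------------------------
# whole-complex evaluation


def ligand_arrays(mol: Molecule, params: ParameterSet) -> dict:
    """Cache per-atom numeric arrays used by the vectorized evaluators."""
    cache = getattr(mol, "_score_cache", None)
    if cache is not None and cache.get("params") is params:
        return cache
    ti = params.type_indices([a.type_code for a in mol.atoms])
    cache = {
        "params": params,
        "types": ti,
        "q": np.array([a.partial_charge for a in mol.atoms]),
        "donor": np.array([a.is_donor for a in mol.atoms]),
        "acceptor": np.array([a.is_acceptor for a in mol.atoms]),
        "s": params.s_array[ti],
        "v": params.v_array[ti],
        "occmax": params.occmax_array[ti],
        "donor_h": {
            i: mol.attached_polar_hydrogens(i)
            for i in range(len(mol.atoms))
            if mol.atoms[i].is_donor
        },
        "intra_pairs": _intra_pairs(mol),
    }
    mol._score_cache = cache
    return cache


def _intra_pairs(mol: Molecule) -> np.ndarray:
    """(n, 2) index pairs >= 4 bonds apart and in different rigid fragments."""
    import networkx as nx

    n = len(mol.atoms)
    if n < 2 or mol.torsion_tree is None or not mol.torsion_tree.branches:
        return np.zeros((0, 2), dtype=int)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from([(a, b) for a, b, _ in mol.bonds])
    # rigid fragment id: root is one fragment, each branch another
    frag = np.zeros(n, dtype=int)
    for k, br in enumerate(mol.torsion_tree.branches, start=1):
        for i in br.atoms:
            frag[i] = k
    # a branch's atoms include nested sub-branches; later branches overwrite,
    # which is exactly the innermost-fragment assignment given BFS order
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=None))
    pairs = []
    for i in range(n):
        di = dist.get(i, {})
        for j in range(i + 1, n):
            if frag[i] == frag[j]:
                continue
            if di.get(j, 10 ** 9) >= 4:
                pairs.append((i, j))
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _hbond_energy_for_pair(
    coords_d: np.ndarray,
    coords_a: np.ndarray,
    h_coords: list[np.ndarray],
    r: float,
    params: ParameterSet,
) -> float:
    """12-10 well with E(t) from the donor's best-aligned hydrogen."""
    well = params.hbond
    radial = well.c / r ** 12 - well.d / r ** 10
    if not h_coords:
        return radial
    best = 0.0
    for h in h_coords:
        v1 = coords_d - h
        v2 = coords_a - h
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cos_t = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
        t = math.degrees(math.acos(cos_t))
        best = max(best, angular_weight(t, params.angular))
    return best * radial


def intra_ligand_energy(
    mol: Molecule, coords: np.ndarray, params: ParameterSet
) -> tuple[float, float]:
    """Unweighted intra-ligand (vdw, elec) over the eligible pair list."""
    cache = ligand_arrays(mol, params)
    pairs = cache["intra_pairs"]
    if len(pairs) == 0:
        return 0.0, 0.0
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    within = (d <= params.cutoff) & (d > 0)
    if not within.any():
        return 0.0, 0.0
    i, j, d = i[within], j[within], d[within]
    ti, tj = cache["types"][i], cache["types"][j]
    a = params.A_matrix[ti, tj]
    b = params.B_matrix[ti, tj]
    vdw = float(np.sum(a / d ** 12 - b / d ** 6))
    qq = cache["q"][i] * cache["q"][j]
    elec = float(np.sum(COULOMB_CONSTANT * qq / (params.epsilon(d) * d)))
    return vdw, elec


def binding_free_energy(
    rec,
    mol: Molecule,
    pose: Pose | None,
    params: ParameterSet,
) -> EnergyBreakdown:
    """Evaluate the five-term score for one ligand placement.

    ``rec`` is a Receptor (typed, charged, with solvation resolved);
    ``pose=None`` scores the molecule at its stored coordinates.  A
    steric overlap below the hard-clash distance still returns an
    energy, flagged via ``clash``.
    """
    lig_xyz = realize_pose(mol, pose)
    rec_xyz = rec.coords
    w = params.weights
    n_tor = mol.n_tor

    if len(mol.atoms) == 0:
        return EnergyBreakdown.zero()

    lig = ligand_arrays(mol, params)
    rar = rec.score_arrays(params)

    d = cdist(rec_xyz, lig_xyz)
    within = d <= params.cutoff
    clash = bool((d < HARD_CLASH_DISTANCE).any())

    elig = (
        (rar["donor"][:, None] & lig["acceptor"][None, :])
        | (rar["acceptor"][:, None] & lig["donor"][None, :])
    )
    pair_hb = within & elig
    pair_vdw = within & ~elig

    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(d > 0, 1.0 / np.maximum(d, 1e-12), 0.0)
    r6 = inv ** 6
    r12 = r6 * r6

    amat = params.A_matrix[rar["types"][:, None], lig["types"][None, :]]
    bmat = params.B_matrix[rar["types"][:, None], lig["types"][None, :]]
    vdw_sum = float(np.sum((amat * r12 - bmat * r6)[pair_vdw]))

    hb_sum = 0.0
    for ri, lj in np.argwhere(pair_hb):
        r = d[ri, lj]
        e_best = None
        # donor on receptor side
        if rar["donor"][ri] and lig["acceptor"][lj]:
            hs = [rec_xyz[h] for h in rar["donor_h"].get(int(ri), [])]
            e_best = _hbond_energy_for_pair(
                rec_xyz[ri], lig_xyz[lj], hs, r, params
            )
        # donor on ligand side; keep the better-aligned orientation
        if rar["acceptor"][ri] and lig["donor"][lj]:
            hs = [lig_xyz[h] for h in lig["donor_h"].get(int(lj), [])]
            e2 = _hbond_energy_for_pair(lig_xyz[lj], rec_xyz[ri], hs, r, params)
            e_best = e2 if e_best is None else min(e_best, e2)  # deeper well
        hb_sum += e_best if e_best is not None else 0.0

    qq = np.outer(rar["q"], lig["q"])
    elec_sum = float(
        np.sum((COULOMB_CONSTANT * qq * inv / params.epsilon(d))[within])
    )

    # dehydration: occupancy of each ligand atom from receptor + self
    g = np.exp(-(d ** 2) / (2.0 * params.sigma ** 2))
    occ = (rar["v"][:, None] * g * within).sum(axis=0)
    dl = cdist(lig_xyz, lig_xyz)
    gl = np.exp(-(dl ** 2) / (2.0 * params.sigma ** 2))
    np.fill_diagonal(gl, 0.0)
    gl[dl > params.cutoff] = 0.0
    occ += gl @ lig["v"]
    desolv_sum = float(np.sum(lig["s"] * np.clip(lig["occmax"] - occ, 0.0, None)))

    intra_vdw, intra_elec = intra_ligand_energy(mol, lig_xyz, params)

    return EnergyBreakdown.from_terms(
        vdw=w.vdw * (vdw_sum + intra_vdw),
        hbond=w.hbond * hb_sum,
        elec=w.elec * (elec_sum + intra_elec),
        torsion=torsion_penalty(n_tor, w.tor),
        desolvation=w.sol * desolv_sum,
        clash=clash,
    )
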