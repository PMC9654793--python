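"""Grid-map precomputation and stochastic pose search.

Affinity grids store, at every node of a rectilinear box, the summed
receptor interaction a probe atom of each ligand type would feel (12-6
van der Waals toward non-complementary receptor atoms, isotropic 12-10
toward hydrogen-bond partners), the electrostatic potential per unit
charge under the sigmoidal dielectric, and the Gaussian-weighted
receptor volume occupancy used by the dehydration term.  A pose is then
scored by trilinear interpolation per ligand atom plus the exact
torsion penalty and intra-ligand terms.

The search is a seed-deterministic genetic algorithm over translation,
orientation (quaternion) and torsion offsets, with a Nelder-Mead local
refinement of each run's best individual.  Runs are independent: run k
draws from ``default_rng([seed, k])``, so results do not depend on
execution order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .geometry import (
    Pose,
    normalize_quaternion,
    quaternion_multiply,
    random_unit_quaternion,
    realize_pose,
    rotvec_to_quaternion,
    wrap_angle,
)
from .mol_model import Molecule
from .params import COULOMB_CONSTANT, ParameterSet
from .scoring import (
    EnergyBreakdown,
    intra_ligand_energy,
    ligand_arrays,
    torsion_penalty,
)

log = logging.getLogger(__name__)

__all__ = [
    "Box", "GridMaps", "SearchConfig", "DockingResult",
    "build_grids", "grid_energy", "dock", "pose_rmsd", "cluster_poses",
]


@dataclass(frozen=True)
class Box:
    """Search box: origin corner, node counts per axis, spacing (A)."""

    origin: tuple[float, float, float]
    dims: tuple[int, int, int]
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 2 for d in self.dims):
            raise ValueError("need at least 2 nodes per axis")

    @classmethod
    def from_center_extent(
        cls, center, extent, spacing: float = 0.375
    ) -> "Box":
        center = np.asarray(center, float)
        extent = np.broadcast_to(np.asarray(extent, float), 3)
        dims = tuple(int(np.floor(e / spacing)) + 1 for e in extent)
        origin = center - (np.array(dims) - 1) * spacing / 2.0
        return cls(tuple(origin), dims, spacing)

    @classmethod
    def whole_domain(cls, rec, margin: float = 6.0, spacing: float = 0.375) -> "Box":
        """A box enclosing the entire receptor plus a margin."""
        xyz = rec.coords
        lo, hi = xyz.min(axis=0) - margin, xyz.max(axis=0) + margin
        center = (lo + hi) / 2.0
        return cls.from_center_extent(center, hi - lo, spacing)

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.array(self.dims) - 1) * self.spacing

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.origin)
        return np.all((xyz >= lo) & (xyz <= self.upper), axis=-1)

    def node_coords(self) -> np.ndarray:
        axes = [
            np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
            for k in range(3)
        ]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([x.ravel() for x in g], axis=1)


@dataclass
class GridMaps:
    """Precomputed receptor field maps over a box."""

    box: Box
    vdw_maps: dict[str, np.ndarray]     # per ligand type: 12-6 sum
    hbond_maps: dict[str, np.ndarray]   # per ligand type: isotropic 12-10 sum
    elec_map: np.ndarray                # potential per unit charge
    occ_map: np.ndarray                 # Gaussian-weighted receptor volume

    @property
    def origin(self):
        return self.box.origin

    @property
    def spacing(self):
        return self.box.spacing

    @property
    def dims(self):
        return self.box.dims


def _interpolate(grid: np.ndarray, frac_idx: np.ndarray) -> np.ndarray:
    """Vectorized trilinear interpolation at fractional grid indices."""
    dims = np.array(grid.shape)
    i0 = np.floor(frac_idx).astype(int)
    i0 = np.clip(i0, 0, dims - 2)
    f = frac_idx - i0
    out = np.zeros(len(frac_idx))
    for dx, dy, dz in itertools.product((0, 1), repeat=3):
        wgt = (
            (f[:, 0] if dx else 1 - f[:, 0])
            * (f[:, 1] if dy else 1 - f[:, 1])
            * (f[:, 2] if dz else 1 - f[:, 2])
        )
        out += wgt * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def build_grids(
    rec,
    box: Box,
    params: ParameterSet,
    ligand_types: list[str] | None = None,
    chunk: int = 32768,
) -> GridMaps:
    """Precompute affinity, electrostatic and occupancy maps.

    ``ligand_types`` restricts the per-type maps (default: every type in
    the parameter table except polar hydrogen variants, which have no
    pair well of their own).
    """
    rar = rec.score_arrays(params)
    rec_xyz = rec.coords
    if not box.contains(rec_xyz).any():
        log.warning("search box excludes every receptor atom")
    if ligand_types is None:
        ligand_types = [t for t in sorted(params.atom_types)]
    nodes = box.node_coords()
    n_nodes = len(nodes)
    shape = box.dims

    # probe variants: a donor-capable type may arrive with its donor role
    # stripped (no attached polar H), which changes pair eligibility
    probes: list[tuple[str, str]] = []
    for t in ligand_types:
        tp = params.atom_types[t]
        base = ("D" if tp.is_donor else "") + ("A" if tp.is_acceptor else "")
        probes.append((t, base))
        if "D" in base:
            probes.append((t, base.replace("D", "")))

    vdw_flat = {p: np.zeros(n_nodes) for p in probes}
    hb_flat = {p: np.zeros(n_nodes) for p in probes}
    elec_flat = np.zeros(n_nodes)
    occ_flat = np.zeros(n_nodes)

    rt = rar["types"]
    rq = rar["q"]
    rv = rar["v"]
    r_don, r_acc = rar["donor"], rar["acceptor"]
    well_c, well_d = params.hbond.c, params.hbond.d

    for start in range(0, n_nodes, chunk):
        sl = slice(start, min(start + chunk, n_nodes))
        d = cdist(nodes[sl], rec_xyz)
        within = d <= params.cutoff
        inv = np.where(d > 0, 1.0 / np.maximum(d, 1e-12), 0.0)
        r6 = inv ** 6
        r10 = r6 * inv ** 4
        r12 = r6 * r6
        elec_flat[sl] = np.sum(
            (COULOMB_CONSTANT * rq * inv / params.epsilon(d)) * within, axis=1
        )
        occ_flat[sl] = np.sum(rv * np.exp(-(d ** 2) / (2 * params.sigma ** 2))
                              * within, axis=1)
        hb_radial = well_c * r12 - well_d * r10
        for t, role in probes:
            ti = params.type_index(t)
            elig = (r_don & ("A" in role)) | (r_acc & ("D" in role))
            a = params.A_matrix[rt, ti]
            b = params.B_matrix[rt, ti]
            vdw_flat[(t, role)][sl] = np.sum(
                (a * r12 - b * r6) * (within & ~elig), axis=1
            )
            if elig.any():
                hb_flat[(t, role)][sl] = np.sum(hb_radial * (within & elig), axis=1)

    return GridMaps(
        box=box,
        vdw_maps={p: v.reshape(shape) for p, v in vdw_flat.items()},
        hbond_maps={p: v.reshape(shape) for p, v in hb_flat.items()},
        elec_map=elec_flat.reshape(shape),
        occ_map=occ_flat.reshape(shape),
    )


def grid_energy(
    grids: GridMaps,
    mol: Molecule,
    pose: Pose | None,
    params: ParameterSet,
    out_of_box: str = "reject",
) -> EnergyBreakdown:
    """Interpolated score of a pose; exact torsion and intra-ligand terms.

    Atoms outside the box reject the pose (infinite total) by default;
    ``out_of_box='raise'`` raises instead.  The hydrogen-bond term is
    the isotropic map value (grids cannot carry pose-dependent
    directionality).
    """
    xyz = realize_pose(mol, pose)
    inside = grids.box.contains(xyz)
    if not inside.all():
        if out_of_box == "raise":
            raise ValueError("ligand atom outside the grid box")
        return EnergyBreakdown(
            vdw=np.inf, hbond=0.0, elec=0.0, torsion=0.0,
            desolvation=0.0, total=np.inf,
        )
    lig = ligand_arrays(mol, params)
    frac = (xyz - np.asarray(grids.origin)) / grids.spacing

    vdw = 0.0
    hb = 0.0
    keys = [
        (
            a.type_code,
            ("D" if a.is_donor else "") + ("A" if a.is_acceptor else ""),
        )
        for a in mol.atoms
    ]
    for key in set(keys):
        sel = np.array([k == key for k in keys])
        fi = frac[sel]
        if key not in grids.vdw_maps:
            raise KeyError(
                f"grids lack a map for probe {key}; rebuild with this ligand type"
            )
        vdw += float(np.sum(_interpolate(grids.vdw_maps[key], fi)))
        hbmap = grids.hbond_maps.get(key)
        if hbmap is not None and hbmap.any():
            hb += float(np.sum(_interpolate(hbmap, fi)))
    elec = float(np.sum(lig["q"] * _interpolate(grids.elec_map, frac)))

    occ = _interpolate(grids.occ_map, frac)
    dl = cdist(xyz, xyz)
    gl = np.exp(-(dl ** 2) / (2 * params.sigma ** 2))
    np.fill_diagonal(gl, 0.0)
    gl[dl > params.cutoff] = 0.0
    occ = occ + gl @ lig["v"]
    desolv = float(np.sum(lig["s"] * np.clip(lig["occmax"] - occ, 0.0, None)))

    ivdw, ielec = intra_ligand_energy(mol, xyz, params)
    w = params.weights
    return EnergyBreakdown.from_terms(
        vdw=w.vdw * (vdw + ivdw),
        hbond=w.hbond * hb,
        elec=w.elec * (elec + ielec),
        torsion=torsion_penalty(mol.n_tor, w.tor),
        desolvation=w.sol * desolv,
    )


def _batch_totals(
    grids: GridMaps,
    mol: Molecule,
    poses: list[Pose],
    params: ParameterSet,
) -> np.ndarray:
    """Total grid energies of many poses at once (inf when out of box).

    Identical by construction to ``grid_energy(...).total`` per pose;
    the GA uses it to score whole populations in a few array passes.
    """
    n_poses = len(poses)
    n_atoms = len(mol.atoms)
    coords = np.stack([realize_pose(mol, p) for p in poses])
    inside = grids.box.contains(coords.reshape(-1, 3)).reshape(n_poses, n_atoms)
    ok = np.nonzero(inside.all(axis=1))[0]
    totals = np.full(n_poses, np.inf)
    if len(ok) == 0:
        return totals
    sub = coords[ok]
    k = len(ok)
    lig = ligand_arrays(mol, params)
    frac = (sub - np.asarray(grids.origin)) / grids.spacing
    flat = frac.reshape(-1, 3)

    keys = [
        (a.type_code, ("D" if a.is_donor else "") + ("A" if a.is_acceptor else ""))
        for a in mol.atoms
    ]
    vdw = np.zeros(k)
    hb = np.zeros(k)
    for key in set(keys):
        sel = np.array([m == key for m in keys])
        idx = (np.arange(k)[:, None] * n_atoms + np.nonzero(sel)[0]).ravel()
        vals = _interpolate(grids.vdw_maps[key], flat[idx]).reshape(k, -1)
        vdw += vals.sum(axis=1)
        hbmap = grids.hbond_maps.get(key)
        if hbmap is not None and hbmap.any():
            hb += _interpolate(hbmap, flat[idx]).reshape(k, -1).sum(axis=1)
    elec = (_interpolate(grids.elec_map, flat).reshape(k, n_atoms)
            * lig["q"]).sum(axis=1)

    occ = _interpolate(grids.occ_map, flat).reshape(k, n_atoms)
    diff = sub[:, :, None, :] - sub[:, None, :, :]
    d2 = np.sum(diff ** 2, axis=-1)
    gl = np.exp(-d2 / (2 * params.sigma ** 2))
    eye = np.eye(n_atoms, dtype=bool)
    gl[:, eye] = 0.0
    gl[d2 > params.cutoff ** 2] = 0.0
    occ = occ + gl @ lig["v"]
    desolv = np.sum(lig["s"] * np.clip(lig["occmax"] - occ, 0.0, None), axis=1)

    ivdw = np.zeros(k)
    ielec = np.zeros(k)
    pairs = lig["intra_pairs"]
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(sub[:, pi] - sub[:, pj], axis=2)
        within = (d <= params.cutoff) & (d > 0)
        d = np.maximum(d, 1e-12)
        a = params.A_matrix[lig["types"][pi], lig["types"][pj]]
        b = params.B_matrix[lig["types"][pi], lig["types"][pj]]
        ivdw = np.sum((a / d ** 12 - b / d ** 6) * within, axis=1)
        qq = lig["q"][pi] * lig["q"][pj]
        ielec = np.sum(
            (COULOMB_CONSTANT * qq / (params.epsilon(d) * d)) * within, axis=1
        )

    w = params.weights
    totals[ok] = (
        w.vdw * (vdw + ivdw)
        + w.hbond * hb
        + w.elec * (elec + ielec)
        + torsion_penalty(mol.n_tor, w.tor)
        + w.sol * desolv
    )
    return totals


# ----------------------------------------------------------------------
# stochastic search


@dataclass(frozen=True)
class SearchConfig:
    """Genetic-algorithm knobs with desk-scale defaults."""

    population: int = 50
    generations: int = 100
    elite: int = 2
    tournament: int = 3
    mutation_rate: float = 0.3
    reset_rate: float = 0.1           # heavy-tail restarts of a gene
    sigma_translation: float = 0.75   # A
    sigma_rotation: float = 0.4       # rad
    sigma_torsion: float = 30.0       # deg
    refine_top: int = 4
    refine_maxiter: int = 120
    margin: float = 1.0               # keep sampled centers off the box faces
    center_bias: float = 0.5          # fraction of initial poses seeded near
                                      # the box center (boxes are centered on
                                      # the site of interest)


@dataclass
class DockingResult:
    poses: list[Pose]                 # one final pose per run
    best: Pose
    clusters: list[list[int]]         # index groups into ``poses``
    history: list[np.ndarray] = field(default_factory=list)

    @property
    def representatives(self) -> list[Pose]:
        return [self.poses[c[0]] for c in self.clusters]


def _sample_pose(
    rng: np.random.Generator, box: Box, n_tor: int, center_bias: float = 0.0
) -> Pose:
    lo = np.asarray(box.origin) + 1.0
    hi = box.upper - 1.0
    if rng.random() < center_bias:
        center = (lo + hi) / 2.0
        t = np.clip(rng.normal(center, (hi - lo) / 6.0), lo, hi)
    else:
        t = rng.uniform(lo, hi)
    return Pose(
        translation=t,
        orientation=random_unit_quaternion(rng),
        torsions=rng.uniform(-180.0, 180.0, size=n_tor),
    )


def _mutate(pose: Pose, rng: np.random.Generator, cfg: SearchConfig) -> Pose:
    p = pose.copy()
    if rng.random() < cfg.mutation_rate:
        p.translation = p.translation + rng.normal(0, cfg.sigma_translation, 3)
    if rng.random() < cfg.mutation_rate:
        # heavy-tailed: occasionally resample the orientation outright so
        # narrow orientational funnels stay reachable late in a run
        if rng.random() < cfg.reset_rate:
            p.orientation = random_unit_quaternion(rng)
        else:
            dq = rotvec_to_quaternion(rng.normal(0, cfg.sigma_rotation, 3))
            p.orientation = normalize_quaternion(
                quaternion_multiply(dq, p.orientation)
            )
    if len(p.torsions) and rng.random() < cfg.mutation_rate:
        k = rng.integers(len(p.torsions))
        if rng.random() < cfg.reset_rate:
            p.torsions[k] = rng.uniform(-180.0, 180.0)
        else:
            p.torsions = wrap_angle(
                p.torsions
                + np.eye(len(p.torsions))[k] * rng.normal(0, cfg.sigma_torsion)
            )
    return p


def _crossover(a: Pose, b: Pose, rng: np.random.Generator) -> Pose:
    t = a.translation if rng.random() < 0.5 else b.translation
    q = a.orientation if rng.random() < 0.5 else b.orientation
    tor = np.where(
        rng.random(len(a.torsions)) < 0.5, a.torsions, b.torsions
    ) if len(a.torsions) else a.torsions
    return Pose(t.copy(), q.copy(), np.array(tor, float))


def _pose_vector(pose: Pose) -> np.ndarray:
    return np.concatenate([np.zeros(6), np.zeros(len(pose.torsions))])


def _apply_vector(base: Pose, x: np.ndarray) -> Pose:
    dq = rotvec_to_quaternion(x[3:6])
    tor = base.torsions + x[6:] if len(base.torsions) else base.torsions
    return Pose(
        base.translation + x[:3],
        normalize_quaternion(quaternion_multiply(dq, base.orientation)),
        wrap_angle(np.asarray(tor, float)),
    )


def _refine(
    pose: Pose, mol, grids, params, cfg: SearchConfig
) -> tuple[Pose, float]:
    def objective(x):
        e = grid_energy(grids, mol, _apply_vector(pose, x), params)
        return e.total if np.isfinite(e.total) else 1e6

    x0 = _pose_vector(pose)
    res = minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxiter": cfg.refine_maxiter, "xatol": 1e-3, "fatol": 1e-5},
    )
    best_x = res.x if res.fun <= objective(x0) else x0
    refined = _apply_vector(pose, best_x)
    e = grid_energy(grids, mol, refined, params)
    refined.score = e
    return refined, e.total


def _run_search(
    mol, grids, params, cfg: SearchConfig, rng: np.random.Generator
) -> tuple[Pose, np.ndarray]:
    n_tor = mol.n_tor
    pop = [_sample_pose(rng, grids.box, n_tor, cfg.center_bias)
           for _ in range(cfg.population)]
    fit = _batch_totals(grids, mol, pop, params)
    trace = []
    for _ in range(cfg.generations):
        order = np.argsort(fit)
        trace.append(fit[order[0]])
        new_pop = [pop[i].copy() for i in order[: cfg.elite]]
        while len(new_pop) < cfg.population:
            # tournament selection of two parents
            idx = rng.integers(len(pop), size=(2, cfg.tournament))
            pa = pop[idx[0][np.argmin(fit[idx[0]])]]
            pb = pop[idx[1][np.argmin(fit[idx[1]])]]
            child = _mutate(_crossover(pa, pb, rng), rng, cfg)
            new_pop.append(child)
        pop = new_pop
        fit = _batch_totals(grids, mol, pop, params)
    order = np.argsort(fit)
    trace.append(fit[order[0]])

    # refine basin-diverse finalists: energy-sorted, but each candidate
    # must sit a translation step away from the ones already chosen, so
    # the local optimizer visits distinct basins rather than polishing
    # one basin three times
    selected: list[int] = []
    for i in order:
        if not np.isfinite(fit[i]):
            continue
        if all(
            np.linalg.norm(pop[i].translation - pop[j].translation) >= 1.5
            for j in selected
        ):
            selected.append(i)
        if len(selected) == cfg.refine_top:
            break
    best_pose, best_e = None, np.inf
    for i in selected:
        refined, e = _refine(pop[i], mol, grids, params, cfg)
        if e < best_e:
            best_pose, best_e = refined, e
    if best_pose is None:
        raise RuntimeError("search never produced a pose inside the box")
    return best_pose, np.minimum.accumulate(np.array(trace))


def dock(
    mol: Molecule,
    grids: GridMaps,
    rec,
    params: ParameterSet,
    n_runs: int = 10,
    seed: int = 0,
    search_cfg: SearchConfig | None = None,
    rmsd_cutoff: float = 2.0,
) -> DockingResult:
    """Run ``n_runs`` independent searches and cluster the outcomes."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = search_cfg or SearchConfig()
    poses: list[Pose] = []
    history: list[np.ndarray] = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        pose, trace = _run_search(mol, grids, params, cfg, rng)
        poses.append(pose)
        history.append(trace)
    best = poses[min(range(len(poses)), key=lambda i: (poses[i].score.total, i))]
    clusters = cluster_poses(mol, poses, cutoff=rmsd_cutoff)
    return DockingResult(poses=poses, best=best, clusters=clusters,
                         history=history)


# ----------------------------------------------------------------------
# RMSD and clustering


def _heavy_automorphisms(mol: Molecule, cap: int = 2000) -> list[dict[int, int]]:
    import networkx as nx
    from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match

    heavy = mol.heavy_indices
    hset = set(heavy)
    g = nx.Graph()
    for i in heavy:
        g.add_node(i, element=mol.atoms[i].element)
    for a, b, _ in mol.bonds:
        if a in hset and b in hset:
            g.add_edge(a, b)
    gm = GraphMatcher(g, g, node_match=categorical_node_match("element", ""))
    out = []
    for mapping in gm.isomorphisms_iter():
        out.append(mapping)
        if len(out) >= cap:
            break
    return out or [{i: i for i in heavy}]


def pose_rmsd(mol: Molecule, pose_a: Pose | None, pose_b: Pose | None) -> float:
    """Symmetry-aware heavy-atom RMSD between two realized poses (A)."""
    xa = realize_pose(mol, pose_a)
    xb = realize_pose(mol, pose_b)
    if xa.shape != xb.shape:
        raise ValueError("pose atom-count mismatch")
    heavy = mol.heavy_indices
    best = np.inf
    for mapping in _heavy_automorphisms(mol):
        src = heavy
        dst = [mapping[i] for i in heavy]
        rmsd = float(np.sqrt(np.mean(np.sum((xa[src] - xb[dst]) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def cluster_poses(
    mol: Molecule, poses: list[Pose], cutoff: float = 2.0
) -> list[list[int]]:
    """Greedy energy-ordered clustering by pairwise RMSD."""
    order = sorted(
        range(len(poses)),
        key=lambda i: poses[i].score.total if poses[i].score else np.inf,
    )
    reps: list[int] = []
    clusters: list[list[int]] = []
    for i in order:
        for k, r in enumerate(reps):
            if pose_rmsd(mol, poses[i], poses[r]) <= cutoff:
                clusters[k].append(i)
                break
        else:
            reps.append(i)
            clusters.append([i])
    return clusters
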