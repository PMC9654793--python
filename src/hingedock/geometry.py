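"""Pose parametrization and coordinate realization.

A :class:`Pose` is a rigid-body placement (translation + unit
quaternion) plus one dihedral offset per rotatable-bond branch of the
ligand's torsion tree.  Torsion angles are offsets from the reference
conformer, applied branch-by-branch in root-outward order before the
rigid transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def normalize_quaternion(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if n == 0 or not np.isfinite(n):
        raise ValueError("cannot normalize zero/non-finite quaternion")
    return q / n


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def rotvec_to_quaternion(v: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, rad) to unit quaternion."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / angle
    return np.concatenate([[np.cos(angle / 2)], np.sin(angle / 2) * axis])


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    return normalize_quaternion(rng.normal(size=4))


def rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    p = points - origin
    # Rodrigues rotation
    return (
        origin
        + p * c
        + np.cross(axis, p) * s
        + np.outer(p @ axis, axis) * (1 - c)
    )


def wrap_angle(a):
    """Wrap angles (deg) into (-180, 180]."""
    w = -(-(np.asarray(a) - 180.0) % 360.0) + 180.0
    return w


@dataclass
class Pose:
    """Ligand placement: translation, orientation and torsion offsets."""

    translation: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )
    torsions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    score: object = None  # EnergyBreakdown once evaluated

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.orientation = normalize_quaternion(self.orientation)
        self.torsions = wrap_angle(np.atleast_1d(np.asarray(self.torsions, float)))

    def copy(self) -> "Pose":
        return Pose(
            self.translation.copy(),
            self.orientation.copy(),
            self.torsions.copy(),
            self.score,
        )


def realize_pose(mol, pose: Pose | None) -> np.ndarray:
    """Cartesian coordinates of ``mol`` under ``pose``.

    ``pose=None`` returns the molecule's own coordinates unchanged.
    Torsion offsets are applied first (root-outward, so parent rotations
    carry child axes along), then the rigid transform about the
    conformer centroid.
    """
    coords = mol.coords
    if pose is None:
        return coords
    tree = mol.torsion_tree
    n_branches = 0 if tree is None else len(tree.branches)
    if len(pose.torsions) not in (0, n_branches):
        raise ValueError(
            f"pose has {len(pose.torsions)} torsions, molecule has {n_branches}"
        )
    if tree is not None and len(pose.torsions) == n_branches:
        for branch, angle in zip(tree.branches, pose.torsions):
            if angle == 0.0:
                continue
            a, b = branch.bond
            idx = list(branch.atoms)
            coords[idx] = rotate_about_axis(
                coords[idx], coords[a], coords[b] - coords[a], angle
            )
    centroid = coords.mean(axis=0)
    R = quaternion_matrix(pose.orientation)
    return (coords - centroid) @ R.T + pose.translation
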