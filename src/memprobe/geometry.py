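"""Periodic-boundary geometry: minimum-image distances, centroids, Kabsch RMSD.

Only orthorhombic boxes are supported (box = three edge lengths); the
systems this package targets use rectangular periodic cells.  Correctness is
favoured over neighbour-list style optimisation — the membranes involved are
a few hundred particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "min_image_displacement",
    "min_image_distance",
    "min_pair_distance",
    "centroid",
    "RigidTransform",
    "kabsch_superpose",
    "rmsd_series",
]


def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape[-1] != 3 or np.any(box <= 0):
        raise ValueError("box must be three positive lengths (Lx, Ly, Lz)")
    return box


def min_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vector(s) into the minimum-image convention.

    ``delta`` may have any leading shape with a trailing axis of 3; ``box``
    broadcasts against it.
    """
    box = _check_box(box)
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(p1, p2, box) -> float:
    """Euclidean distance between two points under periodic boundaries."""
    d = min_image_displacement(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float), box)
    return float(np.linalg.norm(d))


def min_pair_distance(set_a: np.ndarray, set_b: np.ndarray, box, use_min_image: bool = True) -> float:
    """Minimum distance over all pairs between two atom coordinate sets.

    ``set_a``: (na, 3), ``set_b``: (nb, 3), both Å.  With
    ``use_min_image=False`` plain Euclidean distances are used (for
    comparison with analyses that ignored periodicity).
    """
    set_a = np.atleast_2d(np.asarray(set_a, dtype=float))
    set_b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("both atom sets must be non-empty")
    delta = set_a[:, None, :] - set_b[None, :, :]
    if use_min_image:
        delta = min_image_displacement(delta, box)
    return float(np.sqrt(np.sum(delta * delta, axis=-1)).min())


def centroid(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean of a non-empty set of 3-vectors."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("centroid of an empty point set is undefined")
    return points.mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform (reflections are corrected by flipping
    the smallest singular direction) and the RMSD in Å after applying it.
    Requires N >= 3 non-collinear points in each set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("superposition requires N >= 3 points of dimension 3")

    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    # collinear (or coincident) point sets leave the rotation underdetermined
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2 or np.linalg.matrix_rank(ref_c, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point set: rotation is underdetermined")

    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    tf = RigidTransform(rot, trans)
    diff = tf.apply(mobile) - reference
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return tf, rmsd


def rmsd_series(traj, atom_indices=None, reference_frame: int = 0) -> np.ndarray:
    """Per-frame RMSD (Å) versus a reference frame after optimal superposition.

    By default uses all atoms; pass ``atom_indices`` (e.g. the Cα set) to
    restrict the fit, matching the usual backbone-RMSD equilibration check.
    """
    if atom_indices is None:
        atom_indices = np.arange(traj.system.n_atoms)
    atom_indices = np.asarray(atom_indices, dtype=int)
    ref = traj.coordinates[reference_frame][atom_indices]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, out[i] = kabsch_superpose(traj.coordinates[i][atom_indices], ref)
    return out
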