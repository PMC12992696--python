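"""Exact geometric primitives for trajectory analysis.

Distances and angles are the raw observables behind every interaction
criterion and microswitch metric; Kabsch superposition underlies the
ligand-core RMSD used to decide whether a pose is agonist-compatible.
All lengths are in Angstrom, all angles in degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = [
    "RigidTransform",
    "distance",
    "angle",
    "dihedral",
    "kabsch",
    "rmsd_after_fit_on_subset",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t``.

    The rotation is guaranteed orthonormal with determinant +1 (no
    mirror), so chirality of ligand cores is preserved.
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("RigidTransform needs a 3x3 rotation and 3-vector")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise GeometryError("rotation determinant must be +1 (proper rotation)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise GeometryError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector)."""
        xyz = np.asarray(coords, dtype=float)
        return xyz @ self.rotation.T + self.translation


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GeometryError(f"{name} has non-finite components")
    return v


def distance(a, b) -> float:
    """Euclidean distance between two points, Angstrom."""
    return float(np.linalg.norm(_as_vec3(a, "a") - _as_vec3(b, "b")))


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    u = _as_vec3(a, "a") - _as_vec3(b, "b")
    v = _as_vec3(c, "c") - _as_vec3(b, "b")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _COLLINEAR_TOL or nv < _COLLINEAR_TOL:
        raise GeometryError("angle undefined: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle of the four points, degrees in (-180, 180].

    IUPAC sign convention: looking down the p2->p3 bond, a clockwise
    rotation of the far bond relative to the near bond is positive;
    cis = 0, trans = +180 (the -180 branch is folded onto +180).
    """
    p1, p2 = _as_vec3(p1, "p1"), _as_vec3(p2, "p2")
    p3, p4 = _as_vec3(p3, "p3"), _as_vec3(p4, "p4")
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < _COLLINEAR_TOL:
        raise GeometryError("dihedral undefined: central bond degenerate")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise GeometryError("dihedral undefined: collinear points")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / nb2)
    ang = float(np.degrees(np.arctan2(y, x)))
    # fold the branch cut so trans is exactly +180
    if ang <= -180.0 + 1e-12 or ang == -180.0:
        ang = 180.0
    return ang


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Both inputs are (N, 3) with positional correspondence, N >= 3. The
    returned transform minimises sum ||T(m_i) - r_i||^2 over proper
    rotations (reflections are excluded via the smallest-singular-value
    sign correction), and the second return value is the residual RMSD.
    """
    m = np.asarray(mobile, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.ndim != 2 or m.shape[1] != 3 or m.shape != r.shape:
        raise GeometryError("kabsch needs matching (N, 3) arrays")
    if m.shape[0] < 3:
        raise GeometryError("kabsch needs at least 3 points")
    cm = m.mean(axis=0)
    cr = r.mean(axis=0)
    p = m - cm
    q = r - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = cr - rot @ cm
    transform = RigidTransform(rot, t)
    diff = transform.apply(m) - r
    rmsd = float(np.sqrt((diff * diff).sum() / m.shape[0]))
    return transform, rmsd


def rmsd_after_fit_on_subset(
    mobile_fit: np.ndarray,
    ref_fit: np.ndarray,
    mobile_eval: np.ndarray,
    ref_eval: np.ndarray,
) -> float:
    """Fit on one atom subset, evaluate the deviation on another.

    This is the ligand-core RMSD primitive: superpose the receptor-frame
    atoms (``*_fit``), then measure the RMSD of the ligand core
    (``*_eval``) in that frame without refitting.
    """
    me = np.asarray(mobile_eval, dtype=float)
    re = np.asarray(ref_eval, dtype=float)
    if me.shape != re.shape or me.ndim != 2 or me.shape[0] < 1:
        raise GeometryError("eval subsets must be matching (K, 3), K >= 1")
    transform, _ = kabsch(mobile_fit, ref_fit)
    diff = transform.apply(me) - re
    return float(np.sqrt((diff * diff).sum() / me.shape[0]))
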