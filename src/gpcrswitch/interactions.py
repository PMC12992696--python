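"""Per-frame geometric interaction detection and occupancy statistics.

Detectors implement the conventional MD geometric criteria (the
"paper-profile" preset): hydrogen bond at donor-acceptor distance
<= 3.5 A with a D-H...A angle >= 120 deg, salt bridge at minimum N-O
distance <= 4.0 A, hydrophobic contact at heavy-atom distance <= 4.5 A,
and pi-stacking at centroid distance <= 5.5 A with parallel (<= 30 deg)
or T-shaped (60-90 deg) ring planes. Occupancy is the percentage of
trajectory frames satisfying a criterion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError, SelectionError, TopologyError
from .geometry import angle, distance
from .presets import Cutoffs, PAPER_PROFILE
from .trajectory import Frame, Trajectory, select_atoms

__all__ = [
    "InteractionSpec",
    "InteractionSeries",
    "OccupancyReport",
    "detect_hbond",
    "detect_salt_bridge",
    "detect_hydrophobic_contact",
    "detect_pi_stack",
    "interaction_series",
    "occupancy",
]

_DH_COVALENT = 1.2  # A; H must sit this close to its donor heavy atom


@dataclass(frozen=True)
class InteractionSpec:
    """A named interaction to evaluate on every frame.

    Selections are expressions for :func:`gpcrswitch.trajectory.select_atoms`.
    For ``hbond``, ``donors`` is a list of (donor-heavy, hydrogen)
    selection pairs and ``acceptors`` a list of acceptor selections; the
    interaction is present if any direction holds (covers ambiguous
    donors such as Thr/Ser hydroxyls).
    """

    kind: str  # hbond | salt_bridge | hydrophobic | pi_stack
    label: str
    donors: tuple = ()       # hbond: ((d_sel, h_sel), ...)
    acceptors: tuple = ()    # hbond: (a_sel, ...)
    group_a: str = ""        # salt_bridge basic N / hydrophobic / ring a
    group_b: str = ""        # salt_bridge acidic O / hydrophobic / ring b

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "salt_bridge", "hydrophobic", "pi_stack"):
            raise SelectionError(f"unknown interaction kind {self.kind!r}")
        if self.kind == "hbond" and (not self.donors or not self.acceptors):
            raise SelectionError(f"{self.label}: hbond needs donors and acceptors")
        if self.kind != "hbond" and (not self.group_a or not self.group_b):
            raise SelectionError(f"{self.label}: needs group_a and group_b selections")


@dataclass
class InteractionSeries:
    spec: InteractionSpec
    present: np.ndarray   # (n_frames,) bool
    geometry: np.ndarray  # (n_frames,) float, A

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.geometry = np.asarray(self.geometry, dtype=float)
        if self.present.shape != self.geometry.shape:
            raise ValueError("present/geometry length mismatch")


@dataclass(frozen=True)
class OccupancyReport:
    label: str
    occupancy_percent: float
    n_frames: int
    mean_dist: float
    min_dist: float


def detect_hbond(frame: Frame, donor: int, hydrogen: int, acceptor: int,
                 cutoffs: Cutoffs = PAPER_PROFILE) -> tuple[bool, float, float]:
    """Evaluate one D-H...A triple; returns (present, D-A dist, angle at H).

    The hydrogen must be covalently bonded to the donor (within 1.2 A),
    otherwise the triple is rejected as a topology error. The geometry
    is returned whether or not the criterion holds.
    """
    coords = frame.coords
    d, h, a = coords[donor], coords[hydrogen], coords[acceptor]
    if distance(d, h) > _DH_COVALENT:
        raise TopologyError(
            f"hydrogen (index {hydrogen}) is not covalent to donor (index {donor})")
    da = distance(d, a)
    theta = angle(d, h, a)
    present = da <= cutoffs.hbond_dist and theta >= cutoffs.hbond_angle
    return present, da, theta


def detect_salt_bridge(frame: Frame, basic_group: list[int], acidic_group: list[int],
                       cutoffs: Cutoffs = PAPER_PROFILE) -> tuple[bool, float]:
    """Minimum basic-N to acidic-O distance criterion."""
    if not basic_group or not acidic_group:
        raise SelectionError("salt bridge groups must be non-empty")
    coords = frame.coords
    dmin = float(cdist(coords[basic_group], coords[acidic_group]).min())
    return dmin <= cutoffs.salt_bridge_dist, dmin


def detect_hydrophobic_contact(frame: Frame, group_a: list[int], group_b: list[int],
                               cutoffs: Cutoffs = PAPER_PROFILE) -> tuple[bool, float]:
    """Any heavy-atom pair within the contact cutoff."""
    if not group_a or not group_b:
        raise SelectionError("contact groups must be non-empty")
    for idx in (*group_a, *group_b):
        if frame.atoms[idx].element == "H":
            raise SelectionError(f"hydrogen atom (index {idx}) in hydrophobic selection")
    coords = frame.coords
    dmin = float(cdist(coords[group_a], coords[group_b]).min())
    return dmin <= cutoffs.hydrophobic_dist, dmin


def ring_plane(coords: np.ndarray, planarity_tol: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a planar ring (SVD plane fit)."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered)
    normal = vt[2]
    residual = float(np.abs(centered @ normal).max())
    if residual > planarity_tol:
        raise GeometryError(f"ring is not planar (max residual {residual:.2f} A)")
    return centroid, normal


def detect_pi_stack(frame: Frame, ring_a: list[int], ring_b: list[int],
                    cutoffs: Cutoffs = PAPER_PROFILE) -> tuple[bool, float, float]:
    """Aromatic stacking: centroid distance plus interplanar angle windows."""
    if len(ring_a) < 5 or len(ring_b) < 5:
        raise SelectionError("rings need at least 5 atoms")
    coords = frame.coords
    ca, na = ring_plane(coords[ring_a])
    cb, nb = ring_plane(coords[ring_b])
    dist = float(np.linalg.norm(ca - cb))
    cosang = abs(float(np.dot(na, nb)))
    plane_angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    parallel = plane_angle <= cutoffs.pi_parallel_angle
    t_shaped = cutoffs.pi_tshape_lo <= plane_angle <= 90.0
    present = dist <= cutoffs.pi_dist and (parallel or t_shaped)
    return present, dist, plane_angle


def _resolve_indices(traj: Trajectory, sel: str) -> list[int]:
    idx = select_atoms(traj, sel)
    if not idx:
        raise SelectionError(f"selection {sel!r} matches no atoms")
    return idx


def _eval_hbond_spec(traj: Trajectory, frame: Frame, spec: InteractionSpec,
                     cutoffs: Cutoffs) -> tuple[bool, float]:
    """Best (minimum-distance) geometry over all donor/acceptor combos."""
    present = False
    best = np.inf
    for d_sel, h_sel in spec.donors:
        d_idx = _resolve_indices(traj, d_sel)
        h_idx = _resolve_indices(traj, h_sel)
        for a_sel in spec.acceptors:
            for a in _resolve_indices(traj, a_sel):
                for d, h in zip(d_idx, h_idx):
                    ok, da, _ = detect_hbond(frame, d, h, a, cutoffs)
                    present = present or ok
                    best = min(best, da)
    return present, best


def interaction_series(traj: Trajectory, specs: list[InteractionSpec],
                       cutoffs: Cutoffs = PAPER_PROFILE) -> list[InteractionSeries]:
    """Evaluate every spec on every frame; deterministic frame order."""
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise SelectionError("interaction labels must be unique")
    out = []
    for spec in specs:
        present = np.zeros(len(traj), dtype=bool)
        geom = np.zeros(len(traj), dtype=float)
        if spec.kind != "hbond":
            ga = _resolve_indices(traj, spec.group_a)
            gb = _resolve_indices(traj, spec.group_b)
        for i, frame in enumerate(traj.frames):
            try:
                if spec.kind == "hbond":
                    present[i], geom[i] = _eval_hbond_spec(traj, frame, spec, cutoffs)
                elif spec.kind == "salt_bridge":
                    present[i], geom[i] = detect_salt_bridge(frame, ga, gb, cutoffs)
                elif spec.kind == "hydrophobic":
                    present[i], geom[i] = detect_hydrophobic_contact(frame, ga, gb, cutoffs)
                else:
                    present[i], geom[i], _ = detect_pi_stack(frame, ga, gb, cutoffs)
            except Exception as exc:
                raise type(exc)(f"{spec.label} at frame {i}: {exc}") from exc
        out.append(InteractionSeries(spec, present, geom))
    return out


def occupancy(series: InteractionSeries) -> OccupancyReport:
    """Exact occupancy percentage; rounding happens only at rendering."""
    n = len(series.present)
    if n < 1:
        raise ValueError("empty interaction series")
    pct = 100.0 * int(series.present.sum()) / n
    return OccupancyReport(
        label=series.spec.label,
        occupancy_percent=pct,
        n_frames=n,
        mean_dist=float(series.geometry.mean()),
        min_dist=float(series.geometry.min()),
    )
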