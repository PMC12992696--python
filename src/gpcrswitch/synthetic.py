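"""Deterministic synthetic trajectory generator with exact ground truths.

Builds a minimal receptor scaffold (one residue per annotated
microswitch/pocket role, a 7x4 Calpha TM bundle, a tryptamine-like
ligand with an indole core, one Na+ and a small water pool) and emits
multi-model PDB trajectories in which every target quantity is
realised by construction, not sampled: an interaction occupancy target
f over n frames places the partner atoms inside the geometric
criterion (2.8 A donor-acceptor distance at a 165 deg D-H...A angle)
in exactly round(f*n) frames chosen by a seeded permutation, and
outside it (5.5 A) otherwise; rotamer schedules rotate the Trp
side-chain to exact chi1/chi2; d_TM/d_IL schedules translate the
marker atoms; pose targets displace the ligand rigidly by 0.5 A
(below the 2 A criterion) or 3.0 A (above); hydration schedules park
or place waters around the Na+ site and along a vestibule-to-pocket
chain. A per-frame random rigid motion of the whole system (seeded)
makes superposition-based analyses non-trivial without changing any
internal geometry. These are geometric constructions, not physical
dynamics.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FixtureSpecError
from .trajectory import (Atom, Frame, ResidueEntry, ResidueMap, Trajectory,
                         dump_residue_map, write_multimodel_pdb)

__all__ = [
    "FixtureSpec",
    "FixtureManifest",
    "PAPER_PROFILE_FIXTURES",
    "build_fixture",
    "generate_fixture",
    "anchor_frames",
    "base_scaffold",
]

# satisfied / unsatisfied interaction geometry (A, deg)
_HB_DIST, _HB_ANGLE, _FAR_DIST = 2.8, 165.0, 5.5
_SALT_NEAR, _SALT_FAR = 3.0, 6.0
_RMSD_BELOW, _RMSD_ABOVE = 0.5, 3.0

_NA_BOUND = np.array([0.0, -2.3, -7.0])
_NA_EXPELLED = np.array([0.0, -4.0, 6.0])
_SHELL_DIRS = np.array([
    [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0],
    [0.577, -0.577, -0.578], [0.0, 0.0, -1.0],
])
_SHELL_R = 2.5
_N_SHELL_SLOTS = 5
_N_CHAIN = 8
_CHAIN_START = np.array([2.6, 0.0, 13.0])
_CHAIN_END = np.array([0.0, 1.5, -5.5])
_LIG_DISPLACE_DIR = np.array([2.0, 2.0, 1.0]) / 3.0  # unit vector


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u."""
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, trial)) > 0.9:
        trial = np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(u, trial))


def place_dihedral(a, b, c, bond: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """NeRF placement: point d with |cd|=bond, angle(b,c,d)=theta and
    dihedral(a,b,c,d)=chi (IUPAC sign)."""
    theta = np.radians(theta_deg)
    chi = np.radians(chi_deg)
    bc = _unit(np.asarray(c, float) - np.asarray(b, float))
    n = _unit(np.cross(np.asarray(b, float) - np.asarray(a, float), bc))
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(chi),
                               np.sin(theta) * np.sin(chi)])
    frame = np.column_stack([bc, m, n])
    return np.asarray(c, float) + frame @ d_local


def _indole_core() -> dict[str, np.ndarray]:
    """Planar 9-atom indole (fused hexagon+pentagon, 1.4 A sides), local xy."""
    s = 1.4
    hexagon = {}
    for name, ang in (("C7A", 30), ("C3A", -30), ("C4", -90),
                      ("C5", -150), ("C6", 150), ("C7", 90)):
        hexagon[name] = s * np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang)), 0.0])
    r5 = s / (2 * np.sin(np.radians(36)))
    a5 = s / (2 * np.tan(np.radians(36)))
    pent_center = np.array([s * np.cos(np.radians(30)) + a5, 0.0, 0.0])
    pentagon = {}
    for name, ang in (("N1", 72), ("C2", 0), ("C3", -72)):
        pentagon[name] = pent_center + r5 * np.array(
            [np.cos(np.radians(ang)), np.sin(np.radians(ang)), 0.0])
    coords = {**hexagon, **pentagon}
    centroid = np.mean(list(coords.values()), axis=0)
    return {k: v - centroid for k, v in coords.items()}


_CORE_ORDER = ("N1", "C2", "C3", "C3A", "C4", "C5", "C6", "C7", "C7A")
_LIG_CENTER = np.array([0.0, 0.0, 4.0])


@dataclass
class _Scaffold:
    """Base topology + coordinates; (resnum, name) -> index lookup."""

    names: list = field(default_factory=list)       # (name, resname, resnum, chain, element)
    coords: list = field(default_factory=list)
    lookup: dict = field(default_factory=dict)

    def add(self, name, resname, resnum, element, xyz, chain="A"):
        self.lookup[(resnum, name)] = len(self.names)
        self.names.append((name, resname, resnum, chain, element))
        self.coords.append(np.asarray(xyz, dtype=float))

    def idx(self, resnum, name) -> int:
        return self.lookup[(resnum, name)]

    def base(self) -> np.ndarray:
        return np.array(self.coords)


def base_scaffold() -> tuple[_Scaffold, ResidueMap]:
    """Construct the annotated scaffold in its reference geometry.

    The reference geometry realises the inactive anchors (d_TM 9 A,
    d_IL 4 A, chi1 -80 deg, Na+ bound with two shell waters) and places
    every targetable interaction in its satisfied state.
    """
    sc = _Scaffold()
    # --- TM bundle: 7 pseudo-helices x 4 Calpha, along z (extracellular +z)
    resnum = 401
    for h in range(7):
        ang = 2 * np.pi * h / 7
        cx, cy = 10 * np.cos(ang), 10 * np.sin(ang)
        for z in (-12.0, -4.0, 4.0, 12.0):
            sc.add("CA", "GLY", resnum, "C", (cx, cy, z))
            resnum += 1
    # --- extracellular vestibule markers
    for resnum, xyz in ((501, (3.0, 0.0, 16.0)), (502, (-1.5, 2.6, 16.0)),
                        (503, (-1.5, -2.6, 16.0))):
        sc.add("CA", "GLY", resnum, "C", xyz)

    # --- ligand: indole core + indole H + amine + methoxy oxygens
    core = _indole_core()
    for n in _CORE_ORDER:
        sc.add(n, "LIG", 900, "N" if n == "N1" else "C", core[n] + _LIG_CENTER)
    n1 = core["N1"] + _LIG_CENTER
    u_n1 = _unit(core["N1"])        # in-plane, away from the core centroid
    sc.add("H1", "LIG", 900, "H", n1 + u_n1)
    nt = np.array([2.0, 1.0, 5.5])
    sc.add("NT", "LIG", 900, "N", nt)
    o1 = np.array([-1.5, 2.5, 6.5])
    sc.add("O1", "LIG", 900, "O", o1)
    o2 = np.array([-2.5, -1.5, 3.0])
    sc.add("O2", "LIG", 900, "O", o2)

    # --- Asp155 (3.32) anchor: carboxylate near the amine, salt bridge formed
    od1 = nt + np.array([_SALT_NEAR, 0.0, 0.0])
    sc.add("OD1", "ASP", 155, "O", od1)
    sc.add("OD2", "ASP", 155, "O", od1 + np.array([0.0, 0.6, 1.0]))
    sc.add("CG", "ASP", 155, "C", od1 + np.array([1.1, -0.6, 0.0]))
    sc.add("CB", "ASP", 155, "C", od1 + np.array([2.1, -0.6, 1.0]))

    # --- Thr160 (3.37) base of the pocket: accepts from the indole N1-H
    og1 = _hbond_acceptor_pos(n1, n1 + u_n1, satisfied=True)
    sc.add("OG1", "THR", 160, "O", og1)
    sc.add("HG1", "THR", 160, "H", og1 + np.array([0.0, 0.0, 1.0]))
    sc.add("CB", "THR", 160, "C", og1 + np.array([0.8, 0.8, 0.5]))

    # --- Asp231 (5.35) backbone amide donating to the para-methoxy O1
    w = _unit(o1 - _LIG_CENTER)
    n_pos, h_pos = _hbond_donor_pos(o1, w, satisfied=True)
    sc.add("N", "ASP", 231, "N", n_pos)
    sc.add("H", "ASP", 231, "H", h_pos)
    sc.add("CA", "ASP", 231, "C", n_pos + np.array([1.2, 0.6, 0.5]))
    sc.add("C", "ASP", 231, "C", n_pos + np.array([2.2, -0.4, 0.5]))
    sc.add("O", "ASP", 231, "O", n_pos + np.array([2.8, 0.2, 1.5]))

    # --- polar triad
    sc.add("OG", "SER", 239, "O", (-2.0, 3.5, 6.0))
    sc.add("OG", "SER", 242, "O", (-3.5, 2.0, 5.0))
    sc.add("ND2", "ASN", 343, "N", (-1.0, -3.5, 6.0))
    sc.add("OD1", "ASN", 343, "O", (-2.0, -3.0, 6.5))

    # --- Trp336 (6.48) toggle: chi1/chi2 via dihedral construction
    trp_n = np.array([0.5, -7.5, -0.5])
    trp_ca = np.array([0.0, -6.2, 0.0])
    trp_cb = np.array([0.6, -5.0, 0.8])
    sc.add("N", "TRP", 336, "N", trp_n)
    sc.add("CA", "TRP", 336, "C", trp_ca)
    sc.add("CB", "TRP", 336, "C", trp_cb)
    cg = place_dihedral(trp_n, trp_ca, trp_cb, 1.52, 114.0, -80.0)
    sc.add("CG", "TRP", 336, "C", cg)
    sc.add("CD1", "TRP", 336, "C", place_dihedral(trp_ca, trp_cb, cg, 1.43, 127.0, 110.0))

    # --- cytoplasmic microswitch markers
    arg_ca = np.array([7.0, 0.0, -14.0])
    sc.add("CA", "ARG", 173, "C", arg_ca)
    nh1 = np.array([6.0, 2.0, -13.0])
    sc.add("NH1", "ARG", 173, "N", nh1)
    sc.add("NH2", "ARG", 173, "N", nh1 + np.array([-1.2, -0.8, 0.4]))
    sc.add("NE", "ARG", 173, "N", nh1 + np.array([0.5, -1.5, -0.8]))
    oe1 = nh1 + np.array([0.0, 4.0, 0.0])
    sc.add("OE1", "GLU", 318, "O", oe1)
    sc.add("OE2", "GLU", 318, "O", oe1 + np.array([0.0, 0.6, 1.0]))
    sc.add("CA", "CYS", 322, "C", arg_ca + np.array([-9.0, 0.0, 0.0]))

    # --- sodium pocket
    sc.add("OD1", "ASP", 120, "O", (0.0, 0.0, -7.0))
    sc.add("OD2", "ASP", 120, "O", (0.0, 2.2, -7.0))
    sc.add("CG", "ASP", 120, "C", (0.0, 1.1, -7.6))
    sc.add("CB", "ASP", 120, "C", (0.0, 1.1, -9.1))
    sc.add("ND2", "ASN", 380, "N", (0.0, 0.0, -9.9))
    sc.add("HD21", "ASN", 380, "H", (0.0, 0.0, -8.9))
    sc.add("HD22", "ASN", 380, "H", (0.94, 0.0, -10.23))
    sc.add("OG", "SER", 162, "O", _NA_BOUND + np.array([0.0, 0.0, 3.0]))
    sc.add("CB", "SER", 162, "C", _NA_BOUND + np.array([0.0, -0.7, 3.7]))
    # Phe332 (6.44) lid ring, hexagon above the ion
    lid_center = _NA_BOUND + np.array([0.0, 0.0, 4.5])
    for name, ang in (("CG", 0), ("CD1", 60), ("CE1", 120), ("CZ", 180),
                      ("CE2", 240), ("CD2", 300)):
        sc.add(name, "PHE", 332, "C",
               lid_center + 1.4 * np.array([np.cos(np.radians(ang)),
                                            np.sin(np.radians(ang)), 0.0]))

    # --- ion and water pool (shell slots + channel slots, parked when unused)
    sc.add("NA", "NA+", 950, "NA", _NA_BOUND)
    for k in range(_N_SHELL_SLOTS + _N_CHAIN):
        parked = np.array([60.0 + 5.0 * k, 60.0, 60.0])
        sc.add("O", "HOH", 960 + k, "O", parked)
    # base state: two first-shell waters
    for k in range(2):
        sc.coords[sc.idx(960 + k, "O")] = _NA_BOUND + _SHELL_R * _SHELL_DIRS[k]

    entries = [ResidueEntry(401 + i, "A", f"{1 + i // 4}.{61 + i % 4}", "tm")
               for i in range(28)]
    entries += [ResidueEntry(n, "A", bw, "vestibule")
                for n, bw in ((501, "23.50"), (502, "23.51"), (503, "23.52"))]
    entries += [
        ResidueEntry(120, "A", "2.50", "na_site"),
        ResidueEntry(155, "A", "3.32", "anchor"),
        ResidueEntry(160, "A", "3.37", "base"),
        ResidueEntry(162, "A", "3.39", "na_backup"),
        ResidueEntry(173, "A", "3.50", "ionic_lock_arg"),
        ResidueEntry(231, "A", "5.35", "depth_anchor"),
        ResidueEntry(239, "A", "5.44", "polar_ser1"),
        ResidueEntry(242, "A", "5.46", "polar_ser2"),
        ResidueEntry(318, "A", "6.30", "ionic_lock_glu"),
        ResidueEntry(322, "A", "6.34", "tm6_gap"),
        ResidueEntry(332, "A", "6.44", "na_lid"),
        ResidueEntry(336, "A", "6.48", "toggle"),
        ResidueEntry(343, "A", "6.55", "polar_asn"),
        ResidueEntry(380, "A", "7.49", "na_stabilizer"),
    ]
    lig_roles = {"H1": "indole_h", "NT": "amine_n", "O1": "methoxy_para",
                 "O2": "methoxy_meta"}
    lig_roles.update({n: "core" for n in _CORE_ORDER})
    rmap = ResidueMap(entries=entries, ligand_residue_name="LIG",
                      ligand_chain_id="A", ligand_atom_roles=lig_roles)
    return sc, rmap


# ---------------------------------------------------------------------------
# satisfied/unsatisfied geometric constructions

def _hbond_acceptor_pos(donor: np.ndarray, hydrogen: np.ndarray,
                        satisfied: bool) -> np.ndarray:
    """Acceptor position for a fixed D-H pair: 2.8 A at a 165 deg angle
    at H when satisfied, 5.5 A along the D-H axis otherwise."""
    u = _unit(hydrogen - donor)
    if not satisfied:
        return donor + _FAR_DIST * u
    v = _perp(u)
    bend = np.radians(180.0 - _HB_ANGLE)
    direction = np.cos(bend) * u + np.sin(bend) * v
    # solve |H + r*direction - D| = 2.8 with |H - D| = 1
    b = 2.0 * np.dot(direction, hydrogen - donor)
    r = (-b + np.sqrt(b * b - 4.0 * (1.0 - _HB_DIST ** 2))) / 2.0
    return hydrogen + r * direction


def _hbond_donor_pos(acceptor: np.ndarray, w: np.ndarray,
                     satisfied: bool) -> tuple[np.ndarray, np.ndarray]:
    """(Donor, hydrogen) positions for a fixed acceptor, along axis w.

    Satisfied: D-A distance 2.8 A with a 165 deg angle at the 1.0 A
    hydrogen; unsatisfied: donor 5.5 A out along w, hydrogen pointing
    back at the acceptor.
    """
    if not satisfied:
        n = acceptor + _FAR_DIST * w
        return n, n - w
    v = _perp(w)
    bend = np.radians(180.0 - _HB_ANGLE)
    # |r*w + cos(bend)*w + sin(bend)*v| = 2.8  ->  (r+cos)^2 + sin^2 = 2.8^2
    r_h = float(np.sqrt(_HB_DIST ** 2 - np.sin(bend) ** 2) - np.cos(bend))
    h = acceptor + r_h * w
    n = h + np.cos(bend) * w + np.sin(bend) * v
    return n, h


# ---------------------------------------------------------------------------
# per-frame drivers; each declares the atoms it moves

def _drv_thr160_n1h(sc, coords, sat: bool):
    n1 = coords[sc.idx(900, "N1")]
    h1 = coords[sc.idx(900, "H1")]
    og1 = _hbond_acceptor_pos(n1, h1, sat)
    coords[sc.idx(160, "OG1")] = og1
    coords[sc.idx(160, "HG1")] = og1 + np.array([0.0, 0.0, 1.0])


def _drv_asp155_salt(sc, coords, sat: bool):
    nt = coords[sc.idx(900, "NT")]
    od1 = nt + np.array([(_SALT_NEAR if sat else _SALT_FAR), 0.0, 0.0])
    coords[sc.idx(155, "OD1")] = od1
    coords[sc.idx(155, "OD2")] = od1 + np.array([0.0, 0.6, 1.0])
    coords[sc.idx(155, "CG")] = od1 + np.array([1.1, -0.6, 0.0])
    coords[sc.idx(155, "CB")] = od1 + np.array([2.1, -0.6, 1.0])


def _drv_asp231_o1(sc, coords, sat: bool):
    o1 = coords[sc.idx(900, "O1")]
    core = np.mean([coords[sc.idx(900, n)] for n in _CORE_ORDER], axis=0)
    w = _unit(o1 - core)
    n_pos, h_pos = _hbond_donor_pos(o1, w, sat)
    coords[sc.idx(231, "N")] = n_pos
    coords[sc.idx(231, "H")] = h_pos
    coords[sc.idx(231, "CA")] = n_pos + np.array([1.2, 0.6, 0.5])
    coords[sc.idx(231, "C")] = n_pos + np.array([2.2, -0.4, 0.5])
    coords[sc.idx(231, "O")] = n_pos + np.array([2.8, 0.2, 1.5])


def _drv_thr160_o2(sc, coords, sat: bool):
    o2 = coords[sc.idx(900, "O2")]
    core = np.mean([coords[sc.idx(900, n)] for n in _CORE_ORDER], axis=0)
    w = _unit(o2 - core)
    og1, hg1 = _hbond_donor_pos(o2, w, sat)
    coords[sc.idx(160, "OG1")] = og1
    coords[sc.idx(160, "HG1")] = hg1


def _drv_rmsd_core(sc, coords, below: bool):
    shift = (_RMSD_BELOW if below else _RMSD_ABOVE) * _LIG_DISPLACE_DIR
    for name in (*_CORE_ORDER, "H1", "NT", "O1", "O2"):
        coords[sc.idx(900, name)] = coords[sc.idx(900, name)] + shift


def _drv_chi(sc, coords, value):
    chi1, chi2 = value
    n = coords[sc.idx(336, "N")]
    ca = coords[sc.idx(336, "CA")]
    cb = coords[sc.idx(336, "CB")]
    cg = place_dihedral(n, ca, cb, 1.52, 114.0, chi1)
    coords[sc.idx(336, "CG")] = cg
    coords[sc.idx(336, "CD1")] = place_dihedral(ca, cb, cg, 1.43, 127.0, chi2)


def _drv_dtm(sc, coords, value: float):
    arg_ca = coords[sc.idx(173, "CA")]
    coords[sc.idx(322, "CA")] = arg_ca + np.array([-float(value), 0.0, 0.0])


def _drv_dil(sc, coords, value: float):
    nh1 = coords[sc.idx(173, "NH1")]
    oe1 = nh1 + np.array([0.0, float(value), 0.0])
    coords[sc.idx(318, "OE1")] = oe1
    coords[sc.idx(318, "OE2")] = oe1 + np.array([0.0, 0.6, 1.0])


def _drv_na(sc, coords, bound: bool):
    coords[sc.idx(950, "NA")] = _NA_BOUND if bound else _NA_EXPELLED


def _drv_shell(sc, coords, count):
    count = int(count)
    if count > _N_SHELL_SLOTS:
        raise FixtureSpecError(f"at most {_N_SHELL_SLOTS} shell waters supported")
    na = coords[sc.idx(950, "NA")]
    for k in range(_N_SHELL_SLOTS):
        if k < count:
            coords[sc.idx(960 + k, "O")] = na + _SHELL_R * _SHELL_DIRS[k]
        else:
            coords[sc.idx(960 + k, "O")] = np.array([60.0 + 5.0 * k, 60.0, 60.0])


def _drv_channel(sc, coords, open_: bool):
    for k in range(_N_CHAIN):
        if open_:
            t = k / (_N_CHAIN - 1)
            coords[sc.idx(960 + _N_SHELL_SLOTS + k, "O")] = (
                (1 - t) * _CHAIN_START + t * _CHAIN_END)
        else:
            coords[sc.idx(960 + _N_SHELL_SLOTS + k, "O")] = np.array(
                [60.0 + 5.0 * (_N_SHELL_SLOTS + k), 60.0, 60.0])


@dataclass(frozen=True)
class _Template:
    driver: callable
    driven: tuple            # (resnum, name) atoms this target controls
    kind: str                # occupancy | rmsd_below | schedule
    priority: int            # ligand movers run before receptor-relative ones


_LIG_ATOMS = tuple((900, n) for n in (*_CORE_ORDER, "H1", "NT", "O1", "O2"))
_TEMPLATES: dict[str, _Template] = {
    "thr160_n1h": _Template(_drv_thr160_n1h, ((160, "OG1"), (160, "HG1")), "occupancy", 1),
    "asp155_salt": _Template(_drv_asp155_salt,
                             ((155, "OD1"), (155, "OD2"), (155, "CG"), (155, "CB")),
                             "occupancy", 1),
    "asp231_o1": _Template(_drv_asp231_o1,
                           ((231, "N"), (231, "H"), (231, "CA"), (231, "C"), (231, "O")),
                           "occupancy", 1),
    "thr160_o2": _Template(_drv_thr160_o2, ((160, "OG1"), (160, "HG1")), "occupancy", 1),
    "rmsd_core": _Template(_drv_rmsd_core, _LIG_ATOMS, "rmsd_below", 0),
    "chi": _Template(_drv_chi, ((336, "CG"), (336, "CD1")), "schedule", 1),
    "d_tm": _Template(_drv_dtm, ((322, "CA"),), "schedule", 1),
    "d_il": _Template(_drv_dil, ((318, "OE1"), (318, "OE2")), "schedule", 1),
    "na": _Template(_drv_na, ((950, "NA"),), "schedule", 0),
    "shell": _Template(_drv_shell, tuple((960 + k, "O") for k in range(_N_SHELL_SLOTS)),
                       "schedule", 1),
    "channel": _Template(_drv_channel,
                         tuple((960 + _N_SHELL_SLOTS + k, "O") for k in range(_N_CHAIN)),
                         "schedule", 1),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Targets for one synthetic trajectory.

    ``targets`` maps a template name to either ``{"fraction": f}``
    (boolean satisfaction pattern realising exactly round(f*n) frames),
    ``{"constant": v}`` or ``{"values": [v0, v1, ...]}``.
    """

    name: str
    n_frames: int
    seed: int
    targets: dict
    rigid_motion: bool = True
    stride_ns: float = 1.0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise FixtureSpecError("n_frames must be >= 1")
        claimed: dict[tuple, str] = {}
        for tname, tspec in self.targets.items():
            if tname not in _TEMPLATES:
                raise FixtureSpecError(f"unknown target template {tname!r}")
            keys = set(tspec) & {"fraction", "constant", "values"}
            if len(keys) != 1:
                raise FixtureSpecError(
                    f"{tname}: give exactly one of fraction/constant/values")
            if "fraction" in tspec and not 0.0 <= tspec["fraction"] <= 1.0:
                raise FixtureSpecError(f"{tname}: fraction must be in [0, 1]")
            if "values" in tspec and len(tspec["values"]) != self.n_frames:
                raise FixtureSpecError(f"{tname}: values length != n_frames")
            for key in _TEMPLATES[tname].driven:
                if key in claimed:
                    raise FixtureSpecError(
                        f"targets {claimed[key]!r} and {tname!r} both drive atom {key}")
                claimed[key] = tname


@dataclass
class FixtureManifest:
    spec: FixtureSpec
    ground_truth: dict       # template -> realised truth (exact counts)
    files: dict              # role -> path (empty for in-memory builds)

    def to_json(self) -> str:
        return json.dumps({
            "name": self.spec.name,
            "n_frames": self.spec.n_frames,
            "seed": self.spec.seed,
            "targets": {k: dict(v) for k, v in self.spec.targets.items()},
            "ground_truth": self.ground_truth,
            "files": {k: str(v) for k, v in self.files.items()},
        }, indent=2, sort_keys=True)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _frame_values(spec: FixtureSpec, template: str, tspec: dict,
                  rng: np.random.Generator):
    """Per-frame driver values plus the realised ground truth."""
    n = spec.n_frames
    kind = _TEMPLATES[template].kind
    if "fraction" in tspec:
        n_sat = int(round(tspec["fraction"] * n))
        order = rng.permutation(n)
        sat = np.zeros(n, dtype=bool)
        sat[order[:n_sat]] = True
        truth_key = ("occupancy_percent" if kind == "occupancy"
                     else "percent_below" if kind == "rmsd_below" else "percent_true")
        truth = {"n_satisfied": n_sat, truth_key: 100.0 * n_sat / n}
        return list(sat), truth
    if "constant" in tspec:
        vals = [tspec["constant"]] * n
    else:
        vals = list(tspec["values"])
    if kind == "schedule" and template in ("na", "channel"):
        n_true = sum(bool(v) for v in vals)
        truth = {"n_true": n_true, "percent_true": 100.0 * n_true / n}
    elif template == "shell":
        truth = {"mean_count": float(np.mean([int(v) for v in vals]))}
    elif template == "chi":
        truth = {"chi1_values": sorted({float(v[0]) for v in vals})}
    else:
        truth = {"mean": float(np.mean([float(v) for v in vals]))}
    return vals, truth


def build_fixture(spec: FixtureSpec) -> tuple[Trajectory, ResidueMap, FixtureManifest]:
    """Realise a fixture spec as an in-memory trajectory."""
    spec.validate()
    sc, rmap = base_scaffold()
    rng = np.random.default_rng(spec.seed)
    per_target = {}
    for tname in sorted(spec.targets):
        per_target[tname] = _frame_values(spec, tname, spec.targets[tname], rng)
    ordered = sorted(per_target, key=lambda t: (_TEMPLATES[t].priority, t))
    motion_rng = np.random.default_rng(spec.seed + 1)

    frames = []
    base = sc.base()
    for i in range(spec.n_frames):
        coords = base.copy()
        for tname in ordered:
            _TEMPLATES[tname].driver(sc, coords, per_target[tname][0][i])
        if spec.rigid_motion:
            rot = _random_rotation(motion_rng)
            trans = motion_rng.uniform(-5.0, 5.0, size=3)
            coords = coords @ rot.T + trans
        atoms = [Atom(j + 1, nm, rn, rnum, ch, el, coords[j])
                 for j, (nm, rn, rnum, ch, el) in enumerate(sc.names)]
        frames.append(Frame(i, i * spec.stride_ns, atoms))
    traj = Trajectory(frames, stride_ns=spec.stride_ns)
    manifest = FixtureManifest(spec=spec,
                               ground_truth={t: per_target[t][1] for t in per_target},
                               files={})
    return traj, rmap, manifest


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureManifest:
    """Write fixture trajectory + residue map + manifest to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, rmap, manifest = build_fixture(spec)
    pdb = out / f"{spec.name}.pdb"
    map_path = out / f"{spec.name}_map.yaml"
    manifest_path = out / f"{spec.name}_manifest.json"
    write_multimodel_pdb(traj, pdb)
    dump_residue_map(rmap, map_path)
    manifest.files = {"trajectory": pdb, "residue_map": map_path,
                      "manifest": manifest_path}
    manifest_path.write_text(manifest.to_json())
    return manifest


def reference_state() -> tuple[Trajectory, ResidueMap]:
    """Single-frame reference structure in the base scaffold geometry.

    Used as the superposition reference for the ligand-core RMSD (a
    synthetic stand-in for the agonist-bound reference structure).
    """
    sc, rmap = base_scaffold()
    coords = sc.base()
    atoms = [Atom(j + 1, nm, rn, rnum, ch, el, coords[j])
             for j, (nm, rn, rnum, ch, el) in enumerate(sc.names)]
    return Trajectory([Frame(0, 0.0, atoms)]), rmap


_INACTIVE_ANCHOR = {"d_tm": 9.0, "d_il": 4.0, "chi1": -80.0, "chi2": 110.0,
                    "na_bound": True, "shell": 2}
_ACTIVE_ANCHOR = {"d_tm": 12.0, "d_il": 16.0, "chi1": -160.0, "chi2": 100.0,
                  "na_bound": False, "shell": 4}


def anchor_frames() -> tuple[Trajectory, Trajectory, ResidueMap]:
    """Single-frame fixtures realising the printed state anchors exactly.

    Inactive: d_TM 9 A, d_IL 4 A, chi1 -80 deg, Na+ coordinated with two
    shell waters. Active: d_TM 12 A, d_IL 16 A, chi1 -160 deg, Na+
    expelled with four shell waters following the ion.
    """
    trajs = []
    for anchor in (_INACTIVE_ANCHOR, _ACTIVE_ANCHOR):
        spec = FixtureSpec(
            name="anchor", n_frames=1, seed=0, rigid_motion=False,
            targets={
                "d_tm": {"constant": anchor["d_tm"]},
                "d_il": {"constant": anchor["d_il"]},
                "chi": {"constant": (anchor["chi1"], anchor["chi2"])},
                "na": {"constant": anchor["na_bound"]},
                "shell": {"constant": anchor["shell"]},
                "channel": {"constant": not anchor["na_bound"]},
            })
        traj, rmap, _ = build_fixture(spec)
        trajs.append(traj)
    return trajs[0], trajs[1], rmap


def _step_values(n: int, n_first: int, first, second) -> list:
    return [first] * n_first + [second] * (n - n_first)


def paper_profile_fixtures() -> dict[str, FixtureSpec]:
    """The packaged fixture registry.

    Ground-truth fractions are set to the headline occupancy and pose
    statistics of the study this package models: the trans-1 inactive-
    state interaction triad (indole N1-H to Thr3.37 70%, amine salt
    bridge to Asp3.32 99%, para-methoxy to the Asp5.35 backbone 43%),
    the agonist-compatible pose fractions (RMSD_i < 2 A for 78% of
    trans-2 and 75% of cis-1 frames), and the cis-2 active-state
    Thr3.37 hydrogen bond (66%).
    """
    n = 1000
    demo_n = 200
    demo_split = 120
    return {
        "trans1_thr160": FixtureSpec("trans1_thr160", n, 42,
                                     {"thr160_n1h": {"fraction": 0.70}}),
        "trans1_asp155": FixtureSpec("trans1_asp155", n, 42,
                                     {"asp155_salt": {"fraction": 0.99}}),
        "trans1_asp231": FixtureSpec("trans1_asp231", n, 42,
                                     {"asp231_o1": {"fraction": 0.43}}),
        "trans2_rmsdi": FixtureSpec("trans2_rmsdi", n, 43,
                                    {"rmsd_core": {"fraction": 0.78}}),
        "cis1_rmsdi": FixtureSpec("cis1_rmsdi", n, 43,
                                  {"rmsd_core": {"fraction": 0.75}}),
        "cis2_thr160_active": FixtureSpec("cis2_thr160_active", n, 44,
                                          {"thr160_o2": {"fraction": 0.66}}),
        "demo_combined": FixtureSpec(
            "demo_combined", demo_n, 7,
            {
                "thr160_n1h": {"fraction": 0.70},
                "asp155_salt": {"fraction": 0.99},
                "rmsd_core": {"fraction": 0.75},
                "chi": {"values": _step_values(demo_n, demo_split,
                                               (-80.0, 110.0), (-160.0, 100.0))},
                "d_tm": {"values": _step_values(demo_n, demo_split, 9.0, 12.0)},
                "d_il": {"values": _step_values(demo_n, demo_split, 4.0, 16.0)},
                "na": {"values": _step_values(demo_n, demo_split, True, False)},
                "shell": {"values": _step_values(demo_n, demo_split, 2, 4)},
                "channel": {"values": _step_values(demo_n, demo_split, False, True)},
            }),
    }


PAPER_PROFILE_FIXTURES = paper_profile_fixtures()
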