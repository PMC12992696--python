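"""Sodium-pocket coordination and water-channel analysis.

The allosteric Na+ site at Asp2.50 reports activation readiness: in the
inactive receptor the ion sits in a dehydrated pocket (about two
first-shell waters) capped by the Phe6.44 aromatic lid and locked by an
Asn7.49-Asp2.50 hydrogen bond; loss of that network opens a continuous
water channel from the extracellular vestibule and the shell grows to
about four waters. Channel existence is decided by breadth-first search
on the water hydrogen-bond graph (O-O <= 3.5 A edges) between waters
attached to the vestibule and waters attached to the Asp2.50
carboxylate.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import SelectionError, TopologyError
from .interactions import detect_hbond
from .presets import Cutoffs, PAPER_PROFILE
from .trajectory import Frame, ResidueMap, Trajectory, is_sodium, is_water_oxygen

__all__ = [
    "NaPocketState",
    "WaterGraph",
    "sodium_index",
    "water_oxygen_indices",
    "na_first_shell_count",
    "na_pocket_state",
    "build_water_graph",
    "water_channel_exists",
    "hydration_series",
]


@dataclass(frozen=True)
class NaPocketState:
    na_index: int
    n_water_first_shell: int
    asp_contact: bool      # Na within 3.2 A of the Asp2.50 carboxylate O
    asn_asp_hbond: bool    # Asn7.49 side-chain amide donating to Asp2.50
    ser_backup: bool       # Ser3.39 OG within 3.2 A of Na (backup ligation)
    lid_closed: bool       # Phe6.44 ring centroid within 6.0 A of Na


@dataclass(frozen=True)
class WaterGraph:
    nodes: tuple[int, ...]           # water oxygen topology indices
    edges: frozenset[frozenset]      # undirected O-O pairs
    sources: frozenset                # waters attached to the vestibule
    sinks: frozenset                  # waters attached to Asp2.50


def sodium_index(traj: Trajectory) -> int:
    idx = [i for i, a in enumerate(traj.topology) if is_sodium(a)]
    if not idx:
        raise SelectionError("no Na+ ion in topology")
    return idx[0]


def water_oxygen_indices(traj: Trajectory) -> list[int]:
    return [i for i, a in enumerate(traj.topology) if is_water_oxygen(a)]


def na_first_shell_count(frame: Frame, na_index: int, water_indices: list[int],
                         cutoff: float = PAPER_PROFILE.na_shell_dist) -> int:
    """Number of water oxygens within the first-shell cutoff of Na+."""
    if not water_indices:
        return 0
    coords = frame.coords
    d = np.linalg.norm(coords[water_indices] - coords[na_index], axis=1)
    return int((d <= cutoff).sum())


def _carboxylate_indices(traj: Trajectory, rmap: ResidueMap, role: str) -> list[int]:
    out = []
    for name in ("OD1", "OD2", "OE1", "OE2"):
        try:
            out.append(rmap.atom_index(traj, role, name))
        except TopologyError:
            continue
    if not out:
        raise TopologyError(f"role {role!r}: no carboxylate oxygens found")
    return out


def na_pocket_state(traj: Trajectory, frame: Frame, rmap: ResidueMap,
                    cutoffs: Cutoffs = PAPER_PROFILE) -> NaPocketState:
    """Evaluate the sodium-pocket coordination network on one frame."""
    na = sodium_index(traj)
    waters = water_oxygen_indices(traj)
    coords = frame.coords

    asp_o = _carboxylate_indices(traj, rmap, "na_site")
    asp_contact = bool(
        np.linalg.norm(coords[asp_o] - coords[na], axis=1).min() <= cutoffs.na_contact_dist)

    # Asn7.49 ND2-H donating to either Asp2.50 carboxylate oxygen
    asn_asp = False
    try:
        nd2 = rmap.atom_index(traj, "na_stabilizer", "ND2")
        for hname in ("HD21", "HD22"):
            try:
                h = rmap.atom_index(traj, "na_stabilizer", hname)
            except TopologyError:
                continue
            for a in asp_o:
                ok, _, _ = detect_hbond(frame, nd2, h, a, cutoffs)
                asn_asp = asn_asp or ok
    except TopologyError:
        pass

    ser_og = rmap.atom_index(traj, "na_backup", "OG")
    ser_backup = bool(np.linalg.norm(coords[ser_og] - coords[na]) <= cutoffs.na_contact_dist)

    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    ring_idx = rmap.atom_indices(traj, "na_lid", ring_names)
    centroid = coords[ring_idx].mean(axis=0)
    lid_closed = bool(np.linalg.norm(centroid - coords[na]) <= cutoffs.lid_dist)

    return NaPocketState(
        na_index=na,
        n_water_first_shell=na_first_shell_count(frame, na, waters, cutoffs.na_shell_dist),
        asp_contact=asp_contact,
        asn_asp_hbond=asn_asp,
        ser_backup=ser_backup,
        lid_closed=lid_closed,
    )


def build_water_graph(traj: Trajectory, frame: Frame, rmap: ResidueMap,
                      cutoffs: Cutoffs = PAPER_PROFILE) -> WaterGraph:
    waters = water_oxygen_indices(traj)
    coords = frame.coords
    edges = set()
    if waters:
        wc = coords[waters]
        dmat = cdist(wc, wc)
        for i in range(len(waters)):
            for j in range(i + 1, len(waters)):
                if dmat[i, j] <= cutoffs.water_edge_dist:
                    edges.add(frozenset((waters[i], waters[j])))
    vest_idx = rmap.role_ca_indices(traj, "vestibule")
    sink_idx = _carboxylate_indices(traj, rmap, "na_site")
    sources, sinks = set(), set()
    if waters:
        wc = coords[waters]
        dv = cdist(wc, coords[vest_idx]).min(axis=1)
        ds = cdist(wc, coords[sink_idx]).min(axis=1)
        for k, w in enumerate(waters):
            if dv[k] <= cutoffs.channel_attach_dist:
                sources.add(w)
            if ds[k] <= cutoffs.channel_attach_dist:
                sinks.add(w)
    return WaterGraph(tuple(waters), frozenset(edges), frozenset(sources), frozenset(sinks))


def water_channel_exists(traj: Trajectory, frame: Frame, rmap: ResidueMap,
                         cutoffs: Cutoffs = PAPER_PROFILE) -> tuple[bool, int]:
    """BFS from vestibule-attached to Asp2.50-attached waters.

    Returns (connected, number of waters on a shortest connecting path);
    (False, 0) when no path exists or there are no waters.
    """
    g = build_water_graph(traj, frame, rmap, cutoffs)
    if not g.sources or not g.sinks:
        return False, 0
    adj: dict[int, list[int]] = {n: [] for n in g.nodes}
    for e in g.edges:
        i, j = tuple(e)
        adj[i].append(j)
        adj[j].append(i)
    dist = {s: 1 for s in g.sources}  # path length counts waters, source included
    queue = deque(sorted(g.sources))
    while queue:
        u = queue.popleft()
        if u in g.sinks:
            return True, dist[u]
        for v in sorted(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return False, 0


def hydration_series(traj: Trajectory, rmap: ResidueMap,
                     cutoffs: Cutoffs = PAPER_PROFILE) -> pd.DataFrame:
    """Per-frame hydration table (one row per frame)."""
    rows = []
    for fr in traj.frames:
        st = na_pocket_state(traj, fr, rmap, cutoffs)
        channel, plen = water_channel_exists(traj, fr, rmap, cutoffs)
        rows.append({
            "frame": fr.index,
            "time_ns": fr.time_ns,
            "n_water_first_shell": st.n_water_first_shell,
            "asp_contact": st.asp_contact,
            "asn_asp_hbond": st.asn_asp_hbond,
            "ser_backup": st.ser_backup,
            "lid_closed": st.lid_closed,
            "channel": channel,
            "path_len": plen,
        })
    return pd.DataFrame(rows)
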