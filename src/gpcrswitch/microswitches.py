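"""Activation microswitch metrics and receptor-state classification.

Class A GPCR activation is reported by four conserved observables: the
Trp6.48 toggle-switch rotamer (chi1/chi2), the Arg3.50-Glu6.30 ionic
lock distance d_IL, the TM3-TM6 cytoplasmic gap d_TM (Calpha 3.50 to
Calpha 6.34), and the allosteric Na+ site. Reference anchors are
d_TM ~ 9 A, d_IL ~ 4 A, chi1 ~ -80 deg, Na+ coordinated for the
inactive state versus d_TM ~ 12 A, d_IL ~ 16 A, chi1 ~ -160 deg, Na+
expelled for the active state; a frame is labelled by 3-of-4 majority
voting with midpoint thresholds between those anchors.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import TopologyError
from .geometry import dihedral, distance
from .hydration import na_first_shell_count, sodium_index, water_oxygen_indices
from .presets import Cutoffs, PAPER_PROFILE
from .trajectory import Frame, ResidueMap, Trajectory

__all__ = [
    "MicroswitchState",
    "ActivationCall",
    "StateReferences",
    "DEFAULT_REFERENCES",
    "ionic_lock_distance",
    "tm6_gap",
    "toggle_dihedrals",
    "classify_toggle",
    "classify_state",
    "microswitch_state",
    "microswitch_series",
]

_ARG_N_NAMES = ("NH1", "NH2", "NE")
_GLU_O_NAMES = ("OE1", "OE2")


@dataclass(frozen=True)
class MicroswitchState:
    d_tm: float          # A, Calpha(6.34)-Calpha(3.50)
    d_il: float          # A, min guanidinium-N to carboxylate-O
    chi1: float          # deg, Trp6.48 N-CA-CB-CG
    chi2: float          # deg, Trp6.48 CA-CB-CG-CD1
    na_bound: bool
    na_hydration: int
    toggle_class: str    # vertical | horizontal | downward | other


@dataclass(frozen=True)
class ActivationCall:
    label: str           # inactive | active | intermediate
    score: float         # fraction of the four metrics voting active
    votes: dict          # metric -> "active" | "inactive"


@dataclass(frozen=True)
class StateReferences:
    """Anchor values and midpoint voting thresholds."""

    d_tm_inactive: float = 9.0
    d_tm_active: float = 12.0
    d_il_inactive: float = 4.0
    d_il_active: float = 16.0
    chi1_inactive: float = -80.0
    chi1_active: float = -160.0
    d_tm_threshold: float = 10.5
    d_il_threshold: float = 10.0


DEFAULT_REFERENCES = StateReferences()


def _role_atom_coords(traj: Trajectory, frame: Frame, rmap: ResidueMap, role: str,
                      names: tuple[str, ...]) -> np.ndarray:
    idx = []
    for n in names:
        try:
            idx.append(rmap.atom_index(traj, role, n))
        except TopologyError:
            continue
    if not idx:
        e = rmap.residue(role)
        raise TopologyError(
            f"residue {e.residue_number} (role {role}) is missing all of {names}")
    return frame.coords[idx]


def ionic_lock_distance(traj: Trajectory, frame: Frame, rmap: ResidueMap) -> float:
    """d_IL: minimum Arg3.50 guanidinium-N to Glu6.30 carboxylate-O distance."""
    arg_n = _role_atom_coords(traj, frame, rmap, "ionic_lock_arg", _ARG_N_NAMES)
    glu_o = _role_atom_coords(traj, frame, rmap, "ionic_lock_glu", _GLU_O_NAMES)
    return float(cdist(arg_n, glu_o).min())


def tm6_gap(traj: Trajectory, frame: Frame, rmap: ResidueMap) -> float:
    """d_TM: Calpha(6.34) to Calpha(3.50) distance."""
    ca_634 = frame.coords[rmap.atom_index(traj, "tm6_gap", "CA")]
    ca_350 = frame.coords[rmap.atom_index(traj, "ionic_lock_arg", "CA")]
    return distance(ca_634, ca_350)


def toggle_dihedrals(traj: Trajectory, frame: Frame, rmap: ResidueMap) -> tuple[float, float]:
    """Trp6.48 side-chain chi1 (N-CA-CB-CG) and chi2 (CA-CB-CG-CD1)."""
    idx = rmap.atom_indices(traj, "toggle", ("N", "CA", "CB", "CG", "CD1"))
    c = frame.coords
    chi1 = dihedral(c[idx[0]], c[idx[1]], c[idx[2]], c[idx[3]])
    chi2 = dihedral(c[idx[1]], c[idx[2]], c[idx[3]], c[idx[4]])
    return chi1, chi2


def classify_toggle(chi1: float, chi2: float) -> str:
    """Half-open rotamer bins on chi1; -120 deg ties break to horizontal.

    vertical (inactive-like): chi1 in (-120, -40]; horizontal
    (active-like): chi1 in (-180, -120]; downward (active-like, seen
    with bulky arrestin-biased agonists): chi1 in (-40, 40] with
    chi2 < 0; anything else is 'other'.
    """
    if -180.0 < chi1 <= -120.0:
        return "horizontal"
    if -120.0 < chi1 <= -40.0:
        return "vertical"
    if -40.0 < chi1 <= 40.0 and chi2 < 0.0:
        return "downward"
    return "other"


def na_bound_status(traj: Trajectory, frame: Frame, rmap: ResidueMap,
                    cutoffs: Cutoffs = PAPER_PROFILE) -> bool:
    """Na+ coordinated iff within the contact cutoff of the Asp2.50 oxygens."""
    try:
        na = sodium_index(traj)
    except Exception:
        return False
    asp_o = []
    for name in ("OD1", "OD2"):
        try:
            asp_o.append(rmap.atom_index(traj, "na_site", name))
        except TopologyError:
            continue
    if not asp_o:
        raise TopologyError("Asp2.50 has no carboxylate oxygens")
    d = np.linalg.norm(frame.coords[asp_o] - frame.coords[na], axis=1).min()
    return bool(d <= cutoffs.na_contact_dist)


def microswitch_state(traj: Trajectory, frame: Frame, rmap: ResidueMap,
                      cutoffs: Cutoffs = PAPER_PROFILE) -> MicroswitchState:
    chi1, chi2 = toggle_dihedrals(traj, frame, rmap)
    try:
        na = sodium_index(traj)
        hydration = na_first_shell_count(frame, na, water_oxygen_indices(traj),
                                         cutoffs.na_shell_dist)
    except Exception:
        hydration = 0
    return MicroswitchState(
        d_tm=tm6_gap(traj, frame, rmap),
        d_il=ionic_lock_distance(traj, frame, rmap),
        chi1=chi1,
        chi2=chi2,
        na_bound=na_bound_status(traj, frame, rmap, cutoffs),
        na_hydration=hydration,
        toggle_class=classify_toggle(chi1, chi2),
    )


def classify_state(state: MicroswitchState,
                   refs: StateReferences = DEFAULT_REFERENCES) -> ActivationCall:
    """3-of-4 majority vote over d_TM, d_IL, toggle rotamer and Na+ status."""
    votes = {
        "d_tm": "active" if state.d_tm > refs.d_tm_threshold else "inactive",
        "d_il": "active" if state.d_il > refs.d_il_threshold else "inactive",
        "toggle": "active" if state.toggle_class in ("horizontal", "downward")
                  else "inactive",
        "na": "inactive" if state.na_bound else "active",
    }
    n_active = sum(1 for v in votes.values() if v == "active")
    if n_active >= 3:
        label = "active"
    elif n_active <= 1:
        label = "inactive"
    else:
        label = "intermediate"
    return ActivationCall(label=label, score=n_active / 4.0, votes=votes)


def microswitch_series(traj: Trajectory, rmap: ResidueMap,
                       refs: StateReferences = DEFAULT_REFERENCES,
                       cutoffs: Cutoffs = PAPER_PROFILE) -> pd.DataFrame:
    """Per-frame microswitch table with the discrete activation label."""
    rows = []
    for fr in traj.frames:
        st = microswitch_state(traj, fr, rmap, cutoffs)
        call = classify_state(st, refs)
        rows.append({
            "frame": fr.index,
            "time_ns": fr.time_ns,
            "d_tm": st.d_tm,
            "d_il": st.d_il,
            "chi1": st.chi1,
            "chi2": st.chi2,
            "na_bound": st.na_bound,
            "na_hydration": st.na_hydration,
            "toggle_class": st.toggle_class,
            "label": call.label,
            "score": call.score,
        })
    return pd.DataFrame(rows)
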