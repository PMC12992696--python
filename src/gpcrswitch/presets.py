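"""Versioned geometric-cutoff presets.

The default ``paper-profile`` preset freezes the conventional MD
criteria used for all occupancy statistics, so results are reproducible
across runs and overrides are always explicit.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["Cutoffs", "PAPER_PROFILE", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class Cutoffs:
    """Geometric interaction criteria; all distances A, angles degrees."""

    version: str = "paper-profile-1"
    hbond_dist: float = 3.5        # donor-acceptor distance
    hbond_angle: float = 120.0     # D-H...A angle, at the hydrogen
    salt_bridge_dist: float = 4.0  # min basic-N to acidic-O
    hydrophobic_dist: float = 4.5  # min heavy-atom pair distance
    pi_dist: float = 5.5           # ring-centroid distance
    pi_parallel_angle: float = 30.0
    pi_tshape_lo: float = 60.0
    na_shell_dist: float = 3.2     # Na+ first hydration shell (Na-Ow)
    na_contact_dist: float = 3.2   # Na+ to Asp2.50 carboxylate O
    lid_dist: float = 6.0          # Phe6.44 ring centroid to Na+
    water_edge_dist: float = 3.5   # water O-O H-bonding edge
    channel_attach_dist: float = 4.0  # water to vestibule/sink attachment

    def with_overrides(self, **kwargs) -> "Cutoffs":
        return replace(self, version=self.version + "+overrides", **kwargs)


PAPER_PROFILE = Cutoffs()

#: looser exploratory preset; not used for reported statistics
PERMISSIVE = Cutoffs(version="permissive-1", hbond_dist=3.9, hbond_angle=110.0,
                     salt_bridge_dist=4.5, hydrophobic_dist=5.0)

PRESETS = {"paper-profile": PAPER_PROFILE, "permissive": PERMISSIVE}


def get_preset(name: str) -> Cutoffs:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
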