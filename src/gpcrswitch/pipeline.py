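"""End-to-end analysis orchestration.

``run_analysis`` composes the module operations on one trajectory +
residue map + config and writes deterministic CSV tables and a JSON
report; every number in the report is reproducible by calling the
underlying operation directly. ``compare_systems`` ranks several run
reports by mean insertion depth and by active-state fraction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ComparisonError, SelectionError
from .hydration import hydration_series
from .interactions import InteractionSpec, interaction_series, occupancy
from .microswitches import DEFAULT_REFERENCES, StateReferences, microswitch_series
from .pose import CoreMapping, depth_series, fraction_below, rmsd_i_series
from .presets import PAPER_PROFILE, Cutoffs, get_preset
from .trajectory import (ResidueMap, Trajectory, load_residue_map,
                         read_multimodel_pdb)

__all__ = ["AnalysisConfig", "run_analysis", "compare_systems",
           "interaction_spec_from_dict"]


def interaction_spec_from_dict(d: dict) -> InteractionSpec:
    """Build an InteractionSpec from a YAML/JSON config entry.

    hbond entries use ``donor: {d: <sel>, h: <sel>}`` (or ``donors:``
    a list of such pairs) and ``acceptor:`` / ``acceptors:``; the other
    kinds use ``group_a`` / ``group_b`` selections.
    """
    kind = d["kind"]
    label = d["label"]
    if kind == "hbond":
        donors = d.get("donors") or [d["donor"]]
        acceptors = d.get("acceptors") or [d["acceptor"]]
        return InteractionSpec(
            kind=kind, label=label,
            donors=tuple((p["d"], p["h"]) for p in donors),
            acceptors=tuple(acceptors),
        )
    return InteractionSpec(kind=kind, label=label,
                           group_a=d["group_a"], group_b=d["group_b"])


@dataclass
class AnalysisConfig:
    """Inputs and options for one analysis run."""

    residue_map: str | Path | None = None
    interactions: list = field(default_factory=list)  # dicts or InteractionSpec
    preset: str = "paper-profile"
    cutoff_overrides: dict = field(default_factory=dict)
    references: StateReferences = DEFAULT_REFERENCES
    stride_ns: float = 1.0
    pose_reference: str | Path | None = None  # single-model PDB + same map
    rmsd_threshold: float = 2.0

    def cutoffs(self) -> Cutoffs:
        base = get_preset(self.preset)
        if self.cutoff_overrides:
            base = base.with_overrides(**self.cutoff_overrides)
        return base

    def specs(self) -> list[InteractionSpec]:
        return [s if isinstance(s, InteractionSpec) else interaction_spec_from_dict(s)
                for s in self.interactions]


def _round1(x: float) -> float:
    return round(x, 1)


def run_analysis(config: AnalysisConfig, trajectory_path: str | Path,
                 out_dir: str | Path,
                 rmap: ResidueMap | None = None,
                 traj: Trajectory | None = None) -> dict:
    """Run all configured stages; write CSV/JSON outputs; return the report.

    Partial outputs are removed if any stage fails. Percentages in the
    CSV tables are rendered to 1 decimal; the JSON report keeps the
    raw values alongside the rendered ones.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if traj is None:
            traj = read_multimodel_pdb(trajectory_path, stride_ns=config.stride_ns)
        if rmap is None:
            if config.residue_map is None:
                raise SelectionError("config needs a residue_map path")
            rmap = load_residue_map(config.residue_map)
        cutoffs = config.cutoffs()
        report: dict = {
            "trajectory": str(trajectory_path),
            "n_frames": len(traj),
            "stride_ns": config.stride_ns,
            "cutoffs_version": cutoffs.version,
        }

        # --- interaction occupancies
        specs = config.specs()
        occ_rows = []
        if specs:
            for series in interaction_series(traj, specs, cutoffs):
                rep = occupancy(series)
                occ_rows.append({
                    "label": rep.label,
                    "occupancy_percent": _round1(rep.occupancy_percent),
                    "n_frames": rep.n_frames,
                    "mean_dist": rep.mean_dist,
                    "min_dist": rep.min_dist,
                })
                report.setdefault("occupancy", {})[rep.label] = {
                    "occupancy_percent": rep.occupancy_percent,
                    "occupancy_percent_rendered": _round1(rep.occupancy_percent),
                    "n_frames": rep.n_frames,
                    "mean_dist": rep.mean_dist,
                    "min_dist": rep.min_dist,
                }
            p = out / "occupancy.csv"
            pd.DataFrame(occ_rows).to_csv(p, index=False)
            written.append(p)

        # --- microswitches
        ms = microswitch_series(traj, rmap, config.references, cutoffs)
        p = out / "microswitches.csv"
        ms.to_csv(p, index=False)
        written.append(p)
        fractions = (ms["label"].value_counts(normalize=True) * 100.0).to_dict()
        report["microswitches"] = {
            "label_percent": {k: fractions.get(k, 0.0)
                              for k in ("inactive", "intermediate", "active")},
            "mean_d_tm": float(ms["d_tm"].mean()),
            "mean_d_il": float(ms["d_il"].mean()),
            "toggle_class_percent": (ms["toggle_class"].value_counts(normalize=True)
                                     * 100.0).to_dict(),
        }

        # --- hydration (requires a Na+ ion in the topology)
        try:
            hyd = hydration_series(traj, rmap, cutoffs)
        except SelectionError:
            hyd = None
        if hyd is not None:
            p = out / "hydration.csv"
            hyd.to_csv(p, index=False)
            written.append(p)
            report["hydration"] = {
                "mean_first_shell": float(hyd["n_water_first_shell"].mean()),
                "channel_percent": float(hyd["channel"].mean() * 100.0),
                "asn_asp_hbond_percent": float(hyd["asn_asp_hbond"].mean() * 100.0),
            }

        # --- pose metrics (requires a reference structure)
        if config.pose_reference is not None:
            ref = read_multimodel_pdb(config.pose_reference)
            mapping = CoreMapping.from_reference(ref, rmap)
            rmsd = rmsd_i_series(traj, mapping, rmap)
            depth = depth_series(traj, rmap)
            p = out / "pose.csv"
            pd.DataFrame({"frame": range(len(traj)), "rmsd_i": rmsd,
                          "depth": depth}).to_csv(p, index=False)
            written.append(p)
            report["pose"] = {
                "fraction_rmsd_below_percent": fraction_below(rmsd, config.rmsd_threshold),
                "rmsd_threshold": config.rmsd_threshold,
                "mean_rmsd_i": float(rmsd.mean()),
                "mean_depth": float(depth.mean()),
            }

        p = out / "report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        written.append(p)
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def compare_systems(reports: list[dict], names: list[str] | None = None) -> pd.DataFrame:
    """Side-by-side table of >=2 run reports, ranked by mean insertion
    depth and by active-state fraction; ties keep input order."""
    if len(reports) < 2:
        raise ComparisonError("need at least two reports to compare")
    if names is None:
        names = [r.get("trajectory", f"system_{i}") for i, r in enumerate(reports)]
    label_sets = [set(r.get("occupancy", {})) for r in reports]
    shared = set.intersection(*label_sets) if label_sets else set()
    if all(ls for ls in label_sets) and not shared:
        raise ComparisonError("reports share no interaction labels")
    rows = []
    for name, rep in zip(names, reports):
        row = {"system": name}
        row["mean_depth"] = rep.get("pose", {}).get("mean_depth", float("nan"))
        row["fraction_rmsd_below_percent"] = rep.get("pose", {}).get(
            "fraction_rmsd_below_percent", float("nan"))
        row["active_percent"] = rep.get("microswitches", {}).get(
            "label_percent", {}).get("active", float("nan"))
        for label in sorted(shared):
            row[f"occ:{label}"] = rep["occupancy"][label]["occupancy_percent"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["depth_rank"] = df["mean_depth"].rank(ascending=False, method="min")
    df["active_rank"] = df["active_percent"].rank(ascending=False, method="min")
    return df.sort_values(["depth_rank", "system"], kind="stable").reset_index(drop=True)
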