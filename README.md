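# gpcrswitch

Post-processing toolkit for molecular-dynamics trajectories of class A
GPCRs, built around the question of how a ligand's binding pose —
especially its **insertion depth** in the orthosteric pocket — relates
to receptor activation. It was developed for photoswitchable
tryptamine ligands of the serotonin 5-HT2A receptor, where a single
methoxy-position change flips a compound between agonist-like and
antagonist-like behaviour, but the machinery is generic to any class A
receptor annotated with Ballesteros–Weinstein (BW) indices.

The package computes, per trajectory frame:

- **Interaction occupancies** — hydrogen bonds (D–A ≤ 3.5 Å,
  D–H⋯A ≥ 120°), salt bridges (min N–O ≤ 4.0 Å), hydrophobic contacts
  (≤ 4.5 Å) and π-stacking, reported as the percentage of frames in
  which each criterion holds.
- **Activation microswitches** — the Trp6.48 toggle rotamer (χ1, χ2),
  the Arg3.50–Glu6.30 ionic lock *d*<sub>IL</sub>, the TM3–TM6
  cytoplasmic gap *d*<sub>TM</sub> (Cα 3.50 ↔ Cα 6.34), and allosteric
  Na⁺ status, combined into an inactive/intermediate/active call by a
  3-of-4 vote against the canonical anchors
  (*d*<sub>TM</sub> ≈ 9 Å, *d*<sub>IL</sub> ≈ 4 Å, χ1 ≈ −80°, Na⁺
  bound ⇒ inactive; 12 Å, 16 Å, −160°, Na⁺ expelled ⇒ active).
- **Sodium-pocket hydration** — first-shell water count around Na⁺,
  the Asn7.49–Asp2.50 hydrogen bond, and water-channel detection from
  the extracellular vestibule to Asp2.50 by breadth-first search on the
  water O–O ≤ 3.5 Å graph.
- **Pose metrics** — RMSD<sub>i</sub> of the ligand indole core versus
  a reference agonist (LSD ergoline) core after receptor-frame Kabsch
  superposition, with the agonist-compatibility criterion
  RMSD<sub>i</sub> < 2 Å, plus the signed insertion depth of the core
  centroid along the receptor principal axis relative to Asp3.32.

Because full production trajectories for such studies are typically not
deposited, the package also ships a deterministic **synthetic fixture
generator** whose interaction occupancies, rotamer schedules,
microswitch distances, water placements and pose fractions are realised
exactly by construction — every pipeline stage is testable to equality
without any download. See `docs/methods.md` for the model, criteria
and limitations.

## Worked example

Generate a 200-frame synthetic trajectory that mixes inactive and
active receptor geometry with known interaction occupancies, then
analyse it:

```bash
gpcrswitch generate-fixture demo_combined --out fx
cat > cfg.yaml <<'YAML'
interactions:
  - label: "lig:N1H-Thr3.37"
    kind: hbond
    donor: {d: "resname LIG and name N1", h: "resname LIG and name H1"}
    acceptor: "resnum 160 and name OG1"
  - label: "lig:NT-Asp3.32"
    kind: salt_bridge
    group_a: "resname LIG and name NT"
    group_b: "resnum 155 and name OD1 or resnum 155 and name OD2"
pose_reference: src/gpcrswitch/data/reference_state_synthetic.pdb
YAML
gpcrswitch analyze fx/demo_combined.pdb --map fx/demo_combined_map.yaml \
    --config cfg.yaml --out run
```

The run directory contains `occupancy.csv`, `microswitches.csv`,
`hydration.csv`, `pose.csv` and `report.json`; the printed report
includes (abridged):

```json
{
  "hydration": {"channel_percent": 40.0, "mean_first_shell": 2.8},
  "microswitches": {"label_percent": {"active": 40.0, "inactive": 60.0,
                                      "intermediate": 0.0}},
  "occupancy": {
    "lig:N1H-Thr3.37": {"occupancy_percent": 70.0},
    "lig:NT-Asp3.32":  {"occupancy_percent": 99.0}
  },
  "pose": {"fraction_rmsd_below_percent": 75.0, "mean_depth": 1.5}
}
```

Reading: the indole N1–H hydrogen bond to Thr3.37 is present in 70.0%
of frames and the amine–Asp3.32 salt bridge in 99.0% (both equal to the
fixture's constructed ground truth); 60% of frames sit in the inactive
microswitch state and 40% in the active one; the sodium pocket carries
2 waters in the inactive segment and 4 in the active segment (mean
2.8), with a continuous vestibule-to-pocket water channel in the active
40% of frames; and 75.0% of frames have an agonist-compatible pose
(RMSD<sub>i</sub> < 2 Å) at a mean core depth of 1.5 Å below the
Asp3.32 anchor.

`gpcrswitch compare run1/report.json run2/report.json` ranks systems by
mean insertion depth and active-state fraction, and
`gpcrswitch presets` lists the frozen cutoff presets.

## Library use

```python
from gpcrswitch import (read_multimodel_pdb, load_residue_map,
                        microswitch_series, classify_state)
from gpcrswitch.synthetic import anchor_frames

inactive, active, rmap = anchor_frames()
df = microswitch_series(inactive, rmap)
print(df[["d_tm", "d_il", "chi1", "toggle_class", "label"]])
```

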