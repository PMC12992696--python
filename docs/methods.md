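# Methods

## Scope and model

`gpcrswitch` post-processes molecular-dynamics trajectories of a class A
GPCR (developed around the serotonin 5-HT2A receptor) to answer one
question: does a given ligand pose stabilise the inactive or the active
receptor state, and how deep does the ligand sit in the orthosteric
pocket? It computes four families of observables:

1. **Interaction occupancies.** Per-frame geometric detection of
   hydrogen bonds, salt bridges, hydrophobic contacts and pi-stacking,
   summarised as the percentage of frames in which the criterion holds.
2. **Activation microswitches.** The Trp6.48 toggle rotamer (chi1 =
   N-CA-CB-CG, chi2 = CA-CB-CG-CD1), the Arg3.50-Glu6.30 ionic-lock
   distance d_IL (minimum guanidinium-N to carboxylate-O), the TM3-TM6
   cytoplasmic gap d_TM (Calpha 3.50 to Calpha 6.34), and the allosteric
   Na+ status, combined into a discrete state call.
3. **Sodium-pocket hydration.** First-shell water count around Na+, the
   Asn7.49-Asp2.50 hydrogen bond, the Ser3.39 backup ligation, the
   Phe6.44 aromatic lid, and existence of a continuous water channel
   from the extracellular vestibule to Asp2.50.
4. **Pose metrics.** RMSD_i — the RMSD of the ligand's indole core
   against the reference agonist (LSD ergoline) core after superposing
   each frame's receptor onto a reference receptor frame — and the
   signed insertion depth of the core centroid along the receptor's
   principal axis relative to the Asp3.32 anchor Cgamma.

Residue roles are bound to concrete residues through a YAML annotation
config using Ballesteros-Weinstein indices, so the analysis is
independent of any particular construct numbering.

## Geometric criteria (the `paper-profile` preset)

All cutoffs live in a frozen, versioned preset; overrides are possible
but always change the recorded version string.

| criterion | default | rationale |
|---|---|---|
| H-bond | D-A <= 3.5 Å and D-H...A >= 120° | conventional MD geometric criterion |
| salt bridge | min N-O <= 4.0 Å | conventional |
| hydrophobic contact | min heavy-atom <= 4.5 Å | conventional |
| pi-stack | centroid <= 5.5 Å, planes <= 30° or 60-90° | parallel + T-shaped windows |
| Na+ first shell | Na-Ow <= 3.2 Å | first-minimum of Na-O RDF |
| Na+ bound | Na to Asp2.50 carboxylate O <= 3.2 Å | direct coordination |
| water-graph edge | O-O <= 3.5 Å | water-water H-bond distance |
| channel attachment | water to vestibule/sink <= 4.0 Å | first+part of second shell |
| Phe6.44 lid closed | ring centroid to Na+ <= 6.0 Å | robust to ring flips |

Ambiguous donors (Ser/Thr hydroxyls that can both donate and accept)
are handled by evaluating every configured donor/acceptor direction and
scoring the interaction present if any direction holds.

## State classification

Reference anchors: inactive (d_TM ≈ 9 Å, d_IL ≈ 4 Å, chi1 ≈ −80°, Na+
coordinated) versus active (d_TM ≈ 12 Å, d_IL ≈ 16 Å, chi1 ≈ −160°,
Na+ expelled). Each metric votes by nearest anchor using midpoint
thresholds (d_TM 10.5 Å, d_IL 10 Å); the toggle votes active for the
horizontal or downward rotamer classes and inactive for vertical/other;
Na+ votes inactive when bound. A frame is labelled `inactive` or
`active` on a 3-of-4 majority and `intermediate` otherwise; the score
is the active-vote fraction. Rotamer bins are half-open with the −120°
edge assigned to horizontal, so classification is deterministic at the
boundary. These thresholds are a codified reading of the anchor values —
the underlying studies publish anchors, not a classifier — and are
overridable in the analysis config.

## Numerical choices

- Dihedrals follow the IUPAC sign convention (cis = 0°, trans = +180°;
  the −180° branch is folded onto +180°), verified against MDAnalysis.
  Note that reversing the four-point order *preserves* the torsion;
  only mirror reflection negates it.
- Kabsch superposition enforces a proper rotation (det = +1) via the
  smallest-singular-value sign correction, so mirror fits can never
  flip ligand chirality. RMSD_i uses a fit on receptor atoms (default:
  Calpha of all TM-annotated residues) and evaluates on the ligand core
  without refitting; the pose criterion is strictly `RMSD_i < 2 Å`
  (boundary values count as not-below).
- The receptor axis is the first principal component of the TM Calpha
  cloud (>= 20 atoms required), sign-fixed so the extracellular
  vestibule projects negative; a near-degenerate cloud (top two
  singular values within 5%) is rejected rather than silently
  resolved.
- Water-channel existence is breadth-first search between
  vestibule-attached and Asp2.50-attached waters on the O-O <= 3.5 Å
  graph; the reported path length is the number of waters on a
  shortest connecting path. The "continuous channel" definition is an
  explicit geometric surrogate for what is usually judged visually.
- Moving averages are trailing means over `min(window, available)`
  frames (default window 20 frames), preserving series length.
- KDE uses a Gaussian kernel with Scott's rule (std · n^(−1/5)) or an
  absolute bandwidth in Å; zero-variance samples fall back to a fixed
  0.05 Å bandwidth with a warning. The default grid spans the samples
  ±5 bandwidths so the density integrates to 1 within 1e−3.
- Multi-model PDB parsing is fixed-column; HETATM is treated as ATOM;
  altlocs other than blank/'A' are dropped with a logged warning;
  coordinates round-trip at the format's 3-decimal precision. Waters
  are recognised as HOH/WAT/SOL/TIP3/OPC and ions by element or the
  NA+/SOD/CLA names, covering common force-field conventions. Frames
  are assumed pre-imaged; there is no periodic-boundary handling.
- Occupancies pool frames with equal weight when replicas are
  concatenated; per-replica tables can be produced by analysing
  replicas separately and comparing reports.

## The synthetic fixture generator

Full production trajectories for this class of study are rarely
deposited (typically only first/last frames), so the package ships a
generator that emulates the analysis-relevant features of such
trajectories with exactly controlled ground truth. The scaffold is a
~30-residue construction: a 7×4 Calpha pseudo-helix bundle (for the
axis and superposition), one residue per annotated role with just the
side-chain atoms the metrics need, a tryptamine-like ligand with a
planar 9-atom indole core, a Na+ ion, and a 13-water pool.

Targets are *constructed, not sampled*: an occupancy target f over n
frames satisfies the criterion in exactly round(f·n) frames chosen by a
seeded permutation (satisfied geometry: 2.8 Å at 165°; unsatisfied:
5.5 Å), rotamer targets place the Trp side chain at exact chi values by
internal-coordinate construction, distance targets translate the marker
atoms, and pose targets displace the ligand rigidly by 0.5 Å (below the
2 Å criterion) or 3.0 Å (above). Every frame then receives a seeded
random global rotation + translation (±5 Å), which leaves all internal
geometry invariant but makes the superposition and invariance
properties non-trivial. Identical spec + seed yields byte-identical
files.

The packaged fixture registry sets these ground truths to the headline
statistics of the study the package models (occupancies 70/99/43/66%,
pose fractions 78/75%, 2 vs 4 first-shell waters, the anchor state
tuples), at 1,000 frames per fixture — the scale at which the original
per-system analyses were reported (frames extracted every 1 ns from
microsecond trajectories). Because satisfaction patterns are exact,
recovering these numbers tests the full pipeline (geometry, detection,
counting, I/O round-trip) to equality rather than statistically.

What the fixtures deliberately do **not** emulate: force-field
dynamics, correlated frame-to-frame motion, thermal geometry noise
around the cutoffs, solvent density, or competing interactions.
Passing tests therefore demonstrate the *analysis* is correct and
deterministic, not that the physical conclusions of any particular
simulation would be reproduced.

## Known limitations

- The water-channel criterion considers water oxygens only; a channel
  bridged through protein polar atoms is not detected.
- `select_atoms` supports field equality with and/or (AND binds
  tighter); no ranges, wildcards or parentheses.
- Only multi-model PDB and a simple XYZ dialect are read; binary
  trajectory formats (XTC/TRR/DCD) are out of scope — convert upstream.
- The state classifier is a frame-wise vote; it does not model kinetics
  or free-energy barriers between states.
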