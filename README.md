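# memprobe

Trajectory analysis for peripheral membrane proteins in heterogeneous
bilayers: per-residue lipid-contact occupancy, interaction lifetimes and
multivalency, membrane insertion depth and tilt topology, lateral lipid
localization maps, and equilibration QC — plus a synthetic trajectory
generator that plants known contact kinetics and topology so every stage of
the pipeline can be verified against ground truth.

## The problem

The C1b domain of protein kinase C-δ anchors the kinase to the plasma
membrane after binding a diacylglycerol-type ligand (phorbol ester,
bryostatin, or analogues). Once inserted, the domain's basic and polar
residues exchange contacts with the headgroups of a compositionally complex
bilayer — phosphatidylserine (PS), -ethanolamine (PE), -choline (PC),
phosphatidylinositol phosphate (PIP), phosphatidic acid (PA), ceramide
(CER) and cholesterol (CHOL) — and the ligand modulates how deep and how
tilted the domain sits. Quantifying those interactions from MD trajectories
requires a small set of standard measurements, which this package
implements as a tested, reusable library:

- **Occupancy** of a tracked protein atom group with a lipid class: the
  fraction of frames in which any molecule of the class is within a
  distance cutoff, `occ = |{t : min_{a,b} d(a,b,t) ≤ r_c}| / T`, with
  `r_c = 6 Å` by default and minimum-image distances in an orthorhombic
  periodic box.
- **Interaction lifetimes**: durations of maximal runs of bound frames for
  one residue–lipid-molecule pair, with optional bridging of short unbound
  gaps; a pair is *transient* when its longest continuous interaction is
  < 10 ns or its total bound time is < 50 ns, *stable* otherwise.
- **Multivalency**: per-frame counts of how many residues engage one lipid
  and how many lipids engage one residue.
- **Insertion depth**: signed z-displacement of a reference atom (G253 Cα)
  from the mean plane of the protein-leaflet PS phosphates, positive toward
  the membrane midplane.
- **Tilt angle**: angle between the domain's long axis (centroid of an
  upper-third Cα set minus centroid of a lower-third set) and the membrane
  normal, folded to [0°, 90°].
- **Lateral maps**: 2D localization-frequency histograms of tracked lipid
  atoms in the protein-containing leaflet, with mean Cα overlay positions.
- **QC**: area per lipid, Cα RMSD vs time (Kabsch superposition), and
  linear-drift stability verdicts on equilibration series.

Because the underlying study's trajectories are available only on request,
the package ships a generator that emulates the analysis-relevant
statistics of such systems — a two-leaflet bilayer with per-leaflet class
counts, lateral lipid diffusion, and planted two-state (bound/unbound)
Markov binding episodes with prescribed stationary occupancy `p` and mean
lifetime `τ` (per-frame switch probabilities `q_off = dt/τ`,
`q_on = q_off·p/(1−p)`) — so every estimator can be checked against what
was planted.

## Worked example

Simulate 500 ns (5000 frames at 0.1 ns) of the phorbol-system membrane
(66/59 lipids per leaflet) with one planted K271–PS contact at 80%
stationary occupancy and 50 ns mean lifetime, then analyse it:

```python
import numpy as np
from memprobe import (
    SyntheticParams, ContactPlan, simulate_trajectory, synthetic_selections,
    compute_contacts, occupancy, lifetimes, classify_interaction,
    topology_series, topology_histogram,
)

params = SyntheticParams(
    n_frames=5000, dt=0.1, seed=7,
    contact_plan=[ContactPlan("K271", "PS", 0.8, 50.0)],
)
traj, truth = simulate_trajectory(params)
records = compute_contacts(traj, synthetic_selections(), cutoff=6.0)

occ = occupancy(records)
row = occ[(occ.protein_group == "K271") & (occ.lipid_class == "PS")]
print(f"K271-PS occupancy: {100 * row.occupancy_fraction.iloc[0]:.1f}%")

mol = next(iter(truth.contact_lipid_ids.values()))
rec = [r for r in records if r.protein_group == "K271" and r.lipid_molecule_id == mol][0]
ls = lifetimes(rec)
print(f"planted-pair lifetimes: {len(ls.segments)} segments, "
      f"mean {np.mean(ls.segments):.1f} ns, longest {ls.max_continuous:.1f} ns")
print(f"interaction class: {classify_interaction(ls)}")

ts = topology_series(traj)
hist = topology_histogram([ts])
print(f"insertion depth: {hist.mean_depth:.2f} A   tilt: {hist.mean_tilt:.1f} deg")
```

Output:

```
K271-PS occupancy: 82.3%
planted-pair lifetimes: 6 segments, mean 67.3 ns, longest 159.6 ns
interaction class: stable
insertion depth: 7.47 A   tilt: 47.9 deg
```

Reading the numbers: the class-level occupancy (82.3%) slightly exceeds the
planted pair's stationary 80% because occupancy uses union semantics — any
PS molecule diffusing within 6 Å counts. Six bound segments over 500 ns
with a 159.6 ns maximum put the pair comfortably in the *stable* class
(≥ 10 ns continuous and ≥ 50 ns total). The mean depth reads 7.47 Å
against a planted 8 Å: while the designated PS is bound it sits near the
protein, a few Å above its leaflet plane, which raises the PS-phosphate
reference plane — a real property of the depth definition, reproduced
faithfully by the generator.

## Command line

```bash
memprobe simulate --seed 42 --n-frames 1000 --out sim/        # + ground_truth.json
memprobe run --config run.yaml                                 # contacts → topology → heatmaps → qc
memprobe contacts --structure sim/structure.pdb --frames sim/frames.pdb \
    --selections sim/selections.yaml --cutoff 6.0 --out results/ --dt 0.1
```

`run` writes a manifest (config hash, per-stage outputs and row counts) and
aborts with the failing stage named on any error. For real CHARMM36
systems, a default selection file encoding the tracked-atom conventions
(lysine NZ, L250 backbone N, W252 NE1, cholesterol O3, phosphate and
carboxylate oxygens per class) ships in
`src/memprobe/data/selections_charmm36.yaml`; every token is overridable.

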