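# Methods

This note records the definitions, conventions and numerical choices behind
memprobe's measurements, what the synthetic generator does and does not
emulate, and the known limitations. Units throughout: Å for length, ns for
time, degrees for angles.

## Data model and units

Coordinates are stored internally in Å; GRO files (nm) are converted on
read, and mdtraj's nm-native arrays are scaled by 10. Boxes are
orthorhombic (three edge lengths); triclinic cells are rejected at
validation. A "molecule" is one residue of the topology (one lipid, or one
protein residue), which is the granularity leaflet assignment and contact
bookkeeping need. Chain identifiers are ignored; `residue_seq` plus
`residue_name` is the lookup key, following the single-chain construct
numbering of the target system (residues 230–280, probes at S240, P241,
H246, L250, W252, G253, K256, K260, D263, K271, K275, V276).

## Contacts

A contact is purely a distance criterion: minimum over all (probe atom,
lipid tracked atom) pairs of the minimum-image distance, compared against
an inclusive cutoff (default 6.0 Å, `d ≤ r_c`). No angular or chemical
criteria are applied; the underlying experimental convention describes
ionic interactions and hydrogen bonds by the same distance rule, and we do
not attempt to distinguish interaction chemistry. Where a residue's tracked
set names two atoms ("side-chain oxygen or amide nitrogen"), the minimum
over the set resolves the "or".

Minimum-image distances are applied throughout; `use_min_image=False` is
available for comparison with analyses that ignored periodicity. Distances
are computed exactly over all pairs (no cell lists) — the systems involved
are hundreds of particles, so correctness wins over asymptotics.

**Occupancy** of (residue group, lipid class) uses union semantics: a frame
counts when *any* molecule of the class is bound. This matches how
residue-by-class occupancies are reported in the field; per-molecule tables
are also emitted, and the per-molecule view is what estimator-recovery
tests check, since the planted two-state chain governs one designated
molecule.

**Lifetimes** are maximal runs of bound frames for one residue–molecule
pair; unbound gaps of at most `gap_tolerance_frames` (default 0) are
bridged, and bridged gap frames count toward the segment duration
(`duration = spanned frames × dt`). The default is no bridging; the knob
exists because frame stride changes apparent gap structure, and lifetime
estimates are stride-sensitive — segments shorter than the stride vanish,
so lifetimes from strided trajectories are biased long. Analyses should
state the stride used.

**Transient/stable rule**: transient iff `max_continuous < 10 ns` OR
`total_bound < 50 ns`; both thresholds are configurable. The boundary is
strict-less-than on both conditions.

**Multivalency** counts, per frame, residues engaging each lipid molecule
and lipid molecules engaging each residue; a frame is multivalent when
either count reaches 2 anywhere. Summaries are reported both as a fraction
of all frames and of bound frames.

**Replicate aggregation** follows the field's convention of mean ±
standard error of the mean across independent simulations; occupancy
tables carry a `replicate_id` column for that purpose.

## Leaflets, depth, tilt

**Leaflet assignment** is per-frame: a lipid is in the lower leaflet iff
the mean z of its headgroup atoms is below the midplane, defined as the
mean z of all lipid headgroup atoms in that frame. Per-frame assignment
(rather than a cached frame-0 assignment) keeps flip events and noisy
headgroups correct. Headgroup atom names per class default to CHARMM36
tokens (phosphate P for glycerophospholipids, O3 for cholesterol and
ceramide) and are fully overridable. This convention assumes the bilayer is
not split across the periodic z boundary, i.e. trajectories are imaged
with the membrane contiguous — the standard convention for membrane
post-processing.

**Insertion depth** is `s · (z_ref − z_plane)` where `z_ref` is the
reference atom's z (default: G253 Cα, since the backbone is the tracked
quantity; configurable), `z_plane` the mean z of PS phosphates *of the
protein-containing leaflet only* (depth against the opposite leaflet would
be meaningless), and `s` a sign chosen so that positive means displaced
from the phosphate plane toward the membrane midplane — deeper insertion —
regardless of which leaflet hosts the protein. Depth is emitted signed; an
atom outside the membrane gives negative values. Note a consequence of the
PS-plane definition: a PS molecule bound to the protein sits above its
leaflet plane and pulls the reference plane toward the protein, slightly
reducing measured depth while bound. This is a property of the definition,
not an artifact of the implementation.

**Tilt** is the angle between the lower-third→upper-third Cα-centroid axis
(upper set: residues 239, 241, 253, 255; lower set: 233, 246, 263, 276)
and the membrane normal z, folded to [0°, 90°] via |cos|. Upright = 0°.
The alternative reading — angle from the membrane plane — is available as
`convention="from_plane"`, but the normal-referenced convention is the
default because reported usage (larger angle described as "more tilted")
is only consistent with that reference.

**Topology histograms** pool per-frame (depth, tilt) pairs across
replicates into a 2D histogram. Bin widths are unspecified upstream;
defaults are 0.5 Å × 2°, exposed in config. Out-of-range frames are
clamped into the edge bins (and countable as such), so total counts always
equal frames aggregated.

## Lateral maps

Each frame, every tracked lipid atom whose parent lipid is assigned to the
chosen leaflet contributes one count at its (x, y) wrapped into the
primary box image. Out-of-grid positions are clamped into edge bins so the
count-conservation invariant (`total = Σ_frames tracked-in-leaflet atoms`)
holds exactly. Default grid: 1 Å bins over the mean box extent (bin size
unspecified upstream). Recentering on the protein Cα centroid (minimum-
image displacement from the centroid, binned on a centered grid) is
provided but off by default: lab-frame maps with a mean-Cα overlay match
the usual presentation, while recentering is the right choice when the
protein drifts laterally over hundreds of ns. Mean protein positions use
the same wrapping/recentering convention as the lipid map so overlay
points land in the same coordinate frame. No kernel smoothing is applied;
raw counts (or frequency normalisation summing to 1) are emitted.

## Geometry

Minimum-image displacement uses `δ − L·round(δ/L)` per axis, valid for
orthorhombic boxes and any input offset. Kabsch superposition is the SVD
closed form with reflection correction (smallest singular direction
flipped when `det < 0`), requiring N ≥ 3 non-collinear points; collinear
sets are rejected because the rotation about the line is underdetermined.
RMSD-vs-time QC uses Cα atoms by default, matching backbone-RMSD
equilibration practice; the atom subset is configurable.

## Stability (equilibration) checks

`stability_check` fits a line to the trailing window (default 50 ns) of a
series (area per lipid, insertion depth, RMSD) and calls the series
drifting when |slope| exceeds a tolerance in units/ns. The default
tolerance of 0.02 Å/ns was calibrated against correlated fluctuation about
a fixed mean: for AR(1) noise with lag-1 correlation φ = 0.9 and σ = 0.5 Å
sampled at 0.1 ns, the OLS slope standard error over a 50 ns window is
`σ·sqrt((1+φ)/(1−φ)) / (sqrt(n)·sd(t)) ≈ 0.007 Å/ns`, so 0.02 sits near
3σ — stationary noise is called stable in ≳ 99% of runs, while settling
drifts an order of magnitude larger are flagged. For series in other units
(e.g. Å² of area per lipid) the tolerance should be rescaled by the user.

## Synthetic generator

The generator emulates exactly the statistics the analysis measures, and
nothing else:

- **Composition**: per-leaflet class counts; defaults are the
  phorbol-system membrane (66 upper / 59 lower lipids across CHOL, PC, PE,
  PS, PA, PIP, CER). A largest-remainder builder converts mole fractions
  to integer counts that sum exactly per leaflet, with ties broken by
  class order. One published percentage (bryostatin membrane, upper
  leaflet PC = 15/73 = 20.55%, printed as 20%) disagrees with
  nearest-integer rounding — evidently forced to a 100% column sum — and
  is documented rather than resolved; likewise the round "25% cholesterol"
  of the source's introduction vs the tables' 21–24% per leaflet.
- **Lipids** are single headgroup pseudo-atoms on planes at ±20 Å (half
  thickness default 20 Å, placing phosphate planes on the scale where an
  8 Å insertion depth is meaningful) with iid z-jitter (σ 0.5 Å) and a
  lateral Gaussian random walk (σ 0.4 Å/frame/axis at dt 0.1 ns,
  equivalent to D ≈ 0.8 Å²/ns, typical of fluid-phase phospholipids),
  wrapped periodically in x/y. z is left unwrapped: the bilayer is centred
  at z = 0, matching the imaging convention the leaflet assignment
  assumes.
- **Protein** is a rigid pseudo-Cα scaffold (residues 230–280) whose
  upper/lower tilt-residue sets sit exactly at the ends of a 30 Å body
  axis, plus probe side-chain atoms named so default selections resolve.
  Per-frame placement draws tilt ~ N(48°, 5°) (clipped to [0°, 90°]) and
  depth ~ N(8 Å, 1 Å) — the deeper, more tilted of the study's reported
  topologies — and anchors G253's Cα at the realized PS-phosphate plane
  plus the drawn depth, so planted depth/tilt series are exactly
  recoverable by the analysis when no PS contact is planted.
- **Contacts** are two-state Markov chains per planted pair:
  `q_off = dt/τ`, `q_on = q_off·p/(1−p)`, started from stationarity, so
  the stationary bound probability is exactly `p` and bound-run lengths
  are geometric with mean `τ/dt` frames (the exact discrete mean `dt/q_off`
  is what recovery tests compare against, avoiding discretisation bias).
  While bound, the designated lipid is placed uniformly in a 2–5.5 Å shell
  around the probe atom (inside the 6 Å cutoff); while unbound it follows
  its random walk but is pushed radially beyond ~8.5 Å whenever it strays
  under 8 Å, so the planted bound series is exactly the measured one.
  Bivalent "bridge" episodes place one lipid 2 Å off the midpoint of two
  probe atoms, within the cutoff of both.
- **Determinism**: all randomness flows from one `numpy` Generator seeded
  by `SyntheticParams.seed`; equal seeds give byte-identical emitted files.

What the generator does **not** emulate: excluded volume (lipids may
overlap), any force field or energetics, membrane undulations, curvature
or thickness fluctuations, lipid flip-flop (planted leaflets are static),
protein conformational change, and — deliberately — the study's specific
occupancy percentages, which depend on 2.5 μs of all-atom MD that is not
redistributable. Passing tests therefore demonstrate that the estimators
recover known statistical structure from coordinates, not that real
membranes behave like the generator.

## Verification sizes and tolerances

Statistical recovery tests run at desk scale chosen to keep the full suite
under a minute of generator time: occupancy recovery uses 5 replicates ×
5000 frames (500 ns at dt 0.1 ns) per stationary level p ∈ {0.1, 0.5,
0.8}; lifetime recovery uses 10 × 10000 frames at τ = 100 ns; topology
recovery pools 5 × 500 frames. Tolerances are 3 standard errors with an
effective-sample-size correction for the chain's autocorrelation
(`n_eff = n(1−ρ)/(1+ρ)`, `ρ = 1 − q_on − q_off`); exact recoveries (bound
series, planted leaflets, depth/tilt series without PS contacts) are
asserted exactly or at float tolerance. Geometry is checked against
independent oracles: 27-image brute force for minimum-image distances
(exhaustive for points within the primary box) and a Nelder-Mead
minimisation over rotation vectors for Kabsch RMSD (agreement within
1e-6 Å).

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- Leaflet assignment assumes a z-contiguous membrane image and breaks on
  membranes split across the periodic z boundary.
- No PMF/free-energy estimation, no angular hydrogen-bond criteria, no
  order parameters, curvature or thickness maps.
- Binary trajectory formats (XTC/DCD) are supported only through mdtraj's
  optional readers behind the same contract; the test suite exercises
  text formats (PDB/GRO) exclusively.
- Lifetime estimates include segments truncated by the trajectory ends;
  for mean lifetimes approaching the trajectory length this biases the
  sample mean low.
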