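# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the design decisions taken where more than one reasonable
convention exists.

## Conventions and units

Lengths are nm, times ps, angles degrees, diffusion coefficients cm²/s.
PDB coordinates (Å) are converted at the I/O boundary.  The z axis is the
bilayer normal by convention; no normal estimation is performed.  Only
orthorhombic boxes are supported, and all inter-atomic distances use the
minimum-image convention uniformly (including ligand–protein minimum
distances, where the convention matters only when selections span the
box).  Residue numbering is 1-based as in the source file, so helix
ranges such as "residues 5–34" are file numbering.  Chain roles
(protein / POPC / POPE / cholesterol / water / ligand / ion) are assigned
from residue names through an editable mapping table; an unknown residue
name is an error rather than a silent default, because a misclassified
atom corrupts every role-based selection downstream.

## Superposition and RMSD

`kabsch_superpose` minimises weighted RMSD by SVD of the weighted
covariance matrix with the usual sign correction, so the returned
rotation is always proper (det = +1).  Weights default to uniform; mass
weighting is available but not the default.  Inputs with fewer than three
points, or with a vanishing second singular value (collinear
configurations, where the rotation is not unique), raise.  The all-to-all
matrix uses the centred-SVD identity RMSD² = (|a|² + |b|² − 2Σσᵢ)/n per
pair, which makes the matrix exactly symmetric with an exactly zero
diagonal.  A frame stride (default 10 in the matrix API, 1 in the
pipeline's desk-scale runs) bounds the O(F²) cost; the stride is recorded
in the result.

### Convergence diagnosis

The leave-and-return reading of an all-to-all RMSD matrix is inherently
visual; we fix a quantitative rule so it is testable.  Frames are
binarised as similar (RMSD ≤ cutoff, default 0.2 nm on Cα — a declared
convention, not a literature value) and the run is split at the boundary
maximising the pooled fraction of similar within-block pairs.  Let the
*early block* be everything before the boundary.  A frame *leaves* when
it is dissimilar to every early frame; a later frame *returns* when it is
again similar to an early frame.  The verdict is:

- `leave_and_return` — at least one frame left and a later frame
  returned;
- `irreversible_transition` — frames left, none returned, and the
  cross-block similar fraction is below 0.05;
- `undetermined` — otherwise.  In particular an all-similar (constant)
  run is undetermined: nothing was ever left, so the pattern is vacuous.

The cross-block similar fraction is reported as `block_overlap_score`.
On constructed two-state fixtures the verdict is invariant under
subsampling frames by two.

### RMSF

Frames are iteratively superposed on the running mean of an alignment
selection (2–3 iterations suffice; capped at 5), then per-atom RMS
fluctuation about the mean position is reported.  A separate rigid
alignment selection lets mobile-atom fluctuations be measured without the
fit absorbing part of the motion.  This plain RMSF is provided as
plumbing; no *per-residue flexibility index* beyond it is implemented.

## Ligand analyses

**Pose clustering.**  The pairwise pose distance between frames i and j
is the RMSD over the ligand selection after superposing frame j onto
frame i on the alignment selection (protein backbone), without a second
fit on the ligand — the pose is defined *relative to the receptor frame*.
Clustering is the greedy neighbour-count algorithm: the frame with the
most neighbours within the cutoff (default 0.2 nm) becomes a centre, the
cluster is removed, repeat.  Ties in neighbour count break toward the
lower frame index for reproducibility.  Clusters are renumbered by
decreasing size; populations are % of analysed frames and sum to 100 by
construction; each cluster's representative is the member minimising the
mean RMSD to the other members.  Analyses meant to represent the
equilibrated part of a run use a trailing window (`last_fraction`,
default 0.5).

**Flipping angle.**  The ligand orientation vector μ is the unit vector
from the centroid of the six-membered ring to the centroid of the
five-membered ring of the xanthine bicyclic core (atom names
configurable).  This choice is deterministic, lies in the core plane, and
is stable to coordinate jitter.  The reported angle is
arccos(μ_τ·μ_ι) with the dot product clamped to [−1, 1]; the angle at
the reference frame is 0 by construction, and the series is invariant
under a joint rigid rotation of ligand and reference.

**COM cloud.**  Every frame is superposed on the reference frame using
the backbone, then the mass-weighted ligand centroid is recorded; the
cloud's per-axis SD and radius of gyration summarise ligand mobility net
of rigid-body motion of the complex.

**Cavity hydration.**  The cavity box is the axis-aligned bounding box of
the cavity-defining residues plus symmetric padding (default 0.15 nm —
the box definition gives residues but no margin, so the padding is a
package choice, configurable).  The box is computed once on a reference
structure and held fixed; frame-wise boxes would make counts
non-comparable.  A water counts when its oxygen lies inside the box with
inclusive bounds; hydrogens are ignored.

## Membrane analyses

**Density profile and thickness.**  z is measured from the instantaneous
midplane (mean z of all lipid phosphorus), making the profile invariant
under rigid z-translation.  The histogram is normalised to number density
(nm⁻³) so that its integral times the lateral box area recovers the mean
selected-atom count to 1e-6 relative.  Thickness is the distance between
the density-weighted mean z of the upper (z > 0) and lower (z < 0)
leaflets; the peak-to-peak distance is also reported.  A profile with no
mass on one side is rejected ("no bilayer detected").  Bin width defaults
to 0.1 nm, so a literal delta-function leaflet is recovered to within one
bin.

**Area per lipid.**  Each leaflet (sign of z relative to the phosphate
midplane) is handled separately.  Every cell of an n×n lateral grid
(default 100×100) is assigned to the laterally nearest reference atom —
one phosphorus per lipid, plus protein heavy atoms lying within ±0.5 nm
of the leaflet's mean phosphate z — using xy minimum-image distances.  A
lipid's area is its cell count times the cell area, so per-leaflet areas
plus the protein-assigned area sum to the box area exactly, every frame.
A lipid receiving zero cells (possible when non-interacting fixture
lipids overlap) is recorded with a warning.  The APL is the mean over
lipids, then frames.  Grid resolution limits per-lipid accuracy to about
one cell ring; on an unjittered lattice the assignment is exact.

**Headgroup tilt.**  P and N atoms are paired per residue id (exactly one
each per lipid; anything else raises).  Φ_PN = arccos(P̂N·n̂) with n̂ the
leaflet's outward normal (+z upper, −z lower), so the two leaflets are
statistically equivalent and a bilayer-symmetric distribution folds onto
a single [0°, 180°] axis.  Per-type normalised distributions and sample
means are provided.

**Hydrogen bonds.**  The geometric criterion is d(D–A) ≤ 0.35 nm and
∠(H–D–A) ≤ 30°, the convention of the major MD analysis suites; both are
configurable since the criterion is not uniquely standard.  Occupancies
are, per class of role pairs (protein↔lipid, lipid↔lipid,
lipid↔solvent), the frame-averaged bond count divided by the number of
acceptor oxygens carrying a role of that class; a class without acceptor
oxygens raises rather than reporting 0/0.

**Lateral diffusion.**  Reference-atom xy tracks are unwrapped by mapping
each per-frame displacement to its minimum image (valid while true
per-frame motion stays below half the box; the generator enforces a 5σ
margin).  MSD(Δ) averages over all molecules and time origins; MSD is
averaged first and fitted once, rather than fitting per molecule and
averaging the fits.  The fit window defaults to 10–50% of the maximum
lag, excluding the short-lag noise-dominated and long-lag
poorly-sampled regimes; D = slope/4 (2-D Einstein relation), converted
with the exact chain 1 nm² = 10⁻¹⁴ cm², 1 ps = 10⁻¹² s ⇒ 1 nm²/ps =
10⁻² cm²/s, which is encoded as a single tested constant.  A negative
fitted slope yields D = 0 with a warning flag.  Proximity
classification: a molecule is *proximal* when any of its atoms is within
0.35 nm of any protein atom in at least one analysed frame — "during the
dynamics" is read as *ever*; a per-frame mode is exposed for users who
want a time-resolved label.

## Helicity

Residue i is helical when the window w = i − 2 satisfies
d(Cα_w, Cα_w+4) ∈ [0.50, 0.65] nm — the Cα(i, i+4) distance band of an
α-helix — over a run of at least three consecutive windows; window-edge
residues (the first and last two) are always coil, and the helix fraction
is taken over the interior residues.  A consecutive-Cα distance above
0.45 nm is treated as a chain break: affected windows are disqualified
and the flanking residues set to coil with a warning.  This deliberately
replaces a full secondary-structure assignment: it needs neither backbone
hydrogens nor H-bond energetics, works on Cα-only traces, and detects
the one event the package cares about, a helix→coil transition.  It does
not distinguish sheets, turns or bends.

## Synthetic systems

The generator's defaults are the study conditions the analyses are
validated against: area per lipid 0.61 nm² with phosphate leaflets at
±1.9 nm (a typical POPC leaflet height giving ~3.8 nm thickness);
POPC tilt 90° ± 36° and POPE 90° ± 28°; 20 ps between stored frames;
pose weights (0.924, 0.038, 0.038) emulating a single dominant binding
pose; 16 cavity waters; lateral diffusion 5×10⁻⁸ (protein-proximal) and
8×10⁻⁸ (free) cm²/s.  Tilt angles are drawn from a normal about the mean
folded into [0°, 180°] (reflection at the axis limits) with uniform
azimuth; the P→N vector length is 0.45 nm.  Desk-scale sizes (tens to
hundreds of lipids, hundreds of frames) keep the full test suite in
seconds; statistical recovery tests state their own n.

Pseudo-lipids are beads (P, a phosphate oxygen, N, an amine hydrogen on
POPE, two tail beads), not atomistic molecules; Brownian lipids do not
interact with each other or with the protein column; the pose-hopping
ligand has no dwell-time correlation unless configured; the helix trace
has no side chains.  Consequently, passing recovery tests demonstrates
the *analysis machinery* is unbiased on data with the assumed statistical
structure — it does not validate force fields, sampling, or any physical
claim about real membranes.

Determinism: a seed is mandatory, and each generator operation draws from
its own RNG stream seeded by (master seed, op tag), so adding one op
never perturbs another's output; identical configs give bit-identical
trajectories.

## Pipeline

`run_pipeline` executes convergence → helicity on a helix-trace
subsystem, the ligand battery (with the trailing-window restriction) on a
receptor–ligand subsystem, and the membrane battery on a protein-in-
bilayer subsystem — generated from the seed, or read from user-supplied
files whose SHA-256 hashes then enter the report.  Every threshold is
echoed into the report, which contains no timestamp, so identical config
and seed reproduce it byte for byte.  When the user does not fix a
membrane composition, the membrane subsystem defaults to an equally mixed
POPC/POPE bilayer so that all three H-bond classes are populated.  The
H-bond stage runs on every 10th frame of the membrane subsystem; all
other stages use all frames at desk scale.

## Known limitations

Triclinic boxes, velocities, bond perception and XTC-native parsing
(beyond the optional mdtraj-backed hook) are out of scope.  The
convergence verdict on real data depends on the similarity cutoff, which
published matrices rarely state; 0.2 nm is this package's declared
default.  The grid APL attributes boundary cells entirely to their
nearest reference atom; per-lipid areas are grid-quantised even though
the leaflet total is exact.  Pose populations from a finite run carry
binomial noise; the clustering recovers the realised pose sequence, not
the underlying mixture weights.
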