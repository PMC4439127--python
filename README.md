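# memtraj

Trajectory analysis for molecular-dynamics studies of membrane proteins —
written for the common study design in which a ligand-bound G-protein
coupled receptor is simulated in several lipid bilayers (pure POPC, mixed
POPC/POPE, cholesterol-rich) and the question is how membrane composition
shifts ligand binding-pose populations, receptor fold stability and
bilayer structure.

It is a library first: the importable API plus the short narrative
scripts in `examples/` are the main interface, with a thin `memtraj`
command for running the whole battery from a shell.  Because production
trajectories of this kind are rarely deposited, the package ships a
deterministic synthetic-system generator (`memtraj.synthgen`) that
produces bilayers, Brownian lipids, pose-hopping ligands, helix traces
and cavity waters with *known* ground truth, so every analysis stage is
validated by parameter recovery.

## What it computes

- **Superposition & convergence** — Kabsch least-squares superposition
  (proper rotations only), RMSD/RMSF, all-to-all Cα RMSD matrices, and a
  quantitative version of the classic visual convergence diagnosis: a
  run whose matrix shows frames that *leave and return* to an early
  similarity block is converged-like, while two non-overlapping blocks
  signal an irreversible conformational transition.
- **Ligand analyses** — greedy neighbour-count ("Gromos") pose clustering
  on ligand heavy atoms after protein-backbone alignment, with cluster
  populations in % of frames; orientational flipping angle
  arccos(μ_τ·μ_ι) of an in-plane bicyclic-core axis; centre-of-mass
  cloud in the receptor-aligned frame; water count in a fixed
  cavity-bounding box; minimum-distance and contact-occupancy series.
- **Membrane analyses** — phosphate density profile along the bilayer
  normal and the leaflet-to-leaflet thickness; grid-based area per lipid
  (each cell of a lateral grid is assigned to the nearest lipid
  phosphorus or protein heavy atom, so cell areas are conserved exactly);
  P→N headgroup tilt Φ_PN = arccos(P̂N·ẑ) with leaflet-symmetric
  normals; geometric hydrogen bonds (d(D–A) ≤ 0.35 nm, ∠H–D–A ≤ 30°) and
  per-class occupancies per acceptor oxygen; lateral diffusion from the
  2-D Einstein relation MSD(Δ) = 4DΔ, with molecules split into
  protein-*proximal* (ever within 0.35 nm of the protein) and *free*.
- **Helicity timeline** — a geometric helix/coil assignment from the
  Cα(i, i+4) distance signature, sufficient to detect partial unfolding
  of an interfacial helix.

Formats: PDB (Å, `CRYST1`/`MODEL`) and GRO (nm, fixed column), single
frames or multi-model/concatenated trajectories; orthorhombic boxes;
minimum-image convention throughout.  Internal units are nm, ps, degrees.

## Worked example

Recovering pose populations from a synthetic receptor–ligand trajectory
whose pose sequence is drawn with weights (0.924, 0.038, 0.038):

```python
from memtraj import ChainRole, SelectionSpec, gromos_cluster
from memtraj.synthgen import SynthConfig, make_ligand_traj, make_receptor

cfg = SynthConfig(seed=2, n_frames=500,
                  pose_weights=(0.924, 0.038, 0.038), pose_jitter=0.02)
traj = make_ligand_traj(cfg, make_receptor(cfg))
out = gromos_cluster(traj,
                     SelectionSpec(roles=(ChainRole.PROTEIN,), atom_names=("CA",)),
                     SelectionSpec(roles=(ChainRole.LIGAND,)), cutoff=0.2)
print([round(p, 1) for p in out.populations])
```

prints `[91.6, 4.6, 3.8]` — exactly the realised pose frequencies of this
finite draw (the weights themselves up to binomial noise), recovered
through backbone alignment, pairwise ligand RMSD and greedy clustering.
Populations always sum to 100%.

The diffusion pipeline on the same seed conventions
(`examples/04_lateral_diffusion.py`) prints

```
proximal : n=  9  D = 4.33e-08 cm^2/s  (r^2 = 0.993)
free     : n=111  D = 7.02e-08 cm^2/s  (r^2 = 1.000)
```

for molecules generated at 5e-8 and 8e-8 cm²/s: the proximal/free split
and the Einstein-relation fit resolve the slowdown of lipids in contact
with the protein.

Run every capability end to end with

```sh
memtraj all --seed 5 --out-dir out/     # JSON report + artifacts
```

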