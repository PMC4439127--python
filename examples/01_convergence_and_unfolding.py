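"""Convergence diagnosis and helix unfolding on a programmed trace.

Builds a 100-frame Cα trace of a 60-residue helix that unfolds its second
half at frame 50, computes the all-to-all RMSD matrix, and reads off the
block structure and the helicity timeline.
"""

import numpy as np

from memtraj import (
    ChainRole,
    SelectionSpec,
    assign_helicity,
    diagnose_convergence,
    pairwise_rmsd_matrix,
)
from memtraj.synthgen import SynthConfig, make_helix_trace

CA = SelectionSpec(roles=(ChainRole.PROTEIN,), atom_names=("CA",))

cfg = SynthConfig(seed=1, n_frames=100, n_residues=60, unfold_frame=50)
traj = make_helix_trace(cfg)

matrix = pairwise_rmsd_matrix(traj, CA, stride=1)
report = diagnose_convergence(matrix, cutoff=0.2)
print(f"verdict: {report.verdict.value}")
print(f"block boundary at frame {report.block_boundaries[0]}, "
      f"cross-block similarity {report.block_overlap_score:.3f}")
# An irreversible transition shows two non-overlapping similarity blocks;
# a converged-like run would instead leave and return to the same basin.

timeline = assign_helicity(traj, CA)
frac = timeline.helix_fraction
drop = int(np.argmax(np.abs(np.diff(frac)))) + 1
print(f"helix fraction: {frac[:50].mean():.2f} before, "
      f"{frac[50:].mean():.2f} after; largest drop at frame {drop}")
# The drop frame recovers the programmed unfolding event; roughly half the
# chain leaves the alpha-helical Cα(i, i+4) distance band.
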