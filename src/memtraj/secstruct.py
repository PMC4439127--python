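"""Simplified per-residue helicity timeline from a Cα trace.

A residue is called helical from the Cα(i, i+4) distance signature of an
α-helix — d(Cα_i, Cα_i+4) in [0.50, 0.65] nm — sustained over a run of at
least three consecutive windows.  This is a geometric stand-in for a full
secondary-structure assignment: it needs no backbone hydrogens or H-bond
energies, and it is sufficient to detect a helix -> coil transition such
as the partial unfolding of an amphipathic interfacial helix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_io import SelectionSpec, Trajectory, select_atoms

HELIX_D14_MIN = 0.50   # nm, Cα(i, i+4) distance band of an α-helix
HELIX_D14_MAX = 0.65
CHAIN_BREAK_D = 0.45   # nm, max plausible consecutive Cα distance
MIN_RUN = 3            # consecutive qualifying windows required


@dataclass
class HelicityTimeline:
    """Per-frame per-residue helix/coil states.

    States are defined for interior residues 3..N-2 (0-based columns
    2..N-3); window-edge residues are always coil.  ``helix_fraction`` is
    taken over the interior residues.
    """

    states: np.ndarray          # (n_frames, n_residues) bool, True = helix
    helix_fraction: np.ndarray  # per frame, over interior residues

    def to_tsv(self, path: str | Path) -> None:
        lines = ["frame\tresidue\tstate"]
        for k in range(self.states.shape[0]):
            for r in range(self.states.shape[1]):
                lines.append(f"{k}\t{r + 1}\t{'helix' if self.states[k, r] else 'coil'}")
        Path(path).write_text("\n".join(lines) + "\n")

    def fraction_tsv(self, path: str | Path) -> None:
        lines = ["frame\thelix_fraction"]
        lines += [f"{k}\t{f:.4f}" for k, f in enumerate(self.helix_fraction)]
        Path(path).write_text("\n".join(lines) + "\n")


def assign_helicity(traj: Trajectory, ca_spec: SelectionSpec) -> HelicityTimeline:
    """Helix/coil assignment per residue per frame from Cα geometry.

    Residue i (1-based) is helix iff its centred window w = i-2 satisfies
    d(Cα_w, Cα_w+4) in the α-band and belongs to a run of >= 3 consecutive
    qualifying windows.  A consecutive-Cα distance above 0.45 nm is a
    chain break: windows spanning it are disqualified and the flanking
    residues forced to coil (with a warning).
    """
    idx = select_atoms(traj.topology, ca_spec)
    n = idx.size
    if n < 5:
        raise ValueError("helicity needs at least 5 consecutive Cα positions")
    coords = traj.xyz[:, idx, :]
    f = traj.n_frames
    states = np.zeros((f, n), dtype=bool)
    warned = False
    for k in range(f):
        d1 = np.linalg.norm(np.diff(coords[k], axis=0), axis=1)   # (n-1,)
        breaks = d1 > CHAIN_BREAK_D
        d4 = np.linalg.norm(coords[k, 4:] - coords[k, :-4], axis=1)  # (n-4,)
        ok = (d4 >= HELIX_D14_MIN) & (d4 <= HELIX_D14_MAX)
        if breaks.any():
            if not warned:
                warnings.warn("chain break detected; flanking residues set to coil")
                warned = True
            for b in np.flatnonzero(breaks):
                lo = max(0, b - 3)
                ok[lo:b + 1] = False
        # runs of >= MIN_RUN consecutive qualifying windows
        run_start = 0
        for w in range(n - 4 + 1):
            if w < n - 4 and ok[w]:
                continue
            run_len = w - run_start
            if run_len >= MIN_RUN:
                # window w0 marks its centre residue w0+2 (0-based)
                states[k, run_start + 2: run_start + run_len + 2] = True
            run_start = w + 1
    interior = slice(2, n - 2)
    frac = states[:, interior].mean(axis=1)
    return HelicityTimeline(states=states, helix_fraction=frac)
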