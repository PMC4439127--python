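"""Ligand-centric analyses: binding-pose clustering and populations,
orientational flipping angle, centre-of-mass cloud, cavity hydration and
minimum-distance/contact series.

Pose clustering follows the classic greedy neighbour-counting algorithm
("Gromos clustering"): the frame with the most neighbours within the RMSD
cutoff becomes a cluster centre, the cluster is removed, and the procedure
repeats on the remainder.  Pose RMSDs are computed on the ligand heavy
atoms after superposing each frame onto the reference on the protein
backbone, so rigid-body motion of the whole complex never creates spurious
poses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_io import (
    Frame,
    SelectionSpec,
    Trajectory,
    pairwise_min_image_distances,
    select_atoms,
)
from .superpose import kabsch_superpose, rmsd

#: Ring atom names of a xanthine bicyclic core (six-membered ring, then the
#: five-membered imidazole ring; C4/C5 are the fusion atoms).
XANTHINE_SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
XANTHINE_FIVE_RING = ("C4", "C5", "N7", "C8", "N9")


@dataclass
class PoseClustering:
    """Greedy-clustering result; cluster 1 is the most populated."""

    cluster_labels: np.ndarray        # per analysed frame, 1-based
    populations: np.ndarray           # per cluster, % of frames
    representatives: np.ndarray       # central frame index per cluster
    cutoff: float
    frame_indices: np.ndarray         # analysed frame indices in the source traj

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def populations_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "cutoff_nm": self.cutoff,
            "populations_percent": {str(i + 1): float(p)
                                    for i, p in enumerate(self.populations)},
            "representative_frames": {str(i + 1): int(r)
                                      for i, r in enumerate(self.representatives)},
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def assignments_tsv(self, times: np.ndarray, path: str | Path) -> None:
        lines = ["frame\ttime_ps\tcluster"]
        for k, (fi, lab) in enumerate(zip(self.frame_indices, self.cluster_labels)):
            lines.append(f"{int(fi)}\t{times[k]:g}\t{int(lab)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _pose_rmsd_matrix(traj: Trajectory, align_spec: SelectionSpec,
                      cluster_spec: SelectionSpec) -> np.ndarray:
    """Pairwise ligand RMSD after per-pair backbone alignment."""
    ai = select_atoms(traj.topology, align_spec)
    ci = select_atoms(traj.topology, cluster_spec)
    if ai.size == 0 or ci.size == 0:
        raise ValueError("alignment and cluster selections must be non-empty")
    f = traj.n_frames
    align = traj.xyz[:, ai, :]
    clust = traj.xyz[:, ci, :]
    m = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            rot, trans, _ = kabsch_superpose(align[j], align[i])
            moved = clust[j] @ rot.T + trans
            m[i, j] = m[j, i] = rmsd(moved, clust[i], superpose=False)
    return m


def gromos_cluster(traj: Trajectory, align_spec: SelectionSpec,
                   cluster_spec: SelectionSpec, cutoff: float = 0.2) -> PoseClustering:
    """Greedy neighbour-count pose clustering with an RMSD ``cutoff`` (nm).

    Ties in neighbour count are broken toward the lower frame index so the
    result is reproducible.  Clusters are renumbered by decreasing size;
    each cluster's representative is the member with the smallest mean RMSD
    to the other members.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = _pose_rmsd_matrix(traj, align_spec, cluster_spec)
    f = dist.shape[0]
    neighbours = dist <= cutoff
    remaining = np.ones(f, dtype=bool)
    raw_clusters: list[np.ndarray] = []
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbours[center] & remaining)
        raw_clusters.append(members)
        remaining[members] = False
    order = sorted(range(len(raw_clusters)),
                   key=lambda k: (-len(raw_clusters[k]), raw_clusters[k][0]))
    labels = np.zeros(f, dtype=int)
    populations = np.zeros(len(order))
    representatives = np.zeros(len(order), dtype=int)
    for new_id, k in enumerate(order, start=1):
        members = raw_clusters[k]
        labels[members] = new_id
        populations[new_id - 1] = 100.0 * len(members) / f
        sub = dist[np.ix_(members, members)]
        representatives[new_id - 1] = members[int(np.argmin(sub.mean(axis=1)))]
    return PoseClustering(cluster_labels=labels, populations=populations,
                          representatives=representatives, cutoff=cutoff,
                          frame_indices=np.arange(f))


@dataclass
class FlippingSeries:
    """Ligand orientation relative to the first analysed frame."""

    reference_vector: np.ndarray
    angles: np.ndarray  # degrees, [0, 180]

    def to_tsv(self, times: np.ndarray, path: str | Path) -> None:
        lines = ["frame\ttime_ps\tangle_deg"]
        for k, a in enumerate(self.angles):
            lines.append(f"{k}\t{times[k]:g}\t{a:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _ring_vector(coords: np.ndarray, six_idx: np.ndarray, five_idx: np.ndarray) -> np.ndarray:
    v = coords[five_idx].mean(axis=0) - coords[six_idx].mean(axis=0)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ValueError("degenerate (zero-length) orientation vector")
    return v / norm


def flipping_angle(traj: Trajectory, ligand_spec: SelectionSpec,
                   reference_frame: int = 0,
                   ring_a: tuple[str, ...] = XANTHINE_SIX_RING,
                   ring_b: tuple[str, ...] = XANTHINE_FIVE_RING) -> FlippingSeries:
    """Orientational flipping angle arccos(mu_tau . mu_iota) in degrees.

    The orientation vector mu is the unit vector from the centroid of
    ``ring_a`` to the centroid of ``ring_b`` within the ligand selection —
    an in-plane axis of the bicyclic core that is deterministic and stable
    to coordinate jitter.  The angle at the reference frame is 0.
    """
    lig = select_atoms(traj.topology, ligand_spec)
    names = traj.topology.atom_names[lig]
    six_idx = np.array([np.flatnonzero(names == n)[0] for n in ring_a])
    five_idx = np.array([np.flatnonzero(names == n)[0] for n in ring_b])
    coords = traj.xyz[:, lig, :]
    mu_ref = _ring_vector(coords[reference_frame], six_idx, five_idx)
    angles = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        mu = _ring_vector(coords[k], six_idx, five_idx)
        angles[k] = np.degrees(np.arccos(np.clip(mu @ mu_ref, -1.0, 1.0)))
    return FlippingSeries(reference_vector=mu_ref, angles=angles)


@dataclass
class ComCloud:
    """Per-frame ligand centre of mass in the receptor-aligned frame."""

    positions: np.ndarray  # (n_frames, 3) nm

    @property
    def mean(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def per_axis_sd(self) -> np.ndarray:
        return self.positions.std(axis=0)

    @property
    def radius_of_gyration(self) -> float:
        c = self.positions - self.mean
        return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def com_cloud(traj: Trajectory, align_spec: SelectionSpec,
              ligand_spec: SelectionSpec, reference_frame: int = 0) -> ComCloud:
    """Mass-weighted ligand COM per frame after receptor alignment.

    Every frame is superposed onto the reference frame on ``align_spec``
    (typically the protein backbone) so the cloud reflects genuine ligand
    mobility inside the cavity, not rigid-body motion of the complex.
    """
    ai = select_atoms(traj.topology, align_spec)
    li = select_atoms(traj.topology, ligand_spec)
    if ai.size == 0 or li.size == 0:
        raise ValueError("alignment and ligand selections must be non-empty")
    masses = traj.topology.masses[li]
    w = masses / masses.sum()
    ref = traj.xyz[reference_frame, ai, :]
    out = np.empty((traj.n_frames, 3))
    for k in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.xyz[k, ai, :], ref)
        lig = traj.xyz[k, li, :] @ rot.T + trans
        out[k] = w @ lig
    return ComCloud(positions=out)


@dataclass
class CavityBox:
    """Axis-aligned box around the binding cavity, held fixed over frames."""

    center: np.ndarray
    half_extents: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float).reshape(3)
        self.half_extents = np.asarray(self.half_extents, float).reshape(3)
        if not np.all(self.half_extents > 0):
            raise ValueError("half-extents must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d = np.abs(np.atleast_2d(points) - self.center)
        return np.all(d <= self.half_extents + 1e-12, axis=1)


def cavity_box_from_residues(frame: Frame, topology, residues: SelectionSpec,
                             padding: float = 0.15) -> CavityBox:
    """Bounding box of the cavity-defining residues plus symmetric padding.

    The box is computed once (conventionally on a time-averaged structure)
    and then held fixed, so water counts are comparable across frames.
    """
    idx = select_atoms(topology, residues)
    if idx.size == 0:
        raise ValueError("cavity residues resolve to no atoms")
    pts = frame.coordinates[idx]
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    half = (hi - lo) / 2.0
    half = np.maximum(half, 1e-9)  # single-atom box degenerates without padding
    return CavityBox(center=(hi + lo) / 2.0, half_extents=half)


def count_cavity_waters(traj: Trajectory, box: CavityBox,
                        water_spec: SelectionSpec) -> tuple[np.ndarray, float]:
    """Water molecules inside the cavity box per frame, and the mean.

    A water counts when its oxygen lies inside the box (inclusive bounds);
    hydrogens are ignored.
    """
    wi = select_atoms(traj.topology, water_spec)
    oxy = wi[np.char.startswith(traj.topology.atom_names[wi].astype(str), "O")]
    counts = np.array([int(box.contains(traj.xyz[k, oxy, :]).sum())
                       for k in range(traj.n_frames)])
    return counts, float(counts.mean())


def min_distance_series(traj: Trajectory, spec_a: SelectionSpec,
                        spec_b: SelectionSpec) -> np.ndarray:
    """Per-frame minimum over all a-b pairs of the minimum-image distance (nm)."""
    ia = select_atoms(traj.topology, spec_a)
    ib = select_atoms(traj.topology, spec_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both selections must be non-empty")
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        d = pairwise_min_image_distances(traj.xyz[k, ia, :], traj.xyz[k, ib, :],
                                         traj.boxes[k])
        out[k] = d.min()
    return out


def contact_occupancy(series: np.ndarray, threshold: float) -> float:
    """Fraction of frames with minimum distance <= ``threshold`` (nm)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    series = np.asarray(series, float)
    return float((series <= threshold).mean())
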