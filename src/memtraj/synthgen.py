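"""Synthetic molecular systems with known ground truth.

Every analysis stage in the package assumes a particular statistical
structure in its input — a lattice bilayer with a known area per lipid,
headgroup vectors with a known tilt distribution, lipids performing 2-D
Brownian motion with a known diffusion coefficient, a ligand hopping
between reference poses with known mixture weights, a helical trace with a
programmed unfolding event, a cavity holding an exact number of waters.
This module generates such systems deterministically from a seed, so each
generator parameter is recoverable by the corresponding analysis stage and
the recovery tolerance is testable.

Pseudo-molecules are intentionally coarse (a few beads per lipid: P, a
phosphate oxygen, N, an amine hydrogen and two tail beads) — the analyses
only need P/N/heavy-atom roles, not atomistic detail.

Determinism: one RNG stream per generator operation, seeded from
``(master seed, op tag)``, so adding an op never perturbs the draws of
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ligand import CavityBox
from .model_io import (
    AtomRecord,
    ChainRole,
    Frame,
    Topology,
    Trajectory,
    role_for_residue,
)

# RNG stream tags, one per generator op
_TAG_BILAYER = 1
_TAG_BROWNIAN = 2
_TAG_LIGAND = 3
_TAG_HELIX = 4
_TAG_WATERS = 5

#: cm^2/s -> nm^2/ps (1 nm^2/ps = 1e-2 cm^2/s)
CM2_PER_S_TO_NM2_PER_PS = 100.0


@dataclass
class SynthConfig:
    """Generator settings.  Defaults mirror the simulated study conditions:
    0.61 nm^2 area per lipid and a 90(36) degree POPC tilt distribution
    (pure-POPC bilayer), phosphate leaflets at ±1.9 nm, 20 ps frame
    spacing, pose weights dominated by one binding pose (92.4%), 16 cavity
    waters, and lateral diffusion of 5e-8 (protein-proximal) vs 8e-8
    (free) cm^2/s.
    """

    seed: int
    n_lipids: dict[str, int] = field(default_factory=lambda: {"POPC": 128})
    apl_true: float = 0.61                     # nm^2
    leaflet_z: float = 1.9                     # nm, phosphate plane height
    tilt_mean: dict[str, float] = field(default_factory=lambda: {"POPC": 90.0, "POPE": 90.0})
    tilt_sd: dict[str, float] = field(default_factory=lambda: {"POPC": 36.0, "POPE": 28.0})
    pn_length: float = 0.45                    # nm, P->N distance
    lattice_jitter: float = 0.02               # nm, in-plane site jitter
    include_protein: bool = False
    protein_radius: float = 0.8                # nm, pseudo-protein column radius
    n_bulk_waters: int = 0
    D_true: dict[str, float] = field(default_factory=lambda: {
        "proximal": 5e-8, "free": 8e-8})       # cm^2/s
    n_proximal: int = 4
    n_frames: int = 200
    dt: float = 20.0                           # ps between stored frames
    pose_weights: tuple[float, ...] = (0.924, 0.038, 0.038)
    pose_jitter: float = 0.02                  # nm
    receptor_wobble_deg: float = 3.0
    receptor_wobble_nm: float = 0.05
    n_cavity_waters: int = 16
    n_outside_waters: int = 50
    n_residues: int = 60                       # helix-trace length
    unfold_frame: int | None = None
    unfold_noise: float = 0.01                 # nm, additive Cα noise

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: no implicit randomness")
        if abs(sum(self.pose_weights) - 1.0) > 1e-9:
            raise ValueError("pose weights must sum to 1")
        for name, val in (("apl_true", self.apl_true), ("leaflet_z", self.leaflet_z),
                          ("pn_length", self.pn_length), ("dt", self.dt)):
            if val <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2 ** 31), tag])


def _folded_angle(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Tilt angles (deg) from a normal about ``mean`` folded into [0, 180].

    Folding reflects at 0 and 180, matching the range of an angle to an
    axis; for the spreads used here at most one reflection matters.
    """
    a = rng.normal(mean, sd, size=n)
    a = np.abs(a)                # reflect at 0
    a = np.where(a > 180.0, 360.0 - a, a)
    return np.clip(a, 0.0, 180.0)


def _tilt_vectors(rng: np.random.Generator, mean: float, sd: float, n: int,
                  length: float) -> np.ndarray:
    """P->N vectors with tilt ~ folded normal about the +z axis, uniform azimuth."""
    theta = np.radians(_folded_angle(rng, mean, sd, n))
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    return length * np.column_stack([
        np.sin(theta) * np.cos(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(theta),
    ])


def make_bilayer(cfg: SynthConfig) -> tuple[Topology, Frame]:
    """Two-leaflet pseudo-lipid bilayer on a jittered lattice.

    Lipids sit on an m x m lattice per leaflet with lattice constant
    sqrt(apl_true), and the box is sized so the true area per lipid equals
    ``apl_true`` exactly.  Each lipid contributes P, a phosphate oxygen O,
    N (at P plus a tilt-distributed PN vector, measured from the leaflet's
    outward normal), an amine hydrogen HN on POPE, and two tail beads.
    Counts that are not a perfect square per leaflet are padded up.

    With ``include_protein`` a static pseudo-protein column of Cα beads
    spans the box centre; lattice sites inside the column are skipped.
    """
    rng = cfg.rng(_TAG_BILAYER)
    total = sum(cfg.n_lipids.values())
    if total < 2:
        raise ValueError("need at least one lipid per leaflet")
    per_leaflet = int(np.ceil(total / 2))
    m = int(np.ceil(np.sqrt(per_leaflet)))
    per_leaflet = m * m
    a = np.sqrt(cfg.apl_true)
    lx = ly = m * a
    lz = 2.0 * (cfg.leaflet_z + 1.5)
    box = np.array([lx, ly, lz])
    center_z = lz / 2.0

    # lipid types interleaved deterministically at the requested ratio
    fracs = {t: c / total for t, c in cfg.n_lipids.items()}
    types: list[str] = []
    acc = {t: 0.0 for t in fracs}
    for _ in range(2 * per_leaflet):
        for t in fracs:
            acc[t] += fracs[t]
        pick = max(acc, key=lambda t: acc[t])
        acc[pick] -= 1.0
        types.append(pick)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    resid = 0
    li = 0
    for sign in (+1, -1):
        sites = [((i + 0.5) * a, (j + 0.5) * a) for i in range(m) for j in range(m)]
        n_leaf = len(sites)
        tilts_by_type = {}
        for t in cfg.n_lipids:
            tilts_by_type[t] = _tilt_vectors(
                rng, cfg.tilt_mean.get(t, 90.0), cfg.tilt_sd.get(t, 30.0),
                n_leaf, cfg.pn_length)
        for s_i, (x, y) in enumerate(sites):
            t = types[li]
            li += 1
            resid += 1
            jitter = rng.normal(0.0, cfg.lattice_jitter, size=2)
            if cfg.include_protein:
                dx, dy = x - lx / 2, y - ly / 2
                if np.hypot(dx, dy) < cfg.protein_radius + 0.2:
                    continue  # site occupied by the protein column
            p = np.array([x + jitter[0], y + jitter[1], center_z + sign * cfg.leaflet_z])
            pn = tilts_by_type[t][s_i].copy()
            pn[2] *= sign  # tilt measured from the leaflet's outward normal
            npos = p + pn
            role = role_for_residue(t)
            beads = [("P", "P", p), ("O", "O", p + np.array([0.1, 0.0, 0.0])),
                     ("N", "N", npos)]
            if t == "POPE":
                beads.append(("HN", "H", npos + np.array([0.0, 0.1, 0.0])))
            for b_k in (1, 2):
                beads.append((f"C{b_k}", "C",
                              p - np.array([0.0, 0.0, sign * 0.45 * b_k])))
            for name, elem, pos in beads:
                atoms.append(AtomRecord(name, t, resid, role, elem))
                coords.append(pos)
    if cfg.include_protein:
        n_ca = int(np.floor(lz / 0.2))
        for k in range(n_ca):
            resid += 1
            ang = 2.4 * k
            atoms.append(AtomRecord("CA", "ALA", resid, ChainRole.PROTEIN, "C"))
            coords.append(np.array([
                lx / 2 + 0.5 * cfg.protein_radius * np.cos(ang),
                ly / 2 + 0.5 * cfg.protein_radius * np.sin(ang),
                0.1 + 0.2 * k,
            ]))
    if cfg.n_bulk_waters:
        for _ in range(cfg.n_bulk_waters):
            resid += 1
            side = 1 if rng.random() < 0.5 else -1
            z = center_z + side * rng.uniform(cfg.leaflet_z + 0.6, lz / 2 - 0.1)
            atoms.append(AtomRecord("OW", "SOL", resid, ChainRole.WATER, "O"))
            coords.append(np.array([rng.uniform(0, lx), rng.uniform(0, ly), z]))
    return Topology(atoms), Frame(np.array(coords), box, time=0.0)


def make_brownian(cfg: SynthConfig, topology: Topology, frame: Frame,
                  mobile_roles: Sequence[ChainRole] = (
                      ChainRole.POPC, ChainRole.POPE, ChainRole.CHOL),
                  ) -> Trajectory:
    """Trajectory of rigid 2-D Brownian motion of whole lipid molecules.

    Each mobile molecule receives i.i.d. lateral increments with per-axis
    variance 2 * D * dt; z is held at the leaflet plane.  When the
    topology contains protein atoms, the ``n_proximal`` molecules nearest
    the protein column start in contact with it (within 0.3 nm) and move
    with ``D_true['proximal']``; all others move with ``D_true['free']``.
    Positions are wrapped into the box (analyses unwrap by minimum-image
    increments).
    """
    rng = cfg.rng(_TAG_BROWNIAN)
    box = frame.box
    roles = topology.roles
    mobile_mask = np.isin(roles, [r.value for r in mobile_roles])
    resids = topology.residue_ids
    mol_ids = np.unique(resids[mobile_mask])
    prot_idx = np.flatnonzero(roles == ChainRole.PROTEIN.value)

    coords0 = frame.coordinates.copy()
    groups: dict[int, str] = {int(r): "free" for r in mol_ids}
    if prot_idx.size and cfg.n_proximal > 0:
        prot_xy = coords0[prot_idx, :2]
        center = prot_xy.mean(axis=0)
        # nearest molecules by their first atom
        first_atom = {int(r): int(np.flatnonzero(mobile_mask & (resids == r))[0])
                      for r in mol_ids}
        dists = {r: np.hypot(*(coords0[first_atom[r], :2] - center))
                 for r in groups}
        chosen = sorted(groups, key=lambda r: dists[r])[:cfg.n_proximal]
        for r in chosen:
            groups[r] = "proximal"
            # park the molecule in contact with the nearest protein bead
            mol_atoms = np.flatnonzero(mobile_mask & (resids == r))
            pa = prot_idx[np.argmin(np.abs(coords0[prot_idx, 2]
                                           - coords0[mol_atoms[0], 2]))]
            target = coords0[pa].copy()
            target[0] += 0.25
            shift = target - coords0[mol_atoms[0]]
            shift[2] = 0.0
            coords0[mol_atoms, :2] += shift[:2]

    sigma = {}
    for g, d_cm2 in cfg.D_true.items():
        d_nm2 = d_cm2 * CM2_PER_S_TO_NM2_PER_PS
        s = np.sqrt(2.0 * d_nm2 * cfg.dt)
        if 5 * s > box[:2].min() / 2:
            raise ValueError("Brownian step size exceeds half the box; "
                             "reduce D or dt")
        sigma[g] = s

    xyz = np.empty((cfg.n_frames, len(topology), 3))
    xyz[0] = coords0
    cur = coords0.copy()
    mol_atoms_by_id = {int(r): np.flatnonzero(mobile_mask & (resids == r))
                       for r in mol_ids}
    for k in range(1, cfg.n_frames):
        for r in mol_ids:
            step = rng.normal(0.0, sigma[groups[int(r)]], size=2)
            ai = mol_atoms_by_id[int(r)]
            cur[ai, 0] = (cur[ai, 0] + step[0]) % box[0]
            cur[ai, 1] = (cur[ai, 1] + step[1]) % box[1]
        xyz[k] = cur
    return Trajectory.from_arrays(topology, xyz, box, frame_stride=cfg.dt)


# ---------------------------------------------------------------------------
# Receptor + ligand


def make_receptor(cfg: SynthConfig, n_residues: int = 40) -> tuple[Topology, Frame]:
    """Rigid pseudo-receptor: an ideal-helix Cα trace in a roomy box."""
    coords = _helix_coords(n_residues) + np.array([4.0, 4.0, 3.0])
    atoms = [AtomRecord("CA", "ALA", i + 1, ChainRole.PROTEIN, "C")
             for i in range(n_residues)]
    return Topology(atoms), Frame(coords, np.array([8.0, 8.0, 12.0]), time=0.0)


_XANTHINE_NAMES = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")


def _xanthine_core() -> np.ndarray:
    """Planar 9-atom bicyclic core (nm), centred at the origin.

    A hexagon (N1 C2 N3 C4 C5 C6) fused with a pentagon (C4 C5 N7 C8 N9)
    sharing the C4-C5 edge; bond lengths ~0.14 nm.
    """
    r = 0.14
    hexagon = np.array([
        [r * np.cos(np.radians(60 * k + 30)), r * np.sin(np.radians(60 * k + 30)), 0.0]
        for k in range(6)
    ])
    # order hexagon as N1 C2 N3 C4 C5 C6 with C4-C5 the rightmost edge
    hex_order = hexagon[[2, 3, 4, 5, 0, 1]]
    c4, c5 = hex_order[3], hex_order[4]
    mid = (c4 + c5) / 2.0
    out = mid / np.linalg.norm(mid)
    n7 = c5 + 0.14 * out
    n9 = c4 + 0.14 * out
    c8 = mid + 0.25 * out
    coords = np.vstack([hex_order, n7, c8, n9])
    return coords - coords.mean(axis=0)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * k + (1 - np.cos(angle_rad)) * (k @ k)


def default_pose_library(n_poses: int = 3) -> list[np.ndarray]:
    """Well-separated reference poses.

    Distinct binding poses differ in both orientation and position inside
    the cavity, so each pose combines a large rotation of the core with a
    sub-nm translation; pairwise RMSDs are well above typical clustering
    cutoffs.
    """
    core = _xanthine_core()
    rotations = [np.eye(3),
                 _rotation_matrix([1.0, 0.0, 0.0], np.pi),
                 _rotation_matrix([0.0, 0.0, 1.0], np.pi / 2),
                 _rotation_matrix([0.0, 1.0, 0.0], np.pi)]
    shifts = [np.zeros(3), np.array([0.45, 0.0, 0.0]), np.array([0.0, 0.45, 0.0]),
              np.array([0.0, 0.0, 0.45])]
    return [core @ rotations[k % len(rotations)].T + shifts[k % len(shifts)]
            for k in range(n_poses)]


def make_ligand_traj(cfg: SynthConfig, receptor: tuple[Topology, Frame],
                     pose_library: list[np.ndarray] | None = None,
                     ligand_offset: np.ndarray | None = None) -> Trajectory:
    """Receptor plus a ligand hopping between reference poses.

    Each frame draws a pose index from the categorical mixture
    ``cfg.pose_weights``; ligand coordinates are the reference pose plus
    isotropic Gaussian jitter of scale ``pose_jitter``.  The whole system
    additionally receives a small rigid-body wobble so that downstream
    analyses must genuinely align on the receptor.
    """
    rng = cfg.rng(_TAG_LIGAND)
    rec_top, rec_frame = receptor
    if pose_library is None:
        pose_library = default_pose_library(len(cfg.pose_weights))
    if len(pose_library) < len(cfg.pose_weights):
        raise ValueError("pose library smaller than the weight vector")
    # minimum pairwise inter-pose RMSD guards against cluster merging
    min_rmsd = np.inf
    for i in range(len(cfg.pose_weights)):
        for j in range(i + 1, len(cfg.pose_weights)):
            d = np.sqrt(np.mean(np.sum(
                (pose_library[i] - pose_library[j]) ** 2, axis=1)))
            min_rmsd = min(min_rmsd, d)
    if np.isfinite(min_rmsd) and cfg.pose_jitter >= min_rmsd / 2:
        raise ValueError(
            f"pose_jitter {cfg.pose_jitter} >= half the minimum inter-pose "
            f"RMSD ({min_rmsd:.3f} nm); clusters would merge by construction")

    offset = (np.asarray(ligand_offset, float) if ligand_offset is not None
              else rec_frame.coordinates.mean(axis=0) + np.array([0.0, 0.0, 1.0]))
    max_res = int(rec_top.residue_ids.max())
    lig_atoms = [AtomRecord(n, "CFF", max_res + 1, ChainRole.LIGAND,
                            "N" if n.startswith("N") else "C")
                 for n in _XANTHINE_NAMES]
    topology = Topology(list(rec_top.atoms) + lig_atoms)
    box = rec_frame.box
    n_rec = len(rec_top)
    xyz = np.empty((cfg.n_frames, len(topology), 3))
    poses = rng.choice(len(cfg.pose_weights), size=cfg.n_frames,
                       p=np.asarray(cfg.pose_weights))
    for k in range(cfg.n_frames):
        lig = (pose_library[poses[k]] + offset
               + rng.normal(0.0, cfg.pose_jitter, size=(len(lig_atoms), 3)))
        full = np.vstack([rec_frame.coordinates, lig])
        # rigid wobble of the entire complex
        angle = np.radians(rng.uniform(-cfg.receptor_wobble_deg,
                                       cfg.receptor_wobble_deg))
        axis = rng.normal(size=3)
        rot = _rotation_matrix(axis, angle)
        shift = rng.uniform(-cfg.receptor_wobble_nm, cfg.receptor_wobble_nm, size=3)
        center = full[:n_rec].mean(axis=0)
        xyz[k] = (full - center) @ rot.T + center + shift
    traj = Trajectory.from_arrays(topology, xyz, box, frame_stride=cfg.dt)
    traj.true_pose_sequence = poses  # ground truth for round-trip tests
    return traj


# ---------------------------------------------------------------------------
# Helix trace


def _helix_coords(n: int, rise: float = 0.15, turn_deg: float = 100.0,
                  radius: float = 0.23) -> np.ndarray:
    k = np.arange(n)
    ang = np.radians(turn_deg) * k
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * k])


def make_helix_trace(cfg: SynthConfig,
                     unfold_range: tuple[int, int] | None = None) -> Trajectory:
    """Ideal α-helix Cα trace, optionally unfolding part-way through.

    Before ``cfg.unfold_frame`` every frame is the ideal helix plus small
    Gaussian noise; from that frame on, the residues in ``unfold_range``
    (default: the second half of the chain, 1-based inclusive) are
    replaced by an extended continuation (0.38 nm per residue), so the
    interior helix fraction step-drops at the programmed frame.
    """
    rng = cfg.rng(_TAG_HELIX)
    n = cfg.n_residues
    helix = _helix_coords(n)
    helix = helix + np.array([5.0, 5.0, 2.0])
    box = np.array([10.0, 10.0, max(10.0, 0.4 * n + 4.0)])
    if unfold_range is None:
        unfold_range = (n // 2 + 1, n)
    r0, r1 = unfold_range
    if not (1 <= r0 <= r1 <= n):
        raise ValueError("unfold_range out of bounds")
    unfolded = helix.copy()
    anchor = helix[r0 - 2] if r0 >= 2 else helix[0]
    direction = np.array([1.0, 0.0, 0.0])
    for j in range(r0 - 1, r1):
        unfolded[j] = anchor + direction * 0.38 * (j - (r0 - 2))
    xyz = np.empty((cfg.n_frames, n, 3))
    for k in range(cfg.n_frames):
        base = helix if (cfg.unfold_frame is None or k < cfg.unfold_frame) else unfolded
        xyz[k] = base + rng.normal(0.0, cfg.unfold_noise, size=(n, 3))
    atoms = [AtomRecord("CA", "ALA", i + 1, ChainRole.PROTEIN, "C")
             for i in range(n)]
    return Trajectory.from_arrays(Topology(atoms), xyz, box, frame_stride=cfg.dt)


# ---------------------------------------------------------------------------
# Waters


def place_waters(cfg: SynthConfig, box: CavityBox,
                 start_resid: int = 1) -> tuple[list[AtomRecord], np.ndarray]:
    """Exactly ``n_cavity_waters`` oxygens inside the cavity box, plus
    ``n_outside_waters`` in a surrounding shell strictly outside it."""
    rng = cfg.rng(_TAG_WATERS)
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    resid = start_resid
    lo = box.center - box.half_extents
    hi = box.center + box.half_extents
    for _ in range(cfg.n_cavity_waters):
        coords.append(rng.uniform(lo, hi))
        atoms.append(AtomRecord("OW", "SOL", resid, ChainRole.WATER, "O"))
        resid += 1
    shell_lo = box.center - 3.0 * box.half_extents
    shell_hi = box.center + 3.0 * box.half_extents
    placed = 0
    while placed < cfg.n_outside_waters:
        p = rng.uniform(shell_lo, shell_hi)
        if bool(box.contains(p)[0]):
            continue
        coords.append(p)
        atoms.append(AtomRecord("OW", "SOL", resid, ChainRole.WATER, "O"))
        resid += 1
        placed += 1
    return atoms, np.array(coords)


def merge_into_trajectory(traj: Trajectory, atoms: list[AtomRecord],
                          coords: np.ndarray) -> Trajectory:
    """Append static atoms (e.g. placed waters) to every frame.

    Appended residue ids are renumbered to continue after the existing
    maximum so residue-based grouping stays unambiguous.
    """
    offset = int(traj.topology.residue_ids.max())
    base = min(a.residue_id for a in atoms)
    renumbered = [replace(a, residue_id=a.residue_id - base + offset + 1)
                  for a in atoms]
    topology = Topology(list(traj.topology.atoms) + renumbered)
    tiled = np.broadcast_to(coords, (traj.n_frames,) + coords.shape)
    xyz = np.concatenate([traj.xyz, tiled], axis=1)
    return Trajectory.from_arrays(topology, xyz, traj.boxes, traj.times,
                                  frame_stride=traj.frame_stride)
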