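"""Lipid-bilayer structure and dynamics.

Covers the standard battery of membrane metrics for a protein-in-bilayer
simulation: phosphate density profile along the bilayer normal and the
derived thickness, grid-based area per lipid (nearest-reference-atom cell
assignment per leaflet), P->N headgroup tilt distributions, geometric
hydrogen-bond occupancies, and lateral diffusion coefficients from the 2-D
Einstein relation with a proximal/free split of molecules around the
protein.

Conventions: the z axis is the bilayer normal; leaflets are assigned by
the sign of z relative to the instantaneous phosphate midplane; the lower
leaflet uses the inward normal (-z) so tilt distributions are
leaflet-symmetric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .model_io import (
    ChainRole,
    Frame,
    SelectionSpec,
    Trajectory,
    minimum_image_displacement,
    pairwise_min_image_distances,
    select_atoms,
)

#: Unit chain 1 nm^2 = 1e-14 cm^2, 1 ps = 1e-12 s  =>  1 nm^2/ps = 1e-2 cm^2/s.
NM2_PER_PS_TO_CM2_PER_S = 1e-2


# ---------------------------------------------------------------------------
# Density profile & thickness


@dataclass
class DensityProfile:
    bin_centers: np.ndarray          # z (nm), measured from the bilayer midplane
    density: np.ndarray              # number density (nm^-3) per bin
    bin_width: float
    box_area: float                  # mean lateral box area (nm^2)
    n_frames: int
    selection: SelectionSpec | None = None

    def integral_count(self) -> float:
        """Mean number of selected atoms recovered from the profile."""
        return float(self.density.sum() * self.bin_width * self.box_area)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["z_nm\tdensity_nm-3"]
        for z, d in zip(self.bin_centers, self.density):
            lines.append(f"{z:.4f}\t{d:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def _midplane_indices(traj: Trajectory, midplane_spec: SelectionSpec | None) -> np.ndarray:
    if midplane_spec is None:
        midplane_spec = SelectionSpec(
            roles=(ChainRole.POPC, ChainRole.POPE), atom_names=("P",))
    idx = select_atoms(traj.topology, midplane_spec)
    if idx.size == 0:
        raise ValueError("midplane selection (lipid phosphorus) is empty")
    return idx


def density_profile(traj: Trajectory, spec: SelectionSpec, bin_width: float = 0.1,
                    midplane_spec: SelectionSpec | None = None) -> DensityProfile:
    """Number-density profile of a selection along z, frame-averaged.

    z is measured from the bilayer midplane, the mean z of all lipid
    phosphorus atoms in each frame, so the profile is invariant under
    rigid z-translation of the whole system.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = select_atoms(traj.topology, spec)
    if idx.size == 0:
        raise ValueError("density profile needs a non-empty selection")
    mid_idx = _midplane_indices(traj, midplane_spec)
    half_span = traj.boxes[:, 2].max() / 2.0
    n_bins = max(1, int(np.ceil(2 * half_span / bin_width)))
    edges = -half_span + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for k in range(traj.n_frames):
        mid = traj.xyz[k, mid_idx, 2].mean()
        z = traj.xyz[k, idx, 2] - mid
        h, _ = np.histogram(z, bins=edges)
        counts += h
    area = float((traj.boxes[:, 0] * traj.boxes[:, 1]).mean())
    density = counts / (traj.n_frames * bin_width * area)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return DensityProfile(bin_centers=centers, density=density,
                          bin_width=bin_width, box_area=area,
                          n_frames=traj.n_frames, selection=spec)


def bilayer_thickness(profile: DensityProfile) -> dict[str, float]:
    """Leaflet separation from a phosphate density profile (nm).

    Returns the distance between the density-weighted mean z of the upper
    (z > 0) and lower (z < 0) leaflets, plus the peak-to-peak distance.
    Raises when the profile has no mass on one side of the midplane (a
    single-mode profile is not a bilayer).
    """
    z = profile.bin_centers
    rho = profile.density
    upper = rho * (z > 0)
    lower = rho * (z < 0)
    if upper.sum() <= 0 or lower.sum() <= 0:
        raise ValueError("no bilayer detected: density is single-sided")
    mean_up = float((z * upper).sum() / upper.sum())
    mean_lo = float((z * lower).sum() / lower.sum())
    peak_up = float(z[np.argmax(np.where(z > 0, rho, -np.inf))])
    peak_lo = float(z[np.argmax(np.where(z < 0, rho, -np.inf))])
    return {
        "thickness": mean_up - mean_lo,
        "peak_to_peak": peak_up - peak_lo,
        "upper_mean_z": mean_up,
        "lower_mean_z": mean_lo,
    }


# ---------------------------------------------------------------------------
# Grid area per lipid


@dataclass
class AplResult:
    per_lipid_area: dict[int, float]     # residue id -> mean area (nm^2)
    mean_apl: float                      # nm^2, over lipids then frames
    grid_shape: tuple[int, int]
    protein_area: float                  # nm^2, mean protein-assigned area
    leaflet_area: float                  # nm^2, per-leaflet box area
    n_frames: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "mean_apl_nm2": self.mean_apl,
            "grid": list(self.grid_shape),
            "protein_area_nm2": self.protein_area,
            "per_lipid_area_nm2": {str(k): v for k, v in
                                   sorted(self.per_lipid_area.items())},
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _leaflet_apl(p_xy: np.ndarray, prot_xy: np.ndarray, box_xy: np.ndarray,
                 grid: int) -> tuple[np.ndarray, float]:
    """Assign grid cells to nearest reference atoms (xy minimum-image).

    Returns per-lipid cell-count areas and the protein-assigned area; the
    cell areas sum to the leaflet box area exactly by construction.
    """
    lx, ly = box_xy
    refs = p_xy if prot_xy.size == 0 else np.vstack([p_xy, prot_xy])
    cx = (np.arange(grid) + 0.5) * lx / grid
    cy = (np.arange(grid) + 0.5) * ly / grid
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    dx = np.abs(cells[:, None, 0] - refs[None, :, 0])
    dx = np.minimum(dx, lx - dx)
    dy = np.abs(cells[:, None, 1] - refs[None, :, 1])
    dy = np.minimum(dy, ly - dy)
    owner = np.argmin(dx ** 2 + dy ** 2, axis=1)
    cell_area = (lx / grid) * (ly / grid)
    n_lip = p_xy.shape[0]
    lipid_cells = np.bincount(owner[owner < n_lip], minlength=n_lip)
    protein_area = float((owner >= n_lip).sum() * cell_area)
    return lipid_cells * cell_area, protein_area


def area_per_lipid_grid(traj: Trajectory, lipid_refs: SelectionSpec,
                        protein_spec: SelectionSpec | None = None,
                        grid: int = 100, protein_slab: float = 0.5) -> AplResult:
    """Grid-based area per lipid, each leaflet handled separately.

    Each cell of an n x n lateral grid is assigned to the nearest
    reference atom — one phosphorus per lipid, plus protein heavy atoms
    lying within ``protein_slab`` nm of the leaflet's mean phosphate z —
    and a lipid's area is its cell count times the cell area.  The APL is
    the mean over lipids, then over frames.
    """
    if grid < 10:
        raise ValueError("grid must be at least 10x10")
    p_idx = select_atoms(traj.topology, lipid_refs)
    if p_idx.size == 0:
        raise ValueError("lipid reference selection is empty")
    prot_idx = (select_atoms(traj.topology, protein_spec)
                if protein_spec is not None else np.array([], dtype=int))
    resids = traj.topology.residue_ids[p_idx]
    area_sum = {int(r): 0.0 for r in resids}
    area_n = {int(r): 0 for r in resids}
    protein_area_sum = 0.0
    for k in range(traj.n_frames):
        box = traj.boxes[k]
        pz = traj.xyz[k, p_idx, 2]
        mid = pz.mean()
        for sign in (+1, -1):
            leaf = np.flatnonzero(sign * (pz - mid) > 0)
            if leaf.size == 0:
                continue
            leaf_z = pz[leaf].mean()
            if prot_idx.size:
                prot_z = traj.xyz[k, prot_idx, 2]
                in_slab = np.abs(prot_z - leaf_z) <= protein_slab
                prot_xy = traj.xyz[k, prot_idx[in_slab], :2] % box[:2]
            else:
                prot_xy = np.empty((0, 2))
            p_xy = traj.xyz[k, p_idx[leaf], :2] % box[:2]
            areas, prot_area = _leaflet_apl(p_xy, prot_xy, box[:2], grid)
            protein_area_sum += prot_area
            for rid, a in zip(resids[leaf], areas):
                if a == 0.0:
                    warnings.warn(f"lipid residue {rid} received 0 grid cells")
                area_sum[int(rid)] += a
                area_n[int(rid)] += 1
    per_lipid = {r: area_sum[r] / max(area_n[r], 1) for r in area_sum}
    mean_apl = float(np.mean(list(per_lipid.values())))
    leaflet_area = float((traj.boxes[:, 0] * traj.boxes[:, 1]).mean())
    return AplResult(per_lipid_area=per_lipid, mean_apl=mean_apl,
                     grid_shape=(grid, grid),
                     protein_area=protein_area_sum / (2 * traj.n_frames),
                     leaflet_area=leaflet_area, n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# Headgroup tilt


@dataclass
class TiltRecord:
    angles: np.ndarray            # (n_frames, n_lipids) degrees in [0, 180]
    lipid_types: np.ndarray       # per lipid residue name
    residue_ids: np.ndarray

    def mean_tilt(self, lipid_type: str | None = None) -> float:
        a = self.angles if lipid_type is None else \
            self.angles[:, self.lipid_types == lipid_type]
        return float(a.mean())

    def distribution(self, lipid_type: str | None = None,
                     bin_width: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
        a = (self.angles if lipid_type is None else
             self.angles[:, self.lipid_types == lipid_type]).ravel()
        edges = np.arange(0.0, 180.0 + bin_width, bin_width)
        h, _ = np.histogram(a, bins=edges, density=True)
        return (edges[:-1] + edges[1:]) / 2.0, h

    def to_tsv(self, path: str | Path, lipid_type: str | None = None) -> None:
        centers, h = self.distribution(lipid_type)
        lines = ["angle_deg\tprobability_density"]
        lines += [f"{c:.2f}\t{v:.6f}" for c, v in zip(centers, h)]
        Path(path).write_text("\n".join(lines) + "\n")


def pn_tilt(traj: Trajectory, p_spec: SelectionSpec | None = None,
            n_spec: SelectionSpec | None = None) -> TiltRecord:
    """Headgroup tilt: angle between each lipid's P->N vector and the
    bilayer normal, in degrees.

    P and N atoms are paired per residue id (exactly one of each per
    lipid).  Lower-leaflet lipids — negative P z relative to the phosphate
    midplane — are measured against the inward normal (-z), making the two
    leaflets statistically equivalent.
    """
    lipid_roles = (ChainRole.POPC, ChainRole.POPE)
    if p_spec is None:
        p_spec = SelectionSpec(roles=lipid_roles, atom_names=("P",))
    if n_spec is None:
        n_spec = SelectionSpec(roles=lipid_roles, atom_names=("N",))
    pi = select_atoms(traj.topology, p_spec)
    ni = select_atoms(traj.topology, n_spec)
    p_res = traj.topology.residue_ids[pi]
    n_res = traj.topology.residue_ids[ni]
    n_by_res = {int(r): i for r, i in zip(n_res, ni)}
    if len(n_by_res) != ni.size or set(p_res) != set(n_by_res) or pi.size != ni.size:
        raise ValueError("P and N atoms do not pair 1:1 per lipid residue")
    ni_paired = np.array([n_by_res[int(r)] for r in p_res])
    pz = traj.xyz[:, pi, 2]
    mid = pz.mean(axis=1, keepdims=True)
    normal_sign = np.where(pz - mid >= 0, 1.0, -1.0)
    vec = traj.xyz[:, ni_paired, :] - traj.xyz[:, pi, :]
    norms = np.linalg.norm(vec, axis=2)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length PN vector")
    cos = np.clip(vec[:, :, 2] * normal_sign / norms, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos))
    return TiltRecord(angles=angles,
                      lipid_types=traj.topology.residue_names[pi],
                      residue_ids=p_res)


# ---------------------------------------------------------------------------
# Hydrogen bonds


@dataclass(frozen=True)
class HBond:
    donor: int      # heavy donor atom index
    hydrogen: int
    acceptor: int   # acceptor oxygen index


def detect_hbonds(frame: Frame, donors: np.ndarray, acceptors: np.ndarray,
                  d_cut: float = 0.35, angle_cut: float = 30.0) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    ``donors`` is an (n, 2) array of (heavy donor, hydrogen) index pairs;
    ``acceptors`` an array of acceptor-oxygen indices.  A bond exists when
    the donor-acceptor minimum-image distance is <= ``d_cut`` nm and the
    H-donor-acceptor angle is <= ``angle_cut`` degrees.
    """
    donors = np.atleast_2d(np.asarray(donors, dtype=int))
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        return []
    box = frame.box
    dpos = frame.coordinates[donors[:, 0]]
    hpos = frame.coordinates[donors[:, 1]]
    apos = frame.coordinates[acceptors]
    da = pairwise_min_image_distances(dpos, apos, box)
    bonds: list[HBond] = []
    cos_cut = np.cos(np.radians(angle_cut))
    for di, ai in zip(*np.nonzero(da <= d_cut)):
        d_idx, h_idx, a_idx = donors[di, 0], donors[di, 1], acceptors[ai]
        if d_idx == a_idx:
            continue
        v_dh = minimum_image_displacement(frame.coordinates[h_idx] - dpos[di], box)
        v_da = minimum_image_displacement(apos[ai] - dpos[di], box)
        denom = np.linalg.norm(v_dh) * np.linalg.norm(v_da)
        if denom < 1e-12:
            continue
        if (v_dh @ v_da) / denom >= cos_cut:
            bonds.append(HBond(int(d_idx), int(h_idx), int(a_idx)))
    return bonds


@dataclass
class HBondOccupancy:
    """Mean H-bond count per acceptor oxygen, per role-pair class."""

    occupancies: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.occupancies, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


_LIPID_ROLES = {ChainRole.POPC.value, ChainRole.POPE.value, ChainRole.CHOL.value}

DEFAULT_HBOND_PARTITION: dict[str, tuple[set[str], set[str]]] = {
    "protein_lipid": ({ChainRole.PROTEIN.value}, _LIPID_ROLES),
    "lipid_lipid": (_LIPID_ROLES, _LIPID_ROLES),
    "lipid_solvent": (_LIPID_ROLES, {ChainRole.WATER.value}),
}


def hbond_occupancies(traj: Trajectory, donors: np.ndarray, acceptors: np.ndarray,
                      partition: dict[str, tuple[set[str], set[str]]] | None = None,
                      d_cut: float = 0.35, angle_cut: float = 30.0) -> HBondOccupancy:
    """H-bond occupancies per class, frame-averaged.

    For each class (an unordered pair of role sets), the occupancy is the
    mean number of bonds whose donor and acceptor roles realise the pair,
    divided by the total number of acceptor oxygens carrying a role that
    appears in the pair.  Classes with zero acceptors raise.
    """
    if partition is None:
        partition = DEFAULT_HBOND_PARTITION
    roles = traj.topology.roles
    acceptors = np.asarray(acceptors, dtype=int)
    per_class_counts = {name: 0.0 for name in partition}
    for k in range(traj.n_frames):
        bonds = detect_hbonds(traj[k], donors, acceptors, d_cut, angle_cut)
        for b in bonds:
            rd, ra = roles[b.donor], roles[b.acceptor]
            for name, (set_a, set_b) in partition.items():
                if (rd in set_a and ra in set_b) or (rd in set_b and ra in set_a):
                    per_class_counts[name] += 1
    occ = {}
    for name, (set_a, set_b) in partition.items():
        class_roles = set_a | set_b
        n_acc = int(np.isin(roles[acceptors], list(class_roles)).sum())
        if n_acc == 0:
            raise ValueError(f"H-bond class {name!r} has no acceptor oxygens")
        occ[name] = per_class_counts[name] / traj.n_frames / n_acc
    return HBondOccupancy(occupancies=occ)


# ---------------------------------------------------------------------------
# Proximity classification & lateral diffusion


class MobilityGroup(str, Enum):
    PROXIMAL = "proximal"
    FREE = "free"


def classify_proximal(traj: Trajectory, group_spec: SelectionSpec,
                      protein_spec: SelectionSpec, cutoff: float = 0.35,
                      per_frame: bool = False):
    """Split molecules into protein-proximal and free.

    A molecule (grouped by residue id within ``group_spec``) is proximal
    when any of its atoms comes within ``cutoff`` nm of any protein atom
    in at least one analysed frame ("during the dynamics" = ever).  With
    ``per_frame=True`` a per-frame boolean matrix is returned instead.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    gi = select_atoms(traj.topology, group_spec)
    pi = select_atoms(traj.topology, protein_spec)
    if gi.size == 0 or pi.size == 0:
        raise ValueError("group and protein selections must be non-empty")
    resids = traj.topology.residue_ids[gi]
    unique_res = np.unique(resids)
    near = np.zeros((traj.n_frames, unique_res.size), dtype=bool)
    for k in range(traj.n_frames):
        d = pairwise_min_image_distances(traj.xyz[k, gi, :], traj.xyz[k, pi, :],
                                         traj.boxes[k]).min(axis=1)
        for m, r in enumerate(unique_res):
            near[k, m] = bool((d[resids == r] <= cutoff).any())
    if per_frame:
        return {int(r): near[:, m] for m, r in enumerate(unique_res)}
    ever = near.any(axis=0)
    return {int(r): (MobilityGroup.PROXIMAL if ever[m] else MobilityGroup.FREE)
            for m, r in enumerate(unique_res)}


def unwrap_xy(positions: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from an (F, M, 2) lateral position series.

    Each per-frame displacement is mapped to its minimum image; valid as
    long as true per-frame motion stays below half the box.
    """
    out = positions.copy()
    for k in range(1, positions.shape[0]):
        step = positions[k] - positions[k - 1]
        step -= boxes[k, :2] * np.round(step / boxes[k, :2])
        out[k] = out[k - 1] + step
    return out


def lateral_msd(traj: Trajectory, ref_atom_indices: np.ndarray,
                unwrap: bool = True, max_lag_fraction: float = 0.5
                ) -> tuple[np.ndarray, np.ndarray]:
    """Lateral (xy) mean-square displacement over molecules and time origins.

    ``ref_atom_indices`` holds one reference atom per molecule.  Returns
    ``(lags_ps, msd_nm2)`` with MSD(0) = 0.
    """
    if traj.n_frames < 10:
        raise ValueError("MSD needs at least 10 frames")
    ref_atom_indices = np.asarray(ref_atom_indices, dtype=int)
    pos = traj.xyz[:, ref_atom_indices, :2]
    if unwrap:
        pos = unwrap_xy(pos, traj.boxes)
    f = pos.shape[0]
    n_lags = max(2, int(f * max_lag_fraction))
    lags = np.arange(n_lags)
    msd = np.zeros(n_lags)
    for li in range(1, n_lags):
        disp = pos[li:] - pos[:-li]
        msd[li] = float((disp ** 2).sum(axis=2).mean())
    dt = traj.frame_stride if traj.frame_stride > 0 else 1.0
    return lags * dt, msd


@dataclass
class DiffusionEstimate:
    group: str
    lags_ps: np.ndarray
    msd_nm2: np.ndarray
    D_cm2_per_s: float
    fit_window_ps: tuple[float, float]
    r_squared: float
    negative_slope: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "group": self.group,
            "D_cm2_per_s": self.D_cm2_per_s,
            "fit_window_ps": list(self.fit_window_ps),
            "r_squared": self.r_squared,
            "negative_slope": self.negative_slope,
        }, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def fit_diffusion(lags_ps: np.ndarray, msd_nm2: np.ndarray,
                  window: tuple[float, float] = (0.1, 0.5),
                  group: str = "all") -> DiffusionEstimate:
    """Lateral diffusion coefficient from the 2-D Einstein relation.

    A straight line is fitted to MSD(lag) over the ``window`` fraction of
    the maximum lag (default 10-50%, excluding the short-lag ballistic /
    noise regime and the poorly-sampled tail); D = slope / 4, converted
    from nm^2/ps to cm^2/s.  A negative slope yields D = 0 with a warning
    flag set.
    """
    lags_ps = np.asarray(lags_ps, float)
    msd_nm2 = np.asarray(msd_nm2, float)
    lo, hi = window
    if not 0 <= lo < hi <= 1:
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    max_lag = lags_ps[-1]
    mask = (lags_ps >= lo * max_lag) & (lags_ps <= hi * max_lag)
    if mask.sum() < 2:
        raise ValueError("fit window contains fewer than 2 lags")
    x, y = lags_ps[mask], msd_nm2[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    negative = slope < 0
    d = max(slope, 0.0) / 4.0 * NM2_PER_PS_TO_CM2_PER_S
    return DiffusionEstimate(group=group, lags_ps=lags_ps, msd_nm2=msd_nm2,
                             D_cm2_per_s=float(d),
                             fit_window_ps=(float(lo * max_lag), float(hi * max_lag)),
                             r_squared=r2, negative_slope=bool(negative))
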