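"""Domain model for molecular systems and PDB/GRO structure & trajectory I/O.

All quantities are stored in the package's internal units: lengths in nm,
times in ps, angles in degrees.  PDB files (Å) are converted at the boundary;
GRO files are already in nm.  The z axis is the bilayer normal by convention.
Only orthorhombic boxes are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

ANGSTROM_PER_NM = 10.0


class ChainRole(str, Enum):
    """Coarse role of the chain/residue an atom belongs to."""

    PROTEIN = "protein"
    POPC = "POPC"
    POPE = "POPE"
    CHOL = "CHOL"
    WATER = "water"
    LIGAND = "ligand"
    ION = "ion"


#: Editable residue-name -> role mapping.  Unknown residue names raise —
#: silent misclassification would corrupt every downstream metric.
DEFAULT_ROLE_MAP: dict[str, ChainRole] = {
    "POPC": ChainRole.POPC,
    "POPE": ChainRole.POPE,
    "CHL1": ChainRole.CHOL,
    "CHOL": ChainRole.CHOL,
    "SOL": ChainRole.WATER,
    "HOH": ChainRole.WATER,
    "WAT": ChainRole.WATER,
    "TIP3": ChainRole.WATER,
    "CFF": ChainRole.LIGAND,
    "LIG": ChainRole.LIGAND,
    "NA": ChainRole.ION,
    "CL": ChainRole.ION,
    "NA+": ChainRole.ION,
    "CL-": ChainRole.ION,
    "K": ChainRole.ION,
    "K+": ChainRole.ION,
}

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HIE", "HID", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
    "THR", "TRP", "TYR", "VAL",
}

#: Standard atomic masses (u) for the elements the fixtures use.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098, "X": 1.0,
}


class ParseError(ValueError):
    """Raised when a structure/trajectory file fails to parse."""


class UnknownResidueError(ValueError):
    """Raised when a residue name has no chain-role mapping."""


def role_for_residue(resname: str, role_map: dict[str, ChainRole] | None = None) -> ChainRole:
    name = resname.strip().upper()
    table = DEFAULT_ROLE_MAP if role_map is None else role_map
    if name in table:
        return table[name]
    if name in _AMINO_ACIDS:
        return ChainRole.PROTEIN
    raise UnknownResidueError(
        f"residue name {resname!r} has no chain-role mapping; extend the role map"
    )


def guess_element(atom_name: str) -> str:
    """Element from an atom name (first alphabetic character, PDB-style)."""
    stripped = atom_name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter ions
            if stripped.upper() in ("NA", "CL", "NA+", "CL-"):
                return stripped.upper().rstrip("+-")
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.  ``residue_id`` is 1-based as in source files."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_role: ChainRole
    element: str

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element.upper()]
        except KeyError:
            raise KeyError(f"no mass tabulated for element {self.element!r}") from None


class Topology:
    """Ordered sequence of :class:`AtomRecord` with fast vectorised views."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_ids = np.array([a.residue_id for a in self.atoms], dtype=int)
        self.roles = np.array([a.chain_role.value for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self.atoms[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms

    def subset(self, indices: Sequence[int]) -> "Topology":
        return Topology(self.atoms[i] for i in indices)


@dataclass
class Frame:
    """One snapshot: coordinates (nm), orthorhombic box (nm) and time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an N x 3 array")
        if not np.all(self.box > 0):
            raise ValueError(f"box components must be positive, got {self.box}")


class Trajectory:
    """Topology plus an ordered stack of frames sharing that topology.

    Internally the coordinates live in a single (n_frames, n_atoms, 3)
    array; :class:`Frame` views are materialised on indexing.
    """

    def __init__(self, topology: Topology, frames: Sequence[Frame],
                 frame_stride: float | None = None):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = len(topology)
        for k, fr in enumerate(frames):
            if fr.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )
        self.topology = topology
        self.xyz = np.stack([fr.coordinates for fr in frames])
        self.boxes = np.stack([fr.box for fr in frames])
        self.times = np.array([fr.time for fr in frames], dtype=float)
        if len(self.times) > 1:
            if not np.all(np.diff(self.times) > 0):
                raise ValueError("frame times must be strictly increasing")
        self.frame_stride = frame_stride if frame_stride is not None else (
            float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0
        )

    @classmethod
    def from_arrays(cls, topology: Topology, xyz: np.ndarray, box: np.ndarray,
                    times: np.ndarray | None = None,
                    frame_stride: float = 20.0) -> "Trajectory":
        xyz = np.asarray(xyz, dtype=float)
        box = np.asarray(box, dtype=float)
        if box.ndim == 1:
            box = np.broadcast_to(box, (xyz.shape[0], 3))
        if times is None:
            times = np.arange(xyz.shape[0]) * frame_stride
        frames = [Frame(xyz[i], box[i], float(times[i])) for i in range(xyz.shape[0])]
        return cls(topology, frames, frame_stride=frame_stride)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.xyz[i], self.boxes[i], float(self.times[i]))

    def window(self, last_fraction: float) -> "Trajectory":
        """Trailing window of the run (e.g. 0.5 = analyse the last half)."""
        if not 0 < last_fraction <= 1:
            raise ValueError("last_fraction must be in (0, 1]")
        start = self.n_frames - max(1, int(round(self.n_frames * last_fraction)))
        return Trajectory.from_arrays(
            self.topology, self.xyz[start:], self.boxes[start:],
            self.times[start:], frame_stride=self.frame_stride,
        )


# ---------------------------------------------------------------------------
# Atom selection


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: all stated conditions must hold.

    ``residue_range`` is an inclusive 1-based (first, last) pair, the
    convention used for helix ranges like H1 = residues 5-34.
    """

    roles: tuple[ChainRole, ...] | None = None
    residue_range: tuple[int, int] | None = None
    residue_ids: tuple[int, ...] | None = None
    residue_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None

    @classmethod
    def ca_of_residues(cls, first: int, last: int) -> "SelectionSpec":
        return cls(atom_names=("CA",), residue_range=(first, last))

    @classmethod
    def by_role(cls, *roles: ChainRole) -> "SelectionSpec":
        return cls(roles=tuple(roles))


def select_atoms(topology: Topology, spec: SelectionSpec) -> np.ndarray:
    """Resolve a selection to a sorted (source-order) integer index array.

    Empty selections are legal but emit a warning; references to residue
    ids absent from the topology are errors.
    """
    mask = np.ones(len(topology), dtype=bool)
    if spec.roles is not None:
        mask &= np.isin(topology.roles, [r.value for r in spec.roles])
    if spec.residue_range is not None:
        lo, hi = spec.residue_range
        present = topology.residue_ids
        if not ((present >= lo) & (present <= hi)).any():
            raise ValueError(f"no residues in range {lo}-{hi} exist in the topology")
        mask &= (present >= lo) & (present <= hi)
    if spec.residue_ids is not None:
        missing = set(spec.residue_ids) - set(topology.residue_ids.tolist())
        if missing:
            raise ValueError(f"unknown residue ids in selection: {sorted(missing)}")
        mask &= np.isin(topology.residue_ids, spec.residue_ids)
    if spec.residue_names is not None:
        mask &= np.isin(topology.residue_names, spec.residue_names)
    if spec.atom_names is not None:
        mask &= np.isin(topology.atom_names, spec.atom_names)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {spec} matched no atoms", stacklevel=2)
    return idx


def complement(topology: Topology, indices: np.ndarray) -> np.ndarray:
    mask = np.ones(len(topology), dtype=bool)
    mask[indices] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Periodic geometry


def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Minimum-image distance between two points in an orthorhombic box."""
    d = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return float(np.linalg.norm(d))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray,
                                 box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distance matrix, shape (len(a), len(b))."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image_displacement(d, np.asarray(box, float))
    return np.sqrt((d ** 2).sum(axis=-1))


# ---------------------------------------------------------------------------
# GRO format (fixed column, nm)


def _build_topology(names, resnames, resids, role_map) -> Topology:
    atoms = []
    for nm, rn, ri in zip(names, resnames, resids):
        atoms.append(AtomRecord(
            atom_name=nm, residue_name=rn, residue_id=int(ri),
            chain_role=role_for_residue(rn, role_map),
            element=guess_element(nm),
        ))
    return Topology(atoms)


def _parse_gro_block(lines: list[str], lineno0: int, role_map) -> tuple[Topology, Frame, int]:
    """Parse one GRO frame starting at lines[0]; returns consumed line count."""
    if len(lines) < 3:
        raise ParseError(f"line {lineno0 + 1}: truncated GRO frame")
    title = lines[0]
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.split("t=")[1].split()[0])
        except (IndexError, ValueError):
            pass
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"line {lineno0 + 2}: expected atom count, got {lines[1]!r}") from None
    if len(lines) < natoms + 3:
        raise ParseError(f"line {lineno0 + 1}: GRO frame declares {natoms} atoms but file ends early")
    names, resnames, resids, coords = [], [], [], []
    for k in range(natoms):
        ln = lines[2 + k]
        lno = lineno0 + 3 + k
        try:
            resids.append(int(ln[0:5]))
            resnames.append(ln[5:10].strip())
            names.append(ln[10:15].strip())
            coords.append([float(ln[20:28]), float(ln[28:36]), float(ln[36:44])])
        except (ValueError, IndexError):
            raise ParseError(f"line {lno}: malformed GRO atom record {ln!r}") from None
    box_fields = lines[2 + natoms].split()
    if len(box_fields) < 3:
        raise ParseError(f"line {lineno0 + natoms + 3}: missing or malformed GRO box line")
    box = np.array([float(x) for x in box_fields[:3]])
    if len(box_fields) > 3 and any(abs(float(x)) > 1e-9 for x in box_fields[3:]):
        raise ParseError(f"line {lineno0 + natoms + 3}: only orthorhombic boxes are supported")
    topo = _build_topology(names, resnames, resids, role_map)
    return topo, Frame(np.array(coords), box, time), natoms + 3


def _format_gro_frame(topology: Topology, frame: Frame, title: str) -> str:
    out = [f"{title} t= {frame.time:.1f}", f"{len(topology):5d}"]
    for i, a in enumerate(topology):
        x, y, z = frame.coordinates[i]
        out.append(
            f"{a.residue_id % 100000:5d}{a.residue_name:<5s}{a.atom_name:>5s}"
            f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    out.append("{:10.5f}{:10.5f}{:10.5f}".format(*frame.box))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# PDB format (Å, converted at the boundary)


def _parse_pdb(text: str, role_map) -> tuple[Topology | None, list[Frame], np.ndarray | None]:
    box = None
    frames: list[Frame] = []
    topo: Topology | None = None
    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    coords: list[list[float]] = []
    times: list[float] = []
    model_index = 0
    in_model = False

    def close_model(lineno: int):
        nonlocal topo, coords, names, resnames, resids
        if not coords:
            return
        if topo is None:
            topo = _build_topology(names, resnames, resids, role_map)
        elif len(coords) != len(topo):
            raise ParseError(
                f"model {model_index}: atom count {len(coords)} differs from "
                f"first model ({len(topo)})"
            )
        if box is None:
            raise ParseError("PDB has no CRYST1 record; a box is required")
        frames.append(Frame(np.array(coords) / ANGSTROM_PER_NM, box,
                            time=float(len(frames))))
        coords, names, resnames, resids = [], [], [], []

    for lineno, ln in enumerate(text.splitlines(), start=1):
        rec = ln[:6]
        if rec == "CRYST1":
            try:
                a, b, c = float(ln[6:15]), float(ln[15:24]), float(ln[24:33])
                alpha, beta, gamma = float(ln[33:40]), float(ln[40:47]), float(ln[47:54])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed CRYST1 record") from None
            if not all(abs(x - 90.0) < 1e-6 for x in (alpha, beta, gamma)):
                raise ParseError(f"line {lineno}: only orthorhombic boxes are supported")
            box = np.array([a, b, c]) / ANGSTROM_PER_NM
        elif rec == "MODEL ":
            in_model = True
            model_index += 1
        elif rec == "ENDMDL":
            close_model(lineno)
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            try:
                name = ln[12:16].strip()
                resname = ln[17:21].strip()
                resid = int(ln[22:26])
                xyz = [float(ln[30:38]), float(ln[38:46]), float(ln[46:54])]
            except (ValueError, IndexError):
                raise ParseError(f"line {lineno}: malformed {rec.strip()} record {ln!r}") from None
            elem = ln[76:78].strip()
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            coords.append(xyz)
            if topo is None and not in_model and model_index == 0:
                pass  # single-model file without MODEL cards
    close_model(0)
    if topo is None:
        raise ParseError("no ATOM/HETATM records found")
    del times
    return topo, frames, box


def _format_pdb(topology: Topology, frames: Sequence[Frame], multi: bool) -> str:
    out = []
    box = frames[0].box * ANGSTROM_PER_NM
    out.append(
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}  90.00  90.00  90.00 P 1           1"
    )
    for m, fr in enumerate(frames, start=1):
        if multi:
            out.append(f"MODEL     {m:4d}")
        for i, a in enumerate(topology):
            x, y, z = fr.coordinates[i] * ANGSTROM_PER_NM
            name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
            out.append(
                f"ATOM  {(i + 1) % 100000:5d} {name:<4s} {a.residue_name:<4s}"
                f" {a.residue_id % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {a.element:>2s}"
            )
        if multi:
            out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Public readers/writers


def _format_from_path(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.upper()
    suffix = Path(path).suffix.lower()
    if suffix == ".gro":
        return "GRO"
    if suffix == ".pdb":
        return "PDB"
    raise ValueError(f"cannot infer format from {path}; pass format='PDB' or 'GRO'")


def read_structure(path: str | Path, format: str | None = None,
                   role_map: dict[str, ChainRole] | None = None) -> tuple[Topology, Frame]:
    """Read a single-frame structure (first frame of a multi-frame file)."""
    fmt = _format_from_path(path, format)
    text = Path(path).read_text()
    if fmt == "GRO":
        topo, frame, _ = _parse_gro_block(text.splitlines(), 0, role_map)
        return topo, frame
    if fmt == "PDB":
        topo, frames, _ = _parse_pdb(text, role_map)
        return topo, frames[0]
    raise ValueError(f"unsupported format {fmt!r}")


def read_trajectory(path: str | Path, format: str | None = None,
                    frame_stride: float = 20.0,
                    role_map: dict[str, ChainRole] | None = None) -> Trajectory:
    """Read a multi-model PDB or concatenated GRO trajectory.

    GRO frame times come from ``t=`` in the title line when present,
    otherwise ``index * frame_stride`` (ps).
    """
    fmt = _format_from_path(path, format)
    text = Path(path).read_text()
    if fmt == "GRO":
        lines = text.splitlines()
        topo = None
        frames = []
        pos = 0
        while pos < len(lines) and lines[pos].strip():
            t, fr, used = _parse_gro_block(lines[pos:], pos, role_map)
            if topo is None:
                topo = t
            elif len(t) != len(topo):
                raise ParseError(
                    f"model {len(frames) + 1}: atom count {len(t)} differs from "
                    f"first model ({len(topo)})"
                )
            frames.append(fr)
            pos += used
    elif fmt == "PDB":
        topo, frames, _ = _parse_pdb(text, role_map)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    times = np.array([fr.time for fr in frames])
    if len(frames) > 1 and not np.all(np.diff(times) > 0):
        for i, fr in enumerate(frames):
            fr.time = i * frame_stride
    return Trajectory(topo, frames, frame_stride=frame_stride)


def write_structure(path: str | Path, topology: Topology, frame: Frame,
                    format: str | None = None, title: str = "memtraj") -> None:
    fmt = _format_from_path(path, format)
    if fmt == "GRO":
        Path(path).write_text(_format_gro_frame(topology, frame, title))
    elif fmt == "PDB":
        Path(path).write_text(_format_pdb(topology, [frame], multi=False))
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def write_trajectory(path: str | Path, traj: Trajectory,
                     format: str | None = None, title: str = "memtraj") -> None:
    fmt = _format_from_path(path, format)
    if fmt == "GRO":
        Path(path).write_text(
            "".join(_format_gro_frame(traj.topology, traj[i], title)
                    for i in range(traj.n_frames))
        )
    elif fmt == "PDB":
        Path(path).write_text(
            _format_pdb(traj.topology, [traj[i] for i in range(traj.n_frames)], multi=True)
        )
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_trajectory_xtc(path: str | Path, topology: Topology,
                        frame_stride: float = 20.0) -> Trajectory:
    """Plug-in point for a compressed-trajectory backend (XTC).

    Delegates to :mod:`mdtraj` when it is importable; XTC support is
    optional and never a hard dependency.  ``topology`` supplies names and
    roles since XTC stores only coordinates, box and time.
    """
    try:
        import mdtraj as md
    except ImportError as exc:  # pragma: no cover
        raise ImportError("XTC support requires the optional mdtraj backend") from exc
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".gro", mode="w", delete=False) as fh:
        dummy = Frame(np.zeros((len(topology), 3)), np.ones(3))
        fh.write(_format_gro_frame(topology, dummy, "xtc topology"))
        top_path = fh.name
    t = md.load_xtc(str(path), top=top_path)
    if t.unitcell_lengths is None:
        raise ParseError("XTC has no box information; a box is required")
    return Trajectory.from_arrays(
        topology, t.xyz.astype(float), t.unitcell_lengths.astype(float),
        times=t.time.astype(float), frame_stride=frame_stride,
    )
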