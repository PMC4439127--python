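import numpy as np
import pytest

from memtraj.model_io import AtomRecord, ChainRole, Frame, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_point_topology(n, role=ChainRole.PROTEIN, atom_name="CA",
                        residue_name="ALA", element="C", start_resid=1):
    return Topology(
        AtomRecord(atom_name, residue_name, start_resid + i, role, element)
        for i in range(n)
    )


def traj_from_xyz(xyz, box=(10.0, 10.0, 10.0), role=ChainRole.PROTEIN,
                  atom_name="CA", dt=20.0):
    xyz = np.asarray(xyz, float)
    topo = make_point_topology(xyz.shape[1], role=role, atom_name=atom_name)
    return Trajectory.from_arrays(topo, xyz, np.asarray(box, float),
                                  frame_stride=dt)


@pytest.fixture
def random_cloud(rng):
    def _make(n=10, scale=1.0):
        return rng.normal(0.0, scale, size=(n, 3))
    return _make
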