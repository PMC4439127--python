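"""Bilayer structure metrics, hydrogen bonds and lateral diffusion."""

import numpy as np
import pytest

from memtraj.membrane import (
    NM2_PER_PS_TO_CM2_PER_S,
    DensityProfile,
    MobilityGroup,
    area_per_lipid_grid,
    bilayer_thickness,
    classify_proximal,
    density_profile,
    detect_hbonds,
    fit_diffusion,
    hbond_occupancies,
    lateral_msd,
    pn_tilt,
)
from memtraj.model_io import (
    AtomRecord,
    ChainRole,
    Frame,
    SelectionSpec,
    Topology,
    Trajectory,
    minimum_image_distance,
    select_atoms,
)
from memtraj.synthgen import SynthConfig, make_bilayer, make_brownian

P_SPEC = SelectionSpec(atom_names=("P",))
LIPIDS = (ChainRole.POPC, ChainRole.POPE)


def _bilayer_traj(cfg, n_frames=1):
    topo, frame = make_bilayer(cfg)
    xyz = np.repeat(frame.coordinates[None], n_frames, axis=0)
    return Trajectory.from_arrays(topo, xyz, frame.box)


class TestDensityAndThickness:
    def test_delta_leaflets_two_peaks(self):
        cfg = SynthConfig(seed=1, n_lipids={"POPC": 32}, leaflet_z=2.0,
                          lattice_jitter=0.0)
        traj = _bilayer_traj(cfg)
        prof = density_profile(traj, P_SPEC, bin_width=0.1)
        occupied = prof.bin_centers[prof.density > 0]
        assert len(occupied) == 2
        assert occupied[1] - occupied[0] == pytest.approx(4.0, abs=0.1)

    def test_integral_recovers_atom_count(self):
        cfg = SynthConfig(seed=2, n_lipids={"POPC": 50})
        traj = _bilayer_traj(cfg, n_frames=3)
        prof = density_profile(traj, P_SPEC, bin_width=0.07)
        n_p = select_atoms(traj.topology, P_SPEC).size
        assert prof.integral_count() == pytest.approx(n_p, rel=1e-6)

    def test_uniform_z_is_flat_within_poisson(self, rng):
        n = 5000
        atoms = [AtomRecord("OW", "SOL", i + 1, ChainRole.WATER, "O")
                 for i in range(n)]
        coords = rng.uniform(0, 5, size=(n, 3))
        # midplane ref: 2 phosphate atoms at the box centre
        patoms = [AtomRecord("P", "POPC", n + 1 + i, ChainRole.POPC, "P")
                  for i in range(2)]
        pcoords = np.array([[2.5, 2.5, 2.5], [2.6, 2.5, 2.5]])
        topo = Topology(atoms + patoms)
        traj = Trajectory.from_arrays(topo, np.vstack([coords, pcoords])[None],
                                      np.full(3, 5.0))
        prof = density_profile(traj, SelectionSpec(roles=(ChainRole.WATER,)),
                               bin_width=0.5)
        core = prof.density[np.abs(prof.bin_centers) < 2.0]
        expect = n / 125.0  # number density of the uniform box
        sigma = np.sqrt(expect * 0.5 * 25.0) / (0.5 * 25.0)
        assert np.all(np.abs(core - expect) < 3 * sigma)

    def test_gaussian_leaflets_thickness(self, rng):
        z = np.concatenate([rng.normal(1.9, 0.2, 20000),
                            rng.normal(-1.9, 0.2, 20000)])
        edges = np.arange(-3.0, 3.01, 0.05)
        h, _ = np.histogram(z, bins=edges)
        prof = DensityProfile(bin_centers=(edges[:-1] + edges[1:]) / 2,
                              density=h.astype(float), bin_width=0.05,
                              box_area=1.0, n_frames=1)
        out = bilayer_thickness(prof)
        assert out["thickness"] == pytest.approx(3.8, abs=0.02)

    def test_invariant_under_z_translation(self):
        cfg = SynthConfig(seed=4, n_lipids={"POPC": 32})
        topo, frame = make_bilayer(cfg)
        base = Trajectory.from_arrays(topo, frame.coordinates[None], frame.box)
        shifted_xyz = frame.coordinates + np.array([0.0, 0.0, 0.9])
        shifted = Trajectory.from_arrays(topo, shifted_xyz[None], frame.box)
        t1 = bilayer_thickness(density_profile(base, P_SPEC))
        t2 = bilayer_thickness(density_profile(shifted, P_SPEC))
        assert t1["thickness"] == pytest.approx(t2["thickness"], abs=1e-9)

    def test_single_mode_profile_rejected(self):
        prof = DensityProfile(bin_centers=np.array([0.1, 0.2]),
                              density=np.array([1.0, 2.0]), bin_width=0.1,
                              box_area=1.0, n_frames=1)
        with pytest.raises(ValueError, match="no bilayer"):
            bilayer_thickness(prof)


class TestAreaPerLipid:
    @pytest.mark.parametrize("apl", [0.61, 1.0, 2.56])
    def test_lattice_closed_form(self, apl):
        """Unjittered lattice: every lipid gets exactly a^2 = apl."""
        cfg = SynthConfig(seed=5, n_lipids={"POPC": 32}, apl_true=apl,
                          lattice_jitter=0.0)
        traj = _bilayer_traj(cfg)
        out = area_per_lipid_grid(traj, P_SPEC, grid=100)
        assert out.mean_apl == pytest.approx(apl, rel=1e-9)
        for area in out.per_lipid_area.values():
            assert area == pytest.approx(apl, rel=1e-9)

    def test_cell_area_conservation_exact(self):
        cfg = SynthConfig(seed=6, n_lipids={"POPC": 32, "POPE": 32},
                          lattice_jitter=0.05)
        traj = _bilayer_traj(cfg)
        out = area_per_lipid_grid(traj, P_SPEC, grid=60)
        total = sum(out.per_lipid_area.values()) + 2 * out.protein_area
        assert total == pytest.approx(2 * out.leaflet_area, rel=1e-12)

    def test_protein_column_decreases_apl(self):
        """Appending a protein column to the same lipid configuration can
        only take grid cells away from lipids."""
        cfg = SynthConfig(seed=7, n_lipids={"POPC": 128}, lattice_jitter=0.0)
        topo, frame = make_bilayer(cfg)
        apl_free = area_per_lipid_grid(
            Trajectory.from_arrays(topo, frame.coordinates[None], frame.box),
            P_SPEC).mean_apl
        center = frame.box / 2
        n_ca = 30
        prot = [AtomRecord("CA", "ALA", 10000 + i, ChainRole.PROTEIN, "C")
                for i in range(n_ca)]
        prot_xyz = np.column_stack([
            center[0] + 0.6 * np.cos(np.linspace(0, 6 * np.pi, n_ca)),
            center[1] + 0.6 * np.sin(np.linspace(0, 6 * np.pi, n_ca)),
            np.linspace(0.2, frame.box[2] - 0.2, n_ca)])
        topo2 = Topology(list(topo.atoms) + prot)
        xyz2 = np.vstack([frame.coordinates, prot_xyz])[None]
        apl_prot = area_per_lipid_grid(
            Trajectory.from_arrays(topo2, xyz2, frame.box), P_SPEC,
            protein_spec=SelectionSpec(roles=(ChainRole.PROTEIN,))).mean_apl
        assert apl_prot < apl_free

    def test_apl_thickness_anticorrelation(self):
        """With a fixed leaflet z-spread, growing the area per lipid never
        grows the computed thickness."""
        thicknesses = []
        for apl in (0.50, 0.56, 0.61):
            cfg = SynthConfig(seed=8, n_lipids={"POPC": 50}, apl_true=apl,
                              leaflet_z=1.9)
            traj = _bilayer_traj(cfg)
            t = bilayer_thickness(density_profile(traj, P_SPEC))["thickness"]
            thicknesses.append(t)
        assert thicknesses[0] >= thicknesses[1] >= thicknesses[2] - 1e-9


class TestPnTilt:
    def _two_lipid_traj(self, pn_vectors, signs=(1, -1)):
        atoms, coords = [], []
        for i, (pn, sgn) in enumerate(zip(pn_vectors, signs)):
            p = np.array([1.0 + i, 1.0, 5.0 + sgn * 2.0])
            atoms += [AtomRecord("P", "POPC", i + 1, ChainRole.POPC, "P"),
                      AtomRecord("N", "POPC", i + 1, ChainRole.POPC, "N")]
            coords += [p, p + pn]
        traj = Trajectory.from_arrays(Topology(atoms),
                                      np.array(coords)[None], np.full(3, 10.0))
        return traj

    def test_outward_normal_is_zero_degrees(self):
        traj = self._two_lipid_traj([np.array([0, 0, 0.45]),
                                     np.array([0, 0, -0.45])])
        out = pn_tilt(traj)
        np.testing.assert_allclose(out.angles, 0.0, atol=1e-9)

    def test_in_plane_is_ninety(self):
        traj = self._two_lipid_traj([np.array([0.45, 0, 0]),
                                     np.array([0, 0.45, 0])])
        out = pn_tilt(traj)
        np.testing.assert_allclose(out.angles, 90.0, atol=1e-9)

    def test_invariant_under_rotation_about_z(self):
        vecs = [np.array([0.3, 0.1, 0.3]), np.array([0.1, -0.2, -0.35])]
        traj = self._two_lipid_traj(vecs)
        base = pn_tilt(traj).angles
        theta = np.radians(73.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = Trajectory.from_arrays(traj.topology, traj.xyz @ rot.T,
                                       np.full(3, 10.0))
        np.testing.assert_allclose(pn_tilt(moved).angles, base, atol=1e-9)

    def test_unpaired_pn_raises(self):
        atoms = [AtomRecord("P", "POPC", 1, ChainRole.POPC, "P"),
                 AtomRecord("P", "POPC", 2, ChainRole.POPC, "P"),
                 AtomRecord("N", "POPC", 1, ChainRole.POPC, "N")]
        traj = Trajectory.from_arrays(Topology(atoms),
                                      np.zeros((1, 3, 3)) + 1.0, np.full(3, 5.0))
        with pytest.raises(ValueError, match="pair 1:1"):
            pn_tilt(traj)

    def test_mean_recovery_at_programmed_tilt(self):
        """Generator round trip at n ~ 1e4: the sample mean of the tilt
        angle reproduces the programmed 65-degree mean within a degree."""
        cfg = SynthConfig(seed=9, n_lipids={"POPC": 10000},
                          tilt_mean={"POPC": 65.0}, tilt_sd={"POPC": 10.0})
        topo, frame = make_bilayer(cfg)
        traj = Trajectory.from_arrays(topo, frame.coordinates[None], frame.box)
        out = pn_tilt(traj)
        assert out.angles.size >= 10000
        assert out.mean_tilt("POPC") == pytest.approx(65.0, abs=1.0)


def _hbond_frame():
    """Three-atom donor/acceptor toy: D-H pointing at A."""
    atoms = [AtomRecord("N", "POPE", 1, ChainRole.POPE, "N"),
             AtomRecord("HN", "POPE", 1, ChainRole.POPE, "H"),
             AtomRecord("O", "POPC", 2, ChainRole.POPC, "O")]
    return Topology(atoms)


class TestHbonds:
    def test_geometric_criterion_accepts(self):
        topo = _hbond_frame()
        coords = np.array([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.29, 1.05, 1.0]])
        frame = Frame(coords, np.full(3, 5.0))
        bonds = detect_hbonds(frame, np.array([[0, 1]]), np.array([2]))
        assert len(bonds) == 1

    def test_distance_cut_rejects(self):
        topo = _hbond_frame()
        coords = np.array([[1.0, 1.0, 1.0], [1.1, 1.0, 1.0], [1.40, 1.0, 1.0]])
        frame = Frame(coords, np.full(3, 5.0))
        assert detect_hbonds(frame, np.array([[0, 1]]), np.array([2])) == []

    def test_angle_cut_rejects(self):
        coords = np.array([[1.0, 1.0, 1.0], [1.0, 1.1, 1.0], [1.30, 1.0, 1.0]])
        frame = Frame(coords, np.full(3, 5.0))
        # H sits perpendicular to the D->A direction: angle 90 degrees
        assert detect_hbonds(frame, np.array([[0, 1]]), np.array([2])) == []

    def test_matches_brute_force_scan(self, rng):
        n = 100
        atoms = []
        for i in range(n):
            atoms.append(AtomRecord(["N", "HN", "O"][i % 3], "POPE",
                                    i // 3 + 1, ChainRole.POPE,
                                    ["N", "H", "O"][i % 3]))
        topo = Topology(atoms)
        coords = rng.uniform(0, 3, size=(n, 3))
        frame = Frame(coords, np.full(3, 3.0))
        donors = np.array([[i, i + 1] for i in range(0, n - 2, 3)])
        acceptors = np.arange(2, n, 3)
        got = {(b.donor, b.acceptor)
               for b in detect_hbonds(frame, donors, acceptors)}
        expect = set()
        for d, h in donors:
            for a in acceptors:
                if minimum_image_distance(coords[d], coords[a], frame.box) > 0.35:
                    continue
                vdh = coords[h] - coords[d]
                vda = coords[a] - coords[d]
                vdh -= frame.box * np.round(vdh / frame.box)
                vda -= frame.box * np.round(vda / frame.box)
                cosang = vdh @ vda / np.linalg.norm(vdh) / np.linalg.norm(vda)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30.0:
                    expect.add((int(d), int(a)))
        assert got == expect

    def test_occupancy_arithmetic(self, rng):
        """5 geometric bonds over 20 acceptor oxygens give occupancy 0.25."""
        atoms, coords = [], []
        rid = 0
        for i in range(5):  # bonded donor/acceptor pairs, far apart
            rid += 1
            base = np.array([1.0 + 4.0 * i, 1.0, 1.0])
            atoms += [AtomRecord("N", "POPE", rid, ChainRole.POPE, "N"),
                      AtomRecord("HN", "POPE", rid, ChainRole.POPE, "H")]
            coords += [base, base + [0.1, 0, 0]]
            rid += 1
            atoms.append(AtomRecord("O", "POPC", rid, ChainRole.POPC, "O"))
            coords.append(base + [0.3, 0, 0])
        for i in range(15):  # acceptors far from any donor
            rid += 1
            atoms.append(AtomRecord("O", "POPC", rid, ChainRole.POPC, "O"))
            coords.append(np.array([1.0 + 4.0 * (i % 5), 10.0, 5.0 + 0.5 * (i // 5)]))
        topo = Topology(atoms)
        traj = Trajectory.from_arrays(topo, np.array(coords)[None],
                                      np.array([40.0, 20.0, 20.0]))
        donors = np.array([[i * 3, i * 3 + 1] for i in range(5)])
        acceptors = np.flatnonzero(topo.atom_names == "O")
        assert acceptors.size == 20
        occ = hbond_occupancies(traj, donors, acceptors,
                                partition={"lipid_lipid": (
                                    {"POPC", "POPE"}, {"POPC", "POPE"})})
        assert occ.occupancies["lipid_lipid"] == pytest.approx(0.25)

    def test_invariant_under_frame_duplication(self, rng):
        cfg = SynthConfig(seed=10, n_lipids={"POPC": 16, "POPE": 16})
        topo, frame = make_bilayer(cfg)
        from memtraj.pipeline import build_hbond_tables
        donors, acceptors = build_hbond_tables(topo)
        one = Trajectory.from_arrays(topo, frame.coordinates[None], frame.box)
        two = Trajectory.from_arrays(
            topo, np.repeat(frame.coordinates[None], 3, axis=0), frame.box)
        o1 = hbond_occupancies(one, donors, acceptors).occupancies
        o2 = hbond_occupancies(two, donors, acceptors).occupancies
        assert o1 == o2

    def test_empty_acceptor_class_raises(self):
        cfg = SynthConfig(seed=10, n_lipids={"POPC": 8})
        topo, frame = make_bilayer(cfg)
        traj = Trajectory.from_arrays(topo, frame.coordinates[None], frame.box)
        from memtraj.pipeline import build_hbond_tables
        donors, acceptors = build_hbond_tables(topo)
        with pytest.raises(ValueError, match="no acceptor"):
            hbond_occupancies(traj, donors.reshape(-1, 2), acceptors,
                              partition={"protein_solvent": (
                                  {"protein"}, {"water"})})


class TestProximity:
    def _system(self):
        atoms = [AtomRecord("CA", "ALA", 1, ChainRole.PROTEIN, "C"),
                 AtomRecord("C1", "CHOL", 2, ChainRole.CHOL, "C"),
                 AtomRecord("C1", "CHOL", 3, ChainRole.CHOL, "C")]
        return Topology(atoms)

    def test_ever_touching_is_proximal(self):
        topo = self._system()
        xyz = np.array([
            [[5.0, 5, 5], [5.3, 5, 5], [8.0, 8, 8]],   # mol 2 touches here
            [[5.0, 5, 5], [7.0, 7, 7], [8.0, 8, 8]],
        ])
        labels = classify_proximal(
            Trajectory.from_arrays(topo, xyz, np.full(3, 20.0)),
            SelectionSpec(roles=(ChainRole.CHOL,)),
            SelectionSpec(roles=(ChainRole.PROTEIN,)), cutoff=0.35)
        assert labels[2] is MobilityGroup.PROXIMAL
        assert labels[3] is MobilityGroup.FREE

    def test_partition_exhaustive_exclusive(self):
        topo = self._system()
        xyz = np.full((3, 3, 3), 5.0)
        xyz[:, 2] = 9.0
        labels = classify_proximal(
            Trajectory.from_arrays(topo, xyz, np.full(3, 20.0)),
            SelectionSpec(roles=(ChainRole.CHOL,)),
            SelectionSpec(roles=(ChainRole.PROTEIN,)))
        assert set(labels) == {2, 3}
        assert all(v in (MobilityGroup.PROXIMAL, MobilityGroup.FREE)
                   for v in labels.values())


class TestDiffusion:
    def test_unit_conversion_chain(self):
        # 1 nm^2 = 1e-14 cm^2 and 1 ps = 1e-12 s
        assert NM2_PER_PS_TO_CM2_PER_S == pytest.approx(1e-14 / 1e-12)

    def test_stationary_msd_zero(self):
        topo = Topology([AtomRecord("C1", "CHOL", i + 1, ChainRole.CHOL, "C")
                         for i in range(4)])
        xyz = np.repeat(np.arange(12, dtype=float).reshape(1, 4, 3), 20, axis=0)
        lags, msd = lateral_msd(Trajectory.from_arrays(topo, xyz, np.full(3, 50.0)),
                                np.arange(4))
        np.testing.assert_allclose(msd, 0.0)
        est = fit_diffusion(lags, msd)
        assert est.D_cm2_per_s == 0.0

    def test_ballistic_msd_quadratic(self):
        topo = Topology([AtomRecord("C1", "CHOL", 1, ChainRole.CHOL, "C")])
        v = np.array([0.01, 0.02])  # nm/ps
        dt = 20.0
        xyz = np.zeros((40, 1, 3)) + 5.0
        for k in range(40):
            xyz[k, 0, :2] = 5.0 + v * k * dt
        traj = Trajectory.from_arrays(topo, xyz, np.full(3, 1e4), frame_stride=dt)
        lags, msd = lateral_msd(traj, np.array([0]), unwrap=False)
        expect = (v @ v) * lags ** 2
        np.testing.assert_allclose(msd, expect, rtol=1e-9)

    def test_exact_line_recovers_d(self):
        d0 = 3.0e-6  # nm^2/ps
        lags = np.arange(0, 1000.0, 20.0)
        msd = 4 * d0 * lags
        est = fit_diffusion(lags, msd)
        assert est.D_cm2_per_s == pytest.approx(d0 * NM2_PER_PS_TO_CM2_PER_S,
                                                rel=1e-12)
        assert not est.negative_slope

    def test_negative_slope_flagged(self):
        lags = np.arange(0, 200.0, 20.0)
        est = fit_diffusion(lags, -0.01 * lags)
        assert est.negative_slope
        assert est.D_cm2_per_s == 0.0

    def test_brownian_increment_variance(self):
        cfg = SynthConfig(seed=12, n_lipids={"POPC": 36}, n_frames=300,
                          D_true={"free": 8e-8})
        topo, frame = make_bilayer(cfg)
        traj = make_brownian(cfg, topo, frame)
        p_idx = select_atoms(topo, P_SPEC)
        from memtraj.membrane import unwrap_xy
        pos = unwrap_xy(traj.xyz[:, p_idx, :2], traj.boxes)
        steps = np.diff(pos, axis=0)
        var = steps.var()
        expect = 2 * 8e-8 * 100.0 * cfg.dt  # 2 D dt in nm^2
        assert var == pytest.approx(expect, rel=0.05)

    def test_brownian_round_trip_recovers_d(self):
        """Seed-averaged Einstein-relation estimate recovers the generator
        diffusion coefficient within 10%."""
        estimates = []
        for seed in range(6):
            cfg = SynthConfig(seed=200 + seed, n_lipids={"POPC": 64},
                              n_frames=300, D_true={"free": 8e-8})
            topo, frame = make_bilayer(cfg)
            traj = make_brownian(cfg, topo, frame)
            p_idx = select_atoms(topo, P_SPEC)
            lags, msd = lateral_msd(traj, p_idx)
            estimates.append(fit_diffusion(lags, msd).D_cm2_per_s)
        assert np.mean(estimates) == pytest.approx(8e-8, rel=0.10)
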