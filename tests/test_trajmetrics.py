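"""Trajectory statistics: RMSD family, bound fraction, contacts, grids."""

import numpy as np
import pytest

from peptriage.core_io import (
    SelectionError,
    Trajectory,
    select_atoms,
    superpose,
    rmsd as plain_rmsd,
)
from peptriage.synthetic import gen_binding_trajectory
from peptriage.trajmetrics import (
    BindingSiteDefinition,
    ContactSpec,
    average_structure,
    bound_fraction,
    contact_frequencies,
    interface_rmsd,
    ligand_rmsd_series,
    occupancy_grid,
    rmsf,
    secondary_structure_mask,
)
from tests.conftest import build_chain


@pytest.fixture(scope="module")
def two_chain_system():
    """Receptor chain A (10 residues) + peptide chain B (3 residues)."""
    rec = build_chain(10, chain_id="A", seed=1)
    pep = build_chain(3, chain_id="B", seed=2)
    from peptriage.core_io import MolecularStructure

    pep_coords = pep.coordinates - pep.coordinates.mean(0) + rec.coordinates.mean(0) + [0, 5.0, 0]
    return MolecularStructure(
        serials=np.arange(1, rec.n_atoms + pep.n_atoms + 1),
        names=list(rec.names) + list(pep.names),
        elements=list(rec.elements) + list(pep.elements),
        residue_names=list(rec.residue_names) + list(pep.residue_names),
        residue_indices=list(rec.residue_indices) + list(pep.residue_indices),
        chain_ids=list(rec.chain_ids) + list(pep.chain_ids),
        coordinates=np.vstack([rec.coordinates, pep_coords]),
    )


class TestLigandRmsd:
    def test_static_trajectory_is_zero(self, two_chain_system):
        s = two_chain_system
        traj = Trajectory(s, [s.coordinates.copy()] * 4)
        rec = select_atoms(s, "chain A and name CA")
        lig = select_atoms(s, "chain B and heavy")
        np.testing.assert_allclose(ligand_rmsd_series(traj, rec, lig), 0.0, atol=1e-9)

    def test_rigid_ligand_shift_reads_exactly(self, two_chain_system):
        s = two_chain_system
        lig_idx = select_atoms(s, "chain B").resolved_indices
        shifted = s.coordinates.copy()
        shifted[lig_idx] += np.array([0.0, 0.0, 5.0])
        traj = Trajectory(s, [s.coordinates.copy(), shifted])
        series = ligand_rmsd_series(
            traj, select_atoms(s, "chain A and name CA"), select_atoms(s, "chain B")
        )
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        assert series[1] == pytest.approx(5.0, abs=1e-6)

    def test_matches_two_step_oracle(self, two_chain_system):
        s = two_chain_system
        rng = np.random.default_rng(3)
        frames = [s.coordinates + rng.normal(0, 0.4, s.coordinates.shape) for _ in range(5)]
        traj = Trajectory(s, frames)
        fit = select_atoms(s, "chain A and name CA")
        lig = select_atoms(s, "chain B")
        series = ligand_rmsd_series(traj, fit, lig)
        for k, frame in enumerate(frames):
            _, _, fitted = superpose(frame, frames[0], fit.resolved_indices,
                                     weights=s.masses)
            expected = plain_rmsd(fitted, frames[0], lig.resolved_indices)
            assert series[k] == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_global_rigid_motion(self, two_chain_system):
        s = two_chain_system
        rng = np.random.default_rng(4)
        frames = [s.coordinates + rng.normal(0, 0.3, s.coordinates.shape) for _ in range(3)]
        fit = select_atoms(s, "chain A and name CA")
        lig = select_atoms(s, "chain B")
        base = ligand_rmsd_series(Trajectory(s, frames), fit, lig)
        theta = 0.9
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = [f @ R.T + np.array([7.0, -3.0, 2.0]) for f in frames]
        np.testing.assert_allclose(
            ligand_rmsd_series(Trajectory(s, moved), fit, lig), base, atol=1e-6
        )


class TestInterfaceRmsd:
    def test_identity_is_zero(self, two_chain_system):
        s = two_chain_system
        a = select_atoms(s, "chain A")
        b = select_atoms(s, "chain B")
        assert interface_rmsd(s, s, a, b) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_peptide_reads_unbound_like(self, two_chain_system):
        s = two_chain_system
        a = select_atoms(s, "chain A")
        b = select_atoms(s, "chain B")
        coords = s.coordinates.copy()
        coords[b.resolved_indices] += 50.0
        assert interface_rmsd(s.with_coordinates(coords), s, a, b) > 10.0

    def test_gaussian_perturbation_matches_sqrt3_sigma(self, two_chain_system):
        s = two_chain_system
        a = select_atoms(s, "chain A")
        b = select_atoms(s, "chain B")
        sigma = 0.3
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(100):
            coords = s.coordinates + rng.normal(0, sigma, s.coordinates.shape)
            vals.append(interface_rmsd(s.with_coordinates(coords), s, a, b))
        assert np.mean(vals) == pytest.approx(np.sqrt(3) * sigma, rel=0.20)

    def test_empty_interface_is_an_error_not_zero(self, two_chain_system):
        s = two_chain_system
        a = select_atoms(s, "chain A")
        b = select_atoms(s, "chain B")
        coords = s.coordinates.copy()
        coords[b.resolved_indices] += 500.0
        far = s.with_coordinates(coords)
        with pytest.raises(SelectionError, match="I-RMSD|interface"):
            interface_rmsd(far, far, a, b)


class TestRmsf:
    def test_static_is_zero(self, two_chain_system):
        s = two_chain_system
        traj = Trajectory(s, [s.coordinates.copy()] * 3)
        vals = rmsf(traj, select_atoms(s, "all"))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in vals.values())

    def test_two_point_oscillation_reads_one(self):
        s = build_chain(6, atoms_per_residue=("CA",), seed=0)
        up = s.coordinates.copy()
        down = s.coordinates.copy()
        up[5, 0] += 1.0
        down[5, 0] -= 1.0
        traj = Trajectory(s, [up, down])
        align = np.arange(5)  # align on the static atoms only
        vals = rmsf(traj, select_atoms(s, "all"), align_selection=align)
        assert vals[("A", 6)] == pytest.approx(1.0, abs=1e-6)
        assert vals[("A", 1)] == pytest.approx(0.0, abs=1e-6)

    def test_floppy_loop_exceeds_stiff_loop(self):
        s = build_chain(20, atoms_per_residue=("CA",), seed=1)
        rng = np.random.default_rng(6)
        frames = []
        for _ in range(30):
            f = s.coordinates.copy()
            f[10:14] += rng.normal(0, 1.0, (4, 3))   # floppy: residues 11-14
            f[2:6] += rng.normal(0, 0.05, (4, 3))    # stiff: residues 3-6
            frames.append(f)
        vals = rmsf(
            Trajectory(s, frames),
            select_atoms(s, "all"),
            align_selection=np.concatenate([np.arange(0, 2), np.arange(15, 20)]),
        )
        floppy = np.mean([vals[("A", r)] for r in range(11, 15)])
        stiff = np.mean([vals[("A", r)] for r in range(3, 7)])
        assert floppy > stiff

    def test_single_frame_rejected(self, two_chain_system):
        s = two_chain_system
        with pytest.raises(ValueError):
            rmsf(Trajectory(s, [s.coordinates.copy()]), select_atoms(s, "all"))


class TestBoundFraction:
    def test_generator_mask_recovered_exactly(self):
        mask = np.zeros(200, bool)
        mask[:120] = True
        traj, _, man = gen_binding_trajectory(bound_mask=mask, seed=8)
        pep = select_atoms(traj.topology, "chain B")
        rec = select_atoms(traj.topology, "chain A")
        site = BindingSiteDefinition.from_reference(traj.frame_structure(0), pep, rec)
        frac, dist, got_mask = bound_fraction(traj, site, pep)
        assert frac == man.planted_truth["bound_fraction"] == 0.6
        np.testing.assert_array_equal(got_mask, mask)

    def test_cutoff_boundary(self):
        # single receptor residue at the origin, peptide carbon straight above
        s = build_chain(1, atoms_per_residue=("CA",), seed=0)
        from peptriage.core_io import MolecularStructure

        sys = MolecularStructure(
            serials=[1, 2],
            names=["CA", "C1"],
            elements=["C", "C"],
            residue_names=["ALA", "LIG"],
            residue_indices=[1, 1],
            chain_ids=["A", "B"],
            coordinates=np.array([[0.0, 0, 0], [0.0, 0, 4.0]]),
        )
        pep = select_atoms(sys, "chain B")
        rec = select_atoms(sys, "chain A")
        site = BindingSiteDefinition.from_reference(sys, pep, rec)

        def frame(z):
            c = sys.coordinates.copy()
            c[1, 2] = z
            return c

        frac_in, _, _ = bound_fraction(Trajectory(sys, [frame(5.9)]), site, pep)
        frac_out, _, _ = bound_fraction(Trajectory(sys, [frame(6.1)]), site, pep)
        assert frac_in == 1.0 and frac_out == 0.0

    def test_distance_series_matches_brute_force(self):
        traj, _, _ = gen_binding_trajectory(bound_mask=np.ones(10, bool), seed=9)
        top = traj.topology
        pep = select_atoms(top, "chain B")
        rec = select_atoms(top, "chain A")
        site = BindingSiteDefinition.from_reference(traj.frame_structure(0), pep, rec)
        _, dist, _ = bound_fraction(traj, site, pep)
        site_idx = site.com_indices(top)
        for k, frame in enumerate(traj.frames):
            m = top.masses
            site_com = (m[site_idx, None] * frame[site_idx]).sum(0) / m[site_idx].sum()
            pep_idx = pep.resolved_indices
            pep_com = (m[pep_idx, None] * frame[pep_idx]).sum(0) / m[pep_idx].sum()
            assert dist[k] == pytest.approx(np.linalg.norm(pep_com - site_com), abs=1e-9)

    def test_parameter_recovery_across_fractions_and_seeds(self):
        # planted fractions are recovered exactly under guaranteed separability
        for frac10 in range(1, 10):
            for seed in range(2):
                n = 100
                mask = np.zeros(n, bool)
                mask[: int(n * frac10 / 10)] = True
                traj, _, _ = gen_binding_trajectory(bound_mask=mask, seed=seed)
                pep = select_atoms(traj.topology, "chain B")
                rec = select_atoms(traj.topology, "chain A")
                site = BindingSiteDefinition.from_reference(
                    traj.frame_structure(0), pep, rec
                )
                got, _, _ = bound_fraction(traj, site, pep)
                assert got == frac10 / 10


class TestContacts:
    def test_planted_contacts_at_construction_frequency(self):
        mask = np.zeros(100, bool)
        mask[:60] = True
        traj, _, man = gen_binding_trajectory(bound_mask=mask, seed=10)
        filtered, full = contact_frequencies(
            traj,
            select_atoms(traj.topology, "chain A"),
            select_atoms(traj.topology, "chain B"),
        )
        for planted in man.planted_truth["contacts"]:
            rows = full[
                (full["residue_a"] == planted["residue_a"])
                & (full["residue_b"] == planted["residue_b"])
                & (full["kind"] == planted["kind"])
            ]
            assert len(rows) == 1
            assert rows["frequency"].iloc[0] == pytest.approx(0.6)

    def test_25_percent_rule(self):
        for target, kept in ((0.2, False), (0.6, True)):
            mask = np.zeros(100, bool)
            mask[: int(100 * target)] = True
            traj, _, _ = gen_binding_trajectory(bound_mask=mask, seed=11)
            filtered, full = contact_frequencies(
                traj,
                select_atoms(traj.topology, "chain A"),
                select_atoms(traj.topology, "chain B"),
            )
            salt = filtered[filtered["kind"] == "salt_bridge"]
            assert (len(salt) > 0) is kept
            assert (full["frequency"] <= 1.0).all() and (full["frequency"] >= 0.0).all()
            assert len(filtered) <= len(full)

    def test_static_salt_bridge_full_frequency(self):
        from peptriage.core_io import MolecularStructure

        s = MolecularStructure(
            serials=[1, 2],
            names=["NH1", "OE1"],
            elements=["N", "O"],
            residue_names=["ARG", "GLU"],
            residue_indices=[1, 1],
            chain_ids=["A", "B"],
            coordinates=np.array([[0.0, 0, 0], [3.2, 0, 0]]),
        )
        traj = Trajectory(s, [s.coordinates.copy()] * 5)
        _, full = contact_frequencies(
            traj, select_atoms(s, "chain A"), select_atoms(s, "chain B")
        )
        salt = full[full["kind"] == "salt_bridge"]
        assert len(salt) == 1 and salt["frequency"].iloc[0] == 1.0


class TestOccupancyAndAverage:
    def test_static_atom_single_voxel(self):
        s = build_chain(1, atoms_per_residue=("CA",), seed=0)
        traj = Trajectory(s, [s.coordinates.copy()] * 7)
        counts, _ = occupancy_grid(traj, np.array([0]))
        assert counts.max() == 7 and counts.sum() == 7

    def test_two_sites_two_voxels(self):
        s = build_chain(1, atoms_per_residue=("CA",), seed=0)
        a = s.coordinates.copy()
        b = s.coordinates + np.array([5.0, 0, 0])
        counts, _ = occupancy_grid(Trajectory(s, [a, b]), np.array([0]))
        assert (counts == 1).sum() == 2 and counts.sum() == 2

    def test_count_conservation(self, two_chain_system):
        s = two_chain_system
        rng = np.random.default_rng(7)
        frames = [s.coordinates + rng.normal(0, 2, s.coordinates.shape) for _ in range(4)]
        sel = select_atoms(s, "chain B").resolved_indices
        counts, _ = occupancy_grid(Trajectory(s, frames), sel)
        assert counts.sum() == 4 * len(sel)

    def test_average_structure(self, two_chain_system):
        s = two_chain_system
        static = average_structure(Trajectory(s, [s.coordinates.copy()] * 3))
        np.testing.assert_allclose(static.coordinates, s.coordinates, atol=1e-9)
        # anchor atoms 0-3 fixed so the fit is the identity: plain mean
        rng = np.random.default_rng(8)
        frames = []
        for _ in range(5):
            f = s.coordinates.copy()
            f[4:] += rng.normal(0, 0.5, f[4:].shape)
            frames.append(f)
        avg = average_structure(Trajectory(s, frames), fit_selection=np.arange(4))
        np.testing.assert_allclose(avg.coordinates, np.mean(frames, axis=0), atol=1e-9)


class TestSecondaryStructure:
    def test_ideal_helix_detected(self):
        # build an ideal alpha-helix backbone from internal coordinates
        import itertools

        n_res = 12
        names, resids, coords = [], [], []
        rise, twist, radius = 1.5, np.radians(100), 2.3
        for r in range(n_res):
            for k, (nm, dz, dth) in enumerate(
                [("N", -0.4, -0.4), ("CA", 0.0, 0.0), ("C", 0.5, 0.45), ("O", 0.6, 0.9)]
            ):
                th = twist * r + dth
                coords.append(
                    [radius * np.cos(th), radius * np.sin(th), rise * r + dz]
                )
                names.append(nm)
                resids.append(r + 1)
        from peptriage.core_io import MolecularStructure

        s = MolecularStructure(
            serials=np.arange(1, len(names) + 1),
            names=names,
            elements=[n[0] for n in names],
            residue_names=["ALA"] * len(names),
            residue_indices=resids,
            chain_ids=["A"] * len(names),
            coordinates=np.array(coords),
        )
        ca = secondary_structure_mask(s)
        # a regular helical geometry should yield one contiguous run
        assert len(ca) >= 4
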