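"""PDB I/O, selections, and rigid-body geometry."""

import numpy as np
import pytest

from peptriage.core_io import (
    DegenerateFitError,
    PDBParseError,
    SelectionError,
    StructuralMismatchError,
    center_of_mass,
    parse_structure,
    parse_trajectory,
    rmsd,
    select_atoms,
    superpose,
    write_structure,
    write_trajectory,
)
from peptriage.core_io import Trajectory

ONE_ATOM = (
    "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C\n"
    "END\n"
)


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_fit_rmsd(mobile, reference):
    """Independent quaternion-method superposition (Kearsley matrix)."""
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)
    xm, ym, zm = m.T
    xr, yr, zr = r.T
    xp, yp, zp = xm + xr, ym + yr, zm + zr
    xn, yn, zn = xm - xr, ym - yr, zm - zr
    K = np.empty((4, 4))
    K[0, 0] = (xn**2 + yn**2 + zn**2).sum()
    K[1, 1] = (xn**2 + yp**2 + zp**2).sum()
    K[2, 2] = (xp**2 + yn**2 + zp**2).sum()
    K[3, 3] = (xp**2 + yp**2 + zn**2).sum()
    K[0, 1] = K[1, 0] = (yp * zn - yn * zp).sum()
    K[0, 2] = K[2, 0] = (xn * zp - xp * zn).sum()
    K[0, 3] = K[3, 0] = (xp * yn - xn * yp).sum()
    K[1, 2] = K[2, 1] = (xn * yn - xp * yp).sum()
    K[1, 3] = K[3, 1] = (xn * zn - xp * zp).sum()
    K[2, 3] = K[3, 2] = (yn * zn - yp * zp).sum()
    eigval = np.linalg.eigvalsh(K)[0]
    return np.sqrt(max(eigval, 0.0) / len(mobile))


class TestParsing:
    def test_single_atom_coordinates(self):
        s = parse_structure(ONE_ATOM)
        assert s.n_atoms == 1
        np.testing.assert_allclose(s.coordinates[0], [1.0, 2.0, 3.0])
        assert s.atom(0).name == "CA"
        assert s.atom(0).element == "C"

    def test_roundtrip_identity(self, tripeptide):
        s, _ = tripeptide
        s2 = parse_structure(write_structure(s))
        np.testing.assert_allclose(s2.coordinates, s.coordinates, atol=5e-4)
        assert list(s2.names) == list(s.names)
        assert list(s2.residue_indices) == list(s.residue_indices)
        assert list(s2.chain_ids) == list(s.chain_ids)

    def test_tripeptide_matches_manifest(self, tripeptide):
        s, manifest = tripeptide
        s2 = parse_structure(write_structure(s))
        assert s2.n_atoms == manifest["n_atoms"]
        assert len(s2.residue_groups()) == manifest["n_residues"]

    def test_empty_input_raises(self):
        with pytest.raises(PDBParseError):
            parse_structure("REMARK nothing here\nEND\n")

    def test_malformed_line_names_line_number(self):
        bad = ONE_ATOM.replace("   1.000", "   x.000")
        with pytest.raises(PDBParseError, match="line 1"):
            parse_structure(bad)


class TestTrajectoryParsing:
    def test_two_identical_models(self, tripeptide):
        s, _ = tripeptide
        traj = Trajectory(topology=s, frames=[s.coordinates.copy()] * 2)
        parsed = parse_trajectory(write_trajectory(traj))
        assert parsed.n_frames == 2
        np.testing.assert_allclose(parsed.frames[0], parsed.frames[1])

    def test_single_model_single_frame(self, tripeptide):
        s, _ = tripeptide
        parsed = parse_trajectory(write_structure(s))
        assert parsed.n_frames == 1

    def test_roundtrip_frames(self, tripeptide):
        s, _ = tripeptide
        rng = np.random.default_rng(1)
        frames = [s.coordinates + rng.normal(0, 1, s.coordinates.shape) for _ in range(5)]
        parsed = parse_trajectory(write_trajectory(Trajectory(s, frames)))
        assert parsed.n_frames == 5
        for a, b in zip(parsed.frames, frames):
            np.testing.assert_allclose(a, b, atol=5e-4)

    def test_inconsistent_models_raise(self, tripeptide):
        s, _ = tripeptide
        text = write_trajectory(Trajectory(s, [s.coordinates.copy()] * 2))
        lines = text.splitlines()
        # drop one atom from the second model
        second_atoms = [i for i, l in enumerate(lines) if l.startswith("ATOM")][s.n_atoms:]
        del lines[second_atoms[0]]
        with pytest.raises(StructuralMismatchError):
            parse_trajectory("\n".join(lines))


class TestSelections:
    def test_name_ca_on_tripeptide(self, tripeptide):
        s, _ = tripeptide
        assert len(select_atoms(s, "name CA")) == 3

    def test_backbone_heavy_range_counts(self, chain160):
        sel = select_atoms(chain160, "resid 103-117 and backbone and heavy")
        # 15 residues x 4 backbone heavy atoms, counted by enumeration
        expected = sum(
            1
            for i in range(chain160.n_atoms)
            if 103 <= chain160.residue_indices[i] <= 117
            and str(chain160.names[i]) in {"N", "CA", "C", "O"}
            and str(chain160.elements[i]) != "H"
        )
        assert expected == 60
        assert len(sel) == expected

    def test_missing_residue_is_empty_not_error(self, chain160):
        assert len(select_atoms(chain160, "resid 999")) == 0

    def test_boolean_combinations(self, chain160):
        a = select_atoms(chain160, "resid 1-10 or resid 20-30")
        b = select_atoms(chain160, "not (resid 11-19 or resid 31-160)")
        np.testing.assert_array_equal(a.resolved_indices, b.resolved_indices)

    @pytest.mark.parametrize("expr", ["resid", "chain", "bogus CA", "name", "(resid 1"])
    def test_grammar_errors_report_position(self, chain160, expr):
        with pytest.raises(SelectionError, match="position|empty"):
            select_atoms(chain160, expr)


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        R, t, fitted = superpose(x, x)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_exact_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(12, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = ref @ Rz.T + np.array([5.0, 0.0, 0.0])
        _, _, fitted = superpose(mobile, ref)
        assert rmsd(fitted, ref) < 1e-9
        R, _, _ = superpose(mobile, ref)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_matches_quaternion_oracle_with_noise(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(10, 3)) * 3
        mobile = ref @ random_rotation(rng).T + rng.normal(0, 0.1, (10, 3)) + 4.0
        _, _, fitted = superpose(mobile, ref)
        assert rmsd(fitted, ref) == pytest.approx(
            quaternion_fit_rmsd(mobile, ref), abs=1e-6
        )

    def test_fit_is_global_minimum_over_random_rotations(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3)) * 2
        mobile = ref + rng.normal(0, 0.3, (10, 3))
        _, _, fitted = superpose(mobile, ref)
        best = rmsd(fitted, ref)
        centered = fitted - fitted.mean(axis=0)
        for _ in range(1000):
            rot = centered @ random_rotation(rng).T + ref.mean(axis=0)
            # optimal translation for this rotation is centroid matching
            assert rmsd(rot, ref) >= best - 1e-9

    def test_mass_weighted_fit_prioritizes_heavy_atoms(self):
        ref = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mobile = ref + np.array([[0.0, 0, 0], [0, 0, 0], [0, 0, 0], [1.0, 0, 0]])
        w = np.array([100.0, 100.0, 100.0, 1e-6])
        _, _, fitted = superpose(mobile, ref, weights=w)
        assert rmsd(fitted[:3], ref[:3]) < 1e-3

    def test_degenerate_inputs_raise(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateFitError):
            superpose(line, line + 1.0)
        with pytest.raises(DegenerateFitError):
            superpose(line[:2], line[:2])


class TestRmsdCom:
    def test_uniform_shift_is_345(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(8, 3))
        assert rmsd(a, a + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0)

    def test_matches_brute_force_and_is_pseudometric(self):
        rng = np.random.default_rng(5)
        a, b, c = (rng.normal(size=(6, 3)) for _ in range(3))
        brute = np.sqrt(np.mean([(ai - bi) @ (ai - bi) for ai, bi in zip(a, b)]))
        assert rmsd(a, b) == pytest.approx(brute, abs=1e-12)
        assert rmsd(a, b) == pytest.approx(rmsd(b, a))
        assert rmsd(a, c) <= rmsd(a, b) + rmsd(b, c) + 1e-12

    def test_center_of_mass(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(center_of_mass(pts), [1, 0, 0])
        np.testing.assert_allclose(
            center_of_mass(pts, weights=np.array([1.0, 3.0])), [1.5, 0, 0]
        )

    def test_com_matches_brute_force(self, tripeptide):
        s, _ = tripeptide
        com = center_of_mass(s.coordinates, weights=s.masses)
        brute = (s.masses[:, None] * s.coordinates).sum(0) / s.masses.sum()
        np.testing.assert_allclose(com, brute, atol=1e-12)

    def test_empty_selection_raises(self):
        with pytest.raises(SelectionError):
            center_of_mass(np.zeros((3, 3)), indices=np.array([], int))
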