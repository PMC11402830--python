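"""Structure parsing, superposition, B-factors, distances, SASA, interface."""

import numpy as np
import pandas as pd
import pytest

import padi6tools as pt
from padi6tools.simulate import simulate_helix_chain, simulate_toy_dimer
from padi6tools.structure import (
    _ATOM_COLUMNS,
    SelectorError,
    StructureModel,
    align_and_rmsd,
    atom_distance,
    interface_stats,
    kabsch_superpose,
    read_structure,
    region_bfactor_mean,
    sasa,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40 10.00           C
END
"""


def random_rotation(seed=0):
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def quaternion_superpose_rmsd(P, Q):
    """Independent oracle: optimal superposition RMSD via the quaternion
    eigenvalue method (largest eigenvalue of the 4x4 key matrix)."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = Q.T @ P
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (np.sum(P**2) + np.sum(Q**2) - 2 * lam) / len(P)
    return np.sqrt(max(e2, 0.0))


class TestReadStructure:
    def test_minimal_pdb_text(self):
        model = read_structure(MINIMAL_PDB)
        assert len(model.atoms) == 2
        ca = model.atoms[model.atoms["atom"] == "CA"].iloc[0]
        assert ca["x"] == pytest.approx(1.458)
        assert ca["b"] == pytest.approx(20.0)

    def test_altloc_keeps_highest_occupancy(self):
        model = read_structure(ALTLOC_PDB)
        assert len(model.atoms) == 1
        assert model.atoms.iloc[0]["x"] == pytest.approx(0.0)  # occ 0.60 wins

    def test_unparseable_input_raises(self):
        with pytest.raises((ValueError, FileNotFoundError)):
            read_structure("not a structure at all\nreally not\n")

    def test_pdb_write_read_round_trip(self, tmp_path, toy_dimer):
        path = tmp_path / "toy.pdb"
        write_pdb(toy_dimer.model, path)
        back = read_structure(path)
        assert len(back.atoms) == len(toy_dimer.model.atoms)
        np.testing.assert_allclose(
            back.coords(), toy_dimer.model.coords(), atol=1e-3
        )


class TestKabsch:
    def test_identity_on_same_coords(self, helix):
        X = helix.coords()
        sup = kabsch_superpose(X, X)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_exact_on_rigid_copy(self, helix):
        X = helix.coords()
        R = random_rotation(4)
        Y = X @ R.T + np.array([3.0, -2.0, 7.0])
        sup = kabsch_superpose(X, Y)
        assert sup.rmsd < 1e-8
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_rotation_orthonormal(self, helix):
        X = helix.coords()
        rng = np.random.default_rng(1)
        Y = X + rng.normal(0, 0.5, X.shape)
        sup = kabsch_superpose(X, Y)
        assert np.linalg.norm(sup.rotation.T @ sup.rotation - np.eye(3)) < 1e-10

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(12)
        P = rng.normal(size=(4, 3)) * 5
        Q = P @ random_rotation(3).T + rng.normal(0, 0.3, (4, 3))
        sup = kabsch_superpose(P, Q)
        assert sup.rmsd == pytest.approx(quaternion_superpose_rmsd(P, Q), abs=1e-10)

    def test_matches_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        P = rng.normal(size=(20, 3)) * 4
        Q = P @ random_rotation(9).T + rng.normal(0, 0.2, (20, 3)) + 5.0
        sup = kabsch_superpose(P, Q)
        rot, _ = Rotation.align_vectors(P - P.mean(0), Q - Q.mean(0))
        np.testing.assert_allclose(rot.as_matrix(), sup.rotation, atol=1e-8)

    def test_rejects_mismatched_and_degenerate(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + 1.0)


class TestAlignAndRmsd:
    def test_chain_vs_itself(self, helix):
        sup = align_and_rmsd(helix, helix, "A", "A")
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert sup.rejected_pairs == 0

    def test_displaced_residues_rejected(self, helix):
        atoms = helix.atoms.copy()
        mask = atoms["resnum"].between(20, 24)
        atoms.loc[mask, "x"] += 6.0
        pert = StructureModel(atoms)
        sup = align_and_rmsd(helix, pert, "A", "A", reject_cutoff=2.0)
        assert sup.rejected_pairs == 5
        assert sup.rmsd < 0.01
        assert sup.n_pairs == len(helix.atoms) - 5

    def test_symmetric_in_arguments(self, helix):
        rng = np.random.default_rng(3)
        atoms = helix.atoms.copy()
        atoms[["x", "y", "z"]] += rng.normal(0, 0.3, (len(atoms), 3))
        pert = StructureModel(atoms)
        ab = align_and_rmsd(helix, pert, "A", "A")
        ba = align_and_rmsd(pert, helix, "A", "A")
        assert ab.rmsd == pytest.approx(ba.rmsd, abs=1e-6)

    def test_rmsd_invariant_under_rigid_motion(self, helix):
        rng = np.random.default_rng(5)
        atoms = helix.atoms.copy()
        atoms[["x", "y", "z"]] += rng.normal(0, 0.4, (len(atoms), 3))
        pert = StructureModel(atoms)
        base = align_and_rmsd(helix, pert, "A", "A").rmsd
        R = random_rotation(6)
        moved = pert.atoms.copy()
        moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() @ R.T + 11.0
        assert align_and_rmsd(helix, StructureModel(moved), "A", "A").rmsd == pytest.approx(
            base, rel=1e-6
        )


class TestBfactor:
    def test_uniform_region(self):
        model = simulate_helix_chain(b_factor=50.0)
        assert region_bfactor_mean(model, "A", 1, 10) == 50.0

    def test_arithmetic_mean(self):
        rows = [
            ("A", i + 1, "", "ALA", "CA", "C", float(i), 0, 0, b, 1.0, "", False, False)
            for i, b in enumerate([10.0, 20.0, 30.0])
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        assert region_bfactor_mean(model, "A", 1, 3) == 20.0

    def test_main_chain_selection(self):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 10.0, 1.0, "", False, False),
            ("A", 1, "", "ALA", "CB", "C", 1, 0, 0, 90.0, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        assert region_bfactor_mean(model, "A", 1, 1, "main_chain") == 10.0
        assert region_bfactor_mean(model, "A", 1, 1, "all_atoms") == 50.0

    def test_empty_selection_rejected(self, helix):
        with pytest.raises(ValueError):
            region_bfactor_mean(helix, "Z", 1, 5)


class TestAtomDistance:
    def test_same_atom_zero(self, helix):
        assert atom_distance(helix, "A:1:CA", "A:1:CA") == 0.0

    def test_unit_separation(self):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 1, 1.0, "", False, False),
            ("A", 2, "", "ALA", "CA", "C", 0, 0, 1, 1, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        assert atom_distance(model, "A:1", "A:2") == 1.0

    def test_ambiguous_selector_rejected(self):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 1, 1.0, "", False, False),
            ("A", 1, "", "ALA", "CB", "C", 1, 0, 0, 1, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        with pytest.raises(SelectorError):
            atom_distance(model, "A:1", "A:1")
        with pytest.raises(SelectorError):
            atom_distance(model, "A:9", "A:1:CA")

    def test_cross_model_with_superposition(self, helix):
        R = random_rotation(7)
        moved = helix.atoms.copy()
        moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() @ R.T + 9.0
        other = StructureModel(moved)
        sup = align_and_rmsd(helix, other, "A", "A")
        d = atom_distance(helix, "A:5:CA", "A:5:CA", model_b=other, post_superposition=sup)
        assert d == pytest.approx(0.0, abs=1e-6)


def single_atom_model(radius_element="C"):
    rows = [("A", 1, "", "ALA", "CA", radius_element, 0, 0, 0, 1, 1.0, "", False, False)]
    return StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = sasa(single_atom_model())[0]
        assert area == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-6)

    def test_distant_atoms_no_occlusion(self):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 1, 1.0, "", False, False),
            ("B", 1, "", "ALA", "CA", "C", 100, 0, 0, 1, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        areas = sasa(model)
        assert areas.sum() == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)

    @pytest.mark.parametrize("d", [2.0, 4.0, 5.5])
    def test_overlapping_spheres_match_cap_formula(self, d):
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 1, 1.0, "", False, False),
            ("B", 1, "", "ALA", "CA", "C", d, 0, 0, 1, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        R = 1.7 + 1.4
        cap = 2 * np.pi * R**2 * (1 - d / (2 * R))  # spherical-cap loss per atom
        expected = 2 * (4 * np.pi * R**2 - cap)
        assert sasa(model).sum() == pytest.approx(expected, rel=0.01)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            sasa(single_atom_model("ZZ"))

    def test_rigid_motion_invariance(self, toy_dimer):
        # the sample-point lattice is fixed in space, so invariance holds to
        # sampling precision (not machine precision) at 960 points
        base = sasa(toy_dimer.model).sum()
        R = random_rotation(11)
        moved = toy_dimer.model.atoms.copy()
        moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() @ R.T - 4.0
        assert sasa(StructureModel(moved)).sum() == pytest.approx(base, rel=0.005)

    def test_translation_invariance_exact(self, toy_dimer):
        base = sasa(toy_dimer.model).sum()
        moved = toy_dimer.model.atoms.copy()
        moved[["x", "y", "z"]] += np.array([13.0, -7.0, 2.5])
        assert sasa(StructureModel(moved)).sum() == pytest.approx(base, rel=1e-9)

    def test_point_count_convergence(self, toy_dimer):
        a = sasa(toy_dimer.model, n_sphere_points=960).sum()
        b = sasa(toy_dimer.model, n_sphere_points=1920).sum()
        assert abs(a - b) / b < 0.005


class TestInterface:
    def test_far_apart_chains_zero(self):
        far = simulate_toy_dimer(separation=100.0)
        st = interface_stats(far.model, "A", "B")
        assert st.buried_area == pytest.approx(0.0, abs=1e-9)
        assert st.total_residues_at_interface == 0

    def test_designed_patch_recovered(self, toy_dimer):
        st = interface_stats(toy_dimer.model, "A", "B")
        found_a = set(
            st.per_residue_buried.query("chain == 'A'")["resnum"].astype(int)
        )
        assert found_a == set(toy_dimer.contact_residues_a)
        assert st.residue_counts["B"] == len(toy_dimer.contact_residues_b)

    def test_buried_area_matches_cap_oracle(self):
        # one bead per chain at distance d: buried area is one full cap
        rows = [
            ("A", 1, "", "ALA", "CA", "C", 0, 0, 0, 1, 1.0, "", False, False),
            ("B", 1, "", "ALA", "CA", "C", 0, 0, 5.0, 1, 1.0, "", False, False),
        ]
        model = StructureModel(pd.DataFrame(rows, columns=_ATOM_COLUMNS))
        st = interface_stats(model, "A", "B")
        R = 3.1
        cap = 2 * np.pi * R**2 * (1 - 5.0 / (2 * R))
        assert st.buried_area == pytest.approx(cap, rel=0.02)

    def test_missing_chain_rejected(self, toy_dimer):
        with pytest.raises(ValueError):
            interface_stats(toy_dimer.model, "A", "Q")

    def test_zero_iff_no_reachable_pair(self):
        # centres at exactly the reach limit (ri + rj + 2 probe = 6.2 A)
        just_out = simulate_toy_dimer(separation=6.3)
        st = interface_stats(just_out.model, "A", "B")
        assert st.buried_area == pytest.approx(0.0, abs=1e-9)
        just_in = simulate_toy_dimer(separation=5.9)
        assert interface_stats(just_in.model, "A", "B").buried_area > 0
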