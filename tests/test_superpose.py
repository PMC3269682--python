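import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import _oracles as oracle
from conftest import make_nodes, random_blob
from enmkit import (
    SyntheticSpec,
    helix_bend_angle,
    kabsch_superpose,
    make_structure,
    match_by_residue,
    trimmed_superpose,
)
from enmkit.errors import DegenerateGeometryError, ValidationError


def rotz(deg):
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


class TestMatchByResidue:
    def test_identical_sets_fully_match(self, dumbbell):
        pairs, report = match_by_residue(dumbbell.nodes, dumbbell.nodes)
        assert pairs == [(i, i) for i in range(dumbbell.nodes.n_nodes)]
        assert not report["unmatched_ref"] and not report["unmatched_mov"]

    def test_missing_residues_are_reported(self):
        ref = random_blob(10, seed=1)
        keep = [0, 1, 2, 4, 5, 6, 8]  # drop residues 4, 8, 10
        mov = make_nodes(ref.coords[keep], resnums=ref.residue_numbers[keep])
        pairs, report = match_by_residue(ref, mov)
        assert len(pairs) == 7
        assert len(report["unmatched_ref"]) == 3

    def test_disjoint_numbering_is_error(self):
        ref = random_blob(5, seed=1)
        mov = make_nodes(ref.coords, resnums=np.arange(100, 105))
        with pytest.raises(ValidationError, match="no residues in common"):
            match_by_residue(ref, mov)


class TestKabschSuperpose:
    def test_translated_copy(self):
        ref = random_blob(8, seed=2).coords
        result = kabsch_superpose(ref, ref + [5.0, 0.0, 0.0])
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(result.translation, [-5.0, 0.0, 0.0], atol=1e-10)

    def test_rotated_copy(self):
        ref = random_blob(8, seed=3).coords
        rotation = rotz(90.0)
        result = kabsch_superpose(ref, ref @ rotation.T)
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(result.rotation @ rotation, np.eye(3), atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(6, 3))
        mirrored = ref * [-1.0, 1.0, 1.0]  # reflection: det correction must kick in
        result = kabsch_superpose(ref, mirrored)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-10)
        orth = result.rotation @ result.rotation.T
        np.testing.assert_allclose(orth, np.eye(3), atol=1e-10)

    def test_planted_displacement_recovered_exactly(self):
        ref = np.array([
            [0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 0.0], [0.0, 0.0, 4.0]
        ])
        mov = ref.copy()
        mov[3] += [0.0, 0.0, 1.0]  # 1 Å along z
        result = kabsch_superpose(ref, mov, fit_selection=np.array([0, 1, 2]))
        np.testing.assert_allclose(result.per_residue_deviation[:3], 0.0, atol=1e-10)
        assert result.per_residue_deviation[3] == pytest.approx(1.0, abs=1e-8)
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rmsd_is_mean_square_of_fit_deviations(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(12, 3)) * 5.0
        mov = ref + rng.normal(size=(12, 3)) * 0.5
        result = kabsch_superpose(ref, mov)
        expected = np.sqrt(np.mean(result.per_residue_deviation**2))
        assert result.rmsd == pytest.approx(expected, abs=1e-10)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(10, 3)) * 5.0
        mov = ref + rng.normal(size=(10, 3)) * 0.8
        base = kabsch_superpose(ref, mov).rmsd
        for _ in range(10):
            rot, trans = oracle.random_rigid_transform(rng)
            moved = mov @ rot.T + trans
            assert kabsch_superpose(ref, moved).rmsd == pytest.approx(base, abs=1e-8)
            rot2, trans2 = oracle.random_rigid_transform(rng)
            ref2 = ref @ rot2.T + trans2
            assert kabsch_superpose(ref2, mov).rmsd == pytest.approx(base, abs=1e-8)

    def test_self_superposition_is_identity(self):
        x = random_blob(7, seed=8).coords
        result = kabsch_superpose(x, x)
        np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(result.translation, 0.0, atol=1e-10)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line @ rotz(30.0).T)

    def test_beats_monte_carlo_rotations(self):
        """Kabsch optimality: no random rotation does better (fixed seed)."""
        rng = np.random.default_rng(9)
        for trial in range(3):
            n = rng.integers(4, 7)
            ref = rng.normal(size=(n, 3)) * 4.0
            mov = ref + rng.normal(size=(n, 3)) * 1.0
            kabsch = kabsch_superpose(ref, mov).rmsd
            mc = oracle.best_random_rotation_rmsd(ref, mov, 10_000, seed=trial)
            assert kabsch <= mc + 1e-12

    def test_agrees_with_biopython_svd_superimposer(self):
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(10)
        ref = rng.normal(size=(15, 3)) * 6.0
        mov = ref + rng.normal(size=(15, 3)) * 0.7
        ours = kabsch_superpose(ref, mov)
        sup = SVDSuperimposer()
        sup.set(ref, mov)
        sup.run()
        assert ours.rmsd == pytest.approx(sup.get_rms(), abs=1e-8)
        rot, tran = sup.get_rotran()  # Biopython applies as mov @ rot + tran
        np.testing.assert_allclose(ours.rotation, rot.T, atol=1e-8)
        np.testing.assert_allclose(ours.translation, tran, atol=1e-8)


class TestTrimmedSuperpose:
    def test_localizes_planted_deformation(self):
        """Fit on the rigid core: a deformation planted in a terminal segment
        stays there instead of leaking into the whole-chain deviations."""
        helix = make_structure(SyntheticSpec(kind="helix", n=30)).nodes.coords
        bent = helix.copy()
        pivot = bent[24]
        bend = Rotation.from_euler("x", 35, degrees=True).as_matrix()
        bent[24:] = (bent[24:] - pivot) @ bend.T + pivot
        result = trimmed_superpose(helix, bent, trim_fraction=0.2)
        core = result.per_residue_deviation[:20]
        tail = result.per_residue_deviation[26:]
        assert core.max() < 0.5
        assert tail.min() > 1.0

    def test_zero_trim_equals_plain_kabsch(self):
        rng = np.random.default_rng(11)
        ref = rng.normal(size=(10, 3)) * 5.0
        mov = ref + rng.normal(size=(10, 3)) * 0.5
        trimmed = trimmed_superpose(ref, mov, trim_fraction=0.0)
        plain = kabsch_superpose(ref, mov)
        assert trimmed.rmsd == pytest.approx(plain.rmsd, abs=1e-12)


class TestHelixBendAngle:
    def test_straight_ideal_helix(self, helix20):
        angle = helix_bend_angle(helix20.nodes, (0, 19), split=9)
        assert angle < 2.0

    def test_constructed_30_degree_bend(self, helix20):
        coords = helix20.nodes.coords.copy()
        pivot = coords[10]
        bend = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        coords[10:] = (coords[10:] - pivot) @ bend.T + pivot
        angle = helix_bend_angle(coords, (0, 19), split=9)
        assert angle == pytest.approx(30.0, abs=2.0)

    def test_mirror_symmetric_halves_have_zero_bend(self, helix20):
        # second half = first half reflected through the z=const midplane and
        # continued along +z: both halves share the same axis direction
        first = helix20.nodes.coords[:10]
        top = first[-1, 2]
        second = first[::-1] * [1.0, 1.0, -1.0] + [0.0, 0.0, 2 * top + 1.5]
        coords = np.vstack([first, second[::-1]])
        angle = helix_bend_angle(coords, (0, 19), split=9)
        assert angle == pytest.approx(0.0, abs=1e-8)

    def test_invariant_under_rigid_transform_and_scaling(self, helix20):
        coords = helix20.nodes.coords.copy()
        pivot = coords[10]
        bend = Rotation.from_euler("y", 25, degrees=True).as_matrix()
        coords[10:] = (coords[10:] - pivot) @ bend.T + pivot
        base = helix_bend_angle(coords, (0, 19), split=9)
        rng = np.random.default_rng(12)
        rot, trans = oracle.random_rigid_transform(rng)
        moved = coords @ rot.T + trans
        assert helix_bend_angle(moved, (0, 19), split=9) == pytest.approx(base, abs=1e-8)
        assert helix_bend_angle(coords * 7.5, (0, 19), split=9) == pytest.approx(
            base, abs=1e-8
        )

    def test_short_half_rejected(self, helix20):
        with pytest.raises(DegenerateGeometryError, match=">= 4"):
            helix_bend_angle(helix20.nodes, (0, 19), split=1)

    def test_bad_split_rejected(self, helix20):
        with pytest.raises(ValidationError):
            helix_bend_angle(helix20.nodes, (0, 19), split=19)
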