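import numpy as np
import pytest

import _oracles as oracle
from conftest import make_nodes, random_blob
from enmkit import (
    EnmParameters,
    SyntheticSpec,
    build_kirchhoff,
    cross_correlation,
    decompose,
    make_structure,
    mode_fluctuation,
    msf,
)
from enmkit.errors import RigidModeError, ValidationError

TWO_NODE = make_nodes([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])

FIXTURE_SPECS = [
    SyntheticSpec(kind="chain", n=12),
    SyntheticSpec(kind="ring", n=20),
    SyntheticSpec(kind="helix", n=25),
    SyntheticSpec(kind="bundle"),
    SyntheticSpec(kind="dumbbell"),
    SyntheticSpec(kind="chain", n=15, noise_sd=0.3, seed=7),
]


class TestBuildKirchhoff:
    def test_two_nodes_in_contact(self):
        k = build_kirchhoff(TWO_NODE, EnmParameters(cutoff=7.3))
        np.testing.assert_array_equal(k.matrix, [[1, -1], [-1, 1]])
        assert k.contact_count == 1

    def test_two_nodes_beyond_cutoff(self):
        nodes = make_nodes([[0, 0, 0], [8.0, 0, 0]])
        k = build_kirchhoff(nodes, EnmParameters(cutoff=7.3))
        np.testing.assert_array_equal(k.matrix, np.zeros((2, 2)))
        assert k.contact_count == 0

    def test_cutoff_is_inclusive(self):
        nodes = make_nodes([[0, 0, 0], [7.3, 0, 0]])
        k = build_kirchhoff(nodes, EnmParameters(cutoff=7.3))
        assert k.matrix[0, 1] == -1

    def test_ring_every_node_has_two_contacts(self):
        ring = make_structure(SyntheticSpec(kind="ring", n=20))
        k = build_kirchhoff(ring.nodes, EnmParameters(cutoff=5.0))
        np.testing.assert_array_equal(np.diag(k.matrix), np.full(20, 2))
        assert k.contact_count == 20
        np.testing.assert_array_equal(
            k.matrix, oracle.brute_force_kirchhoff(ring.nodes.coords, 5.0)
        )

    @pytest.mark.parametrize("spec", FIXTURE_SPECS, ids=lambda s: s.kind)
    def test_matches_brute_force_and_rows_sum_to_zero(self, spec):
        nodes = make_structure(spec).nodes
        k = build_kirchhoff(nodes)
        np.testing.assert_array_equal(
            k.matrix, oracle.brute_force_kirchhoff(nodes.coords, 7.3)
        )
        np.testing.assert_array_equal(k.matrix.sum(axis=1), np.zeros(nodes.n_nodes))


class TestDecompose:
    def test_two_node_closed_form(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        np.testing.assert_allclose(spectrum.eigenvalues, [0.0, 2.0], atol=1e-12)
        lam, u = spectrum.nonrigid(1)
        assert lam == pytest.approx(2.0)
        np.testing.assert_allclose(np.abs(u), [1 / np.sqrt(2)] * 2, atol=1e-12)
        assert u[np.argmax(np.abs(u))] > 0  # sign convention

    @pytest.mark.parametrize("n", [6, 13, 30])
    def test_ring_eigenvalues_are_circulant(self, n):
        ring = make_structure(SyntheticSpec(kind="ring", n=n))
        spectrum = decompose(build_kirchhoff(ring.nodes, EnmParameters(cutoff=5.0)))
        np.testing.assert_allclose(
            spectrum.eigenvalues, oracle.ring_eigenvalues(n), atol=1e-8
        )

    def test_disconnected_components_count_as_zero_modes(self):
        coords = np.vstack([
            random_blob(6, seed=1).coords,
            random_blob(6, seed=2).coords + 100.0,
        ])
        spectrum = decompose(build_kirchhoff(make_nodes(coords)))
        assert spectrum.n_zero_modes == 2

    @pytest.mark.parametrize("spec", FIXTURE_SPECS, ids=lambda s: s.kind)
    def test_zero_modes_equal_graph_components(self, spec):
        nodes = make_structure(spec).nodes
        spectrum = decompose(build_kirchhoff(nodes))
        assert spectrum.n_zero_modes == oracle.component_count(nodes.coords, 7.3)

    def test_eigenvectors_orthonormal(self, dumbbell):
        spectrum = decompose(build_kirchhoff(dumbbell.nodes))
        gram = spectrum.eigenvectors.T @ spectrum.eigenvectors
        np.testing.assert_allclose(gram, np.eye(spectrum.n_modes), atol=1e-8)


class TestModeFluctuation:
    def test_two_node_closed_form(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        values, normalized = mode_fluctuation(spectrum, 1)
        np.testing.assert_allclose(values, [0.25, 0.25], atol=1e-12)
        np.testing.assert_allclose(normalized.sum(), 1.0, atol=1e-12)

    def test_kt_scale_multiplies(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        values, _ = mode_fluctuation(spectrum, 1, EnmParameters(kT_scale=3.0))
        np.testing.assert_allclose(values, [0.75, 0.75], atol=1e-12)

    def test_ring_slowest_profile_is_uniform(self, ring30):
        spectrum = decompose(
            build_kirchhoff(ring30.nodes, EnmParameters(cutoff=5.0))
        )
        # the slowest ring eigenvalue is doubly degenerate; symmetry holds
        # for the summed pair, so check the two-mode sum per node
        combined = sum(mode_fluctuation(spectrum, m)[0] for m in (1, 2))
        np.testing.assert_allclose(combined, combined[0], atol=1e-8)

    def test_rigid_mode_rejected(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        with pytest.raises(RigidModeError):
            mode_fluctuation(spectrum, 0)
        with pytest.raises(RigidModeError):
            mode_fluctuation(spectrum, 2)


class TestMsf:
    def test_two_node_all_modes(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        np.testing.assert_allclose(msf(spectrum, "all"), [0.25, 0.25], atol=1e-12)

    def test_matches_pseudo_inverse_diagonal(self):
        nodes = random_blob(15, seed=11)
        k = build_kirchhoff(nodes)
        spectrum = decompose(k)
        assert spectrum.n_zero_modes == 1
        np.testing.assert_allclose(
            msf(spectrum, "all"), oracle.pinv_msf(k.matrix), atol=1e-8
        )

    def test_monotone_in_mode_count(self):
        nodes = random_blob(15, seed=11)
        spectrum = decompose(build_kirchhoff(nodes))
        prev = np.zeros(15)
        for m in range(1, spectrum.n_nonrigid + 1):
            current = msf(spectrum, (1, m))
            assert np.all(current >= prev - 1e-15)
            prev = current

    def test_empty_range_is_error(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        with pytest.raises(ValidationError, match="empty"):
            msf(spectrum, (2, 5))


class TestCrossCorrelation:
    def test_two_node_anti_phase(self):
        spectrum = decompose(build_kirchhoff(TWO_NODE))
        cmap = cross_correlation(spectrum, (1, 1))
        assert cmap.matrix[0, 1] == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(cmap.matrix), [1.0, 1.0])

    def test_shape_invariants(self, dumbbell):
        spectrum = decompose(build_kirchhoff(dumbbell.nodes))
        cmap = cross_correlation(spectrum, (1, 40))
        matrix = cmap.matrix
        np.testing.assert_allclose(matrix, matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(matrix), 1.0, atol=1e-10)
        assert np.all(np.abs(matrix) <= 1.0 + 1e-12)

    def test_full_mode_map_matches_pinv_oracle(self):
        nodes = random_blob(15, seed=3)
        k = build_kirchhoff(nodes)
        spectrum = decompose(k)
        cmap = cross_correlation(spectrum, "all")
        np.testing.assert_allclose(
            cmap.matrix, oracle.pinv_correlation(k.matrix), atol=1e-8
        )

    def test_mode_count_clipped_with_warning(self, caplog):
        nodes = random_blob(10, seed=5)
        spectrum = decompose(build_kirchhoff(nodes))
        with caplog.at_level("WARNING", logger="enmkit.gnm"):
            cmap = cross_correlation(spectrum, (1, 40))
        assert cmap.mode_range == (1, 9)
        assert any("clipped" in rec.message for rec in caplog.records)


class TestRigidInvariance:
    @pytest.mark.parametrize("spec", FIXTURE_SPECS[:3], ids=lambda s: s.kind)
    def test_gnm_outputs_invariant_under_rigid_transforms(self, spec):
        nodes = make_structure(spec).nodes
        spectrum = decompose(build_kirchhoff(nodes))
        base_msf = msf(spectrum, "all")
        base_corr = cross_correlation(spectrum, "all").matrix
        rng = np.random.default_rng(42)
        for _ in range(10):
            rotation, translation = oracle.random_rigid_transform(rng)
            moved = nodes.transformed(rotation, translation)
            moved_spectrum = decompose(build_kirchhoff(moved))
            np.testing.assert_allclose(
                moved_spectrum.eigenvalues, spectrum.eigenvalues, atol=1e-10
            )
            np.testing.assert_allclose(msf(moved_spectrum, "all"), base_msf, atol=1e-10)
            np.testing.assert_allclose(
                cross_correlation(moved_spectrum, "all").matrix, base_corr, atol=1e-10
            )
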