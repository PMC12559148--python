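import numpy as np
import pytest

import synchropat as sp
from conftest import random_regular_digraph


def _collinear(u, v, tol=1e-8):
    u, v = np.asarray(u, float).ravel(), np.asarray(v, float).ravel()
    u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
    return min(np.linalg.norm(u - v), np.linalg.norm(u + v)) < tol


class TestAdjacencySpectrum:
    def test_example1_eigenpairs(self, example1_spec):
        spec = example1_spec
        assert np.allclose(spec.eigenvalues, [-1, 0, 2])
        assert np.array_equal(spec.multiplicities, [1, 1, 1])
        assert _collinear(spec.eigenvectors[0], [1, -2, 1])
        assert _collinear(spec.eigenvectors[1], [0, 0, 1])
        assert _collinear(spec.eigenvectors[2], [1, 1, 1])

    def test_vpc_minimal_eigenpair(self, vpc_spec):
        assert np.isclose(vpc_spec.eigenvalues[0].real, -2)
        assert _collinear(vpc_spec.eigenvectors[0], [1, -1, 1, -1, 1, -1])

    def test_perron_frobenius_on_builders(self, vpc6, torus16):
        for net in (vpc6, torus16, sp.validate_regular([[0, 1], [1, 0]])):
            spec = sp.adjacency_spectrum(net)
            top = spec.eigenvalues[spec.max_index]
            assert np.isclose(top.real, net.valence) and abs(top.imag) < 1e-9
            assert spec.multiplicities[spec.max_index] == 1
            assert _collinear(
                spec.eigenvectors[spec.max_index], np.ones(net.n_nodes)
            )

    def test_zero_trace_invariant(self, rng=np.random.default_rng(7)):
        for _ in range(20):
            net = random_regular_digraph(rng, int(rng.integers(3, 9)), int(rng.integers(1, 4)))
            spec = sp.adjacency_spectrum(net)
            total = np.sum(spec.eigenvalues * spec.multiplicities)
            assert abs(total) < 1e-7
            assert np.min(spec.eigenvalues.real) < 0  # some eigenvalue left of zero

    def test_multiplicity_sums_to_node_count(self, torus16):
        spec = sp.adjacency_spectrum(torus16)
        assert int(spec.multiplicities.sum()) == 256
        # symmetric table: orthonormal eigenspace bases of matching dimension
        for basis, alpha in zip(spec.eigenvectors, spec.multiplicities):
            assert basis.shape[1] == alpha
            assert np.allclose(basis.T @ basis, np.eye(alpha), atol=1e-8)

    def test_complex_spectrum_flagged_not_rejected(self):
        # directed 3-cycle: eigenvalues 1, exp(+-2*pi*i/3)
        net = sp.validate_regular([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
        spec = sp.adjacency_spectrum(net)
        assert not spec.is_real_spectrum
        assert int(spec.multiplicities.sum()) == 3


class TestJacobianSpectrum:
    @pytest.mark.parametrize("lam", [0.0, 0.7, 1.5])
    def test_example1_closed_form(self, example1_spec, lam):
        lin = sp.Linearization(Q=[[-3.0]], R=[[-2.0 * lam]])
        pairs = sp.jacobian_spectrum(lin, example1_spec)
        got = sorted(p.eigenvalue.real for p in pairs)
        assert np.allclose(got, sorted([-3 + 2 * lam, -3, -3 - 4 * lam]))

    def test_zero_dynamics(self, vpc_spec):
        lin = sp.Linearization(Q=np.zeros((2, 2)), R=np.zeros((2, 2)))
        pairs = sp.jacobian_spectrum(lin, vpc_spec)
        assert len(pairs) == 12
        assert all(abs(p.eigenvalue) < 1e-12 for p in pairs)

    def test_oracle_equivalence_ensemble(self):
        """Reduced-matrix spectra match dense full-Jacobian spectra.

        Each reduced eigenvalue must be an eigenvalue of the assembled
        Jacobian to 1e-8 backward error (the dense eigensolve itself
        loses accuracy on repeated eigenvalues of non-normal matrices,
        so the multiset comparison is done by minimum-cost matching at
        the oracle's own accuracy).
        """
        import scipy.optimize

        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            net = random_regular_digraph(rng, n, int(rng.integers(1, 4)))
            s = int(rng.integers(1, 3))
            lin = sp.Linearization(
                Q=rng.uniform(-2, 2, (s, s)), R=rng.uniform(-2, 2, (s, s))
            )
            spec = sp.adjacency_spectrum(net)
            reduced = np.array(
                [p.eigenvalue for p in sp.jacobian_spectrum(lin, spec)]
            )
            j = sp.assemble_full_jacobian(lin, net)
            dense = np.linalg.eigvals(j)
            assert len(reduced) == n * s
            scale = max(1.0, np.linalg.norm(j, 2))
            for w in reduced:
                smin = np.linalg.svd(
                    j - w * np.eye(n * s), compute_uv=False
                )[-1]
                assert smin <= 1e-8 * scale
            # trace accounts for multiplicities exactly
            assert abs(np.sum(reduced) - np.trace(j)) <= 1e-8 * scale * n
            # one-to-one matching against the dense spectrum
            cost = np.abs(reduced[:, None] - dense[None, :])
            rows, cols = scipy.optimize.linear_sum_assignment(cost)
            assert np.max(cost[rows, cols]) <= 1e-5 * scale

    def test_kronecker_eigenvector_identity(self, vpc6, vpc_spec):
        rng = np.random.default_rng(3)
        lin = sp.Linearization(Q=rng.uniform(-2, 2, (2, 2)), R=rng.uniform(-2, 2, (2, 2)))
        j = sp.assemble_full_jacobian(lin, vpc6)
        for p in sp.jacobian_spectrum(lin, vpc_spec):
            w = p.full_vector
            assert np.linalg.norm(j @ w - p.eigenvalue * w) <= 1e-8 * np.linalg.norm(w)


class TestFullJacobian:
    def test_example1_hand_derived_rows(self, example1_net):
        lam = 0.9
        lin = sp.Linearization(Q=[[-3.0]], R=[[-2.0 * lam]])
        j = sp.assemble_full_jacobian(lin, example1_net)
        expect = np.array(
            [
                [-3 - 2 * lam, -2 * lam, 0],
                [-4 * lam, -3, 0],
                [-2 * lam, -2 * lam, -3],
            ]
        )
        assert np.allclose(j, expect)
        assert np.allclose(
            sorted(np.linalg.eigvals(j).real),
            sorted([-3 + 2 * lam, -3, -3 - 4 * lam]),
        )

    def test_uncoupled_block_diagonal(self, vpc6):
        q = np.array([[-1.0, 0.5], [0.0, -2.0]])
        lin = sp.Linearization(Q=q, R=np.zeros((2, 2)))
        j = sp.assemble_full_jacobian(lin, vpc6)
        assert np.allclose(
            sorted(np.linalg.eigvals(j).real), sorted([-1.0, -2.0] * 6)
        )


class TestCriticalPatternSpace:
    def test_vpc_minimal_space(self, vpc_spec):
        basis = sp.critical_pattern_space(vpc_spec, [0])
        assert basis.shape == (6, 1)
        v = basis[:, 0]
        assert np.allclose(np.abs(v), np.abs(v[0]))
        assert np.allclose(v[::2], v[0]) and np.allclose(v[1::2], -v[0])

    def test_top_space_is_uniform(self, vpc_spec):
        basis = sp.critical_pattern_space(vpc_spec, [vpc_spec.max_index])
        assert np.allclose(basis[:, 0], basis[0, 0])

    def test_all_indices_full_dimension(self, vpc_spec):
        basis = sp.critical_pattern_space(vpc_spec, range(vpc_spec.n_clusters))
        assert basis.shape == (6, 6)

    def test_empty_set_rejected(self, vpc_spec):
        with pytest.raises(ValueError):
            sp.critical_pattern_space(vpc_spec, [])
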