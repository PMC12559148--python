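import numpy as np
import pytest

import synchropat as sp
from synchropat.classify import NotAtBifurcationError, criticality_tolerance
from conftest import random_symmetric_regular


def marginal_2d_instance(rng, detR_mode="rank1"):
    """Random two-species instance shifted to marginal stability.

    ``detR_mode``: "rank1" forces det R = 0; "nonpos" draws general R
    until det R <= 0.  Q is shifted by a multiple of the identity so the
    maximal real part over all reduced matrices is exactly zero.
    """
    net = random_symmetric_regular(rng)
    spec = sp.adjacency_spectrum(net)
    if detR_mode == "rank1":
        r = np.outer(rng.uniform(-1, 1, 2), rng.uniform(-1, 1, 2))
    else:
        while True:
            r = rng.uniform(-1, 1, (2, 2))
            if np.linalg.det(r) <= 0:
                break
    q = rng.uniform(-2, 2, (2, 2))
    mus = spec.eigenvalues.real
    shift = max(
        np.max(np.linalg.eigvals(q + mu * r).real) for mu in mus
    )
    q = q - shift * np.eye(2)
    lin = sp.Linearization(Q=q, R=r)
    return net, spec, lin


def dense_ground_truth(lin, spec, tol):
    """Critical index set and eigenvalue type by direct eigensolve."""
    crit = []
    types = set()
    for i, mu in enumerate(spec.eigenvalues.real):
        w = np.linalg.eigvals(lin.Q + mu * lin.R)
        m = np.max(w.real)
        if m >= -tol:
            crit.append(i)
            wc = w[np.argmax(w.real)]
            types.add("imaginary_pair" if abs(wc.imag) > tol else "real")
    etype = types.pop() if len(types) == 1 else "mixed"
    return tuple(crit), etype


class TestStabilityPreconditions:
    def test_negative_scalar_ok(self):
        assert sp.stability_preconditions(sp.Linearization(Q=[[-3.0]], R=[[0.0]])) == []

    def test_notch_trace_ok(self):
        lin = sp.Linearization(Q=[[-1, -1], [0, -1]], R=[[0, 0], [1, 0]])
        assert sp.stability_preconditions(lin) == []

    def test_positive_scalar_violates(self):
        out = sp.stability_preconditions(sp.Linearization(Q=[[1.0]], R=[[0.0]]))
        assert len(out) == 1

    def test_three_species_rejected(self):
        lin = sp.Linearization(Q=-np.eye(3), R=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            sp.stability_preconditions(lin)


class TestClassify1d:
    def test_negative_coupling_breaks_synchrony(self, vpc_spec, vpc6):
        # Q + mu_1 R = 0 with R < 0: crossing at the smallest eigenvalue
        res = sp.classify_1d(-2.0, -1.0, vpc_spec, network=vpc6)
        assert res.pattern_space_label == "P_mu1"
        assert res.synchrony_breaking
        assert res.critical_indices == (0,)

    def test_positive_coupling_preserves_synchrony(self, vpc_spec, vpc6):
        res = sp.classify_1d(-2.0, 1.0, vpc_spec, network=vpc6)
        assert res.pattern_space_label == "P_muk"
        assert not res.synchrony_breaking

    def test_zero_coupling_fully_degenerate(self, vpc_spec, vpc6):
        res = sp.classify_1d(0.0, 0.0, vpc_spec, network=vpc6)
        assert res.pattern_space_label == "full_space"
        assert res.degenerate

    def test_not_at_bifurcation(self, vpc_spec):
        with pytest.raises(NotAtBifurcationError):
            sp.classify_1d(-5.0, 0.1, vpc_spec)

    def test_nonreal_spectrum_refused(self):
        net = sp.validate_regular([[0, 0, 1], [1, 0, 0], [0, 1, 0]])
        spec = sp.adjacency_spectrum(net)
        res = sp.classify_1d(-1.0, -1.0, spec)
        assert res.refused

    def test_self_arrow_network_refused(self, example1_net, example1_spec):
        res = sp.classify_1d(-3.0, -2.0 * 1.5, example1_spec, network=example1_net)
        assert res.refused

    def test_trichotomy_exclusivity(self, vpc_spec):
        """Exactly one outcome fires for any critical one-species input."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            r = rng.uniform(-2, 2)
            mu = rng.choice(vpc_spec.eigenvalues.real)
            q = -mu * r  # force criticality at mu
            if np.min(np.abs(q + vpc_spec.eigenvalues.real * r)) > 1e-9:
                continue
            res = sp.classify_1d(q, r, vpc_spec)
            assert res.pattern_space_label in ("P_mu1", "P_muk", "full_space")


class TestDegeneracyStatistics:
    def test_notch_structure(self):
        a, b, d, kappa = -1.0, -0.7, -1.3, 0.8
        lin = sp.Linearization(Q=[[a, b], [0, d]], R=[[0, 0], [kappa, 0]])
        stats = sp.degeneracy_statistics(lin)
        assert stats.tr_R == 0 and stats.det_R == 0
        assert np.isclose(stats.B, -b * kappa) and stats.B > 0
        assert stats.det_line == (pytest.approx(a * d), pytest.approx(-b * kappa))

    def test_same_chemical_coupling(self):
        a, b, c, d, kappa = -0.5, 0.7, 0.2, -1.0, 0.9
        lin = sp.Linearization(Q=[[a, b], [c, d]], R=[[kappa, 0], [0, 0]])
        stats = sp.degeneracy_statistics(lin)
        assert np.isclose(stats.B, d * kappa)

    def test_zero_coupling(self):
        lin = sp.Linearization(Q=[[-1, 0], [0, -2]], R=np.zeros((2, 2)))
        stats = sp.degeneracy_statistics(lin)
        assert stats.B == 0
        assert stats.det_line == (pytest.approx(2.0), 0.0)


class TestNdgConditions:
    def test_notch_single_real(self):
        lin = sp.Linearization(Q=[[-1, -1], [0, -1]], R=[[0, 0], [0.5, 0]])
        out = sp.ndg_conditions(lin, valence=2)
        assert out["single_real_certified"]

    def test_imaginary_pair_certificate(self):
        lin = sp.Linearization(Q=[[-1, 0], [0, -1]], R=[[0, 0], [1, 0]])
        out = sp.ndg_conditions(lin, valence=2)
        # det Q = 1, B = 0: 1 > 0 certifies the Hopf side
        assert out["imaginary_pair_certified"]

    def test_zero_internal_dynamics(self):
        lin = sp.Linearization(Q=np.zeros((2, 2)), R=[[0, 0], [1, 0]])
        out = sp.ndg_conditions(lin, valence=2)
        assert not out["imaginary_pair_certified"]
        assert not out["single_real_certified"]


class TestClassify2d:
    def test_notch_row1_on_vpc(self, vpc6, vpc_spec):
        # det(Q + mu R) = 1 + mu/2 vanishes at mu_1 = -2
        lin = sp.Linearization(Q=[[-1, -1], [0, -1]], R=[[0, 0], [0.5, 0]])
        res = sp.classify_2d_detR0(lin, vpc_spec, network=vpc6)
        assert res.table1_row == 1
        assert res.pattern_space_label == "P_mu1"
        assert res.eigenvalue_type == "real"
        assert res.synchrony_breaking
        assert not res.degenerate

    def test_positive_trace_hopf_row4(self):
        net = sp.validate_regular([[0, 1], [1, 0]])  # eigenvalues -1, 1
        spec = sp.adjacency_spectrum(net)
        lin = sp.Linearization(
            Q=[[-0.05, -1.0], [1.0, -0.05]], R=[[0.1, 0.0], [0.0, 0.0]]
        )
        res = sp.classify_2d_detR0(lin, spec, network=net)
        assert res.table1_row == 4
        assert res.pattern_space_label == "P_muk"
        assert res.eigenvalue_type == "imaginary_pair"
        assert not res.synchrony_breaking
        # det(Q + mu_k R) = det Q + mu_k B = 1.0025 - 0.005
        assert res.hopf_frequency == pytest.approx(np.sqrt(1.0025 - 0.005))

    def test_fully_degenerate_row15(self):
        net = sp.validate_regular([[0, 1], [1, 0]])
        spec = sp.adjacency_spectrum(net)
        lin = sp.Linearization(Q=[[0, 1], [0, 0]], R=[[0, 1], [0, 0]])
        res = sp.classify_2d_detR0(lin, spec, network=net)
        assert res.table1_row == 15
        assert res.pattern_space_label == "full_space"
        assert res.degenerate

    def test_nonzero_detR_refused(self, vpc_spec):
        lin = sp.Linearization(Q=-np.eye(2), R=np.eye(2))
        res = sp.classify_2d_detR0(lin, vpc_spec)
        assert res.refused

    def test_no_bifurcation_raises(self, vpc_spec):
        lin = sp.Linearization(Q=[[-5, 0], [0, -6]], R=[[0, 0], [0.01, 0]])
        with pytest.raises(NotAtBifurcationError):
            sp.classify_2d_detR0(lin, vpc_spec)

    def test_ensemble_agreement_with_dense_oracle(self):
        """Table-driven classification matches dense eigensolve on random
        marginal-stability rank-1-R instances."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(150):
            net, spec, lin = marginal_2d_instance(rng, "rank1")
            tol = criticality_tolerance(lin, spec)
            truth_idx, truth_type = dense_ground_truth(lin, spec, tol)
            res = sp.classify_2d_detR0(lin, spec, network=net, tol=tol)
            if res.degenerate:
                continue
            assert res.critical_indices == truth_idx
            assert res.eigenvalue_type == truth_type
            # valence-inequality certificates (taken with a margin, since at
            # machine scale both sides can vanish) never contradict the type
            stats = sp.degeneracy_statistics(lin)
            nu = net.valence
            if stats.tr_Q < -abs(nu * stats.tr_R) - 1e-6:
                assert res.eigenvalue_type != "imaginary_pair"
            if stats.det_Q > abs(nu * stats.B) + 1e-6:
                assert res.eigenvalue_type != "real"
            checked += 1
        assert checked > 100

    def test_nonpositive_detR_restricts_to_extremes(self):
        """With det R <= 0 the critical index set stays within {1, k}."""
        rng = np.random.default_rng(77)
        for _ in range(60):
            net, spec, lin = marginal_2d_instance(rng, "nonpos")
            tol = criticality_tolerance(lin, spec)
            truth_idx, _ = dense_ground_truth(lin, spec, tol)
            assert set(truth_idx) <= {0, spec.max_index}


class TestTheorem13:
    @pytest.mark.parametrize("det_r", [-0.5, 0.0])
    def test_restricted_set(self, det_r):
        assert sp.theorem13_feasible_spaces(det_r) == {
            "P_mu1",
            "P_muk",
            "P_mu1_plus_P_muk",
            "full_space",
        }

    def test_positive_determinant_unrestricted(self):
        assert "P_mu_interior" in sp.theorem13_feasible_spaces(0.5)
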