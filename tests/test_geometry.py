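"""SPD geometry primitives against independent dense-linear-algebra oracles."""

import numpy as np
import pytest
import scipy.linalg

from spdwave import (
    RunningReference,
    bimap,
    logmap,
    reeig,
    shrink,
    update_running_mean,
    vect,
)
from spdwave.geometry import expm, log_euclidean_mean, logm, unvect

from conftest import random_spd


class TestShrink:
    def test_alpha_zero_is_identity_map(self, spd_factory):
        X = spd_factory(5)
        assert np.allclose(shrink(X, 0.0), X)

    def test_alpha_one_is_scaled_identity(self, spd_factory):
        X = spd_factory(4)
        out = shrink(X, 1.0)
        assert np.allclose(out, np.trace(X) / 4 * np.eye(4))

    def test_trace_preserved_exactly(self, rng):
        X = np.diag([3.0, 1.0])
        for alpha in rng.uniform(0, 1, 20):
            assert np.trace(shrink(X, alpha)) == pytest.approx(4.0, abs=1e-12)

    def test_eigenvalue_spread_non_increasing(self, spd_factory):
        X = spd_factory(6, cond=100)
        w0 = np.linalg.eigvalsh(X)
        w1 = np.linalg.eigvalsh(shrink(X, 0.5))
        assert w1.max() - w1.min() <= w0.max() - w0.min() + 1e-12

    def test_printed_multiplicative_form_differs(self, spd_factory):
        X = spd_factory(3)
        assert not np.allclose(shrink(X, 0.5), shrink(X, 0.5, identity_target=False))

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError):
            shrink(rng.standard_normal((3, 4)), 0.5)


class TestBiMap:
    def test_identity_weight(self, spd_factory):
        X = spd_factory(4)
        assert np.allclose(bimap(X, np.eye(4)), X)

    def test_selector_weight_extracts_principal_submatrix(self, spd_factory):
        X = spd_factory(5)
        W = np.eye(5)[:3]
        assert np.allclose(bimap(X, W), X[:3, :3])

    def test_semi_orthogonal_preserves_positive_definiteness(self, rng):
        for _ in range(20):
            X = random_spd(rng, 6)
            A = rng.standard_normal((6, 4))
            Q, _ = np.linalg.qr(A)
            W = Q[:, :4].T
            out = bimap(X, W)
            assert np.linalg.eigvalsh(out).min() > 0

    def test_dimension_mismatch_rejected(self, spd_factory, rng):
        with pytest.raises(ValueError):
            bimap(spd_factory(4), rng.standard_normal((2, 5)))


class TestReEig:
    def test_noop_above_threshold(self, spd_factory):
        X = spd_factory(5)
        assert np.allclose(reeig(X, eps=1e-12), X, atol=1e-10)

    def test_zero_matrix_becomes_eps_identity(self):
        out = reeig(np.zeros((3, 3)), eps=0.5)
        assert np.allclose(out, 0.5 * np.eye(3))

    def test_idempotent(self, rng):
        X = rng.standard_normal((4, 4))
        X = X + X.T
        once = reeig(X, eps=0.1)
        twice = reeig(once, eps=0.1)
        assert np.allclose(once, twice, atol=1e-10)

    def test_matches_independent_eigensolver(self, rng):
        for _ in range(20):
            S = rng.standard_normal((5, 5))
            S = S + S.T
            w, V = scipy.linalg.eigh(S)
            oracle = V @ np.diag(np.maximum(w, 0.3)) @ V.T
            assert np.allclose(reeig(S, eps=0.3), oracle, atol=1e-10)


class TestVect:
    def test_identity(self):
        assert np.allclose(vect(np.eye(2)), [1.0, 0.0, 1.0])

    def test_off_diagonal_sqrt2(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        v = vect(S)
        assert np.allclose(v, [0.0, np.sqrt(2), 0.0])
        assert np.linalg.norm(v) == pytest.approx(np.linalg.norm(S, "fro"))

    def test_frobenius_isometry(self, rng):
        for _ in range(20):
            S = rng.standard_normal((5, 5))
            S = S + S.T
            assert np.linalg.norm(vect(S)) == pytest.approx(
                np.linalg.norm(S, "fro"), abs=1e-12
            )

    def test_unvect_roundtrip(self, rng):
        S = rng.standard_normal((6, 6))
        S = S + S.T
        assert np.allclose(unvect(vect(S)), S, atol=1e-12)

    def test_asymmetric_input_rejected(self, rng):
        with pytest.raises(ValueError):
            vect(rng.standard_normal((3, 3)))


class TestLogMap:
    def test_zero_vector_at_reference(self, spd_factory):
        X = spd_factory(4)
        ref = RunningReference(theta=0.0)
        update_running_mean(ref, X[None])
        assert np.allclose(logmap(X, ref), 0.0, atol=1e-10)

    def test_closed_form_e_identity(self):
        X = np.e * np.eye(2)
        assert np.allclose(logmap(X, np.eye(2)), [1.0, 0.0, 1.0], atol=1e-12)

    def test_norm_equals_log_euclidean_distance(self, rng):
        for _ in range(10):
            X = random_spd(rng, 5)
            R = random_spd(rng, 5)
            v = logmap(X, R)
            oracle = np.linalg.norm(
                scipy.linalg.logm(X) - scipy.linalg.logm(R), "fro"
            )
            assert np.linalg.norm(v) == pytest.approx(oracle, rel=1e-8)

    def test_identity_reference_is_conventional_logeig(self, rng):
        X = random_spd(rng, 4)
        v = logmap(X, np.eye(4))
        oracle = vect(np.real(scipy.linalg.logm(X)))
        assert np.allclose(v, oracle, atol=1e-8)

    def test_scaling_shifts_log_by_log_c_identity(self, rng):
        # affine-invariance sanity: Log(cX) = Log(X) + log(c) I, so tangent
        # vectors are unchanged once the reference is scaled along
        X = random_spd(rng, 4)
        R = random_spd(rng, 4)
        c = 3.7
        assert np.allclose(logmap(c * X, c * R), logmap(X, R), atol=1e-8)

    def test_uninitialized_reference_rejected(self, spd_factory):
        with pytest.raises(RuntimeError):
            logmap(spd_factory(3), RunningReference())


class TestRunningMean:
    def test_theta_zero_jumps_to_batch_mean(self, rng):
        batch = random_spd(rng, 4, batch=(6,))
        ref = RunningReference(theta=0.0)
        update_running_mean(ref, random_spd(rng, 4, batch=(3,)))
        update_running_mean(ref, batch)
        oracle = sum(scipy.linalg.logm(B) for B in batch) / len(batch)
        assert np.allclose(ref.log_ref, oracle, atol=1e-8)

    def test_fixed_point_when_batch_mean_equals_reference(self, rng):
        X = random_spd(rng, 3)
        ref = RunningReference(theta=0.7)
        update_running_mean(ref, X[None])
        before = ref.log_ref.copy()
        update_running_mean(ref, np.stack([X, X]))
        assert np.allclose(ref.log_ref, before, atol=1e-10)

    def test_geometric_decay_at_rate_theta(self, rng):
        theta = 0.6
        X0 = random_spd(rng, 4)
        B = random_spd(rng, 4)
        ref = RunningReference(theta=theta)
        update_running_mean(ref, X0[None])  # first batch initializes
        log_B = scipy.linalg.logm(B)
        d0 = np.linalg.norm(ref.log_ref - log_B, "fro")
        for k in range(1, 6):
            update_running_mean(ref, B[None])
            dk = np.linalg.norm(ref.log_ref - log_B, "fro")
            assert dk == pytest.approx(theta**k * d0, rel=1e-8)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            update_running_mean(RunningReference(), np.zeros((0, 3, 3)))

    def test_log_euclidean_mean_matches_scipy(self, rng):
        batch = random_spd(rng, 4, batch=(5,))
        mean = log_euclidean_mean(batch)
        oracle = scipy.linalg.expm(
            sum(scipy.linalg.logm(B) for B in batch) / 5
        )
        assert np.allclose(mean, np.real(oracle), atol=1e-8)


class TestMatrixFunctions:
    def test_logm_matches_scipy(self, rng):
        X = random_spd(rng, 5)
        assert np.allclose(logm(X), np.real(scipy.linalg.logm(X)), atol=1e-9)

    def test_expm_inverts_logm(self, rng):
        X = random_spd(rng, 5)
        assert np.allclose(expm(logm(X)), X, atol=1e-9)

    def test_logm_rejects_indefinite_without_eps(self):
        X = np.diag([1.0, -1.0])
        with pytest.raises(np.linalg.LinAlgError):
            logm(X)
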