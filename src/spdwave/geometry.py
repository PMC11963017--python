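"""Operations on symmetric positive (semi-)definite matrices.

Functional NumPy implementations of the geometric primitives used throughout
the package: trace-preserving shrinkage, bilinear mapping, eigenvalue
rectification, log-Euclidean tangent projection about a running reference,
and the isometric half-vectorization.  The differentiable layer counterparts
live in :mod:`spdwave.nn`; these functions are the in-memory API and are what
the baseline model and the interpretation utilities call.

All functions accept batched input ``(..., q, q)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "shrink",
    "bimap",
    "reeig",
    "logmap",
    "vect",
    "unvect",
    "logm",
    "expm",
    "log_euclidean_mean",
    "RunningReference",
    "update_running_mean",
    "REEIG_EPS_SCALE",
    "REEIG_EPS_FLOOR",
]

#: relative ReEig threshold: eps = scale * mean diagonal of the batch
REEIG_EPS_SCALE = 1e-4
#: absolute ReEig floor
REEIG_EPS_FLOOR = 1e-10


def _check_square(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim < 2 or X.shape[-1] != X.shape[-2]:
        raise ValueError("expected square matrices (..., q, q)")
    return X


def _check_symmetric(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    X = _check_square(X)
    scale = max(1.0, float(np.abs(X).max()))
    if np.abs(X - np.swapaxes(X, -1, -2)).max() > tol * scale:
        raise ValueError("input matrix is not symmetric within tolerance")
    return X


def shrink(X: np.ndarray, alpha: float, identity_target: bool = True) -> np.ndarray:
    """Trace-preserving shrinkage ``(1 - a) X + a (Tr(X)/p) I``.

    With ``identity_target=True`` (default) the eigenvalue spread shrinks
    toward the scaled identity and the trace is preserved exactly — the
    Ledoit-Wolf-style regularization.  ``identity_target=False`` applies the
    multiplicative form ``(1 - a) X + a (Tr(X)/p) X`` (kept for audit; it
    rescales instead of regularizing and does not preserve the trace).
    """
    X = _check_square(X)
    p = X.shape[-1]
    tr = np.trace(X, axis1=-2, axis2=-1)[..., None, None]
    if identity_target:
        return (1.0 - alpha) * X + alpha * (tr / p) * np.eye(p)
    return (1.0 - alpha) * X + alpha * (tr / p) * X


def bimap(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Bilinear map ``W X W^T`` (spatial filtering / subspace projection)."""
    X = _check_square(X)
    W = np.asarray(W, dtype=float)
    if W.shape[-1] != X.shape[-1]:
        raise ValueError(
            f"BiMap weight has {W.shape[-1]} columns but input is {X.shape[-1]}-dim"
        )
    return W @ X @ np.swapaxes(W, -1, -2)


def reeig(X: np.ndarray, eps: float = REEIG_EPS_FLOOR) -> np.ndarray:
    """Eigenvalue rectification ``U max(Lambda, eps) U^T`` (idempotent)."""
    X = _check_symmetric(X)
    w, V = np.linalg.eigh(X)
    w = np.maximum(w, eps)
    return (V * w[..., None, :]) @ np.swapaxes(V, -1, -2)


def logm(X: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition.

    When ``eps`` is given, eigenvalues are floored first (combined
    rectify-and-log in a single diagonalization).
    """
    X = _check_symmetric(X)
    w, V = np.linalg.eigh(X)
    if eps is not None:
        w = np.maximum(w, eps)
    elif np.any(w <= 0):
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return (V * np.log(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def expm(S: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix."""
    S = _check_symmetric(S)
    w, V = np.linalg.eigh(S)
    return (V * np.exp(w)[..., None, :]) @ np.swapaxes(V, -1, -2)


def vect(S: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Isometric half-vectorization: upper triangle, off-diagonal * sqrt(2).

    Row-major traversal of the upper triangle including the diagonal, with
    off-diagonal entries scaled by sqrt(2) so that
    ``||vect(S)||_2 = ||S||_F`` and tangent-space Euclidean distances equal
    log-Euclidean distances between the matrices.
    """
    S = _check_symmetric(np.asarray(S, float), tol=tol)
    q = S.shape[-1]
    iu, ju = np.triu_indices(q)
    weights = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return S[..., iu, ju] * weights


def unvect(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vect`."""
    v = np.asarray(v, dtype=float)
    d = v.shape[-1]
    q = int((np.sqrt(8 * d + 1) - 1) / 2)
    if q * (q + 1) // 2 != d:
        raise ValueError("vector length is not q(q+1)/2 for integer q")
    iu, ju = np.triu_indices(q)
    weights = np.where(iu == ju, 1.0, 1.0 / np.sqrt(2.0))
    S = np.zeros(v.shape[:-1] + (q, q))
    S[..., iu, ju] = v * weights
    S[..., ju, iu] = S[..., iu, ju]
    return S


def log_euclidean_mean(batch: np.ndarray, eps: float | None = None) -> np.ndarray:
    """``Exp(mean(Log(X_b)))`` over the leading axis of ``(B, ..., q, q)``."""
    batch = np.asarray(batch, dtype=float)
    if batch.ndim < 3 or batch.shape[0] == 0:
        raise ValueError("need a non-empty batch of matrices")
    return expm(logm(batch, eps=eps).mean(axis=0))


@dataclass
class RunningReference:
    """Running log-Euclidean mean reference for the tangent projection.

    The reference is stored as its matrix logarithm ``log_ref``; the update
    is a convex combination in the log domain with momentum ``theta``::

        log_ref <- (1 - theta) * mean_b Log(X_b) + theta * log_ref

    which is the log-domain form of
    ``X_ref <- Exp((1-theta) Log(mean_LE(batch)) + theta Log(X_ref))``.
    The reference is initialized from the first batch it sees and is frozen
    at evaluation time.
    """

    theta: float = 0.9
    log_ref: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("momentum theta must lie in [0, 1)")

    @property
    def initialized(self) -> bool:
        return self.log_ref is not None

    @property
    def reference(self) -> np.ndarray:
        if not self.initialized:
            raise RuntimeError("running reference has not been initialized")
        return expm(self.log_ref)


def update_running_mean(
    ref: RunningReference, batch: np.ndarray, eps: float | None = None
) -> RunningReference:
    """Update ``ref`` in place from a batch of SPD matrices; returns it."""
    batch = np.asarray(batch, dtype=float)
    if batch.ndim < 3 or batch.shape[0] == 0:
        raise ValueError("need a non-empty batch of SPD matrices")
    batch_log_mean = logm(batch, eps=eps).mean(axis=0)
    if ref.log_ref is None:
        ref.log_ref = batch_log_mean
    else:
        ref.log_ref = (1.0 - ref.theta) * batch_log_mean + ref.theta * ref.log_ref
    return ref


def logmap(
    X: np.ndarray,
    ref: RunningReference | np.ndarray,
    eps: float | None = None,
) -> np.ndarray:
    """Log-Euclidean tangent vector ``vect(Log(X) - Log(X_ref))``.

    ``ref`` may be a :class:`RunningReference` or an SPD matrix.  The output
    Euclidean norm equals the log-Euclidean distance from ``X`` to the
    reference.  Eigenvalue flooring (``eps``) and the logarithm share a
    single diagonalization.
    """
    if isinstance(ref, RunningReference):
        log_ref = ref.log_ref
        if log_ref is None:
            raise RuntimeError("running reference has not been initialized")
    else:
        log_ref = logm(ref)
    return vect(logm(X, eps=eps) - log_ref)
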