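"""Pooling of wavelet coefficients into symmetric feature matrices.

Two feature kinds are supported:

* covariance — ``C_ij = Re(X_i X_j^H) / T`` between the wavelet-transformed
  signals of frequencies i and j.  The Hermitian inner product makes the
  ``i = j`` diagonal the classical band power of each channel.  (The plain
  transpose ``Re(X_i X_j^T)/T`` is available behind ``hermitian=False`` for
  auditability; it does not yield non-negative power.)
* plv — pairwise phase-locking value
  ``P_kl = |sum_t exp(i (theta_k(t) - theta_l(t)))| / T``
  with ``theta`` the instantaneous phase of the analytic signal.  Entries lie
  in [0, 1] with unit diagonal; the matrix is invariant to channelwise
  amplitude rescaling.

Matrices are averaged arithmetically across the E windows of a sample
(a mean of PSD matrices is PSD), giving one matrix stack per sample.  In the
``joint`` layout the covariances of all F frequencies are assembled into a
single ``(F*C) x (F*C)`` block matrix whose off-diagonal blocks hold
cross-frequency interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["FeatureMatrixSet", "covariance", "plv", "pool_features", "PLV_EPS"]

#: guard added to signal moduli before phase normalization
PLV_EPS = 1e-12

_KINDS = ("covariance", "plv")
_LAYOUTS = ("per_frequency", "joint")


@dataclass
class FeatureMatrixSet:
    """Stack of ``P`` symmetric feature matrices for one or more samples.

    ``matrices`` has shape ``(P, q, q)`` (single sample) or ``(B, P, q, q)``.
    With mixed layouts (joint covariance plus per-frequency PLV) sizes differ
    between groups, and the set holds one entry per group instead.
    """

    matrices: np.ndarray
    feature_kinds: tuple
    layout: str


def _hermitian_cross(Xr, Xi, Yr, Yi, T):
    """Re(X Y^H)/T from explicit real/imaginary parts (Tensor or ndarray)."""
    if isinstance(Xr, Tensor) or isinstance(Yr, Tensor):
        return (Xr @ Yr.mT + Xi @ Yi.mT) * (1.0 / T)
    return (Xr @ np.swapaxes(Yr, -1, -2) + Xi @ np.swapaxes(Yi, -1, -2)) / T


def covariance(
    Xi: np.ndarray, Xj: np.ndarray, hermitian: bool = True
) -> np.ndarray:
    """Covariance block between two complex ``C x T`` traces.

    ``(1/T) Re(Xi Xj^H)`` by default; for ``i = j`` this is symmetric PSD and
    its diagonal holds classical band power.
    """
    Xi = np.asarray(Xi)
    Xj = np.asarray(Xj)
    if Xi.shape[-1] != Xj.shape[-1]:
        raise ValueError("traces must have equal length T")
    T = Xi.shape[-1]
    other = np.conj(Xj) if hermitian else Xj
    return np.real(Xi @ np.swapaxes(other, -1, -2)) / T


def _unit_phase(Xr, Xi):
    """Normalize to unit modulus with an epsilon guard (Tensor path)."""
    modulus = (Xr * Xr + Xi * Xi).sqrt() + PLV_EPS
    return Xr / modulus, Xi / modulus


def _plv_from_parts(Ur, Ui, T):
    """PLV matrix from unit-modulus parts; works on Tensors and ndarrays.

    With ``u_k = exp(i theta_k)``, the time sum of ``exp(i(theta_k-theta_l))``
    equals ``(U U^H)_kl``, so the PLV is ``|U U^H| / T``.
    """
    A = _hermitian_cross(Ur, Ui, Ur, Ui, 1.0)  # Re part of U U^H
    if isinstance(Ur, Tensor):
        B = (Ui @ Ur.mT - Ur @ Ui.mT)
        return ((A * A + B * B) + PLV_EPS**2).sqrt() * (1.0 / T)
    B = Ui @ np.swapaxes(Ur, -1, -2) - Ur @ np.swapaxes(Ui, -1, -2)
    return np.sqrt(A**2 + B**2) / T


def plv(Xw: np.ndarray) -> np.ndarray:
    """Pairwise phase-locking value of a complex ``C x T`` trace (or stack)."""
    Xw = np.asarray(Xw, dtype=complex)
    T = Xw.shape[-1]
    U = Xw / (np.abs(Xw) + PLV_EPS)
    out = _plv_from_parts(U.real, U.imag, T)
    out = 0.5 * (out + np.swapaxes(out, -1, -2))
    # unit diagonal holds exactly by definition (theta_k - theta_k = 0)
    idx = np.arange(out.shape[-1])
    out[..., idx, idx] = 1.0
    return np.clip(out, 0.0, 1.0)


def pool_features(
    coeffs,
    kinds=("covariance",),
    layout: str = "per_frequency",
    hermitian: bool = True,
):
    """Pool complex wavelet coefficients into per-sample feature matrices.

    Parameters
    ----------
    coeffs
        Complex array of shape ``(E, F, C, T)`` or ``(B, E, F, C, T)``, or a
        ``(real, imag)`` pair of Tensors for the differentiable path.
    kinds
        Subset of ``{"covariance", "plv"}``.  PLV matrices are computed per
        frequency and appended to the covariance stack.
    layout
        ``"per_frequency"`` gives ``P`` matrices of size ``C x C`` (one per
        wavelet and feature kind); ``"joint"`` assembles the covariances into
        one ``(F*C) x (F*C)`` block matrix (PLV stays per-frequency).

    Returns
    -------
    For ndarray input, a :class:`FeatureMatrixSet` (or a list of them when
    joint covariance is mixed with PLV).  For Tensor input, the matching
    Tensor stack(s).
    """
    for kind in kinds:
        if kind not in _KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
    if layout not in _LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    if not kinds:
        raise ValueError("at least one feature kind is required")

    tensor_mode = isinstance(coeffs, (tuple, list))
    if tensor_mode:
        Yr, Yi = coeffs
    else:
        coeffs = np.asarray(coeffs, dtype=complex)
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("wavelet coefficients must be finite")
        Yr, Yi = coeffs.real, coeffs.imag

    shape = Yr.shape  # (..., E, F, C, T)
    E, F, C, T = shape[-4], shape[-3], shape[-2], shape[-1]
    win_axis = len(shape) - 4

    groups = []
    group_kinds = []

    if "covariance" in kinds:
        if layout == "joint":
            # merge the adjacent (F, C) axes frequency-major: (..., E, F*C, T)
            Z_r = Yr.reshape(*shape[:-3], F * C, T)
            Z_i = Yi.reshape(*shape[:-3], F * C, T)
            cov = _hermitian_cross(Z_r, Z_i, Z_r, -Z_i if not hermitian else Z_i, T)
            cov = cov.mean(axis=win_axis)
            cov = cov.reshape(*shape[:-4], 1, F * C, F * C)
            groups.append(cov)
            group_kinds.append(("covariance",))
        else:
            cov = _hermitian_cross(Yr, Yi, Yr, -Yi if not hermitian else Yi, T)
            cov = cov.mean(axis=win_axis)  # (..., F, C, C)
            groups.append(cov)
            group_kinds.append(("covariance",) * F)

    if "plv" in kinds:
        Ur, Ui = _unit_phase(Yr, Yi) if tensor_mode else _unit_phase_np(Yr, Yi)
        P = _plv_from_parts(Ur, Ui, T)
        P = P.mean(axis=win_axis)  # (..., F, C, C)
        groups.append(P)
        group_kinds.append(("plv",) * F)

    if tensor_mode:
        if len(groups) == 1:
            return groups[0]
        if layout == "per_frequency" and all(
            g.shape[-1] == groups[0].shape[-1] for g in groups
        ):
            return ad.concatenate(groups, axis=win_axis)
        return groups

    if len(groups) == 1:
        return FeatureMatrixSet(groups[0], group_kinds[0], layout)
    if layout == "per_frequency":
        return FeatureMatrixSet(
            np.concatenate(groups, axis=win_axis),
            tuple(k for ks in group_kinds for k in ks),
            layout,
        )
    return [
        FeatureMatrixSet(g, ks, layout) for g, ks in zip(groups, group_kinds)
    ]


def _unit_phase_np(Yr, Yi):
    modulus = np.sqrt(Yr**2 + Yi**2) + PLV_EPS
    return Yr / modulus, Yi / modulus
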