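"""Differentiable layers and optimizer for the wavelet-SPD networks.

The SPD-manifold layers mirror the functional API in
:mod:`spdwave.geometry` but operate on autodiff Tensors so that gradients
flow back to the shrinkage strength, the BiMap weights and — through the
pooling and convolution stages — the wavelet parameters.

Slot convention: models carry ``P`` parallel feature-matrix slots (one per
wavelet and feature kind in the per-frequency layout, a single slot in the
joint layout).  Every slot owns its shrinkage strength, BiMap weights and
running reference; slots are processed batched as ``(B, P, q, q)``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, gelu
from .geometry import REEIG_EPS_FLOOR, REEIG_EPS_SCALE


class Module:
    """Minimal parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)


def _param(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=float), requires_grad=True)


# ---------------------------------------------------------------------------
# SPD layers
# ---------------------------------------------------------------------------

class Shrinkage(Module):
    """Trace-preserving shrinkage toward the scaled identity, per slot.

    The strength ``alpha`` is stored as an unconstrained scalar squashed
    through a sigmoid so ``alpha`` stays in (0, 1).  Initialized near zero
    (raw = -4, alpha ~ 0.018) so training starts close to the unshrunk
    covariance.
    """

    def __init__(self, n_slots: int, raw_init: float = -4.0):
        super().__init__()
        self.raw_alpha = _param(np.full(n_slots, raw_init))

    @property
    def alpha(self) -> np.ndarray:
        from scipy.special import expit

        return expit(self.raw_alpha.data)

    def __call__(self, X: Tensor) -> Tensor:
        # X: (B, P, q, q)
        q = X.shape[-1]
        alpha = self.raw_alpha.sigmoid().reshape(1, -1, 1, 1)
        eye = Tensor(np.eye(q))
        iq = np.arange(q)
        trace = X[..., iq, iq].sum(axis=-1).reshape(*X.shape[:-2], 1, 1)
        return (1.0 - alpha) * X + alpha * (trace * (1.0 / q)) * eye


class BiMap(Module):
    """Per-slot bilinear map ``W X W^T`` with ``W in R^{Q x C}``.

    Weights are initialized semi-orthogonal (rows orthonormal).  By default
    they are optimized unconstrained; with ``semi_orthogonal=True`` the
    weights are projected back onto the Stiefel manifold after each
    optimizer step (``W <- (W W^T)^{-1/2} W``).
    """

    def __init__(
        self,
        n_slots: int,
        dim_out: int,
        dim_in: int,
        rng: np.random.Generator,
        semi_orthogonal: bool = False,
    ):
        super().__init__()
        if dim_out > dim_in:
            raise ValueError("BiMap output dimension cannot exceed input dimension")
        W = np.empty((n_slots, dim_out, dim_in))
        for p in range(n_slots):
            A = rng.standard_normal((dim_in, dim_out))
            Q, _ = np.linalg.qr(A)
            W[p] = Q[:, :dim_out].T
        self.W = _param(W)
        self.semi_orthogonal = semi_orthogonal

    def __call__(self, X: Tensor) -> Tensor:
        W = self.W.reshape(1, *self.W.shape)
        return W @ X @ W.mT

    def project_(self) -> None:
        """Retract weights onto the Stiefel manifold (post-optimizer-step)."""
        W = self.W.data
        G = W @ np.swapaxes(W, -1, -2)
        w, V = np.linalg.eigh(G)
        inv_sqrt = (V * (1.0 / np.sqrt(np.maximum(w, 1e-12)))[..., None, :]) @ \
            np.swapaxes(V, -1, -2)
        self.W.data[:] = inv_sqrt @ W


class ReEigLogMap(Module):
    """Combined eigenvalue rectification and log-Euclidean tangent map.

    A single diagonalization per slot floors the eigenvalues at ``eps`` and
    takes their logarithm; the tangent vector is
    ``vect(Log(X) - log_ref)`` where ``log_ref`` is a running log-Euclidean
    mean with momentum ``theta`` (initialized from the first training batch,
    frozen at evaluation).  ``eps`` follows the batch scale:
    ``max(1e-4 * mean diagonal, 1e-10)`` per slot.
    """

    def __init__(self, n_slots: int, dim: int, theta: float = 0.9):
        super().__init__()
        if not (0.0 <= theta < 1.0):
            raise ValueError("momentum theta must lie in [0, 1)")
        self.theta = theta
        self.n_slots = n_slots
        self.dim = dim
        self.log_ref: np.ndarray | None = None  # (P, q, q), not a parameter
        iu, ju = np.triu_indices(dim)
        self._iu, self._ju = iu, ju
        self._weights = np.where(iu == ju, 1.0, np.sqrt(2.0))

    def _eps(self, X: Tensor) -> np.ndarray:
        q = X.shape[-1]
        iq = np.arange(q)
        diag_mean = X.data[..., iq, iq].mean(axis=(0, -1))  # (P,)
        return np.maximum(REEIG_EPS_SCALE * diag_mean, REEIG_EPS_FLOOR)

    def __call__(self, X: Tensor) -> Tensor:
        eps = self._eps(X)  # (P,)
        w, V = ad.eigh(X)
        # floor eigenvalues per slot, then log — one diagonalization total
        w_rect = ad.stack(
            [w[:, p, :].clamp_min(float(eps[p])) for p in range(self.n_slots)],
            axis=1,
        )
        log_w = w_rect.log()
        log_w_d = log_w.reshape(*log_w.shape[:-1], 1, log_w.shape[-1])
        logX = (V * log_w_d) @ V.mT  # V diag(log w) V^T

        if self.training:
            batch_mean = logX.data.mean(axis=0)  # (P, q, q)
            if self.log_ref is None:
                self.log_ref = batch_mean
            else:
                self.log_ref = (
                    1.0 - self.theta
                ) * batch_mean + self.theta * self.log_ref
        if self.log_ref is None:
            raise RuntimeError(
                "running reference is uninitialized; run a training batch first"
            )
        centered = logX - Tensor(self.log_ref)
        tangent = centered[..., self._iu, self._ju] * Tensor(self._weights)
        # (B, P, q(q+1)/2) -> flatten slots
        return tangent.reshape(tangent.shape[0], -1)


class ReEig(Module):
    """Standalone eigenvalue rectification ``U max(Lambda, eps) U^T``.

    Used between stacked BiMaps; the final rectification is fused into
    :class:`ReEigLogMap`.
    """

    def __init__(self, n_slots: int):
        super().__init__()
        self.n_slots = n_slots

    def __call__(self, X: Tensor) -> Tensor:
        q = X.shape[-1]
        iq = np.arange(q)
        diag_mean = X.data[..., iq, iq].mean(axis=(0, -1))  # (P,)
        eps = np.maximum(REEIG_EPS_SCALE * diag_mean, REEIG_EPS_FLOOR)
        w, V = ad.eigh(X)
        w_rect = ad.stack(
            [w[:, p, :].clamp_min(float(eps[p])) for p in range(self.n_slots)],
            axis=1,
        )
        w_d = w_rect.reshape(*w_rect.shape[:-1], 1, w_rect.shape[-1])
        return (V * w_d) @ V.mT


# ---------------------------------------------------------------------------
# dense head
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, dim_in: int, dim_out: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(dim_in)
        self.W = _param(rng.uniform(-scale, scale, size=(dim_out, dim_in)))
        self.b = _param(np.zeros(dim_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W.mT + self.b


class BatchNorm1d(Module):
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.ravel() - self.running_mean
            )
            self.running_var += self.momentum * (
                var.data.ravel() - self.running_var
            )
            return self.gamma * xc / (var + self.eps).sqrt() + self.beta
        xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xn + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MLPHead(Module):
    """Fully connected head: hidden blocks of Linear-BN-GELU-Dropout.

    ``hidden=()`` gives a single linear readout (the logarithm-only model);
    the default deep head uses two hidden layers of 64 and 32 units with
    batch normalization, dropout p = 0.333 and a GELU nonlinearity.
    """

    def __init__(
        self,
        dim_in: int,
        dim_out: int,
        hidden: tuple = (64, 32),
        dropout: float = 0.333,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.blocks = []
        d = dim_in
        for h in hidden:
            self.blocks.append(Linear(d, h, rng))
            self.blocks.append(BatchNorm1d(h))
            self.blocks.append(Dropout(dropout, rng))
            d = h
        self.readout = Linear(d, dim_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        i = 0
        while i < len(self.blocks):
            x = self.blocks[i](x)          # linear
            x = self.blocks[i + 1](x)      # batch norm
            x = gelu(x)
            x = self.blocks[i + 2](x)      # dropout
            i += 3
        return self.readout(x)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.reshape(-1) - Tensor(np.asarray(target, float).ravel())
    return (diff * diff).mean()


def cross_entropy_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from unnormalized logits ``(B, K)``."""
    labels = np.asarray(labels, dtype=int)
    B = logits.shape[0]
    shift = logits.data.max(axis=1, keepdims=True)  # constant for stability
    z = logits - Tensor(shift)
    lse = z.exp().sum(axis=1).log()
    picked = z[np.arange(B), labels]
    return (lse - picked).mean()


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment stochastic gradient optimizer with parameter groups."""

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8):
        if groups and not isinstance(groups[0], dict):
            groups = [{"params": list(groups), "lr": 1e-3}]
        self.groups = groups
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        for group in self.groups:
            lr = group["lr"]
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad**2
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
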