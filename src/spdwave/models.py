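"""Model assembly: trainable wavelet-SPD networks and the ridge baseline.

The network pipeline follows one layer graph throughout:

    Gabor conv -> pooling -> shrinkage -> BiMap(s) -> ReEig -> LogMap -> FC

Variants differ in which blocks are present and trainable:

======= ===========================================================
variant description
======= ===========================================================
G1      frozen Morlet-49 bank, covariance only, one BiMap (Q = C-1),
        linear readout — the end-to-end twin of the ridge baseline
G1P     G1 plus pairwise phase-locking matrices in the pooling layer
G2      G1 plus one 32-unit hidden layer (nonlinearity beyond the log)
G3      trainable bank (default F = 10), joint cross-frequency
        covariance, two BiMaps (64 -> 32), deep FC head (64, 32)
G3P     G3 plus per-frequency PLV matrices in a parallel branch
G3FB    trainable bank with frequency-specific Riemannian blocks
        (per-frequency covariance, one BiMap per slot), deep head
======= ===========================================================

The non-deep baseline is a Morlet-49 filter-bank covariance pipeline with a
principal-component subspace projection, log-Euclidean tangent embedding and
a ridge model whose penalty is selected by generalized cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.linear_model import RidgeCV, RidgeClassifierCV

from . import nn
from .autodiff import Tensor
from .geometry import log_euclidean_mean, logm, vect
from .pooling import pool_features
from .wavelets import (
    WaveletBank,
    default_kernel_len,
    fft_conv_valid,
    morlet_init,
    sigma_t_from_frequency,
)

__all__ = [
    "ArchitectureConfig",
    "WaveletSPDNet",
    "build_model",
    "extract_interpretables",
    "FilterBankRidge",
    "baseline_predict",
    "covariances_from_windows",
    "RIDGE_ALPHAS",
]

#: penalty grid of the baseline ridge: 100 log-spaced values in [1e-5, 1e5]
RIDGE_ALPHAS = np.logspace(-5, 5, 100)

_VARIANTS = ("G1", "G1P", "G2", "G3", "G3P", "G3FB")


@dataclass
class ArchitectureConfig:
    """Declarative description of a network variant."""

    variant: str = "G3"
    task: str = "regression"  # "regression" | "classification"
    n_classes: int = 2
    n_wavelets: int = 10
    trainable_wavelets: bool = True
    feature_kinds: tuple = ("covariance",)
    layout: str = "joint"
    bimap_dims: tuple = (64, 32)
    hidden: tuple = (64, 32)
    dropout: float = 0.333
    f_min: float = 1.0
    f_max: float = 64.0
    init: str = "morlet"  # "morlet" | "random"
    n_cycles: float = 7.0
    theta: float = 0.9
    semi_orthogonal: bool = False
    kernel_len: int | None = None

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_outputs(self) -> int:
        return self.n_classes if self.task == "classification" else 1

    @classmethod
    def from_variant(cls, variant: str, task: str = "regression", **overrides):
        """Variant presets; any field can be overridden by keyword."""
        presets = {
            "G1": dict(
                n_wavelets=49, trainable_wavelets=False, layout="per_frequency",
                feature_kinds=("covariance",), bimap_dims=None, hidden=(),
            ),
            "G1P": dict(
                n_wavelets=49, trainable_wavelets=False, layout="per_frequency",
                feature_kinds=("covariance", "plv"), bimap_dims=None, hidden=(),
            ),
            "G2": dict(
                n_wavelets=49, trainable_wavelets=False, layout="per_frequency",
                feature_kinds=("covariance",), bimap_dims=None, hidden=(32,),
            ),
            "G3": dict(
                n_wavelets=10, trainable_wavelets=True, layout="joint",
                feature_kinds=("covariance",), bimap_dims=(64, 32),
                hidden=(64, 32),
            ),
            "G3P": dict(
                n_wavelets=10, trainable_wavelets=True, layout="joint",
                feature_kinds=("covariance", "plv"), bimap_dims=(64, 32),
                hidden=(64, 32),
            ),
            "G3FB": dict(
                n_wavelets=10, trainable_wavelets=True, layout="per_frequency",
                feature_kinds=("covariance",), bimap_dims=("half",),
                hidden=(64, 32),
            ),
        }
        kwargs = dict(presets[variant])
        kwargs.update(overrides)
        return cls(variant=variant, task=task, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for key in ("feature_kinds", "bimap_dims", "hidden"):
            if d.get(key) is not None and not isinstance(d[key], tuple):
                d[key] = tuple(d[key])
        return cls(**d)


def _branch_specs(cfg: ArchitectureConfig, C: int):
    """List of (name, kinds, layout, n_slots, dim_in, bimap_dims)."""
    F = cfg.n_wavelets
    specs = []
    if "covariance" in cfg.feature_kinds:
        if cfg.layout == "joint":
            dims = []
            prev = F * C
            for d in cfg.bimap_dims or (prev - 1,):
                d = min(d, prev)
                dims.append(d)
                prev = d
            specs.append(("cov_joint", ("covariance",), "joint", 1, F * C, dims))
        else:
            # "half" marks a filter-bank-style reduction resolved per C
            dims = [
                max(2, int(np.ceil(C / 2))) if d == "half" else min(d, C)
                for d in (cfg.bimap_dims or (C - 1,))
            ]
            specs.append(
                ("cov_per_freq", ("covariance",), "per_frequency", F, C, dims)
            )
    if "plv" in cfg.feature_kinds:
        # PLV matrices are always per-frequency (same-frequency phase
        # locking); connectivity slots get a stronger BiMap reduction than
        # covariance slots to keep the tangent dimension (and the FC head)
        # small when many wavelets are used
        q_plv = max(2, int(np.ceil(C / 2)))
        specs.append(("plv", ("plv",), "per_frequency", F, C, [q_plv]))
    if not specs:
        raise ValueError("at least one feature kind is required")
    return specs


class _Branch(nn.Module):
    """Shrinkage -> BiMap(s with ReEig between) -> fused ReEig+LogMap."""

    def __init__(self, n_slots, dim_in, bimap_dims, theta, semi_orthogonal, rng):
        super().__init__()
        self.shrink = nn.Shrinkage(n_slots)
        self.bimaps = []
        self.relus = []
        prev = dim_in
        for i, d in enumerate(bimap_dims):
            self.bimaps.append(
                nn.BiMap(n_slots, d, prev, rng, semi_orthogonal=semi_orthogonal)
            )
            if i < len(bimap_dims) - 1:
                self.relus.append(nn.ReEig(n_slots))
            prev = d
        self.logmap = nn.ReEigLogMap(n_slots, prev, theta=theta)
        self.n_slots = n_slots
        self.dim_out = prev

    @property
    def tangent_dim(self) -> int:
        return self.n_slots * self.dim_out * (self.dim_out + 1) // 2

    def __call__(self, X: Tensor) -> Tensor:
        X = self.shrink(X)
        for i, bm in enumerate(self.bimaps):
            X = bm(X)
            if i < len(self.bimaps) - 1:
                X = self.relus[i](X)
        return self.logmap(X)


class WaveletSPDNet(nn.Module):
    """End-to-end trainable wavelet filter bank with SPD-manifold layers."""

    def __init__(
        self,
        cfg: ArchitectureConfig,
        n_channels: int,
        fs: float,
        seed: int = 0,
    ):
        super().__init__()
        if n_channels < 2:
            raise ValueError("need at least two channels")
        self.cfg = cfg
        self.n_channels = int(n_channels)
        self.fs = float(fs)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        self.bank = self._build_bank(cfg, fs, rng)
        self.branches = [
            _Branch(n_slots, dim_in, dims, cfg.theta, cfg.semi_orthogonal, rng)
            for (_, _, _, n_slots, dim_in, dims) in _branch_specs(cfg, n_channels)
        ]
        self._specs = _branch_specs(cfg, n_channels)
        tangent_dim = sum(b.tangent_dim for b in self.branches)
        self.head = nn.MLPHead(
            tangent_dim,
            cfg.n_outputs,
            hidden=cfg.hidden,
            dropout=cfg.dropout,
            rng=rng,
        )
        # target normalization fitted by the training loop (regression)
        self.y_loc = 0.0
        self.y_scale = 1.0
        self.trained = False

    @staticmethod
    def _build_bank(cfg: ArchitectureConfig, fs: float, rng) -> WaveletBank:
        F = cfg.n_wavelets
        f_max = min(cfg.f_max, 0.45 * fs)
        if cfg.init == "random":
            freqs = np.exp(
                rng.uniform(np.log(cfg.f_min), np.log(f_max), size=F)
            )
            freqs.sort()
        elif F == 1:
            freqs = np.array([np.sqrt(cfg.f_min * f_max)])
        else:
            freqs = np.geomspace(cfg.f_min, f_max, F)
        sigmas = sigma_t_from_frequency(freqs, cfg.n_cycles)
        kernel_len = cfg.kernel_len
        if kernel_len is None:
            # deterministic support from the slowest admissible frequency
            kernel_len = default_kernel_len(
                float(sigma_t_from_frequency(cfg.f_min, cfg.n_cycles)), fs
            )
        return WaveletBank(
            freqs, sigmas, fs, kernel_len=kernel_len,
            trainable=cfg.trainable_wavelets,
        )

    # -- parameters --------------------------------------------------------
    def parameters(self):
        return self.bank.parameters() + super().parameters()

    def wavelet_parameters(self):
        return self.bank.parameters()

    def other_parameters(self):
        return super().parameters()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def post_step(self) -> None:
        """Constraint projections applied after each optimizer step."""
        if self.bank.trainable:
            self.bank.clamp_()
        if self.cfg.semi_orthogonal:
            for branch in self.branches:
                for bm in branch.bimaps:
                    bm.project_()

    # -- forward -----------------------------------------------------------
    def pooled_features(self, x: np.ndarray):
        """Feature-matrix stacks per branch as Tensors, shape (B, P, q, q).

        ``x`` is a batch of windowed samples ``(B, E, C, T_s)``.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-2] != self.n_channels:
            raise ValueError(
                f"model expects {self.n_channels} channels, got {x.shape[-2]}"
            )
        kr, ki = self.bank.kernel_tensors()
        if not self.bank.trainable:
            kr, ki = kr.detach(), ki.detach()
        yr, yi = fft_conv_valid(x, kr, ki)
        feats = []
        for (_, kinds, layout, *_rest) in self._specs:
            out = pool_features((yr, yi), kinds=kinds, layout=layout)
            feats.append(out if isinstance(out, Tensor) else out[0])
        return feats

    def forward_from_features(self, feats) -> Tensor:
        tangents = []
        for branch, F_mat in zip(self.branches, feats):
            if not isinstance(F_mat, Tensor):
                F_mat = Tensor(np.asarray(F_mat, dtype=np.float64))
            tangents.append(branch(F_mat))
        z = tangents[0] if len(tangents) == 1 else nn.ad.concatenate(tangents, axis=1)
        return self.head(z)

    def forward(self, x: np.ndarray) -> Tensor:
        """Raw windows ``(B, E, C, T_s)`` to predictions ``(B, n_outputs)``."""
        return self.forward_from_features(self.pooled_features(x))

    def __call__(self, x):
        return self.forward(x)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode prediction.

        Regression: returns de-standardized scalars ``(B,)``.
        Classification: returns unnormalized logits ``(B, K)``.
        """
        was_training = self.training
        self.eval()
        try:
            out = self.forward(x).data
        finally:
            self.train(was_training)
        if self.cfg.task == "regression":
            return out.ravel() * self.y_scale + self.y_loc
        return out

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict(x), axis=1)

    # -- serialization -----------------------------------------------------
    def state(self) -> dict:
        arrays = {
            "bank/log_f": self.bank.log_f.data,
            "bank/log_sigma": self.bank.log_sigma.data,
        }
        for bi, branch in enumerate(self.branches):
            arrays[f"branch{bi}/raw_alpha"] = branch.shrink.raw_alpha.data
            for wi, bm in enumerate(branch.bimaps):
                arrays[f"branch{bi}/bimap{wi}/W"] = bm.W.data
            if branch.logmap.log_ref is not None:
                arrays[f"branch{bi}/log_ref"] = branch.logmap.log_ref
        for li, lin in enumerate(
            [m for m in self.head.blocks if isinstance(m, nn.Linear)]
            + [self.head.readout]
        ):
            arrays[f"head/linear{li}/W"] = lin.W.data
            arrays[f"head/linear{li}/b"] = lin.b.data
        for li, bnorm in enumerate(
            [m for m in self.head.blocks if isinstance(m, nn.BatchNorm1d)]
        ):
            arrays[f"head/bn{li}/gamma"] = bnorm.gamma.data
            arrays[f"head/bn{li}/beta"] = bnorm.beta.data
            arrays[f"head/bn{li}/running_mean"] = bnorm.running_mean
            arrays[f"head/bn{li}/running_var"] = bnorm.running_var
        arrays["y_norm"] = np.array([self.y_loc, self.y_scale])
        return arrays

    def load_state(self, arrays: dict) -> None:
        def put(dst, key):
            if key in arrays:
                dst[...] = arrays[key]

        put(self.bank.log_f.data, "bank/log_f")
        put(self.bank.log_sigma.data, "bank/log_sigma")
        for bi, branch in enumerate(self.branches):
            put(branch.shrink.raw_alpha.data, f"branch{bi}/raw_alpha")
            for wi, bm in enumerate(branch.bimaps):
                put(bm.W.data, f"branch{bi}/bimap{wi}/W")
            key = f"branch{bi}/log_ref"
            if key in arrays:
                branch.logmap.log_ref = np.array(arrays[key])
        linears = [m for m in self.head.blocks if isinstance(m, nn.Linear)] + [
            self.head.readout
        ]
        for li, lin in enumerate(linears):
            put(lin.W.data, f"head/linear{li}/W")
            put(lin.b.data, f"head/linear{li}/b")
        bns = [m for m in self.head.blocks if isinstance(m, nn.BatchNorm1d)]
        for li, bnorm in enumerate(bns):
            put(bnorm.gamma.data, f"head/bn{li}/gamma")
            put(bnorm.beta.data, f"head/bn{li}/beta")
            put(bnorm.running_mean, f"head/bn{li}/running_mean")
            put(bnorm.running_var, f"head/bn{li}/running_var")
        if "y_norm" in arrays:
            self.y_loc, self.y_scale = (float(v) for v in arrays["y_norm"])


def build_model(
    cfg: ArchitectureConfig, n_channels: int, fs: float, seed: int = 0
) -> WaveletSPDNet:
    """Construct an initialized network for ``n_channels`` at rate ``fs``."""
    return WaveletSPDNet(cfg, n_channels, fs, seed=seed)


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def extract_interpretables(
    model: WaveletSPDNet,
    windows: np.ndarray,
    conditions: np.ndarray | None = None,
) -> dict:
    """Reusable EEG quantities from a forward pass of a (trained) model.

    Parameters
    ----------
    model : the network (a warning is issued when it has not been trained).
    windows : batch of windowed recordings ``(B, E, C, T_s)``.
    conditions : optional binary labels (condition A = 1, B = 0) to compare.

    Returns
    -------
    dict with:

    * ``frequencies`` — wavelet center frequencies (Hz)
    * ``sigma_f`` — frequency-domain widths ``1/(2 pi sigma_t)`` (Hz)
    * ``power`` — per-sample band power topographies ``(B, F, C)``
      (diagonal of the per-frequency covariance)
    * with conditions: ``topography_a`` / ``topography_b`` (mean ``(F, C)``)
      and ``power_ratio_db`` — ``10 log10(A/B)`` per wavelet, channel-mean
    """
    if not model.trained:
        warnings.warn("model has not been trained; interpreting initial weights")
    windows = np.asarray(windows, dtype=float)
    kr, ki = model.bank.kernel_tensors()
    yr, yi = fft_conv_valid(windows, kr.detach(), ki.detach())
    coeffs = yr.data + 1j * yi.data
    fset = pool_features(coeffs, kinds=("covariance",), layout="per_frequency")
    covs = fset.matrices  # (B, F, C, C)
    idx = np.arange(covs.shape[-1])
    power = covs[..., idx, idx]  # (B, F, C)
    out = {
        "frequencies": model.bank.frequencies,
        "sigma_f": model.bank.sigma_fs,
        "power": power,
    }
    if conditions is not None:
        conditions = np.asarray(conditions).astype(int).ravel()
        mean_a = power[conditions == 1].mean(axis=0)  # (F, C)
        mean_b = power[conditions == 0].mean(axis=0)
        out["topography_a"] = mean_a
        out["topography_b"] = mean_b
        out["power_ratio_db"] = 10.0 * np.log10(
            mean_a.mean(axis=1) / mean_b.mean(axis=1)
        )
    return out


# ---------------------------------------------------------------------------
# helpers shared with the baseline and frozen-bank training
# ---------------------------------------------------------------------------

def covariances_from_windows(
    windows: np.ndarray,
    bank: WaveletBank,
    kinds=("covariance",),
    layout: str = "per_frequency",
    chunk: int = 8,
):
    """Pool feature matrices for a batch of samples, chunked over samples.

    Returns one ndarray per feature group (per-frequency stacks have shape
    ``(B, P, C, C)``; the joint layout gives ``(B, 1, F*C, F*C)``).
    """
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim == 3:
        windows = windows[None]
    kr, ki = bank.kernel_tensors()
    kr, ki = kr.detach(), ki.detach()
    pieces = None
    for lo in range(0, windows.shape[0], chunk):
        part = windows[lo : lo + chunk]
        yr, yi = fft_conv_valid(part, kr, ki)
        out = pool_features((yr.data + 1j * yi.data), kinds=kinds, layout=layout)
        groups = out if isinstance(out, list) else [out]
        mats = [g.matrices for g in groups]
        if pieces is None:
            pieces = [[] for _ in mats]
        for store, m in zip(pieces, mats):
            store.append(m)
    return [np.concatenate(store, axis=0) for store in pieces]


# ---------------------------------------------------------------------------
# non-deep baseline
# ---------------------------------------------------------------------------

class FilterBankRidge:
    """Riemannian filter-bank ridge: the non-deep reference pipeline.

    Morlet-49 covariances per frequency -> projection onto the principal
    subspace of the mean training covariance (rank repair) -> log-Euclidean
    tangent vectors about the mean -> ridge with generalized cross-validation
    over 100 log-spaced penalties in [1e-5, 1e5].
    """

    def __init__(
        self,
        fs: float,
        task: str = "regression",
        f_min: float = 1.0,
        f_max: float = 64.0,
        resolution: int = 8,
        kernel_len: int | None = None,
        rank_tol: float = 1e-10,
    ):
        if task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        self.fs = float(fs)
        self.task = task
        f_max = min(f_max, 0.45 * fs)
        self.bank = morlet_init(
            f_min, f_max, resolution, fs, kernel_len=kernel_len
        )
        self.rank_tol = rank_tol
        self.components_: np.ndarray | None = None
        self.ref_logs_: np.ndarray | None = None
        self.model_ = None

    # -- features ----------------------------------------------------------
    def _covs(self, windows: np.ndarray) -> np.ndarray:
        (covs,) = covariances_from_windows(
            windows, self.bank, kinds=("covariance",), layout="per_frequency"
        )
        return covs  # (B, F, C, C)

    def _tangent(self, covs: np.ndarray) -> np.ndarray:
        proj = self.components_ @ covs @ np.swapaxes(self.components_, -1, -2)
        logs = logm(proj, eps=1e-12)
        return vect(logs - self.ref_logs_).reshape(covs.shape[0], -1)

    def fit(self, windows: np.ndarray, y: np.ndarray) -> "FilterBankRidge":
        windows = np.asarray(windows, dtype=float)
        if windows.shape[0] < 2:
            raise ValueError("need at least two training samples")
        return self.fit_covariances(self._covs(windows), y)

    def fit_covariances(self, covs: np.ndarray, y: np.ndarray) -> "FilterBankRidge":
        """Fit from precomputed per-frequency covariances ``(B, F, C, C)``."""
        if covs.shape[0] < 2:
            raise ValueError("need at least two training samples")
        mean_cov = covs.mean(axis=0)  # (F, C, C)
        C = mean_cov.shape[-1]
        w, V = np.linalg.eigh(mean_cov)
        ranks = (w > self.rank_tol * w.max(axis=-1, keepdims=True)).sum(axis=-1)
        r = int(ranks.min())
        if r < C:
            warnings.warn(
                f"mean covariance is rank deficient; projecting to rank {r}"
            )
        # leading principal components per frequency, (F, r, C)
        self.components_ = np.swapaxes(V[..., -r:], -1, -2)
        proj = self.components_ @ covs @ np.swapaxes(self.components_, -1, -2)
        self.ref_logs_ = logm(log_euclidean_mean(proj, eps=1e-12))
        Z = self._tangent(covs)
        if self.task == "regression":
            self.model_ = RidgeCV(alphas=RIDGE_ALPHAS)
        else:
            self.model_ = RidgeClassifierCV(alphas=RIDGE_ALPHAS)
        self.model_.fit(Z, y)
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit the model before predicting")
        return self.predict_covariances(
            self._covs(np.asarray(windows, dtype=float))
        )

    def predict_covariances(self, covs: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise RuntimeError("fit the model before predicting")
        return self.model_.predict(self._tangent(covs))


def baseline_predict(
    train_windows: np.ndarray,
    y_train: np.ndarray,
    test_windows: np.ndarray,
    fs: float,
    task: str = "regression",
    **kwargs,
) -> np.ndarray:
    """Fit the filter-bank ridge baseline and predict the test samples."""
    model = FilterBankRidge(fs, task=task, **kwargs)
    model.fit(train_windows, y_train)
    return model.predict(test_windows)
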