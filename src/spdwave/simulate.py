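"""Synthetic multichannel EEG with known ground truth.

The generative model mirrors the assumption under which tangent-space
regression on covariances is statistically consistent: the outcome is a
linear combination of the **log power** of stationary band-limited sources,
observed at the sensors after linear mixing (volume conduction)::

    x(t) = A s(t) + n_bg(t) + n_white(t)
    y    = sum_j beta_j * log p_j + eps          (regression)
    y    ~ Bernoulli(sigmoid(linear predictor))  (binary)

Sources are band-passed Gaussian noise (not pure sinusoids, so phase-locking
between mixed channels is non-degenerate), normalized to their drawn power
``p_j``.  The background is 1/f-shaped noise per channel and the sensor
noise is white; both are normalized to unit variance before scaling, so the
analytic sensor covariance is ``A diag(p) A^T + (sd_bg^2 + sd_white^2) I``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import fft as sfft
from scipy import signal as ssig
from scipy.special import expit

__all__ = [
    "SourceSpec",
    "GenerativeConfig",
    "SyntheticDataset",
    "simulate_recording",
    "simulate_dataset",
    "make_alpha_task",
]


@dataclass
class SourceSpec:
    """One band-limited oscillatory source."""

    center: float = 10.0  # Hz
    bandwidth: float = 2.0  # Hz (full width)
    log_power_mean: float = 0.0  # natural-log units
    log_power_sd: float = 1.0
    pattern: np.ndarray | None = None  # length-C mixing column (optional)

    def validate(self, fs: float) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.center + self.bandwidth / 2 >= fs / 2:
            raise ValueError(
                f"source at {self.center} Hz exceeds the Nyquist frequency"
            )


@dataclass
class GenerativeConfig:
    """Full description of a simulated cohort."""

    n_subjects: int = 100
    n_channels: int = 8
    duration: float = 60.0  # seconds
    fs: float = 125.0
    sources: list = field(default_factory=lambda: [SourceSpec()])
    mixing: np.ndarray | str = "random_orthonormal"
    noise_sd: float = 0.1  # white sensor noise
    background_sd: float = 0.3  # 1/f-shaped background
    background_exponent: float = 1.0  # power ~ 1/f^exponent
    outcome_type: str = "regression"  # "regression" | "binary"
    beta: np.ndarray | None = None  # coefficients over log powers
    outcome_noise_sd: float = 0.25  # regression residual sd
    temperature: float = 1.0  # logistic temperature (binary)
    seed: int = 0

    def __post_init__(self):
        if self.outcome_type not in ("regression", "binary"):
            raise ValueError("outcome_type must be 'regression' or 'binary'")
        if len(self.sources) > self.n_channels:
            raise ValueError("need K <= C (no more sources than channels)")
        for src in self.sources:
            src.validate(self.fs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def mixing_matrix(self, rng: np.random.Generator) -> np.ndarray:
        K, C = len(self.sources), self.n_channels
        if K == 0:
            return np.zeros((C, 0))
        explicit = [s.pattern for s in self.sources if s.pattern is not None]
        if isinstance(self.mixing, np.ndarray):
            A = np.asarray(self.mixing, dtype=float)
            if A.shape != (C, K):
                raise ValueError(f"mixing matrix must be {C}x{K}")
            return A
        if len(explicit) == len(self.sources):
            A = np.column_stack([np.asarray(p, float) for p in explicit])
            return A / np.linalg.norm(A, axis=0, keepdims=True)
        # random orthonormal columns, drawn once per dataset
        M = rng.standard_normal((C, K))
        Q, _ = np.linalg.qr(M)
        return Q[:, :K]


@dataclass
class SyntheticDataset:
    """Recordings plus outcomes and the ground truth that generated them."""

    recordings: np.ndarray  # (n, C, T)
    outcomes: np.ndarray  # (n,)
    log_powers: np.ndarray  # (n, K)
    mixing: np.ndarray  # (C, K)
    beta: np.ndarray  # (K,)
    source_freqs: np.ndarray  # (K,)
    linear_predictor: np.ndarray  # (n,) noiseless predictor
    fs: float
    config: GenerativeConfig | None = None

    @property
    def n_subjects(self) -> int:
        return self.recordings.shape[0]


def _bandlimited_noise(rng, n_samples, fs, center, bandwidth):
    """Gaussian noise band-passed to center +- bandwidth/2, unit power."""
    lo = max(center - bandwidth / 2.0, 1e-3)
    hi = center + bandwidth / 2.0
    white = rng.standard_normal(n_samples)
    freqs = sfft.rfftfreq(n_samples, d=1.0 / fs)
    spectrum = sfft.rfft(white)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    x = sfft.irfft(spectrum, n_samples)
    power = np.mean(x**2)
    if power <= 0:
        raise ValueError("degenerate band (no frequency bins in passband)")
    return x / np.sqrt(power)


def _one_over_f_noise(rng, shape, fs, exponent):
    """Per-channel 1/f^exponent-shaped noise, unit variance per channel."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    freqs = sfft.rfftfreq(n, d=1.0 / fs)
    amp = np.ones_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-exponent / 2.0)
    amp[0] = amp[1] if len(amp) > 1 else 1.0
    shaped = sfft.irfft(sfft.rfft(white, axis=-1) * amp, n, axis=-1)
    return shaped / shaped.std(axis=-1, keepdims=True)


def simulate_recording(
    cfg: GenerativeConfig,
    subject: int,
    mixing: np.ndarray | None = None,
    log_powers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one recording; returns ``(C x T signal, log powers)``.

    Per-subject randomness is derived from ``(cfg.seed, subject)`` so any
    single recording can be regenerated in isolation.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject)))
    A = cfg.mixing_matrix(np.random.default_rng(cfg.seed)) if mixing is None else mixing
    K = len(cfg.sources)
    T = cfg.n_samples
    if log_powers is None:
        log_powers = np.array(
            [
                rng.normal(s.log_power_mean, s.log_power_sd)
                for s in cfg.sources
            ]
        )
    sources = np.empty((K, T))
    for j, src in enumerate(cfg.sources):
        s = _bandlimited_noise(rng, T, cfg.fs, src.center, src.bandwidth)
        sources[j] = s * np.sqrt(np.exp(log_powers[j]))
    x = A @ sources
    if cfg.background_sd > 0:
        x = x + cfg.background_sd * _one_over_f_noise(
            rng, (cfg.n_channels, T), cfg.fs, cfg.background_exponent
        )
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * rng.standard_normal((cfg.n_channels, T))
    return x, log_powers


def simulate_dataset(cfg: GenerativeConfig) -> SyntheticDataset:
    """Generate a full cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    A = cfg.mixing_matrix(rng)
    K = len(cfg.sources)
    beta = (
        np.ones(K) if cfg.beta is None else np.asarray(cfg.beta, dtype=float)
    )
    if beta.size != K:
        raise ValueError("beta must have one coefficient per source")
    recordings = np.empty((cfg.n_subjects, cfg.n_channels, cfg.n_samples))
    log_powers = np.empty((cfg.n_subjects, K))
    for i in range(cfg.n_subjects):
        recordings[i], log_powers[i] = simulate_recording(cfg, i, mixing=A)
    predictor = log_powers @ beta
    out_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1 << 20)))
    if cfg.outcome_type == "regression":
        outcomes = predictor + cfg.outcome_noise_sd * out_rng.standard_normal(
            cfg.n_subjects
        )
    else:
        prob = expit((predictor - predictor.mean()) / cfg.temperature)
        outcomes = (out_rng.random(cfg.n_subjects) < prob).astype(float)
    return SyntheticDataset(
        recordings=recordings,
        outcomes=outcomes,
        log_powers=log_powers,
        mixing=A,
        beta=beta,
        source_freqs=np.array([s.center for s in cfg.sources]),
        linear_predictor=predictor,
        fs=cfg.fs,
        config=cfg,
    )


def make_alpha_task(
    n_subjects: int = 200,
    n_channels: int = 8,
    duration: float = 60.0,
    fs: float = 125.0,
    delta: float = 1.0,
    alpha_freq: float = 10.0,
    bandwidth: float = 2.0,
    distractor_freqs: tuple = (6.0, 16.0),
    seed: int = 0,
    background_sd: float = 1.0,
    noise_sd: float = 0.1,
) -> SyntheticDataset:
    """Binary eyes-closed-style task: alpha log power shifted by ``delta``.

    Class 1 ("eyes closed") recordings have the 8-12 Hz source's log power
    shifted by ``delta`` natural-log units; everything else is identical in
    distribution.  The alpha source has an occipital-like spatial pattern
    concentrated on the last channels.

    Two non-discriminative neighboring rhythms (``distractor_freqs``) share
    the alpha source's spatial pattern and fluctuate strongly across
    subjects, emulating the individual variability of theta/beta activity.
    Being spatially collinear with the alpha source, they cannot be removed
    by spatial filtering — only by precise spectral localization, which is
    what makes this task a sharp probe of wavelet learning.  Labels are
    balanced and assigned deterministically (first half class 0).
    """
    pattern = np.ones(n_channels) * 0.15
    n_occ = max(2, n_channels // 4)
    pattern[-n_occ:] = 1.0
    sources = [
        SourceSpec(
            center=alpha_freq,
            bandwidth=bandwidth,
            log_power_mean=0.0,
            log_power_sd=0.4,
            pattern=pattern,
        )
    ]
    for f_d in distractor_freqs:
        sources.append(
            SourceSpec(
                center=f_d,
                bandwidth=1.5 * bandwidth,
                log_power_mean=0.0,
                log_power_sd=1.0,
                pattern=pattern.copy(),
            )
        )
    cfg = GenerativeConfig(
        n_subjects=n_subjects,
        n_channels=n_channels,
        duration=duration,
        fs=fs,
        sources=sources,
        noise_sd=noise_sd,
        background_sd=background_sd,
        outcome_type="binary",
        seed=seed,
    )
    labels = (np.arange(n_subjects) >= n_subjects // 2).astype(float)
    A = cfg.mixing_matrix(np.random.default_rng(seed))
    K = len(sources)
    recordings = np.empty((n_subjects, n_channels, cfg.n_samples))
    log_powers = np.empty((n_subjects, K))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3 << 20)))
    for i in range(n_subjects):
        lp = np.array(
            [rng.normal(delta * labels[i], sources[0].log_power_sd)]
            + [rng.normal(s.log_power_mean, s.log_power_sd) for s in sources[1:]]
        )
        recordings[i], log_powers[i] = simulate_recording(
            cfg, i, mixing=A, log_powers=lp
        )
    beta = np.zeros(K)
    beta[0] = delta
    return SyntheticDataset(
        recordings=recordings,
        outcomes=labels,
        log_powers=log_powers,
        mixing=A,
        beta=beta,
        source_freqs=np.array([s.center for s in sources]),
        linear_predictor=delta * labels,
        fs=fs,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# on-disk format: compressed array archive + CSV outcomes + JSON sidecar
# ---------------------------------------------------------------------------

def save_dataset(ds: SyntheticDataset, directory: str | Path) -> Path:
    """Write a dataset as ``data.npz`` + ``outcomes.csv`` + ``meta.json``."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "data.npz",
        recordings=ds.recordings,
        log_powers=ds.log_powers,
        mixing=ds.mixing,
        beta=ds.beta,
        source_freqs=ds.source_freqs,
        linear_predictor=ds.linear_predictor,
    )
    pd.DataFrame(
        {"subject_id": np.arange(ds.n_subjects), "outcome": ds.outcomes}
    ).to_csv(directory / "outcomes.csv", index=False, float_format="%.17g")
    meta = {"fs": ds.fs, "schema": "spdwave-dataset-v1"}
    if ds.config is not None:
        cfg = asdict(ds.config)
        cfg["sources"] = [
            {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in s.items()
            }
            for s in cfg["sources"]
        ]
        if isinstance(cfg.get("mixing"), np.ndarray):
            cfg["mixing"] = cfg["mixing"].tolist()
        if isinstance(cfg.get("beta"), np.ndarray):
            cfg["beta"] = cfg["beta"].tolist()
        meta["config"] = cfg
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Read a dataset written by :func:`save_dataset`."""
    import pandas as pd

    directory = Path(directory)
    sidecar = directory / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}; refusing to guess metadata"
        )
    meta = json.loads(sidecar.read_text())
    if meta.get("schema") != "spdwave-dataset-v1":
        raise ValueError("unrecognized dataset schema in meta.json")
    arrays = np.load(directory / "data.npz")
    outcomes = pd.read_csv(
        directory / "outcomes.csv", float_precision="round_trip"
    )["outcome"].to_numpy()
    return SyntheticDataset(
        recordings=arrays["recordings"],
        outcomes=outcomes,
        log_powers=arrays["log_powers"],
        mixing=arrays["mixing"],
        beta=arrays["beta"],
        source_freqs=arrays["source_freqs"],
        linear_predictor=arrays["linear_predictor"],
        fs=float(meta["fs"]),
    )
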