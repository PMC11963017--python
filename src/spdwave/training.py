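"""Window sampling, optimization, cross-validation and model comparison.

Protocol defaults follow the standard evaluation recipe for subject-level
EEG prediction: each sample consists of E = 10 windows of T = 10 s drawn
uniformly at random from the recording; models are compared with
Monte-Carlo cross-validation (100 random splits, 20% test) and the
Nadeau-Bengio corrected resampled t-test, whose variance-inflation factor
``(1/K + n_test/n_train)`` compensates for the overlap of training sets
across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, balanced_accuracy_score, r2_score
from sklearn.model_selection import ShuffleSplit

from . import nn
from .models import (
    ArchitectureConfig,
    FilterBankRidge,
    WaveletSPDNet,
    build_model,
)
from .wavelets import EpochTensor

__all__ = [
    "TrainConfig",
    "CVResult",
    "sample_windows",
    "sample_windows_batch",
    "train",
    "monte_carlo_cv",
    "corrected_t_test",
    "wavelet_profile",
    "NetworkEstimator",
    "BaselineEstimator",
]

#: evaluation protocol defaults: E windows of T seconds per sample
DEFAULT_E = 10
DEFAULT_T = 10.0


def sample_windows(
    recording: np.ndarray,
    E: int = DEFAULT_E,
    T: float = DEFAULT_T,
    fs: float = 125.0,
    seed: int | np.random.Generator = 0,
) -> EpochTensor:
    """Draw ``E`` windows of ``T`` seconds with uniform random starts.

    Draws are independent, so windows may overlap; a recording exactly one
    window long yields ``E`` identical windows starting at zero.
    """
    recording = np.asarray(recording, dtype=np.float64)
    if recording.ndim != 2:
        raise ValueError("recording must be (channels, samples)")
    n = recording.shape[-1]
    w = int(round(T * fs))
    if n < w:
        raise ValueError(
            f"recording ({n} samples) shorter than one window ({w} samples)"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    starts = rng.integers(0, n - w + 1, size=E)
    values = np.stack([recording[:, s : s + w] for s in starts])
    return EpochTensor(values, fs)


def sample_windows_batch(
    recordings: np.ndarray,
    E: int = DEFAULT_E,
    T: float = DEFAULT_T,
    fs: float = 125.0,
    seed: int = 0,
) -> np.ndarray:
    """Windows for a batch of recordings, shape ``(B, E, C, T_s)``.

    Each recording gets its own deterministic substream so the draw for
    subject ``i`` does not depend on the batch composition.
    """
    recordings = np.asarray(recordings, dtype=np.float64)
    return np.stack(
        [
            sample_windows(
                rec, E=E, T=T, fs=fs,
                seed=np.random.default_rng(np.random.SeedSequence((seed, i))),
            ).values
            for i, rec in enumerate(recordings)
        ]
    )


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer and protocol settings for one training run."""

    epochs: int = 300
    patience: int = 100
    batch_size: int = 32
    lr: float = 1e-3
    lr_wavelets: float = 5e-2
    lr_sigma: float | None = None  # default: lr_wavelets / 5
    val_frac: float = 0.2
    E: int = DEFAULT_E
    T: float = DEFAULT_T
    seed: int = 0
    resample_each_epoch: bool = True
    restore_best: bool = True
    verbose: bool = False


def _loss_fn(model: WaveletSPDNet, out, y):
    if model.cfg.task == "regression":
        return nn.mse_loss(out, y)
    return nn.cross_entropy_loss(out, y)


def train(
    model: WaveletSPDNet,
    recordings: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    features: list | None = None,
) -> dict:
    """Fit the network with Adam and early stopping.

    A held-out validation split (``val_frac`` of the data) drives early
    stopping with the configured patience; the parameters with the best
    validation loss are restored at the end.  Regression targets are
    z-scored internally (the scale is stored on the model, and
    :meth:`WaveletSPDNet.predict` undoes it).

    Windows are drawn fresh every epoch as data augmentation when the
    wavelets are trainable; for frozen banks the wavelet features are
    deterministic given the windows, so features are computed once from a
    fixed draw and cached.  Precomputed pooled feature matrices (one array
    per branch, leading axis = samples) can be passed via ``features`` for
    frozen-bank models to share a wavelet transform across models.

    Returns a history dict with per-epoch train and validation losses.
    """
    cfg = cfg or TrainConfig()
    recordings = np.asarray(recordings, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = recordings.shape[0]
    if n == 0:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_frac * n))) if n >= 5 else 0
    val_idx = order[:n_val]
    tr_idx = order[n_val:]

    if model.cfg.task == "regression":
        model.y_loc = float(y[tr_idx].mean())
        model.y_scale = float(y[tr_idx].std() or 1.0)
        y_t = (y - model.y_loc) / model.y_scale
    else:
        y_t = y.astype(int)

    lr_sigma = cfg.lr_sigma if cfg.lr_sigma is not None else cfg.lr_wavelets / 5.0
    groups = [{"params": model.other_parameters(), "lr": cfg.lr}]
    if model.bank.trainable:
        # center frequencies move faster than envelope widths: letting the
        # width grow at the same rate lets wavelets cover informative bands
        # by broadening instead of centering on them
        groups.append({"params": [model.bank.log_f], "lr": cfg.lr_wavelets})
        groups.append({"params": [model.bank.log_sigma], "lr": lr_sigma})
    opt = nn.Adam(groups)

    resample = cfg.resample_each_epoch and model.bank.trainable
    cached_feats = None
    fixed_windows = val_windows = None
    if features is not None:
        if model.bank.trainable:
            raise ValueError(
                "precomputed features require a frozen wavelet bank"
            )
        cached_feats = [np.asarray(f, dtype=np.float64) for f in features]
    else:
        fixed_windows = sample_windows_batch(
            recordings, E=cfg.E, T=cfg.T, fs=model.fs, seed=cfg.seed
        )
        if not model.bank.trainable:
            feats = model.pooled_features(fixed_windows)
            cached_feats = [f.data for f in feats]
        val_windows = fixed_windows[val_idx] if n_val else None

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = None
    best_epoch = -1

    for epoch in range(cfg.epochs):
        model.train()
        if resample:
            windows = sample_windows_batch(
                recordings, E=cfg.E, T=cfg.T, fs=model.fs,
                seed=cfg.seed + 1 + epoch,
            )
        else:
            windows = fixed_windows
        perm = rng.permutation(tr_idx)
        epoch_losses = []
        for lo in range(0, len(perm), cfg.batch_size):
            idx = perm[lo : lo + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need at least two samples
            opt.zero_grad()
            if cached_feats is not None:
                out = model.forward_from_features(
                    [f[idx] for f in cached_feats]
                )
            else:
                out = model.forward(windows[idx])
            loss = _loss_fn(model, out, y_t[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (non-finite loss at epoch {epoch})"
                )
            loss.backward()
            opt.step()
            model.post_step()
            epoch_losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(epoch_losses)))

        if n_val:
            model.eval()
            if cached_feats is not None:
                val_out = model.forward_from_features(
                    [f[val_idx] for f in cached_feats]
                )
            else:
                val_out = model.forward(val_windows)
            val_loss = float(_loss_fn(model, val_out, y_t[val_idx]).data)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if cfg.verbose:
            print(
                f"epoch {epoch:3d}  train {history['train_loss'][-1]:.4f}"
                f"  val {val_loss:.4f}"
            )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: np.array(v) for k, v in model.state().items()}
        elif epoch - best_epoch >= cfg.patience:
            break

    if cfg.restore_best and best_state is not None:
        model.load_state(best_state)
    model.trained = True
    model.eval()
    history["best_epoch"] = best_epoch
    return history


# ---------------------------------------------------------------------------
# estimator wrappers (shared fit/predict interface over recordings)
# ---------------------------------------------------------------------------

class NetworkEstimator:
    """fit/predict wrapper around :class:`WaveletSPDNet` for CV loops."""

    def __init__(
        self,
        arch: ArchitectureConfig,
        fs: float,
        train_cfg: TrainConfig | None = None,
        seed: int = 0,
    ):
        self.arch = arch
        self.fs = fs
        self.train_cfg = train_cfg or TrainConfig()
        self.seed = seed
        self.model: WaveletSPDNet | None = None

    def fit(self, recordings, y):
        self.model = build_model(
            self.arch, recordings.shape[1], self.fs, seed=self.seed
        )
        train(
            self.model, recordings, y,
            replace(self.train_cfg, seed=self.seed),
        )
        return self

    def _windows(self, recordings):
        return sample_windows_batch(
            recordings, E=self.train_cfg.E, T=self.train_cfg.T, fs=self.fs,
            seed=self.seed,
        )

    def predict(self, recordings):
        out = self.model.predict(self._windows(recordings))
        if self.arch.task == "classification":
            return np.argmax(out, axis=1)
        return out


class BaselineEstimator:
    """fit/predict wrapper around :class:`FilterBankRidge` for CV loops."""

    def __init__(
        self,
        fs: float,
        task: str = "regression",
        E: int = DEFAULT_E,
        T: float = DEFAULT_T,
        seed: int = 0,
        **kwargs,
    ):
        self.fs = fs
        self.task = task
        self.E, self.T = E, T
        self.seed = seed
        self.kwargs = kwargs
        self.model: FilterBankRidge | None = None

    def _windows(self, recordings):
        return sample_windows_batch(
            recordings, E=self.E, T=self.T, fs=self.fs, seed=self.seed
        )

    def fit(self, recordings, y):
        self.model = FilterBankRidge(self.fs, task=self.task, **self.kwargs)
        self.model.fit(self._windows(recordings), y)
        return self

    def predict(self, recordings):
        return self.model.predict(self._windows(recordings))


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-split scores of one or more models on shared splits."""

    scores: pd.DataFrame  # columns: split, model, score
    splits: list  # list of (train_idx, test_idx)
    n_train: int
    n_test: int

    def score_matrix(self) -> pd.DataFrame:
        return self.scores.pivot(index="split", columns="model", values="score")

    def summary(self) -> pd.DataFrame:
        return self.scores.groupby("model")["score"].agg(["mean", "std"])

    def compare(self, model_a: str, model_b: str):
        """Corrected resampled t-test on paired score differences A - B."""
        mat = self.score_matrix()
        diffs = (mat[model_a] - mat[model_b]).to_numpy()
        return corrected_t_test(diffs, self.n_train, self.n_test)


def _score(task, scoring, y_true, y_pred):
    if task == "regression":
        return r2_score(y_true, y_pred)
    if scoring == "balanced_accuracy":
        return balanced_accuracy_score(y_true, y_pred)
    return accuracy_score(y_true, y_pred)


def monte_carlo_cv(
    factories: dict,
    recordings: np.ndarray,
    y: np.ndarray,
    K: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    task: str = "regression",
    scoring: str | None = None,
) -> CVResult:
    """Monte-Carlo (shuffle-split) cross-validation with shared splits.

    ``factories`` maps model names to callables ``factory(seed) -> estimator``
    with fit/predict over recordings.  All models see identical splits so
    their per-split score differences form a paired sample; splits whose
    training part misses a class are redrawn with a warning.
    """
    recordings = np.asarray(recordings, dtype=np.float64)
    y = np.asarray(y)
    n = recordings.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for Monte-Carlo CV")
    splitter = ShuffleSplit(n_splits=K, test_size=test_frac, random_state=seed)
    splits = list(splitter.split(np.arange(n)))
    if task == "classification":
        classes = np.unique(y)
        redraw_rng = np.random.default_rng(seed + 10_000)
        for k in range(K):
            tr, te = splits[k]
            tries = 0
            while len(np.unique(y[tr])) < len(classes):
                warnings.warn(f"split {k} misses a class in training; redrawing")
                perm = redraw_rng.permutation(n)
                te = perm[: len(te)]
                tr = perm[len(te) :]
                splits[k] = (tr, te)
                tries += 1
                if tries > 100:
                    raise RuntimeError("cannot draw a split containing all classes")
    rows = []
    for name, factory in factories.items():
        for k, (tr, te) in enumerate(splits):
            est = factory(seed * 100_003 + k)
            est.fit(recordings[tr], y[tr])
            pred = est.predict(recordings[te])
            rows.append(
                {
                    "split": k,
                    "model": name,
                    "score": _score(task, scoring, y[te], pred),
                }
            )
    n_test = len(splits[0][1])
    return CVResult(
        scores=pd.DataFrame(rows),
        splits=splits,
        n_train=n - n_test,
        n_test=n_test,
    )


def corrected_t_test(
    diffs: np.ndarray, n_train: int, n_test: int
) -> tuple[float, float]:
    """Corrected resampled t-test for paired CV score differences.

    ``t = m / sqrt((1/K + n_test/n_train) * s^2)`` where ``m`` is the mean
    difference and ``s^2`` the unbiased sample variance over the K splits;
    the p value is two-sided from the t distribution with K - 1 degrees of
    freedom.  The ``n_test/n_train`` term inflates the naive variance to
    account for the overlap of training sets across resampled splits.
    """
    diffs = np.asarray(diffs, dtype=float).ravel()
    K = diffs.size
    if K < 2:
        raise ValueError("need at least two splits")
    m = diffs.mean()
    s2 = diffs.var(ddof=1)
    if s2 == 0.0:
        if m == 0.0:
            return 0.0, 1.0
        warnings.warn("zero variance with nonzero mean difference")
        return float(np.sign(m) * np.inf), 0.0
    t = m / np.sqrt((1.0 / K + n_test / n_train) * s2)
    p = 2.0 * stats.t.sf(abs(t), df=K - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# filter-bank size profiling
# ---------------------------------------------------------------------------

def wavelet_profile(
    factory,
    recordings: np.ndarray,
    y: np.ndarray,
    F_grid=tuple(range(1, 16)),
    reps: int = 5,
    test_frac: float = 0.2,
    seed: int = 0,
    task: str = "classification",
    scoring: str | None = None,
) -> dict:
    """Performance versus filter-bank size on a single held-out fold.

    ``factory(F, seed)`` must return a fit/predict estimator whose bank has
    ``F`` wavelets (random initializations seeded by ``seed``).  For each
    ``F`` the model is trained ``reps`` times; the selected size is the
    smallest ``F`` whose mean score is within one standard deviation of the
    largest bank's mean.  Also reports the learned center frequencies at the
    selected size.
    """
    recordings = np.asarray(recordings, dtype=np.float64)
    y = np.asarray(y)
    n = recordings.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_frac * n)))
    te, tr = perm[:n_test], perm[n_test:]

    F_grid = sorted(F_grid)
    scores = np.zeros((len(F_grid), reps))
    freqs: dict = {}
    for fi, F in enumerate(F_grid):
        freqs[F] = []
        for rep in range(reps):
            est = factory(F, seed * 1009 + 7 * rep + F)
            est.fit(recordings[tr], y[tr])
            pred = est.predict(recordings[te])
            scores[fi, rep] = _score(task, scoring, y[te], pred)
            model = getattr(est, "model", None)
            if model is not None and hasattr(model, "bank"):
                freqs[F].append(np.array(model.bank.frequencies))
    mean = scores.mean(axis=1)
    sd = scores.std(axis=1, ddof=1) if reps > 1 else np.zeros(len(F_grid))
    threshold = mean[-1] - sd[-1]
    ok = np.nonzero(mean >= threshold)[0]
    selected_F = F_grid[int(ok[0])] if ok.size else F_grid[-1]
    return {
        "F_grid": list(F_grid),
        "mean": mean,
        "sd": sd,
        "scores": scores,
        "selected_F": selected_F,
        "frequencies": {F: np.array(v) for F, v in freqs.items()},
        "threshold": float(threshold),
    }
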