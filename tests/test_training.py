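"""Window sampling, optimization loop, Monte-Carlo CV and the corrected t-test."""

import numpy as np
import pytest

from spdwave import (
    ArchitectureConfig,
    build_model,
    corrected_t_test,
    monte_carlo_cv,
    sample_windows,
    sample_windows_batch,
    train,
)
from spdwave.simulate import GenerativeConfig, SourceSpec, simulate_dataset
from spdwave.training import DEFAULT_E, DEFAULT_T, TrainConfig


class TestSampleWindows:
    def test_default_protocol_is_ten_windows_of_ten_seconds(self):
        assert DEFAULT_E == 10
        assert DEFAULT_T == 10.0

    def test_shapes_and_determinism(self, rng):
        rec = rng.standard_normal((3, 2000))
        a = sample_windows(rec, E=4, T=2.0, fs=125.0, seed=5)
        b = sample_windows(rec, E=4, T=2.0, fs=125.0, seed=5)
        assert a.values.shape == (4, 3, 250)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_recording_gives_identical_windows(self, rng):
        rec = rng.standard_normal((2, 250))
        out = sample_windows(rec, E=3, T=2.0, fs=125.0, seed=0)
        assert np.array_equal(out.values[0], rec)
        assert np.array_equal(out.values[1], rec)

    def test_too_short_recording_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            sample_windows(rng.standard_normal((2, 100)), E=2, T=2.0, fs=125.0)

    def test_batch_draws_are_per_subject_deterministic(self, rng):
        recs = rng.standard_normal((4, 2, 1000))
        full = sample_windows_batch(recs, E=2, T=2.0, fs=125.0, seed=1)
        sub = sample_windows_batch(recs[:2], E=2, T=2.0, fs=125.0, seed=1)
        assert np.array_equal(full[:2], sub)


class TestCorrectedTTest:
    def test_all_zero_differences(self):
        t, p = corrected_t_test(np.zeros(10), 80, 20)
        assert t == 0.0 and p == 1.0

    def test_matches_hand_coded_formula(self):
        diffs = np.array([0.1, 0.2, 0.1, 0.2])
        K = 4
        m = diffs.mean()
        s2 = diffs.var(ddof=1)
        oracle_t = m / np.sqrt((1 / K + 20 / 80) * s2)
        t, p = corrected_t_test(diffs, 80, 20)
        assert t == pytest.approx(oracle_t, abs=1e-12)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(oracle_t), df=3), abs=1e-12)

    def test_vanishing_test_fraction_recovers_standard_t(self, rng):
        diffs = rng.standard_normal(20) + 0.3
        t_corr, _ = corrected_t_test(diffs, n_train=10**9, n_test=1)
        from scipy import stats

        t_std, _ = stats.ttest_1samp(diffs, 0.0)
        assert t_corr == pytest.approx(t_std, rel=1e-3)

    def test_zero_variance_nonzero_mean_warns_infinite(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = corrected_t_test(np.full(5, 0.2), 80, 20)
        assert np.isinf(t) and p == 0.0

    def test_single_split_rejected(self):
        with pytest.raises(ValueError):
            corrected_t_test(np.array([0.1]), 80, 20)


class _ConstantModel:
    """Predicts the training mean; scores R^2 <= 0 on any split."""

    def fit(self, recs, y):
        self.mean = float(np.mean(y))
        return self

    def predict(self, recs):
        return np.full(recs.shape[0], self.mean)


class _LogPowerRidge:
    """Cheap honest model: ridge on log channel variances of seeded windows."""

    def __init__(self, seed=0, task="regression"):
        self.seed = seed
        self.task = task

    def _feats(self, recs):
        rng = np.random.default_rng(self.seed)
        # window-subsampled log power per channel
        n = recs.shape[-1]
        w = n // 2
        starts = rng.integers(0, n - w + 1, size=2)
        segs = np.stack([recs[..., s : s + w] for s in starts], axis=1)
        return np.log(segs.var(axis=-1) + 1e-12).reshape(recs.shape[0], -1)

    def fit(self, recs, y):
        from sklearn.linear_model import Ridge, RidgeClassifier

        cls = Ridge if self.task == "regression" else RidgeClassifier
        self.model = cls(alpha=1.0).fit(self._feats(recs), y)
        return self

    def predict(self, recs):
        return self.model.predict(self._feats(recs))


def quick_regression_dataset(n=30, seed=0):
    cfg = GenerativeConfig(
        n_subjects=n,
        n_channels=3,
        duration=4.0,
        fs=64.0,
        sources=[SourceSpec(center=8.0, bandwidth=2.0, log_power_sd=1.0)],
        outcome_noise_sd=0.1,
        seed=seed,
    )
    return simulate_dataset(cfg)


class TestMonteCarloCV:
    def test_constant_model_never_beats_r2_zero(self):
        ds = quick_regression_dataset()
        res = monte_carlo_cv(
            {"const": lambda s: _ConstantModel()},
            ds.recordings, ds.outcomes, K=5, seed=0,
        )
        assert (res.scores["score"] <= 0).all()

    def test_identical_factories_have_zero_differences(self):
        ds = quick_regression_dataset()
        res = monte_carlo_cv(
            {
                "a": lambda s: _LogPowerRidge(seed=7),
                "b": lambda s: _LogPowerRidge(seed=7),
            },
            ds.recordings, ds.outcomes, K=4, seed=1,
        )
        mat = res.score_matrix()
        assert np.allclose(mat["a"], mat["b"])
        t, p = res.compare("a", "b")
        assert t == 0.0 and p == 1.0

    def test_split_sizes_follow_protocol(self):
        ds = quick_regression_dataset(n=30)
        res = monte_carlo_cv(
            {"m": lambda s: _ConstantModel()},
            ds.recordings, ds.outcomes, K=3, test_frac=0.2, seed=0,
        )
        assert res.n_test == 6 and res.n_train == 24
        for tr, te in res.splits:
            assert len(set(tr) & set(te)) == 0

    def test_class_resampling_keeps_all_classes(self, rng):
        recs = rng.standard_normal((12, 2, 200))
        y = np.r_[np.zeros(11), np.ones(1)]  # nearly-degenerate class
        with pytest.warns(UserWarning, match="redrawing"):
            res = monte_carlo_cv(
                {"m": lambda s: _LogPowerRidge(task="classification")},
                recs, y, K=8, seed=0, task="classification",
            )
        for tr, _ in res.splits:
            assert len(np.unique(y[tr])) == 2


class TestWaveletProfile:
    def test_selection_rule_picks_smallest_sufficient_size(self, rng):
        # stub estimators with known score profile: F>=2 is as good as F=15
        from spdwave import wavelet_profile

        class Stub:
            def __init__(self, F, s):
                self.F, self.rng = F, np.random.default_rng(s)

            def fit(self, recs, y):
                return self

            def predict(self, recs):
                # the true label is readable from the first sample; small
                # banks only get it right half the time
                truth = (recs[:, 0, 0] > 0).astype(float)
                level = 0.5 if self.F < 2 else 0.9 + self.rng.normal(0, 0.02)
                flip = self.rng.random(len(truth)) > level
                return np.where(flip, 1 - truth, truth)

        recs = rng.standard_normal((40, 2, 100))
        y = (recs[:, 0, 0] > 0).astype(float)
        out = wavelet_profile(
            lambda F, s: Stub(F, s), recs, y,
            F_grid=(1, 2, 3, 15), reps=3, seed=0, task="classification",
        )
        assert out["selected_F"] == 2
        assert len(out["F_grid"]) == 4
        assert out["scores"].shape == (4, 3)


@pytest.fixture(scope="module")
def tiny_task():
    cfg = GenerativeConfig(
        n_subjects=24,
        n_channels=3,
        duration=6.0,
        fs=64.0,
        sources=[SourceSpec(center=8.0, bandwidth=2.0, log_power_sd=1.0)],
        outcome_noise_sd=0.1,
        background_sd=0.2,
        seed=3,
    )
    return simulate_dataset(cfg)


class TestTrainLoop:
    def test_loss_decreases_on_synthetic_regression(self, tiny_task):
        arch = ArchitectureConfig.from_variant(
            "G3", n_wavelets=2, f_min=4.0, f_max=16.0
        )
        model = build_model(arch, 3, 64.0, seed=0)
        hist = train(
            model, tiny_task.recordings, tiny_task.outcomes,
            TrainConfig(epochs=20, batch_size=8, E=2, T=2.0, seed=0),
        )
        # windows are redrawn every epoch, so individual epochs are noisy;
        # the late-phase loss should still sit below the starting loss
        assert min(hist["train_loss"][-5:]) <= hist["train_loss"][0]
        assert model.trained

    def test_frozen_wavelets_stay_bit_identical(self, tiny_task):
        arch = ArchitectureConfig.from_variant(
            "G1", n_wavelets=4, f_min=4.0, f_max=16.0
        )
        model = build_model(arch, 3, 64.0, seed=0)
        f0 = model.bank.log_f.data.copy()
        s0 = model.bank.log_sigma.data.copy()
        train(
            model, tiny_task.recordings, tiny_task.outcomes,
            TrainConfig(epochs=5, batch_size=8, E=2, T=2.0, seed=0),
        )
        assert np.array_equal(model.bank.log_f.data, f0)
        assert np.array_equal(model.bank.log_sigma.data, s0)

    def test_shrinkage_moves_up_on_rank_deficient_features(self, rng):
        # gradient direction: on rank-deficient covariances the rectified
        # eigenvalue floor is active and shrinkage raising small eigenvalues
        # reduces the loss noise floor -> alpha should increase from ~0
        from spdwave.autodiff import Tensor
        from spdwave import nn as N

        C, rank, B = 6, 3, 16
        A = rng.standard_normal((B, C, rank))
        X = A @ np.swapaxes(A, -1, -2)
        y = rng.standard_normal(B)
        sh = N.Shrinkage(1, raw_init=-6.0)
        bm = N.BiMap(1, C - 1, C, rng=np.random.default_rng(0))
        lm = N.ReEigLogMap(1, C - 1)
        head = N.Linear((C - 1) * C // 2, 1, rng=np.random.default_rng(1))
        a0 = sh.alpha[0]
        opt = N.Adam([{ "params": [sh.raw_alpha] + bm.parameters() + head.parameters(), "lr": 1e-2 }])
        for _ in range(30):
            opt.zero_grad()
            out = head(lm(bm(sh(Tensor(X[:, None])))))
            loss = N.mse_loss(out, y)
            loss.backward()
            opt.step()
        assert sh.alpha[0] > a0

    def test_same_seed_reproduces_metrics_exactly(self, tiny_task):
        arch = ArchitectureConfig.from_variant(
            "G3", n_wavelets=2, f_min=4.0, f_max=16.0
        )
        outs = []
        for _ in range(2):
            model = build_model(arch, 3, 64.0, seed=4)
            hist = train(
                model, tiny_task.recordings, tiny_task.outcomes,
                TrainConfig(epochs=6, batch_size=8, E=2, T=2.0, seed=4),
            )
            outs.append((hist["train_loss"], model.bank.frequencies.copy()))
        assert outs[0][0] == outs[1][0]
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_divergence_aborts_with_diagnostic(self, tiny_task):
        arch = ArchitectureConfig.from_variant(
            "G3", n_wavelets=2, f_min=4.0, f_max=16.0
        )
        model = build_model(arch, 3, 64.0, seed=0)
        bad = tiny_task.outcomes.copy()
        bad[0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(
                model, tiny_task.recordings, bad,
                TrainConfig(epochs=2, batch_size=8, E=2, T=2.0, seed=0),
            )
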