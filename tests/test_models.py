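"""Variant assembly, forward-pass invariants, interpretation, baseline."""

import numpy as np
import pytest

from spdwave import ArchitectureConfig, build_model, extract_interpretables
from spdwave.models import RIDGE_ALPHAS, FilterBankRidge
from spdwave.pooling import pool_features
from spdwave.wavelets import fft_conv_valid

FS = 250.0


def tiny_windows(rng, B=4, E=2, C=4, T=400):
    return rng.standard_normal((B, E, C, T))


class TestArchitectureConfig:
    def test_g1_mirrors_the_non_deep_pipeline(self):
        cfg = ArchitectureConfig.from_variant("G1")
        assert not cfg.trainable_wavelets
        assert cfg.hidden == ()
        assert cfg.layout == "per_frequency"
        assert cfg.feature_kinds == ("covariance",)

    def test_g3_is_fully_trainable_with_joint_layout(self):
        cfg = ArchitectureConfig.from_variant("G3")
        assert cfg.trainable_wavelets
        assert cfg.layout == "joint"
        assert cfg.bimap_dims == (64, 32)
        assert cfg.hidden == (64, 32)
        assert cfg.n_wavelets == 10

    def test_plv_variants_add_plv_kind(self):
        assert "plv" in ArchitectureConfig.from_variant("G1P").feature_kinds
        assert "plv" in ArchitectureConfig.from_variant("G3P").feature_kinds

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(variant="G9")

    def test_dict_roundtrip(self):
        cfg = ArchitectureConfig.from_variant("G3P", task="classification")
        back = ArchitectureConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestBuildModel:
    def test_g1_bimap_output_is_channels_minus_one(self):
        cfg = ArchitectureConfig.from_variant("G1", n_wavelets=10)
        m = build_model(cfg, n_channels=21, fs=FS)
        branch = m.branches[0]
        assert branch.bimaps[0].W.data.shape == (10, 20, 21)
        assert len(m.head.blocks) == 0  # linear readout only

    def test_g3_joint_dims_follow_f_times_c(self):
        cfg = ArchitectureConfig.from_variant("G3")
        m = build_model(cfg, n_channels=21, fs=FS)
        (bm1, bm2) = m.branches[0].bimaps
        assert bm1.W.data.shape == (1, 64, 210)
        assert bm2.W.data.shape == (1, 32, 64)

    def test_g2_adds_exactly_one_hidden_block(self):
        F = 10
        g1 = build_model(
            ArchitectureConfig.from_variant("G1", n_wavelets=F), 21, FS
        )
        g2 = build_model(
            ArchitectureConfig.from_variant("G2", n_wavelets=F), 21, FS
        )
        tangent = F * (20 * 21 // 2)
        # hidden Linear(tangent->32)+BN(32), readout 32->1 replaces tangent->1
        expected_extra = (tangent * 32 + 32) + 2 * 32 + (32 + 1) - (tangent + 1)
        assert g2.n_parameters - g1.n_parameters == expected_extra

    def test_all_variants_under_1e5_parameters_at_f10_c21(self):
        for variant in ("G1", "G1P", "G2", "G3", "G3P", "G3FB"):
            cfg = ArchitectureConfig.from_variant(variant, n_wavelets=10)
            m = build_model(cfg, n_channels=21, fs=FS)
            assert m.n_parameters < 100_000, variant

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            build_model(ArchitectureConfig.from_variant("G3"), 1, FS)


class TestForward:
    @pytest.fixture
    def small_model(self):
        cfg = ArchitectureConfig.from_variant(
            "G3", task="regression", n_wavelets=2, f_min=4.0, f_max=20.0,
        )
        return build_model(cfg, n_channels=4, fs=125.0, seed=0)

    def test_eval_forward_is_deterministic(self, small_model, rng):
        x = tiny_windows(rng)
        small_model.forward(x)  # initialize running reference (train mode)
        small_model.eval()
        a = small_model.forward(x).data
        b = small_model.forward(x).data
        assert np.array_equal(a, b)

    def test_window_permutation_invariance(self, small_model, rng):
        x = tiny_windows(rng, E=4)
        small_model.forward(x)
        small_model.eval()
        a = small_model.forward(x).data
        b = small_model.forward(x[:, ::-1]).data
        assert np.allclose(a, b, atol=1e-10)

    def test_input_scaling_squares_band_power(self, small_model, rng):
        x = tiny_windows(rng)
        f1 = small_model.pooled_features(x)[0].data
        f10 = small_model.pooled_features(10.0 * x)[0].data
        idx = np.arange(f1.shape[-1])
        assert np.allclose(
            f10[..., idx, idx], 100.0 * f1[..., idx, idx], rtol=1e-10
        )

    def test_channel_mismatch_rejected(self, small_model, rng):
        with pytest.raises(ValueError):
            small_model.forward(tiny_windows(rng, C=5))

    def test_checkpoint_roundtrip_bit_exact(self, small_model, rng, tmp_path):
        from spdwave.io import load_checkpoint, save_checkpoint

        x = tiny_windows(rng)
        small_model.forward(x)
        small_model.eval()
        ref = small_model.forward(x).data
        save_checkpoint(small_model, tmp_path / "m.h5")
        clone = load_checkpoint(tmp_path / "m.h5")
        assert np.array_equal(clone.forward(x).data, ref)


class TestInterpretables:
    def test_sigma_f_follows_uncertainty_relation(self, rng):
        cfg = ArchitectureConfig.from_variant("G3", n_wavelets=2, f_min=4, f_max=20)
        m = build_model(cfg, 4, 125.0)
        m.bank.log_sigma.data[:] = np.log([0.1, 0.05])
        with pytest.warns(UserWarning, match="not been trained"):
            info = extract_interpretables(m, tiny_windows(rng))
        assert info["sigma_f"][0] == pytest.approx(1 / (2 * np.pi * 0.1))
        assert info["sigma_f"][1] == pytest.approx(1 / (2 * np.pi * 0.05))

    def test_identical_conditions_give_zero_db(self, rng):
        cfg = ArchitectureConfig.from_variant("G3", n_wavelets=2, f_min=4, f_max=20)
        m = build_model(cfg, 4, 125.0)
        m.trained = True
        x = tiny_windows(rng, B=6)
        x = np.concatenate([x, x])  # class 0 and class 1 identical
        cond = np.r_[np.zeros(6), np.ones(6)]
        info = extract_interpretables(m, x, conditions=cond)
        assert np.allclose(info["power_ratio_db"], 0.0, atol=1e-10)


class TestBaseline:
    def test_penalty_grid_matches_gcv_protocol(self):
        assert len(RIDGE_ALPHAS) == 100
        assert RIDGE_ALPHAS[0] == pytest.approx(1e-5)
        assert RIDGE_ALPHAS[-1] == pytest.approx(1e5)

    def test_bank_has_49_wavelets_spanning_1_to_64(self):
        model = FilterBankRidge(fs=256.0)
        assert model.bank.n_wavelets == 49
        assert model.bank.frequencies[0] == pytest.approx(1.0)
        assert model.bank.frequencies[-1] == pytest.approx(64.0)

    def test_fit_predict_on_trivial_signal(self, rng):
        # band power of a single source drives y; tiny sanity fit
        fs = 64.0
        n = 24
        t = np.arange(int(6 * fs)) / fs
        amp = np.exp(rng.normal(0, 0.5, n))
        recs = np.stack(
            [
                a * np.sin(2 * np.pi * 8 * t + rng.uniform(0, 6))
                + 0.1 * rng.standard_normal(t.size)
                for a in amp
            ]
        )[:, None, :]
        recs = np.repeat(recs, 2, axis=1)  # 2 channels
        windows = recs[:, None, :, : int(4 * fs)]
        y = 2 * np.log(amp)
        from spdwave import baseline_predict

        with pytest.warns(UserWarning, match="rank deficient"):
            pred = baseline_predict(
                windows[: n // 2], y[: n // 2], windows[n // 2 :],
                fs=fs, f_min=2.0, f_max=16.0, resolution=2,
            )
        r = np.corrcoef(pred, y[n // 2 :])[0, 1]
        assert r > 0.9

    def test_too_few_samples_rejected(self, rng):
        model = FilterBankRidge(fs=64.0, f_min=2.0, f_max=8.0, resolution=1)
        with pytest.raises(ValueError):
            model.fit(rng.standard_normal((1, 1, 2, 256)), np.array([1.0]))


class TestRankRepair:
    def test_pipeline_repairs_rank_deficient_covariances(self, rng):
        # pooling + shrinkage + BiMap on rank-deficient inputs gives PD output
        from spdwave.autodiff import Tensor
        from spdwave import nn as _nn  # noqa: F401

        from spdwave.nn import BiMap, Shrinkage

        C, rank = 8, 5
        fails = 0
        for _ in range(20):
            A = rng.standard_normal((C, rank))
            X = (A @ A.T)[None, None]  # rank C-3
            sh = Shrinkage(1, raw_init=-2.0)
            bm = BiMap(1, C - 1, C, rng=np.random.default_rng(1))
            out = bm(sh(Tensor(X))).data[0, 0]
            if np.linalg.eigvalsh(out).min() <= 0:
                fails += 1
        assert fails == 0
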