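# spdwave

Learnable Gabor wavelet filter banks with SPD-manifold layers for
predicting biomedical outcomes from multichannel EEG.

## The problem

Outcome-relevant EEG structure lives in band-limited oscillatory power and
phase coupling, but volume conduction mixes cortical sources linearly across
all scalp electrodes, so sensor-space power does not reflect source power.
Two established remedies are (i) filter-bank covariance features embedded in
the tangent space of the SPD manifold, fed to regularized linear models, and
(ii) end-to-end deep networks on raw EEG.  The first is robust and
interpretable but relies on a fixed, handcrafted filter bank; the second
learns its own features but at high parameter cost and with little contact
with neuroscience concepts.

`spdwave` implements a lightweight middle path: a neural network whose first
layer is a *parametrized* complex Gabor wavelet filter bank (two parameters
per wavelet — center frequency `f` and envelope width `σ_t`), whose pooling
layer computes covariance and phase-locking matrices, and whose geometric
layers (trainable Ledoit-Wolf-style shrinkage, BiMap `W X Wᵀ`, eigenvalue
rectification, log-Euclidean tangent projection about a running mean
reference) operate on the SPD manifold before a small fully connected head.
The whole pipeline is differentiable, so the filter bank itself is learned
from the prediction objective, and every intermediate quantity (band-power
topographies, spectral widths, power ratios) has a name in the EEG
literature.

The package also provides the matching non-deep baseline (Morlet-49
covariances → PCA subspace → tangent ridge with GCV), a synthetic-data
generator with known ground truth (linearly mixed band-limited sources whose
log power drives the outcome), Monte-Carlo cross-validation, and the
Nadeau–Bengio corrected resampled t-test
`t = m / sqrt((1/K + n_test/n_train) σ̂²)` for paired model comparison.

## Worked example

Train the two-wavelet trainable-bank variant on a synthetic Berger-effect
task (class 1 has the log power of a 10 Hz occipital source shifted by 1.0;
two spatially collinear distractor rhythms at 6 and 16 Hz make spectral
localization necessary):

```python
import numpy as np
from spdwave import (ArchitectureConfig, TrainConfig, build_model,
                     extract_interpretables, make_alpha_task,
                     sample_windows_batch, train)

ds = make_alpha_task(n_subjects=80, duration=30.0, seed=7)
cfg = ArchitectureConfig.from_variant(
    "G3", task="classification", n_wavelets=2,
    init="random", n_cycles=2.0, f_min=3.0, f_max=40.0,
)
model = build_model(cfg, n_channels=8, fs=ds.fs, seed=0)
print(f"initial frequencies (Hz): {np.round(model.bank.frequencies, 2)}")

train(model, ds.recordings, ds.outcomes,
      TrainConfig(epochs=80, batch_size=32, lr_wavelets=5e-2, lr_sigma=5e-2,
                  E=5, T=4.0, seed=0, restore_best=False))

windows = sample_windows_batch(ds.recordings, E=5, T=4.0, fs=ds.fs, seed=1)
info = extract_interpretables(model, windows, conditions=ds.outcomes)
print(f"learned frequencies (Hz): {np.round(info['frequencies'], 2)}")
print(f"spectral widths (Hz):     {np.round(info['sigma_f'], 2)}")
print(f"class power ratio (dB):   {np.round(info['power_ratio_db'], 2)}")
```

Output:

```
initial frequencies (Hz): [ 6.03 15.62]
learned frequencies (Hz): [10.67 13.17]
spectral widths (Hz):     [1.62 3.47]
class power ratio (dB):   [3.55 1.44]
```

One wavelet migrated from its random 6 Hz start into the alpha band and
narrowed its passband (σ_f 1.62 Hz — tighter than the constant-cycles
convention would place it); the between-class band-power ratio peaks at
that wavelet (+3.6 dB), i.e. the trained model's own forward pass exposes
the simulated physiology.

## Command line

```sh
spdwave simulate --out data/demo --task alpha --seed 1
spdwave train    --data data/demo --out runs/g3 --variant G3 --task classification
spdwave evaluate --data data/demo --out runs/cv --variants baseline,G1 --splits 100
spdwave compare  --cv-a runs/cv/cv_scores.csv --model-a baseline --model-b G1 \
                 --n-train 160 --n-test 40
spdwave inspect  --checkpoint runs/g3/G3.h5 --data data/demo --out runs/inspect
```

Every command echoes its effective configuration (including implicit
defaults) to a JSON log in the output directory.

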