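"""Parametrized complex Gabor wavelet filter banks.

A Gabor wavelet is a complex sinusoid of center frequency ``f`` modulated by
a Gaussian envelope of temporal standard deviation ``sigma_t``::

    phi_f(t) = 1/(sqrt(2*pi)*sigma_t) * exp(-t^2/(2*sigma_t^2)) * exp(2i*pi*f*t)

Applied as a convolution kernel it acts as a band-pass filter centered on
``f`` with frequency-domain standard deviation ``sigma_f = 1/(2*pi*sigma_t)``
(the Gabor uncertainty relation).  Banks with the classical Morlet
parametrization keep the number of cycles under the envelope constant, i.e.
``sigma_t`` proportional to ``1/f``, which gives physiologically sensible
spectral smoothing on the 1/f-dominated EEG spectrum.

All wavelets in a bank share one discrete support length so that the
transformed signals of every frequency have identical length, which in turn
allows the pooling stage to form cross-frequency covariance blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .autodiff import Tensor

__all__ = [
    "EpochTensor",
    "WaveletBank",
    "gabor_kernel",
    "morlet_init",
    "wavelet_transform",
    "sigma_t_from_frequency",
    "default_kernel_len",
]

#: truncation half-width of the kernel support, in units of sigma_t.  Three
#: standard deviations keep 99.7% of the Gaussian mass while letting the
#: default 1-64 Hz bank (sigma_t up to ~1.1 s) fit inside 10-s windows.
KERNEL_SD = 3.0

#: constant-cycles rule for Morlet initialization: sigma_t = n_cycles/(2 pi f)
N_CYCLES = 7.0

#: hard clamp window for trainable center frequencies, as fraction of fs
F_MIN_HZ = 0.1
F_MAX_FRAC = 0.45

#: floor for trainable temporal widths (seconds)
SIGMA_T_FLOOR = 3e-3


@dataclass
class EpochTensor:
    """A stack of ``E`` windows of multichannel signal.

    ``values`` has shape ``(E, C, T_s)`` (windows x channels x samples) or
    ``(B, E, C, T_s)`` for a batch of samples.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (3, 4):
            raise ValueError("EpochTensor expects (E, C, T) or (B, E, C, T)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[-2]


def sigma_t_from_frequency(f: np.ndarray | float, n_cycles: float = N_CYCLES):
    """Constant-cycles temporal width: ``sigma_t = n_cycles / (2 pi f)``.

    Implies ``sigma_t(2f)/sigma_t(f) = 1/2`` — log-linear decrease with slope
    -1, the classical Morlet convention.
    """
    return n_cycles / (2.0 * np.pi * np.asarray(f, dtype=float))


def default_kernel_len(sigma_t_max: float, fs: float, k_sd: float = KERNEL_SD) -> int:
    """Odd common support length covering ``k_sd`` standard deviations."""
    return 2 * int(np.ceil(k_sd * sigma_t_max * fs)) + 1


def gabor_kernel(f: float, sigma_t: float, fs: float, kernel_len: int) -> np.ndarray:
    """Sample one complex Gabor wavelet on a symmetric grid.

    Returns ``phi_f(t)`` at ``t = k/fs`` for ``k = -(L-1)/2 .. (L-1)/2``.
    The envelope carries the normalized-Gaussian prefactor
    ``1/(sqrt(2 pi) sigma_t)``; no extra unit-energy rescaling is applied.
    """
    if f <= 0 or sigma_t <= 0:
        raise ValueError("f and sigma_t must be strictly positive")
    if fs <= 0 or kernel_len <= 0:
        raise ValueError("fs and kernel_len must be positive")
    if kernel_len % 2 == 0:
        raise ValueError("kernel_len must be odd (symmetric support)")
    half = (kernel_len - 1) // 2
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2)) / (np.sqrt(2.0 * np.pi) * sigma_t)
    return envelope * np.exp(2j * np.pi * f * t)


class WaveletBank:
    """Ordered bank of ``F`` Gabor wavelets with one shared support length.

    Center frequencies and temporal widths are stored as trainable log
    parameters (positivity by construction).  Frequencies are clamped to
    ``[0.1 Hz, 0.45 fs]`` after every optimizer step; widths are floored.
    """

    def __init__(
        self,
        frequencies: np.ndarray,
        sigma_ts: np.ndarray,
        fs: float,
        kernel_len: int | None = None,
        trainable: bool = False,
    ):
        frequencies = np.atleast_1d(np.asarray(frequencies, dtype=float))
        sigma_ts = np.atleast_1d(np.asarray(sigma_ts, dtype=float))
        if frequencies.size != sigma_ts.size or frequencies.size < 1:
            raise ValueError("need one sigma_t per frequency, at least one wavelet")
        if np.any(frequencies <= 0) or np.any(sigma_ts <= 0):
            raise ValueError("frequencies and sigma_t must be strictly positive")
        if np.any(frequencies >= fs / 2):
            raise ValueError("center frequencies must lie below the Nyquist frequency")
        if kernel_len is None:
            kernel_len = default_kernel_len(float(sigma_ts.max()), fs)
        if kernel_len % 2 == 0 or kernel_len <= 0:
            raise ValueError("kernel_len must be odd and positive")
        self.fs = float(fs)
        self.kernel_len = int(kernel_len)
        self.trainable = bool(trainable)
        self.log_f = Tensor(np.log(frequencies), requires_grad=trainable)
        self.log_sigma = Tensor(np.log(sigma_ts), requires_grad=trainable)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_wavelets(self) -> int:
        return self.log_f.data.size

    @property
    def frequencies(self) -> np.ndarray:
        return np.exp(self.log_f.data)

    @property
    def sigma_ts(self) -> np.ndarray:
        return np.exp(self.log_sigma.data)

    @property
    def sigma_fs(self) -> np.ndarray:
        """Frequency-domain widths via the Gabor uncertainty relation."""
        return 1.0 / (2.0 * np.pi * self.sigma_ts)

    def parameters(self):
        return [self.log_f, self.log_sigma] if self.trainable else []

    def clamp_(self) -> None:
        """Project parameters back into their admissible box (post-step)."""
        np.clip(
            self.log_f.data,
            np.log(F_MIN_HZ),
            np.log(F_MAX_FRAC * self.fs),
            out=self.log_f.data,
        )
        half_support = (self.kernel_len - 1) / (2.0 * self.fs)
        np.clip(
            self.log_sigma.data,
            np.log(SIGMA_T_FLOOR),
            np.log(half_support / 2.0),
            out=self.log_sigma.data,
        )

    # -- kernels -----------------------------------------------------------
    def _time_grid(self) -> np.ndarray:
        half = (self.kernel_len - 1) // 2
        return np.arange(-half, half + 1) / self.fs

    def kernel_tensors(self) -> tuple[Tensor, Tensor]:
        """Differentiable (real, imaginary) kernels, shape ``(F, L)`` each."""
        t = Tensor(self._time_grid()[None, :])  # (1, L) constant
        f = self.log_f.exp().reshape(-1, 1)
        sigma = self.log_sigma.exp().reshape(-1, 1)
        env = (-(t * t) / (2.0 * sigma * sigma)).exp() / (
            sigma * np.sqrt(2.0 * np.pi)
        )
        phase = 2.0 * np.pi * f * t
        return env * phase.cos(), env * phase.sin()

    def kernels(self) -> np.ndarray:
        """Complex kernel array of shape ``(F, L)``."""
        kr, ki = self.kernel_tensors()
        return kr.data + 1j * ki.data

    def state(self) -> dict:
        return {
            "frequencies": self.frequencies,
            "sigma_ts": self.sigma_ts,
            "fs": self.fs,
            "kernel_len": self.kernel_len,
            "trainable": self.trainable,
        }


def morlet_init(
    f_min: float,
    f_max: float,
    resolution: int,
    fs: float,
    n_cycles: float = N_CYCLES,
    kernel_len: int | None = None,
    trainable: bool = False,
) -> WaveletBank:
    """Morlet-style bank: base-2 log-spaced frequencies, constant cycles.

    ``resolution`` is the number of wavelets per octave; the grid runs from
    ``f_min`` to ``f_max`` inclusive.  The default 1-64 Hz bank at resolution
    8 has 6 octaves * 8 + 1 = 49 wavelets.
    """
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if f_max >= fs / 2:
        raise ValueError("f_max must lie below the Nyquist frequency")
    n_octaves = np.log2(f_max / f_min)
    n_steps = int(round(n_octaves * resolution))
    if not np.isclose(n_steps / resolution, n_octaves):
        n_steps = int(np.ceil(n_octaves * resolution))
    freqs = f_min * 2.0 ** (np.arange(n_steps + 1) / resolution)
    freqs[-1] = min(freqs[-1], f_max)
    sigmas = sigma_t_from_frequency(freqs, n_cycles)
    return WaveletBank(freqs, sigmas, fs, kernel_len=kernel_len, trainable=trainable)


# -- convolution front-end -------------------------------------------------

def _check_lengths(n_samples: int, kernel_len: int) -> None:
    if kernel_len > n_samples:
        raise ValueError(
            f"kernel ({kernel_len} samples) longer than window ({n_samples}); "
            "use longer windows or a shorter kernel support"
        )


def fft_conv_valid(x: np.ndarray, kr: Tensor, ki: Tensor) -> tuple[Tensor, Tensor]:
    """Valid-mode convolution of real signals with a complex kernel bank.

    ``x`` has shape ``(..., C, T_s)`` and is treated as constant data; the
    kernels ``(F, L)`` are differentiable.  Returns real and imaginary parts
    of shape ``(..., F, C, T_s - L + 1)``.  Linear convolution is carried out
    in the frequency domain; the gradient with respect to each kernel is the
    cross-correlation of the input with the upstream gradient, accumulated in
    the frequency domain so only ``F`` inverse transforms are needed.
    """
    x = np.asarray(x, dtype=np.float64)
    F, L = kr.data.shape
    Ts = x.shape[-1]
    _check_lengths(Ts, L)
    nfft = sfft.next_fast_len(Ts + L - 1)
    xhat = sfft.rfft(x, nfft, axis=-1)  # (..., C, nf)
    xhat_b = xhat[..., None, :, :]  # (..., 1, C, nf)
    valid = slice(L - 1, Ts)
    batch_axes = tuple(range(x.ndim - 2)) + (x.ndim - 1,)  # all but F in output

    def _forward(k: Tensor) -> Tensor:
        khat = sfft.rfft(k.data, nfft, axis=-1)  # (F, nf)
        yfull = sfft.irfft(xhat_b * khat[:, None, :], nfft, axis=-1)
        y = np.ascontiguousarray(yfull[..., valid])

        def bw(g, k=k):
            ghat = sfft.rfft(np.concatenate(
                [np.zeros(g.shape[:-1] + (L - 1,)), g], axis=-1
            ), nfft, axis=-1)
            dkhat = np.sum(ghat * np.conj(xhat_b), axis=batch_axes)
            k.accumulate(sfft.irfft(dkhat, nfft, axis=-1)[:, :L])

        return Tensor._op(y, (k,), bw)

    return _forward(kr), _forward(ki)


def wavelet_transform(x: EpochTensor | np.ndarray, bank: WaveletBank) -> np.ndarray:
    """Apply the bank to windowed signal; returns complex coefficients.

    Output shape ``(..., F, C, T_s - L + 1)``: valid-mode convolution trims
    ``(L-1)/2`` samples from each edge so every frequency yields the same
    length and covariance estimates see no zero-padding transients.
    """
    values = x.values if isinstance(x, EpochTensor) else np.asarray(x, float)
    if isinstance(x, EpochTensor) and abs(x.fs - bank.fs) > 1e-9:
        raise ValueError("sampling rate of input and bank differ")
    kr, ki = bank.kernel_tensors()
    yr, yi = fft_conv_valid(values, kr.detach(), ki.detach())
    return yr.data + 1j * yi.data
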