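"""Mel-frequency cepstral coefficients.

Standard MFCC pipeline: pre-emphasis, fixed-length Hamming-windowed frames,
periodogram power spectrum, HTK-style mel filterbank (mel = 2595 *
log10(1 + f/700)), log energies, and an orthonormal DCT-II over the filter
axis.  Parameters follow the common speech defaults (13 coefficients, 25 ms
frames, 10 ms hop) and are all overridable.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: float,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape ``(n_filters, n_fft // 2 + 1)``."""
    if fmax is None:
        fmax = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for j in range(n_filters):
        lo, mid, hi = bins[j], bins[j + 1], bins[j + 2]
        for k in range(lo, mid):
            if mid > lo:
                fb[j, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fb[j, k] = (hi - k) / (hi - mid)
    return fb


def mfcc(
    signal: np.ndarray,
    sample_rate: float,
    n_mfcc: int = 13,
    frame_len_s: float = 0.025,
    hop_len_s: float = 0.010,
    n_filters: int = 26,
    preemphasis: float = 0.97,
    eps: float = 1e-10,
) -> np.ndarray:
    """MFCC matrix of shape ``(n_mfcc, n_frames)``.

    Raises if the signal is shorter than one analysis frame.
    """
    x = np.asarray(signal, dtype=float)
    flen = int(round(frame_len_s * sample_rate))
    hop = int(round(hop_len_s * sample_rate))
    if len(x) < flen:
        raise ValueError(f"signal of {len(x)} samples shorter than one {flen}-sample frame")
    if preemphasis:
        x = np.concatenate([[x[0]], x[1:] - preemphasis * x[:-1]])
    n_frames = 1 + (len(x) - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(flen)[None, :]
    n_fft = int(2 ** np.ceil(np.log2(flen)))
    power = np.abs(np.fft.rfft(frames, n_fft, axis=1)) ** 2 / n_fft
    fb = mel_filterbank(n_filters, n_fft, sample_rate)
    logmel = np.log(power @ fb.T + eps)
    coeffs = dct(logmel, type=2, norm="ortho", axis=1)[:, :n_mfcc]
    return coeffs.T
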