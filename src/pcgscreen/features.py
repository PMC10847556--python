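"""MFCC feature blocks for the murmur regressor.

Each four-cycle audio block becomes a 13 x 200 matrix: the first 13
Mel-frequency cepstral coefficients (c0..c12) of a Hann-windowed
spectrogram (35 ms window = 25 ms hop + 10 ms overlap), cubically
interpolated along time to exactly 200 columns, then standardized to zero
mean and unit standard deviation over the whole matrix.

Conventions the framing numbers do not pin down (filter count, mel scale,
log floor, keeping c0) are set here and exposed as parameters: 26
triangular HTK-mel filters spanning 0 to Nyquist, log floor 1e-10, c0 kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import dct, rfft
from scipy.interpolate import CubicSpline

N_MFCC = 13
N_TIME = 200
WINDOW_S = 0.035   # hop + overlap
HOP_S = 0.025
N_MEL_FILTERS = 26
LOG_FLOOR = 1e-10


@dataclass
class FeatureBlock:
    """Standardized 13 x 200 MFCC matrix with its provenance."""

    matrix: np.ndarray
    recording_id: str = ""
    block_index: int = 0


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@lru_cache(maxsize=8)
def _mel_filterbank(sample_rate_hz: int, n_fft: int, n_filters: int) -> np.ndarray:
    """Triangular mel filterbank, 0 to Nyquist, shape (n_filters, n_fft//2+1)."""
    ny = sample_rate_hz / 2.0
    mel_pts = np.linspace(0.0, float(_hz_to_mel(ny)), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / sample_rate_hz).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        for b in range(lo, mid):
            if mid > lo:
                fb[i, b] = (b - lo) / (mid - lo)
        for b in range(mid, hi):
            if hi > mid:
                fb[i, b] = (hi - b) / (hi - mid)
    return fb


def frame_count(n_samples: int, sample_rate_hz: int = 2205,
                window_s: float = WINDOW_S, hop_s: float = HOP_S) -> int:
    win = int(round(window_s * sample_rate_hz))
    hop = int(round(hop_s * sample_rate_hz))
    if n_samples < win:
        return 0
    return (n_samples - win) // hop + 1


def mfcc(samples, sample_rate_hz: int = 2205, n_mfcc: int = N_MFCC,
         window_s: float = WINDOW_S, hop_s: float = HOP_S,
         n_filters: int = N_MEL_FILTERS, keep_c0: bool = True) -> np.ndarray:
    """Mel-frequency cepstral coefficients, shape (n_mfcc, T)."""
    x = np.asarray(samples, dtype=float)
    win = int(round(window_s * sample_rate_hz))
    hop = int(round(hop_s * sample_rate_hz))
    t_frames = frame_count(x.size, sample_rate_hz, window_s, hop_s)
    if t_frames == 0:
        raise ValueError(
            f"block of {x.size} samples shorter than one {win}-sample analysis window")
    n_fft = 1 << (win - 1).bit_length()
    window = np.hanning(win)
    idx = hop * np.arange(t_frames)[:, None] + np.arange(win)[None, :]
    frames = x[idx] * window
    spec = np.abs(rfft(frames, n=n_fft, axis=1)) ** 2
    fb = _mel_filterbank(int(sample_rate_hz), n_fft, n_filters)
    energies = spec @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    cepstra = dct(log_e, type=2, norm="ortho", axis=1)
    start = 0 if keep_c0 else 1
    return cepstra[:, start:start + n_mfcc].T.copy()


def resize_and_standardize(matrix, n_time: int = N_TIME,
                           recording_id: str = "", block_index: int = 0) -> FeatureBlock:
    """Cubic time-axis interpolation to ``n_time`` columns, then whole-matrix
    standardization (subtract scalar mean, divide by scalar std)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least two time frames")
    t_in = m.shape[1]
    x_old = np.arange(t_in)
    x_new = np.linspace(0.0, t_in - 1.0, n_time)
    spline = CubicSpline(x_old, m, axis=1)  # not-a-knot ends
    resized = spline(x_new)
    sd = resized.std()
    if sd < 1e-12:
        raise ValueError("zero-variance feature matrix (degenerate block)")
    out = (resized - resized.mean()) / sd
    return FeatureBlock(out, recording_id, block_index)


def block_features(samples, blocks, sample_rate_hz: int = 2205,
                   recording_id: str = "", **mfcc_kwargs):
    """MFCC + resize for every extracted block of one recording."""
    out = []
    for blk in blocks:
        seg = np.asarray(samples)[blk.start_sample:blk.end_sample]
        mat = mfcc(seg, sample_rate_hz, **mfcc_kwargs)
        if mat.shape[1] < 2:
            continue
        out.append(resize_and_standardize(mat, recording_id=recording_id,
                                          block_index=blk.block_index))
    return out
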