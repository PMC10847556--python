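"""Audio conditioning: Schmidt-style spike removal and anti-aliased downsampling.

Spike removal partitions the signal into 500 ms windows and, while the
largest per-window maximum absolute amplitude (MAA) exceeds three times the
median MAA, zeroes the span around the offending sample out to the nearest
zero-crossings. Friction spikes from stethoscope handling are orders of
magnitude louder than heart sounds, so this removes them while leaving the
cardiac signal untouched.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import signal

WORKING_RATE_HZ = 2205
SPIKE_WINDOW_S = 0.5
SPIKE_MAA_FACTOR = 3.0


def _window_slices(n: int, win: int):
    # last partial window is kept
    return [slice(s, min(s + win, n)) for s in range(0, n, win)]


def remove_spikes(samples, sample_rate_hz: float) -> np.ndarray:
    """Remove friction spikes by iterative windowed amplitude clipping.

    Returns a new array of the same length; spans around offending samples
    are set to exactly zero.
    """
    x = np.asarray(samples, dtype=float).copy()
    if x.size == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    win = max(1, int(round(SPIKE_WINDOW_S * sample_rate_hz)))
    slices = _window_slices(x.size, win)
    max_iter = len(slices) * 10
    for _ in range(max_iter):
        maa = np.array([np.max(np.abs(x[sl])) for sl in slices])
        med = np.median(maa)
        k = int(np.argmax(maa))
        if maa[k] <= SPIKE_MAA_FACTOR * med:
            break
        sl = slices[k]
        seg = x[sl]
        p = int(np.argmax(np.abs(seg)))
        signs = np.sign(seg)
        # expand to nearest zero-crossings (or window edges) on both sides
        lo = p
        while lo > 0 and signs[lo - 1] * signs[p] > 0:
            lo -= 1
        hi = p
        while hi < seg.size - 1 and signs[hi + 1] * signs[p] > 0:
            hi += 1
        seg[lo:hi + 1] = 0.0
    return x


def downsample(samples, from_hz: float, to_hz: float = WORKING_RATE_HZ) -> np.ndarray:
    """Polyphase FIR rate conversion; identity when rates already match."""
    if from_hz < to_hz:
        raise ValueError(f"no upsampling path: from_hz={from_hz} < to_hz={to_hz}")
    x = np.asarray(samples, dtype=float)
    if from_hz == to_hz:
        return x.copy()
    frac = Fraction(to_hz).limit_denominator(10**6) / Fraction(from_hz).limit_denominator(10**6)
    up, down = frac.numerator, frac.denominator
    return signal.resample_poly(x, up, down)


def preprocess_recording(samples, sample_rate_hz: float, to_hz: float = WORKING_RATE_HZ) -> np.ndarray:
    """Spike removal at the native rate, then downsampling to the working rate."""
    x = remove_spikes(samples, sample_rate_hz)
    return downsample(x, sample_rate_hz, to_hz)


def window_maa(samples, sample_rate_hz: float) -> np.ndarray:
    """Per-window maximum absolute amplitude, for diagnostics and tests."""
    x = np.asarray(samples, dtype=float)
    win = max(1, int(round(SPIKE_WINDOW_S * sample_rate_hz)))
    return np.array([np.max(np.abs(x[sl])) for sl in _window_slices(x.size, win)])
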