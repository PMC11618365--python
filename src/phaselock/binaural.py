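"""Imposing and estimating interaural time and level differences.

Sign convention used throughout the package: positive ITD means the right
ear leads (the sound arrives at the right ear first), positive ILD means the
right ear is more intense. The mirror property holds exactly:
``impose_itd(w, -tau)`` equals ``impose_itd(w, +tau)`` with the ears swapped.

Whole-waveform ITDs are realized by a windowed-sinc fractional delay,
because 1 µs steps are sub-sample at audio rates of 20–50 kHz.
Fine-structure ITDs shift the carrier phase under a shared, undelayed
envelope, as required by tone-lateralization experiments in which only the
temporal fine structure carries the interaural delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate, hilbert

from .stimuli import Waveform

__all__ = ["BinauralWaveform", "impose_itd", "impose_ild", "estimate_itd", "fractional_delay"]


@dataclass
class BinauralWaveform:
    """A pair of calibrated waveforms, one per ear."""

    left: Waveform
    right: Waveform

    def __post_init__(self) -> None:
        if self.left.fs != self.right.fs:
            raise ValueError("ears must share a sampling rate")
        if self.left.n != self.right.n:
            raise ValueError("ears must share a length")

    @property
    def fs(self) -> float:
        return self.left.fs

    @property
    def n(self) -> int:
        return self.left.n

    def swapped(self) -> "BinauralWaveform":
        return BinauralWaveform(left=self.right, right=self.left)


def fractional_delay(x: np.ndarray, delay_samples: float, n_taps: int = 81) -> np.ndarray:
    """Delay ``x`` by a possibly fractional number of samples.

    Integer part by shifting, fractional part by a Hanning-windowed sinc
    interpolator of ``n_taps`` taps (band-limited interpolation). Output has
    the same length; samples shifted in from beyond the edge are zero.
    """
    if delay_samples < 0:
        raise ValueError("delay must be non-negative (swap ears for the other sign)")
    n_int = int(np.floor(delay_samples))
    frac = delay_samples - n_int
    y = np.asarray(x, dtype=float)
    if frac > 1e-12:
        half = n_taps // 2
        k = np.arange(n_taps) - half
        kern = np.sinc(k - frac) * np.hanning(n_taps)
        kern /= kern.sum()
        y = np.convolve(y, kern, mode="full")[half : half + y.size]
    if n_int > 0:
        y = np.concatenate([np.zeros(n_int), y[:-n_int]])
    return y


def impose_itd(
    w: Waveform,
    itd: float,
    mode: str = "whole_waveform",
    carrier_freq: float | None = None,
) -> BinauralWaveform:
    """Impose an interaural time difference of ``itd`` seconds on ``w``.

    mode='whole_waveform'
        The lagging ear is the other ear delayed by |itd| via band-limited
        (sub-sample) interpolation.
    mode='fine_structure'
        Requires ``carrier_freq``. The two ears share the undelayed Hilbert
        envelope; the carrier phase is offset symmetrically by
        ±pi*carrier_freq*itd so that the interaural carrier phase equals
        2*pi*carrier_freq*itd.
    """
    if abs(itd) >= w.duration:
        raise ValueError("|itd| must be smaller than the waveform duration")
    if mode == "whole_waveform":
        if itd >= 0:  # right leads: left ear delayed
            left = w.copy(samples=fractional_delay(w.samples, itd * w.fs))
            right = w.copy()
        else:
            left = w.copy()
            right = w.copy(samples=fractional_delay(w.samples, -itd * w.fs))
        return BinauralWaveform(left=left, right=right)
    if mode == "fine_structure":
        if carrier_freq is None:
            raise ValueError("fine_structure mode requires carrier_freq")
        a = hilbert(w.samples)
        env = np.abs(a)
        ph = np.unwrap(np.angle(a))
        dphi = np.pi * carrier_freq * itd  # half the interaural phase
        right = w.copy(samples=env * np.cos(ph + dphi))
        left = w.copy(samples=env * np.cos(ph - dphi))
        return BinauralWaveform(left=left, right=right)
    raise ValueError(f"unknown mode {mode!r}")


def impose_ild(w: Waveform, ild: float) -> BinauralWaveform:
    """Impose an interaural level difference of ``ild`` dB on ``w``.

    The split is symmetric: each ear is offset by ±ild/2 dB so the mean level
    of the two ears equals the input level. Positive ILD makes the right ear
    louder.
    """
    if not np.isfinite(ild):
        raise ValueError("ild must be finite")
    g = 10.0 ** (ild / 40.0)  # ±ild/2 dB
    return BinauralWaveform(
        left=w.copy(samples=w.samples / g),
        right=w.copy(samples=w.samples * g),
    )


def estimate_itd(b: BinauralWaveform, max_lag: float = 1e-3) -> float:
    """ITD (s) maximizing the interaural cross-correlation.

    The peak lag is refined by parabolic interpolation around the maximum.
    Positive return value = right ear leads, matching :func:`impose_itd`.
    """
    l, r = b.left.samples, b.right.samples
    if np.sqrt(np.mean(l**2)) == 0 or np.sqrt(np.mean(r**2)) == 0:
        raise ValueError("silent channel")
    fs = b.fs
    m = int(np.ceil(max_lag * fs))
    if m < 1:
        raise ValueError("max_lag shorter than one sample")
    # correlate(l, r)[k] peaks at positive displacement when l is delayed
    # relative to r, i.e. when the right ear leads.
    c = correlate(l, r, mode="full")
    mid = l.size - 1
    c = c[mid - m : mid + m + 1]
    lags = np.arange(-m, m + 1)
    i = int(np.argmax(c))
    lag = float(lags[i])
    if 0 < i < c.size - 1:  # parabolic refinement
        y0, y1, y2 = c[i - 1], c[i], c[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag / fs
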