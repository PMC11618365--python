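"""Calibrated stimulus synthesis and ERB-scale frequency utilities.

Samples are sound pressure in pascal; levels are dB SPL re 20 µPa RMS.
Carrying physical units through the whole pipeline avoids a digital
full-scale convention: a tone synthesized at 60 dB SPL has an RMS of
exactly 0.02 Pa, and the periphery's rate-level functions read instantaneous
pressure directly.

Frequencies are placed on the ERB-number scale (Glasberg & Moore):

    E(f) = 21.4 * log10(0.00437 * f + 1)

Equal steps in E approximate equal distances along the cochlea, which is
why cochlear channel axes throughout the package are ERB-spaced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "P_REF",
    "Waveform",
    "ErbAxis",
    "erb_number",
    "erb_to_hz",
    "erb_bandwidth",
    "erb_space",
    "synth_tone",
    "synth_complex",
    "synth_noise",
    "apply_ramp",
    "mix_at_snr",
    "read_wav",
    "write_wav",
]

#: reference pressure for dB SPL (Pa)
P_REF = 20e-6


def spl_to_pa(level_db: float) -> float:
    """RMS pressure (Pa) of a sound at ``level_db`` dB SPL."""
    return P_REF * 10.0 ** (level_db / 20.0)


def pa_to_spl(rms_pa: float) -> float:
    """dB SPL of an RMS pressure (Pa)."""
    if rms_pa <= 0:
        raise ValueError("RMS pressure must be positive")
    return 20.0 * np.log10(rms_pa / P_REF)


@dataclass
class Waveform:
    """A calibrated sound-pressure time series.

    Parameters
    ----------
    samples : ndarray
        Sound pressure per sample, in pascal.
    fs : float
        Sampling rate in Hz.
    meta : str
        Free-text provenance.
    """

    samples: np.ndarray
    fs: float
    meta: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.fs <= 0:
            raise ValueError("Sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times (s), starting at 0."""
        return np.arange(self.n) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_dbspl(self) -> float:
        """Measured level in dB SPL (re 20 µPa RMS)."""
        return pa_to_spl(self.rms())

    def copy(self, samples: np.ndarray | None = None, meta: str | None = None) -> "Waveform":
        return Waveform(
            samples=self.samples.copy() if samples is None else np.asarray(samples, float),
            fs=self.fs,
            meta=self.meta if meta is None else meta,
        )


# ---------------------------------------------------------------------------
# ERB-number scale
# ---------------------------------------------------------------------------

def erb_number(f):
    """ERB-number E(f) = 21.4*log10(0.00437*f + 1) for frequency f in Hz.

    Strictly increasing bijection from [0, inf) onto [0, inf).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 21.4 * np.log10(0.00437 * f + 1.0)
    return out if out.ndim else float(out)


def erb_to_hz(e):
    """Inverse of :func:`erb_number`."""
    e = np.asarray(e, dtype=float)
    out = (10.0 ** (e / 21.4) - 1.0) / 0.00437
    return out if out.ndim else float(out)


def erb_bandwidth(f):
    """Equivalent rectangular bandwidth (Hz) at frequency f (Hz).

    ERB(f) = 24.7*(0.00437*f + 1); the derivative convention consistent with
    :func:`erb_number`.
    """
    f = np.asarray(f, dtype=float)
    out = 24.7 * (0.00437 * f + 1.0)
    return out if out.ndim else float(out)


@dataclass
class ErbAxis:
    """Frequencies equally spaced on the ERB-number scale.

    ``mode='edges'`` includes both endpoints; ``mode='centers'`` holds the
    midpoints (in ERB-number) of the n+1-edge partition of the interval.
    """

    f_lo: float
    f_hi: float
    values: np.ndarray
    mode: str = "edges"

    @property
    def n_points(self) -> int:
        return self.values.size

    def erb_numbers(self) -> np.ndarray:
        return erb_number(self.values)


def erb_space(f_lo: float, f_hi: float, n: int, mode: str = "edges") -> ErbAxis:
    """Place ``n`` frequencies uniformly on the ERB-number scale in [f_lo, f_hi].

    mode='edges'   : n points with endpoints exactly f_lo and f_hi.
    mode='centers' : midpoints of the (n+1)-edge partition of [E(f_lo), E(f_hi)].
    """
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    if n < 2:
        raise ValueError("n must be >= 2")
    e_lo, e_hi = erb_number(f_lo), erb_number(f_hi)
    if mode == "edges":
        e = np.linspace(e_lo, e_hi, n)
        vals = erb_to_hz(e)
        vals[0], vals[-1] = f_lo, f_hi  # exact endpoints
    elif mode == "centers":
        edges = np.linspace(e_lo, e_hi, n + 1)
        e = 0.5 * (edges[:-1] + edges[1:])
        vals = erb_to_hz(e)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ErbAxis(f_lo=f_lo, f_hi=f_hi, values=vals, mode=mode)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def _calibrate(x: np.ndarray, level_dbspl: float) -> np.ndarray:
    """Scale ``x`` so its measured RMS sits exactly at ``level_dbspl``."""
    r = np.sqrt(np.mean(x**2))
    if r == 0:
        raise ValueError("cannot calibrate a silent signal")
    return x * (spl_to_pa(level_dbspl) / r)


def synth_tone(
    freq: float,
    dur: float,
    fs: float,
    level: float = 60.0,
    phase: float = 0.0,
) -> Waveform:
    """Pure tone, cosine convention: p(t) = A*cos(2*pi*freq*t + phase).

    ``phase=0`` is "cosine phase" (the waveform starts at its peak). The
    output is calibrated so the measured RMS equals ``level`` dB SPL exactly.
    """
    if dur <= 0:
        raise ValueError("duration must be positive")
    if not (0 < freq < fs / 2):
        raise ValueError(f"tone frequency {freq} Hz must lie in (0, fs/2)")
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = np.cos(2 * np.pi * freq * t + phase)
    x = _calibrate(x, level)
    return Waveform(x, fs, meta=f"tone f={freq}Hz L={level}dBSPL")


def synth_complex(
    freqs,
    amps=None,
    dur: float = 0.2,
    fs: float = 20000.0,
    level: float = 60.0,
    phase=0.0,
) -> Waveform:
    """Sum of cosines at ``freqs`` with relative linear weights ``amps``.

    Total RMS is calibrated to ``level`` dB SPL. ``phase`` may be a scalar
    (shared starting phase) or per-component array.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if freqs.size == 0:
        raise ValueError("at least one component is required")
    if np.any(freqs >= fs / 2) or np.any(freqs <= 0):
        raise ValueError("component frequencies must lie in (0, fs/2)")
    if amps is None:
        amps = np.ones_like(freqs)
    amps = np.broadcast_to(np.asarray(amps, dtype=float), freqs.shape)
    phases = np.broadcast_to(np.asarray(phase, dtype=float), freqs.shape)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a, p in zip(freqs, amps, phases):
        x += a * np.cos(2 * np.pi * f * t + p)
    x = _calibrate(x, level)
    return Waveform(x, fs, meta=f"complex n={freqs.size} L={level}dBSPL")


def synth_noise(
    dur: float,
    fs: float,
    level: float = 60.0,
    seed: int | None = None,
    band: tuple[float, float] | None = None,
) -> Waveform:
    """Gaussian noise at ``level`` dB SPL, optionally band-passed (FFT brickwall)."""
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    x = rng.standard_normal(n)
    if band is not None:
        lo, hi = band
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        spec[(f < lo) | (f > hi)] = 0.0
        x = np.fft.irfft(spec, n)
    x = _calibrate(x, level)
    return Waveform(x, fs, meta=f"noise L={level}dBSPL seed={seed}")


def apply_ramp(w: Waveform, shape: str = "hanning", ramp_dur: float = 0.015) -> Waveform:
    """Apply onset and offset ramps of duration ``ramp_dur`` (s).

    ``hanning``, ``half_hanning`` and ``squared_cosine`` are the same
    raised-cosine gain curve 0.5*(1 - cos(pi*t/T)) — half of a Hanning window
    equals a squared-(co)sine ramp — and are accepted as aliases. ``linear``
    ramps the gain linearly. First and last samples are scaled to zero;
    samples beyond the ramps are untouched.
    """
    if ramp_dur < 0:
        raise ValueError("ramp duration must be non-negative")
    if ramp_dur == 0:
        return w.copy()
    n_r = int(round(ramp_dur * w.fs))
    if 2 * n_r > w.n:
        raise ValueError("ramps longer than half the waveform")
    if n_r == 0:
        return w.copy()
    t = np.arange(n_r) / n_r  # 0 .. (n_r-1)/n_r, gain 0 at first sample
    if shape in ("hanning", "half_hanning", "squared_cosine"):
        g = 0.5 * (1 - np.cos(np.pi * t))
    elif shape == "linear":
        g = t
    else:
        raise ValueError(f"unknown ramp shape {shape!r}")
    x = w.samples.copy()
    x[:n_r] *= g
    x[-n_r:] *= g[::-1]
    return w.copy(samples=x, meta=w.meta + f" ramp={shape}/{ramp_dur}s")


def mix_at_snr(
    target: Waveform,
    noise: Waveform,
    snr: float,
    crop: bool = False,
) -> Waveform:
    """Add ``noise`` to ``target`` at a signal-to-noise ratio of ``snr`` dB.

    The target is passed through unscaled; the noise is rescaled so that
    RMS(target)/RMS(noise) = 10^(snr/20). ``snr=inf`` returns the target
    unchanged (the noiseless condition). Length mismatch is an error unless
    ``crop=True``, which crops both to the shorter length.
    """
    if target.fs != noise.fs:
        raise ValueError("sampling rates differ")
    if np.isposinf(snr):
        return target.copy(meta=target.meta + " snr=inf")
    ts, ns = target.samples, noise.samples
    if ts.size != ns.size:
        if not crop:
            raise ValueError("lengths differ; pass crop=True to crop to the shorter")
        m = min(ts.size, ns.size)
        ts, ns = ts[:m], ns[:m]
    noise_rms = np.sqrt(np.mean(ns**2))
    if noise_rms == 0:
        raise ValueError("silent noise with finite SNR")
    target_rms = np.sqrt(np.mean(ts**2))
    scale = target_rms / noise_rms / 10.0 ** (snr / 20.0)
    return Waveform(ts + scale * ns, target.fs, meta=target.meta + f" snr={snr}dB")


# ---------------------------------------------------------------------------
# WAV + JSON sidecar I/O
# ---------------------------------------------------------------------------

def write_wav(path, w: Waveform) -> None:
    """Write float PCM WAV plus a JSON sidecar recording calibration."""
    path = Path(path)
    wavfile.write(path, int(round(w.fs)), w.samples.astype(np.float32))
    sidecar = {
        "units": "pascal",
        "fs": w.fs,
        "level_dbspl": w.level_dbspl(),
        "meta": w.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_wav(path) -> Waveform:
    """Read a float PCM WAV written by :func:`write_wav` (sidecar optional)."""
    path = Path(path)
    fs, x = wavfile.read(path)
    if x.dtype.kind == "i":  # integer PCM: scale to [-1, 1) — uncalibrated
        x = x / float(np.iinfo(x.dtype).max)
    meta = ""
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        meta = info.get("meta", "")
        fs = info.get("fs", fs)
    return Waveform(np.asarray(x, dtype=float), float(fs), meta=meta)
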