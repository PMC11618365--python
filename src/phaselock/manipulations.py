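"""Psychoacoustic stimulus manipulations.

* Tone vocoding: frequency channels above a cutoff channel are replaced by
  pure-tone carriers at each channel's center frequency, amplitude-modulated
  by the Hilbert envelope of the original band, refiltered, and summed with
  the intact channels. This removes informative temporal fine structure
  while preserving envelope cues.
* Inharmonic jitter: harmonics above the fundamental are shifted by amounts
  drawn uniformly in ±50% of F0, with whole patterns rejection-sampled until
  all adjacent components are at least 30 Hz apart.
* Speech-shaped noise: white noise carrying the reference's magnitude
  spectrum (phase randomization).
* Sinusoidal dB-scale amplitude modulation (default 8 Hz, 30 dB
  peak-to-valley), the modulated-noise manipulation of speech-in-noise
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, hilbert

from .stimuli import ErbAxis, Waveform, erb_bandwidth, erb_space

__all__ = [
    "VocoderFilterbank",
    "JitterPattern",
    "gammatone_ir",
    "tone_vocode",
    "jitter_harmonics",
    "speech_shaped_noise",
    "sinusoidal_db_modulate",
]


def gammatone_ir(
    cf: float,
    fs: float,
    dur: float = 0.05,
    order: int = 4,
    bw_scale: float = 1.019,
) -> np.ndarray:
    """Truncated gammatone impulse response centered at ``cf``.

    g(t) = t^(order-1) * exp(-2*pi*b*t) * cos(2*pi*cf*t) with bandwidth
    b = bw_scale * ERB(cf), normalized to unit peak magnitude response at cf.
    """
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    b = bw_scale * erb_bandwidth(cf)
    g = t ** (order - 1) * np.exp(-2 * np.pi * b * t) * np.cos(2 * np.pi * cf * t)
    # unit gain at the center frequency
    resp = np.abs(np.sum(g * np.exp(-2j * np.pi * cf * t)))
    return g / resp


@dataclass
class VocoderFilterbank:
    """The band-pass filterbank used for tone vocoding.

    ``n_channels`` gammatone bands with 33 edges equally spaced on the
    ERB-number scale across [f_lo, f_hi]; channel centers sit at ERB-number
    midpoints. Analysis filters are applied zero-phase (forward convolution
    with the kernel and its time reverse) so that the analysis-synthesis sum
    over all channels reconstructs in-band signals with high fidelity.
    """

    f_lo: float = 100.0
    f_hi: float = 10000.0
    n_channels: int = 32
    fs: float = 20000.0
    order: int = 4
    ir_dur: float = 0.05
    edges: np.ndarray = field(init=False)
    centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.edges = erb_space(self.f_lo, self.f_hi, self.n_channels + 1, mode="edges").values
        self.centers = erb_space(self.f_lo, self.f_hi, self.n_channels, mode="centers").values
        if np.any(self.centers >= self.fs / 2):
            raise ValueError("channel centers exceed Nyquist")
        self._irs = [gammatone_ir(cf, self.fs, self.ir_dur, self.order) for cf in self.centers]

    def filter_channel(self, x: np.ndarray, k: int) -> np.ndarray:
        """Zero-phase band-pass of channel ``k`` (same length as input)."""
        ir = self._irs[k]
        y = fftconvolve(x, ir, mode="full")
        y = fftconvolve(y, ir[::-1], mode="full")
        d = ir.size - 1  # group delay of the symmetric composite kernel
        return y[d : d + x.size]

    def refilter_channel(self, x: np.ndarray, k: int) -> np.ndarray:
        """Single-pass band-pass of channel ``k``, group-delay compensated.

        Used to refilter vocoded bands: one pass keeps the channel's nominal
        bandwidth (zero-phase doubles the magnitude order, over-smoothing
        envelopes), while the delay compensation keeps the vocoded bands
        time-aligned with the zero-phase intact bands.
        """
        ir = self._irs[k]
        d = int(np.argmax(np.abs(hilbert(ir))))
        y = fftconvolve(x, ir, mode="full")
        return y[d : d + x.size]

    def analyze(self, x: np.ndarray) -> np.ndarray:
        """[n_channels x n_time] subband decomposition."""
        return np.stack([self.filter_channel(x, k) for k in range(self.n_channels)])


def tone_vocode(w: Waveform, cutoff_channel: int, fb: VocoderFilterbank | None = None) -> Waveform:
    """Tone-vocode all filterbank channels above ``cutoff_channel``.

    Channels 1..cutoff (1-based; cutoff 0 vocodes everything, cutoff
    n_channels leaves the analysis-synthesis reconstruction intact) pass
    through unmodified. Above the cutoff, each band is replaced by a tone
    carrier at the channel center frequency modulated by the band's Hilbert
    envelope, then refiltered with the same channel filter. All bands are
    summed; the output has the input's duration.
    """
    if fb is None:
        fb = VocoderFilterbank(fs=w.fs)
    if w.fs != fb.fs:
        raise ValueError("waveform and filterbank sampling rates differ")
    if not (0 <= cutoff_channel <= fb.n_channels):
        raise ValueError(f"cutoff_channel must lie in [0, {fb.n_channels}]")
    t = np.arange(w.n) / w.fs
    out = np.zeros(w.n)
    for k in range(fb.n_channels):
        band = fb.filter_channel(w.samples, k)
        if k < cutoff_channel:  # intact channel
            out += band
        else:  # vocoded: envelope on a fixed-phase tone carrier, refiltered
            env = np.abs(hilbert(band))
            carrier = np.cos(2 * np.pi * fb.centers[k] * t)
            out += fb.refilter_channel(env * carrier, k)
    return w.copy(samples=out, meta=w.meta + f" vocoded(cutoff={cutoff_channel})")


@dataclass
class JitterPattern:
    """Component frequencies of an inharmonic complex.

    The first component is exactly F0; components k >= 2 sit at
    (k + jitter_k)*F0 with jitter_k uniform in [-0.5, +0.5], accepted only
    if all adjacent spacings are at least ``min_spacing`` Hz.
    """

    f0: float
    frequencies: np.ndarray
    jitters: np.ndarray
    min_spacing: float = 30.0

    def __post_init__(self) -> None:
        if abs(self.frequencies[0] - self.f0) > 1e-12:
            raise ValueError("component 1 must equal f0 exactly")
        if np.any(np.diff(self.frequencies) < self.min_spacing - 1e-12):
            raise ValueError("adjacent spacing below the minimum")
        if np.any(np.abs(self.jitters) > 0.5 + 1e-12):
            raise ValueError("|jitter| must be <= 0.5")


def jitter_harmonics(
    f0: float,
    n_harmonics: int,
    seed: int | None = None,
    min_spacing: float = 30.0,
    max_attempts: int = 10000,
    zero_jitter: bool = False,
) -> JitterPattern:
    """Sample an inharmonic jitter pattern.

    Harmonics 2..n are shifted by independent uniform(-0.5, +0.5) fractions
    of F0; whole patterns are resampled until all adjacent components are at
    least ``min_spacing`` Hz apart (pattern-level rejection keeps the jitter
    law independent-uniform conditional on acceptance). Deterministic for a
    given seed. ``zero_jitter=True`` is the harmonic diagnostic mode.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    k = np.arange(1, n_harmonics + 1)
    if zero_jitter or n_harmonics == 1:
        freqs = k * f0
        return JitterPattern(f0, freqs.astype(float), np.zeros(n_harmonics), min_spacing)
    if f0 < min_spacing:
        # even unjittered spacing is below the floor: unsatisfiable on average
        raise ValueError("constraint unsatisfiable: f0 below the minimum spacing")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        jit = np.zeros(n_harmonics)
        jit[1:] = rng.uniform(-0.5, 0.5, size=n_harmonics - 1)
        freqs = (k + jit) * f0
        if np.all(np.diff(freqs) >= min_spacing):
            return JitterPattern(f0, freqs, jit, min_spacing)
    raise RuntimeError(f"no acceptable pattern in {max_attempts} attempts")


def speech_shaped_noise(ref: Waveform, seed: int | None = None) -> Waveform:
    """Noise with the magnitude spectrum of ``ref`` and randomized phases.

    Output matches the reference's length and RMS. The reference's power
    spectrum is imposed exactly; only the phases are replaced by i.i.d.
    uniform draws (Hermitian-symmetric, so the result is real).
    """
    x = ref.samples
    if np.sqrt(np.mean(x**2)) == 0:
        raise ValueError("silent reference")
    rng = np.random.default_rng(seed)
    mag = np.abs(np.fft.rfft(x))
    phases = rng.uniform(0, 2 * np.pi, size=mag.size)
    phases[0] = 0.0
    if x.size % 2 == 0:
        phases[-1] = 0.0  # Nyquist bin must stay real
    y = np.fft.irfft(mag * np.exp(1j * phases), n=x.size)
    y *= np.sqrt(np.mean(x**2)) / np.sqrt(np.mean(y**2))
    return ref.copy(samples=y, meta=ref.meta + f" ssn(seed={seed})")


def sinusoidal_db_modulate(
    w: Waveform,
    rate: float = 8.0,
    peak_to_valley: float = 30.0,
    phase: float = 0.0,
) -> Waveform:
    """Amplitude-modulate ``w`` with a sinusoid on a decibel scale.

    The instantaneous gain in dB is (peak_to_valley/2)*sin(2*pi*rate*t +
    phase), so the max/min gain ratio is exactly ``peak_to_valley`` dB.
    """
    if rate <= 0:
        raise ValueError("modulation rate must be positive")
    if rate >= w.fs / 2:
        raise ValueError("modulation rate above Nyquist")
    gain_db = (peak_to_valley / 2.0) * np.sin(2 * np.pi * rate * w.t + phase)
    return w.copy(
        samples=w.samples * 10.0 ** (gain_db / 20.0),
        meta=w.meta + f" dbmod({rate}Hz,{peak_to_valley}dB)",
    )
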