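"""Simplified cochlear model with a configurable phase-locking limit.

Pipeline (per ear): gammatone FIR filterbank -> half-wave rectification ->
inner-hair-cell (IHC) low-pass filter -> anti-aliased downsampling to the
output rate -> pointwise rate-level sigmoids for three auditory nerve fiber
types -> optional binomial spike sampling for a 32,000-fiber population.

The IHC low-pass filter is the package's knob for degrading temporal
coding: its cutoff sets the upper frequency limit of phase locking (the
frequency up to which instantaneous firing rates follow the stimulus fine
structure). The filter is a cascade of 7 identical first-order low-pass
sections, realized as a 50 ms truncated, Hanning-windowed FIR with unit DC
gain. Note the composite -3 dB point of the 7-section cascade lies below
the per-section cutoff fc; the model is parameterized by fc, matching the
convention of detailed auditory nerve models.

Spike counts per time-frequency-fiber bin follow Binomial(n, p) with
p = rate / fs_out and n = fiber-type fraction x total fibers / number of
frequency channels, approximated by rounding Normal(np, np(1-p)) draws
(clipped to [0, n]). A slower per-fiber Bernoulli sampler with 1 ms dead
time is available to check that refractoriness is negligible at the
population level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import fftconvolve, resample_poly

from .binaural import BinauralWaveform
from .manipulations import gammatone_ir
from .stimuli import P_REF, Waveform, erb_space

__all__ = [
    "FiberType",
    "DEFAULT_FIBER_TYPES",
    "PeripheryConfig",
    "NerveResponse",
    "SpikeResponse",
    "make_cf_axis",
    "gammatone_subbands",
    "ihc_fir",
    "ihc_lowpass",
    "rate_level",
    "periphery_response",
    "sample_spikes",
    "vector_strength",
    "save_response",
    "load_response",
]


@dataclass(frozen=True)
class FiberType:
    """An auditory nerve fiber class.

    Rates range 0–``max_rate`` spikes/s over ``dynamic_range`` dB starting at
    ``threshold`` dB SPL. ``spont_fraction`` is this class's share of the
    total fiber population.
    """

    name: str
    threshold: float  # dB SPL
    dynamic_range: float  # dB
    spont_fraction: float
    max_rate: float = 250.0


#: canonical high/medium/low spontaneous-rate fiber split (60/25/15%)
DEFAULT_FIBER_TYPES = (
    FiberType("high", threshold=0.0, dynamic_range=20.0, spont_fraction=0.60),
    FiberType("medium", threshold=12.0, dynamic_range=40.0, spont_fraction=0.25),
    FiberType("low", threshold=28.0, dynamic_range=80.0, spont_fraction=0.15),
)


def make_cf_axis(n: int = 50, f_lo: float = 125.0, f_hi: float = 8000.0) -> np.ndarray:
    """Characteristic frequencies uniformly spaced on the ERB-number scale.

    Endpoints inclusive: the first CF is ``f_lo`` and the last is ``f_hi``.
    """
    return erb_space(f_lo, f_hi, n, mode="edges").values


@dataclass
class PeripheryConfig:
    """Parameters of the simplified cochlear model."""

    cf_axis: np.ndarray = field(default_factory=make_cf_axis)
    ihc_cutoff: float = 3000.0  # Hz; phase-locking limit knob
    ihc_order: int = 7
    fs_out: float = 10000.0
    total_fibers: int = 32000  # per ear
    fiber_types: tuple[FiberType, ...] = DEFAULT_FIBER_TYPES
    ir_dur: float = 0.05  # s; FIR truncation for filterbank and IHC filter

    def __post_init__(self) -> None:
        self.cf_axis = np.asarray(self.cf_axis, dtype=float)
        if self.ihc_cutoff <= 0:
            raise ValueError("ihc_cutoff must be positive")
        total = sum(ft.spont_fraction for ft in self.fiber_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("fiber-type fractions must sum to 1")

    @property
    def n_cf(self) -> int:
        return self.cf_axis.size

    def n_per_bin(self, ft: FiberType) -> int:
        """Fibers per time-frequency bin for one fiber type."""
        n = int(round(ft.spont_fraction * self.total_fibers / self.n_cf))
        if n < 1:
            raise ValueError("fewer than one fiber per bin; raise total_fibers")
        return n


@dataclass
class NerveResponse:
    """Instantaneous firing rates, shape [n_CF, n_time, n_fiber_types]."""

    rates: np.ndarray
    cf_axis: np.ndarray
    fs_out: float
    ihc_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.rates.ndim != 3:
            raise ValueError("rates must be [CF x time x fiber type]")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def shape(self):
        return self.rates.shape

    def time_averaged(self) -> np.ndarray:
        """Mean rate per [CF, fiber type] — the excitation pattern."""
        return self.rates.mean(axis=1)


@dataclass
class SpikeResponse:
    """Sampled spike counts, shape [n_CF, n_time, n_fiber_types]."""

    counts: np.ndarray
    n_per_bin: np.ndarray  # fibers per bin, one entry per fiber type
    cf_axis: np.ndarray
    fs_out: float
    seed: int | None = None

    @property
    def shape(self):
        return self.counts.shape

    def summed(self) -> np.ndarray:
        """Population spike train summed over CF and fiber type."""
        return self.counts.sum(axis=(0, 2))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def gammatone_subbands(w: Waveform, cfs: np.ndarray, ir_dur: float = 0.05) -> np.ndarray:
    """FIR gammatone filterbank: [n_CF x n_time] causal subband outputs.

    Impulse responses are truncated to ``ir_dur`` seconds; the convolution is
    causal, so an impulse input returns each channel's truncated impulse
    response exactly.
    """
    cfs = np.asarray(cfs, dtype=float)
    if np.any(cfs >= w.fs / 2):
        raise ValueError("CF at or above Nyquist")
    irs = np.stack([gammatone_ir(cf, w.fs, ir_dur) for cf in cfs])
    out = fftconvolve(irs, w.samples[None, :], mode="full", axes=1)
    return out[:, : w.n]


def ihc_fir(cutoff: float, fs: float, order: int = 7, dur: float = 0.05) -> np.ndarray:
    """FIR kernel of the IHC low-pass filter.

    Impulse response of ``order`` cascaded identical first-order sections
    with per-section cutoff ``cutoff`` (a gamma-shaped kernel), truncated to
    ``dur`` seconds, multiplied by the falling half of a Hanning window (so
    the tail fades to zero at the truncation point), and normalized to unit
    DC gain. All taps are non-negative, so the filter maps non-negative
    inputs to non-negative outputs.
    """
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    a = 2 * np.pi * cutoff
    # gamma-density shape; scale fixed afterwards by DC normalization
    with np.errstate(over="ignore", under="ignore"):
        h = t ** (order - 1) * np.exp(-a * t)
    h *= 0.5 * (1 + np.cos(np.pi * t / dur))  # fade to zero at dur
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate IHC kernel; check cutoff and fs")
    return h / s


def ihc_lowpass(
    subbands: np.ndarray,
    cutoff: float,
    fs: float,
    order: int = 7,
    dur: float = 0.05,
) -> np.ndarray:
    """Half-wave rectify then IHC-low-pass each subband.

    Output = lowpass(max(x, 0)) with the FIR of :func:`ihc_fir` applied
    causally. Constant non-negative input passes unchanged (unit DC gain);
    fine structure above the cutoff is attenuated at ~order x 6 dB/octave,
    which is what limits phase locking.
    """
    if cutoff >= fs / 2:
        raise ValueError("cutoff at or above Nyquist of the subband rate")
    h = ihc_fir(cutoff, fs, order, dur)
    rect = np.maximum(np.asarray(subbands, dtype=float), 0.0)
    out = fftconvolve(rect, h[None, :], mode="full", axes=1)
    return out[:, : subbands.shape[-1]]


def rate_level(
    subbands_pa: np.ndarray,
    fiber: FiberType,
    eps: float = 1e-9,
) -> np.ndarray:
    """Pointwise rate-level sigmoid for one fiber type.

    Instantaneous amplitude a (Pa, non-negative) maps to instantaneous level
    L = 20*log10(max(a, eps)/20e-6) dB SPL; the rate is logistic in L with
    midpoint threshold + DR/2 and slope set so the rate spans 5%–95% of
    ``max_rate`` across [threshold, threshold + DR].
    """
    x = np.asarray(subbands_pa, dtype=float)
    if np.any(x < 0):
        raise ValueError("rate_level requires non-negative (rectified) input")
    level = 20.0 * np.log10(np.maximum(x, eps) / P_REF)
    l_mid = fiber.threshold + fiber.dynamic_range / 2.0
    k = 2.0 * np.log(19.0) / fiber.dynamic_range  # 5% -> 95% across DR
    return fiber.max_rate / (1.0 + np.exp(-k * (level - l_mid)))


def _downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased polyphase downsampling along the last axis."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def periphery_response(w, cfg: PeripheryConfig | None = None):
    """Run the full simplified cochlear model.

    For a :class:`~phaselock.stimuli.Waveform` returns a
    :class:`NerveResponse`; for a
    :class:`~phaselock.binaural.BinauralWaveform` returns a (left, right)
    tuple of them.
    """
    if cfg is None:
        cfg = PeripheryConfig()
    if isinstance(w, BinauralWaveform):
        return (periphery_response(w.left, cfg), periphery_response(w.right, cfg))
    sub = gammatone_subbands(w, cfg.cf_axis, cfg.ir_dur)
    sub = ihc_lowpass(sub, cfg.ihc_cutoff, w.fs, cfg.ihc_order, cfg.ir_dur)
    sub = _downsample(sub, w.fs, cfg.fs_out)
    np.clip(sub, 0.0, None, out=sub)  # polyphase filtering can ring negative
    rates = np.stack([rate_level(sub, ft) for ft in cfg.fiber_types], axis=-1)
    return NerveResponse(rates, cfg.cf_axis, cfg.fs_out, ihc_cutoff=cfg.ihc_cutoff)


def sample_spikes(
    r: NerveResponse,
    cfg: PeripheryConfig | None = None,
    seed: int | None = None,
    refractory: bool = False,
) -> SpikeResponse:
    """Sample spike counts from instantaneous firing rates.

    Default sampler: per-bin Binomial(n, p) with p = rate/fs_out, via the
    rounded-Gaussian approximation Normal(np, np(1-p)) clipped to [0, n].
    ``refractory=True`` instead simulates each fiber as a Bernoulli process
    with a 1 ms dead time after every spike (much slower; intended for
    small fiber populations).
    """
    if cfg is None:
        cfg = PeripheryConfig(cf_axis=r.cf_axis, fs_out=r.fs_out)
    rng = np.random.default_rng(seed)
    p = r.rates / r.fs_out
    if np.any(p > 1.0):
        raise ValueError("firing rate exceeds the sampling rate (p > 1)")
    ns = np.array([cfg.n_per_bin(ft) for ft in cfg.fiber_types])
    if refractory:
        counts = _sample_refractory(p, ns, r.fs_out, rng)
    else:
        mean = ns[None, None, :] * p
        var = mean * (1.0 - p)
        counts = np.rint(rng.normal(mean, np.sqrt(var)))
        counts = np.clip(counts, 0, ns[None, None, :]).astype(np.int32)
    return SpikeResponse(counts, ns, r.cf_axis, r.fs_out, seed=seed)


def _sample_refractory(p: np.ndarray, ns: np.ndarray, fs: float, rng) -> np.ndarray:
    """Per-fiber Bernoulli sampling with 1 ms absolute refractoriness."""
    n_cf, n_t, n_s = p.shape
    dead = max(1, int(round(1e-3 * fs)))
    counts = np.zeros((n_cf, n_t, n_s), dtype=np.int32)
    for s in range(n_s):
        n_fib = int(ns[s])
        # refractory countdown per (CF, fiber)
        timer = np.zeros((n_cf, n_fib), dtype=np.int32)
        for t in range(n_t):
            ready = timer == 0
            u = rng.random((n_cf, n_fib))
            spikes = ready & (u < p[:, t, s][:, None])
            counts[:, t, s] = spikes.sum(axis=1)
            timer[~ready] -= 1
            timer[spikes] = dead
    return counts


def vector_strength(x: np.ndarray, f: float, fs: float) -> float:
    """Synchronization index of a rate or spike-count series to frequency f.

    VS = |sum_t w(t) exp(-i 2 pi f t)| / sum_t w(t) with non-negative bin
    weights w (rates or counts). 0 = no locking, 1 = perfect locking.
    """
    w = np.asarray(x, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("vector strength undefined for all-zero input")
    t = np.arange(w.size) / fs
    return float(np.abs(np.sum(w * np.exp(-2j * np.pi * f * t))) / total)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_response(path, resp) -> None:
    """Save a NerveResponse or SpikeResponse to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        if isinstance(resp, NerveResponse):
            d = f.create_dataset("rates", data=resp.rates)
            if resp.ihc_cutoff is not None:
                d.attrs["ihc_cutoff"] = resp.ihc_cutoff
        elif isinstance(resp, SpikeResponse):
            d = f.create_dataset("counts", data=resp.counts)
            d.attrs["n_per_bin"] = resp.n_per_bin
            if resp.seed is not None:
                d.attrs["seed"] = resp.seed
        else:
            raise TypeError("expected NerveResponse or SpikeResponse")
        d.attrs["cf_axis"] = resp.cf_axis
        d.attrs["fs_out"] = resp.fs_out


def load_response(path):
    """Load a response saved by :func:`save_response`."""
    import h5py

    with h5py.File(path, "r") as f:
        if "rates" in f:
            d = f["rates"]
            return NerveResponse(
                d[...], np.asarray(d.attrs["cf_axis"]), float(d.attrs["fs_out"]),
                ihc_cutoff=float(d.attrs["ihc_cutoff"]) if "ihc_cutoff" in d.attrs else None,
            )
        d = f["counts"]
        return SpikeResponse(
            d[...], np.asarray(d.attrs["n_per_bin"]), np.asarray(d.attrs["cf_axis"]),
            float(d.attrs["fs_out"]), seed=int(d.attrs["seed"]) if "seed" in d.attrs else None,
        )
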