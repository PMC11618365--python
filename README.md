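# phaselock

A simplified spiking model of the auditory periphery with a **configurable
phase-locking limit**, together with the psychoacoustic machinery needed to
probe what that limit does to hearing: calibrated stimulus synthesis,
binaural cue manipulation, tone vocoding and related signal manipulations,
psychometric threshold analysis, human–model similarity statistics, and
desk-scale experiment protocols driven by simple reference observers.

## Who this is for

Auditory neuroscientists and psychoacousticians who want to ask: *which
perceptual tasks actually require precise spike timing in the auditory
nerve?* Auditory nerve fibers fire at preferred phases of a stimulus
("phase locking") up to a frequency limit set by the low-pass filtering of
the inner hair cell (IHC) membrane. This package makes that limit an
explicit knob — the IHC filter cutoff, settable to 3000, 1000, 320, or
50 Hz (or anything else) — and provides the full simulation and analysis
chain to measure its behavioral consequences.

## The model

Per ear, sound pressure (pascal) is processed as:

1. **Gammatone filterbank** — FIR approximations (impulse responses
   truncated to 50 ms) of 4th-order gammatone filters at N = 50
   characteristic frequencies spaced uniformly on the ERB-number scale
   E(f) = 21.4·log₁₀(0.00437·f + 1) between 125 and 8000 Hz (or 16 kHz).
2. **Half-wave rectification + IHC low-pass** — the phase-locking knob: a
   7th-order low-pass (7 cascaded identical first-order sections with
   per-section cutoff f_c), applied as a 50 ms truncated, Hanning-windowed
   FIR with unit DC gain. Fine structure above f_c is removed from the
   instantaneous drive; envelopes and mean drive ("place" cues) survive.
3. **Downsampling** to a 10 kHz output rate (anti-aliased).
4. **Rate-level sigmoids** for three fiber classes — high/medium/low
   spontaneous rate (60/25/15% of fibers) with thresholds 0/12/28 dB SPL
   and dynamic ranges 20/40/80 dB, rates spanning 0–250 spikes/s.
5. **Binomial spike sampling** — counts per time–frequency–fiber bin from
   Binomial(n, p) with p = rate/10 kHz and n = fiber fraction × 32,000 /
   N channels (for the default 50-channel axis: n = 384/160/96), via a
   rounded-Gaussian approximation Normal(np, np(1−p)). A per-fiber sampler
   with 1 ms dead time is available to check that refractoriness is
   negligible at the population level.

On top of the periphery sit the field's standard psychophysical analyses:
cumulative-Normal psychometric fits (binomial maximum likelihood, optional
2AFC chance floor), thresholds at 70.7% / 75% / half-maximal criteria,
fine-structure and whole-waveform ITD imposition with sub-sample precision,
dimensionless ITD/ILD perceptual weights, speech-reception thresholds and
benefit-from-TFS tables, Pearson / min-max-normalized-RMS similarity
metrics with bootstrap confidence intervals, split-half reliability
correction, and a permutation test for between×within interactions.

## Worked example

Measure the phase-locking roll-off directly — the synchrony of simulated
firing to a 60 dB SPL tone at its own characteristic frequency, as the IHC
cutoff is lowered:

```python
import numpy as np
from phaselock import PeripheryConfig, periphery_response, vector_strength
from phaselock.stimuli import synth_tone, apply_ramp

tone = apply_ramp(synth_tone(500, 0.2, 40000, level=60), "hanning", 0.01)
for cutoff in (3000, 1000, 320, 50):
    cfg = PeripheryConfig(ihc_cutoff=cutoff)
    resp = periphery_response(tone, cfg)
    ch = np.argmin(np.abs(cfg.cf_axis - 500))
    vs = vector_strength(resp.rates[ch, 300:, 2], 500, cfg.fs_out)
    print(f"IHC cutoff {cutoff:>4} Hz: vector strength at 500 Hz = {vs:.3f}")
```

```
IHC cutoff 3000 Hz: vector strength at 500 Hz = 0.568
IHC cutoff 1000 Hz: vector strength at 500 Hz = 0.194
IHC cutoff  320 Hz: vector strength at 500 Hz = 0.005
IHC cutoff   50 Hz: vector strength at 500 Hz = 0.001
```

Vector strength (0 = no locking, 1 = perfect locking) of the
low-spontaneous-rate fiber rates collapses as the cutoff falls below the
tone frequency — the periphery still *excites* the same channels (place
cues are preserved; the time-averaged excitation patterns correlate above
0.95 across all four cutoffs), but the temporal fine structure is gone.
The `protocols` module turns this into behavior: a binaural
cross-correlation observer loses measurable fine-structure ITD thresholds
frequency-by-frequency as the cutoff drops, and a spike-timing observer's
frequency-discrimination advantage over a rate-place (excitation-centroid)
observer vanishes at the 50 Hz cutoff.

A command-line interface mirrors the library
(`phaselock stim|binaural|manip|periphery|psych|similarity|protocol`).

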