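# Methods

This note documents the models and procedures implemented in `phaselock`,
the parameter choices that matter, and what the tests do and do not
establish.

## Units and calibration

All waveforms carry sound pressure in pascal; levels are dB SPL re
20 µPa RMS. Synthesized tones, complexes and noises are calibrated by
scaling to the *measured* RMS, so a requested level is met exactly for any
duration (not only for integer cycle counts). A JSON sidecar accompanies
WAV output to record the convention, because a float WAV alone does not fix
physical units.

## Frequency axes

Channel axes use the ERB-number scale E(f) = 21.4·log₁₀(0.00437·f + 1)
with bandwidth ERB(f) = 24.7·(0.00437·f + 1). `erb_space(mode="edges")`
includes both endpoints exactly; `mode="centers"` takes the midpoints (in
ERB-number) of the edge partition. The characteristic-frequency axis of
the periphery is endpoint-inclusive (first CF = f_lo, last = f_hi). With 33
edges spanning 100–10,000 Hz, the boundary between channels 24 and 25
falls at 4102 Hz; this printed correspondence is what fixes the
Glasberg–Moore constants above, since "ERB-number scale" alone does not
pin them down.

## Periphery

**Gammatone filterbank.** 4th-order gammatone impulse responses
g(t) ∝ t³·e^(−2πbt)·cos(2πf_c t) with b = 1.019·ERB(f_c), truncated to
50 ms, normalized to unit magnitude response at f_c, applied causally by
FFT convolution. Linearity and the impulse-response identity are tested
sample-exactly.

**IHC low-pass (the phase-locking knob).** Seven cascaded identical
first-order sections with per-section cutoff f_c give the gamma-shaped
impulse response h(t) ∝ t⁶·e^(−2πf_c t). It is truncated at 50 ms,
multiplied by the falling half of a Hanning window (so the tail fades to
zero at the truncation point rather than being cut abruptly), and
normalized to unit DC gain. The rectification is part of this stage's
contract: output = lowpass(max(x, 0)). Two consequences are documented
rather than "fixed":

* the composite −3 dB point of the 7-section cascade lies *below* the
  per-section f_c (each section contributes −3.01 dB at f_c, −21.07 dB
  total); the model is parameterized by f_c, matching the convention of
  detailed nerve models;
* for f_c = 50 Hz the impulse response mass extends tens of milliseconds,
  so the 50 ms truncation window reshapes it measurably (the FIR sits a
  few dB above the analytic cascade at f_c after DC renormalization). The
  attenuation of fine structure well above f_c — what the manipulation is
  for — is unaffected (>60 dB at 2 kHz).

**Rate-level functions.** The sigmoid family is a modeling choice here:
rates are logistic in instantaneous level, L(t) = 20·log₁₀(max(a, ε)/20 µPa)
with ε = 1e−9 Pa, midpoint at threshold + DR/2, and slope set so rates
span 5%→95% of 250 spikes/s across [threshold, threshold + DR]. The 5–95%
span convention propagates to the checkpoint "rate = 237.5 spikes/s at
threshold + DR". Fiber classes: high/medium/low spontaneous rate with
thresholds 0/12/28 dB SPL, dynamic ranges 20/40/80 dB, fractions
60/25/15%.

**Downsampling.** Polyphase anti-aliased resampling to 10 kHz, needed
because the 3000 Hz-cutoff spectrum is not negligible near 5 kHz. The
polyphase filter can ring slightly negative; the output is clipped at zero
before the (pointwise, non-negative) rate-level stage.

**Spike sampling.** Per bin, Binomial(n, p) with p = rate/f_s and
n = fraction × 32,000 / N channels, approximated by rounding
Normal(np, np(1−p)) draws and clipping to [0, n] (the rounded Gaussian can
otherwise go negative). Identical seeds give bit-identical counts. The
refractory variant simulates each fiber as a Bernoulli process with a 1 ms
absolute dead time; it is O(fibers × time) and intended for checks, not
production. Because single draws at 0.1 ms resolution are dominated by
independent sampling noise (two *non*-refractory draws of the same rates
correlate only ≈0.84 for a 1 kHz tone), the refractory-vs-default
comparison is made between trial-averaged summed population responses
(40 draws each), where the correlation exceeds 0.99; refractoriness
removes ≈15% of spikes but leaves the response shape intact.

**Vector strength.** VS = |Σ w(t)·e^(−i2πft)| / Σ w(t) over bin weights
w (rates or counts). Analytic anchors: a half-wave-rectified sine gives
π/4, a raised cosine gives 1/2; both are reproduced to 1e−3 on dense
sampling and used as oracle values in the tests.

## Binaural operations

Positive ITD/ILD favors the right ear throughout (the convention is
arbitrary but enforced by tests; the mirror identity
impose(−τ) = swap(impose(+τ)) holds exactly). Whole-waveform ITDs use a
Hanning-windowed sinc fractional delay (81 taps), since µs steps are
sub-sample at 20–50 kHz. Fine-structure ITDs shift the carrier phase
symmetrically (±πfτ) under the shared Hilbert envelope, so the interaural
envelope disparity is zero by construction. ILDs are split symmetrically
(±ild/2) to conserve the binaural mean level. `estimate_itd` returns the
interaural cross-correlation peak refined by parabolic interpolation;
round trips on broadband noise recover imposed ITDs within a quarter
sample across ±800 µs.

## Stimulus manipulations

**Tone vocoder.** 32 gammatone channels with 33 ERB-spaced edges between
f_lo and f_hi (defaults 100–10,000 Hz). Analysis (and intact-channel
synthesis) filters are applied zero-phase — forward convolution with the
kernel and its time reverse — so the all-channels-intact condition is an
analysis–synthesis identity up to magnitude ripple (correlation > 0.95
with in-band input). Channels above the cutoff channel are replaced by the
band's Hilbert envelope imposed on a cosine carrier at the channel center
(carrier phase 0, keeping the operation deterministic), then refiltered
with a *single* pass of the channel filter, group-delay compensated: one
pass keeps the channel's nominal 4th-order bandwidth (a zero-phase second
pass would over-smooth the envelopes), and the delay compensation keeps
vocoded and intact bands time-aligned. Vocoded-band envelopes correlate
> 0.9 with the original subband envelopes.

**Inharmonic jitter.** Component 1 is exactly F0; components k ≥ 2 sit at
(k + jitter_k)·F0 with jitter_k ~ Uniform(−0.5, 0.5) i.i.d. Whole patterns
are rejection-sampled until all adjacent spacings are ≥ 30 Hz —
pattern-level rejection preserves the independent-uniform law conditional
on acceptance, whereas per-component resampling would not. A bounded
attempt budget turns unsatisfiable constraints (low F0) into errors.

**Speech-shaped noise.** Phase randomization: the reference's rFFT
magnitudes with i.i.d. uniform phases (DC and Nyquist kept real), RMS
matched. The magnitude spectrum is preserved exactly, which is stronger
than the FIR-filtered-noise alternative.

**dB-scale modulation.** Gain in dB is (PV/2)·sin(2πrt + φ), giving a
max/min gain ratio of exactly PV dB (defaults 8 Hz, 30 dB — the modulated
noise of speech-in-noise experiments).

## Psychophysics

Psychometric functions are cumulative Normals fitted by binomial maximum
likelihood (Nelder–Mead on (μ, log σ), probit-regression start values;
statsmodels' probit GLM serves as an independent cross-check in the
tests). An optional chance floor γ models 2AFC accuracy as
γ + (1−γ)·Φ((x−μ)/σ). There is no lapse parameter by default.
Perfect-separation data (every level at floor or ceiling) are flagged
non-converged, since σ is then unidentified. Standard errors come from the
finite-difference observed information with a delta-method transform;
simulated 2AFC data recover the 70.7% threshold within 3 SE in ≥93% of
replicates.

Thresholds: the fit method returns μ + σ·Φ⁻¹((c−γ)/(1−γ)); the
interpolation method linearly interpolates the first crossing.
Psychometric functions that never reach the criterion — or, in the ITD
protocol, whose fitted threshold exceeds the largest imposed |ITD| — are
reported *unmeasurable* rather than extrapolated.

SRTs fit a logistic with a fitted upper asymptote; "half-maximal
performance" means half the fitted asymptote (the logistic midpoint), with
a fixed-proportion criterion available for the 50%-of-words convention.
The logistic family is a choice (the sigmoid family is otherwise
unconstrained); threshold *differences* — the benefit-from-TFS measure,
benefit(k) = SRT(0) − SRT(k) — are insensitive to it, and the closed-loop
harness recovers a built-in 5 dB benefit within 0.3 dB.

Perceptual weights divide the response shift, expressed in cue units via
an azimuth→cue map, by the imposed cue amount; rear-hemifield responses
are reflected across the coronal plane first. The bundled maps
(Woodworth spherical-head ITD, sinusoidal broadband ILD) are synthetic
stand-ins for measured-head mappings and are labeled as such; supply
measured tables for fidelity. Ties in lateralization judgments are broken
at random with the experiment seed.

## Similarity statistics

Pearson r compares relative performance across conditions; min-max RMS
compares absolute performance after normalizing *both* vectors with the
human minimum and range (optionally shared across grouped experiments so a
null-effect experiment cannot zero out artificially). Bootstrap CIs are
percentile intervals over resampled unit means (percentile intervals
undercover slightly at small unit counts — ≈93% at 40 units — which the
tests acknowledge rather than hide). Two-tailed p-values for manipulations
come from a Normal fitted to a bootstrapped null distribution. Split-half
reliabilities are Spearman–Brown corrected (2r/(1+r)) and the human–model
r² is divided by their product to give the fraction of explainable
variance. The interaction permutation test exploits that with two
within-unit conditions the between×within interaction F equals the one-way
F of per-unit condition differences; within-unit labels are swapped
independently (exchangeable under the null), with +1 smoothing so p > 0.
Null p-values are uniform by simulation; a crossover interaction with 10
units per group is detected at p < 0.01.

## Protocols and reference observers

The observers are deliberately simple decoders, not models of listeners
and not stand-ins for trained systems' absolute performance; their role is
to let the protocols run end-to-end and to expose the *qualitative*
dependence of task information on the phase-locking limit.

* **Rate-place observer** — ERB-number centroid of the time-averaged
  spike counts; uses only place information, so its performance is
  insensitive to the IHC cutoff by construction.
* **Timing observer** — dominant periodicity of the summed population
  spike train from the zero-padded DFT magnitude restricted to the trial
  band (half-octave guards), parabolic peak refinement, with a
  significance gate (peak ≥ 4× the in-band median magnitude); when no
  significant peak exists it falls back to the rate-place judgment, which
  is what makes it collapse onto the rate-place observer at low cutoffs.
* **Cross-correlation observer** — per-CF interaural cross-correlation of
  summed spike trains over ±1 ms, pooled across CFs, parabolic peak → ITD
  in µs.

**Frequency discrimination.** Two-interval trials: f1 at the band center,
interval magnitudes on a log grid (9 points, 5e−4 to 5e−1 octaves by
default), random direction, levels roved independently in 37–43 dB SPL,
200 ms cosine-phase tones padded with 50 ms of silence at 20 kHz audio;
high-spontaneous-rate fibers only, 200 per CF. Thresholds are the 75%
point of a chance-floored cumulative-Normal fit in log magnitude. All
observers judge the same spike responses, making timing-vs-rate-place a
paired comparison. Desk-scale problem sizes (12–15 trials per magnitude)
were chosen so the full four-cutoff comparison runs in well under a
minute; they suffice for the ordering properties, not for precise absolute
thresholds.

**ITD lateralization vs frequency.** Linear-ramped pure tones carry
fine-structure ITDs; default desk-scale grids are frequencies
{250, 500, 1000, 2000, 3500} Hz and ITDs ±160 µs in 10 µs steps (the
laboratory-scale 50 Hz × 1 µs sweep is available by passing explicit
grids). All stimulus pairs are judged rightward/leftward, pooled by ΔITD,
fitted, and thresholded at 70.7%.

**Localization grids.** The 19×5 loudspeaker evaluation grid (180°
frontal azimuth × 0–40° elevation, 10° spacing; 95 positions) and the
72×7 source-location class space (5° azimuth bins over 360°, 10° elevation
bins centered 0–60°; 504 classes) are provided as enumerations; rendering
binaural audio for them (HRTFs, rooms) is out of scope.

**SRT harness.** Word-recognition accuracy on real speech is out of scope,
so `run_vocoding_srt` is defined over accuracy tables or callables
(cutoff channel × noise type × SNR, default grid −15…+15 dB in 3 dB steps,
cutoffs 0…32 in steps of 4) and is validated closed-loop with a synthetic
generator whose built-in benefit it must recover.

## What the synthetic conditions do and do not show

All inputs are synthesized (tones, complexes, noises); there is no speech,
no HRTF rendering, and no trained observer. Passing tests therefore
establish the *mechanics* — calibration, filtering, sampling laws,
threshold machinery, statistics — and the qualitative signatures of the
phase-locking manipulation (roll-off above the cutoff, preserved
excitation patterns, loss of fine-structure ITD information, vanishing
timing advantage). They do not establish absolute behavioral performance
of any listener, human or artificial, on natural stimuli.

## Known limitations

* The rate-level sigmoid family and its dB mapping are conventions; every
  number that depends on them (e.g., the 95%-at-DR checkpoint) is flagged
  where it appears.
* The 50 Hz IHC FIR deviates from the analytic cascade near its cutoff
  (truncation-window reshaping, see above).
* Reference observers are heuristic; their absolute thresholds have no
  human counterpart and only ordering/measurability claims are tested.
* The bundled azimuth→cue maps are spherical-head approximations, not
  measured HRTF mappings.
* Percentile bootstrap CIs undercover by a few points at small unit
  counts.
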