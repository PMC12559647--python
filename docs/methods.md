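# Methods

This note documents the models behind `caeqsim`, the defaults and units
of their tunable parameters, the choices made where the design was
genuinely open, and what the synthetic-data components do and do not
emulate.

## Signal conventions

All stimuli are sampled at 44.1 kHz. Digital amplitudes are full-scale
units with a fixed calibration: a full-scale sinusoid corresponds to
100 dB SPL. The constant is arbitrary — every quantity in the pipeline
(SNR, insertion gain, comfort offsets) is a level difference — but
fixing it makes absolute dB SPL values reproducible. The 63 dB SPL
presentation level of targets and maskers therefore maps to a digital
RMS of about 10^((63−100)/20)/√2.

**Pink noise** is realized by FFT-domain 1/√f magnitude shaping of
Gaussian white noise between 10 Hz and 22.05 kHz, normalized to unit
RMS. **The speech surrogate** stands in for a recorded female speech
target, which is not redistributable: a 100 Hz–8 kHz noise carrier with
a −6 dB/octave tilt above 500 Hz, amplitude-modulated by a positive
envelope derived from 2–8 Hz band-passed noise so the modulation
spectrum peaks near 5 Hz (`modulation_depth`, default 1, scales the
envelope excursion; 0 gives a stationary signal). It reproduces the
slow-modulation and narrowband character of speech, not its phonetic,
pitch or pause structure — quality ratings on it say nothing about
intelligibility-linked effects.

Trial timing: maskers are 2.5 s and lead the 2 s target by 0.5 s in
rating sessions; in detection trials all sources start together and
targets are 1 s segments drawn seed-deterministically from a 2 s
parent. Raised-cosine ramps default to 10 ms.

## Distortions

- **Spectral ripple**: zero-phase FFT filter whose log-magnitude is
  sinusoidal in log2(f) with exactly 10 periods across 50 Hz–16 kHz
  (≈1.2 ripples/octave); the amount is the peak-to-valley ratio in dB.
  The ripple phase (cosine, gain maximum at 50 Hz) and the unity gain
  outside the band are conventions chosen here; nothing downstream
  depends on them.
- **Saturation**: y = x − α·x³ applied sample-wise. The cubic's slope
  reaches zero at x_c = 1/√(3α); inputs beyond ±x_c are pinned to the
  stationary value ±(2/3)·x_c, i.e. the curve saturates completely
  (soft clipping) rather than folding back.
- **Intensity**: a pure broadband gain of Δ dB; **spatial**: the target
  is rendered at a nonzero azimuth through the room model.
- **Anchor**: 8th-order Butterworth low-pass at 3.5 kHz (order chosen
  for a clearly audible cut; only ≥20 dB attenuation above 5 kHz is
  relied upon), saturation with α = 0.55, rendering at 40° azimuth.

### THD metrology and amplitude calibration

`thd_at_peak` drives a sinusoid of given peak amplitude through the
clipper (441 Hz, one second = an integer number of periods, exact FFT
bins) and reports harmonic RMS over fundamental RMS
(fundamental-referenced, the primary convention) alongside the
total-referenced variant. In the regime without clipping the
closed-form cubic expansion THD = (αA²/4)/(1 − 3αA²/4) serves as an
independent oracle.

The amount of nonlinear distortion is usefully summarized by THD at the
*peak* of the reference signal, but that peak amplitude is a property
of the stimulus normalization, so `calibrate_peak_amplitude` recovers
it from printed (α, THD%) pairs by inverting the forward map (single
pair) or least squares (several pairs). Under the
fundamental-referenced convention a single shared amplitude (≈2.0 full
scale, as computed by the calibration) reproduces the full grid of
printed pairs to within half a percentage point, which is why that
convention is the primary one; the total-referenced variant fits
visibly worse and is only reported.

## Room model

Two shoebox rooms: the living-room lab (4.97 × 3.78 × 2.71 m, target
T60 0.5 s) and a large room (7.5 × 4.52 × 3 m, target T60 1.5 s).
Uniform wall absorption is solved from Eyring's formula,
ᾱ = 1 − exp(−0.161·V/(S·T60)); with a single broadband target T60 the
per-band solution is flat, so the absorption is frequency-independent.

Early reflections: image sources up to third order, pressure amplitude
β^order/d with β = √(1−ᾱ). Late field: an 8-line feedback delay
network (mutually prime delays scattered around the mean free path
4V/(cS), Householder feedback matrix, per-line attenuation set to decay
exactly 60 dB per T60), gated in at the third-order image horizon with
a 5 ms cross-fade. The tail's energy is set from diffuse-field theory —
total reverberant energy 16π/A in the 1/d pressure units, A = 0.161·V/T60,
times the decay fraction remaining after the gate — so
direct-to-reverberant ratios follow the physics of the two rooms rather
than an arbitrary mixing level.

Binaural cues come from a spherical head (radius 8.75 cm): Woodworth
ITD split per ear (−(a/c)·sinθ ipsilateral, +(a/c)·θ contralateral,
nearest-sample placement) and a first-order Brown–Duda head-shadow
filter per image and ear. This deliberately replaces measured HRTFs:
absolute DRR values of a real head are not reproduced, and only their
ordering across rooms (less direct-to-reverberant energy in the more
reverberant room) plus the T60 targets (±15 %) are treated as
meaningful. Scene geometry: receiver faces the long axis with a 0.3 m
lateral offset (an asymmetric placement; exact coordinates are a
choice), target at 2.55 m (LRL) or 2 m (Large), maskers at 1.59 m/2 m,
separated maskers at ±45°, heights 1.05/1.10/1.02 m (LRL) and 1.7 m
(Large). LRL maskers are attenuated by the inverse-distance ratio
1.59/2.55 (−4.1 dB) so target and maskers have approximately the level
of a 2.55 m source.

T60 estimation uses Schroeder backward integration with a −5…−35 dB
line fit (T30 × 2), averaged over ears; it refuses inputs whose decay
range is under 35 dB or whose "decay" appears only at the tail end of
the integral (stationary noise). DRR uses a ±2.5 ms direct window and
is capped at +50 dB.

## Hearing loss and compensation

Audiograms cover 125 Hz–6 kHz. The N1 ("very mild") and N3
("moderate") standard audiogram profiles embedded in
`hearing.BISGAARD_PROFILES` come from the published standard-profile
literature, since they are the canonical descriptions of these loss
categories; they are not measured data of any cohort. Synthetic
audiograms add independent uniform ±5 dB jitter per ear and frequency,
which bounds interaural asymmetry by 10 dB — the study population's
inclusion criterion — by construction.

NAL-R insertion gain: G_f = X + 0.31·H_f + k_f with
X = 0.05·(H₅₀₀ + H₁₀₀₀ + H₂₀₀₀) and
k = {250: −17, 500: −8, 1000: +1, 1500: +1, 2000: −1, 3000: −2,
4000: −2, 6000: −2} dB, floored at 0 dB. Note that a flat 0 dB HL
audiogram prescribes +1 dB at 1–1.5 kHz before flooring — a property
of the real constants, not a bug. The gain table is realized as a
512-tap minimum-phase FIR (log-frequency interpolation, real-cepstrum
method), accurate to ±1 dB at the audiometric frequencies; the comfort
offset (−5/0/+5 dB, population split 14:8:2) is a broadband gain after
the filter.

Better-ear PTA is the mean hearing level over 0.5/1/2/4 kHz of
whichever ear has the smaller mean.

## Adaptive procedure

1-up/2-down, 3-AFC: the distortion amount drops after two consecutive
correct responses and rises after any error, converging on the
p = 0.5^(1/2) = 70.7 % correct point. Step schedules (start, initial
step, minimum step): ripple 30/5/1.5 dB, saturation 0.82/0.2/0.035 α,
intensity 8/2/0.4 dB, spatial 28/4/0.5°. Steps are additive in the
printed units. The step halves at each reversal until the minimum step
— the conventional default of adaptive-procedure frameworks; halving
per down-step was evaluated and rejected because it starts the
measurement phase during the initial descent, far above threshold.
Once at the minimum step, six reversals are averaged per run and two
independent runs (test–retest) are averaged into the threshold. A
400-trial cap guards non-converging tracks (e.g. an observer that is
always correct rides the zero floor forever and is reported as an
error with its partial track).

The six-reversal estimate retains a small entry transient — the track
approaches equilibrium from the high starting value — whose bias stays
below one minimum step for all four schedules (verified in the test
suite). The rule's *asymptotic* convergence point is measured
separately (`measure_convergence`) on long tracks (24 minimum-step
reversals, first 8 discarded, 200 tracks), where the observer's
percent-correct at the mean converged level sits at 70.7 ± 2 points.

## Simulated listeners

Percent-correct: p(a) = γ + (1 − γ − λ)·F((g(a) − g(t))/σ + c), F
logistic, γ = 1/3, lapse rate λ ≤ 0.05 (default 0.01), g = log for
ratio-like amounts (ripple depth, α) and identity for dB/degree
amounts, and c chosen so p(t) = 0.707 exactly — the observer's nominal
threshold and the staircase's tracked point coincide by construction.
Psychometric slopes are not known quantities here; the default spread
σ corresponds to two minimum steps of the kind's schedule, an
assumption, not a reproduction.

Default thresholds per (kind, group, context) encode the qualitative
pattern the simulation is meant to emulate: masked contexts are
hardest; moderate loss (ON3) costs most in the presence of maskers and
for the saturating nonlinearity everywhere; very mild loss (ON1) and
normal hearing (YNH) differ little for ripples and intensity without
maskers. Cohort generation couples each listener's thresholds to their
better-ear PTA (strongly in masked contexts and for saturation,
weakly elsewhere) plus lognormal/normal jitter, which yields
significant positive PTA–threshold correlations in masked contexts and
the ON3 > ON1 group ordering by construction. These are *modelling
choices that reproduce directions, not magnitudes*: passing tests show
the pipeline's statistics behave correctly on a cohort built to have
these properties, and say nothing about effect sizes in real
listeners.

Ratings: score = 100 − slope·d (+ masker term + noise, clipped to
0–100 integers), where d = max(0, log2(amount/threshold)) is the
threshold-normalized perceptual distance (log2 of the SDDR; 0 at or
below threshold) and the anchor has a fixed distance of 3.5. The
masker term raises distorted items for ON1/YNH (partial masking,
release × min(d, 2)) and penalizes every masked item including the
hidden reference (penalty: 2/8/20 points for YNH/ON1/ON3). Group
parameters (slope 20/18/11, noise sd 4/5/8) are free defaults chosen
so that ON1 anchors are the session minimum without maskers, ON3
down-rates masked references, and ON3 test–retest reliability is
lower; they are not fits to any measured rating data.

## Problem sizes and numerics

Staircase statistics use 200 tracks per condition; BRIRs are ~1.2·T60
long (about 0.6 s and 1.9 s); THD uses one second of steady state;
spectral oracles use Welch averaging over 2–8 s signals and up to 50
seeds. All randomness flows through `numpy.random.Generator` seeded
from explicit integers; the acceptance script derives all of its
streams from a single `--seed`. Zero-phase FFT filtering is used where
a transfer magnitude must be hit exactly (ripple); minimum-phase FIRs
where causality matters (compensation).

## Known limitations

- No cochlear model: supra-threshold effects of hearing loss enter
  only through observer thresholds and rating parameters, not through
  the audio path.
- The spherical-head model has no pinna or torso cues; elevation is
  ignored in the ITD/ILD computation beyond the geometric path length.
- The FDN tail is frequency-flat (matching the flat Eyring solution);
  real rooms decay faster at high frequencies.
- Rating scores are integers; a continuous scale would change nothing
  in the statistics here but may matter for fine-grained reliability
  analyses.
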