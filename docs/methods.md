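# Methods

This note documents the models, defaults and design choices behind
`mouseeg`, in the spirit of a methods appendix: what is simulated, what is
estimated, which knobs matter, and what the synthetic benchmarks do and do
not demonstrate about real recordings.

## Signal model of the synthetic generator

A session is a two-channel (EEG, EMG) recording sampled at 1000 Hz. The
EEG background of each vigilance stage is Gaussian noise with one-sided
power spectral density

    S(f) = 10^b · f^(−χ)  +  Σ_k (A_k²/2) · N(f; c_k, σ_k²)      [µV²/Hz]

synthesized by spectral shaping of white noise per same-stage run. The
aperiodic term matches the model fitted downstream (offset `b` in
log10 µV²/Hz at 1 Hz, exponent `χ` dimensionless); each oscillatory peak
contributes exactly `A²/2` µV² of band power, the power of a sinusoid of
amplitude `A`. Power outside 0.5–100 Hz is zeroed, emulating the
acquisition bandpass; this keeps the 1/f model integrable so epoch variance
matches the PSD integral. EMG is white noise at a stage-dependent RMS.

Stage defaults (chosen once as rodent-typical; all config-exposed):

| stage | b (log10 µV²/Hz) | χ | peaks (c Hz, A µV, σ Hz) | EMG RMS (µV) |
|-------|------------------|-----|--------------------------|--------------|
| WAKE  | 2.0 | 2.0 | (7, 5, 1), (40, 2, 5)  | 40 |
| NREM  | 2.5 | 2.5 | (2, 20, 0.6), (40, 2, 5) | 10 |
| REM   | 1.8 | 2.2 | (7, 14, 1), (40, 2, 5) | 5  |

These produce delta-dominated NREM (~380 µV² delta), theta-dominated REM
(θ/δ ≈ 2.4), a desynchronized wake spectrum, and a clear bimodal EMG
separation — the discriminative structure the staging cascade relies on.
Every stage carries a 40 Hz gamma peak so genotype gamma effects apply in
all states.

**Hypnograms** follow a semi-Markov chain WAKE → NREM → (REM with
probability q) → WAKE on 10-s epochs (the rodent scoring convention), with
geometric bout lengths (defaults: NREM 100 s, REM 60 s mean). The wake
bout mean is solved from the target NREM fraction, and q from the target
REM fraction (default 0.15 × NREM fraction), so expected stage fractions
equal their targets; infeasible targets raise an error. Candidate
sequences are redrawn from deterministic substreams until the realized
light-cycle NREM fraction is within a tolerance of the target (0.03 by
default; cohort builders use 0.005 so that injected fraction contrasts are
faithful at n=12). Sessions begin with exactly the requested sleep-onset
latency of wake.

**Spindles** are Hann-enveloped sinusoids at 9/11/13/15 Hz (default rates
2/3/2/1 per NREM minute, amplitude 12 µV, durations 0.8–1.6 s) inserted
during NREM via a refractory renewal process: at least 0.5 s of silence
separates events and the mean onset-to-onset interval equals 60/rate, so
the realized rate matches the nominal rate and distinct events are not
fused by an envelope detector that merges sub-0.3-s gaps. A pure Poisson
process was rejected because its collisions made a nominal 5/min rate
detectably ~15% lower. Durations below ~0.7 s would be truncated past the
detector's 0.5-s minimum (the 1.5×-median crossings of a raised-cosine
envelope span ~72% of the true duration), hence the 0.8 s lower default.

**ASSR sessions** present trains (1 s, randomized order, ≥1.5 s
inter-train silence) at 10–50 Hz; during a train a sinusoid at the
stimulation frequency with amplitude `gain × background RMS` is added. For
a Hann Welch window of length T, an on-bin sinusoid of amplitude A yields
a bin density of (A²/2)/ENBW with ENBW = 1.5/T, so the gain producing a
target evoked/baseline excess e at frequency f is
`A = sqrt(2·e·ENBW·S_bg(f))`; cohort builders calibrate the wild-type
excess to 3 (ratio ≈ 4) at every stimulation frequency.

**Oddball sessions** place 100 deviants among 900 standards by
stars-and-bars sampling (never two adjacent deviants), 0.75 s ISI. Each
event adds its condition's component sum — polarity-signed Gaussian bumps
P1 (+25 µV at 18 ms, σ 6 ms), N1 (−40 µV at 50 ms, σ 10 ms) and, for
deviants only, P3a (+60 µV at 180 ms, σ 35 ms) — to the ongoing
background. Component separations were chosen so each peak of the summed
template stays within 10% of its nominal amplitude. The 900/100 trial
counts follow the standard oddball design; tone acoustics are not
modelled.

**Genotype effects** are multiplicative scalings (`EffectConfig`): gamma
band power, spindle rate, entrainment gain, deviant P3a amplitude, NREM
fraction. The gamma effect is defined on the *model's* 30–50 Hz band
power: the generator solves for the peak-amplitude rescaling that changes
the analytic band power by exactly the requested factor, so the injected
ground truth equals the stated relative change. Spindle-rate effects thin
a candidate stream drawn at the shared wild-type base rate, making a
lower-rate cohort's events a strict subset of its pair's.

**Pairing (common random numbers).** Subject *i* of every genotype shares
one base seed; noise and event randomness flow through separate named
substreams, so amplitude-type effects leave the noise realization
untouched. Injected contrasts are therefore isolated from simulation noise
at n = 12/group, which is what makes the ±25% recovery bounds meaningful
at that cohort size. The analysis pipeline never sees seeds, effects or
ground truth.

## Sleep staging

Per 10-s epoch: log10 band powers (δ, θ, σ, γ), θ/δ ratio, EMG RMS and
normalized spectral entropy, from a Welch PSD (4 s window, 2 s overlap)
of the epoch. Classification cascade:

1. **WAKE** when log EMG RMS falls in the upper cluster of a two-cluster
   1-D k-means split (seeded at the 30th/70th percentiles), provided the
   cluster centers are at least a factor 2 apart. A fixed EMG quantile was
   rejected: it pins the labelled wake fraction at the quantile's
   complement regardless of the true fraction, so it can neither label an
   all-wake recording correctly nor track genotype differences in sleep
   amount. When the EMG distribution is unimodal the recording is treated
   as single-state: all wake if median EMG RMS exceeds the median EEG
   (δ+θ) RMS, otherwise staged from the EEG cascade alone.
2. **REM** among sleep epochs when θ/δ > 1.5 and sigma power lies below
   the median over sleep candidates (REM lacks spindle-band power).
3. **NREM** otherwise.

Labels are smoothed with a 3-epoch majority filter (ties keep the center
label) and REM immediately after WAKE is relabelled WAKE. At least 60
epochs are required; constant-feature inputs raise an error; all-zero
epochs are flagged and labelled WAKE by the smoother's neighbors.
Thresholds (θ/δ 1.5, separation factor 2) are config-exposed defaults.

"Asleep" in the sleep-onset score counts NREM and REM. The light cycle
defaults to the first 12 h of the session (the whole session if shorter).

## Spectral analysis

Resting-state PSDs average per-epoch Welch spectra (Hann, 4 s window, 2 s
overlap — declared defaults; the evoked analysis uses its own stated
parameters) over all epochs of a stage. Band power is the trapezoidal
integral of the density with interpolated band edges. Spectral entropy is
Shannon entropy of the probability-normalized density over 0.5–50 Hz
divided by log(#bins).

The aperiodic fit works in log10–log10 coordinates over 0.5–50 Hz: line
fit → detect up to 4 residual peaks above 2 SD (apex + half-maximum width
seed a Gaussian refined by least squares) → refit the line on bins at
least 2.5σ from any peak; two refinement passes. The fixed (knee-free)
form is used since only an exponent is reported downstream. Optimizer
failures fall back to moment estimates and flag the fit rather than
raising. On peaked spectra the recovered exponent is an *effective* slope
over the fit range and need not equal the generating χ of one stage.

The Tort modulation index uses 18 phase bins, phase from the analytic
signal of the slow band and envelope of the fast band (defaults δ/θ →
γ, config-exposed); MI = (log N − H(P))/log N ∈ [0, 1].

## Spindle detection

Bandpass center ±1 Hz (4th-order Butterworth, forward–backward), analytic
envelope, 0.2-s moving RMS; candidates where the envelope exceeds 3× the
NREM median, boundaries extended to the 1.5× crossings, merged below
0.3 s gaps, kept at 0.5–3.0 s fully inside NREM. Median-relative
thresholds make detection invariant to amplitude rescaling across
subjects. The ±1 Hz bandwidth keeps the four reported center frequencies
disjoint. Density divides event count by light-cycle NREM minutes.

On Gaussian 1/f background the detector produces a small false-positive
density (≈0.3/min at default settings, bounded below 0.5/min in tests).
Because false positives add equally to both cohorts of a contrast, a
relative rate reduction is attenuated by roughly `FP/(rate+FP)`; with the
default 3/min insertion rate an injected 25% reduction is recovered around
20–23%, within the ±25% recovery tolerance the benchmarks use.

## Evoked analyses

Epoching slices −0.5–1.0 s (ASSR) or −0.1–0.4 s (ERP) around events;
trials crossing the recording edges are dropped and counted; ERP trials
are baseline-corrected to the −50–0 ms mean (a short pre-stimulus quiet
span, standard for rodent auditory ERPs) and rejected above a 400 µV
absolute ceiling (config-exposed). The ASSR ratio averages per-trial Welch
PSDs (0.5 s window, 0.25 s overlap) within the evoked (0.2–1 s) and
baseline (−0.5–0 s) windows before taking the ratio at the bin containing
the stimulation frequency — averaging PSDs first has lower variance than
averaging per-trial ratios. ERP peaks: P1 = positive maximum in 10–50 ms,
N1 = negative minimum in 30–100 ms after P1, P3a = positive maximum in
100–300 ms after N1 (mouse-typical windows, config-exposed); extrema on a
window edge of a monotone segment, or on a flat waveform, are flagged
absent rather than reported.

## Group statistics

One-way ANOVA from between/within sums of squares with an F-distribution
p-value; Tukey HSD with `q = |m_i − m_j|/sqrt(MSW/n_h)` (harmonic-mean
n for unbalanced groups) and p from the studentized-range distribution
(evaluated by scipy's numeric integration). Zero within-group variance
with equal means raises a degenerate-input error. No correction is applied
across metrics or frequency bands — tests are reported per band/metric, as
is conventional for these phenotyping panels; this is a deliberate,
documented choice. Percent change is reported relative to the wild-type
group mean.

## Benchmark problem sizes

The recovery benchmarks use 12 subjects per genotype — the study design
scale — with 1-h (tests: 0.5-h) sleep sessions, ASSR sessions of ≥100
trains at the frequency of interest, and 900/100 oddball sessions;
property suites use 10-min single-stage sessions and 20-seed staging
ensembles. These sizes keep a full run in minutes on one CPU while leaving
the recovery estimates' simulation error well inside the ±25% tolerance
(the common-random-number pairing does most of that work).

## What the generator does not emulate

Real mouse EEG contains movement and chewing artifacts, electrode drift,
state transitions with ambiguous epochs, microarousals, circadian
structure beyond a light/dark split, volume-conducted cardiac signal, and
spindles with variable intra-event frequency and asymmetric envelopes.
None of these are modelled. Passing benchmarks therefore demonstrate the
*correctness* of the implementations against known ground truth — not that
the detector thresholds or staging rules are optimal for any particular
recording rig. The defaults are the package's declared operating point and
every threshold is exposed in configuration.

## Numerical conventions

Sample intervals are 0-based and half-open throughout; epoch k covers
`[k·L·fs, (k+1)·L·fs)` and trailing partial epochs are dropped. EDF export
quantizes to 16 bits over each channel's observed range (≤ 1 step
round-trip error) with 1-s records. Zero-phase filtering uses 4th-order
Butterworth sections applied forward–backward; no notch filter is applied.
All randomness flows from a single seed through named `SeedSequence`
substreams; fixed seeds reproduce sessions bit-identically. Welch
estimates use Hann tapers with constant detrending; a per-epoch
variance-vs-PSD-integral comparison fluctuates ±20% for 10-s epochs of
steep 1/f signals (few slow cycles per epoch), so Parseval calibration is
asserted on ensembles and long windows.
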