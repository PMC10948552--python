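# Methods

## Overview

The package implements a vocal-biomarker pipeline for mental-health
symptom-severity stratification: eight classical acoustic features are
extracted from a short (~30 s) mono speech recording, normalized against
reference distributions, and averaged into a 0–100 Mental Fitness Vocal
Biomarker (MFVB) score with a display category. Repeated scores from a
voice-journaling cohort are paired in time with questionnaire assessments,
and the association is quantified as relative risk (RR) of elevated
symptom severity per score category, with the Pay-Attention vs Excellent
RR Ratio as the primary statistic. A synthetic voice generator and a
cohort simulator provide ground truth for every stage, so the whole
pipeline is testable without clinical data.

## The eight vocal features

All extraction is closed-form signal processing; no learned models are
used anywhere.

| feature | definition | units |
|---|---|---|
| jitter | 100·mean\|T_{i+1}−T_i\|/mean(T) over pitch periods | % |
| shimmer | 100·mean\|A_{i+1}−A_i\|/mean(A) over cycle amplitudes | % |
| pitch variability | SD of log₂F0 over voiced frames | octaves |
| energy variability | SD of frame energy (dB) over speech frames | dB |
| vowel space | mean (F2−F1)² over voiced frames, ×10⁻⁶ | "MHz²" |
| phonation duration | mean phonation-segment length | msec |
| speech rate | syllable-nuclei count / 1.5 · 60 / duration | words/min |
| pause duration | median gap ≥ 100 ms between phonation segments | sec |

Jitter and shimmer are the *local* (first-difference) variants, computed
within contiguous voiced runs only, so period pairs never straddle a
pause or an intonational F0 jump. The exact feature formulas used by the
commercial app are not public; the local variants are the standard
reading of the feature descriptions, and the reference
interquartile bands are consistent with them.

The "MHz²" vowel-space unit is dimensionally ambiguous as printed; the
only scaling under which typical formant separations (500–700 Hz) land in
the published 0.33–0.43 band is mean squared separation in Hz² divided by
10⁶, which is the convention adopted here.

Speech rate cannot come from transcripts (journaling transcriptions were
not part of the study data), so a transcript-free proxy is used: local
maxima of the smoothed energy envelope inside phonation segments count as
syllable nuclei (at least one per segment), divided by a configurable
1.5 syllables/word.

## Signal-processing choices

* Frames: 40 ms length, 10 ms hop. F0 search range 60–400 Hz, voicing
  threshold 0.45 on the normalized autocorrelation. All configurable;
  defaults are Praat-like conventions.
* **F0 tracking** runs on the normalized autocorrelation of the *Hilbert
  envelope*, not the raw waveform. At the jitter magnitudes typical of
  the reference population (5–8%), cycle-to-cycle misalignment
  decorrelates the formant-carrying fine structure and the raw-waveform
  autocorrelation peak collapses; the envelope follows glottal-pulse
  positions and keeps the periodicity peak. Among near-best peaks
  (≥ 0.9 of the maximum) the smallest lag wins, guarding against
  period-doubling; a 5-point median filter over the voiced-frame F0
  sequence removes residual isolated octave errors. Parabolic
  interpolation gives sub-bin precision.
* **Formants**: audio is resampled to 10 kHz, pre-emphasized (0.97), and
  each voiced frame gets an order-12 autocorrelation-method LPC fit;
  complex root pairs with bandwidth < 400 Hz and center in (90, 4950) Hz
  are kept, the two lowest being F1 and F2. LPC formant estimates carry
  the classic harmonic-sampling bias at conversational F0 (~−35 Hz on the
  F1–F2 separation at F0 ≈ 120 Hz); this is inherent to the method and
  left uncorrected.
* **Cycle tracking** (for jitter/shimmer): each phonation segment is
  whitened by an inverse filter of two second-order resonators. A
  low-order LPC fit seeds the resonance parameters, which are then
  refined by sparse deconvolution — Nelder–Mead minimization of the L1
  norm of the residual, which is smallest when the residual collapses
  onto the glottal excitation pulses. Pulse instants come from the local
  residual centroid (sub-sample); per-cycle amplitude is the signed
  residual sum over a ±3-sample window, which stays linear in the pulse
  amplitude however the pulse splits across sample instants. The first
  and last cycle of each run are dropped (truncated analysis windows).
  The filter warm-up at each segment onset is blanked and the peak gate
  uses a robust quantile rather than the maximum.
* **Voice-activity segmentation** runs on a fine RMS envelope (15 ms
  window, 2.5 ms hop): detection at 10 dB above the 5th-percentile noise
  floor, boundary refinement to the crossing of the segment's own median
  level − 6 dB with the envelope window's overlap bias compensated
  analytically. Minimum phonation 50 ms; gaps ≥ 100 ms count as pauses,
  shorter gaps are articulatory. Utterances with no dynamic range fall
  back on the voicing track (all-speech vs all-silence).
* Degenerate inputs: audio < 1 s, sample rate < 8 kHz, and voiceless
  audio are rejected with distinct errors; an utterance with no pause at
  all substitutes a configured 0.1 s floor for the pause feature rather
  than failing. Per-feature failures are collected and reported together,
  never imputed silently.

## Score construction

Each feature x is normalized with a robust z-score built from its
reference 25th/75th percentiles (q25, q75): center m = (q25+q75)/2,
spread s = (q75−q25)/1.349 (normal-consistent IQR). The z is sign-flipped
for features that worsen with depression (jitter, shimmer, pause), pushed
through the standard normal CDF, and scaled to [0, 100]; the eight
subscores are averaged. A feature at its band midpoint scores 50; at its
adverse band edge, 25. Categories are half-open real intervals:
Excellent [80, 100], Good [70, 80), Pay Attention [0, 70); display
rounding plays no role.

The published description states only that normalized features are
averaged; this functional form is the package's own choice. It uses
exactly the published quartiles, is smooth, bounded and monotone, but
absolute scores need not match the commercial app's — orderings,
monotonicity and the category logic are what the tests pin down. The
missing-feature policy is strict by default with an opt-in
mean-of-available mode, flagged on the result.

## Pairing and risk statistics

Two association methods join an assessment at time t to session scores:

* *closest*: the single score with the smallest |Δt| ≤ 14 days (inclusive
  window, exact ties to the earlier session);
* *time-weighted*: every score within the window, weighted
  w_i ∝ max(0, 1 − |Δt_i|/14 d), normalized to sum to 1; a score exactly
  at the window edge gets weight zero. The weighted mean score is then
  categorized ("weighted-mean-then-categorize" — the natural reading of
  a weighted-average pairing).

Assessments with no in-window score are flagged unpaired and excluded
from tabulation; paired + unpaired always equals the assessment total.

For a domain, paired observations are cross-tabulated as score category ×
dichotomized severity (moderate/severe = elevated, normal/mild = lower).
Per category, RR = (a/n)/(a_ref/n_ref) against the whole cohort; the
primary statistic is the Pay/Excellent quotient, algebraically
(a₁/n₁)/(a₂/n₂) since the reference prevalence cancels. Confidence
intervals use the independent-groups log-scale standard error
SE = √(1/a₁ − 1/n₁ + 1/a₂ − 1/n₂) with z = 1.959964, and
p = 2Φ(−|ln RRR|/SE). The reference cohort *contains* each category, so
the independent-groups SE is an approximation — it is, however, the
convention under which the published intervals are reproduced exactly, so
it is adopted and stated rather than replaced. Zero cells make the
log-scale SE undefined: such estimates are returned flagged degenerate
(NaN interval) by default, with an optional Haldane-style +0.5 correction
that stays off unless requested. Subgroup analyses recompute the
reference prevalence within each level.

## Synthetic voice generator

Phonation is a glottal-pulse train: periods T_i = (1/F0)(1+ε_i) with
independent zero-mean Gaussian ε. The local jitter statistic of such a
sequence has expectation 2σ/√π, so σ = (target/100)·√π/2 makes the
*measured* statistic match the request; amplitudes are perturbed
analogously for shimmer. Pulses are split across adjacent samples to
preserve sub-sample timing, filtered through a cascade of two-pole
resonators (F1, F2), and modulated by a smooth Gaussian loudness envelope
(AR(1) on a 0.2 s grid, 2 s timescale, clipped at ±2 SD) whose marginal
SD is the energy-variability parameter. Pauses carry Gaussian noise 45 dB
below the phonation level — not digital silence — so activity detection
is exercised realistically; the assembled utterance keeps phonation RMS
≥ 40 dB above pause RMS and is peak-normalized.

The journaling-plan generator emits bursts of 3–5 syllable-scale
phonation segments (190–305 ms) separated by sub-pause articulatory gaps
(55–80 ms), with inter-burst pauses of 0.32–0.60 s; per-syllable F0 is
log-normal around the base F0 (SD 0.215 octaves) and vowel targets cycle
through a five-vowel F1/F2 inventory. Defaults (jitter 6.3%, shimmer
4.2%, energy modulation 8.2 dB) sit at the midpoints of the reference
interquartile bands, and the vowel-inventory separations (~640–665 Hz)
are set so the *extracted* vowel space lands mid-band given the known LPC
separation bias. Ground truth records the exact per-cycle period and
amplitude sequences, the segment table, and the analytically determined
features (pause median over gaps ≥ 100 ms, mean phonation duration,
duration-weighted pitch variability).

What the generator does not emulate: continuous F0 contours within a
syllable, consonants and frication, breathiness/aspiration noise,
room acoustics, device/codec coloration, and speaker identity. Passing
recovery tests therefore demonstrates correctness of the extractors on
signals whose generative structure matches their assumptions, not
robustness to real-world recording conditions.

## Cohort simulator

Defaults mirror the published study conditions: 104 participants,
engagement mix 38/33/29% (high/medium/low) with bounded session-count
draws averaging ≈21/12/3.5 (so realized counts always match their
engagement class), session times uniform over a 28-day window,
assessments at day 1 and — with probability 0.78 — day 28. Each
participant carries a daily AR(1) latent severity trajectory (lag-1-day
autocorrelation 0.97, stationary N(0,1)). Session scores are
baseline − coupling·severity + noise (defaults 76, 6, 9, clipped to
[0, 100]). Questionnaire categories come from thresholding a per-domain
latent that loads on the shared trait (loadings 0.9/0.8/0.6/0.6/0.45 for
total/depression/anxiety/PTSD/bipolar), with moderate thresholds set by
target elevated prevalences 62/46/26/25/8% and the severe level taking
the upper 40% of the elevated mass. Coupling = 0 gives an exact null for
calibration checks; positive coupling produces RR Ratios above 1, larger
under time-weighted pairing than closest pairing because averaging
suppresses session-level score noise — reproducing the qualitative
mechanism the study reports.

Simulation-based checks in the test suite use 200 participants and 50
replicates, sizes at which the null-coverage and directional properties
are stable while the suite stays fast.

## Known limitations

* Absolute MFVB scores are calibrated to the published quartiles, not to
  the commercial implementation; only relative statements transfer.
* The sparse-deconvolution whitening assumes two dominant resonances; on
  real wideband speech more resonators (configurable) may be needed.
* The bipolar time-weighted Pay-Attention cell in the published table
  contains a zero count yet prints finite estimates; whatever correction
  produced them is unstated, so this package reports that configuration
  as degenerate rather than guessing.
* Engagement-stratified ratios depend on unpublished per-category counts
  and are exercised only on simulated cohorts.
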