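# mfvb — Mental Fitness Vocal Biomarker toolkit

Voice carries measurable correlates of mental-health symptom burden:
vocal-cord instability (jitter, shimmer), flattened prosody (pitch and
energy variability), reduced articulatory range (vowel space), and
altered timing (phonation duration, speech rate, pauses). This package
implements a complete vocal-biomarker pipeline around those eight
features, for researchers who want to study how a composite voice score
stratifies questionnaire-reported symptom severity in longitudinal
voice-journaling cohorts — and to test every stage against synthetic
ground truth, since clinical audio is rarely shareable.

The pipeline:

1. **acoustics** — extract the eight features from a ~30 s mono WAV with
   classical DSP (autocorrelation F0, LPC formants, inverse-filtered
   cycle tracking, energy-based voice-activity segmentation).
2. **scoring** — normalize each feature against reference quartiles with
   a robust z-score, map through the normal CDF, and average into the
   0–100 MFVB score: Excellent (80–100), Good (70–79), Pay Attention
   (0–69).
3. **study** — pair repeated scores with assessments, either the single
   *closest* score within ±14 days or a *time-weighted* average with
   weights decaying linearly to zero at 14 days.
4. **riskstats** — per score category, the relative risk of elevated
   (moderate-or-severe) symptoms versus the cohort,

   RR = (a/n) / (a_ref/n_ref),

   and the primary endpoint, the Pay-Attention vs Excellent **RR Ratio**
   with 95% CI from the log-scale standard error
   SE = √(1/a₁ − 1/n₁ + 1/a₂ − 1/n₂) and a two-sided normal p-value.
5. **voicesim / study.simulate_cohort** — glottal-pulse speech synthesis
   with exact per-cycle ground truth, and a latent-severity cohort
   simulator, so parameter recovery and endpoint calibration are testable
   end to end.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Synthesize a journaling-style utterance, extract features, and score it:

```bash
$ mfvb synth --duration 30 --seed 7 --out u.wav
$ mfvb extract u.wav --out f.json
$ mfvb score f.json
{
  "score": 52.18885819762848,
  "category": "pay_attention",
  "subscores": {
    "jitter_pct": 51.224304809644806,
    ...
  }
}
```

The extracted features (jitter 6.28%, shimmer 4.69%, pitch variability
0.208 oct, ...) all sit near their reference-band midpoints, so every
subscore lands near 50 and the composite is 52.2 — just below the Good
boundary, hence "pay_attention".

Simulate a cohort, pair, and analyze:

```bash
$ mfvb --verbose simulate --seed 1 --sessions-out s.csv --assessments-out a.csv
{"n_participants": 104, "n_sessions": 1380, "n_assessments": 177, ...}
$ mfvb --verbose pair --sessions s.csv --assessments a.csv \
    --method time_weighted --out p.csv
paired 175/177 assessments (time_weighted)
$ mfvb analyze --paired p.csv --domain total
```

The report lists, per score category, the elevated/lower counts and RR
with 95% CI, and the Pay/Excellent RR Ratio (2.91 for this seed, p <
0.001): participants whose paired scores fall in the Pay-Attention range
are about three times as likely to report elevated symptoms as those in
the Excellent range. The same machinery runs on real session/assessment
CSVs with columns `participant_id, timestamp, mfvb_score` and
`participant_id, timestamp, total, depression, anxiety, ptsd, bipolar`.

From Python:

```python
from mfvb import extract_feature_vector, score_features, read_wav

features = extract_feature_vector(read_wav("u.wav"))
result = score_features(features)
print(result.score, result.category)
```

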