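# dyadspeech

Quantitative analysis of conversational speech in dyadic clinical
interviews: prosodic statistics, blockwise (TAMA) synchrony between
interlocutors, turn-taking and pause features, cohort-level group
statistics, and feature-subset classification/regression against symptom
scores.

The package targets semi-structured interviews between a participant and
an administrator (e.g. an ADOS "Emotions" activity), where speech has
been segmented into **inter-pausal units** (IPUs): one speaker's speech
intervals bounded by silences longer than 200 ms. From IPU timelines and
frame-level prosodic tracks it derives 13 per-participant speech
features and the downstream group analyses. Because such recordings are
rarely shareable, a synthetic dyad generator with known ground truth
stands in for real sessions, so the entire pipeline is testable end to
end.

## The measures

Let `f0[i]` and `J[i]` be the natural-log fundamental frequency and the
intensity (dB) at frame *i* (10 ms frame shift), computed only within a
speaker's own non-overlapping IPUs. Per session the package computes:

- **Overall prosody** — mean and population SD of log F0 over voiced
  frames; population SD of intensity (the intensity *mean* is excluded:
  it depends on the unknown microphone distance).
- **TAMA blockwise statistics** — the time-aligned moving average
  represents a track by block means
  `x_B[k] = mean{ x[i] : i in block k }` over 16 s windows hopped by
  8 s. The SD of `x_B` captures slow prosodic modulation; the Pearson
  correlation `r_xy` of the two speakers' paired block means quantifies
  prosodic **synchrony** (entrainment).
- **Turn-taking gaps** — the signed latency from the end of an
  administrator utterance to the participant's next utterance; negative
  when the answer starts before the question ends. Fully overlapped
  utterances (backchannels) are excluded.
- **Pause-to-turn ratio** — total silence inside the participant's
  speaking turns divided by total turn duration, with turns delimited by
  utterances longer than 0.5 s.
- **Speech rate** (morae per second of actual speech) and speaking-time
  statistics.

Cohort analyses mirror the study design: Kolmogorov–Smirnov normality
screening; log transforms of the skewed turn-taking features (shifted so
the cohort minimum maps to log 1 for the mean gap); two-sided F tests on
variances and t tests on means with Benjamini–Hochberg correction per
family; the distance-from-TD-mean transform `|x − m_TD|` for features
that differ in spread but not location; and Pearson/permutation
correlations with symptom scores. Classification (ASD vs TD) and score
regression use linear SVMs with inverse-class-size weighting, evaluated
by leave-one-out cross-validation, including an exhaustive search over
all `2^13 − 1 = 8191` feature subsets.

## Worked example

```python
import dyadspeech as ds

cfg = ds.DyadSimConfig(seed=7)                      # one ~8 min interview
timeline, tracks, truth = ds.simulate_session(cfg)
vec = ds.assemble_features(
    timeline,
    tracks["participant"]["f0"], tracks["participant"]["intensity"],
    tracks["administrator"]["f0"], tracks["administrator"]["intensity"],
)
print(f"questions answered: {len(ds.turn_taking_gaps(timeline))}")
print(f"mean log F0:          {vec.mean_log_f0:.3f}")
print(f"mean turn gap:        {vec.mean_turn_gap_s:+.3f} s")
print(f"pause-to-turn ratio:  {vec.pause_to_turn_ratio:.3f}")
print(f"intensity synchrony:  {vec.corr_block_intensity:+.3f}  (generator rho = {truth.rho})")
```

prints

```
questions answered: 121
mean log F0:          4.788
mean turn gap:        -0.176 s
pause-to-turn ratio:  0.051
intensity synchrony:  +0.224  (generator rho = 0.34)
```

i.e. an adult-male pitch around 120 Hz, answers that on average begin
0.18 s *before* the question ends (typical for Japanese conversation),
5% silence inside turns, and moderate loudness synchrony whose
single-session estimate (+0.22) scatters around the generating coupling
(0.34).

Cohort-level work follows the same pattern:

```python
cohort, truths = ds.simulate_cohort(n_asd=62, n_td=17, seed=5)
table = ds.comparison_table(cohort)          # F/t tests, B-H adjusted
d3 = ds.run_setting(cohort, "D3")            # exhaustive 8191-subset search
r4 = ds.run_setting(cohort, "R4", domain="reciprocity")
```

A command-line interface wraps the same steps
(`dyadspeech simulate | features | compare | classify | regress`).

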