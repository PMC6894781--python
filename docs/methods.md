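# Methods

This note documents the models, conventions and numerical choices behind
`dyadspeech`, and what the synthetic generator does and does not emulate.

## Session model

A session is two speakers' inter-pausal units (IPUs) on a common clock.
Times are seconds from session start; intervals are half-open
`[start, end)`, and every frame is assigned by the membership of its
*center* in an interval — this makes frame bookkeeping exact at
boundaries (no double counting where an IPU ends exactly on a frame
center). Speech intervals of one speaker separated by silences of at
most 200 ms are merged into a single IPU (a silence of exactly 200 ms
merges; only *longer* silences split). Merging is idempotent and can
only absorb silence, never discard speech. Mora counts are summed across
merged intervals and dropped if any part lacks one.

## Prosodic tracks

Log-F0 and intensity are frame series (10 ms shift) with a validity
mask. F0 is analyzed on the **natural-log** scale: session means near
4.8 correspond to ≈120 Hz, an adult male voice. The two-pass pitch
procedure runs a pluggable detector once with a wide fixed range
(32–200 Hz), then re-runs it with the floor at 0.75× the 25th percentile
and the ceiling at 2× the 75th percentile of the voiced pass-1 values.
"Lower/upper quantile" is interpreted as the quartiles with numpy's
linear-interpolation estimator; both quantiles and multipliers are
configurable, and a manual floor/ceiling override bypasses adaptation
entirely (for voices the adaptation fails on). The pitch detector itself
is a backend contract, not part of this package: any callable returning
per-frame F0 in Hz with unvoiced frames as NaN works (a Praat binding,
e.g. parselmouth, is the natural choice). The canonical pipeline path
consumes precomputed frame-track CSVs, so no audio stack is needed.

Intensity is the windowed mean square (32 ms window) in dB re (20 µPa)²;
the reference only shifts the scale and cancels out of every downstream
use (SDs and correlations).

Frames are kept only where the speaker is talking: a frame is valid iff
it was valid in the raw track, its center lies in one of the speaker's
own IPUs, and (by default) not inside any other-speaker IPU — overlapped
speech is excluded from all prosodic statistics.

## Overall and blockwise statistics

All session-level SDs are **population** SDs (divide by N): the session
is the entire population of its frames/blocks, and one convention is
used consistently for frames, blocks, speaking times and gap series.

The TAMA (time-aligned moving average) representation uses 16 s blocks
hopped by 8 s from t = 0, enumerated until the session end; block k
averages the valid frames with centers in `[8k, 8k + 16)` seconds.
Blocks with no valid frame are skipped — not imputed — for both the
blockwise SD and the synchrony correlation, and the correlation uses
only blocks where *both* speakers have at least one valid frame. With
fewer than two common blocks, or a constant series, synchrony is
reported as undefined rather than zero (zero would fabricate evidence of
asynchrony).

Undefined features generally propagate as explicit missing values with a
recorded reason (e.g. "no turn-taking gaps"); nothing is silently
zeroed, and the feature-table CSV writes empty cells plus a sidecar
reason column.

## Turn-taking

A gap event is emitted for each participant utterance that directly
follows administrator speech; the gap is measured from the administrator
IPU with the latest end among those starting earlier, so a response that
begins before the question ends yields a negative gap. Utterances fully
contained in the other speaker's utterance are treated as backchannels:
contained participant IPUs yield no gap event, and contained
administrator IPUs do not break the participant's floor. Turns start at
an utterance longer than 0.5 s and end at the holder's last utterance
before the other speaker's next above-threshold utterance; time occupied
by the other speaker's sub-threshold interjections inside a turn counts
as the holder's pause (it is not the holder's speech). The
pause-to-turn ratio is pooled over the session (total pause over total
turn time), not a mean of per-turn ratios.

## Group statistics

The mean turn-taking gap, its SD, and the pause-to-turn ratio are
right-skewed; they are log-transformed at the cohort level. The mean gap
can be negative, so it is shifted so the pooled-cohort minimum equals 1
before the log (the transformed minimum is 0). A zero pause-to-turn
ratio has no defined log; the pipeline marks it undefined rather than
imputing, while the strict transform API raises naming the participant.

F tests use the sample-variance ratio with a two-sided p (twice the
smaller tail); t tests default to Welch (variance inequality between the
groups is itself a finding here), with the pooled variant selectable.
Benjamini–Hochberg correction is applied within the 13-test F family and
within the 13-test t family separately (a pooled 26-test family is an
option). KS normality screening defaults to the classical one-sample
test with estimated moments; a Lilliefors-corrected mode is available
and results record which ran. Permutation p-values use
`(1 + hits) / (1 + n_perm)` with a seeded generator (default 10 000
permutations), so they are reproducible and never exactly zero.

For features whose groups differ in spread but not location, the
distance transform `|x − m_TD|` maps both unusually high and unusually
low values to large scores before correlating with symptom severity.

## Classification and regression

Models are linear-kernel SVMs (C = 1) and epsilon-SVR (ε = 0.1).
Classification weights each class's errors inversely to its size
(w_c ∝ 1/n_c, implemented as n/(2 n_c)), compensating the 62/17
imbalance. Features are standardized with training-fold statistics only;
without scaling, margin solutions depend on arbitrary feature units.
Evaluation is leave-one-out: each participant is predicted by a model
trained on the other n − 1.

Subset selection evaluates the LOOCV criterion (accuracy, or RMSE for
regression) for every non-empty subset of the 13 features and is
deliberately *outside* the folds, reproducing the original selection
procedure — the winning subset's criterion is therefore optimistically
biased as an estimate of generalization. Ties break toward smaller
subsets, then lexicographic bitmask, making rankings deterministic.
Because a full search performs ~650 000 tiny SVM fits, the engine calls
scikit-learn's low-level libsvm binding directly (identical solver,
~20× less per-call overhead); the public SVC/SVR path is retained as a
fallback and the test suite asserts exact agreement between the two on
random problems. The ASD class is positive for precision/recall/F (this
convention, not TD-positive, is consistent with the reference metric
values). Regression metrics (Pearson r, MAE, RMSE) are computed on the
pooled LOO predictions; r is undefined (and flagged) when predictions
are constant.

## The synthetic dyad generator

`simulate_session` emulates a structured question/answer interview:
~2 s administrator questions; participant response latencies drawn from
a shifted lognormal (shift −1.2 s) so that roughly 60% of typical
responses begin before the question ends; answers as chains of lognormal
IPUs (mean 1.5 s, SD 1.2 s) with within-turn pauses; and short (<0.5 s)
backchannels placed strictly inside the other speaker's utterances so
the exclusion rules are exercised. Defaults describe a typically
developing participant; group-level shifts (`DEFAULT_EFFECTS`) move the
ASD group in the directions of the reported contrasts — longer and more
variable gaps, more within-turn pausing (TD ratio ≈ 0.04, ASD ≈ 0.10),
weaker intensity synchrony, flatter blockwise intensity, and a wider
across-participant spread of the blockwise log-F0 SD. The per-person
pause rate is floored above zero: a participant who never pauses would
have a pause-to-turn ratio of exactly 0, for which the cohort log
transform is undefined.

Prosody is generated at the block scale, matching what the synchrony
statistic measures: a stationary AR(1) latent z (φ = 0.4) per prosodic
dimension, piecewise constant over 8 s segments, drives the
administrator (`a = μ_a + σ_a z`) while the participant follows
`p = μ_p + σ_p (ρ z + √(1−ρ²) ε)` with an independent AR(1) ε — so the
expected blockwise correlation between the speakers equals ρ. Frame
values add white noise; with ~800 frames per block the noise contributes
negligibly to block means. Two attenuations of the *measured* synchrony
are inherent and documented rather than corrected: (i) restricting
frames to each speaker's own IPUs reweights a block's two latent
segments speaker-specifically, which caps the measured correlation near
0.92 even at ρ = 1; (ii) the correlation of overlapping block means of
coupled AR(1) segments equals ρ in expectation, but finite sessions
(~59 blocks) scatter single-session estimates by ≈0.1. The recovery
check therefore compares the *mean* over 50 sessions against ρ with a
0.1 tolerance, which holds across ρ ∈ {−0.5, 0, 0.3, 0.65}.

Ground truth records exactly what was drawn; with backchannels disabled
the pipeline's gap statistics and pause-to-turn ratio agree with the
generator's bookkeeping to 1e-9 (exact bookkeeping, not a statistical
match).

What the generator does **not** emulate: lexical content and fillers,
microphone/channel effects, F0 microprosody (declination, accent), rater
noise in symptom scores beyond a simple latent-plus-noise model, and
within-session nonstationarity of turn-taking. Both prosodic dimensions
share a single coupling ρ, so simulated cohorts also show a (weaker)
group difference in log-F0 synchrony — a place where the simulator is
deliberately simpler than real data, where loudness and pitch
entrainment can dissociate. Passing tests demonstrate that the
*measurement and inference machinery* is correct under known ground
truth, not that real cohorts behave like the generator.

Symptom scores are integers driven by each participant's latent gap,
pause and synchrony parameters plus noise (ASD reciprocity centered at
8.9, SD ≈ 2), so score regressions have a recoverable signal.

## Problem sizes and determinism

Statistical calibration (null false-positive rates over 500 cohorts)
uses a feature-level cohort generator — a documented synthetic stand-in
that draws the 13 features directly from realistic marginals — because
the calibration exercises `comparison_table`, not the session pipeline.
Power and search checks run the full session pipeline: five cohorts at
the study size (62/17, 8-minute sessions) for detection, and complete
8191-subset searches for the dominance check (the exhaustive winner's
criterion can never be below the full feature set's, since the full set
is itself one of the candidates). Every stochastic component takes an
explicit seed; identical seeds reproduce sessions byte-for-byte.

## Known limitations

- The manual-annotation clause that IPU boundaries never split a word
  cannot be enforced without transcripts; only the 200 ms rule is
  implemented, and mora counts are trusted inputs.
- Whether a "gap anchor" should be the administrator's single IPU with
  the latest end or the merged chain is ambiguous for fragmented
  questions; the single-IPU rule is default and the merged alternative
  is a flag (`merge_admin_ipus`).
- Subset selection shares data with evaluation (see above); treat
  selected-subset metrics as descriptive, not as unbiased performance
  estimates.
- The two-pass pitch procedure's behaviour depends on the external
  detector's voicing decisions; the contract constrains only the output
  range and frame grid.
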