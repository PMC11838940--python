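# Methods

## Model and assumptions

`teco` predicts a binary ICU endpoint (death vs non-death) at a fixed
horizon h from the most recent window of monitoring data.  The unit of
analysis is the *encounter* (one ICU admission); all timestamps are minutes
since ICU admission, so wall-clock ingestion requires pre-subtracting the
admission time.  The model assumes:

- the seven monitored variables (temperature, respiration rate, SpO2,
  mSOFA, mSOFA respiratory sub-score, SF ratio, BMI) are noisy observations
  of a piecewise-smooth patient state, so a 15-minute interval mean with
  last-observation-carried-forward completion is an adequate summary;
- baseline covariates (age, sex, race, ethnicity, optional baseline BMI)
  are static over the encounter;
- only data at or before the prediction anchor may influence a prediction
  (enforced structurally: windows are built solely from measurements with
  t ≤ anchor, and this is property-tested).

### Preprocessing

Per variable, records are averaged within half-open intervals
[15k, 15(k+1)) minutes, k ≥ 0 anchored at admission (the interval
convention is a package choice).  Interior empty intervals inherit the
previous interval's value (observed = false).  Variables are joined on a
shared interval index running from the first observation of *any* variable;
a variable's leading gap (before its own first observation) is filled with
its training-split median and masked — carry-forward is only defined for
interior gaps, and a median fill avoids sentinel values while keeping the
sequence dense.  Trailing gaps carry the last value forward.  Sequences
contain no intervals before the first observation, so long unmonitored
stretches are not imputed.

Continuous features (the seven variables, age, continuous baseline BMI) are
z-scored with statistics learned on the training split only and recorded in
the `FeatureSchema` for exact reproducibility.  Categorical baselines are
one-hot blocks with explicit Unknown levels: sex (3), race (4),
ethnicity (3), WHO BMI class (5), giving a 17-wide baseline block and a
24-dimensional per-interval feature vector.  The block composition is
configurable; only the total width is pinned by the reference parameter
count.

### Windows

- *Training policy*: one window per encounter, anchored h hours before its
  endpoint, labelled with that endpoint.  Encounters whose anchor falls
  at/before admission, or with no pre-anchor data, are dropped (a retained
  encounter with zero measurements is excluded from windows only).
  Incomplete lookbacks are allowed: the window simply holds fewer
  intervals.
- *Rolling policy* (external-validation style): windows at caller-chosen
  anchors after admission; the label is death within (anchor, anchor + h];
  encounters whose outcome precedes the anchor are excluded.

The default lookback is 96 h for every horizon and is configurable per
call; the scaled-down fixtures use 6–24 h lookbacks (below).

### Network

Affine embedding R^F → R^512, plus a parameter-free sinusoidal encoding of
the anchor-relative interval offset (relative positions are added to the
embedding; a learned relative-attention bias is deliberately not used, to
stay consistent with the reference parameter count).  Six post-norm
encoder layers — multi-head attention (8 heads) and a GELU feed-forward
block of width 2048, each followed by residual + layer norm — with no final
stack norm; this post-norm/no-final-norm layout is required for the closed
form

    params = F·d + d
           + L·[(3d² + 3d) + (d² + d) + (d·d_ff + d_ff) + (d_ff·d + d) + 4d]
           + d·C + C

to equal 18,928,130 at L=6, d=512, d_ff=2048, F=24, C=2.  d_ff = 2048 is
the conventional 4×d ratio and is the unique conventional choice consistent
with that count.  Sequence pooling takes the encoder output at the anchor
position (most-recent-state semantics); mean pooling is available behind a
config switch.  The head is affine to 2 logits under a softmax.

The numerical core is a small tape-based reverse-mode autodiff engine on
numpy (float64) written for this package; every operation's backward pass
is checked against central finite differences in the test suite, and the
full model gradient is spot-checked the same way.

### Optimization

Cross-entropy loss (the canonical choice for a softmax head), SGD with
momentum 0.9, lr(epoch) = 0.01 · 0.5^⌊epoch/50⌋, batch size 32 with
per-epoch reshuffling under the run seed (last partial batch kept), global
gradient-norm clipping at 1.0, at most 500 epochs.  Early stopping is
operationalized as max − min of the trailing 100 validation losses ≤ 1e-4
(the plain-language rule "did not change by more than 1e-4 after 100
epochs" is ambiguous between absolute change and best-improvement; the
max−min reading is implemented).  The returned weights are those of the
best validation epoch.  No class re-weighting is applied: the generator's
~36% death prevalence is treated as already balanced.  Splitting is
repeated 80/20 holdout at the encounter level (20 splits by default), each
split an independent uniform permutation from a spawned seed sequence; a
single run seed fans out deterministically to split/init/bootstrap/
simulation sub-seeds.

### Evaluation

AUC is the Mann–Whitney statistic with ties counted one half.  CIs are
percentile 2.5/97.5 over 500 whole-dataset bootstrap resamples (encounter
level, not outcome-stratified; single-class resamples are redrawn).
Correlated AUCs are compared with the fast DeLong structural-components
test (two-sided normal p; zero-variance differences report p = 1).
Internal validation reports the median AUC across splits (min/max also
available).  Rolling evaluation flags single-class anchors as undefined
rather than failing.  Probability trajectories group encounters by eventual
outcome and report mean ± 1.96·SE across encounters.

### Comparators and importance

Tree baselines consume the same windows flattened to last/mean/min/max per
variable plus the baseline block (width 45 by default); a raveled-grid
variant exists behind a flag.  Tree hyperparameters are library defaults
with documented overrides (RF 200 trees; XGBoost 200 trees, depth 4,
lr 0.1).  The proprietary-index comparator is fit-free: score = mean index
over the preceding 24 h, ROC swept over the observed score range.

Elimination importance retrains the model with one variable removed from
the schema (feature_dim F−1, i.e. exactly one embedding column = d_model
fewer parameters) on the same splits with the same seeds as the full model
(variance reduction); the per-split importance is the signed AUC difference,
summarized by the median.  The ablation contrasts full vs
time-dependent-only models per family.

## Synthetic generator

Each encounter draws baseline covariates (age normal; sex/race/ethnicity/
BMI mixes patterned on a development-style ICU population), a latent
severity z ~ N(0,1), and a death indicator from a logistic model on
standardized age, male sex and z, with the intercept bisected so the mean
death probability hits the target prevalence (0.359 by default).  Stay
length is log-normal (median 96 h, σ=0.6 by default; the endpoint — death
or discharge — ends the record).  Measurement times per variable are
independent Poisson processes over the stay; values are a personal level
(population mean + between-encounter spread) plus observation noise.
Dying encounters deteriorate: each signal-bearing variable drifts toward
abnormal with a slow whole-stay component (15% of the terminal rate) plus a
terminal linear ramp over the final τ = 48 h before death (SF ratio and
SpO2 downward; mSOFA, its respiratory sub-score, respiration rate and
temperature upward; BMI carries no signal).  Healthy ranges follow clinical
convention (SF ratio ~380±40, SpO2 ~96.5, temperature ~37 °C) purely for
realism.

What the generator does *not* emulate: measurement artifacts and device
error spikes, informative sampling (sicker patients measured more often),
competing discharge dynamics, inter-variable physiological correlation
beyond the shared drift, or any distributional fidelity to a real cohort.
Passing tests therefore demonstrate that the pipeline recovers planted
signal under its own assumptions, not clinical performance.

Presets: `strong-signal-small` (n=300, 3× drift, short stays),
`null` (no drift, no baseline effects, no latent coupling),
`baseline-only` (signal only in age/sex), `table1-like` (n=2579,
development-scale mixes, sparse sampling).  A generic score series for the
threshold comparator can be derived from latent severity and drift
progress.

## Scaled-down study sizes

The slower end-to-end checks run deliberately small so the whole suite
executes on one CPU in minutes; these sizes are package choices:

- signal recovery: tiny model (2 layers, 2 heads, d=32, d_ff=64), 12-h
  lookback, ≤12 epochs, n=300; the null check scores an independent
  n=1000 null cohort so it measures model bias rather than the binomial
  noise of a ~60-encounter split;
- rolling trend: 5 seeds, anchors 24/48/72 h, independent n=400 test
  cohorts, drift at its default scale (the amplified preset saturates AUC
  at every anchor, which would make a trend unmeasurable);
- importance: 5 seeds × 3 splits, 1-layer d=16 model, 6-h lookback,
  7 epochs, a single planted variable (SF ratio);
- bootstrap coverage: 1000 binormal datasets at n=500, true AUC 0.75.

## Numerical choices and degenerate inputs

float64 throughout; attention masking uses a −1e9 additive bias, which
underflows to exactly zero attention on padded keys, so padding is exactly
output-neutral at real positions.  Layer-norm ε = 1e-5.  Glorot-uniform
init from a per-model seed; two builds with one seed are bitwise identical,
and training is deterministic given (seed, data).  Ties in AUC are handled
by midranks (scipy `rankdata`); age quartiles use linear interpolation.
Single-class label vectors raise explicit degenerate-label/undefined-AUC
errors (training, tree fits, AUC); empty binning input returns an empty
frame; rolling anchors beyond every stay yield a flagged-undefined result.
Checkpoints embed config + feature schema + a schema hash and refuse to
load against a mismatched schema.

## Known limitations

- The transformer runs on a numpy autodiff core: fine at fixture scale,
  not intended for GPU-scale training of the full 18.9M-parameter model.
- Relative position enters additively as a sinusoidal encoding; attention-
  bias style relative encodings are out of scope.
- The proprietary-index comparator stands in for closed-source scores via a
  generic score series; no attempt is made to reproduce any vendor's index.
- mSOFA and SF ratio are consumed as inputs, never derived from raw labs.
- Horizon 0 is supported under the training policy (predict at the
  endpoint); under the rolling policy it is degenerate by construction and
  reported as undefined.
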