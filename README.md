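# teco

Transformer-based, encounter-level prediction of ICU mortality from
irregular continuous-monitoring EHR streams.

## The problem

ICU devices stream vital signs and severity scores at irregular, per-variable
paces (a respiration rate every few minutes, an mSOFA score a few times a
day).  `teco` implements an encoder-only transformer that consumes these
streams together with static baseline covariates and predicts a binary
endpoint — death vs non-death in the ICU — at a fixed horizon h ∈ {0, 12,
24, …, 96} hours ahead of the prediction time, one sub-model per horizon.
It is aimed at methods researchers in clinical risk modelling who need the
full training / evaluation / comparison / importance pipeline to run
end-to-end on synthetic data, with no access to protected cohorts.

## The model

Each monitored variable x_v(t) is averaged within 15-minute intervals
aligned to ICU admission; empty interior intervals carry the previous value
forward (LOCF).  At a prediction anchor t₀, the most recent 96 h of
intervals form a sequence of feature vectors u_k ∈ R^F (F = 24 by default:
7 z-scored time-dependent variables + a 17-wide encoded baseline block held
static across the sequence).  The network computes

    h_k = W u_k + b + PE(|k − k₀|)        (affine embedding, d = 512,
                                           sinusoidal relative positional
                                           encoding of the interval offset)

followed by 6 post-norm transformer encoder layers (8 attention heads,
feed-forward width 2048, GELU, dropout 0), anchor-position pooling and an
affine 2-class head under a softmax.  This configuration has exactly
**18,928,130** trainable parameters.  Training uses SGD (momentum 0.9),
lr 0.01 halved every 50 epochs, batch 32, gradient-norm clipping at 1.0, at
most 500 epochs with early stopping once the validation loss moves less than
1e-4 over 100 epochs, across 20 random 80/20 encounter-level splits.

Evaluation is the Mann–Whitney AUC with 500-iteration bootstrap CIs and
DeLong tests; a rolling-window protocol repositions a sub-model at
successive hours since admission, predicting death within the next horizon
from the most recent data.  Comparators: random forest and XGBoost on the
identically prepared windows (flattened to last/mean/min/max summaries), and
a generic proprietary-index score thresholded on its preceding-24-h mean.
Feature importance retrains the model without each variable (AUC gain over
the same splits); an ablation drops the baseline block.

The neural network core (reverse-mode autodiff, attention, layer norm,
optimizer) is implemented in numpy inside the package and is
gradient-checked against finite differences in the test suite.

## Worked example

A small cohort from the bundled generator, a scaled-down model (2 layers,
2 heads, d = 32), and a rolling evaluation on an independent cohort:

```python
import dataclasses
from teco import (
    TECOConfig, TrainConfig, fit_feature_schema, make_splits, make_windows,
    preset, roc_auc, rolling_evaluate, simulate_cohort, train_submodel,
)

cohort, truth = simulate_cohort(preset("strong-signal-small", seed=7))
plan = make_splits(cohort.encounter_ids, n_splits=1, seed=7)
schema = fit_feature_schema(cohort, train_ids=plan[0][0])
windows = make_windows(cohort, schema, horizon_h=24, lookback_h=12.0,
                       policy="training")
tiny = TECOConfig(n_layers=2, n_heads=2, d_model=32, d_ff=64,
                  feature_dim=schema.feature_dim)
model, history = train_submodel(
    windows, plan[0], tiny,
    TrainConfig(max_epochs=12, early_stop_patience=12, seed=7))

val_ids = set(plan[0][1])
val = [w for w in windows if w.encounter_id in val_ids]
auc = roc_auc(model.predict_proba(val), [w.label for w in val])
print(f"validation AUC (24-h horizon): {auc:.3f}")

test_cohort, _ = simulate_cohort(
    preset("strong-signal-small", seed=1007, n_encounters=400))
for r in rolling_evaluate(model, test_cohort, schema, 24,
                          [24.0, 48.0, 72.0], lookback_h=12.0,
                          n_boot=200, seed=7):
    print(f"anchor {r.anchor_h:5.0f} h  AUC {r.auc:.3f} "
          f"[{r.ci_lo:.3f}, {r.ci_hi:.3f}]  n={r.n} deaths={r.n_deaths}")
```

prints

```
validation AUC (24-h horizon): 0.974
anchor    24 h  AUC 0.983 [0.970, 0.993]  n=392 deaths=27
anchor    48 h  AUC 0.992 [0.983, 0.998]  n=316 deaths=42
anchor    72 h  AUC 0.995 [0.987, 1.000]  n=187 deaths=32
```

The validation AUC is the discrimination of the 24-hour sub-model on held-out
encounters; the rolling rows show AUC (with bootstrap 95% CI) when the model
is repositioned 24, 48 and 72 hours after admission on a fresh cohort — the
planted deterioration signal strengthens toward death, so later anchors
discriminate at least as well as early ones.

The same pipeline is scriptable from the shell:

```
teco simulate --preset strong-signal-small --seed 7 --out sim/
teco train --measurements sim/measurements.csv --baseline sim/baseline.csv \
    --horizon 24 --n-splits 1 --lookback 12 --seed 7 --out fit/ --config tiny.yml
teco rolling-eval --measurements sim/measurements.csv --baseline sim/baseline.csv \
    --checkpoint fit/teco_h24_s0.npz --anchors 24,72:12 --out roll/
```

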