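"""Tree comparators and the score-threshold (proprietary-index) evaluation."""

import numpy as np
import pandas as pd
import pytest

from teco.baselines import (
    DEFAULT_SUMMARIES,
    flat_feature_names,
    flatten_window,
    flatten_windows,
    mean_score_preceding,
    score_threshold_eval,
    train_tree_baseline,
    windows_provenance_hash,
)
from teco.errors import DegenerateLabelError, TecoError
from teco.evaluation import roc_auc
from teco.preprocess import make_windows
from teco.synthetic import simulate_score_series
from teco.training import make_splits


def test_flat_row_width_and_constant_variable(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    w = make_windows(cohort, strong_schema, 24, 24.0, "training")[0]
    row = flatten_window(w, strong_schema)
    assert row.shape == (4 * 7 + 17,)
    assert len(flat_feature_names(strong_schema)) == 45
    # a constant-valued variable has last == mean == min == max
    w.features[:, 0] = 1.234
    row = flatten_window(w, strong_schema)
    assert np.allclose(row[:4], 1.234)


def test_flattening_is_leak_free(strong_cohort, strong_schema):
    # flattening only reads the window features, which are pre-anchor by
    # construction; identical windows give identical rows
    cohort, _ = strong_cohort
    windows = make_windows(cohort, strong_schema, 24, 24.0, "training")
    h1 = windows_provenance_hash(windows)
    h2 = windows_provenance_hash(windows)
    assert h1 == h2
    X, y, meta = flatten_windows(windows, strong_schema)
    assert X.shape == (len(windows), 45)
    assert meta["encounter_id"].tolist() == [w.encounter_id for w in windows]


@pytest.mark.parametrize("kind", ["rf", "xgb"])
def test_tree_baselines_learn_planted_signal(kind, strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    windows = make_windows(cohort, strong_schema, 24, 24.0, "training")
    plan = make_splits([w.encounter_id for w in windows], n_splits=1, seed=2)
    train_ids, val_ids = set(plan[0][0]), set(plan[0][1])
    model = train_tree_baseline(
        [w for w in windows if w.encounter_id in train_ids], strong_schema, kind, seed=0
    )
    val_w = [w for w in windows if w.encounter_id in val_ids]
    auc = roc_auc(model.score_windows(val_w), [w.label for w in val_w])
    assert auc > 0.8
    # determinism under the same seed
    model2 = train_tree_baseline(
        [w for w in windows if w.encounter_id in train_ids], strong_schema, kind, seed=0
    )
    np.testing.assert_array_equal(model.score_windows(val_w), model2.score_windows(val_w))
    if kind == "rf":
        imp = model.impurity_importance()
        assert imp.sum() == pytest.approx(1.0)
        assert list(imp.index) == flat_feature_names(strong_schema, DEFAULT_SUMMARIES)


def test_degenerate_labels_rejected(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    windows = [
        w for w in make_windows(cohort, strong_schema, 24, 24.0, "training") if w.label == 0
    ]
    with pytest.raises(DegenerateLabelError):
        train_tree_baseline(windows, strong_schema, "rf")


def test_mean_score_window_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = int(rng.integers(1, 50))
        t = rng.uniform(0, 4000, n)
        s = rng.normal(size=n)
        anchor = float(rng.uniform(0, 4000))
        mine = mean_score_preceding(t, s, anchor, 24 * 60.0)
        inside = [s[i] for i in range(n) if anchor - 24 * 60.0 < t[i] <= anchor]
        if inside:
            assert mine == pytest.approx(np.mean(inside))
        else:
            assert np.isnan(mine)


def _score_frame(values_by_enc):
    rows = []
    for eid, vals in values_by_enc.items():
        for i, v in enumerate(vals):
            rows.append({"encounter_id": eid, "t_minutes": 60.0 * (i + 1), "score": v})
    return pd.DataFrame(rows)


def test_score_threshold_degenerate_and_perfect_cases():
    labels = {"a": 1, "b": 1, "c": 0, "d": 0}
    same = _score_frame({k: [0.7] * 30 for k in labels})
    res, excluded = score_threshold_eval(same, labels, anchor_h=30.0, n_boot=50)
    assert res.auc == 0.5 and excluded == 0
    perfect = _score_frame(
        {k: [1.0 if y else 0.0] * 30 for k, y in labels.items()}
    )
    res, _ = score_threshold_eval(perfect, labels, anchor_h=30.0, n_boot=50)
    assert res.auc == 1.0


def test_score_threshold_monotone_invariance_and_exclusions(strong_cohort):
    cohort, gt = strong_cohort
    series = simulate_score_series(cohort, gt, seed=3)
    anchor = 48.0
    labels = {}
    for eid in cohort.encounter_ids:
        rec = cohort.baseline_record(eid)
        if rec.outcome_time <= anchor * 60.0:
            continue
        labels[eid] = int(
            rec.outcome == "death" and rec.outcome_time <= (anchor + 24.0) * 60.0
        )
    if len(set(labels.values())) < 2:
        pytest.skip("degenerate labels at this anchor")
    res, excluded = score_threshold_eval(series, labels, anchor_h=anchor, n_boot=50)
    assert 0.0 <= res.auc <= 1.0 and res.n + excluded == len(labels)
    # positive affine rescaling of the raw series commutes with the 24-h mean,
    # and the threshold-free ROC is rank-based, so the AUC is unchanged
    rescaled = series.assign(score=100.0 * series["score"] - 7.0)
    res2, _ = score_threshold_eval(rescaled, labels, anchor_h=anchor, n_boot=50)
    assert res2.auc == pytest.approx(res.auc)
    # monotone warping of the aggregated classifier score is likewise rank-free
    means = np.array(
        [mean_score_preceding(
            series.loc[series.encounter_id == e, "t_minutes"].to_numpy(),
            series.loc[series.encounter_id == e, "score"].to_numpy(),
            anchor * 60.0, 24 * 60.0) for e in labels]
    )
    keep = ~np.isnan(means)
    y = np.array(list(labels.values()))[keep]
    assert roc_auc(np.exp(5 * means[keep]), y) == pytest.approx(res.auc)
    with pytest.raises(TecoError):
        score_threshold_eval(series, labels, anchor_h=1e6)
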