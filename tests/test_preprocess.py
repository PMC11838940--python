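"""Binning, carry-forward, grids, baseline encoding and window extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teco.data_model import BaselineRecord, CohortSchema, validate_cohort
from teco.errors import ConfigurationError, EncodingError
from teco.preprocess import (
    FeatureSchema,
    bin_15min,
    build_grid,
    collate,
    encode_baseline,
    fit_feature_schema,
    make_windows,
)
from teco.synthetic import preset, simulate_cohort


def brute_force_bin(t, v):
    """Per-interval loop oracle for 15-minute mean binning with carry-forward."""
    t, v = np.asarray(t, float), np.asarray(v, float)
    if t.size == 0:
        return [], [], []
    k = np.floor(t / 15.0).astype(int)
    out_idx, out_val, out_obs = [], [], []
    prev = None
    for i in range(k.min(), k.max() + 1):
        vals = [v[j] for j in range(len(t)) if k[j] == i]
        if vals:
            prev = sum(vals) / len(vals)
            out_idx.append(i), out_val.append(prev), out_obs.append(True)
        else:
            out_idx.append(i), out_val.append(prev), out_obs.append(False)
    return out_idx, out_val, out_obs


def test_two_point_mean():
    df = bin_15min([3.0, 7.0], [40.0, 38.0])
    assert list(df["interval"]) == [0]
    assert df["value"].iloc[0] == pytest.approx(39.0)
    assert bool(df["observed"].iloc[0])


def test_interior_gap_carries_previous_value():
    df = bin_15min([3.0, 40.0], [39.0, 37.0])
    assert list(df["interval"]) == [0, 1, 2]
    assert list(df["value"]) == [39.0, 39.0, 37.0]
    assert list(df["observed"]) == [True, False, True]


def test_empty_input_gives_empty_output():
    assert len(bin_15min([], [])) == 0


def test_binning_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = rng.integers(1, 40)
        t = rng.uniform(0, rng.uniform(30, 2000), n)
        v = rng.normal(size=n)
        df = bin_15min(t, v)
        idx, val, obs = brute_force_bin(t, v)
        assert list(df["interval"]) == idx
        assert np.allclose(df["value"], val)
        assert list(df["observed"]) == obs


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(0.0, 3000.0, allow_nan=False),
            st.floats(-1e6, 1e6, allow_nan=False),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_binning_property_matches_oracle(records):
    t = [r[0] for r in records]
    v = [r[1] for r in records]
    df = bin_15min(t, v)
    idx, val, obs = brute_force_bin(t, v)
    assert list(df["interval"]) == idx
    np.testing.assert_allclose(df["value"], val, rtol=1e-12, atol=1e-9)
    assert list(df["observed"]) == obs


def test_rebinning_binned_series_is_identity():
    rng = np.random.default_rng(7)
    t = np.sort(rng.uniform(0, 600, 25))
    df = bin_15min(t, rng.normal(size=25))
    # place one point at each binned interval midpoint carrying the binned value
    t2 = df["interval"].to_numpy() * 15.0 + 7.5
    df2 = bin_15min(t2, df["value"].to_numpy())
    assert np.allclose(df2["value"], df["value"])
    assert list(df2["interval"]) == list(df["interval"])


def _grid_cohort():
    measurements = pd.DataFrame(
        {
            "encounter_id": ["e"] * 3,
            "variable": ["sf_ratio", "sf_ratio", "msofa"],
            "t_minutes": [0.0, 70.0, 65.0],  # sf_ratio at intervals 0 and 4; msofa at 4
            "value": [400.0, 300.0, 6.0],
        }
    )
    baseline = pd.DataFrame(
        {
            "encounter_id": ["e"], "age": [60.0], "sex": ["Male"], "race": ["White"],
            "ethnicity": ["Hispanic"], "bmi": [25.0], "outcome": ["death"],
            "outcome_time_minutes": [500.0],
        }
    )
    return validate_cohort(measurements, baseline, CohortSchema())


def test_grid_fills_leading_gaps_with_training_median():
    cohort = _grid_cohort()
    schema = FeatureSchema(
        time_variables=("sf_ratio", "msofa"),
        variable_median=(350.0, 5.0),
        variable_mean=(350.0, 5.0),
        variable_sd=(50.0, 2.0),
    )
    grid = build_grid(cohort, "e", schema)
    assert list(grid.interval_index) == [0, 1, 2, 3, 4]
    # msofa first observed at interval 4: rows 0-3 carry its training median, masked
    assert np.allclose(grid.values[:4, 1], 5.0)
    assert not grid.observed[:4, 1].any()
    assert grid.values[4, 1] == 6.0 and grid.observed[4, 1]
    # sf_ratio: observed 0, carried 1-3, observed 4 — matches bin_15min output
    binned = bin_15min([0.0, 70.0], [400.0, 300.0])
    assert np.allclose(grid.values[:, 0], binned["value"])


def test_single_record_yields_single_row_grid():
    cohort = _grid_cohort()
    schema = FeatureSchema(time_variables=("msofa",), variable_median=(5.0,))
    grid = build_grid(cohort, "e", schema, t_max=66.0)
    assert grid.values.shape == (1, 1)
    with pytest.raises(KeyError):
        build_grid(cohort, "nope", schema)


def test_baseline_encoding_layout():
    schema = FeatureSchema(age_mean=60.0, age_sd=10.0)
    rec = BaselineRecord("x", 60.0, "Male", "White", "Hispanic", None, "death", 100.0)
    vec = encode_baseline(rec, schema)
    assert vec.shape == (17,)
    assert schema.feature_dim == 24
    assert vec[0] == 0.0  # age at the training mean standardizes to zero
    assert list(vec[1:4]) == [1.0, 0.0, 0.0]  # sex=Male
    assert list(vec[4:8]) == [1.0, 0.0, 0.0, 0.0]  # race=White
    assert list(vec[11:15]) == [0.0, 0.0, 0.0, 0.0]  # named BMI classes all zero
    assert vec[-2] == 1.0  # bmi category = Unknown one-hot tail
    assert vec[-1] == 0.0  # missing continuous BMI encodes as zero
    with pytest.raises(EncodingError, match="Martian"):
        encode_baseline(
            BaselineRecord("x", 50.0, "Male", "Martian", "Hispanic", None, "death", 1.0),
            schema,
        )


def test_training_windows_anchor_at_outcome_minus_horizon(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    windows = make_windows(cohort, strong_schema, 24, lookback_h=24.0, policy="training")
    by_id = {w.encounter_id: w for w in windows}
    for eid, w in list(by_id.items())[:20]:
        rec = cohort.baseline_record(eid)
        assert w.t_pred == pytest.approx(rec.outcome_time - 24 * 60.0)
        assert w.label == int(rec.outcome == "death")
        assert (w.rel_offsets <= 0).all()
        assert (np.diff(w.rel_offsets) > 0).all()
    # anchors at/before admission drop the encounter
    assert all(
        cohort.baseline_record(eid).outcome_time > 24 * 60.0 for eid in by_id
    )


def test_unsupported_horizon_rejected(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    with pytest.raises(ConfigurationError):
        make_windows(cohort, strong_schema, 13)


def test_rolling_windows_label_death_within_horizon(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    anchor = 48.0
    windows = make_windows(
        cohort, strong_schema, 24, lookback_h=24.0, policy="rolling", anchors_hours=[anchor]
    )
    for w in windows:
        rec = cohort.baseline_record(w.encounter_id)
        assert rec.outcome_time > anchor * 60.0  # still in the ICU at the anchor
        expected = int(
            rec.outcome == "death" and rec.outcome_time <= (anchor + 24) * 60.0
        )
        assert w.label == expected


def test_windows_ignore_post_anchor_measurements(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    windows = make_windows(cohort, strong_schema, 24, lookback_h=24.0, policy="training")
    w0 = windows[0]
    tampered = cohort.measurements.copy()
    after = (tampered["encounter_id"] == w0.encounter_id) & (
        tampered["t_minutes"] > w0.t_pred
    )
    tampered.loc[after, "value"] += 1e6
    cohort2 = validate_cohort(tampered, cohort.baseline.reset_index(drop=True), cohort.schema)
    w1 = [
        w
        for w in make_windows(cohort2, strong_schema, 24, lookback_h=24.0, policy="training")
        if w.encounter_id == w0.encounter_id
    ][0]
    np.testing.assert_array_equal(w0.features, w1.features)


def test_baseline_subvector_static_across_sequence(strong_cohort, strong_schema):
    cohort, _ = strong_cohort
    windows = make_windows(cohort, strong_schema, 24, lookback_h=24.0, policy="training")
    n_time = len(strong_schema.time_variables)
    for w in windows[:30]:
        base_block = w.features[:, n_time:]
        assert np.ptp(base_block, axis=0).max() == 0.0


def test_collate_pads_and_masks():
    cohort, _ = simulate_cohort(preset("strong-signal-small", seed=3, n_encounters=20))
    schema = fit_feature_schema(cohort)
    windows = make_windows(cohort, schema, 24, lookback_h=24.0, policy="training")
    feats, offsets, mask, labels = collate(windows)
    lengths = np.array([w.features.shape[0] for w in windows])
    assert (mask.sum(axis=1) == lengths).all()
    assert feats.shape[0] == len(windows) and feats.shape[2] == schema.feature_dim
    assert (feats[~mask] == 0).all()
    assert set(labels) <= {0, 1}
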