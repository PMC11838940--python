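"""Data preparation for the transformer and the tree baselines.

The pipeline mirrors how the model consumes irregular monitoring streams:

1. each variable is averaged within 15-minute intervals aligned to ICU
   admission; empty interior intervals inherit the previous interval's value
   (last observation carried forward);
2. per-encounter variables are joined on a shared interval index into an
   :class:`AlignedGrid`; intervals before a variable's first observation are
   filled with the training-split median and flagged unobserved;
3. the grid values are z-scored with training-split statistics and
   concatenated with an encoded baseline vector (static across the sequence)
   to form fixed-width feature vectors;
4. windows are cut at a prediction anchor, keeping only the most recent
   ``lookback_h`` hours, with interval offsets relative to the anchor.

Only measurements with ``t <= anchor`` ever enter a window: features are a
pure function of the pre-anchor stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    BMI_LEVELS,
    ETHNICITY_LEVELS,
    RACE_LEVELS,
    SEX_LEVELS,
    TIME_VARIABLES,
    BaselineRecord,
    CohortDataset,
    bmi_category,
)
from .errors import ConfigurationError, EncodingError

INTERVAL_MINUTES = 15.0
#: The nine supported prediction horizons, hours ahead of the anchor.
SUPPORTED_HORIZONS: tuple[int, ...] = (0, 12, 24, 36, 48, 60, 72, 84, 96)


def bin_15min(t_minutes: np.ndarray, values: np.ndarray) -> pd.DataFrame:
    """Average one variable's records within 15-minute intervals.

    Returns a frame with columns ``interval`` (k, covering [15k, 15(k+1))
    minutes), ``value`` and ``observed``; interior intervals with no record
    carry the previous interval's value with ``observed=False``.  Empty input
    yields an empty frame.
    """
    t = np.asarray(t_minutes, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return pd.DataFrame({"interval": np.array([], dtype=int), "value": [], "observed": []})
    k = np.floor(t / INTERVAL_MINUTES).astype(np.int64)
    k0, k1 = int(k.min()), int(k.max())
    width = k1 - k0 + 1
    sums = np.bincount(k - k0, weights=v, minlength=width)
    counts = np.bincount(k - k0, minlength=width)
    observed = counts > 0
    out = np.empty(width, dtype=float)
    with np.errstate(invalid="ignore"):
        out[observed] = sums[observed] / counts[observed]
    # carry forward: index of most recent observed interval at or before each slot
    src = np.where(observed, np.arange(width), -1)
    src = np.maximum.accumulate(src)
    out = out[src]
    return pd.DataFrame(
        {"interval": np.arange(k0, k1 + 1, dtype=int), "value": out, "observed": observed}
    )


@dataclass
class AlignedGrid:
    """Per-encounter 15-minute grid: values, observation mask, interval index."""

    encounter_id: str
    interval_index: np.ndarray  # (S,) int, contiguous
    values: np.ndarray  # (S, n_variables) float
    observed: np.ndarray  # (S, n_variables) bool
    variables: tuple[str, ...]


@dataclass(frozen=True)
class FeatureSchema:
    """Feature layout and training-split standardization statistics.

    The feature vector is the z-scored time-dependent variables followed by
    the baseline block: z-scored age, one-hot sex/race/ethnicity/BMI-category
    blocks (each including its Unknown level) and z-scored continuous
    baseline BMI (0 when missing).  The default layout is 7 + 17 = 24 wide.
    """

    time_variables: tuple[str, ...] = TIME_VARIABLES
    sex_levels: tuple[str, ...] = SEX_LEVELS
    race_levels: tuple[str, ...] = RACE_LEVELS
    ethnicity_levels: tuple[str, ...] = ETHNICITY_LEVELS
    bmi_levels: tuple[str, ...] = BMI_LEVELS
    include_baseline: bool = True
    # training-split statistics (fitted via `fit_feature_schema`)
    variable_mean: tuple[float, ...] = ()
    variable_sd: tuple[float, ...] = ()
    variable_median: tuple[float, ...] = ()
    age_mean: float = 0.0
    age_sd: float = 1.0
    bmi_mean: float = 0.0
    bmi_sd: float = 1.0

    @property
    def baseline_width(self) -> int:
        if not self.include_baseline:
            return 0
        return (
            1
            + len(self.sex_levels)
            + len(self.race_levels)
            + len(self.ethnicity_levels)
            + len(self.bmi_levels)
            + 1
        )

    @property
    def feature_dim(self) -> int:
        return len(self.time_variables) + self.baseline_width

    @property
    def feature_names(self) -> tuple[str, ...]:
        names = list(self.time_variables)
        if self.include_baseline:
            names.append("age")
            names += [f"sex={s}" for s in self.sex_levels]
            names += [f"race={r}" for r in self.race_levels]
            names += [f"ethnicity={e}" for e in self.ethnicity_levels]
            names += [f"bmi_cat={b}" for b in self.bmi_levels]
            names.append("bmi_baseline")
        return tuple(names)

    def drop_variable(self, variable: str) -> "FeatureSchema":
        """Schema with one time-dependent variable eliminated (for importance)."""
        if variable not in self.time_variables:
            raise EncodingError(f"{variable!r} is not a time-dependent variable")
        keep = [i for i, v in enumerate(self.time_variables) if v != variable]
        return replace(
            self,
            time_variables=tuple(self.time_variables[i] for i in keep),
            variable_mean=tuple(self.variable_mean[i] for i in keep) if self.variable_mean else (),
            variable_sd=tuple(self.variable_sd[i] for i in keep) if self.variable_sd else (),
            variable_median=tuple(self.variable_median[i] for i in keep)
            if self.variable_median
            else (),
        )

    def without_baseline(self) -> "FeatureSchema":
        return replace(self, include_baseline=False)


def fit_feature_schema(
    cohort: CohortDataset,
    train_ids: list[str] | None = None,
    schema: FeatureSchema | None = None,
) -> FeatureSchema:
    """Learn standardization statistics on the training encounters only."""
    schema = schema or FeatureSchema(time_variables=cohort.schema.time_variables)
    ids = set(train_ids if train_ids is not None else cohort.encounter_ids)
    meas = cohort.measurements
    meas = meas[meas["encounter_id"].isin(ids)]
    means, sds, medians = [], [], []
    for var in schema.time_variables:
        v = meas.loc[meas["variable"] == var, "value"].to_numpy(dtype=float)
        if v.size == 0:
            means.append(0.0), sds.append(1.0), medians.append(0.0)
            continue
        sd = float(v.std())
        means.append(float(v.mean()))
        sds.append(sd if sd > 0 else 1.0)
        medians.append(float(np.median(v)))
    base = cohort.baseline.loc[cohort.baseline.index.isin(ids)]
    age = base["age"].to_numpy(dtype=float)
    bmi = base["bmi"].to_numpy(dtype=float)
    bmi = bmi[np.isfinite(bmi)]
    return replace(
        schema,
        variable_mean=tuple(means),
        variable_sd=tuple(sds),
        variable_median=tuple(medians),
        age_mean=float(age.mean()) if age.size else 0.0,
        age_sd=float(age.std()) if age.size and age.std() > 0 else 1.0,
        bmi_mean=float(bmi.mean()) if bmi.size else 0.0,
        bmi_sd=float(bmi.std()) if bmi.size and bmi.std() > 0 else 1.0,
    )


def _one_hot(level: str, levels: tuple[str, ...], what: str) -> np.ndarray:
    if level not in levels:
        raise EncodingError(f"unseen {what} level {level!r} (declared: {levels})")
    out = np.zeros(len(levels))
    out[levels.index(level)] = 1.0
    return out


def encode_baseline(record: BaselineRecord, schema: FeatureSchema) -> np.ndarray:
    """Encode one baseline record into the schema's baseline block."""
    if not schema.include_baseline:
        return np.zeros(0)
    parts = [np.array([(record.age - schema.age_mean) / schema.age_sd])]
    parts.append(_one_hot(record.sex, schema.sex_levels, "sex"))
    parts.append(_one_hot(record.race, schema.race_levels, "race"))
    parts.append(_one_hot(record.ethnicity, schema.ethnicity_levels, "ethnicity"))
    parts.append(_one_hot(bmi_category(record.bmi_baseline), schema.bmi_levels, "bmi"))
    if record.bmi_baseline is None:
        parts.append(np.array([0.0]))
    else:
        parts.append(np.array([(record.bmi_baseline - schema.bmi_mean) / schema.bmi_sd]))
    return np.concatenate(parts)


def build_grid(
    cohort: CohortDataset,
    encounter_id: str,
    schema: FeatureSchema,
    t_max: float | None = None,
) -> AlignedGrid:
    """Join the encounter's binned variables on a shared interval index.

    Rows span from the first observation of *any* variable to the last (both
    limited to ``t <= t_max`` when given).  Leading gaps of an individual
    variable are filled with its training-split median (unobserved); trailing
    gaps carry the last value forward (unobserved).
    """
    meas = cohort.measurements_for(encounter_id)
    if t_max is not None:
        meas = meas[meas["t_minutes"] <= t_max]
    if len(meas) == 0:
        raise KeyError(f"encounter {encounter_id!r} has no usable measurements")
    per_var = {}
    for j, var in enumerate(schema.time_variables):
        sub = meas[meas["variable"] == var]
        per_var[var] = bin_15min(sub["t_minutes"].to_numpy(), sub["value"].to_numpy())
    starts = [df["interval"].iat[0] for df in per_var.values() if len(df)]
    ends = [df["interval"].iat[-1] for df in per_var.values() if len(df)]
    if not starts:
        raise KeyError(f"encounter {encounter_id!r} has no measurements of schema variables")
    k0, k1 = int(min(starts)), int(max(ends))
    width = k1 - k0 + 1
    values = np.empty((width, len(schema.time_variables)))
    observed = np.zeros((width, len(schema.time_variables)), dtype=bool)
    medians = schema.variable_median or (0.0,) * len(schema.time_variables)
    for j, var in enumerate(schema.time_variables):
        df = per_var[var]
        if len(df) == 0:
            values[:, j] = medians[j]
            continue
        a, b = int(df["interval"].iat[0]) - k0, int(df["interval"].iat[-1]) - k0
        values[:a, j] = medians[j]
        values[a : b + 1, j] = df["value"].to_numpy()
        values[b + 1 :, j] = df["value"].iat[-1]  # trailing carry-forward
        observed[a : b + 1, j] = df["observed"].to_numpy()
    return AlignedGrid(
        encounter_id=encounter_id,
        interval_index=np.arange(k0, k1 + 1, dtype=int),
        values=values,
        observed=observed,
        variables=schema.time_variables,
    )


@dataclass
class WindowSample:
    """One (anchor, horizon) instance: feature sequence, offsets, label."""

    encounter_id: str
    t_pred: float  # anchor, minutes since admission
    horizon_h: int
    features: np.ndarray  # (S, F)
    rel_offsets: np.ndarray  # (S,) int <= 0, intervals before the anchor
    label: int  # 1 = death
    grid: AlignedGrid | None = field(default=None, repr=False)


def _window_for_anchor(
    cohort: CohortDataset,
    schema: FeatureSchema,
    encounter_id: str,
    t_pred: float,
    horizon_h: int,
    lookback_h: float,
    label: int,
) -> WindowSample | None:
    try:
        grid = build_grid(cohort, encounter_id, schema, t_max=t_pred)
    except KeyError:
        return None
    anchor_k = int(np.floor(t_pred / INTERVAL_MINUTES))
    lookback_k = int(round(lookback_h * 60.0 / INTERVAL_MINUTES))
    sel = (grid.interval_index > anchor_k - lookback_k) & (grid.interval_index <= anchor_k)
    if not sel.any():
        return None
    idx = grid.interval_index[sel]
    vals = grid.values[sel]
    mean = np.asarray(schema.variable_mean or np.zeros(vals.shape[1]))
    sd = np.asarray(schema.variable_sd or np.ones(vals.shape[1]))
    z = (vals - mean) / sd
    base_vec = encode_baseline(cohort.baseline_record(encounter_id), schema)
    feats = np.hstack([z, np.broadcast_to(base_vec, (z.shape[0], base_vec.size))])
    return WindowSample(
        encounter_id=encounter_id,
        t_pred=float(t_pred),
        horizon_h=horizon_h,
        features=feats,
        rel_offsets=(idx - anchor_k).astype(int),
        label=int(label),
        grid=grid,
    )


def make_windows(
    cohort: CohortDataset,
    schema: FeatureSchema,
    horizon_h: int,
    lookback_h: float = 96.0,
    policy: str = "training",
    anchors_hours: list[float] | None = None,
) -> list[WindowSample]:
    """Extract model windows under the training or rolling policy.

    Training policy: one window per encounter anchored ``horizon_h`` hours
    before its ICU endpoint, labelled with that endpoint; encounters whose
    anchor falls at/before admission (or with no pre-anchor data) are
    dropped.  Rolling policy: one window per (encounter, anchor) for the
    caller's anchors, labelled death iff death occurs within
    ``(anchor, anchor + horizon_h]``; encounters whose outcome precedes the
    anchor are excluded.
    """
    if horizon_h not in SUPPORTED_HORIZONS:
        raise ConfigurationError(
            f"horizon {horizon_h} h unsupported; choose from {SUPPORTED_HORIZONS}"
        )
    windows: list[WindowSample] = []
    if policy == "training":
        for eid in cohort.encounter_ids:
            rec = cohort.baseline_record(eid)
            t_pred = rec.outcome_time - horizon_h * 60.0
            if t_pred <= 0:
                continue
            w = _window_for_anchor(
                cohort, schema, eid, t_pred, horizon_h, lookback_h,
                label=int(rec.outcome == "death"),
            )
            if w is not None:
                windows.append(w)
    elif policy == "rolling":
        if not anchors_hours:
            raise ConfigurationError("rolling policy requires anchors_hours")
        for anchor in anchors_hours:
            t_pred = float(anchor) * 60.0
            for eid in cohort.encounter_ids:
                rec = cohort.baseline_record(eid)
                if rec.outcome_time <= t_pred:
                    continue
                label = int(
                    rec.outcome == "death" and rec.outcome_time <= t_pred + horizon_h * 60.0
                )
                w = _window_for_anchor(
                    cohort, schema, eid, t_pred, horizon_h, lookback_h, label=label
                )
                if w is not None:
                    windows.append(w)
    else:
        raise ConfigurationError(f"unknown window policy {policy!r}")
    return windows


def collate(windows: list[WindowSample]):
    """Pad a window list into dense batch arrays for the model.

    Returns ``(features (B,S,F), offsets (B,S), mask (B,S) bool, labels (B,))``
    where ``mask`` is True at real (non-padding) positions and sequences are
    right-padded; the anchor-most interval of each window is its last real
    position.
    """
    B = len(windows)
    S = max(w.features.shape[0] for w in windows)
    F = windows[0].features.shape[1]
    feats = np.zeros((B, S, F))
    offsets = np.zeros((B, S), dtype=int)
    mask = np.zeros((B, S), dtype=bool)
    labels = np.zeros(B, dtype=int)
    for i, w in enumerate(windows):
        s = w.features.shape[0]
        feats[i, :s] = w.features
        offsets[i, :s] = w.rel_offsets
        mask[i, :s] = True
        labels[i] = w.label
    return feats, offsets, mask, labels
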