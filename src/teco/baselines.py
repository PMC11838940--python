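"""Comparator models on identically prepared data.

Random forest and gradient-boosted trees consume the same windows as the
transformer, flattened to fixed-width per-variable summaries (last, mean,
min, max over the lookback) concatenated with the encoded baseline block.
The proprietary-index comparator (an EDI-style score) is evaluated with no
fitting at all: the classifier score is the mean index over the preceding
24 hours, thresholded over its whole observed range (i.e. a plain ROC).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .errors import DegenerateLabelError, TecoError
from .evaluation import EvalResult, bootstrap_ci, roc_auc
from .preprocess import FeatureSchema, WindowSample

#: Per-variable summaries applied over the lookback window, in order.
DEFAULT_SUMMARIES: tuple[str, ...] = ("last", "mean", "min", "max")

_SUMMARY_FN = {
    "last": lambda a: a[-1],
    "mean": np.mean,
    "min": np.min,
    "max": np.max,
}


def flatten_window(
    window: WindowSample,
    schema: FeatureSchema,
    summaries: tuple[str, ...] = DEFAULT_SUMMARIES,
    raveled: bool = False,
) -> np.ndarray:
    """Flatten one window to a fixed-width feature row.

    Default: ``len(summaries)`` statistics per time-dependent variable plus
    the (static) baseline block — width 4*7 + 17 = 45 under the default
    schema.  ``raveled=True`` instead ravels the full grid right-aligned to
    the maximum lookback length.
    """
    n_time = len(schema.time_variables)
    tvals = window.features[:, :n_time]
    base = window.features[-1, n_time:]
    if raveled:
        return np.concatenate([tvals.ravel(), base])
    stats = [
        _SUMMARY_FN[s](tvals[:, j]) for j in range(n_time) for s in summaries
    ]
    return np.concatenate([np.asarray(stats, dtype=float), base])


def flatten_windows(
    windows: list[WindowSample],
    schema: FeatureSchema,
    summaries: tuple[str, ...] = DEFAULT_SUMMARIES,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack flattened rows; returns (X, y, meta) with encounter/anchor meta."""
    X = np.vstack([flatten_window(w, schema, summaries) for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    meta = pd.DataFrame(
        {"encounter_id": [w.encounter_id for w in windows],
         "t_pred": [w.t_pred for w in windows],
         "horizon_h": [w.horizon_h for w in windows]}
    )
    return X, y, meta


def flat_feature_names(
    schema: FeatureSchema, summaries: tuple[str, ...] = DEFAULT_SUMMARIES
) -> list[str]:
    names = [f"{v}:{s}" for v in schema.time_variables for s in summaries]
    return names + list(schema.feature_names[len(schema.time_variables) :])


def windows_provenance_hash(windows: list[WindowSample]) -> str:
    """Digest of the prepared features, shared by every model consuming them."""
    h = hashlib.sha256()
    for w in windows:
        h.update(w.encounter_id.encode())
        h.update(np.ascontiguousarray(w.features).tobytes())
    return h.hexdigest()[:16]


@dataclass
class TreeBaseline:
    """A fitted tree model plus the flattening recipe it was trained with."""

    model: object
    kind: str  # "rf" | "xgb"
    schema: FeatureSchema
    summaries: tuple[str, ...]
    provenance: str

    def score_windows(self, windows: list[WindowSample]) -> np.ndarray:
        X = np.vstack([flatten_window(w, self.schema, self.summaries) for w in windows])
        return self.model.predict_proba(X)[:, 1]

    __call__ = score_windows

    def impurity_importance(self) -> pd.Series:
        if self.kind != "rf":
            raise TecoError("impurity importance is reported for the random forest only")
        return pd.Series(
            self.model.feature_importances_, index=flat_feature_names(self.schema, self.summaries)
        )


def train_tree_baseline(
    windows: list[WindowSample],
    schema: FeatureSchema,
    kind: str = "rf",
    params: dict | None = None,
    seed: int = 0,
    summaries: tuple[str, ...] = DEFAULT_SUMMARIES,
) -> TreeBaseline:
    """Fit RF or XGBoost on flattened windows."""
    X, y, _ = flatten_windows(windows, schema, summaries)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("tree baseline requires both outcome classes")
    params = dict(params or {})
    if kind == "rf":
        model = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 200), random_state=seed, **params
        )
    elif kind == "xgb":
        model = XGBClassifier(
            n_estimators=params.pop("n_estimators", 200),
            max_depth=params.pop("max_depth", 4),
            learning_rate=params.pop("learning_rate", 0.1),
            random_state=seed,
            eval_metric="logloss",
            **params,
        )
    else:
        raise TecoError(f"unknown tree baseline kind {kind!r}")
    model.fit(X, y)
    return TreeBaseline(
        model=model, kind=kind, schema=schema, summaries=summaries,
        provenance=windows_provenance_hash(windows),
    )


def mean_score_preceding(
    t_minutes: np.ndarray,
    scores: np.ndarray,
    anchor_minutes: float,
    window_minutes: float,
) -> float:
    """Mean score over ``(anchor - window, anchor]``; NaN when empty."""
    t = np.asarray(t_minutes, dtype=float)
    s = np.asarray(scores, dtype=float)
    sel = (t > anchor_minutes - window_minutes) & (t <= anchor_minutes)
    return float(s[sel].mean()) if sel.any() else float("nan")


def score_threshold_eval(
    score_series: pd.DataFrame,
    labels: dict[str, int],
    anchor_h: float,
    window_h: float = 24.0,
    n_boot: int = 500,
    seed: int = 0,
    horizon_h: int = 24,
) -> tuple[EvalResult, int]:
    """Evaluate a proprietary-index score by 24-h-mean thresholding.

    ``score_series`` has columns encounter_id, t_minutes, score.  Encounters
    with no score in the preceding window are excluded; their count is
    returned alongside the AUC result.  No fitting is involved: the ROC is
    swept over the observed range of mean scores.
    """
    anchor_min = anchor_h * 60.0
    means, ys = [], []
    n_excluded = 0
    for eid, y in labels.items():
        sub = score_series[score_series["encounter_id"] == eid]
        m = mean_score_preceding(
            sub["t_minutes"].to_numpy(), sub["score"].to_numpy(), anchor_min, window_h * 60.0
        )
        if np.isnan(m):
            n_excluded += 1
            continue
        means.append(m)
        ys.append(int(y))
    if not means:
        raise TecoError("no encounter has a usable score in the preceding window")
    means_a, ys_a = np.asarray(means), np.asarray(ys)
    auc = roc_auc(means_a, ys_a)
    lo, hi = bootstrap_ci(means_a, ys_a, n_boot=n_boot, seed=seed)
    result = EvalResult(
        horizon_h=horizon_h, anchor_h=anchor_h, context="score-threshold",
        auc=auc, ci_lo=lo, ci_hi=hi, n=len(ys_a), n_deaths=int(ys_a.sum()),
    )
    return result, n_excluded
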