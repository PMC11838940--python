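"""ROC/AUC machinery and the time-anchored (rolling-window) validation protocol.

AUC is the Mann-Whitney statistic (ties counted one half), confidence
intervals come from a 500-iteration whole-dataset bootstrap (percentile
2.5/97.5), and correlated AUCs are compared with the fast DeLong
structural-components test.  Rolling evaluation repositions a fixed-horizon
model at successive hours since ICU admission, scoring each anchor's
predictions against death within the following horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import TecoError, UndefinedAUCError
from .preprocess import FeatureSchema, make_windows
from .data_model import CohortDataset


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError(f"scores shape {s.shape} != labels shape {y.shape}")
    return s, y


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s, y = _as_arrays(scores, labels)
    m = int(y.sum())
    n = y.size - m
    if m == 0 or n == 0:
        raise UndefinedAUCError("AUC undefined: only one class present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a matrix of resampled (scores, labels)."""
    ranks = rankdata(scores, axis=1)
    m = labels.sum(axis=1)
    n = labels.shape[1] - m
    pos_rank_sum = (ranks * labels).sum(axis=1)
    return (pos_rank_sum - m * (m + 1) / 2.0) / (m * n)


def bootstrap_ci(scores, labels, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Percentile 95% CI over whole-dataset bootstrap resamples of the AUC.

    Resamples that draw a single class are redrawn.
    """
    s, y = _as_arrays(scores, labels)
    if y.min() == y.max():
        raise UndefinedAUCError("AUC undefined: only one class present")
    rng = np.random.default_rng(seed)
    n = y.size
    idx = rng.integers(0, n, size=(n_boot, n))
    yb = y[idx]
    bad = np.flatnonzero((yb.sum(axis=1) == 0) | (yb.sum(axis=1) == n))
    while bad.size:
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        yb = y[idx]
        bad = np.flatnonzero((yb.sum(axis=1) == 0) | (yb.sum(axis=1) == n))
    aucs = _auc_rows(s[idx], yb)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _midrank_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    x, w = scores[y == 1], scores[y == 0]
    m, n = x.size, w.size
    tz = rankdata(np.concatenate([x, w]))
    tx = rankdata(x)
    ty = rankdata(w)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return v10, v01, float(auc)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Two-sided DeLong test for two correlated AUCs on shared labels.

    Returns ``(auc_a, auc_b, p_value)``; a zero-variance difference (e.g.
    identical score vectors) yields p = 1.0.
    """
    sa, y = _as_arrays(scores_a, labels)
    sb, _ = _as_arrays(scores_b, labels)
    if y.min() == y.max():
        raise UndefinedAUCError("AUC undefined: only one class present")
    v10a, v01a, auc_a = _midrank_components(sa, y)
    v10b, v01b, auc_b = _midrank_components(sb, y)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, float(2.0 * norm.sf(abs(z)))


@dataclass
class EvalResult:
    """AUC with bootstrap CI at one evaluation context."""

    horizon_h: int
    anchor_h: float | None
    context: str  # split id or cohort id
    auc: float
    ci_lo: float
    ci_hi: float
    n: int
    n_deaths: int
    undefined: bool = False


def results_to_frame(results: list[EvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _score_windows(model_or_scorer, windows) -> np.ndarray:
    if callable(model_or_scorer) and not hasattr(model_or_scorer, "predict_proba"):
        return np.asarray(model_or_scorer(windows), dtype=float)
    return model_or_scorer.predict_proba(windows)


def rolling_evaluate(
    model_or_scorer,
    cohort: CohortDataset,
    schema: FeatureSchema,
    horizon_h: int,
    anchors_hours: list[float],
    lookback_h: float = 96.0,
    n_boot: int = 500,
    seed: int = 0,
    context: str = "cohort",
) -> list[EvalResult]:
    """Score the cohort at each anchor with the most recent ``lookback_h`` data.

    At anchor t the evaluated set is every encounter still in the ICU at t
    with any pre-anchor data; the label is death within (t, t + horizon].
    Anchors where only one class remains yield a result flagged undefined
    rather than failing the sweep.
    """
    results = []
    for anchor in anchors_hours:
        windows = make_windows(
            cohort, schema, horizon_h, lookback_h, policy="rolling", anchors_hours=[anchor]
        )
        labels = np.array([w.label for w in windows], dtype=int)
        if len(windows) == 0 or labels.min() == labels.max():
            results.append(
                EvalResult(horizon_h, anchor, context, np.nan, np.nan, np.nan,
                           len(windows), int(labels.sum()) if len(windows) else 0,
                           undefined=True)
            )
            continue
        scores = _score_windows(model_or_scorer, windows)
        auc = roc_auc(scores, labels)
        lo, hi = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
        results.append(
            EvalResult(horizon_h, anchor, context, auc, lo, hi, labels.size, int(labels.sum()))
        )
    return results


def median_auc(results: list[EvalResult]) -> float:
    """Median AUC across splits/contexts (the internal-validation summary)."""
    aucs = [r.auc for r in results if not r.undefined]
    if not aucs:
        raise TecoError("no defined AUCs to aggregate")
    return float(np.median(aucs))


@dataclass
class TrajectorySummary:
    """Mean predicted death probability per eventual-outcome group and anchor."""

    horizon_h: int
    rows: pd.DataFrame = field(repr=False)  # anchor_h, group, n, mean, ci_lo, ci_hi


def trajectory_summary(
    model_or_scorer,
    cohort: CohortDataset,
    schema: FeatureSchema,
    horizon_h: int,
    anchors_hours: list[float],
    lookback_h: float = 96.0,
) -> TrajectorySummary:
    """Group-level probability trajectories over hours since admission.

    Groups are the eventual ICU outcome (death vs discharge) of the
    encounters still under evaluation at each anchor; the interval is the
    normal approximation mean +/- 1.96 SE across encounters.  Empty groups
    at an anchor are omitted.
    """
    rows = []
    for anchor in anchors_hours:
        windows = make_windows(
            cohort, schema, horizon_h, lookback_h, policy="rolling", anchors_hours=[anchor]
        )
        if not windows:
            continue
        probs = _score_windows(model_or_scorer, windows)
        eventual = np.array(
            [cohort.baseline_record(w.encounter_id).outcome for w in windows]
        )
        for group in ("death", "discharge"):
            p = probs[eventual == group]
            if p.size == 0:
                continue
            se = p.std(ddof=1) / np.sqrt(p.size) if p.size > 1 else 0.0
            rows.append(
                {"anchor_h": anchor, "group": group, "n": int(p.size),
                 "mean": float(p.mean()),
                 "ci_lo": float(p.mean() - 1.96 * se),
                 "ci_hi": float(p.mean() + 1.96 * se)}
            )
    return TrajectorySummary(horizon_h=horizon_h, rows=pd.DataFrame(rows))
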