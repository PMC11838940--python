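"""Feature importance by elimination-and-retraining, and the baseline ablation.

For each time-dependent variable the transformer is retrained from scratch
with that variable removed from the feature schema (one embedding column
fewer), on the same splits and with the same seeds as the full model; the
importance of the variable on a split is the AUC the model loses without it
(signed; summarized by the median across splits).  Random-forest impurity
importances are reported on the flattened feature index for rank comparison.
The ablation study contrasts full models with models trained on
time-dependent variables only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import train_tree_baseline
from .data_model import CohortDataset
from .errors import TecoError
from .evaluation import roc_auc
from .model import TECOConfig
from .preprocess import FeatureSchema, make_windows
from .training import SplitPlan, TrainConfig, derive_seed, train_submodel


@dataclass
class ImportanceReport:
    """Per-feature AUC-gain distributions plus companion importances."""

    elimination: pd.DataFrame  # feature, split, auc_full, auc_reduced, gain
    rf_impurity: pd.Series | None = None
    ablation: pd.DataFrame | None = None
    failures: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Median and quartiles of the AUC gain per eliminated feature."""
        g = self.elimination.groupby("feature")["gain"]
        out = g.agg(median="median", q1=lambda s: s.quantile(0.25),
                    q3=lambda s: s.quantile(0.75), n="count").reset_index()
        return out.sort_values("median", ascending=False).reset_index(drop=True)

    def ranked_features(self) -> list[str]:
        return list(self.summary()["feature"])


def _val_auc(model, windows, val_ids: set[str]) -> float:
    val_w = [w for w in windows if w.encounter_id in val_ids]
    scores = model.predict_proba(val_w)
    labels = np.array([w.label for w in val_w])
    return roc_auc(scores, labels)


def feature_elimination(
    cohort: CohortDataset,
    schema: FeatureSchema,
    horizon_h: int,
    split_plan: SplitPlan,
    teco_config: TECOConfig,
    train_config: TrainConfig,
    lookback_h: float = 96.0,
) -> ImportanceReport:
    """Retrain without each variable on every split; gain = AUC_full - AUC_reduced.

    Reduced models reuse the split's seed, so full and reduced runs differ
    only in the eliminated feature.  Splits whose training fails are logged,
    skipped and reported.
    """
    if len(schema.time_variables) < 2:
        raise TecoError("feature elimination needs at least 2 time-dependent variables")
    windows_full = make_windows(cohort, schema, horizon_h, lookback_h, policy="training")
    rows, failures = [], []
    for s, (train_ids, val_ids) in enumerate(split_plan.splits):
        seed = derive_seed(train_config.seed, horizon_h, s)
        cfg = replace(train_config, seed=seed)
        try:
            full_model, _ = train_submodel(windows_full, (train_ids, val_ids), teco_config, cfg)
            auc_full = _val_auc(full_model, windows_full, set(val_ids))
        except TecoError as exc:
            failures.append(f"split {s} full model: {exc}")
            continue
        for feature in schema.time_variables:
            red_schema = schema.drop_variable(feature)
            red_config = replace(teco_config, feature_dim=red_schema.feature_dim)
            red_windows = make_windows(
                cohort, red_schema, horizon_h, lookback_h, policy="training"
            )
            try:
                red_model, _ = train_submodel(
                    red_windows, (train_ids, val_ids), red_config, cfg
                )
                auc_red = _val_auc(red_model, red_windows, set(val_ids))
            except TecoError as exc:
                failures.append(f"split {s} without {feature}: {exc}")
                continue
            rows.append(
                {"feature": feature, "split": s, "auc_full": auc_full,
                 "auc_reduced": auc_red, "gain": auc_full - auc_red}
            )
    return ImportanceReport(elimination=pd.DataFrame(rows), failures=failures)


def ablate_baseline(
    cohort: CohortDataset,
    schema: FeatureSchema,
    horizon_h: int,
    split_plan: SplitPlan,
    teco_config: TECOConfig,
    train_config: TrainConfig,
    lookback_h: float = 96.0,
    families: tuple[str, ...] = ("teco", "rf", "xgb"),
) -> pd.DataFrame:
    """Full-model vs time-only-model AUC per family and split."""
    if schema.baseline_width == 0:
        raise TecoError("schema has no baseline block to ablate")
    schema_time = schema.without_baseline()
    cfg_full = replace(teco_config, feature_dim=schema.feature_dim)
    cfg_time = replace(teco_config, feature_dim=schema_time.feature_dim)
    w_full = make_windows(cohort, schema, horizon_h, lookback_h, policy="training")
    w_time = make_windows(cohort, schema_time, horizon_h, lookback_h, policy="training")
    rows = []
    for s, (train_ids, val_ids) in enumerate(split_plan.splits):
        seed = derive_seed(train_config.seed, horizon_h, s)
        cfg = replace(train_config, seed=seed)
        vset = set(val_ids)
        for family in families:
            if family == "teco":
                m_full, _ = train_submodel(w_full, (train_ids, val_ids), cfg_full, cfg)
                m_time, _ = train_submodel(w_time, (train_ids, val_ids), cfg_time, cfg)
                auc_full = _val_auc(m_full, w_full, vset)
                auc_time = _val_auc(m_time, w_time, vset)
            else:
                tset = set(train_ids)
                tb_full = train_tree_baseline(
                    [w for w in w_full if w.encounter_id in tset], schema, family, seed=seed
                )
                tb_time = train_tree_baseline(
                    [w for w in w_time if w.encounter_id in tset], schema_time, family, seed=seed
                )
                val_f = [w for w in w_full if w.encounter_id in vset]
                val_t = [w for w in w_time if w.encounter_id in vset]
                auc_full = roc_auc(tb_full.score_windows(val_f), [w.label for w in val_f])
                auc_time = roc_auc(tb_time.score_windows(val_t), [w.label for w in val_t])
            rows.append(
                {"family": family, "split": s, "auc_full": auc_full,
                 "auc_time_only": auc_time, "delta": auc_full - auc_time}
            )
    return pd.DataFrame(rows)
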