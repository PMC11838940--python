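"""Synthetic ICU cohort generator.

Emulates the statistical structure the predictor assumes: per-encounter
baseline covariates with Table-1-like category mixes, a binary ICU endpoint
(death vs discharge, ~36% death prevalence in development-style cohorts),
irregular per-variable measurement streams from independent Poisson
processes over the stay, and outcome-correlated deterioration in the
monitored variables.  Dying encounters drift toward abnormal values (SF
ratio and SpO2 down; mSOFA, respiration rate and temperature up) with a slow
component over the whole stay plus a steep terminal ramp over the final
``tau_h`` hours before death, so the signal strengthens toward the outcome.

Units follow clinical convention (SF ratio ~300-450, SpO2 ~92-100,
temperature in degrees Celsius); no distributional fidelity to any real
cohort is claimed.  The generator returns a validated
:class:`~teco.data_model.CohortDataset` plus a ground-truth record of the
latent severity, drift onsets and the truly informative variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    BASELINE_COLUMNS,
    MEASUREMENT_COLUMNS,
    CohortDataset,
    CohortSchema,
    validate_cohort,
)
from .errors import ConfigurationError


@dataclass(frozen=True)
class VariableModel:
    """Sampling and deterioration parameters for one monitored variable."""

    healthy_mean: float
    between_sd: float  # between-encounter spread of the personal level
    noise_sd: float  # within-encounter observation noise
    rate_per_h: float  # Poisson sampling rate, events/hour
    drift_per_h: float  # terminal drift, units/hour (signed toward abnormal)


def _default_variables() -> dict[str, VariableModel]:
    return {
        "temperature": VariableModel(37.0, 0.3, 0.3, 1.0, +0.015),
        "resp_rate": VariableModel(18.0, 2.0, 2.5, 2.0, +0.12),
        "spo2": VariableModel(96.5, 1.0, 1.2, 2.0, -0.06),
        "msofa": VariableModel(4.0, 1.5, 1.0, 0.25, +0.08),
        "msofa_resp": VariableModel(1.5, 0.8, 0.5, 0.25, +0.03),
        "sf_ratio": VariableModel(380.0, 40.0, 30.0, 1.0, -2.5),
        "bmi": VariableModel(30.0, 6.0, 0.3, 0.05, 0.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate a development-style cohort."""

    n_encounters: int = 300
    death_fraction: float = 0.359
    stay_median_h: float = 96.0
    stay_sigma: float = 0.6  # log-normal shape of stay length
    stay_min_h: float = 12.0
    variables: dict[str, VariableModel] = field(default_factory=_default_variables)
    rate_scale: float = 1.0  # global multiplier on sampling rates
    tau_h: float = 48.0  # terminal deterioration window before death
    slow_drift_frac: float = 0.15  # whole-stay drift as a fraction of drift_per_h
    drift_scale: float = 1.0  # global multiplier on deterioration
    age_mean: float = 62.0
    age_sd: float = 15.0
    sex_probs: tuple[float, ...] = (0.581, 0.419, 0.0)  # Male, Female, Unknown
    race_probs: tuple[float, ...] = (0.740, 0.155, 0.048, 0.057)
    ethnicity_probs: tuple[float, ...] = (0.276, 0.668, 0.056)
    bmi_mean: float = 31.0
    bmi_sd: float = 7.0
    bmi_missing_frac: float = 0.19
    beta_age: float = 0.4  # per SD of age, log-odds of death
    beta_sex_male: float = 0.2
    beta_latent: float = 0.8  # latent severity coefficient
    baseline_effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.death_fraction < 1.0):
            raise ConfigurationError("death_fraction must be in (0,1)")
        if self.tau_h <= 0 or self.stay_median_h <= 0 or self.rate_scale < 0:
            raise ConfigurationError("rates, stays and tau must be positive")


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Bisect the logistic intercept so the mean death probability hits target."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(lp + mid)))).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def informative_variables(config: SimConfig) -> list[str]:
    """Variables that actually carry outcome signal under this config."""
    if config.drift_scale == 0:
        return []
    return [v for v, m in config.variables.items() if m.drift_per_h != 0.0]


def simulate_cohort(config: SimConfig) -> tuple[CohortDataset, dict]:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_encounters
    ids = [f"enc{i:05d}" for i in range(n)]

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 100.0)
    sex = rng.choice(["Male", "Female", "Unknown"], size=n, p=config.sex_probs)
    race = rng.choice(["White", "Black", "Other", "Unknown"], size=n, p=config.race_probs)
    ethnicity = rng.choice(
        ["Hispanic", "Non-Hispanic", "Unknown"], size=n, p=config.ethnicity_probs
    )
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 60.0)
    bmi_missing = rng.random(n) < config.bmi_missing_frac

    latent = rng.standard_normal(n)
    z_age = (age - config.age_mean) / config.age_sd
    lp = config.baseline_effect_scale * (
        config.beta_age * z_age + config.beta_sex_male * (sex == "Male")
    ) + config.beta_latent * latent
    b0 = _calibrate_intercept(lp, config.death_fraction)
    p_death = 1.0 / (1.0 + np.exp(-(lp + b0)))
    death = rng.random(n) < p_death
    achieved = float(death.mean())
    if abs(achieved - config.death_fraction) > 0.05 and n >= 500:
        warnings.warn(
            f"achieved death fraction {achieved:.3f} differs from target "
            f"{config.death_fraction:.3f}", stacklevel=2,
        )

    stay_h = np.maximum(
        rng.lognormal(np.log(config.stay_median_h), config.stay_sigma, n), config.stay_min_h
    )
    outcome_time_min = stay_h * 60.0
    drift_onset_h = np.where(death, np.maximum(stay_h - config.tau_h, 0.0), np.nan)

    meas_frames = []
    for i in range(n):
        T_min = outcome_time_min[i]
        rows_t, rows_v, rows_var = [], [], []
        for var, m in config.variables.items():
            lam = m.rate_per_h * config.rate_scale * stay_h[i]
            k = rng.poisson(lam)
            if k == 0:
                continue
            t = np.sort(rng.uniform(0.0, T_min * (1.0 - 1e-9), k))
            level = config.bmi_mean if var == "bmi" else m.healthy_mean
            if var == "bmi":
                personal = bmi[i]
            else:
                personal = level + rng.normal(0.0, m.between_sd)
            v = personal + rng.normal(0.0, m.noise_sd, k)
            if death[i] and config.drift_scale != 0.0 and m.drift_per_h != 0.0:
                t_h = t / 60.0
                slow = config.slow_drift_frac * m.drift_per_h * t_h
                ramp = m.drift_per_h * np.maximum(0.0, t_h - drift_onset_h[i])
                v = v + config.drift_scale * (slow + ramp)
            rows_t.append(t)
            rows_v.append(v)
            rows_var.append(np.repeat(var, k))
        if rows_t:
            meas_frames.append(
                pd.DataFrame(
                    {"encounter_id": ids[i],
                     "variable": np.concatenate(rows_var),
                     "t_minutes": np.concatenate(rows_t),
                     "value": np.concatenate(rows_v)}
                )
            )
    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        if meas_frames
        else pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    )
    baseline = pd.DataFrame(
        {"encounter_id": ids, "age": age, "sex": sex, "race": race,
         "ethnicity": ethnicity, "bmi": np.where(bmi_missing, np.nan, bmi),
         "outcome": np.where(death, "death", "discharge"),
         "outcome_time_minutes": outcome_time_min}
    )
    cohort = validate_cohort(measurements, baseline, CohortSchema())
    ground_truth = {
        "per_encounter": pd.DataFrame(
            {"encounter_id": ids, "latent_severity": latent, "p_death": p_death,
             "death": death, "stay_h": stay_h, "drift_onset_h": drift_onset_h}
        ).set_index("encounter_id"),
        "informative_variables": informative_variables(config),
        "achieved_death_fraction": achieved,
        "intercept": b0,
    }
    return cohort, ground_truth


def simulate_score_series(
    cohort: CohortDataset,
    ground_truth: dict,
    interval_h: float = 1.0,
    signal: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """A generic proprietary-index-style score sampled over each stay.

    The score is a logistic transform of latent severity plus terminal-drift
    progress with observation noise — enough structure to exercise the
    24-hour-mean threshold evaluation, with no claim about any real index.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    gt = ground_truth["per_encounter"]
    rows = []
    for eid in cohort.encounter_ids:
        rec = cohort.baseline_record(eid)
        t = np.arange(interval_h * 60.0, rec.outcome_time, interval_h * 60.0)
        if t.size == 0:
            continue
        g = gt.loc[eid]
        progress = np.zeros_like(t)
        if g["death"] and np.isfinite(g["drift_onset_h"]):
            progress = np.maximum(0.0, t / 60.0 - g["drift_onset_h"]) / max(
                1e-9, g["stay_h"] - g["drift_onset_h"]
            )
        x = signal * progress + 0.5 * g["latent_severity"] + rng.normal(0, noise_sd, t.size)
        rows.append(
            pd.DataFrame(
                {"encounter_id": eid, "t_minutes": t, "score": 1.0 / (1.0 + np.exp(-x))}
            )
        )
    return pd.concat(rows, ignore_index=True)


def fixture_presets() -> dict[str, SimConfig]:
    """Named generator configurations used throughout the tests and examples.

    - ``strong-signal-small``: n=300, amplified terminal drift and short
      stays; a tiny model separates the outcomes quickly.
    - ``null``: no drift, no baseline effects, no latent coupling — any
      model should score chance AUC.
    - ``baseline-only``: outcome depends only on age and sex.
    - ``table1-like``: development-cohort scale and category mixes with the
      ~36% death prevalence.
    """
    return {
        "strong-signal-small": SimConfig(
            n_encounters=300, stay_median_h=72.0, stay_sigma=0.5,
            drift_scale=3.0, baseline_effect_scale=0.5,
        ),
        "null": SimConfig(
            n_encounters=300, stay_median_h=72.0, stay_sigma=0.5,
            drift_scale=0.0, baseline_effect_scale=0.0, beta_latent=0.0,
        ),
        "baseline-only": SimConfig(
            n_encounters=300, stay_median_h=72.0, stay_sigma=0.5,
            drift_scale=0.0, baseline_effect_scale=3.0, beta_latent=0.0,
        ),
        "table1-like": SimConfig(
            n_encounters=2579, death_fraction=0.359, rate_scale=0.1,
        ),
    }


def preset(name: str, seed: int | None = None, **overrides) -> SimConfig:
    """Look up a preset, optionally overriding the seed or other fields."""
    presets = fixture_presets()
    if name not in presets:
        raise ConfigurationError(f"unknown preset {name!r}; have {sorted(presets)}")
    cfg = presets[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(cfg, **overrides) if overrides else cfg
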