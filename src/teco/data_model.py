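"""Domain types and delimited-text I/O for ICU monitoring cohorts.

A cohort is two tables.  The *measurement* table holds timestamped
observations of the monitored variables (body temperature, respiration rate,
SpO2, mSOFA, mSOFA respiratory sub-score, SF ratio and BMI), with timestamps
expressed in minutes since ICU admission.  The *baseline* table holds one row
per encounter: age, sex, race, ethnicity, an optional baseline BMI, the ICU
endpoint (death or discharge) and the time at which it occurred.

Timestamps are admission-relative by contract: callers ingesting wall-clock
data must subtract the admission time first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, SchemaError

#: Monitored (time-dependent) variables, in canonical model order.
TIME_VARIABLES: tuple[str, ...] = (
    "temperature",
    "resp_rate",
    "spo2",
    "msofa",
    "msofa_resp",
    "sf_ratio",
    "bmi",
)

SEX_LEVELS: tuple[str, ...] = ("Male", "Female", "Unknown")
RACE_LEVELS: tuple[str, ...] = ("White", "Black", "Other", "Unknown")
ETHNICITY_LEVELS: tuple[str, ...] = ("Hispanic", "Non-Hispanic", "Unknown")
BMI_LEVELS: tuple[str, ...] = ("Underweight", "Normal", "Overweight", "Obese", "Unknown")
OUTCOME_LEVELS: tuple[str, ...] = ("death", "discharge")

MEASUREMENT_COLUMNS = ["encounter_id", "variable", "t_minutes", "value"]
BASELINE_COLUMNS = [
    "encounter_id",
    "age",
    "sex",
    "race",
    "ethnicity",
    "bmi",
    "outcome",
    "outcome_time_minutes",
]


def bmi_category(bmi: float | None) -> str:
    """WHO BMI class; ``Unknown`` for missing values."""
    if bmi is None or (isinstance(bmi, float) and np.isnan(bmi)):
        return "Unknown"
    if bmi < 18.5:
        return "Underweight"
    if bmi < 25.0:
        return "Normal"
    if bmi < 30.0:
        return "Overweight"
    return "Obese"


@dataclass(frozen=True)
class MeasurementRecord:
    """One timestamped observation of one monitored variable."""

    encounter_id: str
    variable: str
    t: float  # minutes since ICU admission
    value: float


@dataclass(frozen=True)
class BaselineRecord:
    """Per-encounter static covariates and the ICU endpoint."""

    encounter_id: str
    age: float
    sex: str
    race: str
    ethnicity: str
    bmi_baseline: float | None
    outcome: str  # "death" | "discharge"
    outcome_time: float  # minutes since admission


@dataclass(frozen=True)
class CohortSchema:
    """Which variables are time-dependent for this cohort.

    BMI is monitored continuously in COVID-like cohorts but only available at
    admission in MIMIC-style cohorts; dropping ``"bmi"`` from
    ``time_variables`` switches it to baseline-only use.
    """

    time_variables: tuple[str, ...] = TIME_VARIABLES

    def __post_init__(self) -> None:
        unknown = set(self.time_variables) - set(TIME_VARIABLES)
        if unknown:
            raise SchemaError(f"unknown time-dependent variables: {sorted(unknown)}")


@dataclass
class ValidationIssue:
    """One rejected input row and the invariant it violated."""

    table: str  # "measurements" | "baseline"
    row: int  # 0-based row index in the input table
    kind: str  # "schema" | "referential" | "temporal" | "value"
    message: str


@dataclass
class CohortDataset:
    """A validated cohort: baseline table keyed by encounter, measurements, schema.

    Invariants: every measurement's encounter has exactly one baseline row and
    every measurement time precedes that encounter's outcome time.
    """

    baseline: pd.DataFrame  # indexed by encounter_id
    measurements: pd.DataFrame  # columns MEASUREMENT_COLUMNS
    schema: CohortSchema = field(default_factory=CohortSchema)
    report: list[ValidationIssue] = field(default_factory=list)

    @property
    def encounter_ids(self) -> list[str]:
        return list(self.baseline.index)

    @property
    def n_encounters(self) -> int:
        return len(self.baseline)

    def measurements_for(self, encounter_id: str) -> pd.DataFrame:
        if encounter_id not in self.baseline.index:
            raise KeyError(f"unknown encounter: {encounter_id}")
        m = self.measurements
        return m[m["encounter_id"] == encounter_id]

    def baseline_record(self, encounter_id: str) -> BaselineRecord:
        row = self.baseline.loc[encounter_id]
        bmi = row["bmi"]
        return BaselineRecord(
            encounter_id=str(encounter_id),
            age=float(row["age"]),
            sex=str(row["sex"]),
            race=str(row["race"]),
            ethnicity=str(row["ethnicity"]),
            bmi_baseline=None if pd.isna(bmi) else float(bmi),
            outcome=str(row["outcome"]),
            outcome_time=float(row["outcome_time_minutes"]),
        )

    def encounters_with_measurements(self) -> list[str]:
        have = set(self.measurements["encounter_id"].unique())
        return [e for e in self.encounter_ids if e in have]


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing column(s): {missing}")


def validate_cohort(
    measurements: pd.DataFrame,
    baseline: pd.DataFrame,
    schema: CohortSchema | None = None,
) -> CohortDataset:
    """Validate raw tables, dropping invalid rows into a per-row report.

    Missing columns raise :class:`SchemaError`; row-level violations
    (unknown variable, non-finite or negative time, unknown encounter,
    measurement at/after the outcome, bad categorical level) reject the row
    and record a :class:`ValidationIssue`.
    """
    schema = schema or CohortSchema()
    _require_columns(measurements, MEASUREMENT_COLUMNS, "measurements")
    _require_columns(baseline, BASELINE_COLUMNS, "baseline")

    report: list[ValidationIssue] = []
    base = baseline.copy().reset_index(drop=True)
    base["encounter_id"] = base["encounter_id"].astype(str)

    keep_base = np.ones(len(base), dtype=bool)
    for i, row in base.iterrows():
        problems = []
        if not np.isfinite(row["age"]) or row["age"] <= 0:
            problems.append(("value", f"non-positive age {row['age']!r}"))
        if row["sex"] not in SEX_LEVELS:
            problems.append(("value", f"unknown sex level {row['sex']!r}"))
        if row["race"] not in RACE_LEVELS:
            problems.append(("value", f"unknown race level {row['race']!r}"))
        if row["ethnicity"] not in ETHNICITY_LEVELS:
            problems.append(("value", f"unknown ethnicity level {row['ethnicity']!r}"))
        if row["outcome"] not in OUTCOME_LEVELS:
            problems.append(("value", f"unknown outcome {row['outcome']!r}"))
        t_out = row["outcome_time_minutes"]
        if not np.isfinite(t_out) or t_out <= 0:
            problems.append(("temporal", f"outcome_time must be > 0, got {t_out!r}"))
        for kind, msg in problems:
            report.append(ValidationIssue("baseline", int(i), kind, msg))
        if problems:
            keep_base[i] = False
    base = base[keep_base]
    if base["encounter_id"].duplicated().any():
        dups = base[base["encounter_id"].duplicated()]
        for i in dups.index:
            report.append(
                ValidationIssue("baseline", int(i), "referential", "duplicate encounter_id")
            )
        base = base[~base["encounter_id"].duplicated()]
    base = base.set_index("encounter_id", drop=False)

    meas = measurements.copy().reset_index(drop=True)
    meas["encounter_id"] = meas["encounter_id"].astype(str)
    outcome_time = base["outcome_time_minutes"]

    t = pd.to_numeric(meas["t_minutes"], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(meas["value"], errors="coerce").to_numpy(dtype=float)
    known_var = meas["variable"].isin(TIME_VARIABLES).to_numpy()
    known_enc = meas["encounter_id"].isin(base.index).to_numpy()
    t_end = meas["encounter_id"].map(outcome_time).to_numpy(dtype=float)

    keep = np.ones(len(meas), dtype=bool)
    for i in range(len(meas)):
        if not known_var[i]:
            report.append(
                ValidationIssue(
                    "measurements", i, "schema", f"unknown variable {meas['variable'].iat[i]!r}"
                )
            )
            keep[i] = False
        elif not known_enc[i]:
            report.append(
                ValidationIssue(
                    "measurements",
                    i,
                    "referential",
                    f"encounter {meas['encounter_id'].iat[i]!r} has no baseline row",
                )
            )
            keep[i] = False
        elif not np.isfinite(t[i]) or t[i] < 0:
            report.append(
                ValidationIssue("measurements", i, "temporal", f"invalid time {t[i]!r}")
            )
            keep[i] = False
        elif t[i] >= t_end[i]:
            report.append(
                ValidationIssue(
                    "measurements",
                    i,
                    "temporal",
                    f"t={t[i]} not before outcome_time={t_end[i]}",
                )
            )
            keep[i] = False
        elif not np.isfinite(v[i]):
            report.append(
                ValidationIssue("measurements", i, "value", f"non-finite value {v[i]!r}")
            )
            keep[i] = False

    meas = meas[keep]
    meas["t_minutes"] = t[keep]
    meas["value"] = v[keep]
    meas = meas[MEASUREMENT_COLUMNS].reset_index(drop=True)
    return CohortDataset(baseline=base, measurements=meas, schema=schema, report=report)


def read_cohort(
    measurements_path,
    baseline_path,
    schema: CohortSchema | None = None,
) -> CohortDataset:
    """Read and validate a cohort from the two CSV files."""
    meas = pd.read_csv(measurements_path, dtype={"encounter_id": str})
    base = pd.read_csv(baseline_path, dtype={"encounter_id": str})
    return validate_cohort(meas, base, schema)


def write_cohort(cohort: CohortDataset, measurements_path, baseline_path) -> None:
    """Write the cohort in canonical order (byte-stable for round-trips)."""
    meas = cohort.measurements.sort_values(
        ["encounter_id", "variable", "t_minutes"], kind="mergesort"
    )
    meas.to_csv(measurements_path, index=False, columns=MEASUREMENT_COLUMNS)
    base = cohort.baseline.reset_index(drop=True).sort_values("encounter_id", kind="mergesort")
    base.to_csv(baseline_path, index=False, columns=BASELINE_COLUMNS)


def cohort_summary(cohort: CohortDataset) -> pd.DataFrame:
    """Table-1-style summary: category counts with percentages and age quartiles.

    Age quartiles use linear interpolation between order statistics (the
    numpy default), which for three ages {50, 60, 70} gives Q1=55, Q3=65.
    """
    if cohort.n_encounters == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    base = cohort.baseline
    n = len(base)
    rows: list[dict] = [{"section": "n", "level": "encounters", "n": n, "pct": 100.0}]

    age = base["age"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(age, [25, 50, 75])
    rows.append(
        {"section": "age", "level": "median (Q1, Q3)", "n": n, "pct": np.nan,
         "median": round(float(med), 1), "q1": round(float(q1), 1), "q3": round(float(q3), 1)}
    )

    bmi_cat = base["bmi"].map(bmi_category)
    sections = {
        "outcome": (base["outcome"], OUTCOME_LEVELS),
        "sex": (base["sex"], SEX_LEVELS),
        "race": (base["race"], RACE_LEVELS),
        "ethnicity": (base["ethnicity"], ETHNICITY_LEVELS),
        "bmi_category": (bmi_cat, BMI_LEVELS),
    }
    for section, (series, levels) in sections.items():
        counts = series.value_counts()
        for level in levels:
            c = int(counts.get(level, 0))
            rows.append(
                {"section": section, "level": level, "n": c, "pct": round(100.0 * c / n, 1)}
            )
    return pd.DataFrame(rows)
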