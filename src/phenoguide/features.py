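"""Feature registry for ICU time-series variables.

Each variable carries its within-window aggregation rule, its role in the
pipeline, inclusive clinical-plausibility bounds used for outlier removal,
and a ``skewed`` flag selecting median[Q1,Q3] instead of mean(SD) in cluster
summary tables.

Roles
-----
``encoder_input``
    Fed to the recurrent encoder (after normalization).
``outcome_source``
    Used only to derive next-step labels (PEEP -> mechanical ventilation,
    documented RRT -> renal replacement therapy); never an encoder input,
    since it would leak the label.
``action_source``
    IV fluid volume and vasopressor rate; they define the treatment action
    space and are excluded from the encoder input so that phenotypes are not
    confounded by the interventions themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

AGGREGATIONS = ("mean", "min", "max", "sum")
ROLES = ("encoder_input", "outcome_source", "action_source", "excluded")


@dataclass(frozen=True)
class FeatureSpec:
    """Registration record for one clinical variable."""

    name: str
    aggregation: str
    role: str
    outlier_min: float
    outlier_max: float
    skewed: bool = False

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"{self.name}: unknown aggregation {self.aggregation!r}")
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}")
        if not self.outlier_min <= self.outlier_max:
            raise ValueError(f"{self.name}: outlier_min > outlier_max")
        if self.role == "action_source" and self.aggregation not in ("sum", "max"):
            raise ValueError(f"{self.name}: action variables aggregate by sum/max")


# name, aggregation, role, lo, hi, skewed
_DEFAULT_TABLE = [
    # vitals
    ("heart_rate", "mean", "encoder_input", 20, 250, False),
    ("sbp", "mean", "encoder_input", 40, 250, False),
    ("mbp", "mean", "encoder_input", 30, 180, False),
    ("dbp", "mean", "encoder_input", 20, 150, False),
    ("spo2", "mean", "encoder_input", 50, 100, False),
    ("resp_rate", "mean", "encoder_input", 4, 60, False),
    ("temperature", "mean", "encoder_input", 30, 43, False),
    ("cvp", "mean", "encoder_input", -5, 40, False),
    # labs
    ("albumin", "mean", "encoder_input", 5, 60, False),
    ("crp", "mean", "encoder_input", 0, 600, True),
    ("ast", "mean", "encoder_input", 5, 4000, True),
    ("alt", "mean", "encoder_input", 5, 4000, True),
    ("bicarbonate", "mean", "encoder_input", 5, 50, False),
    ("bilirubin", "mean", "encoder_input", 1, 500, True),
    ("bun", "mean", "encoder_input", 1, 80, True),
    ("calcium", "mean", "encoder_input", 1.0, 4.0, False),
    ("chloride", "mean", "encoder_input", 70, 140, False),
    ("potassium", "mean", "encoder_input", 1.5, 9.0, False),
    ("creatinine", "mean", "encoder_input", 10, 1500, True),
    ("glucose", "mean", "encoder_input", 1, 50, True),
    ("hematocrit", "mean", "encoder_input", 0.10, 0.70, False),
    ("hemoglobin", "mean", "encoder_input", 2, 12, False),
    ("inr", "mean", "encoder_input", 0.5, 12, True),
    ("lactate", "mean", "encoder_input", 0.1, 30, True),
    ("pao2", "mean", "encoder_input", 20, 600, False),
    ("paco2", "mean", "encoder_input", 10, 150, False),
    ("ph", "mean", "encoder_input", 6.8, 7.8, False),
    ("platelets", "mean", "encoder_input", 1, 1500, False),
    ("sodium", "mean", "encoder_input", 100, 180, False),
    ("wbc", "mean", "encoder_input", 0.1, 200, True),
    # neurological scores: the worst (minimum) value within the window
    ("gcs_eye", "min", "encoder_input", 1, 4, False),
    ("gcs_motor", "min", "encoder_input", 1, 6, False),
    ("gcs_verbal", "min", "encoder_input", 1, 5, False),
    # outcome sources (label derivation only)
    ("peep", "max", "outcome_source", 0, 30, False),
    ("rrt", "max", "outcome_source", 0, 1, False),
    # treatment actions
    ("iv_fluid", "sum", "action_source", 0, 5000, True),
    ("vasopressor", "max", "action_source", 0, 5, True),
]

# per-window demographics broadcast from the admission table
DEMOGRAPHIC_FEATURES = ("age", "weight", "height", "gender")
MISSING_FLAG_FEATURES = ("weight_missing", "height_missing")

WINDOW_HOURS = 4.0


def default_feature_specs() -> dict[str, FeatureSpec]:
    """The default variable registry (event-table vocabulary)."""
    return {
        name: FeatureSpec(name, agg, role, lo, hi, skewed)
        for name, agg, role, lo, hi, skewed in _DEFAULT_TABLE
    }


def specs_by_role(specs: dict[str, FeatureSpec], role: str) -> list[str]:
    return [s.name for s in specs.values() if s.role == role]


def specs_to_frame(specs: dict[str, FeatureSpec]) -> pd.DataFrame:
    """Registry as a table (variable, aggregation, role, min, max, skewed)."""
    return pd.DataFrame(
        [
            (s.name, s.aggregation, s.role, s.outlier_min, s.outlier_max, s.skewed)
            for s in specs.values()
        ],
        columns=["variable", "aggregation", "role", "outlier_min", "outlier_max", "skewed"],
    )


def specs_from_frame(frame: pd.DataFrame) -> dict[str, FeatureSpec]:
    """Inverse of :func:`specs_to_frame` (e.g. user-supplied bound tables)."""
    return {
        row.variable: FeatureSpec(
            row.variable,
            row.aggregation,
            row.role,
            float(row.outlier_min),
            float(row.outlier_max),
            bool(row.skewed),
        )
        for row in frame.itertuples()
    }
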