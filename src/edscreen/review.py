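"""The chart-review reference standard.

Decides, from the **full** record — chart-level history flags (free text,
scanned documents, out-of-network records) and the chart-verified visit BMI —
whether the screening alert *should* have fired.  Three rules distinguish it
from the engine:

* the chart history flags replace the structured ones (chart search finds
  everything the structured record has, and more);
* the chart-verified visit BMI (``chart_bmi``) stands in for the algorithm's
  possibly-missing BMI inputs;
* visits by patients in whom HbA1c is unreliable for diagnosis — pregnancy,
  sickle-cell anemia, HIV — are never "should trigger": alerts for them count
  against the algorithm as false positives, and silent visits count as true
  negatives.

The demographic rule itself (thresholds, age-alone reading for a BMI that is
genuinely unmeasured, lab-order requirement) mirrors the engine's
configuration: the reviewers verified the algorithm's *inputs*, not an
alternative eligibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import PatientRecord
from .engine import RuleConfig, _is_missing
from .errors import RecordValidationError

__all__ = [
    "RationaleCode",
    "ReferenceLabel",
    "review_chart",
    "review_frame",
    "classify_pair",
    "classify_frame",
    "ChartReviewLabeler",
]


class RationaleCode(str, Enum):
    TRULY_ELIGIBLE = "truly_eligible"
    CHART_DIABETES_FOUND = "chart_diabetes_found"
    CHART_HBA1C_FOUND = "chart_hba1c_found"
    EXCLUDED_CONDITION = "excluded_condition"
    AGE_BMI_INELIGIBLE = "age_bmi_ineligible"


@dataclass(frozen=True)
class ReferenceLabel:
    should_trigger: bool
    unreliable_hba1c: bool
    rationale_codes: frozenset[RationaleCode]

    def __post_init__(self) -> None:
        if self.unreliable_hba1c:
            assert not self.should_trigger
        if {RationaleCode.CHART_DIABETES_FOUND, RationaleCode.CHART_HBA1C_FOUND} & self.rationale_codes:
            assert not self.should_trigger


def review_chart(record, config: RuleConfig | None = None) -> ReferenceLabel:
    """Reference-standard label for one visit."""
    config = (config or RuleConfig()).validate()
    get = (lambda k: getattr(record, k, None)) if isinstance(record, PatientRecord) else (
        lambda k: record.get(k, None) if isinstance(record, Mapping) else record.get(k)
    )

    age = get("age")
    chart_bmi = get("chart_bmi")
    if _is_missing(chart_bmi):
        chart_bmi = get("visit_bmi")
    if _is_missing(chart_bmi):
        chart_bmi = get("most_recent_bmi")
    for name, v in (("age", age), ("chart_bmi", chart_bmi)):
        if not _is_missing(v) and v < 0:
            raise RecordValidationError(f"negative {name} in record")

    if _is_missing(age):
        demographic = False
    else:
        age_ok = age >= config.age_threshold_alone
        if _is_missing(chart_bmi):
            bmi_ok = False
            if config.missing_bmi_policy == "suppress":
                age_ok = False
        else:
            bmi_ok = age >= config.age_threshold_with_bmi and chart_bmi >= config.bmi_threshold
        demographic = age_ok or bmi_ok
    if config.require_lab_ordered and not bool(get("lab_ordered")):
        demographic = False

    chart_dm = bool(get("chart_diabetes_history"))
    chart_a1c = bool(get("chart_hba1c_within_3y"))
    exclusion = get("exclusion_condition") or "none"
    unreliable = exclusion != "none"

    codes: set[RationaleCode] = set()
    if not demographic:
        codes.add(RationaleCode.AGE_BMI_INELIGIBLE)
    if chart_dm:
        codes.add(RationaleCode.CHART_DIABETES_FOUND)
    if chart_a1c:
        codes.add(RationaleCode.CHART_HBA1C_FOUND)
    if unreliable:
        codes.add(RationaleCode.EXCLUDED_CONDITION)

    should = demographic and not chart_dm and not chart_a1c and not unreliable
    if should:
        codes.add(RationaleCode.TRULY_ELIGIBLE)
    return ReferenceLabel(should_trigger=should, unreliable_hba1c=unreliable,
                          rationale_codes=frozenset(codes))


def review_frame(cohort: pd.DataFrame, config: RuleConfig | None = None) -> pd.DataFrame:
    """Vectorized :func:`review_chart` over a cohort frame."""
    config = (config or RuleConfig()).validate()
    age = pd.to_numeric(cohort["age"], errors="coerce").to_numpy(dtype=float)
    chart_bmi = cohort["chart_bmi"].to_numpy(dtype=float) if "chart_bmi" in cohort.columns \
        else np.full(len(cohort), np.nan)
    chart_bmi = np.where(np.isnan(chart_bmi), cohort["visit_bmi"].to_numpy(dtype=float), chart_bmi)
    chart_bmi = np.where(np.isnan(chart_bmi), cohort["most_recent_bmi"].to_numpy(dtype=float), chart_bmi)
    for name, v in (("age", age), ("chart_bmi", chart_bmi)):
        if np.nanmin(v, initial=0.0) < 0:
            raise RecordValidationError(f"negative {name} in cohort")

    age_missing = np.isnan(age)
    bmi_missing = np.isnan(chart_bmi)
    age_ok = ~age_missing & (age >= config.age_threshold_alone)
    if config.missing_bmi_policy == "suppress":
        age_ok = age_ok & ~bmi_missing
    bmi_ok = (~age_missing & ~bmi_missing
              & (age >= config.age_threshold_with_bmi)
              & (chart_bmi >= config.bmi_threshold))
    demographic = age_ok | bmi_ok
    if config.require_lab_ordered:
        demographic = demographic & cohort["lab_ordered"].to_numpy(dtype=bool)

    chart_dm = cohort["chart_diabetes_history"].to_numpy(dtype=bool)
    chart_a1c = cohort["chart_hba1c_within_3y"].to_numpy(dtype=bool)
    unreliable = (cohort["exclusion_condition"].fillna("none") != "none").to_numpy(dtype=bool)

    should = demographic & ~chart_dm & ~chart_a1c & ~unreliable
    code_masks = [
        (RationaleCode.TRULY_ELIGIBLE, should),
        (RationaleCode.CHART_DIABETES_FOUND, chart_dm),
        (RationaleCode.CHART_HBA1C_FOUND, chart_a1c),
        (RationaleCode.EXCLUDED_CONDITION, unreliable),
        (RationaleCode.AGE_BMI_INELIGIBLE, ~demographic),
    ]
    n = len(cohort)
    parts: list[list[str]] = [[] for _ in range(n)]
    for code, mask in code_masks:
        for i in np.flatnonzero(mask):
            parts[i].append(code.value)
    return pd.DataFrame(
        {
            "visit_id": cohort["visit_id"].to_numpy(),
            "should_trigger": should,
            "unreliable_hba1c": unreliable,
            "rationale_codes": [";".join(p) for p in parts],
        },
        index=cohort.index,
    )


def classify_pair(decision, label) -> str:
    """Confusion-cell assignment for one (engine decision, reference label) pair."""
    triggered = decision.triggered if hasattr(decision, "triggered") else bool(decision)
    should = label.should_trigger if hasattr(label, "should_trigger") else bool(label)
    if triggered and should:
        return "TP"
    if triggered and not should:
        return "FP"
    if not triggered and should:
        return "FN"
    return "TN"


def classify_frame(triggered, should_trigger) -> np.ndarray:
    """Vectorized :func:`classify_pair` on aligned boolean arrays."""
    t = np.asarray(triggered, dtype=bool)
    s = np.asarray(should_trigger, dtype=bool)
    return np.select([t & s, t & ~s, ~t & s], ["TP", "FP", "FN"], default="TN")


class ChartReviewLabeler(TransformerMixin, BaseEstimator):
    """Scikit-learn wrapper around the reference standard.

    ``transform`` yields the full label frame; ``predict`` yields the boolean
    should-trigger labels so the labeler can stand in as the ground-truth arm
    in sklearn metric computations.
    """

    def __init__(self, age_threshold_alone: float = 45.0, age_threshold_with_bmi: float = 18.0,
                 bmi_threshold: float = 25.0, require_lab_ordered: bool = True,
                 missing_bmi_policy: str = "age-alone"):
        self.age_threshold_alone = age_threshold_alone
        self.age_threshold_with_bmi = age_threshold_with_bmi
        self.bmi_threshold = bmi_threshold
        self.require_lab_ordered = require_lab_ordered
        self.missing_bmi_policy = missing_bmi_policy

    def _config(self) -> RuleConfig:
        return RuleConfig(
            age_threshold_alone=self.age_threshold_alone,
            age_threshold_with_bmi=self.age_threshold_with_bmi,
            bmi_threshold=self.bmi_threshold,
            require_lab_ordered=self.require_lab_ordered,
            missing_bmi_policy=self.missing_bmi_policy,
        ).validate()

    def fit(self, X: pd.DataFrame, y=None) -> "ChartReviewLabeler":
        self.rule_config_ = self._config()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        config = getattr(self, "rule_config_", None) or self._config()
        return review_frame(X, config)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.transform(X)["should_trigger"].to_numpy()
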