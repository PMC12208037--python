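"""The screening-alert rule engine (the algorithm under validation).

A best-practice advisory (BPA) fires for an ED visit when, judging **only from
the structured record**, the patient is eligible for HbA1c screening:

1. age >= 45 years; **or**
2. age >= 18 years with BMI >= 25 kg/m2; **and**
3. no structured history of diabetes; **and**
4. no structured HbA1c result within the 3-year lookback.

If the visit BMI is missing from the structured record, the most recent BMI on
file is used; if neither is available the BMI arm cannot be evaluated.  Under
the default ``missing_bmi_policy="age-alone"`` the age-alone arm can still
fire; ``"suppress"`` reads missing BMI as suppressing the alert entirely.
Missing age always suppresses.  The alert rides on an existing routine lab
order (``require_lab_ordered``), so visits without one never fire.

All threshold comparisons are inclusive (>=).  The 3-year lookback is consumed
as a precomputed boolean; :func:`hba1c_within_lookback` documents the date rule
used to prepare it (3 x 365.25 days, half-open window ending at the visit).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import PatientRecord
from .errors import ParameterError, RecordValidationError

__all__ = [
    "RuleConfig",
    "ReasonCode",
    "BpaDecision",
    "evaluate_bpa",
    "decide_frame",
    "BpaRuleClassifier",
    "hba1c_within_lookback",
]


class ReasonCode(str, Enum):
    """Machine-readable explanation of a BPA verdict."""

    AGE_CRITERION_MET = "age_criterion_met"
    BMI_CRITERION_MET = "bmi_criterion_met"
    BMI_FALLBACK_USED = "bmi_fallback_used"
    NO_STRUCTURED_DIABETES = "no_structured_diabetes"
    NO_STRUCTURED_HBA1C = "no_structured_hba1c"
    SUPPRESSED_MISSING_BMI = "suppressed_missing_bmi"
    SUPPRESSED_MISSING_AGE = "suppressed_missing_age"
    SUPPRESSED_NO_LAB = "suppressed_no_lab"


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and switches of the alert rule."""

    age_threshold_alone: float = 45.0
    age_threshold_with_bmi: float = 18.0
    bmi_threshold: float = 25.0
    hba1c_lookback_years: float = 3.0
    require_lab_ordered: bool = True
    missing_bmi_policy: str = "age-alone"  # or "suppress"

    def validate(self) -> "RuleConfig":
        if min(self.age_threshold_alone, self.age_threshold_with_bmi,
               self.bmi_threshold, self.hba1c_lookback_years) <= 0:
            raise ParameterError("all rule thresholds must be positive")
        if self.age_threshold_with_bmi > self.age_threshold_alone:
            raise ParameterError("age_threshold_with_bmi must not exceed age_threshold_alone")
        if self.missing_bmi_policy not in ("age-alone", "suppress"):
            raise ParameterError(f"unknown missing_bmi_policy {self.missing_bmi_policy!r}")
        return self


@dataclass(frozen=True)
class BpaDecision:
    triggered: bool
    reason_codes: frozenset[ReasonCode]

    def __post_init__(self) -> None:
        codes = self.reason_codes
        if self.triggered:
            assert (ReasonCode.AGE_CRITERION_MET in codes or ReasonCode.BMI_CRITERION_MET in codes)
            assert ReasonCode.NO_STRUCTURED_DIABETES in codes
            assert ReasonCode.NO_STRUCTURED_HBA1C in codes
            assert not any(c.value.startswith("suppressed") for c in codes)


def hba1c_within_lookback(visit_date, last_test_date, lookback_years: float = 3.0) -> bool:
    """Input-preparation rule for criterion 4: was the most recent HbA1c drawn
    within the lookback window ``[visit - years*365.25 days, visit)``?"""
    if last_test_date is None or pd.isna(last_test_date):
        return False
    visit = pd.Timestamp(visit_date)
    test = pd.Timestamp(last_test_date)
    start = visit - pd.Timedelta(days=lookback_years * 365.25)
    return bool(start <= test < visit)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def evaluate_bpa(record, config: RuleConfig | None = None) -> BpaDecision:
    """Evaluate the alert rule for one visit (structured view only).

    ``record`` may be a :class:`PatientRecord`, a mapping, or a pandas row.
    Negative age or BMI raises :class:`RecordValidationError` — that is corrupt
    input, not a clinical state.
    """
    config = (config or RuleConfig()).validate()
    get = (lambda k: getattr(record, k, None)) if isinstance(record, PatientRecord) else (
        lambda k: record.get(k, None) if isinstance(record, Mapping) else record.get(k)
    )

    age = get("age")
    visit_bmi = get("visit_bmi")
    recent_bmi = get("most_recent_bmi")
    for name, v in (("age", age), ("visit_bmi", visit_bmi), ("most_recent_bmi", recent_bmi)):
        if not _is_missing(v) and v < 0:
            raise RecordValidationError(f"negative {name} ({v}) in record")

    codes: set[ReasonCode] = set()
    suppressed = False

    if config.require_lab_ordered and not bool(get("lab_ordered")):
        codes.add(ReasonCode.SUPPRESSED_NO_LAB)
        suppressed = True

    if _is_missing(age):
        codes.add(ReasonCode.SUPPRESSED_MISSING_AGE)
        suppressed = True
        age_ok = bmi_ok = False
    else:
        age_ok = age >= config.age_threshold_alone
        if age_ok:
            codes.add(ReasonCode.AGE_CRITERION_MET)
        if _is_missing(visit_bmi):
            eff_bmi, fallback = recent_bmi, not _is_missing(recent_bmi)
        else:
            eff_bmi, fallback = visit_bmi, False
        if _is_missing(eff_bmi):
            bmi_ok = False
            if config.missing_bmi_policy == "suppress" or not age_ok:
                codes.add(ReasonCode.SUPPRESSED_MISSING_BMI)
                if config.missing_bmi_policy == "suppress":
                    suppressed = True
        else:
            bmi_ok = age >= config.age_threshold_with_bmi and eff_bmi >= config.bmi_threshold
            if bmi_ok:
                codes.add(ReasonCode.BMI_CRITERION_MET)
                if fallback:
                    codes.add(ReasonCode.BMI_FALLBACK_USED)

    no_dm = not bool(get("structured_diabetes_history"))
    no_a1c = not bool(get("structured_hba1c_within_3y"))
    if no_dm:
        codes.add(ReasonCode.NO_STRUCTURED_DIABETES)
    if no_a1c:
        codes.add(ReasonCode.NO_STRUCTURED_HBA1C)

    triggered = (not suppressed) and (age_ok or bmi_ok) and no_dm and no_a1c
    return BpaDecision(triggered=triggered, reason_codes=frozenset(codes))


def decide_frame(cohort: pd.DataFrame, config: RuleConfig | None = None) -> pd.DataFrame:
    """Vectorized :func:`evaluate_bpa` over a cohort frame.

    Returns a frame indexed like ``cohort`` with columns ``visit_id``,
    ``triggered`` and ``reason_codes`` (semicolon-joined, stable order).
    """
    config = (config or RuleConfig()).validate()
    age = pd.to_numeric(cohort["age"], errors="coerce").to_numpy(dtype=float)
    visit_bmi = cohort["visit_bmi"].to_numpy(dtype=float)
    recent_bmi = cohort["most_recent_bmi"].to_numpy(dtype=float)
    for name, v in (("age", age), ("visit_bmi", visit_bmi), ("most_recent_bmi", recent_bmi)):
        if np.nanmin(v, initial=0.0) < 0:
            raise RecordValidationError(f"negative {name} in cohort")
    lab = cohort["lab_ordered"].to_numpy(dtype=bool)
    sdm = cohort["structured_diabetes_history"].to_numpy(dtype=bool)
    sa1c = cohort["structured_hba1c_within_3y"].to_numpy(dtype=bool)

    age_missing = np.isnan(age)
    age_ok = ~age_missing & (age >= config.age_threshold_alone)
    fallback = np.isnan(visit_bmi) & ~np.isnan(recent_bmi)
    eff_bmi = np.where(np.isnan(visit_bmi), recent_bmi, visit_bmi)
    bmi_missing = np.isnan(eff_bmi)
    bmi_ok = (~age_missing & ~bmi_missing
              & (age >= config.age_threshold_with_bmi)
              & (eff_bmi >= config.bmi_threshold))

    no_lab_sup = config.require_lab_ordered & ~lab
    if config.missing_bmi_policy == "suppress":
        bmi_sup = ~age_missing & bmi_missing
    else:
        bmi_sup = ~age_missing & bmi_missing & ~age_ok
    suppressed = no_lab_sup | age_missing | (bmi_missing & ~age_missing
                                             if config.missing_bmi_policy == "suppress"
                                             else np.zeros_like(lab))

    triggered = ~suppressed & (age_ok | bmi_ok) & ~sdm & ~sa1c

    code_masks = [
        (ReasonCode.AGE_CRITERION_MET, age_ok),
        (ReasonCode.BMI_CRITERION_MET, bmi_ok),
        (ReasonCode.BMI_FALLBACK_USED, bmi_ok & fallback),
        (ReasonCode.NO_STRUCTURED_DIABETES, ~sdm),
        (ReasonCode.NO_STRUCTURED_HBA1C, ~sa1c),
        (ReasonCode.SUPPRESSED_MISSING_BMI, bmi_sup),
        (ReasonCode.SUPPRESSED_MISSING_AGE, age_missing),
        (ReasonCode.SUPPRESSED_NO_LAB, no_lab_sup),
    ]
    n = len(cohort)
    parts: list[list[str]] = [[] for _ in range(n)]
    for code, mask in code_masks:
        for i in np.flatnonzero(mask):
            parts[i].append(code.value)
    return pd.DataFrame(
        {
            "visit_id": cohort["visit_id"].to_numpy(),
            "triggered": triggered,
            "reason_codes": [";".join(p) for p in parts],
        },
        index=cohort.index,
    )


class BpaRuleClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn wrapper around the alert rule.

    A deterministic, rule-based classifier: ``fit`` only validates the
    configuration (there is nothing to learn), ``predict`` returns whether the
    alert fires for each row of a cohort frame.  Composes with sklearn
    model-selection utilities for threshold sensitivity analyses.
    """

    def __init__(self, age_threshold_alone: float = 45.0, age_threshold_with_bmi: float = 18.0,
                 bmi_threshold: float = 25.0, hba1c_lookback_years: float = 3.0,
                 require_lab_ordered: bool = True, missing_bmi_policy: str = "age-alone"):
        self.age_threshold_alone = age_threshold_alone
        self.age_threshold_with_bmi = age_threshold_with_bmi
        self.bmi_threshold = bmi_threshold
        self.hba1c_lookback_years = hba1c_lookback_years
        self.require_lab_ordered = require_lab_ordered
        self.missing_bmi_policy = missing_bmi_policy

    def _config(self) -> RuleConfig:
        return RuleConfig(
            age_threshold_alone=self.age_threshold_alone,
            age_threshold_with_bmi=self.age_threshold_with_bmi,
            bmi_threshold=self.bmi_threshold,
            hba1c_lookback_years=self.hba1c_lookback_years,
            require_lab_ordered=self.require_lab_ordered,
            missing_bmi_policy=self.missing_bmi_policy,
        ).validate()

    def fit(self, X: pd.DataFrame, y=None) -> "BpaRuleClassifier":
        self.rule_config_ = self._config()
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        config = getattr(self, "rule_config_", None) or self._config()
        return decide_frame(X, config)["triggered"].to_numpy()

    def decide(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full decision frame with reason codes."""
        config = getattr(self, "rule_config_", None) or self._config()
        return decide_frame(X, config)
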