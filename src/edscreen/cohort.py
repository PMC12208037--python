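"""Synthetic emergency-department visit cohorts.

The generator emulates a one-month census of adult ED visits at an urban
hospital in which a diabetes-screening best-practice advisory (BPA) rides on
routine lab orders.  Every visit carries two views of the same history:

* a **structured** view — the fields the alerting algorithm can actually see
  (discrete diagnosis codes, in-network lab results, the BMI pulled by the
  reporting extract), and
* a **chart** view — what a human reviewer finds when searching notes, scanned
  documents and out-of-network records; by construction a superset of the
  structured view.

Discordance between the two views is modeled at the flag level ("chart-only"
diabetes or HbA1c history) plus one numeric channel: the BMI measured at the
visit (``chart_bmi``, always in the chart) may be invisible to the algorithm
(``visit_bmi`` missing) with no historical BMI on file to fall back on.  Those
channels are what turn algorithm decisions into false positives and false
negatives downstream.

Default marginals reproduce the validation cohort the package ships its
acceptance checks against: mean age 48 (SD 17.9, truncated at 18), mean BMI
30.1 (SD 8.8), 77% of adult visits with a routine lab ordered, and the
race/ethnicity, sex and insurance mix of that cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .errors import CalibrationError, ParameterError

__all__ = [
    "CohortParams",
    "PatientRecord",
    "STUDY_CELLS",
    "generate_cohort",
    "expected_cells",
    "calibrate_to_cells",
    "study_params",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_cohort_jsonl",
    "read_cohort_jsonl",
    "params_to_yaml",
    "params_from_yaml",
]

RACE_ETHNICITY_LEVELS = ("hispanic", "white_nh", "black_nh", "asian_nh", "other_nh", "unknown")
SEX_LEVELS = ("male", "female")
INSURANCE_LEVELS = ("medicaid", "medicare", "private", "other", "uninsured")
EXCLUSION_LEVELS = ("none", "pregnancy", "sickle_cell", "hiv")

#: Published validation 2x2 (TP, FP, FN, TN) used to calibrate default
#: discordance rates: alert fired appropriately for 599 visits, fired for 197
#: it should not have, missed 265 eligible visits and stayed silent for 1,902
#: ineligible ones (N = 2,963 lab-ordered adult visits).
STUDY_CELLS = (599, 197, 265, 1902)

# Exact count fractions from the validation cohort (N = 2,963).
_STRATA_DEFAULT = {
    "hispanic": 763 / 2963,
    "white_nh": 290 / 2963,
    "black_nh": 1649 / 2963,
    "asian_nh": 99 / 2963,
    "other_nh": 125 / 2963,
    "unknown": 37 / 2963,
}
_SEX_DEFAULT = {"male": 1182 / 2963, "female": 1781 / 2963}
_INSURANCE_DEFAULT = {
    "medicaid": 1374 / 2963,
    "medicare": 760 / 2963,
    "private": 613 / 2963,
    "other": 36 / 2963,
    "uninsured": 180 / 2963,
}

#: Columns of a cohort frame, in the order they are generated and written.
COHORT_COLUMNS = [
    "visit_id",
    "age",
    "visit_bmi",
    "most_recent_bmi",
    "chart_bmi",
    "lab_ordered",
    "structured_diabetes_history",
    "chart_diabetes_history",
    "structured_hba1c_within_3y",
    "chart_hba1c_within_3y",
    "exclusion_condition",
    "race_ethnicity",
    "sex",
    "insurance",
]

_BOOL_COLUMNS = [
    "lab_ordered",
    "structured_diabetes_history",
    "chart_diabetes_history",
    "structured_hba1c_within_3y",
    "chart_hba1c_within_3y",
]


@dataclass(frozen=True)
class PatientRecord:
    """One ED visit, carrying both the algorithm-visible and chart-visible views.

    ``visit_bmi`` / ``most_recent_bmi`` are what the alerting algorithm sees;
    ``chart_bmi`` is the visit BMI a chart reviewer verifies (``None`` only when
    the measurement truly does not exist anywhere).  Structured history flags
    are never set without the corresponding chart flag (superset law).
    """

    visit_id: str
    age: int | None
    visit_bmi: float | None
    most_recent_bmi: float | None
    lab_ordered: bool
    structured_diabetes_history: bool
    chart_diabetes_history: bool
    structured_hba1c_within_3y: bool
    chart_hba1c_within_3y: bool
    exclusion_condition: str = "none"
    race_ethnicity: str = "unknown"
    sex: str = "female"
    insurance: str = "uninsured"
    chart_bmi: float | None = None

    def __post_init__(self) -> None:
        if self.exclusion_condition not in EXCLUSION_LEVELS:
            raise ParameterError(f"unknown exclusion_condition {self.exclusion_condition!r}")
        if self.structured_diabetes_history and not self.chart_diabetes_history:
            raise ParameterError("structured diabetes history without chart counterpart (superset law)")
        if self.structured_hba1c_within_3y and not self.chart_hba1c_within_3y:
            raise ParameterError("structured HbA1c history without chart counterpart (superset law)")
        for name in ("visit_bmi", "most_recent_bmi", "chart_bmi"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be > 0 when present, got {v}")


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortParams:
    """Generative parameters for a synthetic ED cohort.

    Probabilities are marginal and independent across fields except where a
    field is a deterministic function of another (chart flags are unions of
    the structured flag and a chart-only draw; pregnancy forces female sex).
    """

    n_patients: int = 3850
    p_lab_ordered: float = 2963 / 3850
    age_distribution: tuple[float, float, float] = (48.0, 17.9, 18.0)  # mean, sd, min (years)
    bmi_distribution: tuple[float, float, float] = (30.1, 8.8, 12.0)  # mean, sd, min (kg/m2)
    p_visit_bmi_missing: float = 0.25
    p_no_bmi_on_file: float = 0.30
    p_structured_diabetes_history: float = 0.25
    p_chart_only_diabetes_history: float = 0.05
    p_structured_hba1c_within_3y: float = 0.20
    p_chart_only_hba1c_within_3y: float = 0.05
    p_exclusion_condition: float = 0.03
    exclusion_split: Mapping[str, float] = field(
        default_factory=lambda: {"pregnancy": 0.5, "sickle_cell": 0.3, "hiv": 0.2}
    )
    strata_proportions: Mapping[str, float] = field(default_factory=lambda: dict(_STRATA_DEFAULT))
    sex_proportions: Mapping[str, float] = field(default_factory=lambda: dict(_SEX_DEFAULT))
    insurance_proportions: Mapping[str, float] = field(default_factory=lambda: dict(_INSURANCE_DEFAULT))
    seed: int = 0

    def validate(self) -> "CohortParams":
        if self.n_patients < 1:
            raise ParameterError(f"n_patients must be >= 1, got {self.n_patients}")
        for name in (
            "p_lab_ordered",
            "p_visit_bmi_missing",
            "p_no_bmi_on_file",
            "p_structured_diabetes_history",
            "p_chart_only_diabetes_history",
            "p_structured_hba1c_within_3y",
            "p_chart_only_hba1c_within_3y",
            "p_exclusion_condition",
        ):
            _check_prob(name, getattr(self, name))
        for label, mapping in (
            ("strata_proportions", self.strata_proportions),
            ("sex_proportions", self.sex_proportions),
            ("insurance_proportions", self.insurance_proportions),
            ("exclusion_split", self.exclusion_split),
        ):
            if not mapping:
                raise ParameterError(f"{label} must not be empty")
            for k, p in mapping.items():
                _check_prob(f"{label}[{k}]", p)
            if abs(sum(mapping.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{label} must sum to 1 within 1e-9, got {sum(mapping.values())!r}")
        mean, sd, lo = self.age_distribution
        if sd <= 0 or lo < 18:
            raise ParameterError("age distribution needs sd > 0 and minimum >= 18 years")
        mean, sd, lo = self.bmi_distribution
        if sd <= 0 or lo <= 0:
            raise ParameterError("bmi distribution needs sd > 0 and a positive lower bound")
        return self

    def replace(self, **changes) -> "CohortParams":
        return dataclasses.replace(self, **changes)


def _trunc_dist(mean: float, sd: float, lower: float):
    return truncnorm((lower - mean) / sd, np.inf, loc=mean, scale=sd)


def _age_dist(params: CohortParams):
    mean, sd, lo = params.age_distribution
    return _trunc_dist(mean, sd, lo)


def _bmi_dist(params: CohortParams):
    mean, sd, lo = params.bmi_distribution
    return _trunc_dist(mean, sd, lo)


def _draw_categorical(rng: np.random.Generator, mapping: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(mapping.keys())
    probs = np.asarray([mapping[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a cohort of ED visits as a DataFrame (one row per visit).

    Reproducible: a single :class:`numpy.random.Generator` seeded with
    ``params.seed`` is consumed in a fixed per-field order (lab order, age,
    chart BMI, the two BMI-missingness masks, the four history draws, the
    exclusion condition, stratum, sex, insurance).  Re-running with identical
    parameters yields an identical frame.
    """
    params.validate()
    n = params.n_patients
    rng = np.random.default_rng(params.seed)

    lab_ordered = rng.random(n) < params.p_lab_ordered
    age = np.floor(_age_dist(params).rvs(size=n, random_state=rng)).astype(np.int64)
    chart_bmi = _bmi_dist(params).rvs(size=n, random_state=rng)
    visit_missing = rng.random(n) < params.p_visit_bmi_missing
    no_file = rng.random(n) < params.p_no_bmi_on_file
    visit_bmi = np.where(visit_missing, np.nan, chart_bmi)
    most_recent_bmi = np.where(no_file, np.nan, chart_bmi)

    structured_dm = rng.random(n) < params.p_structured_diabetes_history
    chart_dm = structured_dm | (rng.random(n) < params.p_chart_only_diabetes_history)
    structured_a1c = rng.random(n) < params.p_structured_hba1c_within_3y
    chart_a1c = structured_a1c | (rng.random(n) < params.p_chart_only_hba1c_within_3y)

    u = rng.random(n)
    exclusion = np.full(n, "none", dtype=object)
    edges = 0.0
    for cond in ("pregnancy", "sickle_cell", "hiv"):
        share = params.p_exclusion_condition * params.exclusion_split.get(cond, 0.0)
        exclusion[(u >= edges) & (u < edges + share)] = cond
        edges += share

    stratum = _draw_categorical(rng, params.strata_proportions, n)
    sex = _draw_categorical(rng, params.sex_proportions, n)
    sex[exclusion == "pregnancy"] = "female"
    insurance = _draw_categorical(rng, params.insurance_proportions, n)

    return pd.DataFrame(
        {
            "visit_id": [f"V{i:06d}" for i in range(n)],
            "age": age,
            "visit_bmi": visit_bmi,
            "most_recent_bmi": most_recent_bmi,
            "chart_bmi": chart_bmi,
            "lab_ordered": lab_ordered,
            "structured_diabetes_history": structured_dm,
            "chart_diabetes_history": chart_dm,
            "structured_hba1c_within_3y": structured_a1c,
            "chart_hba1c_within_3y": chart_a1c,
            "exclusion_condition": exclusion,
            "race_ethnicity": stratum,
            "sex": sex,
            "insurance": insurance,
        },
        columns=COHORT_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Probability tree: expected confusion cells and its inverse (calibration)
# ---------------------------------------------------------------------------

def _tree_terms(params: CohortParams, age_alone: float = 45.0, bmi_threshold: float = 25.0,
                missing_bmi_policy: str = "age-alone") -> dict:
    """Pieces of the analytic outcome tree for one lab-ordered visit.

    With independent fields, conditional on a routine lab being ordered:

    * ``e45``   — P(age >= 45)                       (age-alone criterion)
    * ``ebmi``  — P(BMI >= 25)                       (chart/visit BMI)
    * ``m``     — P(engine sees no BMI) = p_visit_bmi_missing * p_no_bmi_on_file
    * ``q_s``   — P(structured record clean) = (1-a)(1-c)
    * ``q_x``   — P(no chart-only history and no exclusion) = (1-b)(1-d)(1-x)
    """
    # ages are floored to whole years, so floor(X) >= t iff X >= ceil(t)
    e45 = float(_age_dist(params).sf(math.ceil(age_alone)))
    ebmi = float(_bmi_dist(params).sf(bmi_threshold))
    m = params.p_visit_bmi_missing * params.p_no_bmi_on_file
    q_s = (1 - params.p_structured_diabetes_history) * (1 - params.p_structured_hba1c_within_3y)
    q_x = (
        (1 - params.p_chart_only_diabetes_history)
        * (1 - params.p_chart_only_hba1c_within_3y)
        * (1 - params.p_exclusion_condition)
    )
    if missing_bmi_policy == "age-alone":
        p_eng = e45 + (1 - e45) * (1 - m) * ebmi  # engine demographic eligibility
        p_fn_dem = (1 - e45) * m * ebmi  # eligible per chart, engine blind to BMI
    elif missing_bmi_policy == "suppress":
        p_eng = (1 - m) * (e45 + (1 - e45) * ebmi)
        p_fn_dem = m * (e45 + (1 - e45) * ebmi)
    else:
        raise ParameterError(f"unknown missing_bmi_policy {missing_bmi_policy!r}")
    return {"e45": e45, "ebmi": ebmi, "m": m, "q_s": q_s, "q_x": q_x,
            "p_eng": p_eng, "p_fn_dem": p_fn_dem}


def expected_cells(params: CohortParams, age_alone: float = 45.0, bmi_threshold: float = 25.0,
                   missing_bmi_policy: str = "age-alone") -> dict:
    """Expected TP/FP/FN/TN probabilities per lab-ordered visit (closed form).

    TP: engine-eligible demographics, structured record clean, chart adds
    nothing and no exclusion.  FP: engine fires but the chart search or an
    HbA1c-unreliability condition disqualifies.  FN: the chart BMI qualifies
    but the engine has no BMI to evaluate (its only miss mechanism).  TN is
    the remainder.
    """
    t = _tree_terms(params, age_alone, bmi_threshold, missing_bmi_policy)
    tp = t["p_eng"] * t["q_s"] * t["q_x"]
    fp = t["p_eng"] * t["q_s"] * (1 - t["q_x"])
    fn = t["p_fn_dem"] * t["q_s"] * t["q_x"]
    return {"tp": tp, "fp": fp, "fn": fn, "tn": 1.0 - tp - fp - fn}


def calibrate_to_cells(target, base: CohortParams | None = None, *,
                       missing_bmi_policy: str = "age-alone") -> CohortParams:
    """Solve for discordance rates whose expected 2x2 matches ``target``.

    ``target`` is (tp, fp, fn, tn) counts or proportions.  The closed-form
    inverse of :func:`expected_cells` (for the default age-alone reading):

    * ``q_extra = TP / (TP + FP)``
    * ``q_s = (TP + FP)(TP + FN) / (TP * B)`` with ``B = P(chart-eligible demographics)``
    * ``m = FN * B / (A * (TP + FN))`` with ``A = P(age < 45 and BMI >= 25)``

    The 2x2 identifies only the products; within each the base parameters set
    the split (exclusion prevalence kept from ``base``, the two chart-only
    rates equal, the two structured rates equal, BMI-missingness factors
    adjusted minimally from the base).  Raises :class:`CalibrationError` when
    the target needs q_s > 1, m > 1, or a positive cell the model cannot reach.
    """
    base = (base or CohortParams()).validate()
    cells = np.asarray(target, dtype=float)
    if cells.shape != (4,):
        raise CalibrationError("target must be four cells (tp, fp, fn, tn)")
    if (cells < 0).any() or cells.sum() <= 0:
        raise CalibrationError("target cells must be non-negative with a positive total")
    tp, fp, fn, tn = cells / cells.sum()

    t = _tree_terms(base, missing_bmi_policy=missing_bmi_policy)
    e45, ebmi = t["e45"], t["ebmi"]
    A = (1 - e45) * ebmi
    B = e45 + A  # chart-side demographic eligibility probability
    if tp + fp == 0 or tp == 0:
        raise CalibrationError("model cannot split FP from TP without a positive TP cell")
    q_extra = tp / (tp + fp)
    q_s = (tp + fp) * (tp + fn) / (tp * B)
    if not (0 < q_s <= 1):
        raise CalibrationError(
            f"target needs structured-clean probability {q_s:.3f} outside (0, 1]; "
            "demographic eligibility too low to supply the positive margin"
        )
    m = fn * B / (A * (tp + fn)) if fn > 0 else 0.0
    if not (0 <= m <= 1):
        raise CalibrationError(
            f"target FN proportion needs engine-BMI-missing probability {m:.3f} > 1; "
            "no feasible missingness rate produces that many misses"
        )

    p_struct = 1 - math.sqrt(q_s)
    x = base.p_exclusion_condition
    if 1 - x < q_extra:  # exclusions alone already exceed the allowed FP mass
        x = 1 - q_extra
    rest = q_extra / (1 - x) if x < 1 else 1.0
    p_chart_only = 1 - math.sqrt(rest)

    if base.p_no_bmi_on_file > 0 and m <= base.p_no_bmi_on_file:
        p_no_file, p_visit_missing = base.p_no_bmi_on_file, m / base.p_no_bmi_on_file
    else:
        p_no_file = p_visit_missing = math.sqrt(m)

    out = base.replace(
        p_structured_diabetes_history=p_struct,
        p_structured_hba1c_within_3y=p_struct,
        p_chart_only_diabetes_history=p_chart_only,
        p_chart_only_hba1c_within_3y=p_chart_only,
        p_exclusion_condition=x,
        p_visit_bmi_missing=p_visit_missing,
        p_no_bmi_on_file=p_no_file,
    ).validate()

    got = expected_cells(out, missing_bmi_policy=missing_bmi_policy)
    want = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    for k in want:
        if abs(got[k] - want[k]) > 1e-9:
            raise CalibrationError(f"internal: calibrated cell {k} off target ({got[k]:.6f} vs {want[k]:.6f})")
    return out


def study_params(n_patients: int = 3850, seed: int = 0) -> CohortParams:
    """Default study conditions: Table-style marginals with discordance rates
    calibrated so the expected 2x2 matches the published validation cells."""
    base = CohortParams(n_patients=n_patients, seed=seed)
    return calibrate_to_cells(STUDY_CELLS, base)


# ---------------------------------------------------------------------------
# I/O: CSV (RFC-4180, empty cell = absent), JSON lines, YAML params
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].map({True: "true", False: "false"})
    out.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"visit_id": str})
    for c in _BOOL_COLUMNS:
        if df[c].dtype != bool:  # pandas parses true/false itself in most dialects
            df[c] = df[c].map({"true": True, "false": False, True: True, False: False}).astype(bool)
    for c in ("visit_bmi", "most_recent_bmi", "chart_bmi"):
        if c in df.columns:
            df[c] = df[c].astype(float)
    if "age" in df.columns and df["age"].notna().all():
        df["age"] = df["age"].astype(np.int64)
    return df[[c for c in COHORT_COLUMNS if c in df.columns]]


def write_cohort_jsonl(cohort: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in cohort.to_dict(orient="records"):
            clean = {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in rec.items()}
            for k, v in clean.items():
                if isinstance(v, (np.bool_, np.integer, np.floating)):
                    clean[k] = v.item()
            fh.write(json.dumps(clean) + "\n")


def read_cohort_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    for c in ("visit_bmi", "most_recent_bmi", "chart_bmi"):
        df[c] = df[c].astype(float)
    return df


def params_to_yaml(params: CohortParams, path) -> None:
    payload = dataclasses.asdict(params)
    payload["age_distribution"] = list(params.age_distribution)
    payload["bmi_distribution"] = list(params.bmi_distribution)
    for k in ("exclusion_split", "strata_proportions", "sex_proportions", "insurance_proportions"):
        payload[k] = dict(payload[k])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def params_from_yaml(source) -> CohortParams:
    if hasattr(source, "read"):
        payload = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
    for k in ("age_distribution", "bmi_distribution"):
        if k in payload:
            payload[k] = tuple(payload[k])
    return CohortParams(**payload).validate()
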