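"""Diagnostic-accuracy statistics for alert validation.

Builds the (optionally weighted) 2x2 of engine decisions against
chart-review labels under a stratified verification-sampling design, and
computes the standard test characteristics:

* sensitivity, specificity, PPV, NPV with binomial SEs and Wald (default) or
  Wilson 95% CIs;
* likelihood ratios with delta-method SEs computed on the log scale and
  back-transformed to natural-scale SE/CI pairs;
* prevalence-based predictive values (Bayes);
* the AUC of a weighted logistic model predicting *correct* alert behaviour
  from age, BMI and the two history flags, with a seeded stratified bootstrap
  CI;
* acceptability verdicts: sensitivity + specificity >= 150%, LR bands
  (LR+ 5-10 acceptable; LR- 0.1-0.2 acceptable, 0.2-0.5 still informative)
  and AUC bands (0.7-0.8 acceptable, >= 0.8 excellent).

Weighted cells are treated as frequency counts throughout, so all-unit
weights reduce every estimator exactly to its unweighted form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import AlignmentError, DesignError, ParameterError, UndefinedMetricError

__all__ = [
    "ConfusionTable",
    "SamplingDesign",
    "VerificationSample",
    "DiagnosticMetric",
    "AccuracyReport",
    "AucResult",
    "sample_negatives",
    "build_confusion",
    "accuracy_metrics",
    "likelihood_ratios",
    "predictive_values_from_prevalence",
    "weighted_auc",
    "accuracy_report",
    "acceptability",
    "round_half_up",
]

AUC_PREDICTORS = ("age", "bmi", "diabetes_history", "hba1c_history")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report-display convention)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """A (possibly weighted) 2x2 of decisions against reference labels."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> float:
        """Reference-positive margin (truly eligible)."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> float:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.total

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}

    def scaled(self, factor: float) -> "ConfusionTable":
        return ConfusionTable(self.tp * factor, self.fp * factor, self.fn * factor, self.tn * factor)


@dataclass(frozen=True)
class DiagnosticMetric:
    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def as_dict(self) -> dict:
        return {"estimate": self.estimate, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high, "ci_level": self.ci_level}


# ---------------------------------------------------------------------------
# Stratified verification sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplingDesign:
    """Verify all alert-positive visits; verify a stratified random fraction of
    the alert-negative ones and weight them back to the population."""

    sampled_fraction: float = 0.10
    strata: Sequence[str] | None = None  # None: use strata present in the data
    per_stratum_weight: dict = field(default_factory=dict)  # filled by sample_negatives
    seed: int = 0

    def validate(self) -> "SamplingDesign":
        if not (0.0 < self.sampled_fraction <= 1.0):
            raise ParameterError(f"sampled_fraction must be in (0, 1], got {self.sampled_fraction}")
        return self


@dataclass
class VerificationSample:
    """Outcome of :func:`sample_negatives`: which visits are verified and with
    what weight each verified visit stands for the population."""

    index: pd.Index
    weights: pd.Series
    per_stratum_weight: dict


def _round_count(x: float) -> int:
    return int(math.floor(x + 0.5))  # half away from zero for positive x


def sample_negatives(strata: pd.Series, triggered, design: SamplingDesign) -> VerificationSample:
    """Draw the verification subsample.

    ``strata`` is the per-visit race/ethnicity stratum; ``triggered`` the
    engine verdicts, aligned on the same index.  Within each stratum,
    ``round(fraction * n_stratum)`` untriggered visits are drawn without
    replacement and weighted ``n_stratum / n_sampled``.  Triggered visits are
    always fully verified with weight 1.
    """
    design.validate()
    strata = pd.Series(strata)
    trig = pd.Series(np.asarray(triggered, dtype=bool), index=strata.index)
    rng = np.random.default_rng(design.seed)

    keep = [strata.index[trig]]
    weights: dict = {i: 1.0 for i in strata.index[trig]}
    design.per_stratum_weight = {}

    neg = strata[~trig]
    levels = list(design.strata) if design.strata is not None else sorted(neg.unique())
    for level in levels:
        members = neg.index[neg == level]
        n_s = len(members)
        if n_s == 0:
            continue
        if design.sampled_fraction == 1.0:
            k = n_s
        else:
            k = _round_count(design.sampled_fraction * n_s)
        if k == 0:
            raise DesignError(
                f"stratum {level!r} has {n_s} untriggered visits but a zero-size sample; "
                "increase sampled_fraction"
            )
        chosen = rng.choice(np.asarray(members), size=k, replace=False)
        w = n_s / k
        design.per_stratum_weight[level] = w
        keep.append(pd.Index(chosen))
        for i in chosen:
            weights[i] = w

    index = keep[0].append(keep[1:]) if len(keep) > 1 else keep[0]
    index = strata.index[strata.index.isin(index)]  # restore cohort order
    return VerificationSample(index=index,
                              weights=pd.Series(weights).loc[index],
                              per_stratum_weight=dict(design.per_stratum_weight))


def build_confusion(triggered: pd.Series, should_trigger: pd.Series,
                    weights: pd.Series | None = None) -> ConfusionTable:
    """Weighted 2x2 from aligned decision and label series.

    Series must carry identical id sets (index or ``visit_id`` alignment is
    the caller's responsibility); a mismatch raises :class:`AlignmentError`.
    """
    t = pd.Series(triggered)
    s = pd.Series(should_trigger)
    if len(t) != len(s) or not t.index.equals(s.index):
        raise AlignmentError("decisions and labels are not aligned on the same visits")
    if weights is None:
        w = pd.Series(1.0, index=t.index)
    else:
        w = pd.Series(weights).astype(float)
        if not w.index.equals(t.index):
            raise AlignmentError("weights are not aligned with the decisions")
        if (w <= 0).any():
            raise ParameterError("weights must be positive")
    tb = t.to_numpy(dtype=bool)
    sb = s.to_numpy(dtype=bool)
    wv = w.to_numpy(dtype=float)
    return ConfusionTable(
        tp=float(wv[tb & sb].sum()),
        fp=float(wv[tb & ~sb].sum()),
        fn=float(wv[~tb & sb].sum()),
        tn=float(wv[~tb & ~sb].sum()),
    )


# ---------------------------------------------------------------------------
# Test characteristics
# ---------------------------------------------------------------------------

def _z(ci_level: float) -> float:
    return float(norm.ppf(0.5 + ci_level / 2.0))


def _proportion_metric(name: str, num: float, den: float, ci_level: float,
                       method: str) -> DiagnosticMetric:
    if den <= 0:
        raise UndefinedMetricError(f"{name} is undefined: its denominator is zero")
    p = num / den
    se = math.sqrt(p * (1 - p) / den)
    z = _z(ci_level)
    if method == "wald":
        lo, hi = p - z * se, p + z * se
    elif method == "wilson":
        denom = 1 + z * z / den
        center = (p + z * z / (2 * den)) / denom
        half = z * math.sqrt(p * (1 - p) / den + z * z / (4 * den * den)) / denom
        lo, hi = center - half, center + half
    else:
        raise ParameterError(f"unknown CI method {method!r}")
    return DiagnosticMetric(name, p, se, max(0.0, lo), min(1.0, hi), ci_level)


def accuracy_metrics(table: ConfusionTable, ci_level: float = 0.95,
                     method: str = "wald") -> dict[str, DiagnosticMetric]:
    """Sensitivity, specificity, PPV and NPV with binomial SEs and CIs."""
    return {
        "sensitivity": _proportion_metric("sensitivity", table.tp, table.tp + table.fn, ci_level, method),
        "specificity": _proportion_metric("specificity", table.tn, table.tn + table.fp, ci_level, method),
        "ppv": _proportion_metric("ppv", table.tp, table.tp + table.fp, ci_level, method),
        "npv": _proportion_metric("npv", table.tn, table.tn + table.fn, ci_level, method),
    }


def likelihood_ratios(table: ConfusionTable, ci_level: float = 0.95,
                      scale: str = "natural") -> tuple[DiagnosticMetric, DiagnosticMetric]:
    """LR+ and LR- with delta-method SEs.

    The variance is computed for the log likelihood ratio,

        Var(ln LR+) = (1-sens)/(sens*n_pos) + spec/((1-spec)*n_neg)
        Var(ln LR-) = sens/((1-sens)*n_pos) + (1-spec)/(spec*n_neg)

    and back-transformed (SE = LR * sqrt(Var ln LR)) with a natural-scale Wald
    interval by default; ``scale="log"`` exponentiates the log-scale interval
    instead.  Degenerate tables (spec = 1 for LR+, sens in {0, 1}) yield
    infinite/zero estimates with NaN uncertainty rather than raising.
    """
    n_pos, n_neg = table.n_positive, table.n_negative
    if n_pos <= 0 or n_neg <= 0:
        raise UndefinedMetricError("likelihood ratios are undefined without both reference classes")
    sens = table.tp / n_pos
    spec = table.tn / n_neg
    z = _z(ci_level)

    def _one(name: str, est: float, var_log: float) -> DiagnosticMetric:
        if not math.isfinite(est) or est == 0.0 or not math.isfinite(var_log):
            return DiagnosticMetric(name, est, math.nan, math.nan, math.nan, ci_level)
        se = est * math.sqrt(var_log)
        if scale == "natural":
            lo, hi = est - z * se, est + z * se
        elif scale == "log":
            lo = est * math.exp(-z * math.sqrt(var_log))
            hi = est * math.exp(z * math.sqrt(var_log))
        else:
            raise ParameterError(f"unknown LR CI scale {scale!r}")
        return DiagnosticMetric(name, est, se, max(0.0, lo), hi, ci_level)

    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = sens / (1 - spec) if spec < 1 else math.inf
        lr_neg = (1 - sens) / spec if spec > 0 else math.inf
        var_pos = ((1 - sens) / (sens * n_pos) + spec / ((1 - spec) * n_neg)
                   if 0 < sens and spec < 1 else math.inf)
        var_neg = (sens / ((1 - sens) * n_pos) + (1 - spec) / (spec * n_neg)
                   if sens < 1 and spec > 0 else math.inf)
    return _one("lr_pos", lr_pos, var_pos), _one("lr_neg", lr_neg, var_neg)


def predictive_values_from_prevalence(sens: float, spec: float, prevalence: float) -> tuple[float, float]:
    """PPV and NPV implied by Bayes' theorem at a given eligibility prevalence."""
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not (0.0 < v < 1.0):
            raise ParameterError(f"{name} must lie strictly in (0, 1), got {v}")
    ppv = sens * prevalence / (sens * prevalence + (1 - spec) * (1 - prevalence))
    npv = spec * (1 - prevalence) / (spec * (1 - prevalence) + (1 - sens) * prevalence)
    return ppv, npv


# ---------------------------------------------------------------------------
# Weighted logistic ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class AucResult:
    metric: DiagnosticMetric
    roc_points: pd.DataFrame  # fpr, tpr, threshold
    separation: bool  # complete/quasi separation flagged during fitting
    coefficients: dict
    scores: np.ndarray | None = None  # linear predictor per record


def _design_matrix(records: pd.DataFrame) -> np.ndarray:
    """Predictors: continuous age and BMI, binary history flags.

    BMI is the chart-verified visit BMI with fallbacks through the structured
    columns; any row still missing gets the cohort median.  History flags are
    the chart (reference) values when present, otherwise the structured ones.
    """
    age = pd.to_numeric(records["age"], errors="coerce")
    bmi = records.get("chart_bmi", pd.Series(np.nan, index=records.index)).astype(float)
    for fallback in ("visit_bmi", "most_recent_bmi"):
        if fallback in records.columns:
            bmi = bmi.fillna(records[fallback].astype(float))
    bmi = bmi.fillna(bmi.median())
    age = age.fillna(age.median())
    dm_col = "chart_diabetes_history" if "chart_diabetes_history" in records.columns \
        else "structured_diabetes_history"
    a1c_col = "chart_hba1c_within_3y" if "chart_hba1c_within_3y" in records.columns \
        else "structured_hba1c_within_3y"
    X = np.column_stack([
        age.to_numpy(dtype=float),
        bmi.to_numpy(dtype=float),
        records[dm_col].to_numpy(dtype=float),
        records[a1c_col].to_numpy(dtype=float),
    ])
    return sm.add_constant(X, has_constant="add")


def _fit_scores(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool, np.ndarray]:
    """Weighted logistic fit; returns linear-predictor scores and a separation flag."""
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
            res = model.fit(maxiter=100)
            params = np.asarray(res.params, dtype=float)
        except Exception:  # perfect separation can abort IRLS entirely
            separation = True
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(penalty="l2", C=1e6, max_iter=2000)
            lr.fit(X[:, 1:], y, sample_weight=w)
            params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    for wmsg in caught:
        if "separation" in str(wmsg.message).lower() or "divergence" in str(wmsg.message).lower():
            separation = True
    if np.abs(params).max() > 1e3:
        separation = True
    if separation:
        warnings.warn("weighted logistic model shows complete or quasi separation; "
                      "coefficients are unstable but scores still rank the outcomes",
                      RuntimeWarning, stacklevel=3)
    return X @ params, separation, params


def weighted_auc(records: pd.DataFrame, outcome, weights=None, *,
                 ci_level: float = 0.95, n_boot: int = 2000, seed: int = 0) -> AucResult:
    """AUC of the weighted logistic model for correct alert behaviour.

    ``outcome`` is the binary "alert behaved correctly" indicator per visit;
    ``weights`` the verification-sampling weights (unit if ``None``).  The AUC
    is the weighted concordance probability of the fitted scores (ties count
    half), computed with :func:`sklearn.metrics.roc_auc_score`; its CI comes
    from a seeded bootstrap stratified by outcome class, refitting the model
    in each resample.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC needs both outcome classes present")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ParameterError("weights must be positive")
    X = _design_matrix(records)
    scores, separation, params = _fit_scores(X, y, w)

    est = float(roc_auc_score(y, scores, sample_weight=w))
    fpr, tpr, thr = roc_curve(y, scores, sample_weight=w)
    roc_points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boot = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                                  rng.choice(neg, size=len(neg), replace=True)])
            Xb, yb, wb = X[idx], y[idx], w[idx]
            sb, _, _ = _fit_scores(Xb, yb, wb)
            boot[b] = roc_auc_score(yb, sb, sample_weight=wb)
    if n_boot > 0:
        se = float(np.std(boot, ddof=1))
        alpha = 1 - ci_level
        lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    else:
        se, lo, hi = math.nan, math.nan, math.nan
    names = ("const",) + tuple(AUC_PREDICTORS)
    return AucResult(
        metric=DiagnosticMetric("auc", est, se, float(lo), float(hi), ci_level),
        roc_points=roc_points,
        separation=separation,
        coefficients=dict(zip(names, (float(p) for p in params))),
        scores=scores,
    )


# ---------------------------------------------------------------------------
# Report assembly and acceptability rules
# ---------------------------------------------------------------------------

def lr_pos_band(v: float) -> str:
    if v > 10:
        return "strong"
    if 5 <= v <= 10:
        return "acceptable"
    if v >= 2:
        return "moderate"
    return "weak"


def lr_neg_band(v: float) -> str:
    if v < 0.1:
        return "strong"
    if v <= 0.2:
        return "acceptable"
    if v <= 0.5:
        return "informative"
    return "uninformative"


def auc_band(v: float) -> str:
    if v >= 0.8:  # boundary belongs to the upper band
        return "excellent"
    if v >= 0.7:
        return "acceptable"
    return "poor"


@dataclass
class AccuracyReport:
    metrics: dict[str, DiagnosticMetric]
    sens_spec_sum: float
    sens_spec_sum_ok: bool
    lr_pos_band: str
    lr_neg_band: str
    auc_band: str | None
    confusion: ConfusionTable

    def as_dict(self, precision: int | None = None) -> dict:
        rnd = (lambda x: x) if precision is None else (lambda x: round_half_up(x, precision))
        payload = {
            "metrics": {
                name: {k: (rnd(v) if isinstance(v, float) and k != "ci_level" else v)
                       for k, v in m.as_dict().items()}
                for name, m in self.metrics.items()
            },
            "verdicts": {
                "sens_spec_sum": rnd(self.sens_spec_sum),
                "sens_spec_sum_ok": self.sens_spec_sum_ok,
                "lr_pos_band": self.lr_pos_band,
                "lr_neg_band": self.lr_neg_band,
                "auc_band": self.auc_band,
            },
            "confusion": self.confusion.as_dict(),
        }
        return payload


def accuracy_report(table: ConfusionTable, auc: DiagnosticMetric | None = None,
                    ci_level: float = 0.95, method: str = "wald") -> AccuracyReport:
    """Assemble the full report: six test characteristics (+ AUC if supplied)
    and the acceptability verdicts."""
    metrics = accuracy_metrics(table, ci_level, method)
    lrp, lrn = likelihood_ratios(table, ci_level)
    metrics["lr_pos"] = lrp
    metrics["lr_neg"] = lrn
    if auc is not None:
        metrics["auc"] = auc
    ssum = metrics["sensitivity"].estimate + metrics["specificity"].estimate
    return AccuracyReport(
        metrics=metrics,
        sens_spec_sum=ssum,
        sens_spec_sum_ok=bool(ssum >= 1.5),
        lr_pos_band=lr_pos_band(lrp.estimate),
        lr_neg_band=lr_neg_band(lrn.estimate),
        auc_band=auc_band(auc.estimate) if auc is not None else None,
        confusion=table,
    )


def acceptability(report: AccuracyReport) -> dict:
    """Verdict record for a completed report."""
    return {
        "sens_spec_sum": report.sens_spec_sum,
        "sens_spec_sum_ok": report.sens_spec_sum_ok,
        "lr_pos_band": report.lr_pos_band,
        "lr_neg_band": report.lr_neg_band,
        "auc_band": report.auc_band,
    }
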