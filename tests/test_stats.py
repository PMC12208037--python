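"""Validation statistics: weighting laws, delta-method intervals against a
bootstrap oracle, Bayes identities, verification sampling, and the weighted
AUC against an O(n^2) concordance oracle."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from edscreen import (
    ConfusionTable,
    DesignError,
    ParameterError,
    SamplingDesign,
    UndefinedMetricError,
    acceptability,
    accuracy_metrics,
    accuracy_report,
    build_confusion,
    likelihood_ratios,
    predictive_values_from_prevalence,
    round_half_up,
    sample_negatives,
    weighted_auc,
)
from edscreen.errors import AlignmentError
from edscreen.stats import auc_band, lr_neg_band, lr_pos_band

from conftest import NEGATIVE_STRATA, TABLE_CELLS


def concordance_oracle(y, scores, weights) -> float:
    """O(n^2) weighted pair loop: concordant pairs count their weight
    product, exact score ties count half."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    num = 0.0
    den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            den += w[i] * w[j]
            if s[i] > s[j]:
                num += w[i] * w[j]
            elif s[i] == s[j]:
                num += 0.5 * w[i] * w[j]
    return num / den


# --- confusion construction -------------------------------------------------

def test_build_confusion_unit_weights():
    t = pd.Series([True, True, False, False])
    s = pd.Series([True, False, True, False])
    table = build_confusion(t, s)
    assert table.as_dict() == {"tp": 1.0, "fp": 1.0, "fn": 1.0, "tn": 1.0}


def test_build_confusion_alignment_error():
    t = pd.Series([True, False], index=[0, 1])
    s = pd.Series([True, False], index=[1, 2])
    with pytest.raises(AlignmentError):
        build_confusion(t, s)


def test_weight_scale_invariance():
    """Doubling every weight doubles every cell and changes no proportion."""
    rng = np.random.default_rng(0)
    t = pd.Series(rng.random(500) < 0.3)
    s = pd.Series(rng.random(500) < 0.3)
    w = pd.Series(rng.uniform(1, 5, 500))
    a = build_confusion(t, s, w)
    b = build_confusion(t, s, 2 * w)
    for cell in ("tp", "fp", "fn", "tn"):
        assert getattr(b, cell) == pytest.approx(2 * getattr(a, cell), rel=1e-12)
    ma, mb = accuracy_metrics(a), accuracy_metrics(b)
    for name in ma:
        assert ma[name].estimate == pytest.approx(mb[name].estimate, abs=1e-12)


# --- test characteristics ---------------------------------------------------

def test_perfect_table():
    m = accuracy_metrics(ConfusionTable(40, 0, 0, 60))
    for metric in m.values():
        assert metric.estimate == 1.0 and metric.se == 0.0


def test_zero_denominator_names_metric():
    with pytest.raises(UndefinedMetricError, match="ppv"):
        accuracy_metrics(ConfusionTable(0, 0, 3, 7))


def test_wilson_interval_inside_unit_range():
    m = accuracy_metrics(ConfusionTable(1, 0, 0, 9), method="wilson")
    sens = m["sensitivity"]
    assert 0.0 <= sens.ci_low <= sens.estimate <= sens.ci_high <= 1.0
    assert sens.ci_low > 0.0  # Wilson does not collapse at the boundary


def test_lr_uninformative_test():
    lrp, lrn = likelihood_ratios(ConfusionTable(25, 25, 25, 25))
    assert lrp.estimate == pytest.approx(1.0)
    assert lrn.estimate == pytest.approx(1.0)


def test_lr_prevalence_invariance():
    """Tables with identical sens/spec but different prevalence give
    identical likelihood ratios."""
    a = ConfusionTable(80, 10, 20, 90)       # prevalence 0.5
    b = ConfusionTable(8, 19, 2, 171)        # prevalence 0.05, same sens/spec
    la, lb = likelihood_ratios(a), likelihood_ratios(b)
    assert la[0].estimate == pytest.approx(lb[0].estimate, abs=1e-12)
    assert la[1].estimate == pytest.approx(lb[1].estimate, abs=1e-12)


def test_lr_degenerate_table_signals_infinity():
    lrp, lrn = likelihood_ratios(ConfusionTable(40, 0, 10, 50))
    assert math.isinf(lrp.estimate) and math.isnan(lrp.se)
    assert math.isfinite(lrn.estimate)


def test_lr_delta_se_matches_bootstrap_oracle():
    """Delta-method SEs for both LRs agree with a nonparametric bootstrap of
    the multinomial table (10,000 resamples) within 10% relative."""
    cells = np.asarray(TABLE_CELLS, dtype=float)
    n = int(cells.sum())
    rng = np.random.default_rng(123)
    draws = rng.multinomial(n, cells / n, size=10_000).astype(float)
    tp, fp, fn, tn = draws.T
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    boot_pos = np.std(sens / (1 - spec), ddof=1)
    boot_neg = np.std((1 - sens) / spec, ddof=1)
    lrp, lrn = likelihood_ratios(ConfusionTable(*TABLE_CELLS))
    assert lrp.se == pytest.approx(boot_pos, rel=0.10)
    assert lrn.se == pytest.approx(boot_neg, rel=0.10)


def test_log_scale_lr_interval_is_positive():
    lrp, _ = likelihood_ratios(ConfusionTable(5, 40, 2, 15), scale="log")
    assert 0 < lrp.ci_low <= lrp.estimate <= lrp.ci_high


# --- predictive values from prevalence --------------------------------------

def test_predictive_value_floor_example():
    ppv, npv = predictive_values_from_prevalence(0.75, 0.75, 0.30)
    assert ppv == pytest.approx(0.5625, abs=1e-12)
    assert npv == pytest.approx(0.875, abs=1e-12)


def test_predictive_values_symmetric_prevalence():
    for s in (0.6, 0.75, 0.9):
        ppv, npv = predictive_values_from_prevalence(s, s, 0.5)
        assert ppv == pytest.approx(s, abs=1e-12)
        assert npv == pytest.approx(s, abs=1e-12)


def test_predictive_values_bayes_consistency():
    """At the sample prevalence, the Bayes formulas reproduce the direct
    PPV/NPV of the table exactly."""
    table = ConfusionTable(*TABLE_CELLS)
    m = accuracy_metrics(table)
    ppv, npv = predictive_values_from_prevalence(
        m["sensitivity"].estimate, m["specificity"].estimate, table.prevalence
    )
    assert ppv == pytest.approx(m["ppv"].estimate, abs=1e-12)
    assert npv == pytest.approx(m["npv"].estimate, abs=1e-12)


def test_degenerate_prevalence_raises():
    with pytest.raises(ParameterError):
        predictive_values_from_prevalence(0.8, 0.8, 0.0)
    with pytest.raises(ParameterError):
        predictive_values_from_prevalence(0.8, 0.8, 1.0)


# --- verification sampling --------------------------------------------------

def _toy_strata(counts: dict, n_pos: int = 100) -> tuple[pd.Series, np.ndarray]:
    strata = []
    for level, n in counts.items():
        strata += [level] * n
    trig = np.zeros(len(strata) + n_pos, dtype=bool)
    trig[len(strata):] = True
    strata += ["black_nh"] * n_pos
    return pd.Series(strata), trig


def test_census_fraction_returns_everything():
    strata, trig = _toy_strata({"hispanic": 30, "white_nh": 20})
    vs = sample_negatives(strata, trig, SamplingDesign(sampled_fraction=1.0, seed=0))
    assert len(vs.index) == len(strata)
    assert (vs.weights == 1.0).all()


def test_weights_sum_to_stratum_population():
    strata, trig = _toy_strata(dict(NEGATIVE_STRATA))
    design = SamplingDesign(sampled_fraction=0.10, seed=3)
    vs = sample_negatives(strata, trig, design)
    neg = strata[~trig]
    for level, n_s in NEGATIVE_STRATA.items():
        members = neg.index[neg == level]
        sampled = vs.index.intersection(members)
        assert vs.weights.loc[sampled].sum() == pytest.approx(n_s, abs=1e-9)


def test_published_subsample_size():
    """With the study's per-stratum negative counts and a 10.19% fraction the
    verified-negative sample is exactly the 221 visits reported."""
    strata, trig = _toy_strata(dict(NEGATIVE_STRATA))
    vs = sample_negatives(strata, trig, SamplingDesign(sampled_fraction=0.1019, seed=0))
    n_verified_negatives = int((vs.weights > 1).sum())
    assert n_verified_negatives == 221
    assert (vs.weights >= 1.0).all()


def test_empty_stratum_sample_raises():
    strata, trig = _toy_strata({"unknown": 3, "black_nh": 500})
    with pytest.raises(DesignError):
        sample_negatives(strata, trig, SamplingDesign(sampled_fraction=0.01, seed=0))


# --- weighted AUC -----------------------------------------------------------

def _auc_frame(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "age": rng.integers(18, 90, n),
        "chart_bmi": np.round(rng.uniform(15, 45, n), 0),  # coarse: forces ties
        "visit_bmi": np.nan,
        "most_recent_bmi": np.nan,
        "chart_diabetes_history": rng.random(n) < 0.3,
        "chart_hba1c_within_3y": rng.random(n) < 0.2,
    })


def test_auc_constant_scores_is_half():
    df = _auc_frame(200, 0)
    df["age"] = 50
    df["chart_bmi"] = 30.0
    df["chart_diabetes_history"] = False
    df["chart_hba1c_within_3y"] = False
    y = np.r_[np.ones(100), np.zeros(100)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = weighted_auc(df, y, n_boot=0, seed=0)
    assert res.metric.estimate == pytest.approx(0.5, abs=1e-12)


def test_auc_step_function_is_one():
    df = _auc_frame(150, 1)
    y = (df["age"] >= 50).to_numpy(dtype=int)
    with pytest.warns(RuntimeWarning, match="separation"):
        res = weighted_auc(df, y, n_boot=0, seed=0)
    assert res.separation
    assert res.metric.estimate == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("n,seed", [(60, 2), (200, 3)])
def test_auc_matches_pairwise_oracle(n, seed):
    """The fast weighted AUC equals the O(n^2) weight-product pair loop
    (ties counted half) to 1e-12 on the model's own scores."""
    rng = np.random.default_rng(seed)
    df = _auc_frame(n, seed)
    y = (rng.random(n) < 0.4).astype(int)
    w = rng.uniform(0.5, 10.0, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = weighted_auc(df, y, w, n_boot=0, seed=0)
    assert res.metric.estimate == pytest.approx(
        concordance_oracle(y, res.scores, w), abs=1e-12
    )


def test_auc_bootstrap_ci_brackets_estimate():
    rng = np.random.default_rng(4)
    n = 300
    df = _auc_frame(n, 4)
    logit = -4 + 0.08 * df["age"].to_numpy()
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    res = weighted_auc(df, y, n_boot=80, seed=5)
    assert res.metric.ci_low <= res.metric.estimate <= res.metric.ci_high
    assert res.metric.se > 0


def test_auc_single_class_raises():
    df = _auc_frame(50, 5)
    with pytest.raises(UndefinedMetricError):
        weighted_auc(df, np.ones(50), n_boot=0)


# --- acceptability ----------------------------------------------------------

def test_acceptability_bands():
    assert lr_pos_band(7.39) == "acceptable"
    assert lr_pos_band(10.0) == "acceptable"  # documented boundary rule
    assert lr_pos_band(12.0) == "strong"
    assert lr_neg_band(0.15) == "acceptable"
    assert lr_neg_band(0.34) == "informative"
    assert lr_neg_band(0.7) == "uninformative"
    assert auc_band(0.74) == "acceptable"
    assert auc_band(0.80) == "excellent"  # boundary assigned to the upper band
    assert auc_band(0.69) == "poor"


def test_sens_spec_sum_rule():
    ok = accuracy_report(ConfusionTable(*TABLE_CELLS))
    assert ok.sens_spec_sum_ok and ok.sens_spec_sum == pytest.approx(1.60, abs=0.005)
    bad = accuracy_report(ConfusionTable(70, 30, 30, 70))
    assert bad.sens_spec_sum == pytest.approx(1.40, abs=1e-12)
    assert not bad.sens_spec_sum_ok
    verdict = acceptability(ok)
    assert verdict["sens_spec_sum_ok"] and verdict["lr_pos_band"] == "acceptable"


def test_round_half_up_convention():
    assert round_half_up(0.875, 2) == 0.88
    assert round_half_up(0.565, 2) == 0.57
    assert round_half_up(56.25, 0) == 56.0
    assert round_half_up(87.5, 0) == 88.0
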