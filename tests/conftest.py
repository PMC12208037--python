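import pytest

from edscreen import decide_frame, generate_cohort, review_frame, study_params
from edscreen.cohort import STUDY_CELLS

#: Published validation 2x2 the statistics modules are checked against.
TABLE_CELLS = STUDY_CELLS  # (TP, FP, FN, TN) = (599, 197, 265, 1902)

#: Per-stratum counts of untriggered visits in the validation cohort.
NEGATIVE_STRATA = {
    "hispanic": 545,
    "white_nh": 176,
    "black_nh": 1260,
    "asian_nh": 61,
    "other_nh": 96,
    "unknown": 29,
}


@pytest.fixture(scope="session")
def study_run_50k():
    """One large calibrated cohort with decisions and labels, shared across
    the recovery and sampling checks (generated once per session)."""
    params = study_params(n_patients=50_000, seed=11)
    cohort = generate_cohort(params)
    decisions = decide_frame(cohort)
    labels = review_frame(cohort)
    study = cohort.index[cohort["lab_ordered"]]
    return {
        "params": params,
        "cohort": cohort,
        "decisions": decisions,
        "labels": labels,
        "study_index": study,
    }


@pytest.fixture
def small_cohort():
    params = study_params(n_patients=2_000, seed=7)
    return generate_cohort(params)


def make_record(**overrides) -> dict:
    """A plain well-formed visit record for scalar engine/review tests."""
    base = dict(
        visit_id="V1",
        age=50,
        visit_bmi=27.0,
        most_recent_bmi=27.0,
        chart_bmi=27.0,
        lab_ordered=True,
        structured_diabetes_history=False,
        chart_diabetes_history=False,
        structured_hba1c_within_3y=False,
        chart_hba1c_within_3y=False,
        exclusion_condition="none",
        race_ethnicity="black_nh",
        sex="female",
        insurance="medicaid",
    )
    base.update(overrides)
    return base
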