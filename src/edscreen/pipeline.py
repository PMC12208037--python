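"""End-to-end pipeline: generate -> decide -> review -> sample -> validate.

One call (or ``bpa pipeline``) reproduces the whole validation study on a
synthetic cohort: draw visits, run the alert engine on the structured view,
run the reference standard on the chart view, restrict to the study
population (adult visits with a routine lab ordered), optionally draw the
stratified verification subsample, build the weighted 2x2 and emit the full
accuracy report plus artifact files.

Two validation modes:

* ``census`` (default for synthetic data) — every study visit's label is
  known, unit weights;
* ``verification-sample`` — only alert positives and a stratified fraction of
  the negatives are "verified"; sampling weights extrapolate the verified
  subsample back to population counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortParams, generate_cohort, write_cohort_csv
from .engine import RuleConfig, decide_frame
from .errors import ParameterError, PipelineStageError
from .review import review_frame
from .stats import (
    AccuracyReport,
    SamplingDesign,
    accuracy_report,
    build_confusion,
    sample_negatives,
    weighted_auc,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_pipeline_config"]

log = logging.getLogger("edscreen")


@dataclass
class PipelineConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    rules: RuleConfig = field(default_factory=RuleConfig)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    output_dir: str | Path = "edscreen_out"
    mode: str = "census"  # or "verification-sample"
    log_level: str = "INFO"
    report_precision: int = 2
    auc_bootstrap: int = 2000

    def validate(self) -> "PipelineConfig":
        self.cohort.validate()
        self.rules.validate()
        self.design.validate()
        if self.mode not in ("census", "verification-sample"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.report_precision < 0:
            raise ParameterError("report_precision must be >= 0")
        return self


@dataclass
class PipelineResult:
    report: AccuracyReport
    cascade: dict
    paths: dict[str, Path]


def _dump_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the artifact files into ``output_dir``.

    Deterministic for a fixed configuration: the cohort seed drives
    generation, the design seed drives verification sampling, and the AUC
    bootstrap is seeded from the cohort seed.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("cohort", "cohort.csv"), ("decisions", "decisions.csv"), ("labels", "labels.csv"),
        ("confusion", "confusion.json"), ("report", "report.json"),
        ("cascade", "cascade.json"), ("roc", "roc_points.csv"),
    ]}

    try:
        cohort = generate_cohort(config.cohort)
        write_cohort_csv(cohort, paths["cohort"])
    except ParameterError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineStageError("generate", str(exc)) from exc

    try:
        decisions = decide_frame(cohort, config.rules)
        decisions.assign(
            reason_codes=decisions["reason_codes"]
        ).to_csv(paths["decisions"], index=False)
    except Exception as exc:
        raise PipelineStageError("decide", str(exc)) from exc

    try:
        labels = review_frame(cohort, config.rules)
        labels.to_csv(paths["labels"], index=False)
    except Exception as exc:
        raise PipelineStageError("review", str(exc)) from exc

    # suppression bookkeeping, echoing the cascade reporting style
    supp_counts = {
        code: int(decisions["reason_codes"].str.contains(code).sum())
        for code in ("suppressed_no_lab", "suppressed_missing_age", "suppressed_missing_bmi")
    }
    for code, count in supp_counts.items():
        log.info("%s: %d visits", code, count)

    study = cohort.index[cohort["lab_ordered"]]
    trig = decisions.loc[study, "triggered"]
    should = labels.loc[study, "should_trigger"]

    try:
        if config.mode == "verification-sample":
            vs = sample_negatives(cohort.loc[study, "race_ethnicity"], trig, config.design)
            verified, weights = vs.index, vs.weights
        else:
            verified, weights = study, pd.Series(1.0, index=study)
        table = build_confusion(trig.loc[verified], should.loc[verified], weights)
    except Exception as exc:
        raise PipelineStageError("sample", str(exc)) from exc

    try:
        correct = (trig.loc[verified] == should.loc[verified]).astype(int)
        auc_res = weighted_auc(cohort.loc[verified], correct, weights,
                               n_boot=config.auc_bootstrap, seed=config.cohort.seed)
        auc_res.roc_points.to_csv(paths["roc"], index=False)
        report = accuracy_report(table, auc_res.metric)
    except Exception as exc:
        raise PipelineStageError("validate", str(exc)) from exc

    cascade = {
        "adults": int(len(cohort)),
        "lab_ordered": int(cohort["lab_ordered"].sum()),
        "bpa_triggered": int((cohort["lab_ordered"] & decisions["triggered"]).sum()),
    }
    log.info("cascade: %d adults -> %d lab ordered -> %d (%.0f%%) BPA triggered",
             cascade["adults"], cascade["lab_ordered"], cascade["bpa_triggered"],
             100 * cascade["bpa_triggered"] / max(cascade["lab_ordered"], 1))

    _dump_json({"mode": config.mode, **table.as_dict()}, paths["confusion"])
    _dump_json(cascade, paths["cascade"])
    payload = report.as_dict(precision=None)
    payload["display"] = report.as_dict(precision=config.report_precision)
    payload["mode"] = config.mode
    payload["suppressions"] = supp_counts
    _dump_json(payload, paths["report"])

    return PipelineResult(report=report, cascade=cascade, paths=paths)


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file with optional
    ``cohort``, ``rules``, ``design`` and top-level output sections."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    cohort_cfg = payload.get("cohort", {})
    for k in ("age_distribution", "bmi_distribution"):
        if k in cohort_cfg:
            cohort_cfg[k] = tuple(cohort_cfg[k])
    config = PipelineConfig(
        cohort=CohortParams(**cohort_cfg),
        rules=RuleConfig(**payload.get("rules", {})),
        design=SamplingDesign(**payload.get("design", {})),
        output_dir=payload.get("output_dir", "edscreen_out"),
        mode=payload.get("mode", "census"),
        log_level=payload.get("log_level", "INFO"),
        report_precision=payload.get("report_precision", 2),
        auc_bootstrap=payload.get("auc_bootstrap", 2000),
    )
    return config.validate()
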