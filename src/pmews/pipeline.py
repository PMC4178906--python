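"""End-to-end study pipeline: simulate/load -> score -> summarise -> evaluate.

One call (:func:`run_study`) reproduces the published analysis on any
cohort: the scored CSV, the characteristics-table summary, ROC analyses for the
total, physiological and social scores, the integer cutoff sweep, and the
score-by-disposal distribution, plus a manifest that makes the run
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .calibrate import default_constraints  # noqa: F401  (re-export convenience)
from .io import read_patient_csv, write_patient_csv
from .roc import (
    RocAnalysis,
    ScoreDisposal,
    analyze_score,
    confusion_at_cutoff,
    cutoff_sweep,
    disposal_by_score,
)
from .scoring import score_dataframe
from .simulate import GeneratorConfig, reference_config, simulate_cohort
from .summary import CohortSummary, describe_cohort

__all__ = ["RunConfig", "StudyReport", "run_study", "SCORE_COLUMNS"]

logger = logging.getLogger("pmews")

#: score column -> label used in reports
SCORE_COLUMNS = {
    "total_pmews": "total",
    "physiological_score": "physiological",
    "social_score": "social",
}


@dataclass
class RunConfig:
    """Configuration of one study run; exactly one input source."""

    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    n: int = 2157
    seed: int = 1
    cutoff: int = 4
    ci_method: str = "delong"
    outdir: Optional[str] = None
    missing_policy: str = "strict"

    def validate(self) -> None:
        simulate = self.generator is not None
        if bool(self.input_csv) == simulate:
            raise ValueError("exactly one input source (input_csv or generator)")
        if not 0 <= self.cutoff <= 24:
            raise ValueError("cutoff must be in [0, 24]")


@dataclass
class StudyReport:
    """In-memory artifacts of one study run."""

    scored: pd.DataFrame
    summary: CohortSummary
    roc: dict[str, RocAnalysis]  # keyed by SCORE_COLUMNS labels; empty if unlabeled
    cutoff_performance: Optional[object]
    sweep: list
    disposal: Optional[ScoreDisposal]
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # where artifacts land is not part of the analysis
    if config.generator is not None:
        d["generator"] = config.generator.to_dict()
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_study(config: RunConfig) -> StudyReport:
    """Run the full pipeline and (optionally) write its artifacts.

    An unlabeled cohort is scored and summarised; the ROC stages are
    skipped with a logged notice.
    """
    config.validate()
    if config.generator is not None:
        cohort = simulate_cohort(config.generator, config.n, config.seed)
        logger.info("simulated cohort: %d records (seed %d)", len(cohort), config.seed)
    else:
        cohort = read_patient_csv(config.input_csv)
        logger.info("loaded cohort: %d records from %s", len(cohort), config.input_csv)

    scored = score_dataframe(cohort, missing_policy=config.missing_policy)
    logger.info("scored %d records", len(scored))
    summary = describe_cohort(scored)

    labeled = "needs_ems" in scored.columns and scored["needs_ems"].notna().all()
    roc: dict[str, RocAnalysis] = {}
    cutoff_perf = None
    sweep: list = []
    disposal = None
    if labeled:
        y = scored["needs_ems"].astype(int).to_numpy()
        for col, label in SCORE_COLUMNS.items():
            roc[label] = analyze_score(
                scored[col].to_numpy(),
                y,
                ci_method=config.ci_method,
                seed=config.seed,
            )
            logger.info(
                "ROC (%s): AUROC %.3f (95%% CI %.3f-%.3f)",
                label,
                roc[label].auroc,
                roc[label].ci_low,
                roc[label].ci_high,
            )
        total = scored["total_pmews"].to_numpy()
        cutoff_perf = confusion_at_cutoff(total, y, config.cutoff)
        sweep = cutoff_sweep(total, y)
        disposal = disposal_by_score(total, y)
    else:
        logger.info("cohort unlabeled: ROC stages skipped")

    manifest = {
        "pmews_version": __version__,
        "seed": config.seed,
        "n": len(scored),
        "cutoff": config.cutoff,
        "ci_method": config.ci_method,
        "input": config.input_csv or "simulated",
        "config_sha256": _config_hash(config),
    }
    report = StudyReport(
        scored=scored,
        summary=summary,
        roc=roc,
        cutoff_performance=cutoff_perf,
        sweep=sweep,
        disposal=disposal,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_artifacts(report, Path(config.outdir))
    return report


def _write_artifacts(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_patient_csv(report.scored, outdir / "scored.csv")
    (outdir / "summary.json").write_text(report.summary.to_json())
    (outdir / "summary.txt").write_text(report.summary.to_text() + "\n")
    if report.roc:
        analysis = {}
        for label, r in report.roc.items():
            analysis[label] = {
                "auroc": r.auroc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "ci_method": r.ci_method,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
            }
            pd.DataFrame(
                [
                    {
                        "threshold": p.threshold,
                        "sensitivity": p.sensitivity,
                        "specificity": p.specificity,
                    }
                    for p in r.points
                ]
            ).to_csv(outdir / f"roc_{label}.csv", index=False)
        cp = report.cutoff_performance
        analysis["cutoff"] = dataclasses.asdict(cp)
        (outdir / "analysis.json").write_text(json.dumps(analysis, indent=2))
        pd.DataFrame([dataclasses.asdict(c) for c in report.sweep]).to_csv(
            outdir / "cutoff_sweep.csv", index=False
        )
        report.disposal.table.to_csv(outdir / "disposal.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    logger.info("artifacts written to %s", outdir)
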