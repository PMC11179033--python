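"""End-to-end pipeline driver: simulate/load -> clean -> trends -> periodic
-> learning curves -> covariation, with every stage's artifacts archived."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cleaning import CleaningReport, clean_dataset
from .config import PipelineConfig
from .covariation import build_residuals, run_full_covariation
from .dataset import StudyDataset
from .learning import characterize_cohort
from .periodicity import periodic_analysis
from .trends import (
    OUTCOMES, ModelComparison, extract_intercepts, run_diagnostics,
    select_trend,
)

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    stage_counts: dict = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)
    selected_models: dict = field(default_factory=dict)
    periodic_terms: dict = field(default_factory=dict)
    learning_summary: dict = field(default_factory=dict)
    covariation_tables: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)  # residual normality etc.

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "cleaning": self.cleaning,
            "selected_models": self.selected_models,
            "periodic_terms": self.periodic_terms,
            "learning_summary": self.learning_summary,
            "covariation_tables": self.covariation_tables,
            "diagnostics": self.diagnostics,
        }


@dataclass
class PipelineResult:
    dataset: StudyDataset
    cleaning_report: CleaningReport
    comparisons: dict[str, ModelComparison]
    periodic: dict[str, dict]
    starting_points: pd.Series
    curves: pd.DataFrame
    residuals: pd.DataFrame
    covariation: dict
    report: RunReport


def run_pipeline(
    raw: StudyDataset, config: PipelineConfig | None = None
) -> PipelineResult:
    """Execute the full analysis on a raw dataset.

    Idempotent for identical inputs and configuration; any stage failure
    raises with the stage name attached.
    """
    config = config or PipelineConfig()
    config.validate()
    report = RunReport(
        config=config.to_dict(), seed=config.seed, version=__version__
    )
    report.stage_counts["input"] = raw.counts()

    stage = "clean"
    try:
        ds, cleaning_report = clean_dataset(
            raw,
            step_threshold=config.nonwear_step_threshold,
            min_per_hour=config.sparse_hour_min,
        )
        report.cleaning = cleaning_report.to_dict()
        report.stage_counts["clean"] = {
            "sessions_kept": int((~ds.sessions["excluded"].astype(bool)).sum()),
            "moods_kept": int((~ds.moods["excluded"].astype(bool)).sum()),
            "wear_days": int(ds.dailies["wear"].astype(bool).sum()),
        }

        stage = "trends"
        comparisons: dict[str, ModelComparison] = {}
        for outcome in OUTCOMES:
            comparisons[outcome] = select_trend(
                ds, outcome,
                transform=config.transforms[outcome],
                alpha=config.selection_alpha,
            )
            report.selected_models[outcome] = {
                "degree": comparisons[outcome].selected_degree,
                "transform": config.transforms[outcome],
                "loglik": comparisons[outcome].selected.loglik,
            }

        stage = "periodic"
        periodic: dict[str, dict] = {}
        final_fits = {}
        for outcome in OUTCOMES:
            periodic[outcome] = periodic_analysis(
                comparisons[outcome], alpha=config.selection_alpha
            )
            final_fits[outcome] = periodic[outcome]["final"]
            report.diagnostics[outcome] = run_diagnostics(final_fits[outcome])
            report.periodic_terms[outcome] = {
                axis: {
                    "chi2": comp.chi2, "df": comp.df, "p": comp.p,
                    "retained": comp.retained,
                }
                for axis, comp in periodic[outcome]["comparisons"].items()
            }

        stage = "learning"
        starting_points = extract_intercepts(comparisons["dprime"].selected)
        active_sessions = ds.sessions[~ds.sessions["excluded"].astype(bool)]
        curves = characterize_cohort(
            active_sessions, starting_points,
            adequacy_alpha=config.adequacy_alpha,
            window=config.smoothing_window,
        )
        adequate = curves[curves["fit_adequate"]]
        report.learning_summary = {
            "n_participants": int(len(curves)),
            "n_adequate": int(len(adequate)),
            "mean_learning_rate_90": (
                float(adequate["learning_rate_90"].mean()) if len(adequate) else None
            ),
            "mean_learning_day_90": (
                float(adequate["learning_day_90"].mean()) if len(adequate) else None
            ),
            "mean_stable_max": (
                float(adequate["stable_max"].mean()) if len(adequate) else None
            ),
        }

        stage = "covary"
        residuals = build_residuals(final_fits)
        covariation = run_full_covariation(
            residuals, curves, alpha=config.selection_alpha
        )
        report.covariation_tables = {
            label: res.table.to_dict(orient="records")
            for label, res in covariation.items()
        }
        report.stage_counts["covary"] = {
            label: res.n_obs for label, res in covariation.items()
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        dataset=ds, cleaning_report=cleaning_report, comparisons=comparisons,
        periodic=periodic, starting_points=starting_points, curves=curves,
        residuals=residuals, covariation=covariation, report=report,
    )


def save_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    """Write CSV tables and the JSON run report for one pipeline run."""
    from .io import write_dataset, write_json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(result.dataset, out / "clean")
    for outcome, comp in result.comparisons.items():
        comp.table.to_csv(out / f"trend_comparison_{outcome}.csv", index=False)
        comp.selected.fixed_table.to_csv(
            out / f"trend_coefficients_{outcome}.csv", index=False
        )
    result.curves.to_csv(out / "learning_curves.csv", index=False)
    result.residuals.to_csv(out / "daily_residuals.csv", index=False)
    for label, res in result.covariation.items():
        res.table.to_csv(out / f"covariation_{label}.csv", index=False)
    write_json(result.report.to_dict(), out / "run_report.json")
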