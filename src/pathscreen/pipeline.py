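"""End-to-end orchestration: simulate (or load) -> summarise -> anova ->
screen -> fit -> r-to-z, with TSV outputs and a JSON run report.

Each stage reads and writes the same interchange formats the standalone
functions use, so any stage can be re-run from the files of the previous
one; re-running the downstream stages on the emitted TSVs reproduces the
result tables bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import pairwise_anova_bonferroni
from .inference import table1_report
from .models import classify_relationship
from .screen import Thresholds, correlation_matrix_set, screen_and_shade
from .simulate import CohortConfig, default_config, generate_cohort
from .summarise import apply_exclusions, summarise_medians, zscore
from .tables import write_event_table, write_matrix, write_truth_table

__all__ = ["PipelineConfig", "PipelineError", "RunReport", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage, keeps prior outputs."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``cohort`` is either a ``CohortConfig`` (simulation) or a mapping of
    cell type to an expression-matrix TSV path (real data; simulation is
    skipped).  ``tie_tolerance`` controls the parsimony margin by which a
    nonlinear form must beat the linear |r|.
    """

    cohort: CohortConfig | dict[str, str] | None = None
    out_dir: str | Path = "pathscreen_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    tie_tolerance: float = 0.01
    bonferroni_family: int | None = None
    dependent_rtoz: bool = False
    exclusions: dict[str, list[str]] = field(default_factory=dict)
    make_plots: bool = False
    sep: str = "\t"
    write_events: bool = False

    def __post_init__(self) -> None:
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be >= 0")


@dataclass
class RunReport:
    versions: dict
    config: dict
    row_counts: dict
    outputs: list[str]
    warnings: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path


def _ext(cfg: PipelineConfig) -> str:
    return "csv" if cfg.sep == "," else "tsv"


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Run every stage and write all result tables under ``out_dir``.

    Deterministic given the seed.  A failing stage aborts with a
    ``PipelineError`` naming the stage; outputs of completed stages are
    retained on disk.
    """
    cfg = config if config is not None else PipelineConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = _ext(cfg)
    outputs: list[str] = []
    row_counts: dict[str, int] = {}
    caught: list[str] = []

    def _record(path: Path) -> None:
        outputs.append(str(path))

    # -- stage: simulate or load ------------------------------------------
    stage = "simulate"
    try:
        if isinstance(cfg.cohort, dict):
            from .tables import read_matrix

            matrices = {ct: read_matrix(p) for ct, p in cfg.cohort.items()}
            truth = None
        else:
            cohort_cfg = cfg.cohort
            if cohort_cfg is None:
                cohort_cfg = default_config(seed=cfg.seed)
            elif cohort_cfg.seed != cfg.seed:
                from dataclasses import replace

                cohort_cfg = replace(cohort_cfg, seed=cfg.seed)
            events, truth = generate_cohort(cohort_cfg)
            _record(write_truth_table(truth, out / "truth_table.tsv"))
            if cfg.write_events:
                _record(write_event_table(events, out / "events.csv"))
            matrices = summarise_medians(events)
        matrices = apply_exclusions(matrices, cfg.exclusions)
        row_counts["samples"] = int(sum(len(m) for m in matrices.values()))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- stage: summarise -------------------------------------------------
    stage = "summarise"
    try:
        for ct, m in matrices.items():
            _record(write_matrix(m, out / f"medians_{ct}.{ext}"))
        zmats = zscore(matrices)
        for ct, zm in zmats.items():
            _record(write_matrix(zm, out / f"zscores_{ct}.{ext}"))
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- stage: anova -----------------------------------------------------
    stage = "anova"
    try:
        anova_tbl = pairwise_anova_bonferroni(zmats, m=cfg.bonferroni_family)
        p = out / f"anova_pairwise.{ext}"
        anova_tbl.to_csv(p, sep=cfg.sep, index=False)
        _record(p)
        row_counts["anova_rows"] = len(anova_tbl)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- stage: screen ----------------------------------------------------
    stage = "screen"
    try:
        all_candidates = []
        shade_rows = []
        for ct, m in matrices.items():
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                cms = correlation_matrix_set(m, cell_type=ct)
            caught.extend(str(w.message) for w in wlist)
            for key, rmat in cms.r.items():
                _record(write_matrix(rmat, out / f"corr_{ct}_{key}.{ext}"))
            calls, cand = screen_and_shade(cms, cfg.thresholds)
            all_candidates.append(cand)
            shade_rows.extend(
                {
                    "cell_type": ct,
                    "x_analyte": c.x_analyte,
                    "y_analyte": c.y_analyte,
                    "transform": c.transform,
                    "r": c.r,
                    "category": c.category,
                }
                for c in calls
            )
            if cfg.make_plots:
                from .plots import plot_correlation_heatmap

                _record(
                    plot_correlation_heatmap(
                        cms, out / f"heatmap_{ct}.png", cfg.thresholds
                    )
                )
        shade_tbl = pd.DataFrame(shade_rows)
        p = out / f"shade_calls.{ext}"
        shade_tbl.to_csv(p, sep=cfg.sep, index=False)
        _record(p)
        candidates = pd.concat(all_candidates, ignore_index=True)
        p = out / f"nonlinear_candidates.{ext}"
        candidates.to_csv(p, sep=cfg.sep, index=False)
        _record(p)
        row_counts["nonlinear_candidates"] = len(candidates)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- stage: fit -------------------------------------------------------
    stage = "fit"
    try:
        fit_rows = []
        for ct, m in matrices.items():
            analytes = list(m.columns)
            for ax in analytes:
                for ay in analytes:
                    if ax == ay:
                        continue
                    x = m[ax].to_numpy(dtype=float)
                    y = m[ay].to_numpy(dtype=float)
                    keep = ~np.isnan(x) & ~np.isnan(y)
                    if keep.sum() < 3:
                        continue
                    call = classify_relationship(
                        x[keep],
                        y[keep],
                        cell_type=ct,
                        x_analyte=ax,
                        y_analyte=ay,
                        strong_threshold=cfg.thresholds.strong,
                        tie_tolerance=cfg.tie_tolerance,
                        dependent_rtoz=cfg.dependent_rtoz,
                    )
                    row = {
                        "cell_type": ct,
                        "x_analyte": ax,
                        "y_analyte": ay,
                        "best_form": call.best.form,
                        "a": call.best.a,
                        "b": call.best.b,
                        "r_linearized": call.best.r_linearized,
                        "n": call.best.n,
                        "switch_label": call.switch_label,
                        "better_than_linear_p": call.better_than_linear_p,
                        "p_method": call.p_method,
                        "inadmissible": ";".join(call.inadmissible),
                    }
                    for form, fit in call.fits.items():
                        row[f"r_{form}"] = fit.r_linearized
                    fit_rows.append(row)
        fit_tbl = pd.DataFrame(fit_rows)
        p = out / f"relationship_calls.{ext}"
        fit_tbl.to_csv(p, sep=cfg.sep, index=False)
        _record(p)
        row_counts["relationship_calls"] = len(fit_tbl)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -- stage: r-to-z contrasts on screening candidates ------------------
    stage = "rtoz"
    try:
        if len(candidates):
            contrast_input = candidates[
                ["cell_type", "r_raw", "r_transformed", "n"]
            ].copy()
            contrasts = table1_report(contrast_input)
            contrasts.insert(1, "x_analyte", candidates["x_analyte"].to_numpy())
            contrasts.insert(2, "y_analyte", candidates["y_analyte"].to_numpy())
            contrasts.insert(3, "transform", candidates["transform"].to_numpy())
        else:
            contrasts = pd.DataFrame()
        p = out / f"rtoz_contrasts.{ext}"
        contrasts.to_csv(p, sep=cfg.sep, index=False)
        _record(p)
        row_counts["rtoz_contrasts"] = len(contrasts)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    report = RunReport(
        versions={
            "pathscreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        config={
            "seed": cfg.seed,
            "thresholds": cfg.thresholds.__dict__,
            "tie_tolerance": cfg.tie_tolerance,
            "bonferroni_family": cfg.bonferroni_family,
            "dependent_rtoz": cfg.dependent_rtoz,
            "simulated": not isinstance(cfg.cohort, dict),
        },
        row_counts=row_counts,
        outputs=outputs,
        warnings=caught,
    )
    report.to_json(out / "run_report.json")
    missing = [p for p in outputs if not Path(p).exists() or Path(p).stat().st_size == 0]
    if missing:  # pragma: no cover - defensive
        raise PipelineError("report", RuntimeError(f"empty outputs: {missing}"))
    return report
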