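"""CSV ingestion, run configuration, and the fit/select/test pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import FourierSpec, assemble_design
from .diagnostics import export_diagnostics, glejser_test
from .estimation import FittedModel, fit_ols
from .exceptions import InputDataError, SpecificationError
from .inference import partial_test_all, simultaneous_test
from .selection import SearchReport, search_combinations, search_uniform

__all__ = ["RunConfig", "read_table", "run_pipeline", "PipelineReport"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    response: str
    predictors: list[str] | None = None  # None: all non-response columns, file order
    T_max: int = 5
    mode: str = "combinations"  # "uniform" | "combinations"
    alpha: float = 0.05
    rescale: bool = False
    adjust: str | None = None  # multiplicity adjustment for partial tests
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise SpecificationError(f"alpha must be in (0, 1), got {self.alpha}")
        if int(self.T_max) < 1:
            raise SpecificationError(f"T_max must be >= 1, got {self.T_max}")
        if self.mode not in ("uniform", "combinations"):
            raise SpecificationError(f"mode must be uniform|combinations, got {self.mode!r}")


def read_table(
    path, response: str | None = None, predictors: list[str] | None = None
) -> pd.DataFrame:
    """Read and validate a CSV with a header row and numeric columns.

    Rows with missing values and non-numeric cells are rejected with their
    locations reported.  When ``response``/``predictors`` are given, their
    presence is checked and the table is restricted to those columns.
    """
    path = Path(path)
    try:
        # round_trip: the default fast float parser can be off by one ulp
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise InputDataError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise InputDataError(f"{path}: no data rows")

    wanted = None
    if response is not None:
        wanted = [response] + (
            predictors
            if predictors is not None
            else [c for c in df.columns if c != response]
        )
        missing = [c for c in wanted if c not in df.columns]
        if missing:
            raise InputDataError(f"{path}: missing columns {missing}")
        df = df[wanted]

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()].tolist()
        if bad:
            raise InputDataError(
                f"{path}: non-numeric value in column {col!r} at row(s) {bad[:5]}"
            )
        df[col] = numeric
    na_rows = df.index[df.isna().any(axis=1)].tolist()
    if na_rows:
        raise InputDataError(f"{path}: missing values at row(s) {na_rows[:10]}")
    return df


@dataclass
class PipelineReport:
    """All artifacts of one fit-select-test-diagnose run."""

    config: RunConfig
    search: SearchReport
    model: FittedModel
    simultaneous: "object"
    partial: pd.DataFrame
    glejser: "object"
    diagnostics: pd.DataFrame
    log: list[str] = field(default_factory=list)


def run_pipeline(config: RunConfig, data: pd.DataFrame) -> PipelineReport:
    """Search for the best oscillation counts, refit, test, and diagnose.

    When ``config.outdir`` is set, writes search.csv, coefficients.csv,
    metrics.csv, diagnostics.csv and run.log there.
    """
    y = data[config.response].to_numpy(dtype=float)
    pred_cols = config.predictors or [c for c in data.columns if c != config.response]
    X_raw = data[pred_cols]

    log: list[str] = [f"n={len(data)} p={len(pred_cols)} predictors={pred_cols}"]
    if config.mode == "uniform":
        search = search_uniform(X_raw, y, config.T_max, rescale=config.rescale)
    else:
        search = search_combinations(X_raw, y, config.T_max, rescale=config.rescale)
    best_T = search.best.spec.T
    log.append(
        f"mode={search.mode} candidates={search.candidates_evaluated} "
        f"selected T={best_T} GCV={search.best.gcv:.6g}"
    )

    design = assemble_design(X_raw, FourierSpec(T=best_T, rescale=config.rescale))
    model = fit_ols(design, y)
    log.append(
        f"L={design.L} rank={design.rank} df_resid={model.df_resid} "
        f"R2={model.metrics.r2:.6g} MSE={model.metrics.mse:.6g}"
    )

    sim = simultaneous_test(model, alpha=config.alpha)
    log.append(
        f"simultaneous F: statistic={sim.statistic:.6g} df={sim.df} "
        f"critical={sim.critical_value:.6g} p={sim.p_value:.6g} -> {sim.decision}"
    )
    partial = partial_test_all(model, alpha=config.alpha, adjust=config.adjust)
    from scipy import stats

    t_crit = float(stats.t.ppf(1 - config.alpha / 2, model.df_resid))
    log.append(f"partial t critical value t(alpha/2, r={model.df_resid}) = {t_crit:.6g}")

    glejser = glejser_test(model, alpha=config.alpha)
    log.append(
        f"glejser: simultaneous p={glejser.simultaneous_p:.6g} -> {glejser.conclusion}"
    )
    diag = export_diagnostics(model)

    report = PipelineReport(
        config=config,
        search=search,
        model=model,
        simultaneous=sim,
        partial=partial,
        glejser=glejser,
        diagnostics=diag,
        log=log,
    )
    if config.outdir is not None:
        _write_report(report, Path(config.outdir))
    return report


def _write_report(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.search.to_csv(outdir / "search.csv")
    report.partial.to_csv(outdir / "coefficients.csv", index=False)
    metrics = report.model.metrics.as_dict()
    pd.DataFrame([metrics]).to_csv(outdir / "metrics.csv", index=False)
    report.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
    (outdir / "run.log").write_text("\n".join(report.log) + "\n")
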