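"""End-to-end orchestration: simulate/ingest -> prevalence -> design ->
ARIMA ITS per stratum -> LSTM -> report bundle.

Outputs mirror the layout of a multi-model ITS effects table: per model the
ARIMA order, Ljung-Box Q and Stationary R^2, then rows for the constant,
ARMA terms and the 11 intervention variables with estimate, 95% CI and
p-value (significance flagged at two-sided p < 0.05).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arima import ArimaOrder, ItsFit, fit_its, select_order
from .interventions import DesignMatrix, build_design_matrix, default_calendar, load_calendar
from .lstm import LstmConfig, make_windows, predict_distribution, train
from .prevalence import stratify, weighted_weekly_prevalence
from .simulate import MicrodataScenario, Scenario, simulate_microdata, simulate_weekly_series
from .weekly import WeeklySeries

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input mode: "simulate" (scenario-driven), "microdata"
    (respondent CSV) or "series" (weekly prevalence CSV).
    """

    mode: str = "simulate"
    scenario: Scenario | None = None
    microdata_scenario: MicrodataScenario | None = None
    microdata_path: str | None = None
    series_path: str | None = None
    calendar_path: str | None = None
    cutoff: int = 15
    lag_weeks: int = 4
    strata: list[str] = field(default_factory=list)
    arima_grid: list[tuple[int, int, int]] = field(default_factory=lambda: [(0, 1, 1)])
    select: bool = False
    include_trend: bool = True
    lstm: LstmConfig | None = None
    run_lstm: bool = False
    output_dir: str = "previts_output"
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self):
        if self.mode not in ("simulate", "microdata", "series"):
            raise ValueError(f"unknown input mode: {self.mode!r}")
        if self.mode == "microdata" and not (self.microdata_path or self.microdata_scenario):
            raise ValueError("microdata mode needs microdata_path or microdata_scenario")
        if self.mode == "series" and not self.series_path:
            raise ValueError("series mode needs series_path")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    return obj


def effects_table(fits: dict[str, ItsFit]) -> pd.DataFrame:
    """Flatten per-stratum fits into one effects table.

    One row per model term per model, with the model-level diagnostics
    (order, Ljung-Box Q, Stationary R^2) repeated on each row, the CI
    rendered as "estimate (lower to upper)", and a significance flag at
    p < 0.05.
    """
    if not fits:
        raise ValueError("no fits to tabulate")
    rows = []
    for label, fit in fits.items():
        for _, r in fit.table.iterrows():
            ci = (
                f"{r['estimate']:.2f} ({r['ci_lower']:.2f} to {r['ci_upper']:.2f})"
                if np.isfinite(r["se"])
                else f"{r['estimate']:.2f}"
            )
            rows.append(
                {
                    "model": label,
                    "arima_order": str(fit.order),
                    "ljung_box_q": fit.ljung_box_stat,
                    "stationary_r2": fit.stationary_r2,
                    "bic": fit.bic,
                    "term": r["term"],
                    "estimate": r["estimate"],
                    "ci_lower": r["ci_lower"],
                    "ci_upper": r["ci_upper"],
                    "estimate_ci": ci,
                    "p_value": r["p_value"],
                    "significant": bool(r["p_value"] < 0.05)
                    if np.isfinite(r["p_value"])
                    else False,
                }
            )
    return pd.DataFrame(rows)


def render_effects_text(table: pd.DataFrame) -> str:
    """Human-readable effects table, one block per model."""
    lines = []
    for label, sub in table.groupby("model", sort=False):
        head = sub.iloc[0]
        lines.append(
            f"== {label}  ARIMA {head['arima_order']}  "
            f"Ljung-Box Q {head['ljung_box_q']:.2f}  "
            f"Stationary R2 {head['stationary_r2']:.2f}"
        )
        for _, r in sub.iterrows():
            star = " *" if r["significant"] else ""
            pv = f"{r['p_value']:.4f}" if np.isfinite(r["p_value"]) else "-"
            lines.append(f"  {r['term']:<12} {r['estimate_ci']:>28}  p={pv}{star}")
        lines.append("")
    return "\n".join(lines)


def plot_series(
    series: WeeklySeries,
    design: DesignMatrix,
    path,
    fitted: np.ndarray | None = None,
    forecast=None,
    mark_lagged_onsets: bool = False,
):
    """Plot the weekly series with the 11 event markers at their actual
    dates (dashed secondary markers at lagged onsets optional), plus
    optional fitted-mean and 95%-band overlays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .interventions import lagged_onset
    from .weekly import week_index

    fig, ax = plt.subplots(figsize=(11, 4.5))
    weeks = np.arange(len(series))
    ax.plot(weeks, series.values, color="tab:red", lw=1.2, label="observed")
    for e in design.events:
        w = week_index(e.date, series.start_date)
        if 0 <= w < len(series):
            ax.axvline(w, color="black", ls=":", lw=0.8)
            ax.annotate(str(e.id), (w, ax.get_ylim()[1]), fontsize=8,
                        ha="center", va="bottom")
        if mark_lagged_onsets:
            lw_ = lagged_onset(e, series.start_date, design.lag_weeks)
            if 0 <= lw_ < len(series):
                ax.axvline(lw_, color="gray", ls="--", lw=0.6)
    if fitted is not None:
        ax.plot(weeks, fitted, color="tab:blue", lw=1.0, label="fitted mean")
    if forecast is not None:
        ax.plot(forecast.target_weeks, forecast.mu, color="tab:blue", lw=1.0,
                label="LSTM mean")
        ax.fill_between(forecast.target_weeks, forecast.lower, forecast.upper,
                        color="gray", alpha=0.35, label="95% interval")
    ax.set_xlabel("week")
    ax.set_ylabel("prevalence (pp)")
    ax.set_title(series.label)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a dict with the in-memory artifacts (series, fits, effects
    table, forecast, manifest); everything is also written under
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage_log: list[dict] = []
    results: dict = {}

    def log_stage(name, t0, **info):
        entry = {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        stage_log.append(entry)
        logger.info("stage %s done in %.2fs %s", name, entry["seconds"], info)

    # ---- stage 1: obtain the weekly series (and optional strata) --------
    t0 = time.time()
    strata_series: dict[str, WeeklySeries] = {}
    if config.mode == "simulate":
        scenario = config.scenario or Scenario(seed=config.seed)
        series = simulate_weekly_series(scenario)
        start_date, n_weeks = scenario.start_date, scenario.n_weeks
        if config.microdata_scenario is not None:
            micro = simulate_microdata(config.microdata_scenario, series, cutoff=config.cutoff)
            micro.to_csv(out / "microdata.csv", index=False)
            series = weighted_weekly_prevalence(
                micro, cutoff=config.cutoff, start_date=start_date, n_weeks=n_weeks
            )
            if config.strata:
                strata_series = stratify(
                    micro, cutoff=config.cutoff, start_date=start_date,
                    n_weeks=n_weeks, variables=config.strata,
                )
        log_stage("simulate", t0, n_weeks=len(series))
    elif config.mode == "microdata":
        micro = pd.read_csv(config.microdata_path)
        series = weighted_weekly_prevalence(micro, cutoff=config.cutoff)
        start_date, n_weeks = series.start_date, len(series)
        if config.strata:
            strata_series = stratify(
                micro, cutoff=config.cutoff, start_date=start_date,
                n_weeks=n_weeks, variables=config.strata,
            )
        log_stage("derive", t0, n_records=len(micro), n_weeks=n_weeks)
    else:
        series = WeeklySeries.read_csv(config.series_path)
        start_date, n_weeks = series.start_date, len(series)
        log_stage("ingest", t0, n_weeks=n_weeks)
    series.to_csv(out / "weekly_series.csv")
    results["series"] = series
    results["strata_series"] = strata_series

    # ---- stage 2: design matrix ----------------------------------------
    t0 = time.time()
    events = load_calendar(config.calendar_path) if config.calendar_path else default_calendar()
    design = build_design_matrix(
        events, n_weeks=n_weeks, start_date=start_date, lag_weeks=config.lag_weeks
    )
    design.to_csv(out / "design_matrix.csv")
    results["design"] = design
    log_stage("design", t0, n_events=len(events), lag_weeks=config.lag_weeks)

    # ---- stage 3: ARIMA ITS fits ----------------------------------------
    t0 = time.time()
    fits: dict[str, ItsFit] = {}
    model_warnings: list[str] = []
    try:
        for label, s in [("total", series)] + sorted(strata_series.items()):
            if np.isnan(s.values).all():
                model_warnings.append(f"{label}: all-missing series skipped")
                continue
            if config.select and len(config.arima_grid) > 1:
                order, _ = select_order(
                    s, design, [ArimaOrder(*o) for o in config.arima_grid],
                    include_trend=config.include_trend,
                    interpolate_missing=True,
                )
            else:
                order = ArimaOrder(*config.arima_grid[0])
            fit = fit_its(
                s, design, order, include_trend=config.include_trend,
                interpolate_missing=True,
            )
            if fit.ljung_box_pvalue < 0.05:
                model_warnings.append(
                    f"{label}: Ljung-Box p={fit.ljung_box_pvalue:.3f} flags residual "
                    "autocorrelation"
                )
            fits[label] = fit
    except Exception as err:
        _write_manifest(out, config, stage_log, model_warnings, failed_stage="fit-arima", error=str(err))
        raise RuntimeError(f"stage fit-arima failed: {err}") from err
    table = effects_table(fits)
    table.to_csv(out / "effects_table.csv", index=False)
    (out / "effects_table.txt").write_text(render_effects_text(table))
    results["fits"] = fits
    results["effects_table"] = table
    log_stage("fit-arima", t0, n_models=len(fits))

    # ---- stage 4: LSTM ---------------------------------------------------
    forecast = None
    if config.run_lstm:
        t0 = time.time()
        lstm_cfg = config.lstm or LstmConfig(seed=config.seed)
        try:
            ds = make_windows(series, design, lstm_cfg)
            model, hist = train(ds, lstm_cfg)
            forecast = predict_distribution(model, ds)
        except Exception as err:
            _write_manifest(out, config, stage_log, model_warnings, failed_stage="fit-lstm", error=str(err))
            raise RuntimeError(f"stage fit-lstm failed: {err}") from err
        pd.DataFrame(
            {
                "epoch": np.arange(1, len(hist.train_mse) + 1),
                "train_loss": hist.train_loss,
                "train_mse": hist.train_mse,
                "test_mse": hist.test_mse,
            }
        ).to_csv(out / "lstm_curves.csv", index=False)
        pd.DataFrame(
            {
                "week": forecast.target_weeks,
                "observed": series.values[forecast.target_weeks],
                "mu": forecast.mu,
                "sigma": forecast.sigma,
                "lower": forecast.lower,
                "upper": forecast.upper,
            }
        ).to_csv(out / "lstm_predictions.csv", index=False)
        results["forecast"] = forecast
        results["lstm_history"] = hist
        log_stage("fit-lstm", t0, epochs=lstm_cfg.epochs,
                  best_epoch=hist.best_epoch())

    # ---- stage 5: report -------------------------------------------------
    t0 = time.time()
    if config.make_figures:
        plot_series(series, design, out / "series.png", forecast=forecast)
    machine = {
        "effects": table.to_dict(orient="records"),
        "models": {
            label: {
                "order": str(f.order),
                "bic": f.bic,
                "loglik": f.loglik,
                "ljung_box_q": f.ljung_box_stat,
                "ljung_box_p": f.ljung_box_pvalue,
                "stationary_r2": f.stationary_r2,
                "sigma2": f.sigma2,
            }
            for label, f in fits.items()
        },
        "warnings": model_warnings,
    }
    (out / "results.json").write_text(json.dumps(_jsonable(machine), indent=2))
    manifest = _write_manifest(out, config, stage_log, model_warnings)
    results["manifest"] = manifest
    results["warnings"] = model_warnings
    log_stage("report", t0)
    logger.info("pipeline done in %.2fs", time.time() - t_start)
    return results


def _write_manifest(out: Path, config: PipelineConfig, stage_log, warnings_,
                    failed_stage=None, error=None) -> dict:
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "stages": stage_log,
        "warnings": list(warnings_),
    }
    if failed_stage:
        manifest["failed_stage"] = failed_stage
        manifest["error"] = error
    (out / "run_manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest


def load_results(output_dir) -> pd.DataFrame:
    """Reload the machine-readable effects table written by run_pipeline."""
    with open(Path(output_dir) / "results.json") as fh:
        data = json.load(fh)
    return pd.DataFrame(data["effects"])
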