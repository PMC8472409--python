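"""Desk-scale orchestration of the full study.

One configuration drives: sample filters (with audit), summary statistics,
the three-estimator comparison (pooled OLS, fixed effects, threshold GMM),
instrument diagnostics, trim-rate sensitivity, skill subgroup refits and
effect-size summaries.  Reports are emitted as machine-readable JSON and
human-readable text tables; given a seed, every output byte is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baselines import fit_fixed_effects, fit_pooled_ols
from .diagnostics import compute_instrument_diagnostics
from .exceptions import ConfigError, PanelKinkError
from .gmm import GmmSpec, ThresholdFit, fit_panel_threshold
from .panel import (FilterAudit, InstrumentTable, PanelDataset,
                    apply_sample_filters, read_instruments_csv, read_panel_csv)
from .simulate import SimulationConfig, default_bcs_config, simulate_panel

logger = logging.getLogger(__name__)

#: significance stars at the conventional thresholds used in the report tables
STAR_THRESHOLDS = ((0.001, "***"), (0.05, "**"), (0.1, "*"))


def stars(p: float) -> str:
    """Significance marker: *** p<0.001, ** p<0.05, * p<0.1."""
    if not np.isfinite(p):
        return ""
    for cut, mark in STAR_THRESHOLDS:
        if p < cut:
            return mark
    return ""


def effect_size_sd(total_effect: float, outcome_sd: float) -> float:
    """Effect expressed as a percentage of an outcome standard deviation."""
    if not outcome_sd > 0:
        raise ValueError("outcome_sd must be strictly positive")
    return 100.0 * total_effect / outcome_sd


@dataclass
class AnalysisConfig:
    """Inputs and settings of one full analysis run.

    Supply either a simulation config (or an arm name to use the packaged
    defaults) or CSV paths for the panel and instruments.
    """

    simulation: SimulationConfig | None = None
    arm: str | None = None
    panel_path: str | None = None
    instruments_path: str | None = None
    covariate_names: list[str] | None = None
    n_individuals: int = 828
    trim_rates: list[float] = field(default_factory=lambda: [0.2, 0.3, 0.4])
    gmm: GmmSpec = field(default_factory=GmmSpec)
    skill_split: bool = True
    skill_period: int = 1
    apply_filters: bool = True
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.arm is None and self.panel_path is None:
            raise ConfigError("need a simulation config, an arm name, or a panel path")
        for r in self.trim_rates:
            if not 0.0 < r < 1.0:
                raise ConfigError("trim rates must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "gmm" in raw:
            raw["gmm"] = GmmSpec(**raw["gmm"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All tables of one analysis run, each traceable to a fit object."""

    summary_table: pd.DataFrame
    estimator_table: pd.DataFrame
    sensitivity_table: pd.DataFrame
    skill_table: pd.DataFrame | None
    effect_sizes: dict
    diagnostics: dict
    audit: FilterAudit
    manifest: dict
    fits: dict


# ---------------------------------------------------------------------------
# summary statistics


def summary_statistics(data: PanelDataset, instruments: InstrumentTable | None = None) -> pd.DataFrame:
    """Mean (SD) of outcome, BMI and covariates by gender x period, plus the
    per-gender childhood instruments.  A single-record cell reports its SD as
    missing rather than zero."""
    df = data.df
    variables = ["hours", "bmi"] + list(data.covariate_names)
    rows = []
    for gender, gdf in df.groupby("gender"):
        for period, pdf in gdf.groupby("period"):
            for var in variables:
                series = pdf[var]
                rows.append({
                    "gender": gender, "period": int(period), "variable": var,
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)) if len(series) > 1 else np.nan,
                    "n": len(series),
                })
        if instruments is not None:
            ids = gdf["id"].unique()
            inst = instruments.df[instruments.df["id"].isin(ids)]
            for var in instruments.instrument_names:
                series = inst[var]
                rows.append({
                    "gender": gender, "period": 0, "variable": var,
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)) if len(series) > 1 else np.nan,
                    "n": len(series),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimator comparison


def _threshold_row(fit: ThresholdFit) -> dict:
    summary = fit.summary_frame()
    out = {}
    for name, label in (("alpha", "alpha"), ("delta", "delta"), ("gamma", "gamma")):
        est, se, p = summary.loc[name, ["estimate", "se", "p"]]
        out[label] = float(est)
        out[f"{label}_se"] = float(se)
        out[f"{label}_stars"] = stars(float(p))
    out["j_statistic"] = fit.j_statistic
    out["j_df"] = fit.j_df
    out["n"] = fit.n_used * 2
    return out


def estimator_comparison(data: PanelDataset, instruments: InstrumentTable,
                         spec: GmmSpec) -> tuple[pd.DataFrame, dict]:
    """Pooled OLS / fixed effects / panel threshold side by side."""
    pooled = fit_pooled_ols(data)
    fe = fit_fixed_effects(data)
    thr = fit_panel_threshold(data, instruments, spec)
    rows = []
    for fit in (pooled, fe):
        p = float(fit.pvalues["bmi"])
        rows.append({
            "estimator": fit.estimator, "alpha": fit.bmi_slope,
            "alpha_se": float(fit.se["bmi"]), "alpha_stars": stars(p),
            "delta": np.nan, "delta_se": np.nan, "delta_stars": "",
            "gamma": np.nan, "gamma_se": np.nan, "gamma_stars": "",
            "r_squared": fit.r_squared, "n": fit.n_obs,
        })
    trow = _threshold_row(thr)
    trow.update({"estimator": "panel_threshold", "r_squared": np.nan})
    rows.append(trow)
    table = pd.DataFrame(rows)
    return table, {"pooled_ols": pooled, "fixed_effects": fe, "panel_threshold": thr}


def trim_sensitivity(data: PanelDataset, instruments: InstrumentTable,
                     rates: list[float], base_spec: GmmSpec | None = None) -> tuple[pd.DataFrame, dict]:
    """Refit the threshold model at each trim rate (total-fraction convention)."""
    base_spec = base_spec or GmmSpec()
    rows, fits = [], {}
    for rate in rates:
        spec = dataclasses.replace(base_spec, trim_rate=rate)
        try:
            fit = fit_panel_threshold(data, instruments, spec)
        except PanelKinkError as err:
            logger.warning("trim rate %.2f failed: %s", rate, err)
            rows.append({"trim_rate": rate, "status": f"failed: {err}"})
            continue
        row = _threshold_row(fit)
        row.update({"trim_rate": rate, "status": "ok"})
        rows.append(row)
        fits[rate] = fit
    return pd.DataFrame(rows), fits


def subgroup_analysis(data: PanelDataset, instruments: InstrumentTable,
                      split: str = "skill", spec: GmmSpec | None = None,
                      membership_period: int = 1) -> tuple[pd.DataFrame, dict]:
    """Threshold refits within subgroups plus the pooled group.

    Subgroup membership is period-agnostic: the label observed in
    ``membership_period`` defines the split (configurable because labels such
    as skill can change between waves).
    """
    if split not in ("skill", "gender"):
        raise ConfigError(f"unknown split {split!r}")
    spec = spec or GmmSpec()
    df = data.df
    label_at = df[df["period"] == membership_period].set_index("id")[split]
    rows, fits = [], {}
    groups = {"all": set(label_at.index)}
    for label in sorted(label_at.unique()):
        groups[label] = set(label_at.index[label_at == label])
    for name, ids in groups.items():
        sub = data.subset(df["id"].isin(ids))
        try:
            fit = fit_panel_threshold(sub, instruments, spec)
        except PanelKinkError as err:
            logger.warning("subgroup %r skipped: %s", name, err)
            rows.append({"group": name, "status": f"skipped: {err}"})
            continue
        row = _threshold_row(fit)
        row.update({"group": name, "status": "ok"})
        rows.append(row)
        fits[name] = fit
    return pd.DataFrame(rows), fits


# ---------------------------------------------------------------------------
# orchestration


def _load_inputs(config: AnalysisConfig):
    if config.simulation is not None or config.arm is not None:
        sim = config.simulation or default_bcs_config(
            config.arm, n_individuals=config.n_individuals, seed=config.seed)
        panel, instruments, truth = simulate_panel(sim)
        return panel, instruments, {"source": "simulation", "arm": sim.gender,
                                    "n_individuals": sim.n_individuals, "seed": sim.seed}
    covs = config.covariate_names
    if covs is None:
        raise ConfigError("covariate_names required when reading CSV inputs")
    panel = read_panel_csv(config.panel_path, covs)
    instruments = read_instruments_csv(config.instruments_path)
    return panel, instruments, {"source": "csv", "panel": str(config.panel_path),
                                "instruments": str(config.instruments_path)}


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline; write reports if an output directory is set."""
    panel, instruments, source = _load_inputs(config)

    if config.apply_filters:
        panel, audit = apply_sample_filters(panel)
    else:
        audit = FilterAudit()

    summary = summary_statistics(panel, instruments)

    est_rows, fits, diag, eff = [], {}, {}, {}
    sens_frames, skill_frames = [], []
    for gender, gdf in panel.df.groupby("gender"):
        sub = panel.subset(panel.df["gender"] == gender)
        try:
            table, gfits = estimator_comparison(sub, instruments, config.gmm)
        except PanelKinkError as err:
            logger.warning("gender group %r skipped: %s", gender, err)
            continue
        table.insert(0, "gender", gender)
        est_rows.append(table)
        fits[gender] = gfits

        diag[gender] = compute_instrument_diagnostics(sub, instruments).to_dict()

        thr = gfits["panel_threshold"]
        below, above = thr.regime_slopes
        hours_p1 = sub.df.loc[sub.df["period"] == 1, "hours"]
        sd1 = float(hours_p1.std(ddof=1))
        eff[gender] = {
            "slope_below": below, "slope_above": above,
            "outcome_sd_period1": sd1,
            "effect_size_above_pct_sd": effect_size_sd(above, sd1),
        }

        sens, _ = trim_sensitivity(sub, instruments, config.trim_rates, config.gmm)
        sens.insert(0, "gender", gender)
        sens_frames.append(sens)

        if config.skill_split:
            skill, _ = subgroup_analysis(sub, instruments, "skill", config.gmm,
                                         config.skill_period)
            skill.insert(0, "gender", gender)
            skill_frames.append(skill)

    estimator_table = pd.concat(est_rows, ignore_index=True) if est_rows else pd.DataFrame()
    sensitivity_table = pd.concat(sens_frames, ignore_index=True) if sens_frames else pd.DataFrame()
    skill_table = pd.concat(skill_frames, ignore_index=True) if skill_frames else None

    manifest = {
        "panelkink_version": __version__,
        "seed": config.seed,
        "input": source,
        "gmm": {f.name: _jsonable(getattr(config.gmm, f.name))
                for f in dataclasses.fields(config.gmm)},
        "trim_rates": list(config.trim_rates),
        "skill_membership_period": config.skill_period,
        "filter_audit": [list(s) for s in audit.steps],
    }
    bundle = ReportBundle(
        summary_table=summary, estimator_table=estimator_table,
        sensitivity_table=sensitivity_table, skill_table=skill_table,
        effect_sizes=eff, diagnostics=diag, audit=audit, manifest=manifest, fits=fits,
    )
    if config.output_dir is not None:
        _write_reports(bundle, Path(config.output_dir))
    return bundle


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return value


def _frame_json(df: pd.DataFrame) -> list[dict]:
    out = []
    for record in df.to_dict(orient="records"):
        out.append({k: (None if isinstance(v, float) and not np.isfinite(v) else _jsonable(v))
                    for k, v in record.items()})
    return out


def _write_reports(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "summary": bundle.summary_table,
        "estimators": bundle.estimator_table,
        "sensitivity": bundle.sensitivity_table,
    }
    if bundle.skill_table is not None:
        tables["subgroups"] = bundle.skill_table
    for name, df in tables.items():
        (outdir / f"{name}.json").write_text(
            json.dumps(_frame_json(df), indent=2, sort_keys=True) + "\n")
        (outdir / f"{name}.txt").write_text(df.to_string(index=False) + "\n")
    (outdir / "effect_sizes.json").write_text(
        json.dumps(bundle.effect_sizes, indent=2, sort_keys=True) + "\n")
    (outdir / "diagnostics.json").write_text(
        json.dumps(bundle.diagnostics, indent=2, sort_keys=True) + "\n")
    (outdir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
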