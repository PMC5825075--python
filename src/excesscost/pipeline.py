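"""End-to-end orchestration: filter, code, cost, fit, and render reports.

``run_pipeline`` chains the stages on delimited-text inputs and writes a
report bundle: the coded episode table, the excess-cost table, the
regression result (JSON, unrounded), rendered summary tables (rounding only
here), a dollar-effect bar chart with a CSV data sidecar, and a run log
whose exclusion waterfall accounts for every input row.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as ecio
from .coding import (
    DEFAULT_LOOKBACK_YEARS,
    DEFAULT_MAX_LOS,
    DEFAULT_MIN_AGE,
    code_episodes,
    filter_cohort,
    load_charlson_config,
    load_complication_rules,
)
from .cost import add_cost_totals, excess_cost, select_above_average
from .regression import ModelSpec, RegressionResult, fit_hierarchical

TABLE1_VARIABLES = [
    ("cost_weight", "Admission severity (cost weight)"),
    ("charlson", "Comorbidity (Charlson Index)"),
    ("age", "Age (years)"),
    ("extra_cost", "Extra cost"),
    ("n_complications", "Complications (number of)"),
]
PREDICTOR_LABELS = {
    "dementia": "Dementia",
    "n_complications": "Complications",
    "cost_weight": "Admission severity (cost weight)",
    "charlson": "Comorbidity (Charlson Index)",
    "age": "Age",
    "surgical": "Surgical status (surgery)",
    "male": "Sex (male)",
}


@dataclass
class PipelineConfig:
    """Paths, filter parameters and model options for one pipeline run."""

    episodes_path: str
    drg_reference_path: str
    rules_path: str | None = None
    charlson_path: str | None = None
    min_age: int = DEFAULT_MIN_AGE
    max_los: int = DEFAULT_MAX_LOS
    lookback_years: float = DEFAULT_LOOKBACK_YEARS
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    robust_se: bool = False
    currency: str = "AUD"
    ppp_multiplier: float | None = None
    outdir: str = "excesscost_out"

    def validate(self) -> None:
        for p in (self.episodes_path, self.drg_reference_path, self.rules_path, self.charlson_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input file not found: {p}")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def build_analysis_table(
    coded: pd.DataFrame, costed: pd.DataFrame
) -> pd.DataFrame:
    """Join coded episodes with their excess-cost records (above-average only)."""
    above = select_above_average(costed)
    cols = ["episode_id", "extra_days", "extra_cost", "daily_variable_cost"]
    if "cost_weight" in above.columns:
        cols.append("cost_weight")
    df = coded.merge(above[cols], on="episode_id", how="inner", validate="one_to_one")
    df["male"] = (df["sex"] == "male").astype(int)
    df["dementia"] = df["dementia"].astype(int)
    df["surgical"] = df["surgical"].astype(int)
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute filter -> code -> cost -> fit and write the report bundle."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    log: dict = {"stages": {}}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    episodes = _stage("read_episodes", ecio.read_episodes, config.episodes_path)
    drg_ref = _stage("read_drg_reference", ecio.read_drg_reference, config.drg_reference_path)
    log["stages"]["input"] = {"n_episodes": len(episodes), "n_drgs": len(drg_ref)}

    rules = _stage("load_rules", load_complication_rules, config.rules_path)
    charlson_cfg = _stage("load_charlson", load_charlson_config, config.charlson_path)

    filtered, exclusions = _stage(
        "filter_cohort", filter_cohort, episodes, config.min_age, config.max_los
    )
    log["stages"]["filter_cohort"] = {"retained": len(filtered), "excluded": exclusions}

    coded = _stage(
        "code_episodes",
        code_episodes,
        filtered,
        rules=rules,
        charlson_config=charlson_cfg,
        lookback_years=config.lookback_years,
    )
    ref_tot = _stage("cost_totals", add_cost_totals, drg_ref)
    costed = _stage("excess_cost", excess_cost, coded, ref_tot)
    analysis = _stage("build_analysis_table", build_analysis_table, coded, costed)
    log["stages"]["above_average"] = {
        "retained": len(analysis),
        "excluded": {"at_or_below_average": int(len(coded) - len(analysis))},
    }
    if config.ppp_multiplier:
        analysis["extra_cost"] = analysis["extra_cost"] * config.ppp_multiplier

    result = _stage("fit_hierarchical", fit_hierarchical, analysis, config.model_spec, config.robust_se)
    log["stages"]["fit"] = {"n": result.n, "dropped_missing": result.n_dropped_missing}
    log["currency"] = config.currency

    # Bundle artifacts.
    paths = {
        "coded": os.path.join(config.outdir, "coded_episodes.csv"),
        "excess": os.path.join(config.outdir, "excess_cost.csv"),
        "regression": os.path.join(config.outdir, "regression.json"),
        "table1": os.path.join(config.outdir, "table1.txt"),
        "table2": os.path.join(config.outdir, "table2.txt"),
        "chart": os.path.join(config.outdir, "effects.png"),
        "chart_data": os.path.join(config.outdir, "effects.csv"),
        "log": os.path.join(config.outdir, "run_log.json"),
    }
    coded_out = coded.copy()
    coded_out["additional_dx"] = coded_out["additional_dx"].map(";".join)
    coded_out["admission_date"] = pd.to_datetime(coded_out["admission_date"]).dt.strftime("%Y-%m-%d")
    coded_out.to_csv(paths["coded"], index=False)
    costed.to_csv(paths["excess"], index=False)
    with open(paths["regression"], "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
    t1, t2 = render_summary_tables(analysis, result)
    with open(paths["table1"], "w") as fh:
        fh.write(t1 + "\n")
    with open(paths["table2"], "w") as fh:
        fh.write(t2 + "\n")
    render_effect_chart(result, paths["chart"], data_path=paths["chart_data"])
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2)

    return {"result": result, "analysis": analysis, "coded": coded, "costed": costed,
            "log": log, "paths": paths}


def render_summary_tables(analysis: pd.DataFrame, result: RegressionResult) -> tuple[str, str]:
    """Render the characteristics table and the regression summary table.

    The first reports mean/min/max of the continuous analysis variables; the
    second reports per-predictor dollar effects, standardised betas and the
    percentage-of-mean column, plus fit statistics.
    """
    rows = []
    for col, label in TABLE1_VARIABLES:
        if col not in analysis.columns:
            continue
        s = analysis[col].astype(float)
        rows.append({"Variable": label, "Mean": s.mean(), "Minimum": s.min(), "Maximum": s.max()})
    t1 = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:,.1f}")

    coef = result.coefficients
    t2_rows = []
    for pred in coef.index:
        t2_rows.append(
            {
                "Explanatory variable": PREDICTOR_LABELS.get(pred, pred),
                "B ($, reverse log-transformed)": f"{coef.loc[pred, 'b_dollars']:,.0f}",
                "Beta (standardised)": f"{coef.loc[pred, 'beta_std']:.2f}",
                "% of average extra cost": f"{int(coef.loc[pred, 'pct_of_mean'])}%",
            }
        )
    t2 = pd.DataFrame(t2_rows).to_string(index=False)
    t2 += (
        f"\n\nR2 (step 1: age, sex) = {result.r2_step1:.3f}"
        f"\nR2 (step 2: full model) = {result.r2_step2:.3f}"
        f"\nAdj. R2 = {result.adj_r2:.3f}; F = {result.f_value:.1f}; N = {result.n}"
        f"\nMean extra cost = {result.mean_extra_cost:,.0f}"
    )
    return t1, t2


def render_effect_chart(
    result: RegressionResult, path: os.PathLike | str, data_path: os.PathLike | str | None = None
) -> None:
    """Bar chart of per-predictor dollar effects; bar data optionally saved as CSV."""
    coef = result.coefficients
    labels = [PREDICTOR_LABELS.get(p, p) for p in coef.index]
    values = coef["b_dollars"].to_numpy()
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar(np.arange(len(values)), values)
    ax.set_xticks(np.arange(len(values)))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("Effect on extra cost ($ per unit)")
    ax.set_title("Dollar effect of each predictor at the mean extra cost")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    if data_path is not None:
        pd.DataFrame({"predictor": coef.index, "b_dollars": values}).to_csv(data_path, index=False)
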