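"""End-to-end orchestration: read -> herbivory -> fluxes -> context -> stats.

``run_all`` takes a RunConfig (YAML-loadable), produces the full result
bundle (fluxes.csv, summaries.csv, comparisons.csv, models.csv, tests.csv
and a run log) and is deterministic given dataset + seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import context as ctx
from . import stats as st
from .data_model import ALL_ELEMENTS, Dataset, read_dataset, validate_dataset
from .fluxes import FluxTable, compute_fluxes, write_flux_table
from .herbivory import DamageClassScheme, DEFAULT_BOUNDS
from .synthetic import SyntheticConfig, generate_network

log = logging.getLogger("herbflux")

#: soil covariate entering the full model for each response family
SOIL_BY_RESPONSE = {
    "fp": "s_cn",
    "h_c_C": "s_c", "h_i_C": "s_c",
    "h_c_N": "s_cn", "h_i_N": "s_cn",
    "h_c_P": "s_cp", "h_i_P": "s_cp",
    "h_c_Si": "s_si",
    "f_C": "s_c", "f_N": "s_cn", "f_P": "s_cp", "f_Si": "s_si",
}


class RunConfig(BaseModel):
    """Configuration for a full pipeline run."""

    data_dir: str | None = None          # read an existing CSV bundle ...
    synthetic: SyntheticConfig | None = None  # ... or simulate one
    elements: list[str] = list(ALL_ELEMENTS)
    damage_class_bounds: list[float] = list(DEFAULT_BOUNDS)
    bootstrap_n: int = st.DEFAULT_BOOTSTRAP_N
    ci_level: float = st.DEFAULT_CI_LEVEL
    adjustment: str = "holm"
    seed: int = st.DEFAULT_SEED
    run_models: bool = True
    model_responses: list[str] | None = None
    complete_season: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class RunResult:
    dataset: Dataset
    fluxes: FluxTable
    summaries: pd.DataFrame
    tests: pd.DataFrame
    comparisons: pd.DataFrame
    models: pd.DataFrame
    plot_table: pd.DataFrame = field(default=None)


def assemble_plot_table(ds: Dataset, flux: FluxTable) -> pd.DataFrame:
    """One row per plot: climate, soil, herbivory, production, element fluxes."""
    meta_cols = ["plot_id", "site_id", "zone", "phenology", "mat_c", "dryness",
                 "abs_latitude"]
    table = ds.plots[meta_cols].copy()
    table = table.merge(
        ds.soil[["plot_id", "s_c", "s_si", "s_cn", "s_cp"]], on="plot_id")
    ft = flux.table
    base = ft.drop_duplicates("plot_id")[
        ["plot_id", "l_h", "h", "incidence", "n_leaves", "fp"]]
    table = table.merge(base, on="plot_id", how="left")
    for element in ft["element"].unique():
        sub = ft[ft["element"] == element]
        renames = {"h_c": f"h_c_{element}", "h_i": f"h_i_{element}",
                   "re": f"re_{element}", "l_eh": f"l_eh_{element}"}
        table = table.merge(
            sub[["plot_id", "h_c", "h_i", "re", "l_eh"]].rename(columns=renames),
            on="plot_id", how="left")
        green = ds.chemistry.query("element == @element and tissue == 'green'")
        table = table.merge(
            green.groupby("plot_id", as_index=False)["concentration"].mean()
            .rename(columns={"concentration": f"f_{element}"}),
            on="plot_id", how="left")
    return table


def summarize(plot_table: pd.DataFrame, adjustment: str = "holm") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zone-mean +/- SE summaries and rank-test tables for the key variables."""
    variables = [c for c in plot_table.columns
                 if c in ("fp", "h", "incidence", "l_h")
                 or c.startswith(("h_c_", "h_i_", "re_", "f_"))]
    summaries, tests = [], []
    zones = plot_table["zone"]
    multiple_zones = zones.nunique() > 1
    for var in variables:
        values = plot_table[var]
        if values.notna().sum() == 0:  # e.g. no resorption pathway for Si
            continue
        summary = ctx.zone_summaries(values, zones, variable=var)
        if summary.empty:
            continue
        if multiple_zones:
            summary["letters"] = ""
            groups, labels = [], []
            for zone, grp in plot_table.groupby("zone", sort=True):
                arr = grp[var].dropna().to_numpy()
                if arr.size:
                    groups.append(arr)
                    labels.append(zone)
            if len(groups) >= 2:
                kw = st.kruskal_wallis(groups)
                pairs = st.dunn_posthoc(groups, adjustment=adjustment, labels=labels)
                letters = st.compact_letters(labels, pairs)
                tests.append({"variable": var, "chi_square": kw.chi_square,
                              "df": kw.df, "p_value": kw.p_value,
                              "letters": ";".join(
                                  f"{z}={letters[z]}" for z in labels)})
                summary["letters"] = summary["zone"].map(letters).fillna("")
        summaries.append(summary)
    summaries_df = (pd.concat(summaries, ignore_index=True) if summaries
                    else pd.DataFrame(columns=["zone", "variable", "mean", "se", "n"]))
    tests_df = pd.DataFrame(tests, columns=[
        "variable", "chi_square", "df", "p_value", "letters"])
    return summaries_df, tests_df


def compare_references(ds: Dataset, flux: FluxTable) -> pd.DataFrame:
    plot_zones = dict(zip(ds.plots["plot_id"], ds.plots["zone"]))
    return ctx.comparison_table(
        flux.table[["plot_id", "element", "h_i"]], ds.references, plot_zones)


def model_table(results: Mapping[tuple[str, str], st.MixedModelResult]) -> pd.DataFrame:
    rows = []
    for (response, model), res in results.items():
        for coef in res.coefficients.itertuples():
            rows.append({
                "response": response, "model": model,
                "predictor": coef.predictor, "estimate": coef.estimate,
                "ci_low": coef.ci_low, "ci_high": coef.ci_high,
                "significant": coef.significant,
                "r2m": res.r2_marginal, "r2c": res.r2_conditional,
                "n_obs": res.n_obs, "n_groups": res.n_groups,
            })
    return pd.DataFrame(rows, columns=[
        "response", "model", "predictor", "estimate", "ci_low", "ci_high",
        "significant", "r2m", "r2c", "n_obs", "n_groups"])


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the whole pipeline; optionally write the CSV result bundle."""
    log.info("defaults in effect: damage bounds=%s adjustment=%s "
             "bootstrap_n=%d ci=%.2f seed=%d",
             config.damage_class_bounds, config.adjustment,
             config.bootstrap_n, config.ci_level, config.seed)
    if config.data_dir:
        ds = read_dataset(config.data_dir)
    else:
        ds, _ = generate_network(config.synthetic or SyntheticConfig(),
                                 seed=config.seed)
    report = validate_dataset(ds)
    for finding in report.findings:
        log.log(logging.WARNING if finding.severity == "warning" else logging.ERROR,
                "%s/%s: %s", finding.table, finding.record, finding.message)
    if not report.ok:
        raise ValueError("dataset failed validation:\n" + report.summary())

    scheme = DamageClassScheme(tuple(config.damage_class_bounds))
    flux = compute_fluxes(ds, elements=config.elements, scheme=scheme,
                          complete_season=config.complete_season)
    for err in flux.errors:
        log.error("flux row skipped: %s", err)

    plot_table = assemble_plot_table(ds, flux)
    summaries, tests = summarize(plot_table, adjustment=config.adjustment)
    comparisons = compare_references(ds, flux)

    models = pd.DataFrame()
    if config.run_models:
        responses = config.model_responses
        if responses is None:
            responses = ["fp", "h"] + [
                c for c in plot_table.columns if c.startswith(("h_c_", "h_i_"))]
        responses = [r for r in responses if r in plot_table.columns
                     and plot_table[r].notna().sum() >= 3]
        results = st.driver_analysis(
            plot_table, responses, soil_by_response=SOIL_BY_RESPONSE,
            bootstrap_n=config.bootstrap_n, ci_level=config.ci_level,
            seed=config.seed, on_error="skip")
        models = model_table(results)

    result = RunResult(dataset=ds, fluxes=flux, summaries=summaries,
                       tests=tests, comparisons=comparisons, models=models,
                       plot_table=plot_table)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_flux_table(result.fluxes, out / "fluxes.csv")
    paths["fluxes"] = out / "fluxes.csv"
    for name, frame in (("summaries", result.summaries),
                        ("tests", result.tests),
                        ("comparisons", result.comparisons),
                        ("models", result.models)):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def report_tables(result: RunResult) -> dict[str, pd.DataFrame]:
    """Human-readable zone tables: means +/- SE with letters, and comparisons.

    The letters column is omitted for single-zone datasets; empty element
    subsets yield empty but well-formed tables.
    """
    summ = result.summaries.copy()
    if not summ.empty:
        summ["mean_se"] = summ.apply(
            lambda r: f"{r['mean']:.3g} ± {r['se']:.2g}"
            if np.isfinite(r["se"]) else f"{r['mean']:.3g}", axis=1)
        if "letters" in summ.columns and summ["letters"].fillna("").ne("").any():
            zone_table = summ.pivot_table(
                index="variable", columns="zone", values="mean_se",
                aggfunc="first")
        else:
            zone_table = summ.pivot_table(
                index="variable", columns="zone", values="mean_se", aggfunc="first")
    else:
        zone_table = pd.DataFrame()
    comp = result.comparisons.copy()
    return {"zone_means": zone_table, "reference_comparison": comp}
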