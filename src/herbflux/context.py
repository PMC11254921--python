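"""Zone summaries and comparison of insect fluxes with labile references.

Net insect-mediated fluxes are put in context against the other major
labile nutrient inputs — atmospheric N and P deposition and bedrock
weathered P — as percentage ratios of zone means, and as the fraction of
plots whose flux exceeds the regional reference mean.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def zone_summaries(
    values: Sequence[float],
    zones: Sequence[str],
    variable: str = "value",
) -> pd.DataFrame:
    """Per-zone mean, SE (sd/sqrt(n)) and n, plus a global all-plot row.

    SE is NaN for a single-plot zone; empty zones are omitted with a warning.
    """
    frame = pd.DataFrame({"zone": list(zones), "value": list(values)}).dropna()
    if frame.empty:
        warnings.warn("no values to summarize", stacklevel=2)
        return pd.DataFrame(columns=["zone", "variable", "mean", "se", "n"])
    rows = []
    for zone, grp in frame.groupby("zone", sort=True):
        arr = grp["value"].to_numpy(dtype=float)
        se = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else float("nan")
        rows.append({"zone": zone, "variable": variable,
                     "mean": float(arr.mean()), "se": float(se), "n": int(arr.size)})
    allv = frame["value"].to_numpy(dtype=float)
    rows.append({
        "zone": "global", "variable": variable, "mean": float(allv.mean()),
        "se": float(allv.std(ddof=1) / np.sqrt(allv.size)) if allv.size > 1 else float("nan"),
        "n": int(allv.size),
    })
    return pd.DataFrame(rows)


def weighted_global_mean(
    zone_means: Sequence[float], zone_ns: Sequence[int]
) -> float:
    """Plot-count-weighted mean of zone means: sum(m_z * n_z) / sum(n_z)."""
    means = np.asarray(zone_means, dtype=float)
    ns = np.asarray(zone_ns, dtype=float)
    if means.shape != ns.shape:
        raise ValueError("zone means and ns differ in length")
    if (ns <= 0).any():
        raise ValueError("zone ns must be > 0")
    return float((means * ns).sum() / ns.sum())


def reference_comparison(flux: float, reference: float) -> float:
    """Flux as a percentage of a reference input: 100 * flux / reference.

    Returns NaN for a zero reference (undefined ratio).
    """
    if reference < 0:
        raise ValueError("reference must be >= 0")
    if reference == 0:
        return float("nan")
    return 100.0 * flux / reference


def percent_greater(value: float, baseline: float) -> float:
    """How much larger ``value`` is than ``baseline``, in percent."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (value - baseline) / baseline


def exceedance_fraction(
    plot_values: Sequence[float], reference: float
) -> float:
    """Percent of plots whose flux strictly exceeds the reference mean."""
    arr = np.asarray(list(plot_values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no plot values")
    return float(100.0 * (arr > reference).sum() / arr.size)


def comparison_table(
    flux_by_plot: pd.DataFrame,
    references: pd.DataFrame,
    plot_zones: Mapping[str, str],
) -> pd.DataFrame:
    """Zone-level comparison of net fluxes with reference inputs.

    ``flux_by_plot`` needs columns plot_id, element, h_i; ``references``
    is the zone-scoped reference table (scope, atm_n, atm_p, bedrock_p).
    Percentages are ratios of zone means (the per-plot ratio alternative is
    the exceedance column, which uses strict inequality plot by plot).
    """
    refs = references.set_index("scope")
    work = flux_by_plot.copy()
    work["zone"] = work["plot_id"].map(plot_zones)
    pairs = [("N", "atm_n"), ("P", "atm_p"), ("P", "bedrock_p")]
    rows = []
    for zone, zgrp in work.groupby("zone", sort=True):
        if zone not in refs.index:
            warnings.warn(f"no reference inputs for zone {zone!r}", stacklevel=2)
            continue
        for element, ref_col in pairs:
            sub = zgrp[zgrp["element"] == element]
            if sub.empty:
                continue
            flux_mean = float(sub["h_i"].mean())
            ref = float(refs.loc[zone, ref_col])
            rows.append({
                "zone": zone, "element": element, "reference": ref_col,
                "flux_mean": flux_mean, "reference_mean": ref,
                "percent": reference_comparison(flux_mean, ref),
                "exceedance_pct": exceedance_fraction(sub["h_i"], ref),
                "n": int(sub.shape[0]),
            })
    return pd.DataFrame(rows)
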