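"""Mass-balance accounting of insect-mediated element fluxes.

Core identities, per plot and element E (units g m^-2 y^-1 unless noted):

* L_H  — annual leaf litterfall per ground area (trap mass / trap area).
* FP   — foliar biomass production, reconstructed as L_H / (1 - H) where H
  is the herbivory rate (proportion of leaf area removed).
* H_c  — gross element flux through folivores: FP * F_E * H, with F_E the
  green-leaf mass fraction of E.  Under steady state this equals the mass
  of E returned to the floor as frass, bodies, moults and fragments.
* RE_E — resorption efficiency, 1 - (c_litter / F_E) * MLCF, where MLCF is
  the leaf mass loss correction factor for senescence (0.78 evergreen,
  0.784 deciduous angiosperm forests).  Defined for C, N, P only.
* H_i  — net element flux: the extra input caused by herbivores
  intercepting foliage before resorption.  Computed as H_c * RE_E, which
  is algebraically identical to the three-term budget
  L_EH + H_c - L_E once the counterfactual (no-herbivore) litter flux is
  L_E = L_EH + FP * H * MLCF * c_litter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ALL_ELEMENTS,
    RESORBING_ELEMENTS,
    Dataset,
    UnsupportedElementError,
)
from .herbivory import (
    DEFAULT_SCHEME,
    DamageClassScheme,
    HerbivoryEstimate,
    annualize_herbivory,
    pool_herbivory,
)

#: senesced:green leaf dry-mass ratios for angiosperm forests
MLCF_BY_PHENOLOGY = {"evergreen": 0.78, "deciduous": 0.784}

#: minimum days spanned for a trap-year series to count as annual coverage
DEFAULT_COVERAGE_DAYS = 300


class CoverageError(ValueError):
    """A trap-year series does not span enough of the year to annualize."""


def trap_annual_litterfall(
    collections,
    coverage_days: int = DEFAULT_COVERAGE_DAYS,
    complete_season: bool = False,
) -> float:
    """Annual leaf litterfall (g m^-2 y^-1) for one trap-year.

    ``collections`` is a DataFrame (or records) of one trap's emptyings with
    ``date_start``, ``date_end``, ``leaf_dry_mass_g`` and ``trap_area_m2``.
    No extrapolation is performed: unless ``complete_season`` asserts that
    the series already covers the whole deposition season (e.g. a deciduous
    stand sampled over the entire leaf-fall period), the spanned interval
    must reach ``coverage_days``.
    """
    frame = pd.DataFrame(collections)
    if frame.empty:
        raise ValueError("no collections")
    if frame["trap_id"].nunique() > 1:
        raise ValueError("collections span multiple traps")
    area = frame["trap_area_m2"].iloc[0]
    if frame["trap_area_m2"].nunique() > 1:
        raise ValueError("inconsistent trap area within a trap-year")

    frame = frame.sort_values("date_start")
    starts = pd.to_datetime(frame["date_start"])
    ends = pd.to_datetime(frame["date_end"])
    if (starts.values[1:] < ends.values[:-1]).any():
        raise ValueError("overlapping collection intervals")
    spanned = (ends.iloc[-1] - starts.iloc[0]).days
    if spanned < coverage_days and not complete_season:
        raise CoverageError(
            f"series spans {spanned} d < {coverage_days} d and is not "
            "flagged as a complete season")
    return float(frame["leaf_dry_mass_g"].sum() / area)


def plot_litterfall(
    trap_values_by_year: Mapping[object, Sequence[float]],
) -> tuple[float, float]:
    """Plot L_H: mean over traps within year, unweighted mean across years.

    Returns ``(l_h, se)`` where the standard error is across traps
    (sd/sqrt(n), averaged over years); NaN with a single trap.
    """
    if not trap_values_by_year:
        raise ValueError("no trap-year values")
    year_means, year_ses = [], []
    for year, values in trap_values_by_year.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"year {year}: no trap values")
        year_means.append(arr.mean())
        year_ses.append(arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else np.nan)
    return float(np.mean(year_means)), float(np.nanmean(year_ses)) if not all(
        np.isnan(year_ses)) else float("nan")


def foliar_production(l_h: float, h: float) -> float:
    """FP = L_H / (1 - H); warns for H beyond the observed global range."""
    if not 0 <= h < 1:
        raise ValueError(f"herbivory rate {h} outside [0, 1)")
    if h > 0.5:
        warnings.warn(f"herbivory rate {h:.3f} > 0.5; outside observed range",
                      stacklevel=2)
    return l_h / (1.0 - h)


def gross_flux(fp: float, f_e: float, h: float) -> float:
    """Gross insect-mediated element flux H_c = FP * F_E * H."""
    if fp < 0:
        raise ValueError("FP must be >= 0")
    if not 0 < f_e < 1:
        raise ValueError("green-leaf concentration must be a fraction in (0, 1)")
    if not 0 <= h < 1:
        raise ValueError("herbivory rate outside [0, 1)")
    return fp * f_e * h


def mass_loss_correction(phenology: str) -> float:
    """MLCF for a predominantly evergreen or deciduous angiosperm forest."""
    try:
        return MLCF_BY_PHENOLOGY[str(phenology)]
    except KeyError:
        raise ValueError(f"unknown phenology {phenology!r}; "
                         "expected 'evergreen' or 'deciduous'") from None


def resorption_efficiency(
    f_green: float,
    c_litter: float,
    mlcf: float,
    element: str | None = None,
) -> float:
    """RE = 1 - (c_litter / f_green) * MLCF.

    Values outside [0, 1] (possible with noisy chemistry) are returned
    unclamped with a warning so downstream nets are not silently biased.
    """
    if element is not None and element not in RESORBING_ELEMENTS:
        raise UnsupportedElementError(
            f"resorption efficiency is defined for {RESORBING_ELEMENTS}, not {element}")
    if f_green <= 0 or c_litter <= 0:
        raise ValueError("concentrations must be > 0")
    re = 1.0 - (c_litter / f_green) * mlcf
    if not 0 <= re <= 1:
        warnings.warn(f"resorption efficiency {re:.3f} outside [0, 1]",
                      stacklevel=2)
    return re


def net_flux(h_c: float, re: float, element: str | None = None) -> float:
    """Net insect-mediated flux H_i = H_c * RE_E (C, N, P only)."""
    if element is not None and element not in RESORBING_ELEMENTS:
        raise UnsupportedElementError(
            f"net flux is defined for {RESORBING_ELEMENTS}, not {element}")
    return h_c * re


def litter_element_flux(l_h: float, c_litter: float) -> float:
    """Observed litter element flux L_EH = L_H * c_litter."""
    if l_h < 0 or c_litter < 0:
        raise ValueError("inputs must be >= 0")
    return l_h * c_litter


def counterfactual_litter_flux(
    l_eh: float, fp: float, h: float, c_litter: float, mlcf: float
) -> float:
    """Litter element flux had the consumed foliage senesced normally.

    The consumed green mass FP*H, had it stayed on the tree, would have lost
    mass by the factor MLCF during senescence and fallen at the litter
    concentration: L_E = L_EH + FP * H * MLCF * c_litter.  This definition
    makes L_EH + H_c - L_E == H_c * RE hold to machine precision.
    """
    if min(l_eh, fp, h, c_litter, mlcf) < 0:
        raise ValueError("inputs must be >= 0")
    return l_eh + fp * h * mlcf * c_litter


def hc_to_litter_ratio(h_c: float, l_eh: float) -> float:
    """Dimensionless H_c : litter-flux ratio; NaN when the litter flux is 0."""
    if l_eh == 0:
        return float("nan")
    return h_c / l_eh


# ---------------------------------------------------------------------------
# Whole-bundle orchestration
# ---------------------------------------------------------------------------

FLUX_COLUMNS = [
    "plot_id", "element", "l_h", "l_h_se", "h", "incidence", "n_leaves",
    "fp", "h_c", "re", "h_i", "l_eh", "l_e", "mlcf",
]


@dataclass
class FluxTable:
    """Per plot x element flux results plus row-level error messages."""

    table: pd.DataFrame
    errors: list[str] = field(default_factory=list)


def plot_herbivory_estimates(
    ds: Dataset, scheme: DamageClassScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Per-plot herbivory: pooled within calendar year, averaged across years."""
    rows = []
    for plot_id, grp in ds.damage.groupby("plot_id", sort=True):
        years = []
        for _, ygrp in grp.groupby(grp["scan_date"].map(lambda d: d.year)):
            tallies = [
                (r.n_undamaged, [getattr(r, f"n_c{i}") for i in range(1, 7)])
                for r in ygrp.itertuples()
            ]
            years.append(pool_herbivory(tallies, scheme, plot_id=str(plot_id)))
        est = annualize_herbivory(years)
        rows.append({"plot_id": plot_id, "h": est.h,
                     "incidence": est.incidence, "n_leaves": est.n_leaves})
    return pd.DataFrame(rows)


def plot_litterfall_estimates(
    ds: Dataset,
    coverage_days: int = DEFAULT_COVERAGE_DAYS,
    complete_season: bool = False,
) -> pd.DataFrame:
    """Per-plot annual litterfall L_H (trap means by year, then year means)."""
    rows = []
    traps = ds.traps.copy()
    traps["year"] = traps["date_start"].map(lambda d: d.year)
    for plot_id, grp in traps.groupby("plot_id", sort=True):
        by_year: dict[int, list[float]] = {}
        for (trap_id, year), tgrp in grp.groupby(["trap_id", "year"]):
            value = trap_annual_litterfall(
                tgrp, coverage_days=coverage_days, complete_season=complete_season)
            by_year.setdefault(year, []).append(value)
        l_h, se = plot_litterfall(by_year)
        rows.append({"plot_id": plot_id, "l_h": l_h, "l_h_se": se})
    return pd.DataFrame(rows)


def _plot_chemistry(ds: Dataset) -> pd.DataFrame:
    """Season-averaged green and litter concentrations per plot x element."""
    chem = ds.chemistry.groupby(
        ["plot_id", "element", "tissue"], sort=True, as_index=False
    )["concentration"].mean()
    wide = chem.pivot_table(
        index=["plot_id", "element"], columns="tissue",
        values="concentration").reset_index()
    return wide.rename(columns={"green": "f_green", "litter": "c_litter"})


def compute_fluxes(
    ds: Dataset,
    elements: Sequence[str] = ALL_ELEMENTS,
    scheme: DamageClassScheme = DEFAULT_SCHEME,
    coverage_days: int = DEFAULT_COVERAGE_DAYS,
    complete_season: bool = False,
) -> FluxTable:
    """Run the full accounting for every plot and requested element.

    Missing chemistry for a plot/element is recorded as a row-level error and
    the remaining rows are still produced.  Si rows carry the gross flux only
    (no resorption, hence no net flux).
    """
    bad = [e for e in elements if e not in ALL_ELEMENTS]
    if bad:
        raise UnsupportedElementError(f"unknown element(s) {bad}")

    herb = plot_herbivory_estimates(ds, scheme).set_index("plot_id")
    litter = plot_litterfall_estimates(
        ds, coverage_days=coverage_days, complete_season=complete_season
    ).set_index("plot_id")
    chem = _plot_chemistry(ds).set_index(["plot_id", "element"])
    phen = ds.plots.set_index("plot_id")["phenology"]

    rows, errors = [], []
    for plot_id in ds.plots["plot_id"]:
        if plot_id not in herb.index:
            errors.append(f"{plot_id}: no damage tallies")
            continue
        if plot_id not in litter.index:
            errors.append(f"{plot_id}: no trap collections")
            continue
        h = float(herb.loc[plot_id, "h"])
        l_h = float(litter.loc[plot_id, "l_h"])
        mlcf = mass_loss_correction(phen.loc[plot_id])
        fp = foliar_production(l_h, h)
        for element in elements:
            key = (plot_id, element)
            if key not in chem.index:
                errors.append(f"{plot_id}/{element}: missing chemistry")
                continue
            f_green = float(chem.loc[key, "f_green"])
            c_litter = float(chem.loc[key, "c_litter"])
            if np.isnan(f_green) or np.isnan(c_litter):
                errors.append(f"{plot_id}/{element}: incomplete chemistry")
                continue
            h_c = gross_flux(fp, f_green, h)
            l_eh = litter_element_flux(l_h, c_litter)
            l_e = counterfactual_litter_flux(l_eh, fp, h, c_litter, mlcf)
            if element in RESORBING_ELEMENTS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    re = resorption_efficiency(f_green, c_litter, mlcf, element)
                h_i = net_flux(h_c, re, element)
            else:
                re, h_i = float("nan"), float("nan")
            rows.append({
                "plot_id": plot_id, "element": element,
                "l_h": l_h, "l_h_se": float(litter.loc[plot_id, "l_h_se"]),
                "h": h, "incidence": float(herb.loc[plot_id, "incidence"]),
                "n_leaves": int(herb.loc[plot_id, "n_leaves"]),
                "fp": fp, "h_c": h_c, "re": re, "h_i": h_i,
                "l_eh": l_eh, "l_e": l_e, "mlcf": mlcf,
            })
    table = pd.DataFrame(rows, columns=FLUX_COLUMNS)
    return FluxTable(table=table, errors=errors)


def write_flux_table(flux: FluxTable, path) -> None:
    """Write fluxes.csv with percent fields as percent and a unit header."""
    out = flux.table.copy()
    for col in ("h", "incidence", "re"):
        out[col + "_pct"] = out[col] * 100.0
        del out[col]
    with open(path, "w") as fh:
        fh.write("# units: l_h, fp, h_c, h_i, l_eh, l_e in g m-2 y-1; "
                 "h_pct, incidence_pct, re_pct in percent; mlcf dimensionless\n")
        out.to_csv(fh, index=False)
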