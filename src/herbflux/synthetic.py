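"""Synthetic plot-network generator with exposed ground truth.

Emulates a global network of broadleaved-forest plots with the statistical
structure the analysis assumes: mean annual temperature drives herbivory
(logit scale) and foliar production (log scale, together with soil C:N),
green-leaf chemistry and resorption differ by latitude zone, and
observation noise enters at the litter-trap and leaf-scan level.

Litter chemistry is constructed exactly as ``c_litter = F_E (1 - RE) / MLCF``
so the resorption-efficiency estimator recovers the true RE identically.
Damage-class probabilities come from a beta distribution whose mean is
calibrated (1-D root solve) so that the class-midpoint estimator of
herbivory is exactly unbiased for the configured true rate; without that
calibration the midpoint estimator would carry a discretization bias and
never converge to the generator's truth.

Not simulated: outbreak dynamics, multi-species leaf pools, within-year
temporal autocorrelation, spatially explicit layouts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import optimize, stats as sps

from . import published
from .data_model import Dataset
from .fluxes import MLCF_BY_PHENOLOGY
from .herbivory import DEFAULT_BOUNDS, class_midpoints, DamageClassScheme


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _default_chem_means() -> dict:
    # green-leaf concentration means (% dry mass) per element x zone;
    # N and P run lower in the tropics, consistent with the reference network
    return {
        "C": {"tropical": 48.0, "temperate": 47.5, "boreal": 47.0},
        "N": {"tropical": 1.8, "temperate": 2.0, "boreal": 2.4},
        "P": {"tropical": 0.10, "temperate": 0.14, "boreal": 0.18},
        "Si": {"tropical": 0.55, "temperate": 1.6, "boreal": 0.85},
    }


def _default_chem_sds() -> dict:
    return {"C": 1.5, "N": 0.25, "P": 0.02, "Si": 0.2}


def _default_re_means() -> dict:
    # resorption efficiency means (%); temperate N is interpolated between
    # the tropical and boreal reference values
    return {
        "C": {"tropical": 19.7, "temperate": 19.7, "boreal": 19.7},
        "N": {"tropical": 46.5, "temperate": 54.0, "boreal": 61.8},
        "P": {"tropical": 66.5, "temperate": 57.9, "boreal": 55.2},
    }


class SyntheticConfig(BaseModel):
    """Generator configuration; defaults mirror the reference study design."""

    n_sites: int = 40
    plots_per_site: tuple[int, int] = (1, 3)
    traps_per_plot: tuple[int, int] = published.TRAPS_PER_PLOT
    trap_area_m2: tuple[float, float] = published.TRAP_AREA_M2
    leaves_scored_per_scan: int = 400
    scans_per_year: int = 4
    years: int = 1
    mat_range: tuple[float, float] = published.MAT_RANGE_C
    dryness_range: tuple[float, float] = published.DRYNESS_RANGE

    # herbivory model, logit scale: logit H = a + b z(MAT) + site + plot noise
    herbivory_intercept: float = _logit(0.04)
    herbivory_mat_slope: float = 0.4
    herbivory_site_sd: float = 0.3
    herbivory_plot_sd: float = 0.1

    # production model, log scale: log FP = c + d z(MAT) - e z(soil C:N) + noise
    fp_log_intercept: float = float(np.log(320.0))
    fp_mat_slope: float = 0.5
    fp_soilcn_slope: float = 0.15
    fp_log_sd: float = 0.25

    #: incidence = min(incidence_factor * H, 0.95)
    incidence_factor: float = 12.0
    #: beta concentration for per-leaf damage severity among damaged leaves
    damage_kappa: float = 2.0

    trap_lognormal_sd: float = 0.2
    chemistry_means: dict = Field(default_factory=_default_chem_means)
    chemistry_sds: dict = Field(default_factory=_default_chem_sds)
    re_means: dict = Field(default_factory=_default_re_means)
    re_sd: float = 5.0
    seed: int = 20240717

    @model_validator(mode="after")
    def _ranges(self) -> "SyntheticConfig":
        for name in ("plots_per_site", "traps_per_plot", "trap_area_m2",
                     "mat_range", "dryness_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name}: upper bound below lower bound")
        if self.years not in (1, 2):
            raise ValueError("years must be 1 or 2")
        if self.leaves_scored_per_scan < 1 or self.scans_per_year < 1:
            raise ValueError("leaf and scan counts must be >= 1")
        return self


@dataclass
class GroundTruth:
    """True parameter vector and per-plot latent values of a synthetic bundle."""

    config: SyntheticConfig
    sites: pd.DataFrame   # site_id, mat_c, zone, dryness
    plots: pd.DataFrame   # plot_id, site_id, zone, h_true, incidence_true,
                          # fp_true, l_h_true, f_green_*, re_* per element
    slopes: dict


@lru_cache(maxsize=256)
def _calibrated_class_probs(
    target_mean: float, kappa: float, bounds: tuple[float, ...]
) -> tuple[float, ...]:
    """Damage-class probabilities whose midpoint mean equals ``target_mean``.

    Solves for the beta mean m such that the discretized midpoint expectation
    of Beta(m*kappa, (1-m)*kappa) over the class bins matches the target; the
    discretized mean is strictly increasing in m.
    """
    mids = np.asarray(class_midpoints(DamageClassScheme(bounds)))
    barr = np.asarray(bounds)

    def disc_mean(m: float) -> float:
        cdf = sps.beta.cdf(barr, m * kappa, (1 - m) * kappa)
        p = np.diff(cdf)
        return float(p @ mids / p.sum())

    lo, hi = 1e-6, 1 - 1e-6
    if not disc_mean(lo) < target_mean < disc_mean(hi):
        raise ValueError(f"target class mean {target_mean} out of reachable range")
    m = optimize.brentq(lambda x: disc_mean(x) - target_mean, lo, hi, xtol=1e-12)
    cdf = sps.beta.cdf(barr, m * kappa, (1 - m) * kappa)
    p = np.diff(cdf)
    return tuple(p / p.sum())


#: relative monthly litterfall profiles (sum to 1)
_SEASONAL_WEIGHTS = {
    "deciduous": np.array(
        [0.01, 0.01, 0.01, 0.02, 0.03, 0.05, 0.06, 0.08, 0.13, 0.30, 0.22, 0.08]),
    "evergreen": np.full(12, 1.0 / 12.0),
}

_LAT_RANGE = {"tropical": (0.0, 23.0), "temperate": (28.0, 50.0),
              "boreal": (52.0, 68.0)}


def _month_intervals(year: int) -> list[tuple[dt.date, dt.date]]:
    """Twelve consecutive collection intervals covering a calendar year."""
    starts = [dt.date(year, m, 1) for m in range(1, 13)]
    ends = starts[1:] + [dt.date(year + 1, 1, 1)]
    return list(zip(starts, ends))


def generate_network(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[Dataset, GroundTruth]:
    """Simulate a complete plot-network dataset bundle with ground truth.

    All randomness flows from one seed through spawned sub-streams per table,
    so identical config+seed yields byte-identical bundles.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    r_site, r_soil, r_chem, r_trap, r_scan = (
        np.random.default_rng(s) for s in root.spawn(5))

    # --- sites: climate and zone (MAT terciles -> boreal/temperate/tropical)
    ns = config.n_sites
    mat = r_site.uniform(*config.mat_range, size=ns)
    dryness = r_site.uniform(*config.dryness_range, size=ns)
    order = np.argsort(mat)
    zone = np.empty(ns, dtype=object)
    thirds = np.array_split(order, 3)
    for labels, idx in zip(("boreal", "temperate", "tropical"), thirds):
        zone[idx] = labels
    site_ids = [f"S{i + 1:02d}" for i in range(ns)]
    z_mat = (mat - mat.mean()) / mat.std(ddof=1)
    site_eff = r_site.normal(0.0, config.herbivory_site_sd, size=ns)

    sites = pd.DataFrame({
        "site_id": site_ids, "mat_c": mat, "zone": zone, "dryness": dryness,
        "z_mat": z_mat,
    })

    # --- plots
    lo, hi = config.plots_per_site
    n_plots_per_site = r_site.integers(lo, hi + 1, size=ns)
    plot_rows = []
    for i in range(ns):
        lat_lo, lat_hi = _LAT_RANGE[zone[i]]
        lat = float(r_site.uniform(lat_lo, lat_hi)) * (1 if r_site.random() < 0.7 else -1)
        if zone[i] == "tropical":
            phen = "evergreen" if r_site.random() < 0.8 else "deciduous"
        elif zone[i] == "temperate":
            phen = "deciduous" if r_site.random() < 0.8 else "evergreen"
        else:
            phen = "deciduous"  # boreal broadleaves are deciduous
        for j in range(n_plots_per_site[i]):
            plot_rows.append({
                "plot_id": f"{site_ids[i]}P{j + 1}", "site_id": site_ids[i],
                "site_index": i, "zone": zone[i], "phenology": phen,
                "latitude": lat + float(r_site.normal(0, 0.1)),
            })
    plots = pd.DataFrame(plot_rows)
    n_p = len(plots)
    si = plots["site_index"].to_numpy()

    # --- soil panels (fractions); C:N similar across zones, C:P higher in tropics
    s_c = np.clip(r_soil.lognormal(np.log(0.05), 0.8, n_p), 0.008, 0.272)
    cn = np.clip(r_soil.normal(15.0, 3.0, n_p), 8.0, 30.0)
    cp_mean = np.select(
        [plots["zone"] == "tropical", plots["zone"] == "temperate"],
        [900.0, 500.0], default=400.0)
    cp = np.clip(r_soil.normal(cp_mean, 0.25 * cp_mean), 60.0, 3000.0)
    s_si = np.clip(r_soil.lognormal(np.log(0.02), 1.0, n_p), 0.001, 0.247)
    soil = pd.DataFrame({
        "plot_id": plots["plot_id"], "s_c": s_c, "s_n": s_c / cn,
        "s_p": s_c / cp, "s_si": s_si,
    })
    z_cn = (cn - cn.mean()) / cn.std(ddof=1)

    # --- latent plot truths
    logit_h = (config.herbivory_intercept
               + config.herbivory_mat_slope * z_mat[si]
               + site_eff[si]
               + r_site.normal(0.0, config.herbivory_plot_sd, n_p))
    h_true = 1.0 / (1.0 + np.exp(-logit_h))
    if ((h_true <= 0) | (h_true >= 0.5)).any():
        raise ValueError("config produced true herbivory outside (0, 0.5)")
    incidence_true = np.minimum(config.incidence_factor * h_true, 0.95)

    fp_true = np.exp(config.fp_log_intercept
                     + config.fp_mat_slope * z_mat[si]
                     - config.fp_soilcn_slope * z_cn
                     + r_site.normal(0.0, config.fp_log_sd, n_p))
    l_h_true = fp_true * (1.0 - h_true)
    mlcf = plots["phenology"].map(MLCF_BY_PHENOLOGY).to_numpy()

    # --- chemistry: green leaves by zone; litter derived exactly from RE truth
    chem_rows = []
    truth_chem: dict[str, np.ndarray] = {}
    for element in ("C", "N", "P", "Si"):
        mean_pct = plots["zone"].map(config.chemistry_means[element]).to_numpy()
        sd_pct = config.chemistry_sds[element]
        f_green = np.maximum(
            r_chem.normal(mean_pct, sd_pct, n_p), 0.2 * mean_pct) / 100.0
        if element in config.re_means:
            re_pct = plots["zone"].map(config.re_means[element]).to_numpy()
            re_true = np.clip(
                r_chem.normal(re_pct, config.re_sd, n_p), 2.0, 95.0) / 100.0
            c_litter = f_green * (1.0 - re_true) / mlcf
        else:
            re_true = np.full(n_p, np.nan)
            c_litter = f_green / mlcf  # no resorption pathway for Si
        truth_chem[f"f_green_{element}"] = f_green
        truth_chem[f"re_{element}"] = re_true
        for k, plot_id in enumerate(plots["plot_id"]):
            chem_rows.append({"plot_id": plot_id, "element": element,
                              "tissue": "green", "concentration": f_green[k],
                              "season": "growing"})
            chem_rows.append({"plot_id": plot_id, "element": element,
                              "tissue": "litter", "concentration": c_litter[k],
                              "season": "annual"})
    chemistry = pd.DataFrame(chem_rows)

    # --- traps: per-trap annual mass lognormal around L_H * area, split into
    #     monthly intervals by the phenology's seasonal profile
    years = [2019, 2020][: config.years]
    tlo, thi = config.traps_per_plot
    n_traps = r_trap.integers(tlo, thi + 1, size=n_p)
    area = np.round(r_trap.uniform(*config.trap_area_m2, size=n_p), 3)
    sd = config.trap_lognormal_sd
    trap_rows = []
    for k in range(n_p):
        weights = _SEASONAL_WEIGHTS[plots["phenology"].iloc[k]]
        for t in range(n_traps[k]):
            trap_id = f"{plots['plot_id'].iloc[k]}T{t + 1:02d}"
            for year in years:
                annual = (l_h_true[k] * area[k]
                          * np.exp(r_trap.normal(-0.5 * sd ** 2, sd)))
                for (d0, d1), w in zip(_month_intervals(year), weights):
                    trap_rows.append({
                        "trap_id": trap_id, "plot_id": plots["plot_id"].iloc[k],
                        "date_start": d0, "date_end": d1,
                        "leaf_dry_mass_g": annual * w, "trap_area_m2": area[k],
                    })
    traps = pd.DataFrame(trap_rows)

    # --- damage tallies: multinomial over undamaged + 6 classes, with class
    #     probabilities calibrated so the midpoint estimator is unbiased
    scan_months = np.linspace(2, 12, config.scans_per_year).astype(int)
    damage_rows = []
    for k in range(n_p):
        inc = incidence_true[k]
        target = h_true[k] / inc  # conditional mean severity among damaged
        probs = np.array(_calibrated_class_probs(
            round(float(target), 10), config.damage_kappa, DEFAULT_BOUNDS))
        full = np.concatenate([[1.0 - inc], inc * probs])
        for year in years:
            for month in scan_months:
                counts = r_scan.multinomial(config.leaves_scored_per_scan, full)
                damage_rows.append({
                    "plot_id": plots["plot_id"].iloc[k],
                    "scan_date": dt.date(year, int(month), 15),
                    "n_undamaged": int(counts[0]),
                    **{f"n_c{i}": int(counts[i]) for i in range(1, 7)},
                })
    damage = pd.DataFrame(damage_rows)

    # --- plot metadata and references
    plots_out = pd.DataFrame({
        "plot_id": plots["plot_id"], "site_id": plots["site_id"],
        "latitude": plots["latitude"].round(4),
        "zone": plots["zone"],
        "mat_c": mat[si], "pet_mm": dryness[si] * 1200.0,
        "map_mm": np.full(n_p, 1200.0),
        "phenology": plots["phenology"],
        "n_traps": n_traps, "trap_area_m2": area,
    })
    plots_out["abs_latitude"] = plots_out["latitude"].abs()
    plots_out["dryness"] = plots_out["pet_mm"] / plots_out["map_mm"]
    references = published.reference_table()

    truth_plots = pd.DataFrame({
        "plot_id": plots["plot_id"], "site_id": plots["site_id"],
        "zone": plots["zone"], "h_true": h_true,
        "incidence_true": incidence_true, "fp_true": fp_true,
        "l_h_true": l_h_true, "mlcf": mlcf, **truth_chem,
    })
    truth = GroundTruth(
        config=config,
        sites=sites,
        plots=truth_plots,
        slopes={
            "herbivory_mat_slope": config.herbivory_mat_slope,
            "fp_mat_slope": config.fp_mat_slope,
            "fp_soilcn_slope": config.fp_soilcn_slope,
        },
    )
    ds = Dataset(plots=plots_out, soil=soil.assign(
        s_cn=soil["s_c"] / soil["s_n"], s_cp=soil["s_c"] / soil["s_p"]),
        traps=traps, damage=damage, chemistry=chemistry,
        references=references, truth=truth)
    return ds, truth


def ground_truth(ds: Dataset) -> GroundTruth:
    """Return the generator's truth record attached to a synthetic bundle."""
    if ds.truth is None or not isinstance(ds.truth, GroundTruth):
        raise ValueError("bundle was not produced by generate_network "
                         "(no ground truth attached)")
    return ds.truth
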