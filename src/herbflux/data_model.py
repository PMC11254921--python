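"""Tabular data model for cross-biome herbivory flux datasets.

A dataset is a bundle of six plain-CSV tables describing a network of forest
plots: plot metadata with climate, soil chemistry panels, litter-trap
collections, leaf damage-class tallies, green-leaf/litter element
concentrations, and zone- or plot-level reference nutrient inputs
(atmospheric deposition, bedrock weathering).

Unit conventions
----------------
* Concentrations are stored internally as mass fractions in [0, 1]; all CSV
  I/O uses percent columns (``*_pct``, ``concentration_pct``) to match how
  such tables are normally printed.  Conversion happens only at the I/O
  boundary, so normalization is idempotent.
* Fluxes are g m^-2 y^-1, trap areas m^2, dates ISO-8601.
* ``zone`` and ``phenology`` are required metadata and never inferred from
  latitude; ``abs_latitude`` and ``dryness`` (PET/MAP) are derived at load.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator


class Zone(str, Enum):
    tropical = "tropical"
    temperate = "temperate"
    boreal = "boreal"


class Phenology(str, Enum):
    evergreen = "evergreen"
    deciduous = "deciduous"


class Element(str, Enum):
    C = "C"
    N = "N"
    P = "P"
    Si = "Si"


#: elements for which resorption efficiency (and hence a net flux) is defined
RESORBING_ELEMENTS = ("C", "N", "P")
ALL_ELEMENTS = ("C", "N", "P", "Si")

DAMAGE_CLASS_COLUMNS = tuple(f"n_c{i}" for i in range(1, 7))

PLOTS_COLUMNS = [
    "plot_id", "site_id", "latitude", "zone", "mat_c", "pet_mm", "map_mm",
    "phenology", "n_traps", "trap_area_m2",
]
SOIL_COLUMNS = ["plot_id", "s_c_pct", "s_n_pct", "s_p_pct", "s_si_pct"]
TRAPS_COLUMNS = [
    "trap_id", "plot_id", "date_start", "date_end", "leaf_dry_mass_g",
    "trap_area_m2",
]
DAMAGE_COLUMNS = ["plot_id", "scan_date", "n_undamaged", *DAMAGE_CLASS_COLUMNS]
CHEMISTRY_COLUMNS = ["plot_id", "element", "tissue", "concentration_pct", "season"]
REFERENCES_COLUMNS = ["scope", "atm_n", "atm_p", "bedrock_p"]

TABLE_FILES = {
    "plots": "plots.csv",
    "soil": "soil.csv",
    "traps": "traps.csv",
    "damage": "damage.csv",
    "chemistry": "chemistry.csv",
    "references": "references.csv",
}

_TABLE_COLUMNS = {
    "plots": PLOTS_COLUMNS,
    "soil": SOIL_COLUMNS,
    "traps": TRAPS_COLUMNS,
    "damage": DAMAGE_COLUMNS,
    "chemistry": CHEMISTRY_COLUMNS,
    "references": REFERENCES_COLUMNS,
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class UnsupportedElementError(ValueError):
    """Requested an element outside the supported panel for this quantity."""


# ---------------------------------------------------------------------------
# Row-level record types
# ---------------------------------------------------------------------------

class PlotRecord(BaseModel):
    """One forest plot: identity, climate, zone and trap layout.

    ``dryness`` is PET/MAP and ``abs_latitude`` is |latitude|; both are
    derived, never supplied.
    """

    plot_id: str
    site_id: str
    latitude: float
    zone: Zone
    mat_c: float
    pet_mm: float
    map_mm: float
    phenology: Phenology
    n_traps: int
    trap_area_m2: float

    @field_validator("map_mm")
    @classmethod
    def _map_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("MAP must be > 0")
        return v

    @field_validator("n_traps")
    @classmethod
    def _traps_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_traps must be >= 1")
        return v

    @field_validator("trap_area_m2")
    @classmethod
    def _area_range(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("trap area must lie in (0, 1] m^2")
        return v

    @property
    def abs_latitude(self) -> float:
        return abs(self.latitude)

    @property
    def dryness(self) -> float:
        return self.pet_mm / self.map_mm


class SoilPanel(BaseModel):
    """Soil element concentrations (mass fractions) with derived C:N and C:P."""

    plot_id: str
    s_c: float
    s_n: float
    s_p: float
    s_si: float

    @field_validator("s_c", "s_n", "s_p", "s_si")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("soil concentrations are mass fractions in [0, 1]")
        return v

    @property
    def s_cn(self) -> float:
        return self.s_c / self.s_n

    @property
    def s_cp(self) -> float:
        return self.s_c / self.s_p


class TrapCollection(BaseModel):
    """One emptying of one litter trap: interval dates and leaf dry mass."""

    trap_id: str
    plot_id: str
    date_start: dt.date
    date_end: dt.date
    leaf_dry_mass_g: float
    trap_area_m2: float

    @model_validator(mode="after")
    def _dates_ordered(self) -> "TrapCollection":
        if self.date_end <= self.date_start:
            raise ValueError(f"trap {self.trap_id}: date_end must be after date_start")
        return self

    @field_validator("leaf_dry_mass_g")
    @classmethod
    def _mass_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("leaf dry mass must be >= 0")
        return v

    @property
    def interval_days(self) -> int:
        return (self.date_end - self.date_start).days


class DamageTally(BaseModel):
    """Counts of scored leaves per damage class for one litter scan.

    ``n_class`` holds the six leaf-area-removal classes
    (0-1, 1-5, 5-25, 25-50, 50-75, >75 %); undamaged leaves are counted
    separately because the first printed class is ambiguous about
    zero-damage leaves.
    """

    plot_id: str
    scan_date: dt.date
    n_undamaged: int
    n_class: tuple[int, int, int, int, int, int]

    @model_validator(mode="after")
    def _counts(self) -> "DamageTally":
        if self.n_undamaged < 0 or any(c < 0 for c in self.n_class):
            raise ValueError("damage counts must be >= 0")
        return self

    @property
    def n_total(self) -> int:
        return self.n_undamaged + sum(self.n_class)


class ElementPanelRow(BaseModel):
    """One tissue concentration: green leaf (F_E) or senesced litter."""

    plot_id: str
    element: Element
    tissue: str  # "green" | "litter"
    concentration: float  # mass fraction
    season: str = "annual"

    @field_validator("tissue")
    @classmethod
    def _tissue(cls, v: str) -> str:
        if v not in ("green", "litter"):
            raise ValueError(f"unknown tissue label {v!r}")
        return v

    @field_validator("concentration")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("concentrations are mass fractions in (0, 1)")
        return v


class ReferenceInputs(BaseModel):
    """Labile nutrient reference fluxes (g m^-2 y^-1) for a plot or zone."""

    scope: str
    atm_n: float
    atm_p: float
    bedrock_p: float

    @field_validator("atm_n", "atm_p", "bedrock_p")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("reference fluxes must be >= 0")
        return v


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """In-memory bundle of the six tables, in internal (fraction) units.

    ``truth`` is populated only for synthetic bundles and carries the
    generator's ground-truth record.
    """

    plots: pd.DataFrame
    soil: pd.DataFrame
    traps: pd.DataFrame
    damage: pd.DataFrame
    chemistry: pd.DataFrame
    references: pd.DataFrame
    truth: object | None = None

    def write(self, directory: str | Path) -> dict[str, Path]:
        return write_dataset(self, directory)

    @classmethod
    def read(cls, directory: str | Path) -> "Dataset":
        return read_dataset(directory)


def _require_columns(frame: pd.DataFrame, columns: Iterable[str], table: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {', '.join(missing)}")


def normalize_plots(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate labels and attach the derived abs_latitude/dryness columns."""
    _require_columns(frame, PLOTS_COLUMNS, "plots")
    out = frame.copy()
    bad_zone = set(out["zone"]) - {z.value for z in Zone}
    if bad_zone:
        raise ValueError(f"plots: unknown zone label(s) {sorted(bad_zone)}")
    bad_phen = set(out["phenology"]) - {p.value for p in Phenology}
    if bad_phen:
        raise ValueError(f"plots: unknown phenology label(s) {sorted(bad_phen)}")
    out["abs_latitude"] = out["latitude"].abs()
    out["dryness"] = out["pet_mm"] / out["map_mm"]
    return out


def normalize_soil(frame: pd.DataFrame) -> pd.DataFrame:
    """Percent columns -> fractions; derive C:N and C:P ratios."""
    if all(c in frame.columns for c in ("s_c", "s_n", "s_p", "s_si")):
        out = frame.copy()  # already normalized
    else:
        _require_columns(frame, SOIL_COLUMNS, "soil")
        out = frame[["plot_id"]].copy()
        for el in ("c", "n", "p", "si"):
            out[f"s_{el}"] = frame[f"s_{el}_pct"] / 100.0
    out["s_cn"] = out["s_c"] / out["s_n"]
    out["s_cp"] = out["s_c"] / out["s_p"]
    return out


def normalize_traps(frame: pd.DataFrame) -> pd.DataFrame:
    _require_columns(frame, TRAPS_COLUMNS, "traps")
    out = frame.copy()
    for col in ("date_start", "date_end"):
        out[col] = pd.to_datetime(out[col]).dt.date
    return out


def normalize_damage(frame: pd.DataFrame) -> pd.DataFrame:
    _require_columns(frame, DAMAGE_COLUMNS, "damage")
    out = frame.copy()
    out["scan_date"] = pd.to_datetime(out["scan_date"]).dt.date
    counts = out[["n_undamaged", *DAMAGE_CLASS_COLUMNS]]
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = out.loc[totals <= 0, ["plot_id", "scan_date"]]
        rows = "; ".join(f"{r.plot_id}@{r.scan_date}" for r in bad.itertuples())
        raise ValueError(f"damage: tally with zero scored leaves at {rows}")
    return out


def normalize_chemistry(frame: pd.DataFrame) -> pd.DataFrame:
    """Percent -> fraction, keyed on the presence of ``concentration_pct``."""
    if "concentration" in frame.columns:
        return frame.copy()
    _require_columns(frame, CHEMISTRY_COLUMNS, "chemistry")
    out = frame.drop(columns=["concentration_pct"]).copy()
    out["concentration"] = frame["concentration_pct"] / 100.0
    bad_el = set(out["element"]) - set(ALL_ELEMENTS)
    if bad_el:
        raise ValueError(f"chemistry: unknown element label(s) {sorted(bad_el)}")
    return out


def normalize_references(frame: pd.DataFrame) -> pd.DataFrame:
    _require_columns(frame, REFERENCES_COLUMNS, "references")
    return frame.copy()


def read_dataset(source: str | Path | Mapping[str, str | Path]) -> Dataset:
    """Read and validate a CSV bundle.

    ``source`` is either a directory holding the canonically named files
    (``plots.csv`` etc.) or a mapping from table name to file path.
    Percent columns are converted to fractions and derived columns attached.
    """
    if isinstance(source, (str, Path)):
        directory = Path(source)
        paths = {name: directory / fname for name, fname in TABLE_FILES.items()}
    else:
        paths = {name: Path(p) for name, p in source.items()}

    raw = {}
    for name, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        raw[name] = pd.read_csv(path, comment="#")

    return Dataset(
        plots=normalize_plots(raw["plots"]),
        soil=normalize_soil(raw["soil"]),
        traps=normalize_traps(raw["traps"]),
        damage=normalize_damage(raw["damage"]),
        chemistry=normalize_chemistry(raw["chemistry"]),
        references=normalize_references(raw["references"]),
    )


def write_dataset(ds: Dataset, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as percent-unit CSVs; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    plots = ds.plots[PLOTS_COLUMNS]
    soil = ds.soil[["plot_id"]].copy()
    for el in ("c", "n", "p", "si"):
        soil[f"s_{el}_pct"] = ds.soil[f"s_{el}"] * 100.0
    chem = ds.chemistry[["plot_id", "element", "tissue"]].copy()
    chem["concentration_pct"] = ds.chemistry["concentration"] * 100.0
    chem["season"] = ds.chemistry["season"]

    frames = {
        "plots": plots,
        "soil": soil,
        "traps": ds.traps[TRAPS_COLUMNS],
        "damage": ds.damage[DAMAGE_COLUMNS],
        "chemistry": chem[CHEMISTRY_COLUMNS],
        "references": ds.references[REFERENCES_COLUMNS],
    }
    for name, frame in frames.items():
        path = directory / TABLE_FILES[name]
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    table: str
    record: str
    message: str
    severity: str = "error"  # "error" | "warning"


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> str:
        if not self.findings:
            return "ok"
        lines = [
            f"[{f.severity}] {f.table}/{f.record}: {f.message}"
            for f in self.findings
        ]
        return "\n".join(lines)


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Check every record-level invariant; findings never raise."""
    rep = ValidationReport()

    p = ds.plots
    for row in p.itertuples():
        if row.map_mm <= 0:
            rep.findings.append(Finding("plots", row.plot_id, "MAP must be > 0"))
            continue
        expected = row.pet_mm / row.map_mm
        if "dryness" in p.columns and not np.isclose(row.dryness, expected, rtol=1e-12, atol=1e-12):
            rep.findings.append(Finding(
                "plots", row.plot_id,
                f"dryness {row.dryness} != pet/map (recomputed {expected})"))
        if abs(row.latitude) != row.abs_latitude:
            rep.findings.append(Finding("plots", row.plot_id, "abs_latitude != |latitude|"))
        if not 0 < row.trap_area_m2 <= 1:
            rep.findings.append(Finding("plots", row.plot_id, "trap area outside (0, 1] m^2"))
        if row.zone not in {z.value for z in Zone}:
            rep.findings.append(Finding("plots", row.plot_id, f"unknown zone {row.zone!r}"))
        if row.phenology not in {ph.value for ph in Phenology}:
            rep.findings.append(Finding("plots", row.plot_id, f"unknown phenology {row.phenology!r}"))

    for row in ds.soil.itertuples():
        for col in ("s_c", "s_n", "s_p", "s_si"):
            v = getattr(row, col)
            if not 0 <= v <= 1:
                rep.findings.append(Finding("soil", row.plot_id, f"{col}={v} outside [0, 1]"))

    for row in ds.traps.itertuples():
        if row.date_end <= row.date_start:
            rep.findings.append(Finding("traps", row.trap_id, "date_end <= date_start"))
            continue
        days = (row.date_end - row.date_start).days
        if not 1 <= days <= 120:
            rep.findings.append(Finding("traps", row.trap_id, f"interval {days} d outside [1, 120]"))
        elif not 14 <= days <= 31:
            rep.findings.append(Finding(
                "traps", row.trap_id, f"interval {days} d outside usual 14-31", "warning"))
        if row.leaf_dry_mass_g < 0:
            rep.findings.append(Finding("traps", row.trap_id, "negative leaf mass"))
        if not 0 < row.trap_area_m2 <= 1:
            rep.findings.append(Finding("traps", row.trap_id, "trap area outside (0, 1] m^2"))

    counts = ds.damage[["n_undamaged", *DAMAGE_CLASS_COLUMNS]]
    neg = (counts < 0).any(axis=1)
    zero = counts.sum(axis=1) <= 0
    for row in ds.damage.loc[neg | zero].itertuples():
        rec = f"{row.plot_id}@{row.scan_date}"
        rep.findings.append(Finding("damage", rec, "negative or all-zero tally"))

    for row in ds.chemistry.itertuples():
        if not 0 < row.concentration < 1:
            rep.findings.append(Finding(
                "chemistry", f"{row.plot_id}/{row.element}/{row.tissue}",
                f"concentration {row.concentration} outside (0, 1)"))

    for row in ds.references.itertuples():
        for col in ("atm_n", "atm_p", "bedrock_p"):
            if getattr(row, col) < 0:
                rep.findings.append(Finding("references", row.scope, f"negative {col}"))

    return rep
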