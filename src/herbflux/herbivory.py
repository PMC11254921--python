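"""Herbivory rate estimation from binned leaf-damage tallies.

A single observer scores each litter leaf into one of six leaf-area-removal
classes (0-1, 1-5, 5-25, 25-50, 50-75, >75 %) or as undamaged.  The plot
herbivory rate H is the class-midpoint mean leaf area removed per leaf;
incidence is the fraction of leaves with any recorded damage.  Tallies
within a year are pooled by summing counts (leaf-weighted); across years
the annual estimates are averaged unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: default class boundaries as fractions of leaf area removed
DEFAULT_BOUNDS = (0.0, 0.01, 0.05, 0.25, 0.50, 0.75, 1.0)


@dataclass(frozen=True)
class DamageClassScheme:
    """Ordered damage-class boundaries; midpoints impute per-leaf removal."""

    bounds: tuple[float, ...] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        b = self.bounds
        if len(b) < 2 or b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("bounds must run from 0 to 1")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("bounds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.bounds) - 1

    @property
    def midpoints(self) -> tuple[float, ...]:
        return class_midpoints(self)


DEFAULT_SCHEME = DamageClassScheme()


@dataclass(frozen=True)
class HerbivoryEstimate:
    """Plot-level herbivory: mean leaf area removed (h) and damage incidence."""

    plot_id: str
    h: float
    incidence: float
    n_leaves: int


def class_midpoints(scheme: DamageClassScheme = DEFAULT_SCHEME) -> tuple[float, ...]:
    """Arithmetic midpoint of each damage-class interval."""
    b = scheme.bounds
    return tuple((lo + hi) / 2.0 for lo, hi in zip(b, b[1:]))


def _counts(tally) -> tuple[int, np.ndarray]:
    """Accept a DamageTally-like object or an (n_undamaged, counts) pair."""
    if hasattr(tally, "n_class"):
        return int(tally.n_undamaged), np.asarray(tally.n_class, dtype=float)
    n_undamaged, counts = tally
    return int(n_undamaged), np.asarray(counts, dtype=float)


def herbivory_rate(tally, scheme: DamageClassScheme = DEFAULT_SCHEME) -> float:
    """Class-midpoint mean proportion of leaf area removed per leaf.

    Undamaged leaves contribute zero; raises on an empty tally.
    """
    n_undamaged, counts = _counts(tally)
    if len(counts) != scheme.n_classes:
        raise ValueError(
            f"tally has {len(counts)} classes, scheme {scheme.n_classes}")
    total = n_undamaged + counts.sum()
    if total <= 0:
        raise ValueError("zero scored leaves")
    return float(counts @ np.asarray(scheme.midpoints) / total)


def damage_incidence(tally) -> float:
    """Fraction of scored leaves assigned to any damage class."""
    n_undamaged, counts = _counts(tally)
    total = n_undamaged + counts.sum()
    if total <= 0:
        raise ValueError("zero scored leaves")
    return float(counts.sum() / total)


def pool_herbivory(
    tallies: Iterable,
    scheme: DamageClassScheme = DEFAULT_SCHEME,
    plot_id: str = "",
) -> HerbivoryEstimate:
    """Pool scan-level tallies of one plot-year by summing counts.

    Leaf-count weighting: the pooled H is the leaf-weighted mean of the
    scan-level rates.  Empty (all-zero) tallies are skipped with a warning.
    """
    n_undamaged = 0
    counts = np.zeros(scheme.n_classes)
    n_used = 0
    for tally in tallies:
        nu, c = _counts(tally)
        if nu + c.sum() <= 0:
            warnings.warn(f"plot {plot_id}: skipping empty tally", stacklevel=2)
            continue
        n_undamaged += nu
        counts += c
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable tallies to pool")
    pooled = (n_undamaged, counts)
    return HerbivoryEstimate(
        plot_id=plot_id,
        h=herbivory_rate(pooled, scheme),
        incidence=damage_incidence(pooled),
        n_leaves=int(n_undamaged + counts.sum()),
    )


def annualize_herbivory(
    year_estimates: Sequence[HerbivoryEstimate],
) -> HerbivoryEstimate:
    """Unweighted mean of 1-2 yearly estimates; leaf counts are summed."""
    if len(year_estimates) == 0:
        raise ValueError("no yearly estimates")
    return HerbivoryEstimate(
        plot_id=year_estimates[0].plot_id,
        h=float(np.mean([e.h for e in year_estimates])),
        incidence=float(np.mean([e.incidence for e in year_estimates])),
        n_leaves=int(sum(e.n_leaves for e in year_estimates)),
    )
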