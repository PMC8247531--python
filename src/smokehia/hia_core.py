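"""Log-linear health impact function and its gridded inputs.

The excess (fire-attributable) hospital admissions in grid cell ``s`` on day
``t`` follow from a log-linear model of the admission rate:

    ΔY(s,t) = YNF(s) · (exp(β·ΔX(s,t)) − 1) · Pop(s)

where ``YNF`` is the background daily admission rate per person (annual county
rate / 100,000 / 365), ``β = ln(RR)/increment`` is the log-rate coefficient of
the concentration–response function (RR per 10 µg/m³ of 2-day average PM2.5),
``ΔX`` the 2-day average fire-originated PM2.5 and ``Pop`` the cell
population. Daily totals ``n(t)`` sum ΔY over cells; the window total sums
over days. Point estimates with RR < 1 may be negative and are reported as
computed; rounding to whole admissions happens only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import FirePMSurface

DAYS_PER_YEAR = 365.0
RATE_DENOMINATOR = 100_000.0

VALID_OUTCOMES = ("respiratory", "cardiovascular", "asthma")


@dataclass(frozen=True)
class CRFSpec:
    """Concentration–response function: rate ratio with 95% CI per increment.

    ``crf_type`` is ``"WF"`` for wildfire-specific or ``"NF"`` for ambient
    (non-wildfire) functions; ``increment`` is the concentration step the RR
    refers to (10 µg/m³) and ``averaging_window`` the exposure averaging
    period in days (2).
    """

    outcome: str
    subgroup: str
    crf_type: str
    rr: float
    rr_lo: float
    rr_hi: float
    increment: float = 10.0
    averaging_window: int = 2

    def __post_init__(self):
        if not (self.rr > 0 and self.rr_lo > 0 and self.rr_hi > 0):
            raise ValueError("rate ratios must be positive")
        if not (self.rr_lo <= self.rr <= self.rr_hi):
            raise ValueError(
                f"CI bounds must bracket the rate ratio: "
                f"{self.rr_lo} <= {self.rr} <= {self.rr_hi} fails"
            )
        if self.increment <= 0:
            raise ValueError("increment must be positive")

    @property
    def beta(self) -> float:
        """Risk coefficient per µg/m³, ln(RR)/increment."""
        return math.log(self.rr) / self.increment

    @property
    def percent_increase(self) -> float:
        """Percent increase in admissions at ΔX equal to one increment."""
        return 100.0 * (math.exp(self.beta * self.increment) - 1.0)


def beta_from_rr(crf: CRFSpec) -> float:
    """Risk coefficient β = ln(RR)/increment (per µg/m³)."""
    return crf.beta


@dataclass
class RateAndPopulationGrid:
    """Gridded background daily admission rate, population and county labels.

    ``ynf`` is the daily per-person admission rate (constant within each
    county), ``pop`` persons per cell, ``county_id`` an integer label grid.
    """

    ynf: np.ndarray
    pop: np.ndarray
    county_id: np.ndarray
    outcome: str = "respiratory"

    def __post_init__(self):
        self.ynf = np.asarray(self.ynf, dtype=float)
        self.pop = np.asarray(self.pop, dtype=float)
        self.county_id = np.asarray(self.county_id, dtype=int)
        if not (self.ynf.shape == self.pop.shape == self.county_id.shape):
            raise ValueError("ynf, pop and county_id grids must be congruent")
        if np.any(self.ynf < 0):
            raise ValueError("background rates must be non-negative")
        if np.any(self.pop < 0):
            raise ValueError("population must be non-negative")


def regrid_rates(rates: pd.DataFrame, county_id: np.ndarray, outcome: str) -> np.ndarray:
    """County annual admission rates → gridded daily per-person rate.

    ``rates`` columns: ``county_id``, ``outcome``, ``annual_rate_per_100k``.
    The gridded rate is piecewise constant per county:
    ``YNF(s) = annual_rate(county(s)) / 100000 / 365``.
    """
    county_id = np.asarray(county_id, dtype=int)
    sub = rates[rates["outcome"] == outcome]
    lookup = dict(zip(sub["county_id"].astype(int), sub["annual_rate_per_100k"].astype(float)))
    present = np.unique(county_id)
    missing = sorted(int(c) for c in present if int(c) not in lookup)
    if missing:
        raise ValueError(f"no {outcome!r} rate for county ids {missing}")
    ynf = np.zeros(county_id.shape, dtype=float)
    for cid in present:
        ynf[county_id == cid] = lookup[int(cid)] / RATE_DENOMINATOR / DAYS_PER_YEAR
    return ynf


def regrid_population(tracts: pd.DataFrame, shape: tuple[int, int]) -> np.ndarray:
    """Tract population table → population-per-cell grid.

    ``tracts`` has one row per (tract, cell): columns ``tract_id``, ``x``,
    ``y``, ``population``; the ``population`` value is the tract total,
    repeated on each of the tract's rows, and is split equally across them
    (the equal-area convention for synthetic square tracts). The grid total
    equals the sum of tract totals.
    """
    required = {"tract_id", "x", "y", "population"}
    if not required.issubset(tracts.columns):
        raise ValueError(f"tract table needs columns {sorted(required)}")
    pop = np.zeros(shape, dtype=float)
    ny, nx = shape
    for tract_id, grp in tracts.groupby("tract_id"):
        total = grp["population"].iloc[0]
        if not np.allclose(grp["population"], total):
            raise ValueError(f"tract {tract_id} rows disagree on its total population")
        xs = grp["x"].to_numpy(dtype=int)
        ys = grp["y"].to_numpy(dtype=int)
        if len(xs) == 0:
            raise ValueError(f"tract {tract_id} maps to no cells")
        if xs.min() < 0 or xs.max() >= nx or ys.min() < 0 or ys.max() >= ny:
            raise ValueError(f"tract {tract_id} has cells outside the grid")
        pop[ys, xs] += float(total) / len(xs)
    return pop


@dataclass
class ImpactResult:
    """Attributable admissions: per cell-day field, daily series and totals."""

    dy: np.ndarray
    daily: np.ndarray
    total: float
    county_totals: pd.Series
    provenance: dict = field(default_factory=dict)
    ci_lo: float | None = None
    ci_hi: float | None = None

    def rounded_total(self) -> int:
        """Window total rounded half-up to whole admissions (presentation)."""
        return round_half_up(self.total)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def excess_admissions(dx: FirePMSurface, crf: CRFSpec,
                      rp: RateAndPopulationGrid) -> ImpactResult:
    """Evaluate the health impact function on a fire-PM2.5 field.

    Requires ``dx`` to carry 2-day averaged concentrations (matching the CRF
    averaging window). Returns the full-precision per-cell-day field, the
    daily totals ``n(t)``, the window total and per-county totals.
    """
    if not dx.two_day_averaged:
        raise ValueError(
            "the CRF applies to 2-day average PM2.5; pass a two-day-averaged ΔX"
        )
    if dx.dx.shape[1:] != rp.ynf.shape:
        raise ValueError(
            f"ΔX grid {dx.dx.shape[1:]} and rate/population grid {rp.ynf.shape} "
            "are misaligned"
        )
    beta = crf.beta
    dy = rp.ynf[None] * np.expm1(beta * dx.dx) * rp.pop[None]
    daily = dy.sum(axis=(1, 2))
    total = float(daily.sum())
    dy_window = dy.sum(axis=0)
    county_totals = pd.Series(
        {int(cid): float(dy_window[rp.county_id == cid].sum())
         for cid in np.unique(rp.county_id)}
    ).sort_index()
    prov = dict(dx.provenance)
    prov.update({"outcome": crf.outcome, "subgroup": crf.subgroup,
                 "crf_type": crf.crf_type, "rr": crf.rr})
    return ImpactResult(dy=dy, daily=daily, total=total,
                        county_totals=county_totals, provenance=prov)


def stratified_assessment(dx: FirePMSurface, crf_set: list[CRFSpec],
                          rp_by_subgroup: dict[str, RateAndPopulationGrid],
                          ) -> dict[str, ImpactResult]:
    """Independent impact evaluations per subgroup.

    Each subgroup uses its own CRF and rate/population grids; subgroup totals
    are not constrained to sum to the all-population total because each
    subgroup CRF is estimated independently.
    """
    out: dict[str, ImpactResult] = {}
    for crf in crf_set:
        if crf.subgroup not in rp_by_subgroup:
            raise ValueError(f"no rate/population grid for subgroup {crf.subgroup!r}")
        out[crf.subgroup] = excess_admissions(dx, crf, rp_by_subgroup[crf.subgroup])
    return out
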