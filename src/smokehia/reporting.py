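"""Sensitivity matrix, comparison summaries and result tables.

The assessment is sensitive to three choices: the total-PM2.5 estimation
method, the background (fire-PM isolation) method, and the CRF family. The
default sensitivity matrix holds a base case (data fusion total, ratio
zero-out background, wildfire CRF, both uncertainty sources) and ten
alternatives that change one input at a time — two alternative totals, one
alternative background, one alternative CRF, and six single-uncertainty-source
runs (three totals × {crf only, exposure only}).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import crfs
from .exposure import FirePMSurface, exposure_summaries, isolate_fire
from .hia_core import ImpactResult, round_half_up
from .synthetic_data import ScenarioData
from .uncertainty import McConfig, McResult, monte_carlo_assessment

TOTAL_METHODS = ("datafusion", "kriging", "ctm")
BACKGROUND_METHODS = ("ratio", "baseline")


@dataclass(frozen=True)
class AssessmentConfig:
    """One row of the sensitivity matrix: which inputs this assessment uses."""

    config_id: str
    total_method: str = "datafusion"
    background_method: str = "ratio"
    crf_type: str = "WF"
    sources: tuple[str, ...] = ("exposure", "crf")
    mc: McConfig = field(default_factory=McConfig)

    def __post_init__(self):
        if self.total_method not in TOTAL_METHODS:
            raise ValueError(f"unknown total method {self.total_method!r}")
        if self.background_method not in BACKGROUND_METHODS:
            raise ValueError(f"unknown background method {self.background_method!r}")
        if self.crf_type not in ("WF", "NF"):
            raise ValueError(f"unknown CRF type {self.crf_type!r}")


def default_sensitivity_matrix(mc: McConfig | None = None) -> list[AssessmentConfig]:
    """The 11-configuration matrix: base case plus ten one-change alternatives."""
    mc = mc if mc is not None else McConfig()
    base = AssessmentConfig("base", mc=mc)
    configs = [
        base,
        replace(base, config_id="total_ctm", total_method="ctm"),
        replace(base, config_id="total_kriging", total_method="kriging"),
        replace(base, config_id="background_baseline", background_method="baseline"),
        replace(base, config_id="crf_nf", crf_type="NF"),
    ]
    for method in TOTAL_METHODS:
        for src in ("crf", "exposure"):
            configs.append(replace(
                base, config_id=f"unc_{method}_{src}",
                total_method=method, sources=(src,)))
    return configs


def run_assessment(scenario: ScenarioData, config: AssessmentConfig,
                   outcome: str) -> McResult:
    """Run one configured assessment for one outcome on a scenario."""
    x = scenario.surfaces[config.total_method]
    bg = scenario.background(config.background_method)
    crf = crfs.get_crf(outcome, config.crf_type)
    rp = scenario.rate_population_grid(outcome)
    mc = replace(config.mc, sources=config.sources)
    return monte_carlo_assessment(x, bg, crf, rp, mc)


def run_sensitivity_matrix(scenario: ScenarioData,
                           configs: list[AssessmentConfig] | None = None,
                           outcomes: tuple[str, ...] = ("respiratory", "cardiovascular"),
                           ) -> pd.DataFrame:
    """Window totals with CIs per configuration and outcome, plus the
    fire-PM2.5 exposure summary statistics of each configuration's surface.

    One row per configuration; admission columns are full precision, exposure
    summaries pool all cell-days with the population grid as spatial weight.
    """
    configs = configs if configs is not None else default_sensitivity_matrix()
    rows = []
    for config in configs:
        x = scenario.surfaces[config.total_method]
        bg = scenario.background(config.background_method)
        dx = isolate_fire(x, bg)
        summ = exposure_summaries(dx, scenario.population)
        row = {
            "config_id": config.config_id,
            "total_method": config.total_method,
            "background_method": config.background_method,
            "crf_type": config.crf_type,
            "sources": "+".join(config.sources),
        }
        for outcome in outcomes:
            res = run_assessment(scenario, config, outcome)
            row[f"{outcome}_total"] = res.point
            row[f"{outcome}_lo"] = res.lo
            row[f"{outcome}_hi"] = res.hi
            row[f"{outcome}_rounded"] = round_half_up(res.point)
        row.update({
            "pw_mean": summ.pw_mean, "pw_sd": summ.pw_sd,
            "spatial_mean": summ.spatial_mean, "spatial_sd": summ.spatial_sd,
            "p95": summ.p95,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(base: float, alt: float) -> float:
    """Relative change 100·(alt − base)/base; negative means a decrease."""
    if base == 0:
        raise ValueError("percent change is undefined for a zero base value")
    return 100.0 * (alt - base) / base


def percent_change_rounded(base: float, alt: float) -> int:
    """Percent change rounded half-up to a whole percent (summary text)."""
    return round_half_up(percent_change(base, alt))


def _width(ci) -> float:
    if hasattr(ci, "width"):
        return float(ci.width)
    lo, hi = ci
    return float(hi) - float(lo)


def ci_width_change(base, alt) -> float:
    """Percent change of CI width; accepts McResults or (lo, hi) pairs."""
    wb = _width(base)
    if wb == 0:
        raise ValueError("base CI is degenerate (zero width)")
    return percent_change(wb, _width(alt))


def county_report(result: ImpactResult, county_map: np.ndarray,
                  dx: FirePMSurface, pop: np.ndarray) -> pd.DataFrame:
    """Per-county attributable admissions, exposure and population.

    Columns: admissions (full precision and rounded), county share of the
    regional total (percent, one decimal in ``share_pct``), the
    population-weighted mean and sd of fire-PM2.5 over the county's cell-days,
    and the county total population. Sorted by admissions, descending; ties
    broken by county id.
    """
    county_map = np.asarray(county_map, dtype=int)
    pop = np.asarray(pop, dtype=float)
    dy_window = result.dy.sum(axis=0)
    regional = result.total
    rows = []
    for cid in np.unique(county_map):
        mask = county_map == cid
        admissions = float(dy_window[mask].sum())
        w = np.broadcast_to(pop[mask], dx.dx[:, mask].shape)
        wsum = w.sum()
        if wsum > 0:
            pw_mean = float((w * dx.dx[:, mask]).sum() / wsum)
            pw_sd = float(np.sqrt((w * (dx.dx[:, mask] - pw_mean) ** 2).sum() / wsum))
        else:
            pw_mean = pw_sd = np.nan
        share = 100.0 * admissions / regional if regional != 0 else np.nan
        rows.append({
            "county_id": int(cid),
            "admissions": admissions,
            "admissions_rounded": round_half_up(admissions),
            "share_pct": round(share, 1) if np.isfinite(share) else share,
            "pw_fire_pm_mean": pw_mean,
            "pw_fire_pm_sd": pw_sd,
            "population": float(pop[mask].sum()),
        })
    df = pd.DataFrame(rows)
    return (df.sort_values(["admissions", "county_id"], ascending=[False, True])
              .reset_index(drop=True))


def county_share(regional_total: float, county_total: float) -> float:
    """County share of the regional total, percent, one decimal."""
    if regional_total == 0:
        raise ValueError("regional total is zero")
    return round(100.0 * county_total / regional_total, 1)


def rate_map(result: ImpactResult, pop: np.ndarray) -> np.ndarray:
    """Attributable admissions per 1,000,000 person-days, per cell.

    ``10⁶ · Σ_t ΔY(s,t) / (Pop(s) · n_days)``; cells without population are
    NaN-masked.
    """
    pop = np.asarray(pop, dtype=float)
    n_days = result.dy.shape[0]
    window = result.dy.sum(axis=0)
    out = np.full(pop.shape, np.nan)
    nz = pop > 0
    out[nz] = 1e6 * window[nz] / (pop[nz] * n_days)
    return out
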