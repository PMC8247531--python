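"""Monte Carlo propagation of exposure and CRF uncertainty.

Two uncertain inputs feed the admission estimates:

* the total-PM2.5 surface, whose per-cell estimation variance defines a
  lognormal distribution for each cell-day (method-of-moments match to the
  reported mean and variance);
* the concentration–response function, whose 95% CI defines a lognormal
  rate-ratio distribution, i.e. a normal distribution for β = ln(RR)/increment
  with sd = (ln RR_hi − ln RR_lo)/(2·1.96). Negative β draws are possible when
  the CI straddles RR = 1, which is what produces negative lower confidence
  bounds on admission counts.

Each draw resamples the daily total-PM2.5 field, re-runs background isolation,
2-day averaging and the impact function, and (optionally) resamples β; the CI
is the empirical 2.5–97.5 percentile interval of the window totals. The
background model fields are held fixed: their estimation is not treated as a
source of uncertainty. The point estimate is the plug-in evaluation at the
mean inputs, so the CI is generally asymmetric around it.

Spatial sampling of the exposure field defaults to *comonotonic*: one
standard-normal deviate per draw drives every cell through its own lognormal
quantile, preserving full spatial correlation of the exposure error. Fully
independent per-cell sampling is available but makes exposure uncertainty
nearly vanish in regional sums by cell-level averaging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import (RATIO_EPS, BackgroundModel, ExposureSurface,
                       FirePMSurface, isolate_fire)
from .hia_core import CRFSpec, RateAndPopulationGrid, excess_admissions

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal quantile used to convert a 95% CI into a log-scale sd

VALID_SOURCES = ("exposure", "crf")


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo settings: draw count, seed, uncertainty sources, CI level."""

    n_draws: int = 100_000
    seed: int = 0
    sources: tuple[str, ...] = ("exposure", "crf")
    exposure_sampling_mode: str = "comonotonic"
    ci_level: float = 0.95

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")
        bad = set(self.sources) - set(VALID_SOURCES)
        if bad:
            raise ValueError(f"unknown uncertainty sources {sorted(bad)}")
        if self.exposure_sampling_mode not in ("comonotonic", "independent"):
            raise ValueError("exposure_sampling_mode must be 'comonotonic' or 'independent'")


@dataclass
class McResult:
    """Monte Carlo summary: plug-in point estimate with empirical CI."""

    point: float
    lo: float
    hi: float
    daily_point: np.ndarray
    daily_lo: np.ndarray
    daily_hi: np.ndarray
    sources: tuple[str, ...]
    n_draws: int
    ci_level: float
    provenance: dict = field(default_factory=dict)
    draws: np.ndarray | None = None

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("lower CI bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.hi - self.lo


def lognormal_params_from_mean_var(m, v) -> tuple[np.ndarray, np.ndarray]:
    """Log-scale (location, scale) of a lognormal with given mean and variance.

    Method-of-moments match: ``scale² = ln(1 + v/m²)``,
    ``location = ln m − scale²/2``. Cells with non-positive mean cannot carry a
    lognormal and are returned degenerate (location −inf ⇒ draws of 0, scale
    0); their count is logged.
    """
    m = np.asarray(m, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("variance must be non-negative")
    valid = m > 0
    n_bad = int(np.count_nonzero(~valid & (v > 0)))
    if n_bad:
        logger.info("excluded %d zero-mean cells with positive variance from sampling", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale2 = np.where(valid, np.log1p(np.where(valid, v, 0.0) / np.where(valid, m, 1.0) ** 2), 0.0)
        location = np.where(valid, np.log(np.where(valid, m, 1.0)) - 0.5 * scale2, -np.inf)
    return location, np.sqrt(scale2)


def _lognormal_sigma(mean: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Log-scale sd per cell; degenerate (0) where the mean is non-positive."""
    _, sigma = lognormal_params_from_mean_var(mean, variance)
    return sigma


@dataclass(frozen=True)
class CRFSampler:
    """Sampler over the risk coefficient β implied by a CRF's rate-ratio CI."""

    beta_mean: float
    beta_sd: float
    increment: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.beta_sd == 0.0:
            return np.full(n, self.beta_mean)
        return rng.normal(self.beta_mean, self.beta_sd, size=n)


def crf_distribution(crf: CRFSpec) -> CRFSampler:
    """β sampler: ln RR normal with sd from the 95% CI half-width.

    Degenerates to a point mass when the CI bounds coincide. Negative β draws
    occur with positive probability whenever ``rr_lo < 1``.
    """
    if crf.rr_hi < crf.rr_lo:
        raise ValueError("rr_hi must not be below rr_lo")
    sd_log_rr = (np.log(crf.rr_hi) - np.log(crf.rr_lo)) / (2.0 * Z_95)
    return CRFSampler(beta_mean=np.log(crf.rr) / crf.increment,
                      beta_sd=sd_log_rr / crf.increment,
                      increment=crf.increment)


def _avg2(a: np.ndarray, axis: int) -> np.ndarray:
    """2-day rolling mean along ``axis`` (first day keeps its own value)."""
    out = a.copy()
    lead = [slice(None)] * a.ndim
    lag = [slice(None)] * a.ndim
    lead[axis] = slice(1, None)
    lag[axis] = slice(None, -1)
    out[tuple(lead)] = 0.5 * (a[tuple(lead)] + a[tuple(lag)])
    return out


class _DxEngine:
    """Re-runs background isolation + 2-day averaging on sampled daily fields.

    Uses the same arithmetic as the deterministic isolation routines so that
    zero-variance draws reproduce the plug-in ΔX bit-exactly.
    """

    def __init__(self, bg: BackgroundModel, two_day: bool = True,
                 clamp_before_average: bool = False):
        self.bg = bg
        self.two_day = two_day
        self.clamp_before_average = clamp_before_average
        if bg.kind == "ratio":
            fire = bg.cmaq_fire
            self.ratio = np.where(fire > RATIO_EPS,
                                  bg.cmaq_back / np.where(fire > RATIO_EPS, fire, 1.0),
                                  1.0)
        else:
            self.ratio = None

    def __call__(self, x_daily: np.ndarray) -> np.ndarray:
        """ΔX from a daily total field of shape (..., n_days, ny, nx)."""
        axis = x_daily.ndim - 3
        if self.bg.kind == "ratio":
            xnf = x_daily * self.ratio
            if not self.two_day:
                return np.maximum(x_daily - xnf, 0.0)
            if self.clamp_before_average:
                return _avg2(np.maximum(x_daily - xnf, 0.0), axis)
            return np.maximum(_avg2(x_daily, axis) - _avg2(xnf, axis), 0.0)
        xbar = _avg2(x_daily, axis) if self.two_day else x_daily
        return np.maximum(xbar - self.bg.baseline, 0.0)


def _daily_impacts(dx: np.ndarray, beta, weight: np.ndarray) -> np.ndarray:
    """Daily totals Σ_s YNF·(e^{β ΔX}−1)·Pop for (..., n_days, ny, nx) ΔX."""
    return np.einsum("...dij,ij->...d", np.expm1(beta * dx), weight)


def monte_carlo_assessment(x: ExposureSurface, bg: BackgroundModel, crf: CRFSpec,
                           rp: RateAndPopulationGrid, mc: McConfig,
                           clamp_before_average: bool = False,
                           keep_draws: bool = False) -> McResult:
    """Admissions CI by Monte Carlo over exposure and/or CRF uncertainty.

    Per draw the daily total-PM2.5 field is resampled from its per-cell
    lognormal (if ``"exposure"`` is a source), fire-PM isolation and 2-day
    averaging are re-run, β is resampled (if ``"crf"`` is a source) and the
    impact function is re-evaluated. The reported interval is the empirical
    ``ci_level`` percentile interval of the window totals; daily intervals
    are computed the same way. The point estimate is the deterministic run at
    the mean inputs.
    """
    if not mc.sources:
        raise ValueError("at least one uncertainty source is required")
    if mc.n_draws < 100:
        warnings.warn(f"{mc.n_draws} draws is too few for stable 95% percentile bounds",
                      stacklevel=2)
    engine = _DxEngine(bg, two_day=True, clamp_before_average=clamp_before_average)
    weight = rp.ynf * rp.pop
    beta0 = crf.beta

    point_dx = engine(x.mean)
    daily_point = _daily_impacts(point_dx, beta0, weight)
    point = float(daily_point.sum())

    rng = np.random.default_rng(mc.seed)
    use_exposure = "exposure" in mc.sources
    use_crf = "crf" in mc.sources
    sampler = crf_distribution(crf) if use_crf else None
    sigma = _lognormal_sigma(x.mean, x.variance) if use_exposure else None

    n_days = x.n_days
    daily_draws = np.empty((mc.n_draws, n_days))
    cells = x.mean.size
    chunk = max(1, min(mc.n_draws, int(4_000_000 / max(cells, 1))))
    done = 0
    while done < mc.n_draws:
        c = min(chunk, mc.n_draws - done)
        if use_exposure:
            if mc.exposure_sampling_mode == "comonotonic":
                z = rng.standard_normal(c)[:, None, None, None]
            else:
                z = rng.standard_normal((c,) + x.mean.shape)
            x_draw = x.mean * np.exp(sigma * z - 0.5 * sigma ** 2)
            dx = engine(x_draw)
        else:
            dx = point_dx[None]
        if use_crf:
            betas = sampler.sample(rng, c)[:, None, None, None]
        else:
            betas = beta0
        daily_draws[done:done + c] = _daily_impacts(dx, betas, weight)
        done += c

    totals = daily_draws.sum(axis=1)
    alpha = 100.0 * (1.0 - mc.ci_level) / 2.0
    lo, hi = np.percentile(totals, [alpha, 100.0 - alpha])
    daily_lo, daily_hi = np.percentile(daily_draws, [alpha, 100.0 - alpha], axis=0)
    prov = {"method": x.method, "background": bg.kind, "outcome": crf.outcome,
            "subgroup": crf.subgroup, "crf_type": crf.crf_type,
            "sampling_mode": mc.exposure_sampling_mode, "seed": mc.seed}
    return McResult(point=point, lo=float(lo), hi=float(hi),
                    daily_point=daily_point, daily_lo=daily_lo, daily_hi=daily_hi,
                    sources=tuple(mc.sources), n_draws=mc.n_draws,
                    ci_level=mc.ci_level, provenance=prov,
                    draws=totals if keep_draws else None)


@dataclass
class DecompositionResult:
    """CI widths under both sources, CRF only and exposure only."""

    results: dict[str, McResult]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        w_both = self.results["both"].width
        for name, res in self.results.items():
            rows.append({
                "source_set": name, "total": res.point,
                "ci_lo": res.lo, "ci_hi": res.hi, "width": res.width,
                "width_vs_both": res.width / w_both if w_both > 0 else np.nan,
            })
        return pd.DataFrame(rows)

    def width_increase_adding(self, source: str) -> float:
        """Percent CI-width increase from adding ``source`` to the other one.

        E.g. ``width_increase_adding("crf")`` compares the both-sources width
        with the exposure-only width: how much wider the interval becomes when
        CRF uncertainty is accounted for on top of exposure uncertainty.
        """
        other = "exposure" if source == "crf" else "crf"
        base = self.results[other].width
        if base <= 0:
            raise ValueError(f"{other}-only CI is degenerate")
        return 100.0 * (self.results["both"].width - base) / base

    def dominant_source(self) -> str:
        """Which single source alone yields the wider CI."""
        return ("crf" if self.results["crf"].width >= self.results["exposure"].width
                else "exposure")


def decompose_uncertainty(x: ExposureSurface, bg: BackgroundModel, crf: CRFSpec,
                          rp: RateAndPopulationGrid, mc: McConfig,
                          **kwargs) -> DecompositionResult:
    """Run the assessment under {both}, {crf} and {exposure} uncertainty.

    All three runs share the plug-in point estimate; comparing their CI widths
    shows which input dominates the overall uncertainty and by how much a
    single-source analysis understates it.
    """
    from dataclasses import replace
    results = {}
    for name, sources in (("both", ("exposure", "crf")),
                          ("crf", ("crf",)),
                          ("exposure", ("exposure",))):
        results[name] = monte_carlo_assessment(
            x, bg, crf, rp, replace(mc, sources=sources), **kwargs)
    return DecompositionResult(results=results)


def deterministic_impact(x: ExposureSurface, bg: BackgroundModel, crf: CRFSpec,
                         rp: RateAndPopulationGrid,
                         clamp_before_average: bool = False):
    """Plug-in (mean-input) impact via the standard pipeline, as an
    :class:`~smokehia.hia_core.ImpactResult` with full per-cell detail."""
    kwargs = {"clamp_before_average": clamp_before_average} if bg.kind == "ratio" else {}
    dx: FirePMSurface = isolate_fire(x, bg, **kwargs)
    return excess_admissions(dx, crf, rp)
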