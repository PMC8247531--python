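"""Fire-originated PM2.5 isolation from total-PM2.5 exposure surfaces.

Total PM2.5 during a fire event mixes smoke with the ambient background. Two
standard ways to recover the fire-originated component ``ΔX`` are implemented:

* **ratio zero-out** — a chemical-transport model is run with and without fire
  emissions; the without/with ratio gives the background fraction at each cell
  and day, so the background estimate is ``XNF(s,t) = X(s,t) · back(s,t)/fire(s,t)``
  and ``ΔX = X − XNF``.
* **baseline subtraction** — a static surface from a comparable non-fire period
  is subtracted: ``ΔX = X − XNF_base(s)``.

Because the epidemiological concentration–response functions are defined for
2-day average PM2.5, ``ΔX`` is formed from 2-day averages of the total and of
the background, and negative values (background estimate exceeding the total)
are clamped to zero after differencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Concentrations (µg/m³) below this are treated as zero when forming
#: with/without-fire ratios; the ratio is then taken as 1 (no fire signal).
RATIO_EPS = 1e-6


def _as_3d(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"{name} must be 3-D (day, y, x); got shape {a.shape}")
    return a


@dataclass
class ExposureSurface:
    """Daily gridded total-PM2.5 estimate for one estimation method.

    Parameters
    ----------
    method : str
        Label of the estimation method (e.g. ``"datafusion"``, ``"kriging"``,
        ``"ctm"``).
    mean : ndarray, shape (n_days, ny, nx)
        Daily mean total PM2.5, µg/m³. Non-negative.
    variance : ndarray, shape (n_days, ny, nx)
        Per-cell estimation variance of the mean, (µg/m³)². Non-negative.
    cell_size_km : float
        Grid cell edge length in km.
    days : ndarray of int, optional
        Day index, strictly increasing and contiguous. Defaults to
        ``0..n_days-1``.
    """

    method: str
    mean: np.ndarray
    variance: np.ndarray
    cell_size_km: float = 1.0
    days: np.ndarray | None = None

    def __post_init__(self):
        self.mean = _as_3d(self.mean, "mean")
        self.variance = _as_3d(self.variance, "variance")
        if self.mean.shape != self.variance.shape:
            raise ValueError(
                f"mean {self.mean.shape} and variance {self.variance.shape} "
                "grids are not congruent"
            )
        if np.any(self.mean < 0):
            raise ValueError("mean concentrations must be non-negative")
        if np.any(self.variance < 0):
            raise ValueError("variances must be non-negative")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.days is None:
            self.days = np.arange(self.mean.shape[0])
        else:
            self.days = np.asarray(self.days, dtype=int)
            if self.days.shape != (self.mean.shape[0],):
                raise ValueError("days must have one entry per day slice")
            if len(self.days) and np.any(np.diff(self.days) != 1):
                raise ValueError("day index must be strictly increasing and contiguous")

    @property
    def n_days(self) -> int:
        return self.mean.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mean.shape


@dataclass
class BackgroundModel:
    """Background (non-fire) PM2.5 model.

    ``kind="ratio"`` holds paired with-fire / without-fire model fields
    (day, y, x); ``kind="baseline"`` holds a single static surface (y, x).
    """

    kind: str
    cmaq_fire: np.ndarray | None = None
    cmaq_back: np.ndarray | None = None
    baseline: np.ndarray | None = None

    def __post_init__(self):
        if self.kind == "ratio":
            if self.cmaq_fire is None or self.cmaq_back is None:
                raise ValueError("ratio background needs cmaq_fire and cmaq_back")
            self.cmaq_fire = _as_3d(self.cmaq_fire, "cmaq_fire")
            self.cmaq_back = _as_3d(self.cmaq_back, "cmaq_back")
            if self.cmaq_fire.shape != self.cmaq_back.shape:
                raise ValueError("with-fire and without-fire fields are not congruent")
            if np.any(self.cmaq_fire < 0) or np.any(self.cmaq_back < 0):
                raise ValueError("ratio background fields must be non-negative")
        elif self.kind == "baseline":
            if self.baseline is None:
                raise ValueError("baseline background needs a baseline surface")
            self.baseline = np.asarray(self.baseline, dtype=float)
            if self.baseline.ndim != 2:
                raise ValueError("baseline surface must be 2-D (y, x)")
            if np.any(self.baseline < 0):
                raise ValueError("baseline surface must be non-negative")
        else:
            raise ValueError(f"unknown background kind {self.kind!r}")


@dataclass
class FirePMSurface:
    """Fire-originated PM2.5 field ΔX (µg/m³), clamped at zero."""

    dx: np.ndarray
    two_day_averaged: bool
    provenance: dict = field(default_factory=dict)
    n_clamped: int = 0
    cell_size_km: float = 1.0

    def __post_init__(self):
        self.dx = _as_3d(self.dx, "dx")

    @property
    def n_days(self) -> int:
        return self.dx.shape[0]


def two_day_average(series: np.ndarray) -> np.ndarray:
    """Rolling 2-day mean along the leading (day) axis.

    Day ``t`` becomes the mean of days ``t`` and ``t-1``; the first day, which
    has no predecessor inside the window, keeps its own value so the output
    spans the same days as the input.
    """
    a = np.asarray(series, dtype=float)
    if a.ndim < 1 or a.shape[0] < 1:
        raise ValueError("two_day_average needs at least one day")
    out = a.copy()
    if a.shape[0] > 1:
        out[1:] = 0.5 * (a[1:] + a[:-1])
    return out


def _daily_background_ratio(x_daily: np.ndarray, bg: BackgroundModel,
                            eps: float = RATIO_EPS) -> np.ndarray:
    """Daily background estimate X·back/fire, with ratio treated as 1 where the
    with-fire model concentration is (numerically) zero — those cell-days carry
    no fire signal and contribute ΔX = 0."""
    fire = bg.cmaq_fire
    ratio = np.where(fire > eps, bg.cmaq_back / np.where(fire > eps, fire, 1.0), 1.0)
    return x_daily * ratio


def _finalize(dx_raw: np.ndarray, provenance: dict, two_day: bool,
              cell_size_km: float) -> FirePMSurface:
    n_clamped = int(np.count_nonzero(dx_raw < 0))
    if n_clamped:
        logger.info("clamped %d negative ΔX cell-days to zero", n_clamped)
    return FirePMSurface(
        dx=np.maximum(dx_raw, 0.0),
        two_day_averaged=two_day,
        provenance=provenance,
        n_clamped=n_clamped,
        cell_size_km=cell_size_km,
    )


def isolate_fire_ratio(x: ExposureSurface, bg: BackgroundModel,
                       two_day: bool = True,
                       clamp_before_average: bool = False) -> FirePMSurface:
    """Fire-originated PM2.5 via the ratio zero-out background.

    With ``two_day=True`` (default) the total and the daily background estimate
    are each 2-day averaged before differencing, and the zero-clamp is applied
    to the difference of averages. ``clamp_before_average=True`` instead clamps
    the daily difference and then averages; the two orders differ wherever the
    clamp is active because the clamp is nonlinear.
    """
    if bg.kind != "ratio":
        raise ValueError("isolate_fire_ratio requires a ratio-kind background")
    if bg.cmaq_fire.shape != x.mean.shape:
        raise ValueError(
            f"background {bg.cmaq_fire.shape} and exposure {x.mean.shape} "
            "grids are misaligned"
        )
    xnf = _daily_background_ratio(x.mean, bg)
    prov = {"total_method": x.method, "background_method": "ratio",
            "clamp_before_average": clamp_before_average}
    if not two_day:
        return _finalize(x.mean - xnf, prov, False, x.cell_size_km)
    if clamp_before_average:
        dx = two_day_average(np.maximum(x.mean - xnf, 0.0))
        return _finalize(dx, prov, True, x.cell_size_km)
    dx_raw = two_day_average(x.mean) - two_day_average(xnf)
    return _finalize(dx_raw, prov, True, x.cell_size_km)


def isolate_fire_baseline(x: ExposureSurface, bg: BackgroundModel,
                          two_day: bool = True) -> FirePMSurface:
    """Fire-originated PM2.5 via static-baseline subtraction.

    ΔX(s,t) = max(X̄(s,t) − XNF_base(s), 0), with X̄ the 2-day average total
    (or the daily total when ``two_day=False``).
    """
    if bg.kind != "baseline":
        raise ValueError("isolate_fire_baseline requires a baseline-kind background")
    if bg.baseline.shape != x.mean.shape[1:]:
        raise ValueError(
            f"baseline {bg.baseline.shape} and exposure {x.mean.shape[1:]} "
            "grids are misaligned"
        )
    xbar = two_day_average(x.mean) if two_day else x.mean
    prov = {"total_method": x.method, "background_method": "baseline"}
    return _finalize(xbar - bg.baseline[None, :, :], prov, two_day, x.cell_size_km)


def isolate_fire(x: ExposureSurface, bg: BackgroundModel, **kwargs) -> FirePMSurface:
    """Dispatch to the isolation routine matching the background kind."""
    if bg.kind == "ratio":
        return isolate_fire_ratio(x, bg, **kwargs)
    return isolate_fire_baseline(x, bg, **kwargs)


@dataclass
class ExposureSummary:
    """Distributional summary of a fire-PM2.5 field over cell-days."""

    pw_mean: float
    pw_sd: float
    spatial_mean: float
    spatial_sd: float
    p95: float

    def as_dict(self) -> dict:
        return {
            "pw_mean": self.pw_mean, "pw_sd": self.pw_sd,
            "spatial_mean": self.spatial_mean, "spatial_sd": self.spatial_sd,
            "p95": self.p95,
        }


def exposure_summaries(dx: FirePMSurface, pop: np.ndarray) -> ExposureSummary:
    """Population-weighted mean/sd, spatial mean/sd and 95th percentile of ΔX.

    Statistics pool all cell-days; the population weight of a cell applies on
    every day. The percentile uses linear interpolation of the empirical
    distribution. Weighted statistics require a positive total population.
    """
    pop = np.asarray(pop, dtype=float)
    if pop.shape != dx.dx.shape[1:]:
        raise ValueError("population grid is misaligned with ΔX")
    if np.any(pop < 0):
        raise ValueError("population must be non-negative")
    total_pop = pop.sum()
    if total_pop <= 0:
        raise ValueError("population-weighted statistics need a positive total population")
    vals = dx.dx
    w = np.broadcast_to(pop, vals.shape)
    pw_mean = float((w * vals).sum() / w.sum())
    pw_var = float((w * (vals - pw_mean) ** 2).sum() / w.sum())
    return ExposureSummary(
        pw_mean=pw_mean,
        pw_sd=float(np.sqrt(pw_var)),
        spatial_mean=float(vals.mean()),
        spatial_sd=float(vals.std()),
        p95=float(np.percentile(vals, 95.0)),
    )
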