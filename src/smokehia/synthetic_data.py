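"""Synthetic study-region generator for the smoke health impact pipeline.

Emulates the statistical structure the assessment assumes, at desk scale:

* a "true" total PM2.5 field that decomposes exactly into a smooth non-fire
  background (~5–10 µg/m³) plus a fire field built from drifting Gaussian
  smoke plumes over a multi-day window;
* three total-exposure estimation methods (``datafusion``, ``kriging``,
  ``ctm``) that share the truth but differ in the magnitude of their spatially
  correlated estimation error — data fusion the most precise, the raw
  chemical-transport model the least — each reporting a per-cell variance that
  is exactly the variance its noise was generated with;
* paired with-fire / without-fire model fields for the ratio zero-out
  background and a static baseline surface with a smooth year-to-year drift;
* a contiguous county partition with annual admission rates per 100,000 and a
  clustered tract-level population.

Everything is a pure function of (spec, seed): the same ``ScenarioSpec``
yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exposure import BackgroundModel, ExposureSurface
from .hia_core import RateAndPopulationGrid, regrid_population, regrid_rates

METHOD_NAMES = ("datafusion", "kriging", "ctm")

#: Multiplicative variance factors per estimation method. Chosen so the
#: generated methods span the precision ordering the pipeline is meant to
#: study: data fusion clearly more precise than the CRF's own uncertainty
#: band, the raw CTM clearly less precise, kriging in between.
DEFAULT_VARIANCE_SCALE = {"datafusion": 0.25, "kriging": 1.5, "ctm": 6.0}

#: Annual admission rates per 100,000, log-uniform sampling ranges spanning
#: roughly one order of magnitude around typical U.S. county values.
RATE_RANGES = {
    "respiratory": (400.0, 4000.0),
    "cardiovascular": (600.0, 6000.0),
    "asthma": (30.0, 300.0),
}

# rng stream labels, so adding a stage never reshuffles another stage's draws
_STAGE_TRUTH, _STAGE_SURFACE, _STAGE_BACKGROUND, _STAGE_RATES = 0, 1, 2, 3


@dataclass(frozen=True)
class PlumeSource:
    """One drifting Gaussian smoke plume.

    ``origin`` is the source position in cell coordinates (x, y); from
    ``start_day`` the plume centre moves by ``drift`` cells/day and its peak
    concentration decays exponentially with e-folding time ``decay_days``.
    """

    origin: tuple[float, float]
    start_day: int
    peak: float
    drift: tuple[float, float]
    spread_km: float
    decay_days: float = 7.0

    def __post_init__(self):
        if self.peak < 0:
            raise ValueError("plume peak concentration must be non-negative")
        if self.spread_km <= 0:
            raise ValueError("plume spread must be positive")
        if self.decay_days <= 0:
            raise ValueError("plume decay time must be positive")


def _default_plumes() -> tuple[PlumeSource, ...]:
    return (
        PlumeSource(origin=(8.0, 30.0), start_day=1, peak=90.0,
                    drift=(1.8, -1.2), spread_km=5.0, decay_days=7.0),
        PlumeSource(origin=(30.0, 6.0), start_day=5, peak=60.0,
                    drift=(-1.0, 1.2), spread_km=7.0, decay_days=6.0),
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic study region.

    Defaults describe the reference scenario: a 40×40 grid of 1-km cells, a
    13-day fire window, 6 counties, a ~7 µg/m³ background and two drifting
    plumes peaking near 90 and 60 µg/m³.
    """

    grid_nx: int = 40
    grid_ny: int = 40
    cell_size: float = 1.0
    n_days: int = 13
    n_counties: int = 6
    background_level: float = 7.0
    plume_sources: tuple[PlumeSource, ...] = field(default_factory=_default_plumes)
    method_variance_scale: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_SCALE))
    seed: int = 0
    # estimation-error model: per-cell sd = base + coeff·truth, smoothed over
    # corr_len cells so errors are spatially structured
    noise_base_sd: float = 1.0
    noise_truth_coeff: float = 0.12
    noise_corr_len: float = 3.0
    # multiplicative (lognormal) noise sd on the with/without-fire model pair
    ratio_noise_sd: float = 0.05
    # sd (µg/m³) of the smooth perturbation on the static baseline surface,
    # emulating year-to-year drift of the non-fire background
    baseline_drift_sd: float = 1.0
    # smooth relative variation of the non-fire background field
    nonfire_rel_sd: float = 0.10
    nonfire_corr_len: float = 6.0
    nonfire_time_corr: float = 1.5
    tract_size: int = 4
    n_pop_clusters: int = 3

    def __post_init__(self):
        if min(self.grid_nx, self.grid_ny, self.n_days, self.n_counties) < 1:
            raise ValueError("grid_nx, grid_ny, n_days and n_counties must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")
        if self.n_counties > self.grid_nx * self.grid_ny:
            raise ValueError("more counties than grid cells")
        for name, factor in self.method_variance_scale.items():
            if name not in METHOD_NAMES:
                raise ValueError(
                    f"unknown method name {name!r}; expected one of {METHOD_NAMES}")
            if factor < 0:
                raise ValueError("variance factors must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_days, self.grid_ny, self.grid_nx)

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


def _rng(seed: int, stage: int, sub: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stage, sub)))


def _smooth_unit_noise(rng: np.random.Generator, shape, sigmas) -> np.ndarray:
    """Smoothed white noise renormalized to exact unit per-cell variance.

    Periodic (wrap) smoothing keeps the field stationary, so dividing by the
    l2 norm of the smoothing kernel makes the per-cell variance exactly 1.
    """
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigmas, mode="wrap")
    impulse = np.zeros(shape)
    impulse[(0,) * len(shape)] = 1.0
    kernel = gaussian_filter(impulse, sigmas, mode="wrap")
    return smooth / np.sqrt((kernel ** 2).sum())


def _cell_centers_km(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    x = (np.arange(spec.grid_nx) + 0.5) * spec.cell_size
    y = (np.arange(spec.grid_ny) + 0.5) * spec.cell_size
    return np.meshgrid(x, y)


def plume_concentration(spec: ScenarioSpec, src: PlumeSource, day: int,
                        xk: np.ndarray, yk: np.ndarray) -> np.ndarray:
    """Concentration field of one plume on one day (zero before start)."""
    if day < src.start_day:
        return np.zeros_like(xk)
    age = day - src.start_day
    amp = src.peak * np.exp(-age / src.decay_days)
    cx = (src.origin[0] + 0.5 + src.drift[0] * age) * spec.cell_size
    cy = (src.origin[1] + 0.5 + src.drift[1] * age) * spec.cell_size
    d2 = (xk - cx) ** 2 + (yk - cy) ** 2
    return amp * np.exp(-d2 / (2.0 * src.spread_km ** 2))


def generate_true_fields(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """True fire and non-fire daily fields; their sum is the true total.

    The fire field sums the drifting Gaussian plumes at all cell centres; the
    non-fire field varies smoothly (lognormally, ~``nonfire_rel_sd`` relative
    sd) around ``background_level``.
    """
    xk, yk = _cell_centers_km(spec)
    fire = np.zeros(spec.shape)
    for src in spec.plume_sources:
        for t in range(spec.n_days):
            fire[t] += plume_concentration(spec, src, t, xk, yk)
    if spec.nonfire_rel_sd > 0:
        g = _smooth_unit_noise(
            _rng(spec.seed, _STAGE_TRUTH), spec.shape,
            (spec.nonfire_time_corr, spec.nonfire_corr_len, spec.nonfire_corr_len))
        nonfire = spec.background_level * np.exp(
            spec.nonfire_rel_sd * g - 0.5 * spec.nonfire_rel_sd ** 2)
    else:
        nonfire = np.full(spec.shape, spec.background_level)
    return fire, nonfire


def generate_method_surfaces(spec: ScenarioSpec, truth_total: np.ndarray,
                             ) -> dict[str, ExposureSurface]:
    """Per-method exposure surfaces: truth plus correlated noise, with the
    declared variance field equal to the generating noise variance.

    The per-cell noise sd is ``sqrt(factor) · (base + coeff·truth)``; the
    reported variance field is exactly its square. The mean field is clipped
    at zero (negative concentrations are unphysical); with realistic
    backgrounds the clip is rarely active.
    """
    truth_total = np.asarray(truth_total, dtype=float)
    if truth_total.shape != spec.shape:
        raise ValueError("truth_total does not match the scenario grid")
    base_sd = spec.noise_base_sd + spec.noise_truth_coeff * truth_total
    surfaces: dict[str, ExposureSurface] = {}
    for sub, name in enumerate(METHOD_NAMES):
        if name not in spec.method_variance_scale:
            continue
        factor = spec.method_variance_scale[name]
        variance = factor * base_sd ** 2
        if factor == 0:
            mean = truth_total.copy()
        else:
            noise = _smooth_unit_noise(
                _rng(spec.seed, _STAGE_SURFACE, sub), spec.shape,
                (0.0, spec.noise_corr_len, spec.noise_corr_len))
            mean = np.maximum(truth_total + np.sqrt(variance) * noise, 0.0)
        surfaces[name] = ExposureSurface(
            method=name, mean=mean, variance=variance, cell_size_km=spec.cell_size)
    return surfaces


def generate_background_inputs(spec: ScenarioSpec, fire_field: np.ndarray,
                               nonfire_field: np.ndarray,
                               ) -> tuple[BackgroundModel, BackgroundModel]:
    """Ratio-type and baseline-type background models from the truth fields.

    The ratio pair is the true with-fire / without-fire totals under shared
    multiplicative lognormal noise (plus a smaller independent component), so
    the without/with ratio is close to, but not exactly, the true non-fire
    fraction. The static baseline is the time-averaged non-fire truth plus a
    smooth perturbation standing in for year-to-year background drift.
    """
    fire_field = np.asarray(fire_field, dtype=float)
    nonfire_field = np.asarray(nonfire_field, dtype=float)
    with_fire = nonfire_field + fire_field
    if spec.ratio_noise_sd > 0:
        sigmas = (0.0, spec.noise_corr_len, spec.noise_corr_len)
        common = _smooth_unit_noise(_rng(spec.seed, _STAGE_BACKGROUND, 0),
                                    spec.shape, sigmas)
        e_with = _smooth_unit_noise(_rng(spec.seed, _STAGE_BACKGROUND, 1),
                                    spec.shape, sigmas)
        e_back = _smooth_unit_noise(_rng(spec.seed, _STAGE_BACKGROUND, 2),
                                    spec.shape, sigmas)
        s, s_i = spec.ratio_noise_sd, 0.5 * spec.ratio_noise_sd
        cmaq_fire = with_fire * np.exp(s * common + s_i * e_with)
        cmaq_back = nonfire_field * np.exp(s * common + s_i * e_back)
    else:
        cmaq_fire = with_fire.copy()
        cmaq_back = nonfire_field.copy()
    ratio_bg = BackgroundModel(kind="ratio", cmaq_fire=cmaq_fire, cmaq_back=cmaq_back)

    baseline = nonfire_field.mean(axis=0)
    if spec.baseline_drift_sd > 0:
        drift = _smooth_unit_noise(
            _rng(spec.seed, _STAGE_BACKGROUND, 3),
            (spec.grid_ny, spec.grid_nx),
            (spec.nonfire_corr_len, spec.nonfire_corr_len))
        baseline = baseline + spec.baseline_drift_sd * drift
    baseline_bg = BackgroundModel(kind="baseline", baseline=np.maximum(baseline, 0.0))
    return ratio_bg, baseline_bg


@dataclass
class RatesPopulation:
    """County map, annual rate table, tract table and population grid."""

    county_map: np.ndarray
    rates: pd.DataFrame
    tracts: pd.DataFrame
    population: np.ndarray
    total_population: int


def generate_rates_population(spec: ScenarioSpec) -> RatesPopulation:
    """Counties, annual admission rates and a clustered population.

    Counties partition the grid into contiguous nearest-seed (Voronoi)
    regions. Annual rates per 100,000 are drawn log-uniformly per county and
    outcome within :data:`RATE_RANGES`. Population is laid out in square
    tracts whose totals follow a few Gaussian density clusters over a sparse
    floor; each tract total is an exact multiple of its cell count so the
    equal-split regridding conserves the table total bit-exactly.
    """
    rng = _rng(spec.seed, _STAGE_RATES)
    ny, nx = spec.grid_ny, spec.grid_nx

    flat = rng.choice(ny * nx, size=spec.n_counties, replace=False)
    seed_y, seed_x = np.divmod(flat, nx)
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = ((yy[..., None] - seed_y) ** 2 + (xx[..., None] - seed_x) ** 2)
    county_map = np.argmin(d2, axis=-1).astype(int)

    rows = []
    for cid in range(spec.n_counties):
        for outcome, (lo, hi) in RATE_RANGES.items():
            rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append({"county_id": cid, "outcome": outcome,
                         "annual_rate_per_100k": rate})
    rates = pd.DataFrame(rows)

    centers = rng.integers(0, [nx, ny], size=(spec.n_pop_clusters, 2))
    radii = rng.uniform(3.0, 6.0, size=spec.n_pop_clusters)
    amps = rng.uniform(1500.0, 4000.0, size=spec.n_pop_clusters)
    intensity = np.full((ny, nx), 20.0)
    for (cx, cy), r, a in zip(centers, radii, amps):
        intensity += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * r ** 2))

    tract_rows = []
    tract_id = 0
    ts = spec.tract_size
    for y0 in range(0, ny, ts):
        for x0 in range(0, nx, ts):
            ys, xs = np.mgrid[y0:min(y0 + ts, ny), x0:min(x0 + ts, nx)]
            ys, xs = ys.ravel(), xs.ravel()
            n_cells = len(ys)
            raw = intensity[ys, xs].mean() * n_cells * rng.lognormal(0.0, 0.3)
            per_cell = max(int(round(raw / n_cells)), 0)
            total = per_cell * n_cells
            counties = county_map[ys, xs]
            county = int(np.bincount(counties).argmax())
            for y, x in zip(ys, xs):
                tract_rows.append({"tract_id": tract_id, "county_id": county,
                                   "x": int(x), "y": int(y), "population": total})
            tract_id += 1
    tracts = pd.DataFrame(tract_rows)
    population = regrid_population(tracts, (ny, nx))
    total_population = int(tracts.groupby("tract_id")["population"].first().sum())
    return RatesPopulation(county_map=county_map, rates=rates, tracts=tracts,
                           population=population, total_population=total_population)


@dataclass
class ScenarioData:
    """All generated inputs for one synthetic scenario."""

    spec: ScenarioSpec
    fire_field: np.ndarray
    nonfire_field: np.ndarray
    truth_total: np.ndarray
    surfaces: dict[str, ExposureSurface]
    ratio_bg: BackgroundModel
    baseline_bg: BackgroundModel
    county_map: np.ndarray
    rates: pd.DataFrame
    tracts: pd.DataFrame
    population: np.ndarray
    total_population: int

    def background(self, kind: str) -> BackgroundModel:
        if kind == "ratio":
            return self.ratio_bg
        if kind == "baseline":
            return self.baseline_bg
        raise ValueError(f"unknown background kind {kind!r}")

    def rate_population_grid(self, outcome: str) -> RateAndPopulationGrid:
        """Gridded daily rate + population for one outcome."""
        ynf = regrid_rates(self.rates, self.county_map, outcome)
        return RateAndPopulationGrid(ynf=ynf, pop=self.population,
                                     county_id=self.county_map, outcome=outcome)


def generate_scenario(spec: ScenarioSpec | None = None) -> ScenarioData:
    """Generate every pipeline input for one scenario spec."""
    spec = spec if spec is not None else ScenarioSpec()
    fire, nonfire = generate_true_fields(spec)
    truth_total = fire + nonfire
    surfaces = generate_method_surfaces(spec, truth_total)
    ratio_bg, baseline_bg = generate_background_inputs(spec, fire, nonfire)
    rp = generate_rates_population(spec)
    return ScenarioData(
        spec=spec, fire_field=fire, nonfire_field=nonfire,
        truth_total=truth_total, surfaces=surfaces,
        ratio_bg=ratio_bg, baseline_bg=baseline_bg,
        county_map=rp.county_map, rates=rp.rates, tracts=rp.tracts,
        population=rp.population, total_population=rp.total_population,
    )
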