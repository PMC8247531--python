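# Methods

## The assessment model

`smokehia` estimates hospital admissions attributable to wildfire-smoke PM2.5
over a multi-day fire window on a regular grid. The chain is:

1. **Fire-PM isolation.** Total PM2.5 `X(s,t)` mixes smoke with the ambient
   background. Two background methods isolate the fire-originated component
   ΔX:
   - *ratio zero-out*: an air-quality model run with and without fire
     emissions gives the background fraction `back(s,t)/fire(s,t)`; the
     background estimate is `XNF(s,t) = X(s,t)·back/fire` and
     `ΔX = X − XNF`. The with/without pair is an input, not re-estimated.
   - *baseline subtraction*: a static surface `XNF_base(s)` from a comparable
     non-fire period is subtracted: `ΔX = X − XNF_base`.

   Because the concentration–response functions (CRFs) are defined for 2-day
   average PM2.5, `X` and the daily `XNF` are each 2-day averaged before
   differencing, and negative differences are clamped to zero afterwards
   (the background estimate can exceed the total where the model or baseline
   is biased high). The alternative order — clamp daily, then average — is
   available behind `clamp_before_average`; the two differ only where the
   clamp is active, because `max(·,0)` is nonlinear. The first window day has
   no predecessor and keeps its own value rather than being dropped.
   Where the with-fire model concentration is numerically zero
   (< 10⁻⁶ µg/m³) the ratio is taken as 1, i.e. no fire signal, ΔX = 0.

2. **Health impact function.** From a log-linear admission-rate model,

       ΔY(s,t) = YNF(s) · (e^{β·ΔX(s,t)} − 1) · Pop(s)

   with `YNF` the background daily admission rate per person (annual county
   rate per 100,000, divided by 100,000 and by 365; leap years and seasonal
   rate structure are ignored), `β = ln(RR)/10` per µg/m³ from a CRF rate
   ratio per 10 µg/m³, and `Pop` persons per cell. Daily totals sum ΔY over
   cells; the window total over days. Estimates from CRFs with RR < 1 may be
   negative and are never clamped. All arithmetic is full precision; rounding
   to whole admissions (half-up) is presentation only. `Pop(s)` is a count
   per cell, which coincides with a density at 1-km cells.

3. **CRFs.** Two built-in families, both per 10 µg/m³ of 2-day average
   PM2.5: wildfire-specific rate ratios (respiratory 1.028, cardiovascular
   1.008, asthma 1.048, plus age strata for respiratory and age/sex strata
   for asthma) and ambient non-wildfire ones (respiratory 1.0207,
   cardiovascular 1.0189). Subgroup assessments are independent evaluations
   and are not constrained to sum to the all-population total.

4. **Monte Carlo uncertainty.** Two sources are propagated (100,000 draws by
   default):
   - *exposure*: each cell-day's total PM2.5 is lognormal with the surface's
     mean and estimation variance (method-of-moments:
     `σ² = ln(1+v/m²)`, `μ = ln m − σ²/2`; draws are generated as
     `m·e^{σz−σ²/2}` so zero-variance cells reproduce the mean exactly).
     Cells with zero mean but positive variance cannot carry a lognormal and
     are held at zero (counted and logged).
   - *CRF*: RR is lognormal, i.e. `ln RR` normal with sd
     `(ln RR_hi − ln RR_lo)/(2·1.96)`; β = lnRR/10 can go negative whenever
     the CI straddles 1, which is what produces negative lower bounds on
     admission counts. A literally lognormal β could not produce them.

   Each draw resamples the daily total field, re-runs isolation, averaging
   and the impact function, and resamples β; the CI is the empirical
   2.5–97.5 percentile interval (linear interpolation) of the window totals.
   The point estimate is the plug-in run at mean inputs — consistent with
   asymmetric intervals around a central value. Background fields, population
   and baseline rates are held fixed (their uncertainty is small, not
   time-variant, or unavailable).

   **Spatial sampling mode.** Whether exposure errors should be drawn
   jointly or independently across cells is a genuine modeling choice. The
   default is *comonotonic*: one standard-normal deviate per draw drives all
   cells through their own lognormal quantiles, preserving full spatial
   correlation of the exposure error. Independent per-cell sampling
   (available via `exposure_sampling_mode="independent"`) averages the error
   away in regional sums, making exposure uncertainty nearly vanish — which
   would contradict the premise that a noisy surface yields noisy totals.

5. **Sensitivity matrix and decomposition.** The default matrix is the base
   case (data-fusion total, ratio background, wildfire CRF, both uncertainty
   sources) plus ten alternatives changing one input at a time: two
   alternative totals (kriging, raw CTM), the baseline background, the
   ambient CRF, and six single-uncertainty-source runs (three totals ×
   {CRF only, exposure only}). The decomposition compares CI widths under
   {both}, {CRF}, {exposure}: the dominant source is the single source with
   the wider CI, and `width_increase_adding(src)` reports how much wider the
   both-sources CI is than the other single-source CI.

## The synthetic scenario generator

No real exposure surfaces, county rates or census tables ship with the
package; a generator produces inputs with the statistical structure the
analysis assumes. Defaults (the reference scenario):

| parameter | default | meaning |
|---|---|---|
| grid | 40×40 cells, 1 km | desk-scale study region |
| window | 13 days | multi-day fire episode |
| counties | 6 | contiguous nearest-seed partition |
| background | 7 µg/m³ | smooth lognormal field, 10% relative sd |
| plumes | 2 sources, peaks 90 and 60 µg/m³ | drifting Gaussians, ~5–7 km spread, e-folding decay 6–7 days |
| variance factors | datafusion 0.25, kriging 1.5, ctm 6.0 | method precision ordering |
| noise sd | (1 + 0.12·truth) µg/m³ × √factor | heteroscedastic, smoothed over 3 cells |

The truth decomposes exactly as fire + non-fire; method surfaces add
spatially correlated noise (smoothed white noise on a torus, renormalized by
the kernel's l2 norm so the per-cell variance is exactly the declared
variance field). The variance factors were fixed from a back-of-envelope
comparison with the CRF's own uncertainty (≈24% coefficient of variation for
the wildfire respiratory CRF): data fusion sits well below it, the raw CTM
well above, kriging near it — so the decomposition spans the regimes the
pipeline is designed to expose. The with/without-fire pair carries shared
multiplicative lognormal noise (sd 0.05, plus half that independently per
field); the static baseline is the time-averaged non-fire truth plus a
smooth ~1 µg/m³ perturbation standing in for year-to-year background drift.
County annual rates are log-uniform within roughly an order of magnitude of
typical U.S. values (respiratory 400–4,000, cardiovascular 600–6,000, asthma
30–300 per 100,000). Population lives in 4×4-cell tracts whose totals follow
a few Gaussian density clusters over a sparse floor; tract totals are exact
multiples of the tract cell count so equal-split regridding conserves the
total bit-exactly.

What the generator does **not** emulate: atmospheric chemistry or
meteorology, realistic plume shapes beyond Gaussians, correlation between
exposure error and population, evacuation or time-activity behaviour,
subgroup-resolved rates/populations, or the spatial covariance structure of
any particular estimation method (the correlation length is a free
parameter). Passing tests therefore demonstrate correctness of the
assessment arithmetic and the qualitative uncertainty behaviour, not
fidelity to any real fire episode.

## Numerical choices

- Percentiles (exposure 95th, Monte Carlo CI bounds) use linear
  interpolation of the empirical distribution.
- Ratio guard ε = 10⁻⁶ µg/m³ on the with-fire model field.
- Rounding is half-away-from-zero, applied only in presentation columns.
- County-table ties are broken by county id.
- Monte Carlo draws are chunked (≈4M array elements per chunk) and
  vectorized over draws; identical configuration and seed give bit-identical
  results.
- Problem sizes in the shipped checks: unit tests mostly run a 10×10×5
  scenario; Monte Carlo property checks and the acceptance script use the
  40×40×13 reference scenario with 100,000 draws for base-case CIs and
  20,000 for the sensitivity matrix and decomposition, where only widths and
  orderings — stable well below 100,000 draws — are compared.

## Known limitations

- The order of 2-day averaging vs clamping is a convention; both are
  implemented but results differ slightly where backgrounds exceed totals.
- The averaging-then-isolating commutation holds only where the clamp is
  inactive; with heavy clamping the pipeline's choice (clamp after
  averaging) is the defining one.
- Exposure draws are either fully comonotonic or fully independent; no
  intermediate spatial correlation model for the error field is offered.
- The annual→daily rate conversion is uniform over the year.
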