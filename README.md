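# smokehia

Health impact assessment of wildfire-smoke PM2.5 exposure: how many hospital
admissions did a fire episode cause, and how sure can we be?

Wildfire smoke raises fine-particle (PM2.5) concentrations to hazardous
levels over large regions for days to weeks. Given a gridded daily surface of
total PM2.5 (with per-cell estimation variance), a background model, county
baseline admission rates and a population grid, `smokehia`:

1. **isolates fire-originated PM2.5** (ΔX) by either of two background
   methods — *ratio zero-out* (`ΔX = X − X·back/fire`, using an air-quality
   model run with and without fire emissions) or *baseline subtraction*
   (`ΔX = X − XNF_base` for a static non-fire-period surface) — with 2-day
   averaging to match the epidemiology and a zero-clamp on negative values;
2. **applies the log-linear health impact function**

       ΔY(s,t) = YNF(s) · (e^{β·ΔX(s,t)} − 1) · Pop(s),   β = ln(RR)/10 µg/m³

   with built-in wildfire-specific and ambient concentration–response
   functions (rate ratios per 10 µg/m³ of 2-day average PM2.5) for
   respiratory, cardiovascular and asthma admissions, including age and sex
   strata;
3. **propagates uncertainty by Monte Carlo** from both the exposure surface
   (per-cell lognormal from the reported estimation variance, spatially
   comonotonic by default) and the CRF (lognormal rate ratio), reporting
   empirical 95% intervals around the plug-in estimate;
4. **runs sensitivity and decomposition analyses**: an 11-configuration
   matrix changing one input at a time from the base case, and a CI-width
   decomposition showing whether the CRF or the exposure surface dominates
   the uncertainty.

It is aimed at environmental epidemiologists and air-quality researchers who
want a tested, reproducible implementation of this assessment chain. A
synthetic-scenario generator (drifting Gaussian plumes over a smooth
background, three estimation methods of graded precision, counties, rates and
clustered population) makes the whole pipeline runnable and testable without
any external data.

## Worked example

```python
import smokehia as sh

scenario = sh.generate_scenario(sh.ScenarioSpec(seed=42))
dx = sh.isolate_fire(scenario.surfaces["datafusion"], scenario.ratio_bg)
summ = sh.exposure_summaries(dx, scenario.population)
print(f"pop-weighted fire-PM2.5: {summ.pw_mean:.2f} ({summ.pw_sd:.2f}) ug/m3, "
      f"p95 {summ.p95:.2f}")

rp = scenario.rate_population_grid("respiratory")
res = sh.monte_carlo_assessment(
    scenario.surfaces["datafusion"], scenario.ratio_bg,
    sh.get_crf("respiratory"), rp,
    sh.McConfig(n_draws=20_000, seed=0))
print(f"respiratory admissions: {sh.round_half_up(res.point)} "
      f"(95% CI: {res.lo:.1f}, {res.hi:.1f})")

dec = sh.decompose_uncertainty(
    scenario.surfaces["ctm"], scenario.ratio_bg, sh.get_crf("respiratory"),
    rp, sh.McConfig(n_draws=20_000, seed=0))
print(f"dominant uncertainty source for the raw-CTM surface: {dec.dominant_source()}")
```

prints

```
pop-weighted fire-PM2.5: 8.36 (12.18) ug/m3, p95 34.49
respiratory admissions: 22 (95% CI: 11.1, 33.9)
dominant uncertainty source for the raw-CTM surface: exposure
```

Reading this: over the 13-day synthetic episode the population breathed on
average ~8.4 µg/m³ of fire-originated PM2.5 (heavily right-skewed — the 95th
percentile cell-day is ~34 µg/m³), which at a 2.8% admission increase per
10 µg/m³ yields 22 excess respiratory admissions; the asymmetric CI reflects
lognormal exposure draws and the CRF's CI. Swapping the precise data-fusion
surface for the noisy raw CTM shifts the dominant uncertainty source from
the CRF to the exposure surface itself — the pipeline's central qualitative
finding.

The same steps are available from a shell:

```sh
smokehia simulate --seed 42 --out scen/
smokehia isolate --scenario scen/ --method datafusion --background ratio --out dx.csv
smokehia mc-assess --scenario scen/ --outcome respiratory --draws 20000 --out results/
smokehia decompose --scenario scen/ --method ctm --out decomposition.csv
smokehia report --scenario scen/ --out results/      # full 11-row sensitivity matrix
```

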