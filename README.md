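# soarsel

Resource-selection analysis for soaring avian scavengers — from GPS
relocations to monthly kernel home ranges, habitat and ecoregion
selection ratios, soaring-meteorology covariates, and AICc-model-averaged
effect estimates.

Large obligate soarers such as condors and vultures select not only
terrestrial habitat (where carrion can be found and approached) but also
the *atmospheric* resources that make soaring flight cheap: convective
boundary-layer depth (maximum thermal height), the convective velocity
scale w\* (characteristic thermal updraft strength), and the wind speed
averaged over the boundary layer. `soarsel` implements the full analysis
chain needed to quantify both, and ships a synthetic-data generator with
closed-form ground truth so every stage can be validated end to end.

## The analysis

For each bird and calendar month with at least 100 hourly daytime fixes
(0500–2000 local):

1. **Utilization distribution (UD).** A fixed-kernel density estimate on
   a 100 m grid with a bivariate Gaussian kernel. The reference
   bandwidth is the normal-reference rule
   `h_ref = sqrt((s_x² + s_y²)/2) · n^(−1/6)`, and the working
   bandwidth `h_adhoc = m · h_ref` takes the smallest scanned multiplier
   `m ∈ {0.1, …, 1.0}` whose 99% volume isopleth is a single connected
   polygon (8-connectivity).
2. **Home range.** The 99% volume isopleth: the smallest set of
   highest-density cells holding 99% of UD mass.
3. **Selection ratios.** For each habitat class (and, at the coarser
   scale, each ecoregion) within the home range,

   `ln(rf) = ln(use / availability)`

   where *use* is the probability of occurrence in the unit and
   *availability* its share of home-range area. `ln(rf) > 0` is
   selection, `< 0` avoidance; the log makes a doubled and a halved
   ratio symmetric.
4. **Meteorology.** Thermal height, thermal velocity
   `w* = (g·z_i·Q₀/θ)^(1/3)`, and boundary-layer mean wind are averaged
   from mid-day values to monthly means per 12 km grid cell, then
   averaged over the cells overlapping each ecoregion.
5. **Models.** ln(rf) is the repeated measure in a linear mixed model
   with a random bird intercept and AR(1) within-bird residual
   correlation (chosen over compound symmetry by AICc). Habitat-scale
   effects of sex, age class, breeding status, release site and rearing
   method are screened at P < 0.01 (REML, between-within df). At the
   ecoregion scale, the 8 subsets of the three meteorological covariates
   define an AICc-ranked candidate set; Akaike weights give
   model-averaged coefficients, unconditional SEs, and per-parameter
   importance. A model-averaged slope β per unit covariate means
   selection changes by a factor `exp(β)` per unit — e.g. a thermal
   height slope of 1.080 per km multiplies rf by ≈ 2.95 per km.

## Worked example

```python
import soarsel as ss

scenario = ss.SyntheticScenario(
    seed=11, extent=(0, 0, 60_000, 60_000),
    habitat_weights={1: 1.0, 2: 2.0, 3: 4.0},   # known preference
    n_birds=20, months=[(2008, 7)], fixes_per_day=16,
)
habitat, _ = ss.generate_landscape(11, scenario.extent, n_classes=3,
                                   patch_scale=1000.0)
fixes, attrs, truth = ss.simulate_tracks(scenario, habitat)
panels = ss.build_panels(ss.window_filter(fixes), min_fixes=100)

p = panels[0]
m, ud, hr = ss.select_adhoc_bandwidth(p.points)
print(m, round(hr.mass, 4), hr.n_components)
# 0.5 0.99 1      <- smallest contiguous multiplier, 99% mass, one polygon

out = ss.studies.lnrf_recovery_study(seed=11)
print({k: round(v, 3) for k, v in out["contrasts"].items()})
# {(2, 1): 0.738, (3, 1): 1.413}   <- truth: ln 2 = 0.693, ln 4 = 1.386
```

The contrasts between class-wise mean ln(rf) recover the simulated
preference ratios (2× and 4×) to well within ±0.1, confirming the
UD → home range → selection chain end to end.

The same pipeline runs from files via the CLI:

```sh
soarsel simulate --seed 1 --outdir demo
soarsel all --fixes demo/fixes.csv --attrs demo/birds.csv \
    --habitat demo/habitat.asc --ecoregions demo/ecoregions.geojson \
    --met demo/met.csv --met-cells demo/met_cells.geojson --outdir demo_run
```

which writes the panel manifest, per-panel bandwidth report, selection
tables, zonal meteorology, effect-test and model-average tables, figures,
and a checksummed run manifest.

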