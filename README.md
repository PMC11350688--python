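# camtrap-rem

Camera-trap population analysis for unmarked ungulates, built around the
takin (*Budorcas taxicolor*) surveys of the Eastern Himalayas: independence
filtering of detections, random-encounter-model (REM) density estimation and
population extrapolation, circular kernel-density activity rhythms with
overlap coefficients, a minimal maximum-entropy habitat-suitability model on
1-km² grids, and seasonal elevation-migration profiling. Seeded synthetic
generators (an ideal-gas movement simulator, a survey-table generator, a
Gibbs-landscape generator) give every stage a quantitative truth to test
against.

It is written for ecologists who have camera-trap detection tables and
deployment metadata and want population densities and activity schedules for
species whose individuals cannot be told apart.

## The model

A camera's detection zone is a sector of radius *r* (km) and angle *θ*
(radians, θ ≤ π). Treating animals as randomly moving particles at density
*D* (km⁻²) with day range *v* (km/day), the expected number of independent
events *y* over *t* camera-days is set by the sector's mean profile width
*w̄* = *r*(2 + *θ*)/π (the Cauchy mean width, perimeter/π):

```
y / t = D · v · r · (2 + θ) / π        ⇒        D̂ = (y/t) · π / (v · r · (2+θ))
```

With a day-range bracket [v₁, v₂] the per-speed densities are averaged and
their spread gives a standard error; population size is *N* = *D̄* × habitat
area, with the habitat area taken from a suitability map thresholded at
index ≥ 0.5 (potential habitat 0.5–0.7, highly suitable 0.7–1.0). Daily
activity is the circular density of event times (24 h ≡ 2π), estimated with
a von Mises kernel; two schedules are compared by Δ = ∫ min(f, g), the
coefficient of overlap.

## Worked example

```python
from camtrap_rem.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig())   # packaged survey tables
print(report.tables["density"].to_string())
```

prints

```
               ips  camera_days   mcv      d1      d2  mean_density  se_density  area_km2  population  population_se
species
B. taxicolor  1685         1238  1.36  0.1738  0.1720        0.1729      0.0134   17314.0        2994            232
B. whitei     3152         1594  1.98  0.1429  0.1289        0.1359      0.0264   25006.0        3398            660
```

Reading the first row: 1685 independent events over 1238 camera-days give an
encounter rate (MCV) of 1.36 events per camera-day; the per-speed densities
d1 (v = 5 km/day) and d2 (v = 10 km/day) average to 0.1729 takins/km², and
extrapolating over the 17,314 km² distribution range gives a population of
2994 ± 232. The report also carries a flag: the published headline for this
row is 2995, while the arithmetic gives 0.1729 × 17,314 = 2993.6 — a 0.05%
discrepancy that the pipeline reports rather than hides. The d1/d2 and SE
columns and the areas are fixture inputs (they depend on undeposited rasters
and an undocumented unit convention); every other column is recomputed.

The numbered scripts under `analysis/` run the full set of analyses from the
repository root and write tables under `results/`:

```
python analysis/01_survey_accounting.py    # effort sums, report percentages
python analysis/02_density_population.py   # the table above + report text
python analysis/03_gas_model_validation.py # simulator vs closed form
python analysis/04_activity_rhythms.py     # KDE peaks, overlap, migration
python analysis/05_habitat_suitability.py  # maxent fit, areas, overlap ratio
```

For example, `04_activity_rhythms.py` on the default synthetic year finds
the generated double-peak schedule (peaks at 07.9 h and 17.9 h, overlap
Δ = 0.96 between the two species) and a rainy-season fraction of 0.98 of
events at ≥ 3500 m against 0.00 in the dry season — the altitudinal
migration signature the generator encodes.

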