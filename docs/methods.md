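# Methods

This note records the models implemented in `camtrap_rem`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter.

## Independence filtering

Camera-trap triggers arrive in bursts (here, three photos plus a video per
trigger), so event counts are built by merging records of one species at one
station unless separated by a configurable window.

* **Window**: default 30 minutes. The field literature offers no single
  value; 30 min is the most common camera-trap convention and is exposed as
  a parameter (`window_minutes`).
* **Gap semantics**: the gap is measured from the *start* of the current
  event (default), which makes the partition independent of burst length and
  order-stable; a sliding `rule="last"` variant is provided for comparison.
* **Day/night**: a fixed clock window, default [06:00, 18:00), half-open so
  boundary times classify deterministically. No solar correction is applied
  (no longitude-based transform is defined for these surveys).
* Group events count once toward the event total regardless of group size;
  the largest simultaneous count is kept for composition statistics.
* Records outside their station's deployment interval are excluded, counted
  and returned — never silently dropped — so the partition invariant
  (records in events + excluded = input) is checkable.
* Paired cameras on one transect closer than 500 m can double-count a pass;
  since merging them is a judgement call in the field, `station_pair_qc`
  only flags candidate pairs for review.

Report percentages round half-up at 2 decimals (`round_half_up`), matching
how survey tables are printed; Python's banker's rounding would differ on
exact ties. One published composition share (sub-adults, 11/47) appears in
print as 22.40%; the arithmetic value is 23.40% and that is what the package
returns, treating the printed figure as a typo.

## Random encounter model

The REM converts an encounter rate into a density for animals that cannot be
individually identified, by the ideal-gas analogy: particles at density D
moving at speed v cross a stationary convex region at rate D·v·(perimeter/π).
For a sector of radius r and angle θ ≤ π the perimeter is r(2+θ), giving

    E[y/t] = D v r (2+θ) / π,    D̂ = (y/t) π / (v r (2+θ)).

Assumptions: animals move independently of cameras and of each other,
headings are isotropic, the detector is small relative to daily travel, and
every pass through the sector triggers exactly one independent event.

* **Geometry defaults**: r = 0.01 km, θ = 0.872 rad (50°), the surveyed
  camera model's zone. θ is restricted to (0, π]: beyond π the sector is no
  longer convex and the mean-width formula does not apply.
* **Day range**: v is a daily travel distance treated as speed over the
  24-h day; no activity-time correction is applied, because the encounter
  rates the estimator consumes are per raw camera-day. The field bracket
  5–10 km/day is carried as two candidate speeds whose densities are
  averaged. The average is exactly unbiased when the true day range equals
  the harmonic mean of the bracket (20/3 km/day here) — a property the
  synthetic survey generator uses as its default travel distance.
* **SE of the mean density**: the printed SEs in the source table are not
  derivable from the printed per-speed pairs, so the combination method is
  configurable: the default treats the k candidate speeds as the replicate
  axis (sample SD/√k); a conservative half-range variant is available.
* **Population**: N = D̄ × area, SE_N = SE_D × area, rounded half-up to whole
  animals. The comparison of two groups of replicate densities is a one-way
  ANOVA (between-group df = 1; equal to the squared two-sample t).

The published per-speed densities themselves cannot be reproduced from the
stated v, r, θ (the printed formula text is corrupted and the printed values
are ~170× smaller than the formula yields, suggesting an undocumented unit
conversion). They are therefore carried as fixture inputs, tagged
`[fixture input]` in reports, and only the arithmetic downstream of them
(means, SE combination, populations) is recomputed. The same applies to the
published habitat areas and ANOVA F values, which depend on undeposited
rasters and an unstated replicate structure.

## Ideal-gas simulator

`simulate_gas_model` makes the gas analogy executable so the estimator can
be validated rather than assumed. Point animals are placed uniformly on a
square torus (no edge loss, so the closed-form rate is exact) and move at
constant speed; the "straight" turn model draws a fresh uniform heading at
each day boundary, the "correlated" model perturbs the heading by a von
Mises(0, κ) increment each time step. Detectors are fixed sectors at random
positions and azimuths; an encounter is an *entry* of a path into a sector.

Numerical choices:

* Detection is computed exactly on the straight segments between turn
  events: the segment is clipped against the sector's two half-planes and
  tested against the radius, under the minimal-image convention (the arena
  must exceed twice the per-turn travel distance, which is validated).
  Convexity guarantees at most one entry per segment, so no step-size
  tunnelling is possible. The configured time step is still validated
  against the classical guard (step length < r/2) so configurations remain
  valid for position-sampled detectors too.
* A midpoint distance broad phase discards the vast majority of
  segment–detector pairs; work is chunked over days to bound memory.
* The realized density n/L² (integer animal count) is the truth the
  estimator is compared against, not the requested density.

With 100 detectors × 10,000 days at D = 0.2 km⁻², v = 5 km/day, the
estimator recovers the realized density within ~1–2% (Monte-Carlo error at
~9,000 encounters); across a 3×3×3 grid of density, speed and sector angle,
1,000-block Monte-Carlo confidence intervals for the bias cover zero (the
per-cell level is 99.9% so the 27-cell family-wise false-alarm rate stays
below ~3%). Blocks of a single long run are used as replicates; daily
heading redraws make successive blocks effectively independent.

## Activity rhythms

Event times are samples from a circular density over the day because cameras
operate continuously. The estimator is a von Mises kernel mixture:

* **Bandwidth**: the kernel concentration follows the circular plug-in rule
  ν = [3n κ̂² I₂(2κ̂) / (4√π I₁(κ̂)²)]^(2/5), with κ̂ from the mean resultant
  length (standard large/small-κ approximations), an `adjust` multiplier
  (default 1), and a small floor (0.1) so near-uniform samples stay proper.
* **Grid**: 512 intervals of the circle, with the period closed (513rd point
  repeats the first) so a trapezoidal integral over one period is the total
  mass; the density is renormalized by that integral, keeping it at 1 to
  machine precision for smooth mixtures. Densities evaluated off-grid use
  periodic linear interpolation.
* **Overlap**: Δ = ∫ min(f̂_A, f̂_B) on the common grid (a finer interpolated
  quadrature variant is available as a cross-check). Δ of two large samples
  from known von Mises laws lands within 0.02 of the exact integral of the
  true minimum.
* **Peaks**: local maxima found on an unwrapped triple of the period (so a
  midnight mode is not split), filtered by an absolute prominence (default
  0.02 per radian), each reported with the contiguous interval where the
  density exceeds the circular mean 1/(2π).

Elevation zones follow the regional vertical vegetation belts (<1100
tropical rainforest; 1100–2300 subtropical broad-leaved; 2300–2900
warm-temperate mixed; 2900–3800 cold-temperate conifer; 3800–4200 alpine
shrub meadow; 4200–4800 alpine frost; ≥4800 ice/snow), half-open and
lower-inclusive so printed boundary elevations classify deterministically.
The migration profile is a month × zone count matrix plus the fraction of
events at or above a cut (default 3500 m) in the rainy (May–October) versus
dry season.

## Habitat suitability

A deliberately minimal maximum-entropy model: over non-masked grid cells,
p(cell) ∝ exp(Σ_j λ_j f_j(cell)) with standardized linear features only.
Quadratic or interaction features, clamping and projection — the machinery
of full MaxEnt releases — are out of scope; linear features keep the model
convex and make an exhaustive-search oracle tractable.

* **Penalty**: L2 with strength α (default 0.1). At the optimum the model
  feature expectation differs from the presence mean by exactly αλ_j, a
  bounded slack analogous to MaxEnt's L1 regularization but smooth, fitted
  by L-BFGS-B with an analytic gradient and log-sum-exp stabilization. The
  objective trace is recorded per accepted iterate (non-increasing), and
  non-convergence is reported through a flag, never silently.
* **Background**: all non-masked cells (no subsampling; synthetic grids are
  small). Constant layers standardize to zero and drop out, so a featureless
  landscape yields a uniform distribution.
* **Suitability transform**: complementary log-log, 1 − exp(−e^H·p) with H
  the entropy of p (the convention of recent MaxEnt versions), or raw
  p/max(p); both live on [0, 1].
* **Classes**: unsuitable [0, 0.5), potential [0.5, 0.7), highly suitable
  [0.7, 1.0]; the "distribution range" is index ≥ 0.5. Boundaries are
  lower-inclusive because the printed ranges overlap at their endpoints.
  Areas are qualifying-cell counts × cell resolution (default 1 km²).
* **Overlap ratio**: both maps thresholded, the shared area divided by each
  species' own range area, rounded to 1 dp in report mode (the printed
  "0.4:0.3" convention). The published ratio's base is ambiguous
  (own-range share vs union share); own-range shares are what the function
  returns, and the alternative is one line of arithmetic on the same masks.

Rasters are read and written as ESRI ASCII grids with a NODATA value — a
plain-text format every GIS ingests.

## Synthetic generators: what they emulate and what they do not

`generate_detection_table` emulates the survey's statistical structure:
per-station-day Poisson event counts at the REM-expected rate for the
configured true densities (defaults 0.173 and 0.136 km⁻², the magnitudes of
the two study populations), a bimodal von Mises schedule (modes 08:00 and
18:00, matching morning 07:00–09:00 and evening 16:00–20:00 activity),
seasonal elevation targeting (rainy N(4000, 200) m, dry N(2000, 300) m,
events assigned to the station nearest the target), three-record bursts per
event, and a 90-minute minimum gap between events at one station so the
independence filter can recover the exact generated event count.

It does **not** emulate: spatial autocorrelation between stations, detection
failure or imperfect trigger probability, group-size variation, camera
downtime, species misidentification, or weather-driven activity shifts.
Passing tests therefore demonstrate that the estimators are correct under
their own assumptions — not that those assumptions hold in any particular
field dataset.

`generate_landscape` draws Gaussian-field layers (white noise blurred with a
Gaussian kernel, wrap-around boundary) and presences from the implied Gibbs
law; it retains the exact probability surface so rank-correlation recovery
is a well-defined target. Real environmental layers are collinear and
non-Gaussian in ways these fields are not.

All generators and the simulator are deterministic given their integer seed
(`numpy.random.default_rng` throughout).

## Problem sizes

The default validation sizes — 100 detectors × 10,000 days for the headline
gas-model check, 10-day × 1,000-block replicates on the 3×3×3 grid, 2,000
samples for peak recovery, 8,000 for overlap calibration, a 50×50 landscape
with 200 presences — were chosen so Monte-Carlo error sits well inside each
check's tolerance while the full suite stays comfortably runnable on a
single CPU.

## Known limitations

* The REM assumes every sector pass yields exactly one independent event;
  no detection-probability or group-size correction is fitted.
* The two-speed SE understates uncertainty from the encounter rate itself
  (no bootstrap over stations is implemented).
* The activity estimator uses clock time; solar time would shift peaks by
  longitude and season.
* The maximum-entropy model is linear-feature only and unprojected; it is a
  statistical stand-in for full MaxEnt workflows, suited to method testing
  and small grids rather than production range mapping.
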