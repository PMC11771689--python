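# Methods

This note documents the models behind `fenceflow`, the choices made where
the design was genuinely open, and what the synthetic experiments do and do
not demonstrate.

## Habitat selection model

Use–availability design: every GPS fix is a presence; each presence is
paired with `pseudo_ratio` (default 50) pseudo-absences placed
**area-uniformly** (radius ∝ √u) in the disk of radius equal to that
animal's maximum observed step length, clipped to the landscape. Time-varying
covariates (NDVI, ΔNDVI) are matched to the presence fix's timestamp by
linear interpolation between the two nearest 16-day composites; absences
inherit the presence's timestamp.

The model is a binomial GLMM with logit link: fixed effects for each
covariate (plus a quadratic term for every distance covariate) and a
per-animal random intercept. Estimation is a Laplace/MAP fit
(`BinomialBayesMixedGLM.fit_map`); if it fails or returns non-finite values
the model falls back to fixed-effects logistic regression with animal
indicator variables (a tiny ridge, 1e-8, stabilizes near-separated designs),
flagged in `fit_meta["method"]`. The MAP optimizer's random start for the
random-effect block is drawn with a pinned RNG state so fits are
deterministic. Covariates are z-scored before fitting; the scaler is stored
with the coefficients and reapplied at prediction, and quadratic terms are
squares of the standardized linear term (`standardize_beta` maps raw-scale
coefficients exactly onto this basis for recovery comparisons).

**Intercept correction.** A use–availability logistic intercept absorbs
`-log(n_absence/n_presence)`; left uncorrected, predicted "suitability"
shrinks toward `1/(1+ratio)` (≈0.02 at 50:1) and the linear inverse map
below would produce a nearly flat resistance surface whose structure depends
on an arbitrary sampling ratio. `predict_suitability` therefore adds
`log(n_absence/n_presence)` back by default (disable with
`correct_sampling_ratio=False`); the correction is recorded in `fit_meta`.
Prediction sets the random intercept to zero (population level), NDVI to its
series mean, ΔNDVI to a named snapshot (default mid-series, a green-up
proxy), and clamps output to (0, 1) at machine epsilon.

## Resistance surface

Resistance is inverted suitability. The default is the linear map
`r = r_max − (r_max − r_min)·s` with `r_min = 1`, `r_max = 100`, which makes
the fence barrier value 100 the natural ceiling and keeps resistance
bounded; a `reciprocal` mode (`clip(1/s, r_min, r_max)`) is available. The
functional form of "inverse" is a modeling choice recorded in the raster's
metadata.

Fences are rasterized with a supercover rule: every cell whose closed square
the polyline touches becomes a barrier — conservative for a barrier feature.
Interiors of fully enclosed parcels are filled to the barrier value as well.
All fences are treated as equally impermeable (resistance 100, "no
movement"), a worst-case assumption; non-barrier cells pass through
bit-identically.

Parcel detection nodes all fence polylines into a planar arrangement
(`unary_union` + polygonization) and keeps a bounded face as a parcel when
its boundary uses ≥ 3 distinct original fence lines, or when it lies wholly
inside another enclosed parcel (nested parcels, flagged). Areas are reported
in m² and acres (1 acre = 4046.8564224 m²).

## Circuit solver

Each valid cell is a node; 4-neighbor edges have conductance
`1/((r_i+r_j)/2)` (the average-resistance convention). Focal regions are
contracted to zero-internal-resistance supernodes. For a pair, one unit of
current is injected at the source and the ground row/column eliminated; the
reduced sparse system is solved by direct LU factorization — exact to
machine precision and deterministic, which the test suite verifies against
an independently coded dense solve on small random grids (≤8×8, 1e-8) and
closed forms for series/parallel networks. Per-cell current is half the sum
of absolute incident edge currents (counting pass-through once); member
cells of the injection pair report the injected 1.0. Barrier cells stay in
the graph at finite resistance 100 rather than being removed. Disconnected
pairs return infinite effective resistance and a zero map with a warning,
not an exception.

Cumulative current sums the per-pair maps over all unordered focal pairs.
Corridors are cells **strictly above** the (1 − top_fraction) quantile of
valid cells (default top 10%); the quantile rule, not any absolute current
value, is the operative definition, since the current scale depends on the
injection normalization.

## Restoration scenarios

A scenario buffers a corridor centerline by width/2 (flat caps) and deletes
fence-line portions inside the buffer, clipping at the boundary — removal
effort counts only the inside length. The fenced resistance surface is
rebuilt from the post-removal network and the circuit re-solved. Improvement
is `100·(S_scenario − S_fenced)/(S_pre − S_fenced)` where `S` is cumulative
current summed over the region of interest; it may exceed 100 if a scenario
outperforms the pre-fencing baseline there, and is undefined (error) when
fencing caused no loss. Cost is `unit_cost` (default US$75/acre) times the
enclosed-parcel area intersecting the buffer. Results are ranked by
improvement per dollar. Evaluation is a pure function of
(network, corridor, width): reruns are bit-identical.

## Validation design

Each metric raster (suitability, pre-fencing current, fenced current,
current change) is sampled at presence and pseudo-absence points
(nearest cell; invalid rows dropped and counted) and fitted as
`t(metric) ~ presence + (1|animal)` with a linear mixed model. Transforms:
logit for suitability (in place of a beta-error GLMM; recorded in the
output), log for current (offset = half the smallest positive sampled value
when zeros occur), identity for change. Local scale restricts rows to the
restoration region of interest; regional uses all rows. A degenerate mixed
fit falls back to OLS, recorded in the `model` column.

## Synthetic world

`generate_covariates` builds unit-variance Gaussian random fields by
smoothing white noise (smoothing scale = `correlation_length`), an AR(1)
16-day NDVI series, and exact Euclidean distance transforms from generated
rivers, woodland patches, and roads. `generate_fences` places
non-overlapping rectangular parcels (four fence lines each) preferentially
in high-suitability cells plus non-intersecting open distractor lines.
`simulate_trajectories` draws gamma step lengths (moment-matched; defaults
11 km mean, 9 km SD at 3-h fixes; validation collars 17.3/8.8 km at 4 h)
with uniform turning angles, evaluates `exp(β·x)` at candidate destinations,
and excludes candidates whose straight-line step crosses a fence; if all are
excluded the animal stays put (logged). Animals never start inside an
enclosed parcel. Optional extras: a `uniform_disk` kernel (below) and
migratory taxis toward alternating seasonal targets.

### The severed-corridor study system

`make_fenced_world` constructs a landscape whose ground truth is known: a
70×70 grid at 200 m (14×14 km); three east–west high-suitability corridor
bands (Gaussian TWI ridges, σ = 3 cells) plus one unfenced southern detour
route of equal habitat quality; west/east focal strips spanning the full
margin so every route is a parallel path between the ranges. True selection
(`β_TWI = 0.6` per TWI unit on a ridge of height 7, background noise damped
to SD 1) gives suitability ≈0.9 on bands and ≈0.12 in the matrix
(resistance ≈11 vs ≈88). Each band is crossed by a 2.4×2.8 km block of
contiguous 400-m enclosed parcels at a band-specific longitude; fencing
diverts current to the southern route, which lies outside the rectangular
region of interest covering the three corridors, so the diversion registers
as local connectivity loss (~1–3% of ROI current). A `fences_partial`
network (a 40% random subset of the wall parcels) represents the
fence-expansion era from which validation movement is simulated: those
animals still use the historic corridors that the complete network later
severs, which is what produces the positive regional-connectivity and
negative local-change presence coefficients in the validation experiment.
Band spacing (15 cells) exceeds the wall arm plus the widest corridor
buffer, so adjacent corridors' scenarios do not interact.

The world is deliberately scaled down — a 4,900-cell grid and kilometer-
scale corridors rather than an ecosystem-scale raster — so that a full
12-scenario grid solves in seconds; the circuit mathematics is
scale-invariant, and solver exactness is established separately against the
dense oracle.

### What the experiments show (and don't)

- **Parameter recovery** uses the `uniform_disk` kernel with a disk
  covering the landscape and ~200+ in-bounds candidates per step, so the
  simulation's availability distribution matches the pseudo-absence design
  and the pooled-logistic estimand equals the simulated truth; ≥90% of
  coefficients then fall within 2 SE over replicates. Under the default
  gamma kernel the estimand is a kernel-weighted selection contrast —
  attenuated relative to the step-level truth — which is a property of
  use–availability designs on autocorrelated movement, not of this
  implementation.
- **Scenario monotonicity** (improvement non-decreasing in width) holds on
  the constructed world; it is a consequence of Rayleigh monotonicity plus
  a region of interest that contains the restored routes. It is not a
  theorem for arbitrary ROIs: summed ROI current can fall when removal
  re-routes flow more efficiently through fewer cells.
- Passing on the synthetic world demonstrates internal statistical
  coherence, not realism of any particular ecosystem: real covariates are
  not Gaussian fields, real fences are not rectangles, and real movement
  has behavioral states the gamma/uniform kernel ignores.

## Numerical conventions

Row 0 is the northernmost raster row; coordinates are projected meters; all
randomness flows from explicit integer seeds through `numpy` Generators
(derived seeds stay below 2³¹). Rasters round-trip through plain-text ESRI
ASCII grids at float precision `%.10g`; vector data round-trip through
GeoJSON with geometry preserved exactly. Quantile thresholds use numpy's
linear-interpolation quantile with a strict `>` mask. Degenerate inputs
(single-fix or never-moving trajectories, single-animal tables, one-class
tables, focal regions covering no valid cell, constant current maps,
disconnected focal pairs) raise informative errors or warnings rather than
propagating silently.
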