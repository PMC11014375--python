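# Methods

`spatial-al` implements and evaluates a spatially explicit active-learning
(AL) strategy for crop-type classification from monthly NDVI time series.
This note describes the model and procedure, the parameters that matter, what
the synthetic benchmark does and does not emulate, and the numerical choices
made where the design was open.

## The method

**Pool-based query-by-committee.** The learner keeps a labeled pool L and an
unlabeled pool U of point samples, each described by 12 monthly NDVI values.
A committee of C random forests (default C = 2), each trained on its own
bootstrap resample of L, votes on every candidate in U. Candidates are ranked
by vote entropy

    VE(x) = − Σ_y (V(y)/C) · ln(V(y)/C),

where V(y) is the number of members voting class y. VE is 0 when the
committee is unanimous and ln C when every member disagrees; with C = 2 it is
binary (0 or ln 2), so ties are ubiquitous and are broken by a seeded random
permutation within each entropy level. The top candidate is queried, receives
its oracle label, joins L, and the committee is retrained.

**The spatial filter.** Spatial autocorrelation makes neighboring samples
partially redundant: they share low-frequency reflectance structure (soil,
management, moisture) and contribute less new information than their count
suggests. The semi-variogram quantifies this: the empirical Matheron
estimator

    γ̂(h) = Σ_{pairs at lag h} (z_i − z_j)² / (2 N(h))

is computed per month from the NDVI values of the training samples on
equal-width lag bins up to half the maximum pairwise distance, keeping only
bins with at least 30 pairs (`min_pairs`). Spherical, exponential and
Gaussian models are fitted by weighted least squares (weights = pair counts;
uniform weights available), the per-month fit with the lowest nugget is
selected, and the smallest fitted range across the 12 months becomes the
admissibility threshold. In spatial mode a queried candidate is accepted only
if its Euclidean distance to *every* labeled sample is at least this
threshold; anything closer is discarded permanently (L only grows, so a
discarded candidate could never become admissible later).

**Stopping.** The committee's majority-vote accuracy on the remaining
unlabeled pool (the largest label-available set that does not touch the test
split) is recorded after every accepted query. The loop stops when the best
accuracy in the last `stop_window` accepted queries (default 10) exceeds the
accuracy at the window's start by less than `stop_epsilon` (default 0.001),
when no admissible candidate remains ("exhausted"), or when U empties.

**Evaluation protocol.** Four training sets feed a final random forest
(`ntree` = 1000, `mtry` = ⌊√p⌋, `n_repeats` = 50 independently seeded fits by
default): (1) the full training pool; (2) the spectral-AL selection; (3) the
spatially explicit AL selection; (4) a uniform random draw matched in size to
(3), redrawn each repeat so its mean is an average over draws as well as
forests. Metrics are overall accuracy (OA), Cohen's Kappa, and per-class
user's (precision on predictions) and producer's (recall on reference)
accuracies; classes with an empty predicted row or reference column are
reported as NaN rather than zero so means are not silently deflated. The
train/test split is parcel-disjoint and class-stratified (largest-remainder
rounding of the parcel count per class; a single-parcel class goes to train
with a warning), because within-parcel pixels are spatially dependent and a
random point-level split would overestimate accuracy.

## Model-family parameterization

No closed forms are implied by a family name alone; the package uses the
*effective-range* convention so the fitted `range_m` is comparable across
families as a distance:

- spherical: γ(h) = c₀ + c·(1.5 h/a − 0.5 (h/a)³) for h ≤ a, else c₀ + c
- exponential: γ(h) = c₀ + c·(1 − e^{−3h/a})
- Gaussian: γ(h) = c₀ + c·(1 − e^{−3h²/a²})

with nugget c₀, partial sill c and range a; γ(0) is reported as the nugget
(limit-from-above convention, since zero-distance pairs are excluded from
estimation). The exponential and Gaussian models reach 95% of the sill at
h = a. A consequence worth knowing: when data are generated by a spherical
process, the exponential fit often attains the lowest nugget and its
effective range overshoots the spherical truth by ~20–50%, so the
lowest-nugget selection rule yields a conservative (larger) threshold.

Fitting minimizes SSErr = Σ_j w_j (γ̂_j − γ_model(h_j))² with a trust-region
least-squares solver (`scipy.optimize.least_squares`) from five deterministic
starts, bounded below by 0 for all parameters and above by 2·max_lag for the
range. A quasi-Newton box-constrained minimizer was found to stall in local
minima where the nugget absorbs the sill; the trust-region solver's fits were
verified against a brute-force parameter grid. At least 3 retained lag bins
are required to fit the 3 parameters; estimation itself succeeds with fewer.

## The synthetic benchmark

Real reference data for this problem (national parcel registries plus
Sentinel-2 imagery) are not redistributable, so the package ships a generator
whose output has the statistical structure the method assumes, with known
ground truth:

- **Parcel mosaic** — Voronoi cells of uniform random seeds clipped to the
  extent (or a regular grid), each assigned one crop class, every class
  owning at least one parcel.
- **Seasonal profiles** — piecewise-linear NDVI trajectories (baseline, rise
  from season start to a peak of baseline + amplitude, fall back to baseline
  at season end). Piecewise-linear rather than double-logistic: simpler, and
  sufficient to create the inter-class similarity structure that matters for
  the committee.
- **Spatially autocorrelated residuals** — one independent zero-mean
  Gaussian random field per month, drawn exactly by Cholesky factorization of
  the covariance C(h) = sill − γ(h) implied by a user-set variogram model
  (the nugget acts as an independent component per location). One field per
  month, with no temporal correlation of residuals, because each month's
  variogram is fitted independently downstream.
- **iid noise and clipping** — additional measurement noise
  (`iid_noise_sd`), then clipping to [−1, 1] (events logged) to keep the
  NDVI invariant.

The default benchmark (`default_benchmark_config`) uses 7 crop classes × 50
samples on a 5 km × 5 km mosaic of 110 parcels. Two classes (a maize and a
potato analogue, amplitudes 0.58 vs 0.60 on the same calendar) are
near-identical so that their mutual confusion dominates — the regime where
committee disagreement is informative. The residual field is spherical with
range 400 m, nugget 0.0005 and partial sill 0.006 (pointwise sd ≈ 0.08, the
order of published per-class NDVI standard-deviation bands over cropland).
Published *pooled-sample* variogram sills are an order of magnitude larger,
but they include between-class variance; the generator produces that
component separately through the parcel mosaic of class means, so the
residual field must carry only the within-class part. With ~350 samples on
this extent the typical nearest-neighbor spacing (~270 m) sits below the
field range, so the pool genuinely contains spatially redundant samples —
the situation the filter exists for — and the packing-exhaustion point of
the spatial filter sits just below the spectral plateau.

What the generator does **not** emulate: cloud/gap artifacts, radiative
transfer, within-parcel management gradients, temporal residual correlation,
irregular parcel shapes beyond tessellation, and regional trends. Passing
benchmarks therefore demonstrate the machinery and its relative ordering
under controlled spatial structure, not absolute accuracies on real imagery.

## Defaults and units

| parameter | default | unit | why |
|---|---|---|---|
| committee size C | 2 | members | small committees suffice for QBC; two RF members |
| committee trees | 100 | trees | retrained every query; lighter than the final classifier |
| n_initial | 40 | samples | typical initial pool for a few hundred candidates |
| min_pairs | 30 | pairs/lag | reliability floor for γ̂ per bin |
| n_lags | 15 | bins | resolution vs. per-bin pair count |
| max_lag | half max pairwise distance | m | standard practice; γ̂ unstable beyond |
| stop_window / stop_epsilon | 10 / 0.001 | queries / accuracy | plateau detection |
| ntree / mtry / n_repeats | 1000 / ⌊√p⌋ / 50 | — | final-classifier convention |
| field model (benchmark) | spherical(0.0005, 0.006, 400 m) | NDVI², m | within-class residual, see above |
| iid_noise_sd | 0.02 | NDVI | sensor-scale noise |

Distance exactly equal to the threshold is admissible (strictly "below"
discards). Committee majority ties go to the lower-index member. Nugget ties
in per-month selection break by smaller SSErr, then family order spherical <
exponential < Gaussian. The initial pool is drawn unstratified by default
(`stratified_initial=True` available). Queries are single-sample; batch
selection is out of scope.

## Problem sizes in tests and the acceptance script

Stochastic checks run at desk scale, chosen as the package's own trade-off
between statistical resolution and turnaround: range recovery uses 10
simulated 400-point fields; the admissibility audit sweeps 20 spatial runs of
a reduced landscape (30 samples/class, 60 parcels, 15-tree committees); the
sample-efficiency benchmark sweeps 10–12 seeds of the default benchmark with
200-tree scenario forests and 5 repeats per scenario. The full-scale
defaults (1000 trees, 50 repeats) remain the package defaults for real use.

## Known limitations

- The fitted threshold inherits the upward bias of the lowest-nugget rule
  (see above); in small extents this can over-thin the labeled set. The
  rule is kept because it is the method's defining selection rule; the
  SSErr-minimizing fit per month is also available (`fit_all_families` plus
  a `min` by `sserr`).
- One global threshold assumes stationarity; landscapes with sub-areas of
  different spatial structure would need per-sub-area variograms, which the
  package does not provide.
- The committee-accuracy trace is noisy for small unlabeled pools, which
  makes the plateau rule trigger earlier than a smoothed criterion would;
  `stop_window` can be raised when the pool is small.
- Variograms are estimated from sample locations only, not from full raster
  coverage.
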