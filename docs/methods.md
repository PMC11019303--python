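# Methods

## The estimation problem

Integrated step-selection analysis treats each observed relocation step
as a choice among alternatives: the used step plus control steps drawn
from a tentative movement kernel.  With one used row per stratum
(pack × step time), the per-stratum availability intercept cancels and
the likelihood is the exact stratified conditional form

    sum over strata of [ beta' x_used − log sum over rows exp(beta' x_row) ].

`packstep.fit` maximizes this directly with damped Newton iterations
(analytic gradient and Hessian, start beta = 0, gradient tolerance
1e-6, max 500 iterations; all exposed).  The frequently used
Poisson-device formulation — a Poisson GLMM with per-stratum
intercepts — has the same fixed-effect maximizer; the conditional form
was chosen because it is a small convex optimization with closed-form
curvature, and the test suite cross-checks it against an independent
conditional-logistic implementation.  Standard errors come from the
inverse observed information.  Strata missing any model term are
excluded and counted; likely separation (|beta| > 50) is flagged, never
silent.

Inter-pack variability in selection terms is handled by a two-stage
estimator: conditional fits per pack, then per-term inverse-variance
pooling with a DerSimonian–Laird between-pack variance.  This targets
the same population-level coefficients as a mixed-model random-slopes
fit while remaining testable in closed form (homogeneous packs give
exactly zero between-pack variance; equal-precision packs pool to the
plain mean).  A full Laplace-approximated mixed conditional likelihood
is deliberately out of scope; the two-stage route is the default
backend for random terms.

Model comparison uses BIC = −2 logLik + p·ln(n_strata).  The sample
size is the number of strata — the number of independent conditional
contributions — since no more natural n exists for a conditional
likelihood.

## Covariates

* **Movement.** Step length l (km), its log, and the turn cosine
  cos(γ_t−1 − γ_t).  Zero-length steps leave the heading undefined, so
  the following turn is missing and that step is incomplete; lengths
  are floored at 0.125 km (half a typical grid cell) before the log so
  ln l is finite.  Diel classes interact with ln l and seasons with the
  turn cosine in cell-means coding (one column per class).
* **Seasons** from the calendar month of the step end: denning Jun–Sep,
  pre-denning Feb–May, post-denning Oct–Jan.
* **Diel class** either from solar altitude at the step end
  (crepuscular = within ±6° of the horizon, a civil-twilight band with
  a symmetric daylight margin; configurable) or from a fixed 8-slot
  schedule (2 crepuscular, 3 day, 3 night per day) that the simulator
  also uses — the schedule avoids coupling synthetic tests to solar
  geometry.
* **Landcover**: Euclidean distance (km) to roads, settlements, pans,
  grassland, floodplain, mixed woodland, mopane, sampled bilinearly at
  end-of-step points.
* **Territorial**: for each day and pack, Gaussian-kernel utilization
  distributions over trailing windows of 7/14/30/90 days (half-open
  [day − w, day), so the scored day never feeds its own field), their
  50%/95% isopleths as smallest density super-level sets, and signed
  Euclidean distance to the isopleth outline (negative inside).
  Neighbor values aggregate over packs by the minimum signed distance
  (nearest/most-inside neighbor).  A step is territory-complete only
  when every own and neighbor window × level value is defined.
  Selection covariates use end-of-step locations; movement-modifier
  copies use the stratum's begin-of-step location and are constant
  across a stratum by construction.
* **Social**: focal adult count (> 12 months), pup indicator, tenure
  indicator (> 2 years since the pack was first observed), neighbor pup
  indicator, and neighbor size difference/ratio with min/mean/max
  aggregation, joined by the nearest sighting within 40 days (earlier
  sighting on ties).  The size ratio's denominator is focal adults plus
  all concurrent neighbor adults — the most literal reading of "all
  animals in the area"; flagged as a definition choice.

Covariates are standardized by pooled mean/SD over all used and control
rows (one scale for the population model; a per-pack option exists) and
screened pairwise at |r| < 0.6, dropping the later-listed member so the
priority order territorial > landcover > social decides conflicts.
Scaling constants are stored so effects can be unscaled to kilometers.

## Utilization distributions and isopleths

The UD is the exact Gaussian kernel sum over the window's fixes,
evaluated at cell centers via a separable outer product and normalized
to unit mass; the default bandwidth is the bivariate normal-reference
rule σ·n^(−1/6) on the window's fixes, floored at one grid cell, with
250 m default resolution.  By default each UD's grid extent adapts to
its own window's fixes with ≥ 3 bandwidths of padding, so isopleths
cannot clip the grid edge however far a pack wanders; signed-distance
queries handle off-grid points explicitly (they are necessarily
outside the region).  A window with fewer than 16 fixes (≈ 2 days at
3 h) leaves the field undefined, which propagates to covariate
incompleteness rather than erroring.  The isopleth threshold is the
smallest density whose super-level set holds at least the target mass,
so the enclosed mass overshoots by at most one cell's density; an
isopleth touching the grid edge raises (the extent must be padded).
Signed distances are grid distance transforms: the sign is decided by
the query point's containing cell, so it agrees exactly with a
point-in-region test, and magnitudes are accurate to one cell diagonal.
Nesting of the 50% region inside the 95% region makes the signed
distances ordered at every query point, which the suite checks.

## The simulator

The generator is a redistribution-kernel sampler: at each 3-h step it
draws M candidate endpoints from the tentative kernel and keeps one
with probability softmax(beta' x), log-sum-exp stabilized.  M is an
approximation parameter (default 200, floor 50): selection among a
finite candidate set approximates the continuous step-selection
density, and any finite-M bias is a property to measure, not hide —
recovery runs at M = 1000 gave the same estimates within Monte-Carlo
error, so at the default effect sizes the approximation is not the
limiting factor.

Territorial fields come in two modes.  **Static** (default, used for
recovery): the own field is the signed distance to a circle
(radius 2 km) around the pack's home-range center and the neighbor
field the minimum signed distance to circles (radius 6 km) around the
other packs' centers — truth is fixed and well-defined, which is what
parameter recovery needs.  **Dynamic**: the neighbor field is
recomputed each simulated day from the packs' trailing 30-day UDs
(95% isopleth), giving genuine between-pack feedback; used for the
scale-selection experiment and demos, where only the *selected scale*
(not a coefficient value) is the target, because feedback makes a
"true" coefficient ill-defined.

In static mode truth coefficients live on the standardized scale with
landscape-wide moments (layer and field moments over all grid cells,
territorial fields pooled across packs), and the recovery fits reuse
those same moments so truth and estimate share one scale.  Dynamic-mode
coefficients are per raw km.  The diel schedule is the fixed 8-slot
pattern; start dates are staggered across packs over the calendar year
so all three seasons occur even in ~37-day tracks.  Landscapes scatter
a handful of feature patches per class (roads as extent-crossing
polylines) and take exact Euclidean distance transforms.  Sightings are
generated every 8–16 days, so every fix has one within 40 days.

What the simulator does **not** emulate: collar failure patterns beyond
random gaps and timestamp jitter, dispersal forays, mortality and pack
turnover, prey or predator fields, and habitat-dependent movement
speed.  Passing recovery therefore shows the estimator chain is
self-consistent under the stated generative model — not that wild
packs obey it.

## Recovery experiments and problem sizes

* **Null calibration**: 100 worlds with all coefficients zero
  (2 packs × 160 steps, M = 50); every |estimate| < 3 SE in ≥ 95% of
  replicates.
* **Coefficient recovery**: 10 replicate worlds of 10 packs × 300
  steps at the published wild-dog coefficient set, 20 controls/step
  (100 for the steep neighbor-boundary term, which limits small-sample
  bias); mean recovered coefficients agree with truth within 3
  Monte-Carlo SEs.  The pans × neighbor interaction is the noisiest
  target: its identification depends on pan-feature gradients near the
  neighbor rings, which varies strongly between random landscapes.
* **Scale selection**: 10 dynamic-mode worlds (3 packs × 125 days,
  −0.8/km on the 30-day/95% neighbor distance, −0.15/km static
  residency); the stage-2 neighbor ladder over {7,14,30,90} × {50,95}
  plus the concurrent nearest-neighbor distance recovers the 30-day/95%
  model as the modal winner.

These sizes keep a full validation run to a few minutes on one core
while holding Monte-Carlo error well below the effects of interest.

## Known limitations and open choices

* The KDE estimator, bandwidth rule, grid resolution, and multi-pack
  neighbor aggregation are configuration decisions (no canonical
  definition exists for any of them); all are exposed.
* The base-model and interaction candidate grammars of the ladder are
  explicit finite lists generated from configuration — structured like
  the described selection process, not a literal published candidate
  set.
* Random-term SEs are reported from the two-stage pooling; conditional
  per-pack SEs are also available on the result object, labeled.
* log-RSS intervals are delta-method on the linear-predictor difference
  and exclude between-pack variance unless the fit came from the
  two-stage estimator (whose pooled covariance includes it).
* The trajectory cleaner implements tolerance-based regularization
  only; collar-specific quality screening is out of scope.
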