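# Methods

`benthotrack` implements the analysis chain used to study habitat and
movement selection of benthic animals tracked by a fine-scale acoustic
positioning array over a classified substrate map (a *benthoscape*):
positioning quality control, track regularization, resource selection
functions (RSF), integrated step-selection functions (iSSF), and a
simplified benthoscape classification chain. A synthetic-data generator
reproduces the study conditions so that every stage can be verified by
parameter recovery without any field data.

## The models

### Resource selection (RSF)

Observed presences are contrasted with pseudo-absences (10 per presence)
drawn uniformly from each individual's availability domain — by default
the minimum convex polygon (MCP) of its presences. The model is a
binary logistic regression

    P(presence) = logit^-1( alpha + beta_c 1[substrate = c] + b_i ),

with a normal random intercept `b_i` per individual. To blunt spatial
autocorrelation the model is refit 100 times on random subsets of 100
presences and 100 pseudo-absences per individual; the exponentiated
class coefficients across reruns form the distribution of relative
selection strength (RSS) per substrate against the reference class,
*silt/mud with ≤ 50% gravel* (class 1), summarized by median and IQR. A
class whose IQR spans 1 is flagged as showing no clear selection.

Two readings of "100 presence and pseudo-absence points per individual"
are possible; the default takes 100 of *each* (the use:available ratio
affects only the intercept in this framework, not the class
coefficients), and `subset_mode="paired"` instead keeps each presence's
full complement of absences. Pseudo-absences are drawn once and
subsampled per rerun.

### Integrated step selection (iSSF)

Steps are straight lines between consecutive regularized positions.
Per individual, a *tentative* selection-free movement kernel is fitted
to the observed steps — gamma(shape k, scale θ) for step length, von
Mises(0, κ) for turning angle — and each observed step with a computable
turning angle is matched with 100 random alternatives drawn from that
kernel about the previous bearing. The conditional logistic model is

    case ~ end substrate + log(sl) + cos(ta)
           + start substrate:log(sl) + start substrate:cos(ta) + strata .

Start-substrate main effects are stratum-constant and therefore
inestimable under the conditional likelihood; only their interactions
with the movement terms enter, which is also what the model formula
prescribes. Uncertainty comes from a stratum bootstrap (1000 replicates
by default): strata, not rows, are resampled with replacement and the
per-term mean and SD over converged replicates are reported, alongside
Wald and percentile intervals (the field reports both styles and does
not say which produced its intervals, so both are emitted).

The movement-kernel correction: on the reference substrate the updated
gamma shape is `k + beta(log sl)` and the updated concentration is
`κ + beta(cos ta)`; every other start substrate adds its interaction
coefficient on top. Signs are read behaviourally: negative
`start:cos(ta)` means more turning (lower directionality), negative
`start:log(sl)` means shorter steps (more resident behaviour) on that
substrate.

**Minimum support.** A substrate level an individual used fewer than 5
times identifies its coefficient only through near-separation (huge
estimates with bootstrap SDs an order of magnitude larger — the
signature visible in per-individual tables of studies of this design).
Such levels contribute no term for that individual, the per-individual
analogue of a substrate the animal never used. The design builder
exposes this as `min_support` (0 disables it; the per-individual fit
defaults to 5).

### Statistical engines

All four engines are implemented directly on their estimating equations:

* **Gamma MLE** — Newton on `log k − ψ(k) = log(mean) − mean(log)`
  starting from the standard closed-form approximation; scale =
  mean / k. Exact on sufficient statistics by construction.
* **Von Mises MLE (mean 0)** — solves `I1(κ)/I0(κ) = mean cos θ` by
  bracketed root-finding on exponentially scaled Bessels; a mean cosine
  ≤ 0 gives κ = 0 and degenerate concentration is capped at κ = 500.
* **Conditional logistic regression** — Newton-Raphson on the stratum
  softmax likelihood with analytic gradient `X'(y − p)` and Hessian
  `X' diag(p) X − M'M` (M the per-stratum probability-weighted covariate
  means), step-halving line search far from the optimum, and a
  separation guard: |β| > 15 during iteration raises an error naming the
  term rather than returning a silently divergent fit. Covariates with
  no within-stratum variation anywhere are dropped and reported.
* **Random-intercept logistic regression** — Laplace approximation:
  for a candidate variance σ² the joint penalized likelihood in (β, b)
  is maximized by Newton with a Schur-complement solve on the diagonal
  b-block; the approximate marginal likelihood
  `l_pen − ½ Σ log(1 + σ² h_i)` is maximized over log σ² by bounded 1-D
  search. This is ridge-penalized group intercepts at the optimal
  penalty — sufficient for an intercept-only random effect.

## The synthetic generator

The generator emulates the observation system the analyses were designed
for, with these defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| benthoscape | 200×200 cells of 5 m | 1 km² array neighbourhood |
| class proportions | 22.1% coarse, 11.9% class 1, 10% mixed, 5% deep, 49.1% shallow silt/mud, 1.9% no data | dominant-class availabilities match the emulated array (22.12% / 49.12%) |
| patchiness | 25 m | habitat patches a few step lengths across |
| kernel | gamma(2, 5 m), von Mises κ = 1 | ~10 m moves per 10-min step, moderately directional |
| step interval | 600 s | the analysis sampling rate |
| transmissions | uniform 120–240 s | the tag programming of the emulated design |
| detection probability | 0.9 | dense-array positioning yield |
| error scale σ | 1.97 m base | calibrated once so the median radial error is 2.4 m, the array's tested accuracy |
| error mixture | lognormal(sd 0.6) scale, 10% ×3 outliers | heavy-tailed per-fix quality, p90/p95 near 7.4/10.4 m |
| HPE proxy | `3 σ_i exp(N(0, 0.35))` | Spearman ≈ 0.64 with true error — informative but imperfect, as a quality score must be for a cut-off procedure to be meaningful |

Tracks are generated by running the iSSF generative model forward: at
each step 20 candidate moves are drawn from the kernel about the
previous bearing, candidates leaving the raster are redrawn (then the
animal holds position — rejection-with-retry avoids reflecting-boundary
bias at the cost of slight edge attraction), and one candidate is chosen
with probability ∝ exp(β[end substrate]). The benthoscape is a
Gaussian-smoothed white-noise field cut at the rank-quantiles of the
target proportions, which makes realized proportions track the targets
to cell granularity and keeps generation seedable.

What the generator does **not** emulate: receiver-level detection and
multilateration geometry (error is isotropic and position-independent,
with no array-edge degradation), tides, temperature, tag collisions, or
mortality. Passing recovery tests therefore shows the *estimators* are
correct under the stated observation model, not that any field system
meets that model.

## Positioning QC

Per deployment, the candidate cut-off is the smallest observed HPE
retaining ≥ 95% of sync-tag fixes (retention uses ≤). The final cut-off
is configuration, not algorithm — in the field protocol it is a human
balance of confidence against retention — and the animal filter applies
it strictly (`HPE < cutoff`), plus removal of everything within 48 h of
each tag's release. Percentiles of HPEm use linear interpolation
between order statistics (the field convention is unstated; this one is
declared). Fixes with missing release times are rejected, not silently
kept. Observed positions beyond the raster extent are clipped before
covariate extraction (positioning error can place a fix outside the
mapped area).

## Track regularization

The greedy rule: keep the first fix; from each kept fix keep the
earliest later fix with gap in [rate − tol, rate + tol] (600 ± 120 s);
a gap beyond rate + tol closes the burst, and the fix that broke the
window starts the next one. Bursts shorter than 2 fixes are dropped.
Turning angles are counter-clockwise positive in (−π, π] (only cos ta
enters the models, so the sign convention is inert but fixed). Substrate
is sampled at step endpoints only; unmapped cells keep the NODATA level,
which is an ordinary category everywhere downstream (selection is
estimable for unmapped seabed too).

## Benthoscape classification

Correlation-matrix PCA (layers standardized — bathymetry and
backscatter are on incommensurate scales) retains the smallest prefix of
components explaining ≥ 95% of variance. Clustering is plain k-means
(k-means++ start, Lloyd iterations, empty clusters re-seeded from the
farthest point, within-cluster SSQ non-increasing by construction) —
the split/merge heuristics of full ISODATA and object-based segmentation
are out of scope. Cluster labels are arbitrary; they are mapped to named
classes by majority vote against ground-truth points, and the map is
scored by overall accuracy, Cohen's kappa, and per-class user's accuracy
(undefined, and reported as such, for classes never predicted).

## Verification experiments and problem sizes

`benthotrack.experiments` holds the recovery and calibration
experiments run by both the test suite and `scripts/acceptance.py`:

* **Conditional-logistic oracle** — the Newton fit agrees with a
  brute-force grid maximizer (step 1e-3) on ≥ 10 random small stratified
  datasets, and with the closed form β = ln 2 on a two-strata example.
* **Step-selection recovery** — 50 replicates of 5 individuals × 600
  steps with generating β = +1.0 (mixed sediments) and −0.5 (coarse
  sediments), 25 random steps per stratum, 200 bootstrap replicates per
  fit, strata pooled across individuals (pooling is licit in a
  conditional likelihood and leaves the estimand unchanged). These sizes
  give Monte-Carlo standard errors an order of magnitude below the
  0.1-bias band being checked, in minutes on one CPU. The recovery
  simulations use 100 candidate moves per step: with few candidates the
  generative discrete choice itself attenuates the estimand relative to
  the continuous-availability model the fit assumes (≈ −0.07 on β = 1
  at 20 candidates, ≈ −0.03 at 50, gone at 100), and that is a property
  of the experiment's approximation, not of the estimator.
* **Null calibration** — 50 one-individual replicates with all β = 0;
  the per-term Wald rejection rate at |z| > 1.96 is compared with the
  nominal 5% within binomial error. (The *any-term* rejection rate
  depends on inter-term correlation and has no clean nominal level; it
  is reported but not tested.)
* **RSF known-weights recovery** — presences drawn with relative weight
  3 on one substrate recover median RSS ≈ 3 under the 100×100
  subsample-refit scheme; a null run keeps all medians within ±0.2 of 1.
  Presences and pseudo-absences share an explicit availability domain in
  these experiments: an MCP domain clips the corners of the presence-
  sampling region, and when corner composition differs from the bulk by
  chance the contrast is biased — a genuine (small) artifact of
  MCP-based availability worth knowing about.
* **Observation-error calibration** — a 16-tag synthetic sync array
  reproduces the 2.4 m median design error (p90/p95 near 7.4/10.4 m)
  and Spearman(HPE, HPEm) ≈ 0.64.

## Numerical choices and edge cases

* Half-open cells `[x0, x0+c) × [y0, y0+c)` resolve raster edge ties
  deterministically; row 0 is the southernmost row internally and both
  file formats (ESRI-ASCII grid, single-band GeoTIFF via tifffile tags
  33550/33922) convert at the boundary.
* `wrap(θ)` maps to (−π, π] with π fixed (`wrap(π) = π`).
* Zero-length steps give log sl = −∞ and are filtered with a counted
  reason, as are steps without a predecessor (no turning angle).
* Bootstrap replicates that separate or fail to converge are dropped
  and counted; more than 20% failures raises rather than reporting a
  mean over a broken distribution.
* The Laplace variance search runs on log σ² over [−12, 6] (bounded;
  the boundary is effectively σ² → 0, i.e. no heterogeneity).
* All randomness flows from named seeds through `numpy` SeedSequence
  spawning; identical configuration ⇒ byte-identical artifacts.

## Known limitations

* Estimates fitted to *observed* (error-corrupted) positions are
  attenuated toward zero relative to the generating coefficients —
  classic covariate measurement error when the positioning error (2.4 m
  median) is comparable to the raster cell size (5 m). The recovery
  experiments therefore fit the true tracks; the analysis drivers show
  the attenuated observed-data picture alongside the truth.
* The Laplace approximation can understate intercept-variance
  uncertainty with very few groups; with ≥ 5 individuals and an
  intercept-only effect this is immaterial for the class contrasts.
* K-means is a stand-in for the proprietary object-based segmentation
  chain of real benthoscape mapping; accuracy numbers from the synthetic
  classification exercise are not comparable to field accuracies.
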