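# Methods

## Encounter model and estimators

The package treats track counts as random encounters between moving animals
and fixed transects.  For independently and randomly moving individuals at
density *a*, the expected number of crossings of a transect of length *M*
over an accumulation time *D* is `(2/π)·a·E[L]·M·D`, where `E[L]` is the
mean daily path length.  The geometry constant 2/π comes from averaging the
projection of a unit-length track over uniformly random orientations; the
Monte-Carlo test `test_encounter_law_ideal_gas` verifies it against a
brute-force simulation of straight movers.

The FMP estimator inverts this law on totals,
`â = (π/2)·ΣX/(E[L]·ΣMD)`, and is therefore invariant to how records are
partitioned.  Interval estimates are BCa bootstrap percentile intervals
(1000 resamples) over transect-year records, which are the survey's
independent sampling units; when the statistic is constant under resampling
(all-zero counts, identical records) the interval degenerates to zero width
and is flagged.

The smoothing models embed the same offset in a negative-binomial GLM with
a latent Gaussian state:

* temporal: `z_t = φ z_{t−1} + ε_t`, `ε_t ~ N(0, σ²)`, stationary
  initialization `z_1 ~ N(0, σ²/(1−φ²))`;
* spatio-temporal: the innovations are spatially correlated with a Matérn
  covariance (variance σ², inverse scale κ, smoothness fixed at ν = 1, the
  standard 2-D choice), giving a separable space–time covariance
  `AR1 ⊗ Matérn` evaluated exactly on the site set.

The negative binomial is parameterized by mean and size *r*
(variance μ + μ²/r); the classical success probability is r/(r+μ).

## Priors

Hyperpriors act on transformed parameters θ₁ = log precision of the
innovations and θ₂ = log((1+φ)/(1−φ)):

* `default` (T1): θ₁ log-gamma with Gamma(1, 5·10⁻⁵) on the precision —
  a diffuse prior that nevertheless concentrates mass on large precisions,
  producing the over-smoothing regime — and θ₂ ~ N(0, precision 0.15).
* `relaxed` (T2): θ₁ ~ N(0, 1), θ₂ ~ N(1, 1) (much less smoothing).

Both presets share b ~ N(0, 10²), log r ~ N(0, 1.5²), and (ST only)
log κ ~ N(log 0.01, 1.5²), i.e. a prior median spatial range of 100 km,
the order of the inter-site distances.  The experiment harness uses the
`default` preset for the ST model and both presets for the temporal model
(T1/T2); with the relaxed prior the ST field variance is weakly identified
and the exponential link inflates totals at sparsely observed sites.

## Inference

For fixed hyperparameters the NB log-likelihood is strictly log-concave in
the latent field, so the conditional mode is found by a damped Newton
iteration (gradient tolerance 10⁻⁶, dense Cholesky solves) and the field is
integrated out with a Laplace approximation.  The resulting approximate
marginal posterior of (b, θ₁, θ₂, log r[, log κ]) is sampled with the
emcee affine-invariant ensemble (12 walkers; 400 steps/200 burn-in for the
temporal model, 200/100 for ST by default).  Latent draws are then taken
from the Gaussian conditional at resampled hyperparameter draws.  A fit is
flagged failed when the ensemble acceptance collapses (< 0.02), the
log-posterior is non-finite, or latent draws are non-finite; downstream, a
replicate-year is additionally classed as failed when the estimated total
is non-finite, below 1 or above 1000 individuals, and failed entries are
excluded from metric aggregation but counted in the failed fraction.
Duplicate spatial sites are jittered (10⁻⁶ on the correlation diagonal) and
flagged; otherwise a 10⁻⁸ jitter stabilizes the Cholesky.

Spatio-temporal prediction at new points exploits the Kronecker structure:
conditioning on the full fitted lattice reduces to within-year spatial
kriging, with conditional variance equal to the spatial Schur complement
scaled by the stationary AR1 marginal σ²/(1−φ²).

## Synthetic data generator

The generator reproduces the winter-track-count study conditions:

* **Domain** — a 400 × 830 km rectangle (332,000 km², Finland-like area);
  any simple polygon is accepted for user data.  Coordinates are planar km.
* **Landscape** — five habitat classes (artificial, agricultural, forest,
  wetland, water) with proportions (0.03, 0.07, 0.70, 0.10, 0.10), produced
  by rank-thresholding a smoothed Gaussian field.  Defaults: 0.25-km cells,
  1-km clustering scale — a fine-grained mosaic standing in for 25-m
  land-cover data, chosen so that habitat availability mixes classes within
  the 2-km movement step.  Coarser patches attenuate step-selection
  estimates (see Limitations).
* **Movement** — 4-hour steps for 60 days: wrapped-normal turning angles
  with mean resultant length 0.70, Weibull(shape 2, scale 2 km) step
  lengths, giving a mean daily path of 6·2·Γ(1.5) ≈ 10.63 km.  Territorial
  agents (90% of the population, re-drawn yearly) have their proposed
  heading replaced, with probability 0.30, by the bearing to their
  territory centre whenever they are more than 10 km from it — the "30%
  bias" read as a mixture, not a weighted circular mean.  Habitat-selective
  agents choose among 10 candidate steps with probabilities proportional to
  the class weights (forest 1, wetland 0.5, fields/urban 0.1, water 0.05);
  out-of-domain candidates get weight zero.  All scenarios redraw proposals
  crossing the domain boundary (cap 10⁴).
* **Demography** — each agent is replaced yearly by Poisson(μ) successors,
  μ ~ lognormal(0, 0.1), so E[N] is a martingale (constant in expectation).
  In grouped scenarios the whole group of size 1 + Poisson(4) dies,
  survives (keeping its size), or reproduces, with freshly drawn sizes for
  new groups.
* **Survey** — 1610 equilateral 4-km-sided triangles; 500 sampled per year
  with uniform counting days in 1..60; rotations re-randomized yearly except
  when placement was constrained to ≥ 90% forest perimeter (scenarios E/F).
  The 24-hour accumulation window is the six steps of the counting day.
  Each segment–edge intersection contributes the crossing agent's group
  size; endpoint touches and collinear overlaps count once (a fixed
  convention for measure-zero configurations).  Effort is the
  habitat-weighted in-domain perimeter, sampled at 25-m intervals.
* **Telemetry** — 10 collars per year, fixes at the step resolution over
  the whole season.  The first step of each burst has no turning angle and
  is excluded from step selection.  Null steps are redrawn until inside the
  domain, so availability reflects accessible habitat.

A scale factor shrinks domain area, network, survey sample, and population
together, preserving density and per-transect encounter rates; replicate
*r* of an experiment uses seed `base + r`, so runs are bitwise reproducible
and extending the replicate count leaves earlier replicates unchanged.

What the generator does **not** emulate: observer error, track aging or
erasure, multi-day accumulation (D is carried through the formulas but
fixed at 1 day), agent interactions, energetics, and real geography
(coastlines, lakes as barriers).  Passing tests therefore demonstrate the
estimators' behaviour under the idealized encounter process, not robustness
to field-data artefacts.

## Evaluation

Estimates are scored by α = log((N̂+1)/(N+1)) (mean and 95% quantiles),
by OLS slope β and R² of log(N̂+1) on log(N+1) (the +1 shift keeps the
scales consistent with α and is negligible at N ≈ 200), by 50%/95%
interval coverage, and by the Spearman rank correlation (mid-ranked ties)
between true and predicted abundances on 100-km grid cells, with the truth
snapshotted at day 30.  The ST model's counts are aggregated to the same
100-km cells before fitting (the survey re-randomizes transect positions
yearly, so raw transect-years would define a new site set each year);
cell totals integrate the posterior density over habitat-weighted cell
areas.

## Numerical choices and test scales

Reduced problem sizes used by the test suite were chosen to exercise the
same statistical regime as the full design: scale 0.25 (a quarter of the
area, population, network, and survey) over 10 years and 5 replicates for
estimator comparison; 20 replicates of 20-year series for AR1+NB
calibration; 50 sites × 10 years for spatio-temporal parameter recovery;
10 replicates × 20 bursts for habitat-weight recovery.  Riemann
integration uses 1–5 km cells with fractional boundary cells resolved by
10×10 subsampling.

## Known limitations

* **Step-selection estimand.**  The habitat weights recovered by the
  null-step ratio estimator converge to the *marginal* use/availability
  ratio of the movement process.  When movement chooses among a finite set
  of 10 weighted candidates, that marginal ratio differs from the
  candidate-weighting parameters by a finite-choice-set factor (about
  +6–15% relative for the default weights, e.g. 0.53 recovered for a
  generative 0.50), and coarse habitat patches attenuate it further toward
  1.  The marginal ratio is, however, exactly the realized relative density
  that the abundance weighting needs, which is why population totals in the
  habitat scenarios remain unbiased while the weight point estimates sit
  slightly above the generative values.  Bootstrap intervals over bursts
  reflect sampling noise only, not this estimand offset.
* **Daily-distance spread.**  Six independent Weibull(2,2) steps imply a
  daily path SD of ≈ 2.3 km/day; reported empirical spreads for wide-ranging
  carnivores are larger (≈ 5–6 km/day), reflecting between-day behavioural
  correlation that the step law does not model.  The mean (10.63 km/day),
  which is what the estimators consume, is unaffected.
* The spatio-temporal model uses an exact Matérn covariance on the site
  set; cost grows with (sites × years)³, which is comfortable at the
  aggregation scales used here but not for thousands of sites.
* Habitat weights enter the density integration as plug-in constants;
  their sampling uncertainty is not propagated into the credible
  intervals.
* Laplace-approximated marginals can understate skewness of the
  hyperparameter posterior for very sparse counts; the simulation-based
  calibration tests bound this error at the study's data sizes.
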