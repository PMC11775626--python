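# Methods

## Observational units

A *record* is one photograph (site, species, timestamp, individual count,
burst id). Trail cameras fire three frames per trigger; a burst collapses
to one *detection event* whose time is the first frame's and whose count
is the burst maximum. When burst ids are missing, frames of the same
species at the same site within 30 s (the camera's re-trigger delay) are
grouped. Detection histories binarise events into a site × occasion
matrix with an effort mask for camera-inactive days; the occasion length
defaults to one day and is configurable, since survey protocols rarely
pin it down. Human and livestock *pressure* covariates are per-site sums
of the count field over all photographs (not collapsed events) of the
group; livestock pools cattle/oxen, buffalo and goats. Diel analysis uses
one clock time per collapsed event by default; an `hourly` mode keeping
at most one event per site-hour is provided because repeat triggers can
otherwise overweight single visits.

## Occupancy model

Single-season model with logit-linear covariates on space use ψ and
detection p; p is constant across occasions within a site. The site
likelihood marginalises the latent use state, with masked occasions
excluded. ψ is interpreted as *space use* — the probability the species
uses the site during the window — rather than closed-population
occupancy; nothing in the likelihood changes, only the reading of ψ.

*Maximum likelihood.* L-BFGS-B on the exact log-likelihood; standard
errors from the inverse numerical Hessian at the optimum. `fix_p_at=1`
collapses the history to the ever-detected indicator (with perfect
detection the latent state is observed), making the intercept-only ψ̂ the
naive occupancy proportion — the closed-form cross-check for the sampler.

*Bayesian fit.* Metropolis-within-Gibbs: the latent state zᵢ is drawn
from its exact full conditional (zᵢ = 1 at sites with detections;
otherwise Bernoulli(ψᵢqᵢ/(ψᵢqᵢ+1−ψᵢ)) with qᵢ = (1−pᵢ)^{Jᵢ} over
unmasked occasions), then the ψ- and p-coefficient blocks are updated by
random-walk Metropolis on their complete-data conditionals. Proposal
scales adapt in 50-iteration batches during a dedicated adaptation phase
toward an acceptance rate of 0.30–0.45; adaptation and burn-in are
discarded. Defaults are 3 chains, 1000 adaptation, 1000 burn-in, 10 000
retained iterations, no thinning, and a convergence flag at R̂ > 1.1.
Chains run vectorised in one pass and are exactly reproducible given a
seed.

*Priors.* Independent Normal(0, sd 2) on all logit-scale coefficients —
weakly informative, wide enough to be overwhelmed by ~100 sites of data
but proper enough to stabilise quasi-separation when a covariate nearly
predicts the detected set. Configurable per model.

*Summaries.* Posterior mean/sd, equal-tailed credible limits (95%
default; 99% available), rank-normalized split R̂ and autocorrelation ESS
(via arviz; a classical split-chain R̂ is implemented in-package as the
alternative), and `overlap0` — 1 iff the interval contains zero, using
the closed-interval convention so an interval touching zero is *not*
significant. Zero-variance parameters report R̂ = 1 with a degeneracy
flag rather than NaN. Derived rows `psi` and `p` are per-draw means over
sites of the inverse-logit linear predictors, summarising study-level
space use and detection on the probability scale.

*Standardization.* Covariates are z-scored with the analysed sites' mean
and sd (stored on the design); coefficients are therefore per-sd effects.
Prey-ψ covariates in the tiger stage are standardized the same way by
default (switchable), since a probability-scale covariate with sd ≈ 0.1
would otherwise make its coefficient incomparable with the rest.

## Covariate screening

Two-phase stepwise removal: while any retained pair has |Pearson r| >
0.7, the non-kept member with the larger VIF is dropped (worst pair
first; deterministic given column order); then columns with VIF > 5 are
dropped one at a time. VIF_k = 1/(1−R²_k) by direct least squares. The
published procedure names both a correlation rule and a VIF rule without
stating their order; running the correlation phase first and the VIF
phase second enforces both criteria whichever the original tool applied.
A keep-list encodes ecological preference; keep-set violations are
warned about and reported but the keep is honoured. Screening is
idempotent on its own output.

## Two-stage space use

Stage 1 fits each prey species with constant detection (intercept-only p)
and site covariates on ψ, including a competitor-presence indicator (any
other prey detected at the site). Stage 2 fits the tiger with forest
cover, human and livestock counts and the stage-1 posterior-mean ψ of
blue bull, gaur and wild pig on ψ, and road/water distances on p.
Stage-1 uncertainty is *not* propagated — posterior means enter as fixed
covariates, mirroring the published procedure; this understates stage-2
uncertainty and can attenuate or distort coefficients when stage-1
estimates are noisy (see Limitations). Species with zero detections are
skipped with an explicit report entry; constant covariate columns are
excluded before screening with a report entry.

*IDW map.* ψ̂ projected onto a regular grid of cell-centre queries,
v(s) = Σ dᵢ⁻ᵖ ψᵢ / Σ dᵢ⁻ᵖ with p = 2 and a 250 m cell by default (the
common GIS-tool defaults; the choice is cosmetic, not inferential).
Coincident query/site points return the site value exactly; being a
weighted average the surface is bounded by the site values. Output is an
ESRI-style ASCII raster plus a cell-centre CSV.

## Diel overlap

Clock times map to radians (2π · seconds-since-midnight / 86400; local
clock time, no DST arithmetic). Densities are von Mises kernel estimates;
the kernel concentration comes from the sample's ML concentration κ̂
(resultant-length inversion, capped at 500 for degenerate samples) via
the plug-in rule κ_kernel = (n κ̂² · 3I₂(2κ̂) / (4√π I₁(κ̂)²))^{2/5},
multiplied by `adjust` (0.8 for Dhat1, 1.0 for Dhat4 — the conventional
small/large-sample tuning). Dhat1 integrates min(f̂, ĝ) on a 513-point
closed grid; Dhat4 averages min(ĝ/f̂, 1) and min(f̂/ĝ, 1) at the
observations, which makes identical samples give exactly 1 and makes the
estimator exactly invariant to joint rotation (Dhat1's fixed grid limits
its rotation invariance to the quadrature error, ~10⁻⁴ at 512 points).
The automatic rule uses Dhat1 below 50 observations in the smaller
sample, Dhat4 otherwise.

*Bootstrap.* Smoothed by default: each group is resampled from its
fitted kernel density (an observation plus von Mises noise), bandwidths
re-estimated per resample, 999 resamples. Smoothed resampling avoids the
tie inflation of raw resampling on small circular samples; raw mode is
available. `norm0` centres ±1.96·sd(boot) on the original estimate;
`basic0` and `percentile` are provided. Bounds clamp to [0, 1].

*Randomization test.* Null samples of the original sizes are drawn from
the kernel density fitted to the pooled data; p = (1 + #{null Δ̂ ≤
observed Δ̂})/(n_null + 1), add-one so p ∈ (0, 1] at finite n_null.

*Numerics.* Kernel matrices are built from the angle-difference identity
as a matrix product rather than an elementwise cosine, and the
bootstrap/randomization internals run in float32 (≈10⁻⁷ relative density
error, far below Monte-Carlo noise); user-facing density and overlap
estimates are float64 throughout. Exponentially scaled Bessel functions
keep all κ paths finite up to the κ = 500 cap.

## Synthetic study generator

Emulates the survey the estimators target: 94 cameras ≥ 1 km apart
(uniform placement with rejection on a rectangle whose area scales with
site count to keep the density of the 94-camera design), 21 daily
occasions, a tiger and six ungulate prey species, and overdispersed
anthropogenic counts. Defaults *are* the published study conditions:

* covariate marginals moment-matched to the reported mean ± sd —
  lognormal distances (water 2785.3 ± 2554.6 m, road 1091.46 ± 1507.6 m,
  settlement 3745.6 ± 2110.1 m), scaled-beta canopy (39.52 ± 16.28%) and
  forest cover (0.712 ± 0.134 km² on [0, π·0.25], the 500 m-radius disc),
  negative-binomial counts (humans 53.9 ± 297.5, livestock 2.9 ± 12.8;
  specs with sd² ≤ mean are rejected as non-overdispersed);
* species baseline ψ and p set to the published estimates (tiger ψ 0.543,
  p 0.740; prey ψ 0.365–0.600, p 0.067–0.454), tiger ψ slopes at the
  published coefficient means (wild pig 1.859, gaur 1.370, livestock
  1.398, human 1.349, forest 0.648, blue bull 0.429), and tiger detection
  slopes on road/water set to 0 (detection was found uninfluenced by
  them); prey ψ get modest habitat slopes (±0.2–0.5) so their fields vary
  across sites;
* diel clocks drawn from von Mises mixtures matched to the reported
  activity windows: bimodal crepuscular tiger (components at 19:00 and
  03:00, κ = 3), sambar and wild pig peaking with the tiger, diurnal
  barking deer/chital, midday humans (κ = 1.5 at 12:00) and afternoon
  livestock (16:00).

Exact pairwise overlap Δ of the generating mixtures is computed by
4096-point quadrature and stored as truth. Records are emitted as
three-photo bursts (frames 1 s apart) whose timestamps combine the
occasion date with the diel draw; human/livestock photo counts are
multinomial splits of the per-site totals so the photo-level sums
reproduce the covariate table exactly. Parsing the emitted records back
through the detection pipeline reproduces the histories bit-exactly, and
all randomness flows from the config seed through stage-keyed streams, so
reruns are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not establish about field data: spatial autocorrelation of occupancy,
animal movement and home-range structure, camera failure/theft, temporal
non-closure within the season, within-night autocorrelation of activity,
herd-size variation in wildlife counts, and observation-level
misidentification.

## Problem sizes used in the checks

The statistical acceptance tests run at sizes chosen to make their
Monte-Carlo bounds sharp while keeping the default suite a few minutes
long: likelihood exactness on 1000 random site-histories (J ≤ 4, 1e-12);
parameter recovery and interval coverage over 50 simulated surveys of
200 sites × 10 occasions with 3 × 2000-iteration chains (coverage pooled
over the monitored coefficients); the planted two-stage effect (+1.86
wild-pig slope, n = 300, and its zero-slope null) over 50 replicates
each; overlap accuracy at n = 2000/group against 4096-point quadrature;
randomization-test calibration over 200 null replicates (199 null draws);
and bootstrap coverage over 100 replicates at n = 200/group with the full
999 resamples. The acceptance script runs the complete pipeline at the
94-site design with the full 3 × 10 000-iteration settings.

## Known limitations

* Plug-in prey ψ (no stage-1 error propagation) biases stage-2
  coefficients when prey are poorly detected — blue bull at p ≈ 0.07
  yields nearly flat stage-1 fields, and at 94 sites tiger coefficients
  on such covariates are unstable even when study-mean ψ and p are
  well estimated. `twostage.bootstrap_stage1` (off by default) refits the
  tiger model over prey-psi tables drawn from the stage-1 posteriors and
  is the recommended diagnostic; estimates at the 94-site design should be read
  with the same caution the original wide intervals invite.
* Detection is constant across occasions within a site; no behavioural
  or temporal detection heterogeneity.
* The sampler's random-walk blocks are adequate for the ≤ 10-coefficient
  designs used here; heavily correlated designs would benefit from a
  covariance-adapted proposal, which is not implemented.
* Planar coordinates throughout; no geodesy, no kriging alternative to
  IDW.
* The estimator auto-switch at 50 observations and the `adjust`
  conventions are defensible defaults, not optima; both are exposed.
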