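# Methods

`mtrack` analyses satellite-tag movement data from a double-tagged pelagic
fish deployment (striped marlin in the southwest Pacific, 25 animals tagged
2005–2008): irregular, error-prone position fixes from Argos satellite-linked
tags (SLRT) and light-level geolocations from pop-off archival tags (PSAT),
plus binned time-at-depth summaries. The chain is

1. temporal regularization with a continuous-time correlated random walk
   (CTCRW) Kalman smoother,
2. classification of 12-h trajectory steps into four pseudo-behavioural
   modes,
3. capture-effect analyses (time to first area-restricted behaviour,
   early-vs-late contrasts, return-to-capture), and
4. day/night time-at-depth summaries with a mode-conditioned maximum-depth
   contrast.

A synthetic-data generator reproduces the statistical structure of such
deployments so that every stage can be validated against known ground truth;
the real tag data were never deposited publicly.

## Movement model and regularization

Per planar coordinate the CTCRW state is (position x, velocity v) with an
Ornstein–Uhlenbeck velocity process:

    dv = -beta v dt + sigma dW,        x(t) = x(0) + ∫ v ds

`beta` (1/day) is the velocity-autocorrelation rate (1/beta is the
persistence time scale), `sigma` the velocity diffusion scale
(km·day^-3/2). The exact discrete transition over a lag Δ is

    v(t+Δ) = e^{-βΔ} v(t) + ζ
    x(t+Δ) = x(t) + v(t)(1-e^{-βΔ})/β + ξ

with Var(ζ) = σ²(1-e^{-2βΔ})/(2β),
Var(ξ) = σ²/β² [Δ - 2(1-e^{-βΔ})/β + (1-e^{-2βΔ})/(2β)],
Cov(ξ, ζ) = σ²(1-e^{-βΔ})²/(2β²). These closed forms are verified against
numerical quadrature of the OU moment integrals in the test suite.

Because the transition is linear-Gaussian at arbitrary lags, irregular
observation times are handled exactly by a Kalman filter; the log-likelihood
is the prediction-error decomposition and is checked to 1e-8 relative
against a brute-force joint-Gaussian density on short tracks. Maximum
likelihood runs over log(β), log(σ) with bounded L-BFGS-B (ftol 1e-10,
max 500 iterations); one (β, σ) pair is shared by both plane coordinates by
default (per-coordinate fitting is available). The prior puts the position
at the first fix with its measurement variance and a diffuse (1e6 km²/day²)
velocity variance.

Coordinates are projected per animal onto an azimuthal-equidistant tangent
plane (sphere of radius 6371 km) centred on the track midpoint; tracks span
up to ~40° of longitude, so a per-animal projection bounds distortion.
Longitudes live in [0, 360) internally because the study region crosses the
antimeridian.

Measurement error is class-dependent: Argos classes 3…B get a base SD
(0.5 km) times multipliers (1, 1.5, 3, 6, 12, 24); light/SST geolocations
(class GL) get absolute scales 56.8 km (longitude) and 112.2 km (latitude).
The per-class tables of the original processing are not public; these
defaults reproduce the standard Argos ordering and the reported geolocation
deviation magnitudes, and are config-overridable. Geolocation errors are
generated with Student-t (df = 3) tails but treated as Gaussian with matched
scale inside the filter — the filter requires Gaussian noise, and the class
multiplier plays the role of a robustness dial.

The fixed-interval (RTS) smoother is evaluated on the union of observation
and 12-h grid times; grid times carry no observations and therefore no
information (verified by a grid-refinement invariance test). Grid rows
anchored at multiples of 0.5 days since release; rows inside observation
gaps longer than 20 days (configurable; the worst real gap is 41 days) are
flagged low-confidence rather than dropped. No extrapolation outside the
observation span.

## Behaviour classification

Each 12-h step yields a speed (great-circle displacement / 12 h, km/h) and a
relative turning angle (difference of successive great-circle bearings,
wrapped to (-π, π]). Speeds are modelled with two gamma densities
(slow/fast), angles with two zero-mean wrapped-Cauchy densities
(directed ρ_d / tortuous ρ_t); the four modes are the product:
slow-transit, fast-transit, slow-ARB, fast-ARB (ARB = area-restricted
behaviour). Fast-ARB — fast yet tortuous displacement sustained over 12-h
steps — is biologically implausible and is flagged error-dominated;
downstream analyses can exclude it.

Fitting is EM over the 4-component product mixture (shared speed components
across the angle axis and vice versa), with seeded restarts: two
deterministic anchors (median speed split with canonical concentrations;
a turn-threshold weight anchor) plus random restarts, best likelihood kept.
Gamma M-steps use the weighted log-moment Newton iteration; wrapped-Cauchy
concentrations use bounded 1-D likelihood maximization. Components are
relabelled post hoc so that the fast mean exceeds the slow mean and
ρ_d > ρ_t. A component weight below 1e-3 flags a degenerate fit — real
animals supported 2–4 distinguishable modes, so collapses are expected on
some tracks.

Steps are labelled by the argmax of the four component likelihoods with
equal priors (the classifier reports likelihoods, not posteriors; mixture
weights are used only in fitting). Ties break toward transit. Runs shorter
than `min_run` steps (default 2 = 1 day) are absorbed into the flanking
majority mode, iterated to a fixed point (idempotent). ARB bouts merge
modes {3, 4}; durations are run length × 0.5 days.

### What mode recovery can and cannot show

Wrapped-Cauchy densities have heavy angular tails: with moderate separation
(ρ 0.8 vs 0.1) the per-step Bayes accuracy of any angle-based classifier is
only ~78%, so the end-to-end recovery experiment defines "well-separated"
as ρ_d = 0.97 vs ρ_t = 0 (speed means 0.7 vs 1.9 km/h as in the study's
transit modes), multi-day bouts, and a dense good-quality observation
stream (6 class-3/2 fixes per day), with the mixture fitted on steps pooled
over 8 animals. Under those conditions step-level agreement is ~0.92; under
the study's own error structure (heavy-tailed geolocations, 2.3 fixes/day)
agreement drops substantially, which mirrors the original caution that
fast-ARB segments mostly track location error.

## Capture effects

Time to first ARB is summarized with the Kaplan–Meier product-limit
estimator (lifelines backend), Greenwood variance, and 95% log(-log)
confidence bands; `median_crossing` reports the first event time with
S(t) ≤ 0.5 — the day on which the odds of having shown ARB reach 50:50.
Animals without ARB are censored at their last classified step.

Early-vs-late contrasts (speed, |turning angle|) pool steps across animals,
split at 10 days post-release, and use the Wilcoxon rank-sum test (exact
null for small untied samples, otherwise normal approximation with tie
correction) with a Hodges–Lehmann shift estimate. Heading alignment is the
mean northward component cos(bearing) with a one-sample t-test.

Return-to-capture: an animal "departs" when its distance from release
exceeds 100 km (configurable); a "return" requires first exceeding the
return radius (500 km) and later re-entering it. Tagging season splits at
1 March (release date strictly before = early). The rank-based replacement
for the original study's unidentified θ statistic is a deliberate design
choice: the reported shift and p-value are reproducible quantities.

## Depth profiles

Day/night is the sign of solar elevation from the standard low-accuracy
NOAA/Spencer series (declination and equation of time as Fourier series in
the fractional year; geometric horizon, no refraction). Accuracy is well
under 0.5°, i.e. ≲4 minutes around sunrise/sunset at study latitudes; the
test suite cross-checks the sign against an independently coded Meeus-style
ephemeris.

Heterogeneous tag programmes are aggregated by folding each tag's 12 bins
onto a common bin set by exact edge containment (a bin straddling a common
edge is an error, never silently split), weighting by period length, and
renormalizing. The default common bins are a package choice, not the
original figure's. Transmission gaps are filled per bin by a
tricube-weighted local-linear smoother over time (bandwidth 5 periods),
then clipped to [0, ∞) and renormalized onto the simplex; a bin observed in
fewer than 2 periods stays empty and is flagged.

Period-maximum depths are compared between transiting and ARB behaviour
with the rank-sum contrast after assigning each summary period the
behavioural class covering the majority of it (ties to transit). Under the
null the p-values are uniform (KS-checked); at the study's printed effect
size (127 ± 57 m vs 108 ± 49 m) the standardized difference is only
d ≈ 0.36, so with 100 periods per group the power at α = 0.001 is ~20–25%
(closed form and simulation agree) — detecting that contrast at p ≤ 0.001
requires the thousands of summary periods a real multi-animal deployment
provides. The power experiment reports this honestly rather than inflating
the sample.

## Synthetic-data generator

Movement: a 4-state continuous-time Markov chain (default rates give
~5.5-day ARB bouts and ~14.3 days between bouts) drives a discrete-step
correlated walk at 1-h resolution — truncated-normal speeds (the location is
shifted so the realized mean equals the configured target, e.g. 0.74 and
1.93 km/h for the transit modes) and wrapped-Cauchy heading increments
(transit concentrated, ARB diffuse). The generator is deliberately *not*
a CTCRW: recovery tests against a mechanistically different process are
more honest than self-consistent round trips.

Observations: Argos fixes from a Poisson process (default 2.3/day) thinned
by configurable gap windows, with class frequencies (3/2/1/0/A/B =
5/10/15/20/25/25%; not published, fixed by declaration) and class-scaled
Gaussian errors; one geolocation per day at the local-noon-equivalent time
with scaled-t errors (latitude scatter ≈ 2× longitude). Depth: per
summary period a mode-dependent maximum depth (transit 127 ± 57 m, ARB
108 ± 49 m) and a 12-bin time-at-depth vector whose within-1-m surface
fraction is beta-distributed around 51.4% (day) / 64.0% (night), remaining
mass spread over sub-surface bins up to the period maximum. The generator
uses a crude local-solar-hour day flag (06–18 h); the analysis uses true
solar elevation. Mortality, pop-off, predation, SST fields and light curves
are not simulated.

What passing tests show: the estimators are correct (oracle agreement),
unbiased enough (parameter recovery), and better than the naive alternative
(smoother vs interpolation) under a generator that captures error scales,
irregular sampling, gaps and mode switching. What they do not show:
performance under real geolocation pathologies (longitude bias after rapid
east–west movement, sea-state-dependent surfacing), which the original
study documents qualitatively.

## Numerical choices

- Earth radius 6371.0 km, spherical distances; projection errors are far
  below location error.
- Duplicate timestamps keep the better Argos class (3>2>1>0>A>B>GL).
- EM convergence: relative log-likelihood change < 1e-8 or 500 iterations;
  speed floor 1e-6 km/h keeps gamma densities finite.
- Filter guards: singular innovation covariance raises an error naming the
  timestep; smoother gains use a 1e-12 ridge.
- Optimizer: L-BFGS-B on log-parameters, bounds β ∈ [1e-3, 1e3],
  σ ∈ [1e-2, 1e4].
- All randomness flows from explicit integer seeds; the pipeline spawns
  named substreams per stage from one root seed.

## Problem sizes used in the validation experiments

Oracle agreement: 200 random ≤10-point tracks. Parameter recovery: 20
replicates of 300 observations over 100 days. Smoother comparison: 50
60-day tracks at 2.3 fixes/day. Mode recovery: 8 animals × 150 days at
6 fixes/day. KM-crossing recovery: 20 cohorts of 12 animals × 30 days with
a 16-day suppressed-ARB window. Depth calibration: 200 null datasets of
100 periods; power: 100 replicates at 100 periods per group. These sizes
make the full validation run in a few minutes on one core while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The original supplements (error multiplier tables, density-family
  details, per-animal parameter tables) are unavailable; the gamma ×
  wrapped-Cauchy product mixture and the error-model defaults are declared
  substitutes and cannot be checked against the originals numerically.
- Per-step classification with run-length smoothing approximates the
  original segment-likelihood procedure; no posterior state probabilities
  are produced (by design).
- The KM analysis replaces the original Cox-model phrasing; covariate
  effects (ordinal date) are out of scope.
- Time-at-depth gap filling is a local-linear smoother, not loess; the
  statistical intent (smooth interpolation of bin series) is preserved.
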