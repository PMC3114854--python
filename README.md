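# mtrack

Movement-ecology analysis of satellite-tagged pelagic fish. The package
implements the full telemetry chain used for double-tagged striped marlin in
the southwest Pacific: irregular, error-prone positions from Argos
satellite-linked tags and light-level geolocations are fused into regular
12-hour trajectories with a continuous-time correlated random walk (CTCRW)
Kalman smoother; trajectory steps are classified into four pseudo-behavioural
modes; post-release capture effects are quantified with survival and
rank-based analyses; and pop-up-tag depth records are summarized by day and
night. A synthetic-data generator with the deployment's statistical
structure (mode-switching movement, class-dependent Argos errors,
heavy-tailed geolocation errors, observation gaps, binned depth summaries)
makes every stage testable against known ground truth.

Intended users: movement ecologists and fisheries scientists working with
SLRT/PSAT tag data, and methodologists who want a tested, self-validating
reference implementation of this analysis chain.

## The model

Per planar coordinate the CTCRW is an integrated Ornstein–Uhlenbeck velocity
process

    dv = -beta * v dt + sigma * dW,

which discretizes exactly over any lag Delta:

    v(t+Δ) = e^{-βΔ} v(t) + ζ,     x(t+Δ) = x(t) + v(t)(1-e^{-βΔ})/β + ξ,

with closed-form Gaussian (ξ, ζ) covariances. Irregular observation times
and per-fix error classes therefore slot directly into a Kalman filter;
(β, σ) are estimated by maximum likelihood and a fixed-interval smoother
yields positions and uncertainties every 12 h.

Step speeds are modelled with two gamma densities (slow/fast) and turning
angles with two zero-mean wrapped-Cauchy densities (directed/tortuous); the
four product components are the modes slow-transit, fast-transit, slow-ARB
and fast-ARB (ARB = area-restricted behaviour). Steps take the mode with
the highest component likelihood (equal priors); fast-ARB is flagged as
error-dominated. Time to first ARB is summarized with a Kaplan–Meier curve
(Greenwood variance, log–log CI) and its 50:50 crossing day; early-vs-late
movement contrasts use the Wilcoxon rank-sum test with a Hodges–Lehmann
shift; depth analyses aggregate 12-bin time-at-depth records onto common
bins by day/night (solar elevation) and compare period-maximum depths
between behaviours.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Run the full synthetic pipeline (simulate → regularize → classify →
capture-effects → depth) into a scratch directory:

```sh
mtrack run --seed 3 --out-dir out/
```

or from Python:

```python
from mtrack import load_config, run_pipeline, make_report

cfg = load_config(None)          # documented defaults
cfg["seed"] = 3
cfg["simulate"] = {**cfg["simulate"], "n_animals": 2,
                   "duration_days": 50.0, "with_geolocation": False}
run_pipeline(cfg, "out")
report = make_report("out")
ce = report["sections"]["capture_effects"]
print("KM 50:50 crossing day:", ce["km_crossing_day"])
print("early vs late speed:", ce["early_late_speed"])
```

which prints (numbers from this exact config and seed):

```
KM 50:50 crossing day: 1.0
early vs late speed: {'early_mean_kmh': 0.6262917350530981,
 'late_mean_kmh': 0.34580869418589455,
 'p_value': 0.00010572194024431932, 'hl_shift_kmh': 0.23345204137121806}
```

Reading the output: without any post-release suppression in the generator,
area-restricted behaviour appears almost immediately — the Kaplan–Meier
survival of "no ARB yet" drops below 0.5 on day 1. Early travel speeds
(first 10 days) are nonetheless significantly faster than later ones
(Hodges–Lehmann shift +0.23 km/h, rank-sum p ≈ 1e-4) because simulated
animals are released in fast-transit mode, mirroring the real departure
behaviour. Note that under this default error structure (Argos class mix
with up to 12-km scatter) location error produces occasional spurious ARB
steps, so a generator-imposed ARB-free window is masked in a 2-animal
cohort; the suppressed-window recovery experiment in
`mtrack.experiments.km_crossing_recovery` uses denser, cleaner observation
streams and recovers a 16-day window to within about a day.
`out/report.md` also contains the 25-animal deployment-table summary (mean
weight 79.8 kg, 1431 tag-days, 799 SLRT days, 973 PSAT days).

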