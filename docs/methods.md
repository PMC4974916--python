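# Methods

This note records the models implemented in `proxcal`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not establish about real deployments.

## Physical propagation model

Radio power received a distance `r` (m) from a transmitting tag is
modelled as inverse-square spherical spreading times exponential
absorption in a homogeneous, isotropic medium:

```
Pr/P0 = C * 10^(beta r / 10) / r^2            (linear scale)
RSSI  = K + beta r - 20 log10 r               (dB scale, K = 10 log10 C)
```

`beta` (dB/m, constrained <= 0) captures scattering/absorption and `K`
(dB) everything multiplicative: transmit power, antenna gain, habitat
and height.  Both are treated as functions of a *stratum* — one of 10
combinations of 5 habitat classes and 2 heights (ground 0.1 m, arboreal
4 m).  Two consequences shape everything downstream: RSSI is strictly
decreasing in `r`, and its slope magnitude is greatest at short range,
so close encounters are intrinsically better resolved than distant
ones.

### Dipole directivity

A harness-mounted tag behaves as a dipole tilted ~45° to the
horizontal.  For two tags at the same height, the relevant slice of the
"doughnut" radiation pattern is the horizontal in-plane pattern
`I(theta) = (1 + cos^2 theta)/2` (power fraction; broadside `theta = 0`
radiates twice the front/back power).  The pair effect is the product
of the transmitter pattern and the receiver pattern rotated by `phi`
about the line of sight:

```
D(theta, phi) = (1 + cos^2 theta)(1 + sin^2 phi) / 4   in [1/4, 1]
delta         = 10 log10 D                             in [-6.02, 0] dB
```

`K` is decomposed as `kappa + delta`, giving the working model
`RSSI = kappa(h,z) + beta(h,z) r - 20 log10 r + delta(theta, phi)`.

The orientation average of the directivity is computed on the **power
scale**: `10 log10 E[D] = 10 log10(9/16) ≈ -2.50 dB` for independent
uniform angles.  Averaging `delta` itself on the dB scale would give
≈ −2.75 dB instead; powers add, logarithms do not, so the power-scale
convention is used and the discrepancy is documented in the function
contract.

Angle conventions: angles are accepted in degrees, any real value, and
folded into [0°, 180°] by the pattern's periodicity and reflection
symmetries.  The asymmetric `cos^2`/`sin^2` convention (transmitter
angle measured from broadside, receiver angle from forward) is kept
exactly as defined by the extrema — side-by-side `(0°, 90°)` is the
maximum, aligned `(90°, 0°/180°)` the minimum; reciprocity under
exchanging transmitter and receiver roles is not asserted.

Out of scope by design: anechoic-chamber-measured radiation patterns,
body-shielding corrections and near-field effects.

## Encounter-log handling

Logs are CSV records `(this.ID, enc.ID, first.time, last.time,
RSSI.max, RSSI.min, RSSI.mean, type)` with times in integer 1/64-s
ticks.  Ticks are kept as exact integers internally (10-digit
timestamps lose precision as floats) and converted to seconds only for
presentation.  Cleaning applies three rules in a fixed order — type
code must mark tag-to-tag communication; the log must be single-pulse
(min = mean = max RSSI and equal times); the first pulse time must fall
inside the trial window — and charges each removal to the *first*
failing rule, making the report deterministic.  The set of accepted
type codes is a parameter defaulting to `{1}` (the code semantics
beyond tag-to-tag vs other are hardware-defined and not enumerable
here).  The window test uses `first_time`; for single-pulse logs the
choice is immaterial.  A multi-pulse average whose pulses happened to
be identical is indistinguishable from a single pulse by the stated
rule and is accepted as one.

Multi-pulse aggregation chunks consecutive single pulses for a directed
pair into groups of at most `max_pulses` and records min/max/mean and
first/last times.  The chunk mean never exceeds the chunk max, which is
why threshold-filtering on mean RSSI is conservative.

## Synthetic calibration experiments

The generator emulates field calibration: arrays of 12 (or 18) tags,
three per 1.9-m crossbar, deployed per stratum for 15-minute trials
with one pulse per tag per 20 s (45 pulses per direction by default).
The exact bar layout of the original experiments is not published;
the default layout stacks bars along one axis with the nearest two bars
0.93 m apart and the farthest placed so the longest diagonal pair spans
exactly 25.07 m, reproducing the printed endpoints of the calibration
range.  The counts of *distinct* distances depend on unprinted geometry
and are not reproduced.  Antenna bearings cycle through
{90°, 135°, 0°, 45°} along the array, generating in-plane angle pairs
across the full 0–180° range, including parallel and perpendicular
examples.  Cross-height pairs (one tag on the ground, one in the
canopy) are excluded, matching the calibration design.

Simulated RSSI adds, to the physical model: per-tag `(send, receive)`
effects from a bivariate normal (default variances 1.0, correlation
0.412 — the published point estimate that good transmitters are also
good receivers); a pair-level `exchange` effect with stratum-specific
variance (default 4.0 dB², the dominant component); a directed-pair
`replicate` effect (default 1.0); and residuals (default 4.0).  Each
unordered pair gets two replicate labels per trial (A→B and B→A).
Exchange effects are drawn independently per (pair, stratum): a pair
re-measured in a new stratum gets a new effect (cross-stratum
correlation of pair effects is unknowable from the published design;
independence is the simplest testable reading).

The default per-stratum `(kappa, beta)` are **illustrative**, not
fitted field values (those live in an unpublished supplementary table).
They are ordered to reflect the reported qualitative findings —
arboreal `kappa` and `beta` exceed ground values in every habitat, and
open gallery forest attenuates least while fig and shrub habitat
attenuate most — with magnitudes inside the `K = 20–30 dB`,
`beta = −0.2 … −1.0 dB/m` envelope of the physical model's worked
examples.

What the generator does *not* emulate: body/carcass dielectric effects,
tag malfunction, humidity and weather drift, temporal correlation of
movement, and memory/firmware artefacts.  Passing recovery tests
therefore show the *statistical machinery* is correct under the model's
own assumptions, not that the model captures every field effect.

## Hierarchical model and sampler

The fitted model, on the endogeneity-free response
`y = RSSI + 20 log10 r`:

```
y = kappa(h,z) + beta(h,z) r + gamma delta(theta,phi)
    + send(tx) + receive(rx) + exchange(pair; h,z)
    + replicate(directed pair, trial) + eps
```

All random effects are zero-mean normal with estimated variances;
`(send, receive)` are bivariate with estimated 2×2 covariance;
`exchange` has one variance per stratum; `replicate` is nested as
directed-pair-within-trial.  `gamma` tests the dipole assumption
(`gamma = 1` if the physical directivity is right).

Sampling is a blocked Gibbs scheme with fully conjugate updates: a
joint multivariate-normal draw for the fixed effects; all send effects
as one block given receive effects (each pulse has exactly one sender,
so senders are conditionally independent), then vice versa; an
inverse-Wishart draw for the tag covariance; blocked normal draws for
exchange and replicate effects; inverse-gamma draws for all scalar
variances.  Priors are weakly informative and configurable:
`N(0, 1e8)` on fixed effects, inverse-gamma(0.001, 0.001) on scalar
variances, inverse-Wishart(df 3, 0.01·I) on the tag covariance.  The
default schedule — 130 000 iterations, 30 000 burn-in, thin 20 —
retains exactly 5 000 samples.  Correctness is defined by parameter
recovery and interval coverage on synthetic data (plus an OLS
cross-check of the fixed effects in the residual-noise-only
configuration), not by matching any specific sampler's trajectory.

Posterior point estimates are **modes**, located by maximising a
Gaussian kernel density (Silverman bandwidth) on a 512-point grid over
the sample range; intervals are central 95% sample quantiles; modes are
clipped into their interval for degenerate/skewed cases.  Predictive
bands around the fitted mean use the summed variance components for the
stratum (send + receive + exchange + replicate + residual; send and
receive belong to different tags in any one pulse, so no covariance
term) with ±1.96 half-width — constant in `r`, so both edges fall
monotonically.

Practical notes from the recovery experiments: `gamma` is identified
only through between-pair contrasts and mixes more slowly than the
other fixed effects (short chains visibly under-cover it; the package's
coverage tests run 13 000/3 000/10 on ~260-observation datasets, which
is sufficient), and the tag-level covariance/correlation is essentially
unidentified with only ~12 tags — estimating it usefully needs many
more tags than a single array provides.

## Population simulation

Wild pulses are i.i.d. draws of `(r, stratum, theta, phi, noise)`:

- **Distances** come from one of three scenarios.  `uniform-distance`
  draws `r` uniform on `(0, max]`, with `max` defaulting to 25.07 m
  (the calibration range) — the original support is unstated, and the
  inverted quantiles depend directly on this choice, so it is surfaced
  loudly.  `random-2d` uses the distance between two fresh uniform
  points in the study square (the square line-picking distribution;
  positions are resampled per pulse).  `clustered-groups` scatters
  group centres uniformly in the square, places members uniformly in a
  disc of the given diameter (a hard 10-m diameter by default), and
  draws a uniformly random pair per pulse, pooling within- and
  between-group distances.  Defaults (36 individuals, 4000 m square,
  groups of 3, 10 m diameter) describe the studied crow population.
- **Contexts** are categorical draws from the habitat-preference table
  (the published video-tracking time budget; its percentages sum to
  100.1 and are renormalised).  Both pair members share the stratum.
- **Orientations** `theta, phi` are independent uniform — antenna
  alignment in the wild is assumed unbiased.
- **Noise** re-draws every variance component per pulse (send, receive,
  exchange, replicate, residual), the widest-spread reading of the
  fitted variances; a switch (`persistent_tag_effects`) instead fixes
  send/receive per individual of a virtual population.  Coefficients
  are point estimates (posterior modes); full posterior propagation is
  out of scope.

Note an asymmetry of the default scenarios: the bounded
uniform-distance support caps its distances at 25.07 m, while
clustered-groups pools kilometre-scale between-group pairs — so
clustering yields *both* more mass at very large distances and a spike
of short within-group distances (a fraction 2/(n−1) ≈ 0.057 of pairs
share a group).  That bimodality is precisely what makes the RSSI
filter informative under the clustered scenario.

## Distance inversion

Given simulated pulses and a threshold `T`, the inversion keeps pulses
with `rssi >= T` (inclusive) and reports empirical distance quantiles
(default levels 0.5 and 0.95) and the proportion of retained pulses
within given distance thresholds.  Quantiles use the median-unbiased
(Hyndman–Fan type 8) definition, stable in heavy right tails.  At least
100 retained pulses are required; otherwise the failure message says to
lower the threshold or simulate more pulses.  A threshold sweep runs
the same computation across candidate cut-offs and verifies the
nested-filter property (retained counts non-increasing in the
threshold).

The zero-variance, single-stratum, uniform-distance configuration has a
closed form used as the test oracle: RSSI is strictly decreasing in
`r`, so the retained set is exactly `{r <= r*}` with `r*` the root of
`kappa + beta r - 20 log10 r = T`, and uniform order statistics give
median `r*/2` and 95% quantile `0.95 r*`.  The Monte-Carlo quantiles
match these within 0.05 m at 10⁵ pulses.

Reproducing the original study's printed inversion quantiles (e.g.
3.51/14.51 m under uniform distances, 4.74/11.29 m under clustered
groups, at RSSI ≥ 15) requires its fitted supplementary coefficient
table, which is not publicly printed; given such a table as a CSV the
identical machinery applies (`datasets.read_coefficient_table`).
Assigning calibrated distances to *individual* field logs is
deliberately unsupported — only distributional outputs are exposed.

## Problem sizes and numerical choices

The shipped tests use scaled-down problem sizes chosen as sensible
desk-scale experiments: 12-tag arrays, 2 strata, 2 pulses per direction
(~264 observations) for recovery/coverage runs with the
13 000/3 000/10 MCMC schedule; 10⁵-pulse populations for
distributional checks and the inversion oracle; 3×10⁵ pulses for the
end-to-end pipeline check.  Tolerances follow the governing statistics:
3 standard errors for moment checks, KS distance 0.01 at n = 10⁵ for
distributional fits, 0.05 m for the inversion oracle, ≥ 80% empirical
coverage for 95% intervals over 20 replicates.

Degenerate inputs are handled explicitly: zero variance components
short-circuit to exact zeros in the generator (and the bivariate tag
draw uses an eigen square root, valid for singular covariances);
constant posterior samples summarise to zero-width intervals;
rank-deficient fixed-effect designs fail with the confounded columns
named rather than being silently repaired.

## Known limitations

- Real radiation patterns deviate from the ideal dipole (body
  shielding, ground-plane effects); `gamma` absorbs only a linear
  rescaling of the dipole shape.
- The Gibbs sampler assumes Gaussian effects and residuals throughout;
  no robust/heavy-tailed option.
- Tag covariance estimation needs many tags; with one array it is
  prior-dominated.
- i.i.d. pulse sampling ignores movement and temporal correlation, so
  encounter *durations* are outside the model.
- The inversion output is conditional on the assumed spatial scenario;
  the three scenarios bracket, but do not estimate, the truth.
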