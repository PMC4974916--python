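# proxcal

Calibration toolkit for animal-borne **proximity loggers** — transceiver
tags that log the received signal strength (RSSI, in dB) of radio pulses
exchanged between tagged animals.  RSSI carries information about
tag-to-tag distance, but the mapping is noisy and habitat-dependent, so
converting field-recorded signal strength into animal-to-animal distance
requires a careful, study-specific calibration.  `proxcal` implements a
four-stage calibration pipeline of the kind used for long-range,
raw-RSSI logging systems deployed on wild birds:

1. **Encounter-log handling** — reading, writing and quality-controlling
   logger CSV downloads (single-pulse filtering, tag-to-tag type codes,
   trial time windows), plus emulation of the multi-pulse averaging
   firmware option.
2. **Physical propagation model** — RSSI as inverse-square spreading
   plus exponential absorption, corrected for the relative orientation
   of two tilted dipole antennas:

   ```
   RSSI = kappa(h,z) + beta(h,z) * r - 20 log10(r) + gamma * delta(theta, phi)
   delta(theta, phi) = 10 log10[ (1 + cos^2 theta)(1 + sin^2 phi) / 4 ]
   ```

   with per-stratum offset `kappa` (dB) and absorption `beta` (dB/m,
   <= 0) over 10 habitat-height strata (5 habitats x {ground 0.1 m,
   arboreal 4 m}), and directivity `delta` between −6 and 0 dB
   (orientation average −2.5 dB on the power scale).
3. **Hierarchical statistical model** — the response
   `y = RSSI + 20 log10 r` is fitted as a Bayesian Gaussian mixed model
   with per-stratum fixed effects, a directivity coefficient `gamma`
   (`gamma = 1` validates the dipole assumption), correlated per-tag
   (send, receive) effects, pair-level exchange effects with
   stratum-specific variances, directed-pair replicate effects and
   residual noise — sampled by a blocked Gibbs scheme (default schedule
   130 000 iterations, 30 000 burn-in, thin 20 → 5 000 retained
   samples), summarised as posterior modes with 95% credible intervals.
4. **Population simulation and distance inversion** — wild pulses are
   simulated under a spatial scenario (uniform-distance, random-2d, or
   clustered groups of 3 in a 4 km square), habitat contexts drawn from
   an observed time-budget table, orientations uniform; an RSSI filter
   threshold is then inverted into the distribution of true distances
   among retained pulses ("50% of pulses at RSSI ≥ 15 come from within
   q0.5 metres").

A synthetic calibration-experiment generator (12/18-tag crossbar arrays
spanning 0.93–25.07 m) makes the whole pipeline testable end-to-end with
known ground truth.

## Worked example

`examples/` contains one narrative script per capability.  The fit
example (`python examples/03_calibration_fit.py`) simulates two 12-tag
array trials (528 pulses, 0.93–25.07 m) with known parameters and fits
the mixed model:

```
                           name     mode    lower    upper
         kappa:casuarina:ground   21.162   20.013   22.370
       kappa:paperbark:arboreal   27.360   26.061   28.586
          beta:casuarina:ground   -0.568   -0.616   -0.513
        beta:paperbark:arboreal   -0.375   -0.431   -0.309
                          gamma    0.960    0.680    1.259
...
gamma interval [0.680, 1.259] contains 1 (dipole-model check)
```

The generating values were `kappa = 22, beta = -0.6` (casuarina ground)
and `kappa = 27, beta = -0.35` (paperbark arboreal): the posteriors
recover them, and `gamma`'s interval straddles 1, as the dipole model
predicts.  The inversion example (`python
examples/04_distance_inversion.py`) then pushes 100 000 simulated wild
pulses through the fitted relationship and reports, per spatial
scenario, the distance quantiles of pulses surviving an RSSI ≥ 15
filter, e.g.

```
clustered-groups  :   1299/100000 pulses at RSSI >= 15; q50 =  1.77 m, q95 =  4.25 m
```

— half the retained pulses originate within ~1.8 m, i.e. the filter
isolates close-range encounters.  (These numbers use the package's
illustrative coefficient defaults; with a fitted coefficient table from
a real calibration, the same machinery produces study-specific
estimates.)

There is also a thin CLI mirroring the stages:

```sh
proxcal clean --logs logs.csv --out out/
proxcal end-to-end --config run.toml
```

## Layout

- `src/proxcal/propagation.py` — path-loss and dipole-directivity model
- `src/proxcal/logstore.py` — encounter-log records, CSV I/O, cleaning
- `src/proxcal/synthetic.py` — calibration arrays and the RSSI generator
- `src/proxcal/hierarchy.py` — the Gibbs-sampled mixed model
- `src/proxcal/population.py` — spatial scenarios and wild-pulse simulation
- `src/proxcal/inversion.py` — threshold → distance-quantile inversion
- `src/proxcal/datasets.py` — built-in tables and illustrative defaults
- `src/proxcal/cli.py` — the `proxcal` command
- `docs/methods.md` — model assumptions, defaults and limitations
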