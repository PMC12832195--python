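# sealemerge

Estimating when ringed seals (*Pusa hispida*) stop hauling out in snow lairs
and start basking openly on the sea ice ("emergence") from satellite-tag
wet/dry telemetry.

Ringed seals overwinter in snow lairs excavated over breathing holes and, in
spring, switch to basking on the ice surface to molt. The switch matters for
aerial-survey population monitoring (only basking seals can be counted) and
as a climate-sensitive phenological signal, but tags cannot observe it
directly: a wet/dry sensor cannot tell a dry seal in a lair from a dry seal
basking. What it *can* see is that the two behaviours differ — lair-state
seals haul out a small fraction of the day, mostly at night; emerged seals
haul out over half the day, concentrated at solar noon. `sealemerge` turns
that behavioural contrast into emergence dates.

## The model

Hourly percent-dry timelines are filtered to remove surfacing artifacts (an
hour counts as hauled out if it is ≥ 50% dry, or < 50% but adjacent to an
hour ≥ 95% dry) and summarized into two daily observations per seal:

* `prop_ho` — proportion of the day hauled out, in [0, 1];
* `peak_hr` — weighted circular mean solar hour of haul-out, in radians with
  solar noon at 0 (NA when the day is 0% or 100% hauled out).

These feed a two-state hidden Markov model with states *lair* and *emerged*:

* emissions: `prop_ho` ~ zero–one-inflated beta (masses π₀ at 0 and π₁ at 1,
  Beta(a, b) on the interior); `peak_hr` ~ von Mises(μ, κ);
* transition: the daily emergence probability is logit-linear in covariates,
  `logit p_t = βᵀx_t` (candidates include DOY, daylength, air temperature,
  melt indices, sea-ice concentration and interactions — 15 formulas with
  14–17 total parameters);
* constraints: the emerged state is absorbing (`P(emerged→emerged) = 1`) and
  all February days are forced into the lair state, making the HMM a
  probabilistic change-point model with monotone state paths.

Models are fitted by maximum likelihood (multi-start quasi-Newton over
working-scale parameters) and compared by AIC. The Viterbi path gives each
seal's emergence date (the decoded lair→emerged transition day), a
leave-one-out refit measures the stability of those dates, and post-hoc OLS
regressions of emergence day-of-year on latitude or year (AICc-compared)
describe spatiotemporal trends.

A synthetic-data module generates hourly timelines, covariate trajectories
and latent truth from this same generative model, so the entire pipeline is
testable without any external download.

## Worked example

```python
import sealemerge as se
from sealemerge import covariates, decoding

out = se.simulate(se.SimConfig(n_seals=15, seed=3))     # synthetic tag data
ann = covariates.annotate_series(out.daily_series)       # daylength, TDD, ...
fit = se.fit(se.HMMSpec("air_temp+daylength"), ann, n_restarts=2, seed=0)
tracks = decoding.viterbi_all(fit, ann)
emergence, _ = decoding.emergence_dates(tracks, ann)
print(decoding.state_summaries(tracks, ann))
```

Running `examples/04_decode_emergence.py` (this exact analysis) prints:

```
seal_year_id emergence_date   doy  latitude
 sim000_2015     2015-05-12 132.0 69.248218
 sim001_2015     2015-05-15 135.0 68.272070
 ...
Viterbi vs truth: 100% of seals within 3 days (max |error| 1 d)

Behaviour by decoded state:
  state  mean_prop_pct  sd_prop_pct  peak_solar_hour  kappa_hat
   lair          18.99        22.17            23.01       0.42
emerged          54.67        23.45            11.78       5.64
```

Decoded emergence dates cluster in mid-May and track the simulated truth to
a day; lair-state seals hauled out ~19% of the day near solar midnight with
weak diel concentration, emerged seals ~55% near solar noon with strong
concentration — the behavioural signature the model keys on.

The other examples cover simulation (`01`), the hourly→daily preprocessing
round trip (`02`), AIC model selection and fitted emergence-probability
curves (`03`), and trend regression plus leave-one-out sensitivity (`05`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch: it simulates five field seasons
of adult-like seals, pushes a subsample through hourly rendering and
preprocessing, fits and AIC-ranks candidate transition models, Viterbi-
decodes emergence dates, summarizes behaviour by state, and runs the
latitude/year trend regression, writing its metrics JSON to `--out`.
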