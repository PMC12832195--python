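# Methods

## Observation model

Each seal-year is a contiguous daily series of two observations derived from
hourly wet/dry telemetry.

**Proportion of day hauled out** is the sum of hourly percent-hauled-out
values divided by 24, defined only on days with a complete 24-hour record
(partial days are treated as missing rather than extrapolated, to avoid
sampling bias toward hours when tags transmit). The hourly values come from
the raw percent-dry timeline through a surfacing filter: an hour is accepted
as haul-out if it is ≥ 50% dry, or < 50% dry but chronologically adjacent to
an hour ≥ 95% dry; all other hours are set to 0. Adjacency is evaluated only
within contiguous hourly runs — an hour on the far side of a transmission
gap does not qualify as a neighbour.

**Peak haul-out hour** is the weighted circular mean of the solar hour of
haul-out, with the hourly percent as weight. Each hour is represented by its
midpoint (h + 0.5) — the unbiased representative of an hour-long bin —
converted to mean local solar time (`utc + longitude/15 mod 24`; the ±15-min
equation of time is ignored as small against 1-h bins) and mapped to radians
on [−π, π) with solar noon at 0. Days that are 0% or 100% hauled out carry
no diel information and are set missing, as is the zero-resultant
(antipodal) case where the mean direction is undefined.

Days are binned on the UTC calendar; the solar conversion happens per hour,
not per day. Daily locations are error-weighted means of Argos fixes
(weight 1/error-radius, longitude averaged on the circle), forward-filled
across gaps and back-filled at the start of a record from the first
available location — ringed seals occupy small winter home ranges, so a
carried-forward location errs far less than the 25–32 km covariate grids it
indexes into.

## Covariates

Daylength uses the astronomical formula `(24/π)·arccos(clamp(−tanφ·tanδ))`
with the cosine declination approximation δ = −23.44°·cos(2π(doy+10)/365.25)
(checked against an independent Fourier-series ephemeris to < 0.25 h; the
clamp produces exact 0 h / 24 h polar night and day). Thawing degree days
count days since 1 April with mean temperature ≥ 0 °C, resetting yearly. The
trailing 7-day mean temperature uses whatever days are available in the
window (gaps are pervasive and the transition model needs a value every
day); a window with no data is missing. Melt indices are the observation DOY
minus the satellite melt-onset DOY of the cell. Grid extraction takes the
cell containing the (filled) daily location; masked cells fall back to the
nearest valid cell within a configurable radius (default 2°), replacing the
kriging interpolation a full reanalysis workflow would use.

## The hidden Markov model

Two states, lair (0) and emerged (1). Emissions are state-dependent:
a zero–one-inflated beta for the proportion (masses π₀, π₁ and Beta(a, b)
on the interior — the shape parameterization; only the total parameter
count is structurally constrained, and shapes make the working scale
simplest) and a von Mises(μ, κ) for the peak hour. Missing observation
channels contribute an emission factor of 1, independently per channel.

Structure:

* **Absorbing emerged state.** The transition matrix each day is
  `[[1−p_t, p_t], [0, 1]]` with `logit p_t = βᵀx_t`; covariates are those of
  the day being entered. Emergence is modelled as one-directional: state
  paths are monotone and the HMM is effectively a probabilistic change-point
  model.
* **Known February states.** All February days are forced to lair,
  implemented as an emission mask (emerged emission ≡ 0), which is exactly
  equivalent to restricting the path space.
* **Initial distribution.** One free parameter δ = P(start emerged), giving
  the 14-parameter intercept-only model (8 ZOIB + 4 von Mises + 1 δ + 1 β₀).

The candidate set is 15 fixed transition formulas (null; DOY; DOY×sex;
DOY×latitude; daylength; daylength×latitude; DOY×year; sea-ice
concentration; early/continuous melt index; air temperature; air temperature
+ daylength; 7-day temperature; 7-day temperature + daylength; thawing
degree days), spanning 14–17 parameters, compared by standard AIC with ties
broken toward fewer parameters.

### Likelihood, fitting, numerics

The likelihood is the per-seal-year scaled forward algorithm, vectorized
across seals; per-step emission rescaling in log space keeps it stable for
long series. Optimization is unconstrained quasi-Newton (L-BFGS-B, numerical
gradients) over working parameters: a two-stage logit for (π₀, π₁)
guaranteeing π₀+π₁ ≤ 1, log for a, b, κ, identity for μ (wrapped to [−π, π)
on back-transform; whether the original analysis constrained or wrapped μ is
not determinable, and wrapping keeps the optimizer unconstrained), logit for
δ, identity for β. Covariate columns are z-scored internally for optimizer
conditioning and coefficients reported back on raw units (the linear map is
exact, including for interaction columns). Default 5 restarts (the first
from initial values anchored to prior field estimates — lair ~16% of the day
hauled out, emerged ~55% — the rest perturbed with SD 0.5 on the working
scale); the best log-likelihood is kept. Standard errors come from the
numerically differentiated Hessian of the working-scale negative
log-likelihood; emergence-probability curves carry delta-method CIs built on
the logit scale from the β block of that covariance (validated against a
parametric bootstrap).

### Decoding

Viterbi runs in log space with the same constraints and missing-data rules
as the likelihood. Exact ties are broken toward the **later** transition
(conservative emergence dating; a documented convention, since ties have
probability zero for continuous data but arise in degenerate tests). A
seal's emergence date is the first decoded emerged day; seal-years that
never leave the lair state are reported separately with coverage
diagnostics. State summaries (mean/SD proportion, circular mean peak hour,
resultant-length κ estimate) are computed over observed days only.
Leave-one-out sensitivity refits the selected model with each unit removed —
by default each seal-year; a `unit_col` lets a two-year animal's seasons
drop together — and reports the per-seal SD of emergence DOY across
iterations, with non-convergent refits flagged and excluded.

## Post-hoc trends

Emergence DOY (the date's own calendar year and actual calendar DOY,
including leap years) is regressed on latitude or on year by OLS; the two
single-predictor models are compared by AICc with k = 3 (intercept, slope,
residual variance). No joint latitude+year model is fitted — the two are
strongly rank-correlated in pooled telemetry datasets, and the Spearman
diagnostic is reported instead. `predict_mean` gives the t-based CI for the
conditional mean at a target latitude (a mean-type interval, not a
prediction interval for a new seal).

## Synthetic data: what it does and does not emulate

The generator is the model's own stated world: one stationary home-range
location per seal-year (latitude uniform on 66–72° N by default); air
temperature as a logistic seasonal ramp from −20 °C to +5 °C centred on DOY
135 with width 12 d plus iid N(0, 3²) daily noise; deterministic daylength;
monotone latent paths with raw-scale transition coefficients
(−13.5, 0.35 /°C, 0.65 /h) chosen so emergence probability is ~0 below
−10 °C or 10 h daylength and rises steeply past 0 °C / 15 h; adult-like
emissions (lair: π₀ = 0.35, Beta(1.2, 3.0), μ = +2.8 rad, κ = 0.5 — overall
mean ~19% of the day hauled out near solar midnight; emerged: π₀ = 0.02,
π₁ = 0.05, Beta(2.7, 2.3), μ = −0.05, κ = 5 — ~55% near solar noon);
contiguous transmission gaps starting at 0.02/day with geometric mean length
4 d. Hourly rendering packs each day's haul-out time into a contiguous block
of 100% hours centred on the peak hour (plus one partial edge hour), an
artifact convention — real within-day bout structure is multimodal and is
not claimed — built so the preprocessing round trip recovers the proportion
within 1/24 and the peak within one hour bin.

Not emulated: Argos location error, sea-ice drift or spatial covariate
fields, tag-type differences, age- or sex-structured behaviour, and any
latitude dependence of temperature. That last omission means the synthetic
world has only a weak (daylength-mediated, slightly *negative*) latitudinal
gradient in emergence timing, unlike field data where colder northern
springs delay emergence; green trend-regression tests therefore establish
the regression machinery, not a realistic latitude slope. Likewise, fitted
parameter recovery on synthetic data establishes correctness of the
likelihood and optimizer, not robustness to real-data misspecification
(behavioural intermediacy, gradual transitions, occasional lair revisits).

## Degenerate inputs and tie-breaks

Empty hourly input → empty output; a seal-year with no location fix is
rejected explicitly. Zero-resultant circular means are missing. Likelihood
returns −∞ for non-finite parameters or zero-probability data rather than
raising mid-optimization (the optimizer sees a large finite penalty). AIC
ties → fewer parameters; Viterbi ties → later transition. The emergence
probability of a day whose covariates are missing is an error by
construction — locations are always filled, so annotated covariates exist
every day.

## Known limitations

Standard errors assume the usual asymptotics and ignore the uncertainty
introduced by filled locations (real-data CIs are biased narrow, and should
be read conservatively). The subadult regime — weak state contrast, most
records in the lair state — is expressible but not specifically tuned for;
discrete two-state decoding is known to under-detect gradual transitions.
AICc for the HMM itself is deliberately not offered (effective sample size
for autocorrelated series is ill-defined); AICc applies only to the post-hoc
OLS models.
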