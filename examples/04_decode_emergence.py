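"""Viterbi-decode emergence dates and summarize behaviour by state.

Decodes the most probable lair/emerged path per seal under the fitted model,
extracts each seal's emergence date (the day of the decoded transition), and
compares against the simulation truth.
"""

import sealemerge as se
from sealemerge import covariates, decoding

out = se.simulate(se.SimConfig(n_seals=15, seed=3))
ann = covariates.annotate_series(out.daily_series)
fit = se.fit(se.HMMSpec("air_temp+daylength"), ann, n_restarts=2, seed=0)

tracks = decoding.viterbi_all(fit, ann)
emergence, diagnostics = decoding.emergence_dates(tracks, ann)

truth = out.true_emergence.set_index("seal_year_id")["emergence_date"]
est = emergence.set_index("seal_year_id")["emergence_date"]
err = (est - truth.loc[est.index]).dt.days
print(emergence[["seal_year_id", "emergence_date", "doy", "latitude"]].to_string(index=False))
print(f"\nViterbi vs truth: {100 * (err.abs() <= 3).mean():.0f}% of seals within 3 days "
      f"(max |error| {err.abs().max()} d)")

print("\nBehaviour by decoded state:")
print(decoding.state_summaries(tracks, ann)
      [["state", "mean_prop_pct", "sd_prop_pct", "peak_solar_hour", "kappa_hat"]]
      .round(2).to_string(index=False))
# Lair-state seals haul out ~19% of the day around solar midnight; emerged
# seals ~55% tightly concentrated near solar noon.
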