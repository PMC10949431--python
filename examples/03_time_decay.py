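"""Dissimilarity-time decay: is community change directional?

Builds the genotype-level decay table (mean Bray-Curtis between each pair
of sample dates, per genotype) and regresses dissimilarity on elapsed
time.  A positive slope means communities keep diverging from their past
state (directional drift) rather than only cycling with the seasons.
"""

import microtempo as mt

cfg = mt.SynthConfig(seed=2)
table, metadata, _, _ = mt.generate_dataset(cfg)
sub = mt.srs_subsample(
    table, mt.SubsampleConfig(c_min=int(table.counts.sum(axis=0).min()), seed=0)
)
meta = metadata.loc[sub.sample_ids]
d = mt.bray_curtis(sub)

decay = mt.build_decay_table(d, meta)
print(f"decay table: {len(decay)} genotype x date-pair rows")
fit = mt.fit_time_decay(decay)
print(f"slope = {fit.slope:.4f} per 365 d  "
      f"(95% CI {fit.ci_low:.4f} to {fit.ci_high:.4f}), p = {fit.p:.2e}")
print(f"random-intercept (genotype) slope = {fit.lme_slope:.4f}, p = {fit.lme_p:.2e}")
print("\nThe planted model drifts, so the slope is positive and the CI"
      "\nexcludes 0; the mixed model confirms repeated sampling of clonal"
      "\nindividuals is not driving the trend.")
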