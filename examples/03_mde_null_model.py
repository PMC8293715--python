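"""Mid-domain-effect null model: what range-size profile does geometry
alone predict?

Empirical range sizes are reshuffled 1,000 times: every size is placed once
per simulation at a uniformly drawn feasible midpoint, and the per-plot
mean size of covering ranges is averaged over simulations. The closed-form
expectation is computed alongside as a cross-check.
"""
import numpy as np

import elevrange as er

cfg = er.SyntheticConfig(seed=42)
community = er.generate_community(cfg)
ranges = er.species_ranges(community.occurrences)

domain = (cfg.domain_low, cfg.domain_high)
elevs = np.linspace(1900, 5300, 7)
res = er.simulate_mde(ranges["size"], domain, elevs, n_sims=1000, seed=7)
exact = er.mde_expected_profile(ranges["size"].to_numpy(), domain, elevs)

print("elevation  simulated  exact   n_eff")
for e, row, x in zip(elevs, res.table.itertuples(), exact):
    print(f"{e:9.0f}  {row.predicted_mean_range_m:9.0f}  {x:6.0f}  {row.n_effective_sims:5d}")
# The null prediction peaks near the domain centre (the mid-domain effect):
# ranges placed at random in a bounded domain overlap most in the middle.
# Simulated and exact values agree within Monte-Carlo error.
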