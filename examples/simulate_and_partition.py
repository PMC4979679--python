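"""Simulate a small elevational survey and run the full beta-diversity pipeline.

Generates a turnover-structured community (each species occupies a Gaussian
elevational band), pools replicate blocks into site assemblages, and computes
observed plus null-standardized species and functional beta diversity between
the lowest site and each higher site.
"""

import elevbeta as eb

sim = eb.GradientSimConfig(
    n_species=60,
    site_elevations=(900, 1500, 2100, 2700),
    n_years=1,
    scenario="turnover",
    seed=42,
)
cfg = eb.PipelineConfig(n_iter=199, n_axes=2, seed=7)
result = eb.run_simulated(sim, cfg)

wet = result.results.query("season == 'wet'")
cols = ["composition", "comparison_elevation_m", "beta_sor", "beta_sim", "beta_sne",
        "ses_sor", "ses_sim"]
print(wet[cols].round(3).to_string(index=False))
print(f"\nassemblages excluded by the hull filter: {len(result.exclusions)}")
print(
    "\nbeta_sor is total pairwise dissimilarity; beta_sim the turnover part,\n"
    "beta_sne the nestedness-resultant part (beta_sor - beta_sim). SES values\n"
    "outside +-1.96 depart significantly from the null expectation: here\n"
    "species turnover grows with elevational distance and exceeds the swap\n"
    "null at the largest separation, the signature of deterministic species\n"
    "replacement along the gradient."
)
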