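"""Map where in trait space turnover and nestedness dominate.

Compares the lowest-elevation assemblage's hull (on the first two synthetic
traits) against all higher assemblages: trait-space cells occupied by a
higher assemblage but not by the base hull count as turnover (novel
strategies appear upslope); cells inside the base hull count as nestedness
(higher assemblages re-occupy a subset of lowland trait space).
"""

import elevbeta as eb

sim = eb.GradientSimConfig(n_species=60, n_years=1, seasons=("wet",),
                           scenario="nestedness", trait_coupling=0.8, seed=9)
occ, morphology = eb.simulate_dataset(sim)
pooled = eb.pool_blocks(occ)
traits = eb.compute_trait_indices(morphology)
space = eb.pcoa(eb.species_distance_matrix(traits))

matrix = pooled.stratum_matrix("wet", 1)
hulls = {
    site: eb.assemblage_hull(matrix.columns[matrix.loc[site] > 0], space,
                             n_axes=2, site_id=site)
    for site in matrix.index
}
base = min(hulls)
grid = eb.classify_trait_space_regions(hulls[base], [hulls[s] for s in hulls if s != base],
                                       grid_resolution=60)

covered = grid.dropna(subset=["score"])
print(f"base hull: {base:.0f} m, volume {hulls[base].volume:.2f} on 2 axes")
print(f"grid cells covered by higher assemblages: {len(covered)} / {len(grid)}")
print(f"mean score: {covered['score'].mean():+.2f}")
print(f"pure nestedness cells (score -1): {(covered['score'] == -1).mean():.0%}")
print(f"pure turnover cells  (score +1): {(covered['score'] == +1).mean():.0%}")
print(
    "\nScores near -1 mean higher-elevation assemblages mostly re-occupy the\n"
    "lowland hull (functional nestedness); with strong trait filtering the\n"
    "upslope assemblages collapse toward the centre of trait space, so almost\n"
    "every covered cell is nestedness-dominated."
)
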