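"""Alpha diversity, beta diversity, and distance-decay Mantel tests.

Simulates a selection-structured altitudinal dataset (taxa filtered by a
trait evolving on the phylogeny, environment driven by elevation),
computes per-sample diversity indices, Bray-Curtis/UniFrac/betaMNTD
matrices, and asks — with Mantel and partial Mantel tests — whether
community turnover tracks environmental distance once geographic
distance is controlled.
"""

from phyloassembly import (
    alpha_table,
    beta_mntd,
    bray_curtis,
    env_distance,
    geo_distance,
    mantel,
    partial_mantel,
    simulate_scenario,
    weighted_unifrac,
)

# a continuous environmental gradient assigned independently of the
# spatial transect, so the env and geo distance matrices are not collinear
import numpy as np

env_pattern = np.random.default_rng(5).permutation(np.linspace(-1.5, 1.5, 21))
scen = simulate_scenario(
    "selection", seed=5, n_taxa=200, n_samples=21, reads=1500, sigma_w=0.4,
    env=env_pattern,
)
table, tree = scen.table.drop_empty_taxa(), scen.tree
meta = scen.metadata.set_index("sample_id")

alpha = alpha_table(table, tree, n_null=200, seed=5)
print("Alpha diversity (first 3 samples):")
print(alpha.head(3).round(2))

bc = bray_curtis(table)
# the measured variable that actually drives the filter, alongside soil chemistry
meta["filter_env"] = env_pattern
env = env_distance(meta, ["filter_env"])
geo = geo_distance(meta)

res_env = mantel(bc, env, n_perm=999, seed=5)
res_geo = mantel(bc, geo, n_perm=999, seed=5)
res_partial = partial_mantel(bc, env, geo, n_perm=999, seed=5)
print(f"\nMantel Bray-Curtis ~ environment: r = {res_env.r:.3f}, p = {res_env.p:.3f}")
print(f"Mantel Bray-Curtis ~ geography:   r = {res_geo.r:.3f}, p = {res_geo.p:.3f}")
print(f"Partial (env | geo):              r = {res_partial.r:.3f}, p = {res_partial.p:.3f}")
print(
    "\nUnder environmental selection the env correlation should survive\n"
    "controlling for geography: turnover follows the niche, not the map."
)
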