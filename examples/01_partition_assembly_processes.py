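"""Classify community assembly processes for a dispersal-limited landscape.

Simulates two habitat patches whose species pools share only 20% of their
taxa, computes betaNTI (phylogenetic null) and Raup-Crick (Bray-Curtis
null) for every sample pair, and partitions pairs into the five assembly
processes. Between-patch pairs should be dominated by dispersal
limitation (|betaNTI| < 2 with RCbray > 0.95): turnover is stronger than
the regional null expects, but phylogenetically random.
"""

from phyloassembly import (
    beta_nti,
    classify_pairs,
    partition_fractions,
    raup_crick_bray,
    simulate_scenario,
)

scen = simulate_scenario(
    "dispersal_limited", seed=4, n_taxa=400, n_samples=16, reads=1000,
    n_patches=2, overlap=0.2,
)
table, tree = scen.table, scen.tree

bnti = beta_nti(table, tree, n_null=199, seed=4)
rc = raup_crick_bray(table, n_null=199, seed=4)
pairs = classify_pairs(bnti.bnti, rc.rc)

cols = [
    "n_pairs",
    "variable_selection_pct",
    "homogeneous_selection_pct",
    "dispersal_limitation_pct",
    "homogenizing_dispersal_pct",
    "undominated_pct",
    "stochastic_pct",
]
grouping = scen.metadata.set_index("sample_id")["group"]
print("Within-patch process percentages:")
print(partition_fractions(pairs, grouping, scheme="within_group")[cols].round(1).to_string())
print("\nAll-pairs process percentages (between-patch pairs included):")
print(partition_fractions(pairs, None, scheme="all_pairs")[cols].round(1).to_string())
print(
    "\nThe all-pairs row shows a large dispersal_limitation_pct driven by\n"
    "between-patch comparisons; stochastic_pct is the share of pairs with\n"
    "|betaNTI| < 2 (no selection signal), matching the regime's ground truth."
)
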