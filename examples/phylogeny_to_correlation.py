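"""From a newick tree to the Brownian-motion correlation matrix.

Relabels a stand-in tip to a species missing from the source tree,
expands one species into two population-level tips (one per effect
size), and converts the result to the tip correlation matrix used as
the phylogenetic random-effect structure.
"""

from symmeta import bm_correlation, expand_populations, read_newick, substitute_tips

tree = read_newick("((Wolbachia_A:1,Wolbachia_B:1):1,(Buchnera:1.5,Rhizobium:1.5):0.5);")

# the species we need is absent; its closest available relative stands in
tree = substitute_tips(tree, {"Spiroplasma": "Wolbachia_B"})

# Wolbachia_A contributed two effect sizes -> two population tips
tree = expand_populations(
    tree, {"Wolbachia_A": ["Wolbachia_A|E1", "Wolbachia_A|E2"]}, epsilon=1e-6
)

corr = bm_correlation(tree)
print(corr.to_dataframe().round(3))
print()
print(
    "Entries are shared root-to-tip path length over total depth: the two\n"
    "populations of Wolbachia_A are correlated at ~1, Spiroplasma (standing\n"
    "on the former Wolbachia_B tip) at 0.5 with them, Buchnera-Rhizobium at\n"
    "0.25, and taxa on opposite sides of the root at 0."
)
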