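"""Rao phylogenetic dissimilarity and ordination of simulated communities.

Simulates a pH-spanning survey (ultrametric OTU tree with Brownian pH
optima, communities assembled by pH niche filtering), computes the Rao
among-community dissimilarity matrix, and ordinates it by principal
coordinates.  The first axis should track the pH gradient.
"""

import numpy as np

from tetralink import (
    SimConfig,
    gen_springs,
    gen_tree_communities,
    mantel,
    env_distance,
    pco,
    rao_dissimilarity,
)

cfg = SimConfig(seed=4)
springs = gen_springs(cfg)
tree, communities = gen_tree_communities(springs, cfg)

h = rao_dissimilarity(tree, communities)
res = mantel(h, env_distance(springs, ["ph"]), n_perm=999, seed=0)
print(f"Rao dissimilarity vs |dpH|: Mantel r = {res.r:.2f}, p = {res.p:.3f}")

ordination = pco(h, n_axes=2)
ph = np.array([r.values["ph"] for r in springs])
axis1 = ordination.coordinates["PCO1"].values
r = np.corrcoef(axis1, ph)[0, 1]
print(
    f"PCO axis 1 carries {ordination.pct_variance[0]:.1f}% of the variance "
    f"and correlates with pH at r = {r:.2f}."
)
print(
    "\nA strong axis-1/pH correlation means acidic and alkaline springs "
    "harbor\nphylogenetically distinct archaeal assemblages — the pattern "
    "the niche-filtered\ngenerator builds in."
)
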