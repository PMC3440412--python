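"""Fisher's exact pathway over-representation on a target gene set.

Builds a toy universe of 200 genes with three pathways, spikes the target
list with members of one pathway, and runs the one-sided hypergeometric
test with Benjamini-Hochberg q-values.
"""

import numpy as np

from tilescan import GeneSet, fisher_enrichment

rng = np.random.default_rng(7)
universe = GeneSet("universe", [f"gene{i:03d}" for i in range(200)])
pathways = {
    "olfactory_transduction": {f"gene{i:03d}" for i in range(0, 25)},
    "oxidative_phosphorylation": {f"gene{i:03d}" for i in range(25, 45)},
    "ribosome": {f"gene{i:03d}" for i in range(45, 60)},
}
# 15 targets: 8 from the first pathway, 7 random others
targets = GeneSet(
    "targets",
    [f"gene{i:03d}" for i in rng.choice(25, 8, replace=False)]
    + [f"gene{i:03d}" for i in rng.choice(np.arange(60, 200), 7, replace=False)],
)

for r in fisher_enrichment(targets, pathways, universe):
    print(f"{r.pathway:28s} k={r.k:2d}/{r.K:2d}  OR={r.odds_ratio:6.2f}  "
          f"p={r.p_value:.2e}  q={r.q_value:.2e}")
print("-> k of the n targets fall in a pathway of K genes (universe N=200);"
      " a small one-sided p flags over-representation")
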