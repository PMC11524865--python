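"""Hypergeometric over-representation of a gene list in gene sets.

Builds a small transcription-factor-target style gene-set collection over an
explicit measured-gene universe, then asks whether a query list is enriched
in any set.  The p-value is the upper-tail hypergeometric probability of the
observed overlap; BH-adjusted values control the FDR across sets.
"""

import numpy as np

from orthoexpress import GeneSetCollection, hypergeom_enrich

rng = np.random.default_rng(4)
universe = [f"g{i:03d}" for i in range(400)]

# planted structure: the query is drawn half from SP1 targets
sp1_targets = list(rng.choice(universe, 60, replace=False))
stat1_targets = list(rng.choice(universe, 50, replace=False))
query = sp1_targets[:25] + list(rng.choice(universe, 25, replace=False))

collection = GeneSetCollection(
    sets={"SP1_targets": frozenset(sp1_targets),
          "STAT1_targets": frozenset(stat1_targets)},
    universe=frozenset(universe))

table = hypergeom_enrich(query, collection, alpha=0.05)
print(table.to_string(index=False))
# "expected" is the overlap a random query of this size would produce;
# SP1_targets should be far above it, STAT1_targets near it.
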