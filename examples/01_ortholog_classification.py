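"""Classify zebrafish-mouse ortholog relationships from a homology table.

Builds a synthetic duplicated-genome homology table, partitions it into
ortholog groups (connected components of the bipartite gene graph), and
summarizes the one-to-one / one-to-many / many-to-many classes the way the
published classification table is laid out.
"""

from orthoexpress import (
    SimConfig, build_groups, collapse_redundant, generate_homology,
    ortholog_fraction, round_percent, summarize_relationships,
)

config = SimConfig(seed=1, n_ancestral_genes=5000)
pairs, truth = generate_homology(config)
groups = build_groups(pairs)
summary = summarize_relationships(groups)

print(summary.to_frame().to_string(index=False))
print(f"\nmouse gene list after collapsing zebrafish-paralog redundancy: "
      f"{len(collapse_redundant(groups, 'b'))} genes")

protein_coding = summary.total_a + truth.attrs["n_orphans_a"]
pct = ortholog_fraction(summary, protein_coding, side="a",
                        class_filter="one-to-one")
print(f"one-to-one orthologs cover {round_percent(pct)}% of the "
      f"{protein_coding} zebrafish protein-coding genes")
# The per-class gene counts sum to each species' ortholog total; the mouse
# total is smaller because several zebrafish paralogs map to one mouse gene.
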