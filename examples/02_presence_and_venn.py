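"""Presence calls and the paralog-aware Venn partition.

Generates synthetic per-cell-type expression for zebrafish hair cells (zHC)
and mouse inner/outer hair cells (IHC/OHC), calls genes expressed at the
0.1 RPKM / FDR <= 0.10 cutoff, and partitions ortholog groups by the exact
set of cell types in which they are expressed.  Each zebrafish-containing
cell also reports how many additional zebrafish paralogs (beyond one per
group) were expressed — the "(+n)" increments of a paralog-aware Venn
diagram.
"""

from orthoexpress import (
    SimConfig, generate_expression, generate_homology, groups_from_truth,
    presence_lookup, venn_partition,
)

config = SimConfig(seed=2, n_ancestral_genes=3000)
_, truth = generate_homology(config)
groups = groups_from_truth(truth)
expr, _, _ = generate_expression(groups, config)

calls = presence_lookup(expr)  # 0.1 RPKM, FDR <= 0.10
part = venn_partition(groups, calls, ["zHC", "IHC", "OHC"],
                      config.cell_species, duplicated_species="a")

print(part.to_frame().to_string(index=False))
for ct in ("zHC", "IHC", "OHC"):
    # the partition-sum identity: cells containing a cell type sum to its
    # expressed total (plus paralog increments on the zebrafish side)
    print(f"expressed in {ct}: {part.totals[ct]} "
          f"(cell sum {part.total_from_cells(ct)})")
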