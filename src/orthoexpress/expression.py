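"""Presence calls and paralog-aware set logic over ortholog groups.

Expression tables are long-format DataFrames with columns
``gene, cell_type, rpkm, fdr`` (one row per gene per cell type).  A gene is
called expressed when its abundance clears 0.1 RPKM at detection FDR <= 0.10.
Gene-level calls are lifted to ortholog-group level (any-member semantics) and
the groups are partitioned into disjoint Venn cells over the measured cell
types.  Because the duplicated (zebrafish) side of a group can contribute
several expressed paralogs, each Venn cell also carries a paralog increment:
the number of additional duplicated-species genes beyond one per group.

RPKM values are never compared across species as absolute magnitudes; all
cross-species logic here is presence- or rank-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RPKM_MIN = 0.1
FDR_MAX = 0.10

EXPRESSION_COLUMNS = ("gene", "cell_type", "rpkm", "fdr")


def validate_expression_table(expr: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EXPRESSION_COLUMNS if c not in expr.columns]
    if missing:
        raise ValueError(f"expression table missing columns: {missing}")
    if (expr["rpkm"] < 0).any():
        raise ValueError("negative RPKM values")
    if ((expr["fdr"] < 0) | (expr["fdr"] > 1)).any():
        raise ValueError("FDR values outside [0, 1]")
    if expr.duplicated(subset=["gene", "cell_type"]).any():
        dups = expr[expr.duplicated(subset=["gene", "cell_type"], keep=False)]
        raise ValueError(
            f"duplicate (gene, cell_type) rows: {sorted(set(map(tuple, dups[['gene', 'cell_type']].values.tolist())))}"
        )
    return expr


def call_expressed(rpkm, fdr, rpkm_min: float = RPKM_MIN, fdr_max: float = FDR_MAX):
    """Presence call: RPKM >= rpkm_min AND detection FDR <= fdr_max.

    Accepts scalars or arrays.  Both thresholds are inclusive, matching the
    operational definitions used for the printed gene tables.
    """
    rpkm = np.asarray(rpkm, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    out = (rpkm >= rpkm_min) & (fdr <= fdr_max)
    if out.ndim == 0:
        return bool(out)
    return out


def presence_lookup(expr: pd.DataFrame, rpkm_min: float = RPKM_MIN,
                    fdr_max: float = FDR_MAX) -> dict:
    """Map (gene, cell_type) -> expressed flag for a long expression table."""
    validate_expression_table(expr)
    flags = call_expressed(expr["rpkm"].values, expr["fdr"].values, rpkm_min, fdr_max)
    return {
        (g, ct): bool(f)
        for g, ct, f in zip(expr["gene"], expr["cell_type"], flags)
    }


def _members_for(group, species: str):
    return group.members_a if species == "a" else group.members_b


def n_expressed_members(group, calls: dict, cell_type: str, species: str) -> int:
    """Number of the group's genes (on the given species side) called
    expressed in ``cell_type``.  Genes absent from the calls are unexpressed."""
    return sum(calls.get((g, cell_type), False) for g in _members_for(group, species))


def group_presence(group, calls: dict, cell_type: str, cell_species: dict,
                   require_all: bool = False) -> bool:
    """Lift gene-level presence calls to the ortholog-group level.

    ``cell_species`` maps each measured cell-type label to the species side
    (``"a"`` or ``"b"``) it was measured in.  Default semantics: the group is
    present if ANY member gene of the relevant species is expressed;
    ``require_all`` switches to all-member semantics for sensitivity analysis.
    """
    if cell_type not in cell_species:
        raise KeyError(f"cell type {cell_type!r} not present in the data")
    species = cell_species[cell_type]
    members = _members_for(group, species)
    n = n_expressed_members(group, calls, cell_type, species)
    return n == len(members) if require_all else n > 0


@dataclass
class VennPartition:
    """Disjoint cell-type-subset cells with group counts and paralog increments.

    ``cells`` maps a frozenset of cell-type labels to a dict with
    ``group_count`` (ortholog groups whose presence pattern is exactly that
    subset), ``paralog_increment`` (additional expressed duplicated-species
    paralogs beyond one per group) and ``groups`` (the group ids).
    ``totals[T]`` is the number of expressed genes in cell type T: groups for
    the non-duplicated species, genes (group + extra paralogs) for the
    duplicated one.
    """

    cells: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    duplicated_species: str = "a"
    cell_species: dict = field(default_factory=dict)

    def cell(self, *cell_types) -> dict:
        return self.cells.get(
            frozenset(cell_types), {"group_count": 0, "paralog_increment": 0, "groups": []}
        )

    def total_from_cells(self, cell_type: str) -> int:
        """Recompute a cell-type total by summing its Venn cells (the
        partition-sum identity)."""
        dup = self.cell_species.get(cell_type) == self.duplicated_species
        total = 0
        for subset, data in self.cells.items():
            if cell_type in subset:
                total += data["group_count"]
                if dup:
                    total += data["paralog_increment"]
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell": "&".join(sorted(subset)),
                "group_count": data["group_count"],
                "paralog_increment": data["paralog_increment"],
            }
            for subset, data in sorted(self.cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["cell", "group_count", "paralog_increment"])


def venn_partition(groups, calls: dict, cell_types, cell_species: dict,
                   duplicated_species: str = "a",
                   require_all: bool = False) -> VennPartition:
    """Partition ortholog groups into disjoint Venn cells over cell types.

    Each group is assigned to exactly one cell: the exact subset of cell types
    where it is present (groups present nowhere are dropped).  The paralog
    increment of a cell sums, over its groups and over the duplicated-species
    cell types it contains, the expressed duplicated-species members beyond
    the first.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types for a Venn partition")
    for ct in cell_types:
        if ct not in cell_species:
            raise KeyError(f"cell type {ct!r} has no species assignment")
    cells: dict = {}
    totals = {ct: 0 for ct in cell_types}
    for group in groups:
        present = {}
        n_dup = {}
        for ct in cell_types:
            species = cell_species[ct]
            n = n_expressed_members(group, calls, ct, species)
            members = _members_for(group, species)
            present[ct] = (n == len(members)) if require_all else (n > 0)
            if species == duplicated_species:
                n_dup[ct] = n
            if present[ct]:
                totals[ct] += n if species == duplicated_species else 1
        subset = frozenset(ct for ct in cell_types if present[ct])
        if not subset:
            continue
        data = cells.setdefault(
            subset, {"group_count": 0, "paralog_increment": 0, "groups": []}
        )
        data["group_count"] += 1
        data["paralog_increment"] += sum(
            max(0, n_dup[ct] - 1) for ct in subset if ct in n_dup
        )
        data["groups"].append(group.group_id)
    return VennPartition(
        cells=cells, totals=totals, duplicated_species=duplicated_species,
        cell_species=dict(cell_species),
    )


def unique_expression(expr: pd.DataFrame, target: str, references,
                      rpkm_min: float = RPKM_MIN, fdr_max: float = FDR_MAX,
                      ref_rpkm_max: float = 0.10) -> pd.DataFrame:
    """Genes expressed in ``target`` but at background level in every reference.

    A gene qualifies when it passes the presence call in the target cell type
    and its RPKM in each reference cell type is <= ``ref_rpkm_max`` (a gene
    not measured in a reference counts as background there).  Sorted by target
    RPKM descending, ties broken by gene identifier.
    """
    validate_expression_table(expr)
    references = list(references)
    measured = set(expr["cell_type"])
    for ct in [target, *references]:
        if ct not in measured:
            raise KeyError(f"cell type {ct!r} not measured")
    tgt = expr[expr["cell_type"] == target].copy()
    tgt = tgt[call_expressed(tgt["rpkm"].values, tgt["fdr"].values, rpkm_min, fdr_max)]
    for ref in references:
        ref_rpkm = expr[expr["cell_type"] == ref].set_index("gene")["rpkm"]
        vals = tgt["gene"].map(ref_rpkm).fillna(0.0)
        tgt = tgt[vals.values <= ref_rpkm_max]
    tgt = tgt.sort_values(["rpkm", "gene"], ascending=[False, True], kind="mergesort")
    return tgt.reset_index(drop=True)


def top_n(table: pd.DataFrame, n: int = 200, floor: float = RPKM_MIN,
          rpkm_col: str = "rpkm", gene_col: str = "gene") -> pd.DataFrame:
    """Top-n gene table by RPKM (>= floor), ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = table[table[rpkm_col] >= floor]
    kept = kept.sort_values([rpkm_col, gene_col], ascending=[False, True],
                            kind="mergesort")
    return kept.head(n).reset_index(drop=True)


def threshold_intersection(expr: pd.DataFrame, cell_types, rpkm_min: float,
                           groups=None, cell_species: dict | None = None) -> pd.DataFrame:
    """Genes (or ortholog groups) strictly above ``rpkm_min`` in every listed
    cell type.

    The comparison is strict (> rpkm_min).  Gene mode (``groups=None``)
    requires each gene to be measured in all listed cell types.  Group mode
    scores a group in a cell type by the maximum RPKM over its members on the
    species side of that cell type, and needs ``cell_species``.
    """
    validate_expression_table(expr)
    cell_types = list(cell_types)
    measured = set(expr["cell_type"])
    for ct in cell_types:
        if ct not in measured:
            raise KeyError(f"cell type {ct!r} not measured")
    wide = expr.pivot(index="gene", columns="cell_type", values="rpkm")
    if groups is None:
        sub = wide[cell_types].dropna()
        keep = sub[(sub > rpkm_min).all(axis=1)]
        out = keep.reset_index().rename_axis(None, axis=1)
        return out.sort_values("gene", kind="mergesort").reset_index(drop=True)
    if cell_species is None:
        raise ValueError("group mode needs a cell_species mapping")
    rows = []
    for group in groups:
        vals = {}
        for ct in cell_types:
            members = _members_for(group, cell_species[ct])
            present = [wide.at[g, ct] for g in members
                       if g in wide.index and not pd.isna(wide.at[g, ct])]
            vals[ct] = max(present) if present else 0.0
        if all(vals[ct] > rpkm_min for ct in cell_types):
            rows.append({"group_id": group.group_id, **vals})
    return pd.DataFrame(rows, columns=["group_id", *cell_types])
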