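"""Cross-species ortholog classification from homology pair tables.

Zebrafish underwent an ancient whole-genome duplication, so a single mouse
gene frequently maps to two (or more) zebrafish paralogs.  This module builds
the bipartite gene homology graph from a Biomart-style pair export, classifies
each connected component as one-to-one / one-to-many / many-to-many, flags
high-confidence pairs from the Ensembl confidence scores (gene-order
conservation, whole-genome alignment, percent identity), collapses redundant
genes on the non-duplicated side, and summarizes per-class gene counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ONE_TO_ONE = "one-to-one"
ONE_TO_MANY = "one-to-many"
MANY_TO_MANY = "many-to-many"
RELATIONSHIP_CLASSES = (ONE_TO_ONE, ONE_TO_MANY, MANY_TO_MANY)

#: default Ensembl-style confidence thresholds
GOC_MIN = 75.0
WGA_MIN = 75.0
ID_MIN = 50.0

PAIR_COLUMNS = ("gene_a", "gene_b", "goc", "wga", "pct_id", "homology_label")

DEFAULT_DIALECT = {c: c for c in PAIR_COLUMNS}


class HomologyTableError(ValueError):
    """Malformed or misconfigured homology pair table."""


def read_homology_table(path, dialect=None) -> pd.DataFrame:
    """Read a tab-delimited homology pair export into a canonical pair table.

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        Mapping from canonical column names (``gene_a``, ``gene_b``, ``goc``,
        ``wga``, ``pct_id``, ``homology_label``) to the column names used in
        the file.  Only ``gene_a`` and ``gene_b`` are mandatory; score columns
        default to the canonical names and are optional in the file header
        unless explicitly mapped.  Biomart exports both query->target and
        target->query percent identities; exactly one must be mapped to
        ``pct_id``.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene_a, gene_b, goc, wga, pct_id, homology_label``; missing
        scores are NaN (absent, never zero).

    Raises
    ------
    HomologyTableError
        If a mapped column is missing from the header or the table contains
        duplicate (gene_a, gene_b) rows.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    for key in ("gene_a", "gene_b"):
        if dialect[key] not in raw.columns:
            raise HomologyTableError(
                f"required column {dialect[key]!r} (mapped to {key!r}) "
                f"not found in header {list(raw.columns)}"
            )
    out = pd.DataFrame(
        {
            "gene_a": raw[dialect["gene_a"]].astype(str),
            "gene_b": raw[dialect["gene_b"]].astype(str),
        }
    )
    for key in ("goc", "wga", "pct_id"):
        col = dialect[key]
        if col in raw.columns:
            out[key] = pd.to_numeric(raw[col], errors="coerce")
        elif key in (dialect.keys() - DEFAULT_DIALECT.keys()) or col != key:
            # explicitly mapped but absent
            raise HomologyTableError(
                f"mapped column {col!r} (for {key!r}) not found in header"
            )
        else:
            out[key] = np.nan
    label_col = dialect["homology_label"]
    out["homology_label"] = (
        raw[label_col] if label_col in raw.columns else pd.Series(pd.NA, index=raw.index)
    )
    dup = out.duplicated(subset=["gene_a", "gene_b"], keep=False)
    if dup.any():
        pairs = sorted(map(tuple, out.loc[dup, ["gene_a", "gene_b"]].values.tolist()))
        raise HomologyTableError(f"duplicate gene pairs in table: {sorted(set(pairs))}")
    bad = []
    for key in ("goc", "wga", "pct_id"):
        vals = out[key].dropna()
        if ((vals < 0) | (vals > 100)).any():
            bad.append(key)
    if bad:
        raise HomologyTableError(f"scores outside [0, 100] in columns: {bad}")
    return out


def flag_high_confidence(
    goc, wga, pct_id, goc_min: float = GOC_MIN, wga_min: float = WGA_MIN,
    id_min: float = ID_MIN,
):
    """High-confidence ortholog rule: (GOC >= goc_min OR WGA >= wga_min) AND
    percent identity >= id_min.

    Accepts scalars or array-likes; NaN (absent) scores fail their clause.
    """
    for name, t in (("goc_min", goc_min), ("wga_min", wga_min), ("id_min", id_min)):
        if not 0 <= t <= 100:
            raise ValueError(f"{name} must be within [0, 100], got {t}")
    goc = np.asarray(goc, dtype=float)
    wga = np.asarray(wga, dtype=float)
    pct_id = np.asarray(pct_id, dtype=float)
    # NaN comparisons are False, which is exactly "absent score fails its clause"
    with np.errstate(invalid="ignore"):
        ok = ((goc >= goc_min) | (wga >= wga_min)) & (pct_id >= id_min)
    if ok.ndim == 0:
        return bool(ok)
    return ok


@dataclass(frozen=True)
class OrthologGroup:
    """A connected component of the bipartite cross-species homology graph."""

    group_id: str
    members_a: frozenset
    members_b: frozenset
    pairs: tuple = ()
    high_confidence: tuple = ()  # parallel to pairs

    def __post_init__(self):
        if not self.members_a or not self.members_b:
            raise ValueError("an ortholog group needs members on both sides")

    @property
    def relationship(self) -> str:
        na, nb = len(self.members_a), len(self.members_b)
        if na == 1 and nb == 1:
            return ONE_TO_ONE
        if na == 1 or nb == 1:
            return ONE_TO_MANY
        return MANY_TO_MANY


_LABEL_CLASS = {
    "one2one": ONE_TO_ONE,
    "one2many": ONE_TO_MANY,
    "many2many": MANY_TO_MANY,
}


def _label_class(label) -> str | None:
    if label is None or (isinstance(label, float) and np.isnan(label)) or pd.isna(label):
        return None
    text = str(label).lower()
    for key, cls in _LABEL_CLASS.items():
        if key in text:
            return cls
    return None


def build_groups(
    pairs: pd.DataFrame,
    goc_min: float = GOC_MIN,
    wga_min: float = WGA_MIN,
    id_min: float = ID_MIN,
) -> list[OrthologGroup]:
    """Partition a pair table into ortholog groups (connected components).

    Relationship class is derived from component cardinalities; when a source
    ``homology_label`` disagrees with the derived class a warning is logged and
    the derived class wins.  Per-pair high-confidence flags are attached using
    :func:`flag_high_confidence`.
    """
    if len(pairs) == 0:
        raise ValueError("pair collection is empty")
    graph = nx.Graph()
    rows = {}
    for row in pairs.itertuples(index=False):
        a, b = f"a:{row.gene_a}", f"b:{row.gene_b}"
        graph.add_edge(a, b)
        rows[(row.gene_a, row.gene_b)] = row
    groups = []
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: min(c))
    ):
        members_a = frozenset(n[2:] for n in comp if n.startswith("a:"))
        members_b = frozenset(n[2:] for n in comp if n.startswith("b:"))
        comp_pairs = tuple(
            sorted((a, b) for (a, b) in rows if a in members_a and b in members_b)
        )
        hc = tuple(
            flag_high_confidence(
                rows[p].goc, rows[p].wga, rows[p].pct_id, goc_min, wga_min, id_min
            )
            for p in comp_pairs
        )
        group = OrthologGroup(
            group_id=f"og{i:06d}",
            members_a=members_a,
            members_b=members_b,
            pairs=comp_pairs,
            high_confidence=hc,
        )
        for p in comp_pairs:
            labelled = _label_class(rows[p].homology_label)
            if labelled is not None and labelled != group.relationship:
                logger.warning(
                    "pair %s annotated %r but component is %s; derived class wins",
                    p, rows[p].homology_label, group.relationship,
                )
        groups.append(group)
    return groups


def collapse_redundant(groups, side: str) -> list:
    """Deduplicated, sorted gene list for one species across all groups.

    ``side`` is ``"a"`` or ``"b"``.  Because groups partition the genes, each
    gene appears in exactly one group; this flattens and sorts them.  This is
    the operation that shrinks the mouse list when several zebrafish paralogs
    map to one mouse gene.
    """
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    attr = "members_a" if side == "a" else "members_b"
    genes = set()
    for g in groups:
        genes.update(getattr(g, attr))
    return sorted(genes)


@dataclass
class RelationshipSummary:
    """Per-class gene counts for each species, with ortholog totals.

    ``counts`` maps relationship class to ``(genes_a, genes_b)``.  For
    one-to-one components the two entries are equal by construction.
    """

    counts: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, one_to_one: int, one_to_many: tuple,
                    many_to_many: tuple) -> "RelationshipSummary":
        return cls(counts={
            ONE_TO_ONE: (int(one_to_one), int(one_to_one)),
            ONE_TO_MANY: (int(one_to_many[0]), int(one_to_many[1])),
            MANY_TO_MANY: (int(many_to_many[0]), int(many_to_many[1])),
        })

    @property
    def total_a(self) -> int:
        return sum(v[0] for v in self.counts.values())

    @property
    def total_b(self) -> int:
        return sum(v[1] for v in self.counts.values())

    def protein_coding_total(self, unique_a: int, unique_b: int) -> tuple:
        """Ortholog totals plus species-specific (orphan) gene counts."""
        return self.total_a + unique_a, self.total_b + unique_b

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"relationship": cls, "genes_a": self.counts.get(cls, (0, 0))[0],
             "genes_b": self.counts.get(cls, (0, 0))[1]}
            for cls in RELATIONSHIP_CLASSES
        ]
        rows.append({"relationship": "ortholog_total", "genes_a": self.total_a,
                     "genes_b": self.total_b})
        return pd.DataFrame(rows)


def summarize_relationships(groups) -> RelationshipSummary:
    """Count genes per species in each relationship class.

    Per-species class counts sum to the per-species ortholog totals (each gene
    belongs to exactly one group, each group to exactly one class).
    """
    counts = {cls: [0, 0] for cls in RELATIONSHIP_CLASSES}
    for g in groups:
        counts[g.relationship][0] += len(g.members_a)
        counts[g.relationship][1] += len(g.members_b)
    return RelationshipSummary(counts={k: tuple(v) for k, v in counts.items()})


def ortholog_fraction(
    summary: RelationshipSummary,
    protein_coding_total: int,
    side: str = "a",
    class_filter=None,
) -> float:
    """Percentage of a species' protein-coding genes covered by orthologs.

    Full precision is returned; use :func:`round_percent` for report output
    (round-half-even to integer percent).  ``class_filter`` restricts the
    numerator to a relationship class or iterable of classes.
    """
    if protein_coding_total <= 0:
        raise ValueError("protein_coding_total must be positive")
    idx = 0 if side == "a" else 1
    if class_filter is None:
        classes = RELATIONSHIP_CLASSES
    elif isinstance(class_filter, str):
        classes = (class_filter,)
    else:
        classes = tuple(class_filter)
    count = sum(summary.counts.get(c, (0, 0))[idx] for c in classes)
    if count > protein_coding_total:
        raise ValueError("class counts exceed the protein-coding total")
    return 100.0 * count / protein_coding_total


def round_percent(pct: float) -> int:
    """Report rounding mode for percentages: round half to even."""
    return int(round(pct))
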