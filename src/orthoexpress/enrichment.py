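"""Hypergeometric over-representation analysis against GMT gene sets.

One-sided (enrichment only): for a query list drawn from an explicit
background universe, the p-value for a gene set is the upper-tail
hypergeometric probability of observing at least the realized overlap, with
Benjamini-Hochberg adjustment across sets.  The universe is always explicit
input — here typically the orthologs measured in the relevant cell types
rather than the whole genome, to avoid expression-detection bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe.

    Sets are intersected with the universe on construction; sets left empty by
    the intersection are dropped (with a logged count).
    """

    sets: dict
    universe: frozenset

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        trimmed, dropped = {}, 0
        for name, members in self.sets.items():
            kept = frozenset(members) & self.universe
            if kept:
                trimmed[name] = kept
            else:
                dropped += 1
        if dropped:
            logger.warning("dropped %d gene sets empty after universe intersection",
                           dropped)
        self.sets = trimmed

    @classmethod
    def from_gmt(cls, path, universe) -> "GeneSetCollection":
        """Load sets from a GMT file (tab-delimited: name, description,
        member genes...)."""
        sets = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"GMT row needs >= 3 tab-separated fields: {line!r}"
                    )
                name = fields[0]
                if name in sets:
                    raise ValueError(f"duplicate gene set name {name!r}")
                sets[name] = frozenset(g for g in fields[2:] if g)
        return cls(sets=sets, universe=frozenset(universe))


def hypergeom_enrich(query, collection: GeneSetCollection,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of ``query`` in each set of ``collection``.

    Query genes outside the universe are dropped with a logged count; an
    empty query after the intersection is an error.  Returns one row per set
    with ``set, set_size, overlap, expected, p, adj_p, significant``, sorted
    by p (ties by set name); ``significant`` marks p < alpha.
    """
    query = frozenset(query)
    outside = query - collection.universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
    query &= collection.universe
    if not query:
        raise ValueError("query is empty after intersection with the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        # P(overlap >= k) drawing n genes from a universe with K marked
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "expected": n * K / N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "expected", "p"])
    out["adj_p"] = bh_adjust(out["p"].values) if len(out) else []
    out["significant"] = out["p"] < alpha
    out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return out
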