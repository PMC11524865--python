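import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pairs(pair_list, scores=None):
    """Canonical pair table from a list of (gene_a, gene_b) tuples."""
    df = pd.DataFrame(pair_list, columns=["gene_a", "gene_b"])
    for key in ("goc", "wga", "pct_id"):
        df[key] = (scores or {}).get(key, np.nan)
    df["homology_label"] = pd.NA
    return df


def brute_force_components(pair_list):
    """Independent connected-component oracle: BFS over an adjacency map of
    species-tagged nodes.  Returns a set of (frozenset_a, frozenset_b)."""
    adj = {}
    for a, b in pair_list:
        na, nb = ("a", a), ("b", b)
        adj.setdefault(na, set()).add(nb)
        adj.setdefault(nb, set()).add(na)
    seen, comps = set(), set()
    for node in adj:
        if node in seen:
            continue
        stack, comp = [node], set()
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.add((
            frozenset(g for s, g in comp if s == "a"),
            frozenset(g for s, g in comp if s == "b"),
        ))
    return comps


def classify_sizes(na, nb):
    if na == 1 and nb == 1:
        return "one-to-one"
    if na == 1 or nb == 1:
        return "one-to-many"
    return "many-to-many"


@pytest.fixture
def expr_table():
    """Small long-format expression table covering zHC/zSC/IHC/OHC."""
    rows = []
    layout = {
        # gene: {cell_type: (rpkm, fdr)}
        "za1": {"zHC": (50.0, 0.01), "zSC": (0.05, 0.5)},
        "za2": {"zHC": (12.0, 0.02), "zSC": (11.0, 0.01)},
        "za3": {"zHC": (0.05, 0.01), "zSC": (0.01, 0.9)},
        "mb1": {"IHC": (30.0, 0.01), "OHC": (25.0, 0.02)},
        "mb2": {"IHC": (0.01, 0.9), "OHC": (15.0, 0.01)},
    }
    for gene, cells in layout.items():
        for ct, (rpkm, fdr) in cells.items():
            rows.append({"gene": gene, "cell_type": ct, "rpkm": rpkm, "fdr": fdr})
    return pd.DataFrame(rows)
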