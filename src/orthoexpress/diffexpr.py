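"""Two-group negative-binomial differential expression.

A transparent stand-in for the DESeq2 stage of the original workflow: per-gene
method-of-moments dispersion, a Wald test on the log fold change with a normal
reference, and Benjamini-Hochberg FDR control.  It is deliberately simple (no
dispersion shrinkage, no outlier handling, no multi-factor designs) and is
labelled as such in its outputs; the scientific content downstream of it is
the fold-change/FDR thresholding and set logic, not the test internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Integer count matrix (genes x samples) with a two-group design.

    ``groups`` maps each sample name to one of exactly two group labels.
    Size factors default to DESeq-style median-of-ratios.
    """

    counts: pd.DataFrame
    groups: dict
    size_factors: pd.Series | None = None

    def __post_init__(self):
        if set(self.groups) != set(self.counts.columns):
            raise ValueError("groups must label exactly the count-matrix samples")
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 groups, got {labels}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts.values, np.round(self.counts.values)):
            raise ValueError("counts must be integral")
        self.labels = labels
        if self.size_factors is None:
            self.size_factors = median_of_ratios(self.counts)
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def samples(self, label: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == label]

    def normalized(self) -> pd.DataFrame:
        return self.counts / self.size_factors


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (ratio to the per-gene geometric mean,
    over genes with all-positive counts).  Falls back to 1.0 for all samples
    when no gene is positive everywhere."""
    arr = counts.values.astype(float)
    pos = (arr > 0).all(axis=1)
    if not pos.any():
        return pd.Series(1.0, index=counts.columns)
    log_ref = np.log(arr[pos]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(arr[pos]) - log_ref, axis=0))
    return pd.Series(sf, index=counts.columns)


def log2_fold_change(mean_a, mean_b, pseudocount: float = PSEUDOCOUNT):
    """log2((mean_a + pseudocount) / (mean_b + pseudocount))."""
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if (mean_a < 0).any() or (mean_b < 0).any():
        raise ValueError("means must be non-negative")
    out = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return float(out) if out.ndim == 0 else out


def nb_wald_table(matrix: CountMatrix, pseudocount: float = PSEUDOCOUNT,
                  group_a: str | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group_a`` vs the other group.

    For each gene: group means of size-factor-normalized counts; a pooled
    per-gene method-of-moments dispersion (floored at 1e-8); a Wald statistic
    on the log fold change with model-based (NB) variance of the group means,
    two-sided p from the normal reference.  All-zero genes are flagged
    untestable (estimate 0, p = 1).  Deterministic given inputs.

    Returns columns ``gene, base_mean, log2fc, se, stat, p, untestable``.
    """
    labels = matrix.labels
    if group_a is None:
        group_a = labels[0]
    if group_a not in labels:
        raise ValueError(f"unknown group {group_a!r}")
    group_b = labels[1] if group_a == labels[0] else labels[0]
    norm = matrix.normalized()
    xa = norm[matrix.samples(group_a)].values
    xb = norm[matrix.samples(group_b)].values
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group for testing")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    # per-gene method-of-moments NB dispersion from per-group residuals:
    #   Var(x) = mu + phi * mu^2  =>  phi = sum(v - m) / sum(m^2)
    # The raw per-gene estimate is noisy at n=5; genes whose dispersion is
    # under-estimated by chance would get too-small standard errors and
    # inflate the type-I error, so each gene's dispersion is floored at the
    # cross-gene median (a one-sided moderation: over-estimates, which are
    # merely conservative, are kept).
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (va - ma) + (vb - mb)
        den = ma**2 + mb**2
        phi = np.where(den > 0, num / den, 0.0)
    phi = np.maximum(phi, DISPERSION_FLOOR)
    informative = (ma > 0) & (mb > 0)
    if informative.any():
        phi = np.maximum(phi, np.median(phi[informative]))

    # Wald on the natural-log fold change, delta method through the
    # pseudocounted means; group-mean variance is the NB model variance / n.
    est = np.log(ma + pseudocount) - np.log(mb + pseudocount)
    var_ma = (ma + phi * ma**2) / na
    var_mb = (mb + phi * mb**2) / nb
    se = np.sqrt(var_ma / (ma + pseudocount) ** 2 + var_mb / (mb + pseudocount) ** 2)
    untestable = (ma == 0) & (mb == 0)
    se_safe = np.where(se > 0, se, np.inf)
    stat = np.where(untestable, 0.0, est / se_safe)
    p = np.where(untestable, 1.0, 2.0 * stats.norm.sf(np.abs(stat)))
    return pd.DataFrame(
        {
            "gene": matrix.counts.index,
            "base_mean": (ma * na + mb * nb) / (na + nb),
            "log2fc": np.where(untestable, 0.0, est / np.log(2.0)),
            "se": se / np.log(2.0),
            "stat": stat,
            "p": np.minimum(p, 1.0),
            "untestable": untestable,
        }
    ).reset_index(drop=True)


def nb_wald_test(matrix: CountMatrix, gene, **kwargs) -> dict:
    """Single-gene view of :func:`nb_wald_table`."""
    table = nb_wald_table(matrix, **kwargs).set_index("gene")
    if gene not in table.index:
        raise KeyError(f"gene {gene!r} not in count matrix")
    row = table.loc[gene]
    return {
        "estimate": float(row["log2fc"]),
        "se": float(row["se"]),
        "p": float(row["p"]),
        "untestable": bool(row["untestable"]),
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    adjusted >= raw, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_results(matrix: CountMatrix, group_a: str | None = None,
               pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Full differential-expression table: NB Wald test plus BH adjustment.

    Untestable (all-zero) genes get adjusted p = 1 and are excluded from the
    BH denominator.
    """
    res = nb_wald_table(matrix, pseudocount=pseudocount, group_a=group_a)
    res["adj_p"] = 1.0
    testable = ~res["untestable"].values
    if testable.any():
        res.loc[testable, "adj_p"] = bh_adjust(res.loc[testable, "p"].values)
    return res


def volcano_summary(results: pd.DataFrame, fc_min: float = 1.0,
                    alpha: float = 0.05) -> dict:
    """Up/down-regulated gene counts at |log2 fold change| > fc_min and
    adjusted p < alpha."""
    if len(results) == 0:
        return {"n_up": 0, "n_down": 0}
    sig = results["adj_p"].values < alpha
    lfc = results["log2fc"].values
    return {
        "n_up": int(((lfc > fc_min) & sig).sum()),
        "n_down": int(((lfc < -fc_min) & sig).sum()),
    }
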