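"""End-to-end orchestration: classify -> call -> venn -> de -> enrich.

The pipeline is deterministic given fixed inputs and configuration; its
summary is a plain dict (JSON-serializable) so reruns can be compared by
digest.  Each stage failure is re-raised with the stage name attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import diffexpr, enrichment, expression, homology

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and labels for a full pipeline run.

    Defaults are the study cutoffs: presence at 0.1 RPKM / FDR <= 0.10,
    confidence scores (GOC or WGA) >= 75 with identity >= 50, differential
    expression at |log2 fold change| > 1 and adjusted p < 0.05.
    """

    rpkm_min: float = expression.RPKM_MIN
    fdr_max: float = expression.FDR_MAX
    goc_min: float = homology.GOC_MIN
    wga_min: float = homology.WGA_MIN
    id_min: float = homology.ID_MIN
    fc_min: float = 1.0
    alpha: float = 0.05
    cell_types: tuple = ("zHC", "IHC", "OHC")
    cell_species: dict = field(
        default_factory=lambda: {"zHC": "a", "zSC": "a", "IHC": "b", "OHC": "b"})
    duplicated_species: str = "a"
    de_group_a: str | None = None

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("rpkm_min", "fdr_max"):
            if getattr(cfg, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("goc_min", "wga_min", "id_min"):
            if not 0 <= getattr(cfg, name) <= 100:
                raise ValueError(f"{name} must be within [0, 100]")
        if not 0 < cfg.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(pairs: pd.DataFrame | None, expr: pd.DataFrame,
                 config: RunConfig | None = None,
                 groups=None, counts: pd.DataFrame | None = None,
                 count_groups: dict | None = None,
                 gene_sets: "enrichment.GeneSetCollection | None" = None,
                 query_genes=None) -> dict:
    """Run the full comparison pipeline on in-memory tables.

    Parameters
    ----------
    pairs
        Homology pair table (or None when ``groups`` is given directly).
    expr
        Long-format expression table (may be empty).
    groups
        Pre-built ortholog groups; built from ``pairs`` otherwise.
    counts, count_groups
        Optional count matrix and sample->group mapping for the differential
        stage.
    gene_sets, query_genes
        Optional enrichment inputs.

    Returns
    -------
    dict with keys ``summary`` (classification-table counts), ``venn`` (cells and
    totals), ``de`` (volcano counts and result table) and ``enrichment``.
    """
    config = config or RunConfig()
    report: dict = {"parameters": asdict(config)}

    with _stage("classify"):
        if groups is None:
            groups = homology.build_groups(pairs, config.goc_min, config.wga_min,
                                           config.id_min)
        summary = homology.summarize_relationships(groups)
        report["summary"] = {
            "classes": {k: list(v) for k, v in summary.counts.items()},
            "total_a": summary.total_a,
            "total_b": summary.total_b,
            "n_groups": len(groups),
        }
        report["groups"] = groups

    with _stage("call"):
        if len(expr):
            calls = expression.presence_lookup(expr, config.rpkm_min, config.fdr_max)
        else:
            calls = {}

    with _stage("venn"):
        part = expression.venn_partition(
            groups, calls, config.cell_types, config.cell_species,
            config.duplicated_species,
        )
        report["venn"] = {
            "cells": {
                "&".join(sorted(subset)): {
                    "group_count": data["group_count"],
                    "paralog_increment": data["paralog_increment"],
                }
                for subset, data in part.cells.items()
            },
            "totals": dict(part.totals),
        }
        report["venn_partition"] = part

    with _stage("de"):
        if counts is not None and len(counts):
            matrix = diffexpr.CountMatrix(counts, count_groups)
            res = diffexpr.de_results(matrix, group_a=config.de_group_a)
            report["de"] = {
                "method": "NB Wald stand-in (not DESeq2)",
                **diffexpr.volcano_summary(res, config.fc_min, config.alpha),
            }
            report["de_results"] = res
        else:
            report["de"] = {"method": "NB Wald stand-in (not DESeq2)",
                            "n_up": 0, "n_down": 0}
            report["de_results"] = pd.DataFrame(
                columns=["gene", "log2fc", "p", "adj_p"])

    with _stage("enrich"):
        if gene_sets is not None and query_genes is not None:
            enr = enrichment.hypergeom_enrich(query_genes, gene_sets, config.alpha)
            report["enrichment"] = enr
        else:
            report["enrichment"] = None

    return report


def summary_digest(report: dict) -> str:
    """Stable digest of the machine-readable part of a pipeline report."""
    import hashlib
    import json

    payload = {
        "summary": report["summary"],
        "venn": report["venn"],
        "de": report["de"],
        "parameters": report["parameters"],
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
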