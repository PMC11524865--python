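"""Table and recording I/O: tab-delimited UTF-8 with headers, JSON for
nested summaries.  Every writer here round-trips through its reader."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ephys import Recording
from .expression import validate_expression_table
from .homology import OrthologGroup


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_expression_table(path) -> pd.DataFrame:
    """Long-format expression TSV: gene, cell_type, rpkm, fdr."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     dtype={"gene": str, "cell_type": str})
    return validate_expression_table(df)


def write_groups(groups, path) -> None:
    rows = [
        {
            "group_id": g.group_id,
            "members_a": ";".join(sorted(g.members_a)),
            "members_b": ";".join(sorted(g.members_b)),
            "relationship": g.relationship,
            "n_high_confidence": int(sum(g.high_confidence)),
            "n_pairs": len(g.pairs),
        }
        for g in groups
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_groups(path) -> list[OrthologGroup]:
    df = pd.read_csv(path, sep="\t", encoding="utf-8", dtype=str)
    groups = []
    for row in df.itertuples(index=False):
        groups.append(OrthologGroup(
            group_id=row.group_id,
            members_a=frozenset(row.members_a.split(";")),
            members_b=frozenset(row.members_b.split(";")),
        ))
    return groups


def read_counts(path) -> pd.DataFrame:
    """Counts TSV: first column gene identifiers, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", encoding="utf-8", index_col=0)
    return df


def write_recording(rec: Recording, path, metadata_path=None) -> None:
    cols = {"voltage": rec.voltage}
    if rec.capacitance is not None:
        cols["capacitance"] = rec.capacitance
    if rec.displacement is not None:
        cols["displacement"] = rec.displacement
    write_tsv(pd.DataFrame(cols), path)
    if metadata_path is not None:
        with open(metadata_path, "w", encoding="utf-8") as fh:
            json.dump(rec.metadata, fh, indent=2, sort_keys=True)


def read_recording(path, metadata_path=None) -> Recording:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    meta = {}
    if metadata_path is not None and Path(metadata_path).exists():
        with open(metadata_path, encoding="utf-8") as fh:
            meta = json.load(fh)
    return Recording(
        voltage=df["voltage"].to_numpy(),
        capacitance=df["capacitance"].to_numpy() if "capacitance" in df else None,
        displacement=df["displacement"].to_numpy() if "displacement" in df else None,
        metadata=meta,
    )


def read_gene_list(path) -> list:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_yaml(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, frozenset):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
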