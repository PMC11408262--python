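"""Readers and writers for the plain-text formats used across the pipeline.

Everything is tab-separated text, GMT gene sets, GraphML, or JSON so that all
artifacts stay human-inspectable and diff-friendly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd


# ---------------------------------------------------------------------------
# expression / labels / atlas / annotations
# ---------------------------------------------------------------------------

def write_expression(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a subjects x genes matrix; first column is ``subject_id``."""
    matrix.to_csv(path, sep="\t", index=True, index_label="subject_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_labels(path: str | Path, labels: Mapping[str, str]) -> None:
    pd.Series(dict(labels), name="profile").rename_axis("subject_id").to_csv(
        path, sep="\t"
    )


def read_labels(path: str | Path) -> dict[str, str]:
    s = pd.read_csv(path, sep="\t", index_col="subject_id")["profile"]
    return s.to_dict()


def write_atlas(path: str | Path, atlas: pd.DataFrame) -> None:
    """Write a genes x brain-regions table; first column is ``gene``."""
    atlas.to_csv(path, sep="\t", index=True, index_label="gene")


def read_atlas(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_annotations(path: str | Path, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# typed interaction edge tables
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["source", "target", "layer"]


def write_edges(path: str | Path, edges: pd.DataFrame) -> None:
    edges.loc[:, EDGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_edges(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ValueError(f"edge table missing columns: {missing}")
    return edges


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def write_gmt(path: str | Path, gene_sets: Mapping[str, list[str]],
              description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description or name, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# JSON / GraphML
# ---------------------------------------------------------------------------

def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_graphml(path: str | Path, graph: nx.Graph) -> None:
    nx.write_graphml(graph, path)
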