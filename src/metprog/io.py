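"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and sample annotations are TSV, gene sets are GMT
(GSEA distribution format), networks are 3-column edge lists with
STRING-style scores (integer 0-1000, rescaled to (0, 1], or already
fractional).  All writers round-trip losslessly through the readers.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
]

log = logging.getLogger(__name__)


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene ids in the first column.

    Duplicate gene ids, missing values and non-numeric cells are each
    rejected with a distinct error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in expression matrix")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> pd.DataFrame:
    """Sample annotation TSV: sample id column plus group/time/event etc."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty annotation table")
    return df


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name TAB description TAB member TAB member ...

    Duplicate members within a set are dropped (first kept); a line with
    fewer than three fields is an error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 member ({len(fields)} fields)"
                )
            name = fields[0]
            members = list(dict.fromkeys(f for f in fields[2:] if f))
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_network(path) -> nx.Graph:
    """STRING-style weighted edge list: geneA TAB geneB TAB score.

    Integer scores on the 0-1000 scale are divided by 1000; fractional
    scores in (0, 1] pass through.  Self-loop rows are dropped with a
    warning; duplicate or reversed edges keep the maximum weight.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            a, b, raw = fields[0], fields[1], fields[2]
            if lineno == 1 and _looks_like_header(raw):
                continue
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score {raw!r}") from exc
            if a == b:
                n_self += 1
                continue
            w = score / 1000.0 if score > 1.0 else score
            if not 0.0 < w <= 1.0:
                raise ValueError(f"{path}:{lineno}: score {raw} outside (0, 1000]")
            if g.has_edge(a, b):
                g[a][b]["weight"] = max(g[a][b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
    if n_self:
        log.warning("dropped %d self-loop rows from %s", n_self, path)
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges parsed")
    return g


def _looks_like_header(raw: str) -> bool:
    try:
        float(raw)
        return False
    except ValueError:
        return True


def write_network(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tscore\n")
        for a, b in sorted(map(tuple, map(sorted, g.edges()))):
            fh.write(f"{a}\t{b}\t{g[a][b]['weight']:.6g}\n")
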