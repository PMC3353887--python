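"""Readers and writers for the tabular dialects used across the pipeline.

All tables are tab-separated UTF-8 with a header row; lines starting with
'#' are comments. Interaction networks are accepted either as a two-column
edge list or as SIF ("A pp B").
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx
import pandas as pd


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    """Read a TSV table, ignoring '#' comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edge_rows(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read network edges from SIF ("A pp B") or a 2-column TSV.

    The format is sniffed per line: three whitespace-separated tokens with a
    relation in the middle is SIF; two tab-separated tokens is an edge row.
    A header line named e.g. ``gene_a<TAB>gene_b`` is tolerated and skipped.

    Raises
    ------
    ValueError
        On a malformed row, with its line number.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            if len(tokens) == 3:  # SIF: nodeA relation nodeB
                rows.append((tokens[0], tokens[2]))
            elif len(tokens) == 2:
                if lineno == 1 and {t.lower() for t in tokens} & {
                    "gene_a", "gene_b", "source", "target", "node_a", "node_b"
                }:
                    continue  # header
                rows.append((tokens[0], tokens[1]))
            else:
                raise ValueError(
                    f"{path}: malformed network row at line {lineno}: {line!r}"
                )
    return rows


def write_edge_tsv(graph: nx.Graph, path: str | os.PathLike) -> None:
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_sif(graph: nx.Graph, path: str | os.PathLike, relation: str = "pp") -> None:
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_graphml(graph: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(graph, path)


def read_gene_value_map(path: str | os.PathLike) -> dict[str, float]:
    """Read a two-column gene -> numeric value table (expression, residuals)."""
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, value)")
    gene_col, value_col = df.columns[0], df.columns[1]
    return {str(g).upper(): float(v) for g, v in zip(df[gene_col], df[value_col])}


def read_annotations(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read long-format gene -> term annotations (one pair per row)."""
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (gene, term)")
    out: dict[str, set[str]] = {}
    for g, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(g).upper(), set()).add(str(t))
    return out


def write_annotations(annotations: dict[str, Iterable[str]], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
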