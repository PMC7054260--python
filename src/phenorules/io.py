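"""Readers and writers for the pipeline's plain-text formats.

Measurement tables, annotation maps, and call matrices travel as TSV;
rule tables as CSV; graphs as GraphML or attribute-bearing TSV edge
lists; truth sets as JSON.  Every writer's output is re-readable by the
matching reader.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .calls import CALL_SYMBOLS, CallMatrix
from .synthetic import AnnotationMap

MEASUREMENT_COLUMNS = ["parameter_id", "strain_id", "cohort", "value"]
COHORTS = {"mutant", "control"}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Long measurement TSV -> typed DataFrame; malformed rows are named."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    bad_cohort = df.index[~df["cohort"].isin(COHORTS)]
    if len(bad_cohort):
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{path}: unknown cohort {df.loc[bad_cohort[0], 'cohort']!r} at line {bad_cohort[0] + 2}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad_value = df.index[values.isna()]
    if len(bad_value):
        raise ParseError(
            f"{path}: non-numeric value {df.loc[bad_value[0], 'value']!r} at line {bad_value[0] + 2}"
        )
    out = df[MEASUREMENT_COLUMNS].copy()
    out["value"] = values
    return out


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table[MEASUREMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["parameter_id", "phenotype_id", "stage_type", "biological_systems"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return AnnotationMap(df[required].copy())


def write_annotation(annotation: AnnotationMap, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_call_matrix(path: str | Path) -> CallMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty call matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated phenotype id {dup!r}")
    bad = set(df.to_numpy().ravel()) - set(CALL_SYMBOLS)
    if bad:
        raise ParseError(f"{path}: unknown call symbol(s) {sorted(bad)}")
    return CallMatrix(df)


def write_call_matrix(matrix: CallMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="phenotype_id")


def read_rules(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rules(rules: pd.DataFrame, path: str | Path) -> None:
    rules.to_csv(path, index=False)


def export_graph(graph: nx.DiGraph, fmt: str, path: str | Path) -> None:
    """GraphML or TSV edge list with edge attributes preserved."""
    if fmt == "graphml":
        g = graph.copy()
        for _, _, attrs in g.edges(data=True):
            for k, v in list(attrs.items()):
                if isinstance(v, (list, tuple)):
                    attrs[k] = "|".join(map(str, v))
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        rows = []
        for u, v, attrs in graph.edges(data=True):
            row = {"source": u, "target": v}
            for k, val in attrs.items():
                row[k] = "|".join(map(str, val)) if isinstance(val, (list, tuple)) else val
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["source", "target"] if not rows else None)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported graph format: {fmt!r}")


def read_edgelist(path: str | Path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for r in df.itertuples(index=False):
        attrs = {k: v for k, v in r._asdict().items() if k not in ("source", "target")}
        g.add_edge(r.source, r.target, **attrs)
    return g
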