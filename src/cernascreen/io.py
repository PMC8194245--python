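"""Readers and writers for the tabular and network formats of the pipeline.

Dialect conventions: tab-separated UTF-8 text throughout; expression
matrices are features-in-rows / samples-in-columns with the feature id
in the first column; sample groups and feature classes live in
two-column sidecar tables.  Networks are written as SIF (one edge per
line) or GraphML (via networkx).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .datatypes import (
    CeRNANetwork,
    ExpressionMatrix,
    InteractionPair,
    SurvivalRecord,
)


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------- expression

def read_two_column_sidecar(path: str | Path, key: str, value: str) -> dict[str, str]:
    """Read a headered two-column TSV mapping (e.g. sample -> group)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ParseError(f"{path}: line 1: expected header '{key}\\t{value}'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            if row[0] in mapping:
                raise ParseError(f"{path}: line {lineno}: duplicate id {row[0]!r}")
            mapping[row[0]] = row[1]
    return mapping


def read_expression_matrix(
    path: str | Path,
    class_map: Mapping[str, str],
    groups: str | Path | Mapping[str, str],
    scale: str = "linear",
) -> ExpressionMatrix:
    """Read a feature x sample expression TSV plus its group annotation.

    ``groups`` is either a sample->group mapping or the path of a
    two-column sidecar TSV (sample, group).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ParseError(f"{path}: duplicated feature row {dup!r}")
    non_numeric = frame.columns[frame.dtypes == object]
    if len(non_numeric):
        raise ParseError(
            f"{path}: non-numeric values in column(s) {list(non_numeric)}"
        )
    if not isinstance(groups, Mapping):
        groups = read_two_column_sidecar(groups, "sample", "group")
    return ExpressionMatrix(
        values=frame.astype(float),
        feature_class=dict(class_map),
        sample_group=dict(groups),
        scale=scale,
    )


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    groups_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8") as fh:
            fh.write("sample\tgroup\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.sample_group[s]}\n")


def write_class_map(class_map: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\tclass\n")
        for f, c in class_map.items():
            fh.write(f"{f}\t{c}\n")


# ---------------------------------------------------------------- pair tables

PAIR_COLUMNS = ("source", "source_class", "target", "target_class", "resource")


def read_pair_table(path: str | Path) -> list[InteractionPair]:
    """Read a predicted-interaction TSV with columns
    source, source_class, target, target_class, resource."""
    path = Path(path)
    pairs: list[InteractionPair] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != PAIR_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {' '.join(PAIR_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(PAIR_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(PAIR_COLUMNS)} columns, "
                    f"got {len(row)}"
                )
            source, source_class, target, target_class, resource = (
                c.strip() for c in row
            )
            try:
                pairs.append(
                    InteractionPair(source, source_class, target, target_class, resource)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return pairs


def write_pair_table(pairs: list[InteractionPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.source_id}\t{p.source_class}\t{p.target_id}\t"
                f"{p.target_class}\t{p.resource}\n"
            )


# ---------------------------------------------------------------- survival

def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV (subject, time, event[, expression])."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    required = {"subject", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def write_survival_table(records: list[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject\ttime\tevent\tgroup\n")
        for r in records:
            fh.write(f"{r.subject_id}\t{r.time:.6g}\t{r.event}\t{r.group}\n")


# ---------------------------------------------------------------- triplets

TRIPLET_COLUMNS = (
    "lncRNA", "miRNA", "mRNA",
    "r_lnc_mi", "p_lnc_mi", "r_mi_m", "p_mi_m", "r_lnc_m", "p_lnc_m",
)


def write_triplet_table(triplets, path: str | Path) -> None:
    """Write assembled triplets (ids plus any correlation evidence) as TSV."""
    def fmt(rec, attr):
        return f"{getattr(rec, attr):.6g}" if rec is not None else ""

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRIPLET_COLUMNS) + "\n")
        for t in triplets:
            fields = [t.lncRNA_id, t.miRNA_id, t.mRNA_id]
            for rec in (t.corr_lnc_mi, t.corr_mi_m, t.corr_lnc_m):
                fields += [fmt(rec, "pearson_r"), fmt(rec, "p_value")]
            fh.write("\t".join(fields) + "\n")


def read_triplet_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read the id columns of a triplet TSV back as (lncRNA, miRNA, mRNA)."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"lncRNA", "miRNA", "mRNA"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        (str(r.lncRNA), str(r.miRNA), str(r.mRNA))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------- networks

_SIF_RELATION = {kind: kind for kind in ("lnc-mi", "mi-m", "lnc-m")}


def write_network(network: CeRNANetwork, path: str | Path, format: str = "sif") -> None:
    """Write a ceRNA network as SIF or GraphML.

    SIF carries edges only (isolated nodes appear as bare node lines, as
    Cytoscape's reader accepts); GraphML preserves node classes and edge
    attributes and round-trips through :func:`read_network`.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "sif":
        connected = {e for edge in network.edges for e in edge[:2]}
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, kind, _ in network.edges:
                fh.write(f"{a}\t{_SIF_RELATION[kind]}\t{b}\n")
            for node_id, _ in network.nodes:
                if node_id not in connected:
                    fh.write(f"{node_id}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r} (use 'sif' or 'graphml')")


def read_network(path: str | Path, format: str = "graphml") -> CeRNANetwork:
    """Read a network written by :func:`write_network`.

    SIF does not carry node classes, so only GraphML reading returns a
    fully typed :class:`CeRNANetwork`.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = sorted((n, d["feature_class"]) for n, d in g.nodes(data=True))
        class_of = dict(nodes)
        order = {"lncRNA": 0, "miRNA": 1, "mRNA": 2}
        edges = []
        for a, b, d in g.edges(data=True):
            if order[class_of[a]] > order[class_of[b]]:
                a, b = b, a
            edges.append((a, b, d["pair_kind"], d.get("pearson_r")))
        return CeRNANetwork(nodes=nodes, edges=sorted(edges, key=lambda e: e[:3]))
    raise ValueError(f"reading format {format!r} is not supported")
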