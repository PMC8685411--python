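"""Readers and writers for the pipeline's plain-text formats.

All tabular formats are TSV with a header row; readers validate field
counts line by line and raise :class:`ParseError` naming the offending
line. Writers are deterministic: fixed column order, ``%.10g`` floats,
``\n`` line endings — byte-identical output for identical input.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .cerna import CeRNANetwork, TargetMap
from .enrichment import GeneSet, GeneSetCollection
from .errors import ParseError, ValidationError
from .matrix import ExpressionMatrix

FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# generic checked TSV


def _read_rows(path) -> list[list[str]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        width = None
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(path, lineno, f"expected {width} fields, got {len(row)}")
            rows.append(row)
    if not rows:
        raise ParseError(path, 1, "empty file")
    return rows


def read_tsv(path, columns: list[str] | None = None, numeric: list[str] = ()) -> pd.DataFrame:
    """Read a header-ed TSV with per-line field-count validation."""
    rows = _read_rows(path)
    header, body = rows[0], rows[1:]
    if columns is not None and header[: len(columns)] != columns:
        raise ParseError(path, 1, f"expected columns {columns}, found {header}")
    df = pd.DataFrame(body, columns=header)
    for col in numeric:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except ValueError as exc:
                raise ParseError(path, 0, f"non-numeric value in column {col!r}: {exc}") from exc
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# expression matrices + sample metadata


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.reset_index()
    out.columns = ["feature"] + list(matrix.values.columns)
    write_tsv(out, path)


def write_metadata(samples: pd.DataFrame, path) -> None:
    out = samples.reset_index()
    write_tsv(out, path)


def read_expression(expr_path, meta_path, rna_class: str) -> ExpressionMatrix:
    df = read_tsv(expr_path)
    if df.columns[0] != "feature":
        raise ParseError(expr_path, 1, "first column must be 'feature'")
    values = df.set_index("feature")
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(expr_path, 0, f"non-numeric expression value: {exc}") from exc
    samples = read_tsv(meta_path).set_index("sample")
    return ExpressionMatrix(values=values, rna_class=rna_class, samples=samples)


# ---------------------------------------------------------------------------
# target map, DE/pair/triplet tables, ground truth


def write_target_map(targets: TargetMap, path) -> None:
    write_tsv(targets.edges, path)


def read_target_map(path) -> TargetMap:
    return TargetMap(edges=read_tsv(path, columns=["mirna", "target", "target_class"]))


def write_de_table(table: pd.DataFrame, path) -> None:
    write_tsv(table, path)


def read_de_table(path) -> pd.DataFrame:
    df = read_tsv(path, numeric=["log2fc", "t", "p", "q"])
    for col in ("passes", "degenerate"):
        if col in df.columns:
            df[col] = df[col].map({"True": True, "False": False})
    return df


def write_truth_labels(truth, path) -> None:
    rows = [
        (cls, feature, label)
        for cls, labels in truth.de_labels.items()
        for feature, label in labels.items()
    ]
    write_tsv(pd.DataFrame(rows, columns=["rna_class", "feature", "label"]), path)


def write_truth_triplets(truth, path) -> None:
    write_tsv(
        pd.DataFrame(truth.triplets, columns=["sponge", "sponge_class", "mirna", "mrna"]),
        path,
    )


# ---------------------------------------------------------------------------
# GMT gene sets


def write_gmt(collection: GeneSetCollection, path) -> None:
    """GMT: term <tab> description <tab> gene... ; category encoded as
    ``category|name`` in the description field."""
    with open(path, "w", newline="") as fh:
        for gs in collection:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.category}|{gs.name}\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "GMT line needs term, description, >=1 gene")
            term, desc = fields[0], fields[1]
            category, _, name = desc.partition("|")
            if not name:
                category, name = "pathway", desc
            sets.append(GeneSet(term, name, category, frozenset(fields[2:])))
    if not sets:
        raise ParseError(path, 1, "empty GMT file")
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def write_ct_table(table: pd.DataFrame, path) -> None:
    write_tsv(table, path)


def read_ct_table(path) -> pd.DataFrame:
    df = read_tsv(path, columns=["sample", "group", "gene", "replicate", "ct"],
                  numeric=["replicate", "ct"])
    return df


# ---------------------------------------------------------------------------
# networks: SIF, GraphML, node/edge TSV


def write_sif(network: CeRNANetwork, path) -> None:
    """One line per edge: source <tab> interaction <tab> target."""
    with open(path, "w", newline="") as fh:
        for u, v, data in sorted(network.graph.edges(data=True)):
            fh.write(f"{u}\t{data['interaction']}\t{v}\n")


def write_graphml(network: CeRNANetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def write_network_tsv(network: CeRNANetwork, nodes_path, edges_path) -> None:
    g = network.graph
    nodes = pd.DataFrame(
        [(n, d["kind"], d["direction"]) for n, d in sorted(g.nodes(data=True))],
        columns=["node", "kind", "direction"],
    )
    edges = pd.DataFrame(
        sorted((min(u, v), max(u, v), d["interaction"]) for u, v, d in g.edges(data=True)),
        columns=["source", "target", "interaction"],
    )
    write_tsv(nodes, nodes_path)
    write_tsv(edges, edges_path)


def read_network_tsv(nodes_path, edges_path) -> CeRNANetwork:
    nodes = read_tsv(nodes_path, columns=["node", "kind", "direction"])
    edges = read_tsv(edges_path, columns=["source", "target", "interaction"])
    g = nx.Graph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.node, kind=row.kind, direction=row.direction)
    for row in edges.itertuples(index=False):
        if row.source not in g or row.target not in g:
            raise ValidationError(f"edge endpoint missing from node table: {row.source}-{row.target}")
        g.add_edge(row.source, row.target, interaction=row.interaction)
    n_triplets = sum(1 for _, _, d in g.edges(data=True) if d["interaction"] == "coexpression")
    return CeRNANetwork(graph=g, n_triplets=n_triplets)
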