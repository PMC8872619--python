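"""Readers and writers for the plain-text formats used by the pipeline.

All tables are tab-separated with a header line; writers can prepend
``# key: value`` provenance comment lines, which every reader skips.
Validation failures carry the file path and line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .de import DE_TABLE_COLUMNS, FEATURE_CLASSES, validate_de_table
from .enrichment import GeneSet, GeneSetCollection
from .errors import ParseError, ValidationError
from .impact import PathwayTopology
from .network import EDGE_COLUMNS, REGULATOR_CLASSES, RegulatoryNetwork

PATHWAY_COLUMNS = ("source", "target", "weight", "relation")


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {key}: {provenance[key]}" for key in sorted(provenance)]


def _write_tsv(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    path = Path(path)
    lines = _provenance_lines(provenance)
    body = table.to_csv(sep="\t", index=False, lineterminator="\n")
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def _iter_data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def _read_table(path, required: tuple[str, ...]) -> tuple[pd.DataFrame, list[int]]:
    """Generic TSV reader tracking source line numbers per record."""
    header: list[str] | None = None
    records: list[dict] = []
    line_numbers: list[int] = []
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if header is None:
            if len(set(parts)) != len(parts):
                dup = next(c for c in parts if parts.count(c) > 1)
                raise ParseError(f"duplicate header column {dup!r}", path, lineno)
            missing = [c for c in required if c not in parts]
            if missing:
                raise ParseError(
                    f"missing required column(s): {', '.join(missing)}", path, lineno)
            header = parts
            continue
        if len(parts) != len(header):
            raise ParseError(
                f"expected {len(header)} fields, found {len(parts)}", path, lineno)
        records.append(dict(zip(header, parts)))
        line_numbers.append(lineno)
    if header is None:
        raise ParseError("file contains no header line", path)
    return pd.DataFrame(records, columns=header), line_numbers


# -- DE tables ---------------------------------------------------------------

def read_de_table(path, require_qvalue: bool = True) -> pd.DataFrame:
    required = DE_TABLE_COLUMNS if require_qvalue else DE_TABLE_COLUMNS[:-1]
    table, lines = _read_table(path, required)
    for col in ("log2fc", "pvalue", "qvalue"):
        if col in table.columns:
            try:
                table[col] = table[col].astype(float)
            except ValueError as exc:
                raise ParseError(f"non-numeric value in column {col!r}: {exc}", path)
    for idx, cls in enumerate(table["feature_class"]):
        if cls not in FEATURE_CLASSES:
            raise ParseError(f"unknown feature_class {cls!r}", path, lines[idx])
    validate_de_table(table, require_qvalue=require_qvalue)
    return table


def write_de_table(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    _write_tsv(table, path, provenance)


# -- interaction / network edge tables ---------------------------------------

def read_edge_table(path) -> pd.DataFrame:
    """Interaction records (regulator_id, regulator_class, target_gene,
    source_db, evidence) with per-line validation."""
    table, lines = _read_table(path, EDGE_COLUMNS)
    for idx, cls in enumerate(table["regulator_class"]):
        if cls not in REGULATOR_CLASSES:
            raise ParseError(f"unknown regulator_class {cls!r}", path, lines[idx])
    return table


def write_edge_table(table: pd.DataFrame, path, provenance: dict | None = None) -> None:
    _write_tsv(table[list(EDGE_COLUMNS)], path, provenance)


def write_network(net: RegulatoryNetwork, path, provenance: dict | None = None) -> None:
    write_edge_table(net.edges, path, provenance)


# -- GMT ---------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    collection = GeneSetCollection()
    for lineno, line in _iter_data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError("GMT rows need name, description and >= 1 gene",
                             path, lineno)
        name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise ParseError(f"gene set {name!r} has no genes", path, lineno)
        try:
            collection.add(GeneSet(name=name, description=description, genes=tuple(genes)))
        except ValidationError as exc:
            raise ParseError(str(exc), path, lineno) from exc
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = [
        "\t".join([gs.name, gs.description, *gs.genes]) for gs in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- pathway topology --------------------------------------------------------

def read_pathway(path) -> PathwayTopology:
    table, lines = _read_table(path, PATHWAY_COLUMNS)
    weights = []
    for idx, w in enumerate(table["weight"]):
        try:
            wi = int(w)
        except ValueError:
            wi = 0
        if wi not in (1, -1):
            raise ParseError(f"pathway weight must be +1 or -1, found {w!r}",
                             path, lines[idx])
        weights.append(wi)
    table["weight"] = weights
    nodes = list(dict.fromkeys([*table["source"], *table["target"]]))
    return PathwayTopology(nodes=tuple(nodes), edges=table)


def write_pathway(topology: PathwayTopology, path, provenance: dict | None = None) -> None:
    _write_tsv(topology.edges[list(PATHWAY_COLUMNS)], path, provenance)


# -- network exports for external viewers ------------------------------------

def export_sif(net: RegulatoryNetwork, path) -> None:
    """Simple interaction format: ``regulator<TAB>regulates<TAB>gene``."""
    lines = [
        f"{row.regulator_id}\tregulates\t{row.target_gene}"
        for row in net.edges.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def export_graphml(
    net: RegulatoryNetwork,
    path,
    de_tables: list[pd.DataFrame] | None = None,
) -> None:
    """GraphML with node attributes (class, log2fc, up/down direction)."""
    lfc: dict[str, float] = {}
    if de_tables:
        for table in de_tables:
            for _, row in table.iterrows():
                lfc[str(row["feature_id"])] = float(row["log2fc"])
    g = net.to_graph()
    for node, data in g.nodes(data=True):
        if node in lfc:
            data["log2fc"] = lfc[node]
            data["direction"] = "up" if lfc[node] > 0 else "down"
    nx.write_graphml(g, path)


# -- JSON reports ------------------------------------------------------------

def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
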