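"""Directed bipartite regulator->target network construction and merging.

Networks connect non-coding regulators (miRNA or lncRNA) to differentially
expressed target genes. Edges are unsigned; duplicate (regulator, target)
pairs arising from multiple evidence sources collapse into a single edge
whose ``source_db``/``evidence`` fields accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from ._util import gene_alias_tokens, normalize_gene, normalize_mirna
from .errors import ValidationError

REGULATOR_CLASSES = ("miRNA", "lncRNA")
EDGE_COLUMNS = ("regulator_id", "regulator_class", "target_gene", "source_db", "evidence")

_EVIDENCE_SEP = ";"


def _regulator_keys(regulator_id: str, regulator_class: str) -> list[str]:
    if regulator_class == "miRNA":
        return [normalize_mirna(regulator_id)]
    # lncRNAs carry gene-style symbols, possibly slash-joined aliases
    return gene_alias_tokens(regulator_id)


@dataclass
class RegulatoryNetwork:
    """Deduplicated bipartite edge set plus the regulator roster.

    ``regulators`` keeps every DE regulator that entered construction, so
    zero-degree regulators remain reportable after filtering.
    """

    edges: pd.DataFrame
    regulators: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["regulator_id", "regulator_class"]))

    def __post_init__(self):
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValidationError(f"network edges missing column(s): {missing}")
        self._check_single_class()

    def _check_single_class(self):
        classes = self.edges.groupby("regulator_id")["regulator_class"].nunique()
        conflict = classes[classes > 1]
        if not conflict.empty:
            raise ValidationError(
                f"regulator {conflict.index[0]!r} carries more than one class")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets(self) -> set[str]:
        return set(self.edges["target_gene"])

    def targets_of(self, regulator_ids) -> set[str]:
        keys = set()
        for rid in regulator_ids:
            keys.add(normalize_mirna(rid))
            keys.update(gene_alias_tokens(rid))
        if not len(self.edges):
            return set()
        mask = self.edges.apply(
            lambda row: bool(
                keys & set(_regulator_keys(row["regulator_id"], row["regulator_class"]))),
            axis=1,
        )
        return set(self.edges.loc[mask, "target_gene"])

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for _, row in self.regulators.iterrows():
            g.add_node(row["regulator_id"], kind="regulator",
                       regulator_class=row["regulator_class"])
        for _, row in self.edges.iterrows():
            g.add_node(row["regulator_id"], kind="regulator",
                       regulator_class=row["regulator_class"])
            g.add_node(row["target_gene"], kind="gene")
            g.add_edge(row["regulator_id"], row["target_gene"],
                       source_db=row["source_db"], evidence=row["evidence"])
        return g


def _validate_interactions(interactions: pd.DataFrame) -> None:
    missing = [c for c in EDGE_COLUMNS if c not in interactions.columns]
    if missing:
        raise ValidationError(f"interaction table missing column(s): {missing}")
    bad = set(interactions["regulator_class"]) - set(REGULATOR_CLASSES)
    if bad:
        raise ValidationError(f"unknown regulator_class value(s): {sorted(bad)}")
    per_reg = interactions.groupby("regulator_id")["regulator_class"].nunique()
    conflict = per_reg[per_reg > 1]
    if not conflict.empty:
        raise ValidationError(
            f"regulator {conflict.index[0]!r} has inconsistent class across rows")


def build_network(
    de_regulators: pd.DataFrame,
    de_genes: pd.DataFrame,
    interactions: pd.DataFrame,
) -> RegulatoryNetwork:
    """Filter an interaction table down to DE regulators and DE targets.

    A row survives when its regulator matches a DE regulator (miRNA names
    compared after species-prefix stripping, case-insensitively; lncRNA
    and gene symbols case-insensitively with slash-separated aliases
    treated as synonyms) and its target matches a DE gene. Duplicate
    (regulator, target) pairs merge, concatenating evidence.
    """
    _validate_interactions(interactions)
    if (de_regulators["feature_class"] == "gene").any():
        raise ValidationError("de_regulators must not contain gene-class features")

    reg_lookup: dict[str, tuple[str, str]] = {}
    for _, row in de_regulators.iterrows():
        rid, rclass = str(row["feature_id"]), str(row["feature_class"])
        if rclass == "miRNA":
            reg_lookup[normalize_mirna(rid)] = (rid, rclass)
        else:
            for tok in gene_alias_tokens(rid):
                reg_lookup[tok] = (rid, rclass)

    gene_lookup: dict[str, str] = {}
    for gid in de_genes["feature_id"].astype(str):
        for tok in gene_alias_tokens(gid):
            gene_lookup[tok] = gid

    merged: dict[tuple[str, str], dict] = {}
    for _, row in interactions.iterrows():
        rclass = row["regulator_class"]
        hit = None
        for rkey in _regulator_keys(str(row["regulator_id"]), rclass):
            hit = reg_lookup.get(rkey)
            if hit is not None:
                break
        if hit is None or hit[1] != rclass:
            continue
        canon_reg = hit[0]
        target = None
        for tok in gene_alias_tokens(str(row["target_gene"])):
            if tok in gene_lookup:
                target = gene_lookup[tok]
                break
        if target is None:
            continue
        if normalize_gene(target) == normalize_gene(canon_reg):
            raise ValidationError(f"self-loop rejected: {canon_reg!r} -> {target!r}")
        key = (canon_reg, target)
        entry = merged.setdefault(
            key,
            {"regulator_id": canon_reg, "regulator_class": rclass,
             "target_gene": target, "source_db": [], "evidence": []},
        )
        for fld in ("source_db", "evidence"):
            for tok in str(row[fld]).split(_EVIDENCE_SEP):
                tok = tok.strip()
                if tok and tok not in entry[fld]:
                    entry[fld].append(tok)

    rows = [
        {**e, "source_db": _EVIDENCE_SEP.join(e["source_db"]),
         "evidence": _EVIDENCE_SEP.join(e["evidence"])}
        for e in merged.values()
    ]
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    edges = edges.sort_values(["regulator_id", "target_gene"], kind="mergesort")
    edges = edges.reset_index(drop=True)
    regulators = (
        de_regulators[["feature_id", "feature_class"]]
        .rename(columns={"feature_id": "regulator_id", "feature_class": "regulator_class"})
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return RegulatoryNetwork(edges=edges, regulators=regulators)


def merge_networks(net_a: RegulatoryNetwork, net_b: RegulatoryNetwork) -> RegulatoryNetwork:
    """Edge union of two networks sharing the gene namespace.

    Duplicate (regulator, target) pairs merge with concatenated evidence;
    the same regulator id appearing with two classes is an error.
    """
    combined = pd.concat([net_a.edges, net_b.edges], ignore_index=True)
    per_reg = combined.groupby("regulator_id")["regulator_class"].nunique()
    conflict = per_reg[per_reg > 1]
    if not conflict.empty:
        raise ValidationError(
            f"regulator {conflict.index[0]!r} carries two classes across networks")
    merged: dict[tuple[str, str], dict] = {}
    for _, row in combined.iterrows():
        key = (row["regulator_id"], row["target_gene"])
        entry = merged.setdefault(
            key,
            {"regulator_id": row["regulator_id"],
             "regulator_class": row["regulator_class"],
             "target_gene": row["target_gene"], "source_db": [], "evidence": []},
        )
        if entry["regulator_class"] != row["regulator_class"]:
            raise ValidationError(
                f"regulator {row['regulator_id']!r} carries two classes across networks")
        for fld in ("source_db", "evidence"):
            for tok in str(row[fld]).split(_EVIDENCE_SEP):
                tok = tok.strip()
                if tok and tok not in entry[fld]:
                    entry[fld].append(tok)
    rows = [
        {**e, "source_db": _EVIDENCE_SEP.join(e["source_db"]),
         "evidence": _EVIDENCE_SEP.join(e["evidence"])}
        for e in merged.values()
    ]
    edges = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    edges = edges.sort_values(["regulator_id", "target_gene"], kind="mergesort")
    edges = edges.reset_index(drop=True)
    regulators = (
        pd.concat([net_a.regulators, net_b.regulators], ignore_index=True)
        .drop_duplicates()
        .reset_index(drop=True)
    )
    per_reg = regulators.groupby("regulator_id")["regulator_class"].nunique()
    conflict = per_reg[per_reg > 1]
    if not conflict.empty:
        raise ValidationError(
            f"regulator {conflict.index[0]!r} carries two classes across networks")
    return RegulatoryNetwork(edges=edges, regulators=regulators)
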