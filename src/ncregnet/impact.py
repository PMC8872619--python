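"""Topology-based pathway impact analysis and regulator overlay counts.

Perturbation propagates through a signed pathway graph: each gene's
perturbation factor PF solves

    PF(g_i) = dE(g_i) + sum_j beta_ij / N_ds(g_j) * PF(g_j)

over upstream genes j, where beta is +1 (activation) or -1 (inhibition)
and N_ds is the regulator's outgoing edge count. Accumulated perturbation
Acc = PF - dE sums to tA. Significance combines a hypergeometric DE-count
p-value (pNDE) with a bootstrap p-value for |tA| (pPERT) into
pG = c - c*ln(c) with c = pNDE * pPERT.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve

from ._util import normalize_gene
from .errors import ParameterError, SingularTopologyError, ValidationError
from .network import RegulatoryNetwork

_COND_LIMIT = 1e12


@dataclass
class PathwayTopology:
    """Signed, weighted gene-gene pathway graph.

    edges: (source, target, weight in {+1,-1}, relation label); node ids
    unique; ``n_downstream`` maps each node to its outgoing edge count.
    """

    nodes: tuple[str, ...]
    edges: pd.DataFrame  # source, target, weight, relation

    def __post_init__(self):
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("pathway node ids must be unique")
        required = ["source", "target", "weight"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ValidationError(f"pathway edges missing column(s): {missing}")
        if "relation" not in self.edges.columns:
            self.edges = self.edges.assign(relation="")
        weights = set(self.edges["weight"].astype(int)) if len(self.edges) else set()
        if weights - {1, -1}:
            raise ValidationError("pathway edge weights must be +1 or -1")
        node_set = set(self.nodes)
        for col in ("source", "target"):
            stray = set(self.edges[col]) - node_set
            if stray:
                raise ValidationError(f"edge {col} not in node list: {sorted(stray)[:5]}")

    @property
    def n_downstream(self) -> dict[str, int]:
        counts = self.edges.groupby("source").size() if len(self.edges) else {}
        return {node: int(counts.get(node, 0)) for node in self.nodes}

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["source"], row["target"],
                       weight=int(row["weight"]), relation=row.get("relation", ""))
        return g


@dataclass
class ImpactResult:
    pf: dict[str, float]
    acc: dict[str, float]
    ta: float
    p_nde: float
    p_pert: float
    p_g: float
    n_de_in_pathway: int
    n_pathway_measured: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "tA": self.ta,
            "pNDE": self.p_nde,
            "pPERT": self.p_pert,
            "pG": self.p_g,
            "n_de_in_pathway": self.n_de_in_pathway,
            "n_pathway_measured": self.n_pathway_measured,
            "degenerate": self.degenerate,
            "pf": dict(sorted(self.pf.items())),
            "acc": dict(sorted(self.acc.items())),
        }


def _influence_system(topology: PathwayTopology) -> tuple[list[str], np.ndarray]:
    """Node order and the matrix A = I - W with W[i,j] = beta(j->i)/N_ds(j)."""
    nodes = list(topology.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    n_ds = topology.n_downstream
    w = np.zeros((len(nodes), len(nodes)))
    for _, row in topology.edges.iterrows():
        src, tgt = row["source"], row["target"]
        w[index[tgt], index[src]] += int(row["weight"]) / n_ds[src]
    return nodes, np.eye(len(nodes)) - w


def _describe_cycle(topology: PathwayTopology) -> str:
    try:
        cycle = nx.find_cycle(topology.to_graph())
    except nx.NetworkXNoCycle:
        return "no directed cycle found; system is numerically singular"
    path = " -> ".join([edge[0] for edge in cycle] + [cycle[-1][1]])
    return f"cycle {path}"


def perturbation_factors(
    topology: PathwayTopology, delta_e: dict[str, float]
) -> pd.DataFrame:
    """Per-gene perturbation factor PF and accumulation Acc = PF - dE.

    ``delta_e`` maps gene -> log2 fold change (0 for non-DE); genes absent
    from the mapping count as 0. Raises :class:`SingularTopologyError` when
    I - W is not invertible, naming an offending cycle.
    """
    nodes, a = _influence_system(topology)
    de = np.array([float(delta_e.get(node, 0.0)) for node in nodes])
    if not nodes:
        return pd.DataFrame(columns=["gene", "delta_e", "pf", "acc"])
    singular = False
    try:
        if np.linalg.cond(a) > _COND_LIMIT:
            singular = True
        else:
            pf = np.linalg.solve(a, de)
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        raise SingularTopologyError(
            f"influence system I - B' is singular: {_describe_cycle(topology)}")
    return pd.DataFrame({
        "gene": nodes,
        "delta_e": de,
        "pf": pf,
        "acc": pf - de,
    })


def total_accumulation(topology: PathwayTopology, delta_e: dict[str, float]) -> float:
    return float(perturbation_factors(topology, delta_e)["acc"].sum())


def impact_analysis(
    topology: PathwayTopology,
    de_table: pd.DataFrame,
    all_measured,
    n_boot: int = 2000,
    seed: int = 0,
) -> ImpactResult:
    """SPIA-style significance for one pathway.

    ``de_table`` holds the selected DE genes (feature_id, log2fc);
    ``all_measured`` is the measured gene universe. pNDE is the
    hypergeometric upper tail for the DE count in the pathway; pPERT is the
    add-one-smoothed fraction of ``n_boot`` random re-assignments of the
    observed DE log2FCs to pathway genes with |tA_boot| >= |tA_obs|.
    """
    from .enrichment import hypergeom_tail  # local import avoids a cycle

    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)

    measured = {normalize_gene(g) for g in all_measured}
    node_key = {normalize_gene(node): node for node in topology.nodes}
    pathway_measured = set(node_key) & measured

    de_map: dict[str, float] = {}
    for _, row in de_table.iterrows():
        key = normalize_gene(str(row["feature_id"]))
        if key in measured:
            de_map[key] = float(row["log2fc"])
    de_in_pathway = {k: v for k, v in de_map.items() if k in node_key}

    if not de_in_pathway:
        warnings.warn("impact_analysis: no DE genes in the pathway (degenerate)",
                      stacklevel=2)
        zeros = {node: 0.0 for node in topology.nodes}
        return ImpactResult(
            pf=zeros, acc=dict(zeros), ta=0.0, p_nde=1.0, p_pert=1.0, p_g=1.0,
            n_de_in_pathway=0, n_pathway_measured=len(pathway_measured),
            degenerate=True)

    delta_e = {node_key[k]: v for k, v in de_in_pathway.items()}
    obs = perturbation_factors(topology, delta_e)
    ta_obs = float(obs["acc"].sum())

    p_nde = hypergeom_tail(
        k=len(de_in_pathway), K=len(de_map), n=len(pathway_measured), N=len(measured))

    # factorize I - W once; every bootstrap replicate is then a single solve
    nodes, a = _influence_system(topology)
    lu, piv = lu_factor(a)
    fold_changes = np.array(sorted(de_in_pathway.values()))
    n_hit = len(fold_changes)
    exceed = 0
    for _ in range(n_boot):
        picks = rng.choice(len(nodes), size=n_hit, replace=False)
        values = rng.permutation(fold_changes)
        boot_vec = np.zeros(len(nodes))
        boot_vec[picks] = values
        ta_boot = float((lu_solve((lu, piv), boot_vec) - boot_vec).sum())
        if abs(ta_boot) >= abs(ta_obs):
            exceed += 1
    p_pert = (exceed + 1) / (n_boot + 1)

    c = p_nde * p_pert
    p_g = 1.0 if c >= 1.0 else c - c * math.log(c)

    return ImpactResult(
        pf=dict(zip(obs["gene"], obs["pf"])),
        acc=dict(zip(obs["gene"], obs["acc"])),
        ta=ta_obs, p_nde=p_nde, p_pert=p_pert, p_g=p_g,
        n_de_in_pathway=n_hit, n_pathway_measured=len(pathway_measured))


@dataclass
class OverlayResult:
    table: pd.DataFrame  # gene, n_mirna, n_lncrna, n_total, mirnas, lncrnas
    most_regulated: list[str] = field(default_factory=list)


def regulator_overlay(net: RegulatoryNetwork, pathway_genes) -> OverlayResult:
    """Per pathway gene, the incident DE miRNAs and lncRNAs from ``net``.

    Genes with no incident edges report counts (0, 0). The gene(s) with the
    highest combined regulator count are flagged as most regulated (empty
    when no pathway gene has any regulator).
    """
    genes = list(dict.fromkeys(pathway_genes))
    by_target: dict[str, dict[str, list[str]]] = {}
    for _, row in net.edges.iterrows():
        key = normalize_gene(row["target_gene"])
        slot = by_target.setdefault(key, {"miRNA": [], "lncRNA": []})
        if row["regulator_id"] not in slot[row["regulator_class"]]:
            slot[row["regulator_class"]].append(row["regulator_id"])
    rows = []
    for gene in genes:
        slot = by_target.get(normalize_gene(gene), {"miRNA": [], "lncRNA": []})
        rows.append({
            "gene": gene,
            "n_mirna": len(slot["miRNA"]),
            "n_lncrna": len(slot["lncRNA"]),
            "n_total": len(slot["miRNA"]) + len(slot["lncRNA"]),
            "mirnas": ";".join(sorted(slot["miRNA"])),
            "lncrnas": ";".join(sorted(slot["lncRNA"])),
        })
    table = pd.DataFrame(
        rows, columns=["gene", "n_mirna", "n_lncrna", "n_total", "mirnas", "lncrnas"])
    most = []
    if len(table) and table["n_total"].max() > 0:
        top = table["n_total"].max()
        most = sorted(table.loc[table["n_total"] == top, "gene"])
    return OverlayResult(table=table, most_regulated=most)
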