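"""Seeded synthetic inputs: DE tables, regulator-target interaction tables
with planted hubs and controllable target-set overlap, and small signed
pathway topologies.

Every generator derives an independent sub-stream from ``(seed, stream id)``
so adding one table never perturbs another, and identical parameters
(including the seed) give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import looks_like_mirna
from .de import bh_adjust
from .errors import ParameterError
from .impact import PathwayTopology

# sub-stream ids: one per emitted artefact
_STREAM_GENES, _STREAM_MIRNA, _STREAM_LNCRNA = 0, 1, 2
_STREAM_INT_MIRNA, _STREAM_INT_LNCRNA, _STREAM_PATHWAY = 3, 4, 5


@dataclass(frozen=True)
class SynthParams:
    """Parameters for the synthetic DE + interaction generators.

    ``planted_hubs`` pins exact out-degrees for named regulators (classified
    as miRNA when the id contains a miR/let token, lncRNA otherwise);
    ``overlap_fraction`` is the expected share of lncRNA targets drawn from
    the pooled miRNA targets.
    """

    n_genes: int = 1000
    n_mirna: int = 50
    n_lncrna: int = 15
    de_fraction: float = 0.3
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    null_sd: float = 0.25
    degree_exponent: float = 2.0
    planted_hubs: tuple[tuple[str, int], ...] = ()
    overlap_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_mirna", "n_lncrna"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("de_fraction", "overlap_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.degree_exponent <= 1.0:
            raise ParameterError("degree_exponent must be > 1")
        for name in ("effect_sd", "null_sd"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        object.__setattr__(self, "planted_hubs", tuple(
            (str(rid), int(cnt)) for rid, cnt in self.planted_hubs))
        for rid, cnt in self.planted_hubs:
            if cnt < 0:
                raise ParameterError(f"planted hub {rid!r} target-count must be >= 0")
            if cnt > self.n_genes:
                raise ParameterError(
                    f"planted hub {rid!r} target-count {cnt} exceeds n_genes")


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def _regulator_ids(params: SynthParams) -> tuple[list[str], list[str]]:
    """miRNA and lncRNA id lists with planted hub ids placed first."""
    hub_mirna = [rid for rid, _ in params.planted_hubs if looks_like_mirna(rid)]
    hub_lncrna = [rid for rid, _ in params.planted_hubs if not looks_like_mirna(rid)]
    mirnas = list(hub_mirna)
    i = 1
    while len(mirnas) < max(params.n_mirna, len(hub_mirna)):
        cand = f"miR-sim-{i}"
        if cand not in mirnas:
            mirnas.append(cand)
        i += 1
    lncrnas = list(hub_lncrna)
    i = 1
    while len(lncrnas) < max(params.n_lncrna, len(hub_lncrna)):
        cand = f"LNC-SIM-{i}"
        if cand not in lncrnas:
            lncrnas.append(cand)
        i += 1
    return mirnas, lncrnas


def _de_table(ids: list[str], feature_class: str, params: SynthParams,
              stream: int, force_de: set[str]) -> pd.DataFrame:
    rng = np.random.default_rng([params.seed, stream])
    n = len(ids)
    is_de = rng.random(n) < params.de_fraction
    sign = rng.choice([-1.0, 1.0], size=n)
    effect = sign * rng.normal(params.effect_mean, params.effect_sd, size=n)
    noise = rng.normal(0.0, params.null_sd, size=n)
    forced = np.array([fid in force_de for fid in ids], dtype=bool)
    is_de = is_de | forced
    log2fc = np.where(is_de, effect, noise)
    # one-sided location-shift statistic: |log2fc| / null_sd is N(0,1)
    # under the null, so p is Uniform(0,1) for null features and
    # stochastically small for shifted ones
    z = np.abs(log2fc) / params.null_sd
    pvalues = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    return pd.DataFrame({
        "feature_id": ids,
        "feature_class": feature_class,
        "log2fc": log2fc,
        "pvalue": pvalues,
        "qvalue": bh_adjust(pvalues),
    })


def simulate_de_tables(
    params: SynthParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene, miRNA and lncRNA DE tables from a null + shifted-effect mixture.

    log2FC is centred at 0 (sd ``null_sd``) for null features and at
    +-``effect_mean`` (sd ``effect_sd``) for DE features drawn with
    probability ``de_fraction``; planted hub regulators are always drawn
    from the DE component so the planted structure survives thresholding.
    """
    mirnas, lncrnas = _regulator_ids(params)
    hubs = {rid for rid, _ in params.planted_hubs}
    genes = _de_table(_gene_ids(params.n_genes), "gene", params, _STREAM_GENES, set())
    mirna = _de_table(mirnas, "miRNA", params, _STREAM_MIRNA, hubs)
    lncrna = _de_table(lncrnas, "lncRNA", params, _STREAM_LNCRNA, hubs)
    return genes, mirna, lncrna


def _sample_degree(rng: np.random.Generator, exponent: float, k_max: int, size: int) -> np.ndarray:
    """Truncated discrete power law on {1..k_max}: P(k) proportional to k^-a."""
    if k_max < 1:
        raise ParameterError("no available targets to sample degrees from")
    support = np.arange(1, k_max + 1)
    weights = support.astype(float) ** (-exponent)
    weights /= weights.sum()
    return rng.choice(support, size=size, p=weights)


def _interaction_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["regulator_id", "regulator_class", "target_gene", "source_db", "evidence"],
    )


def simulate_interactions(
    params: SynthParams, de_genes,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA->gene and lncRNA->gene interaction tables over ``de_genes``.

    Background out-degrees follow a truncated power law with
    ``degree_exponent``; planted hubs receive exactly their stated
    target-count. Each lncRNA draws a Binomial(degree, overlap_fraction)
    share of its targets from the pooled miRNA targets and the rest from
    the remaining genes. No duplicate (regulator, target) rows.
    """
    pool = sorted(dict.fromkeys(str(g) for g in de_genes))
    hub_counts = dict(params.planted_hubs)
    if any(cnt > 0 for cnt in hub_counts.values()) and not pool:
        raise ParameterError("planted hubs require a nonempty de_genes pool")
    for rid, cnt in hub_counts.items():
        if cnt > len(pool):
            raise ParameterError(
                f"planted hub {rid!r} target-count {cnt} exceeds available targets "
                f"({len(pool)})")

    mirnas, lncrnas = _regulator_ids(params)
    pool_arr = np.array(pool)

    rng_m = np.random.default_rng([params.seed, _STREAM_INT_MIRNA])
    mirna_rows: list[dict] = []
    background_m = [r for r in mirnas if r not in hub_counts]
    degrees_m = (_sample_degree(rng_m, params.degree_exponent, len(pool), len(background_m))
                 if background_m and pool else np.array([], dtype=int))
    deg_map = {rid: int(d) for rid, d in zip(background_m, degrees_m)}
    deg_map.update({rid: hub_counts[rid] for rid in mirnas if rid in hub_counts})
    for rid in mirnas:
        d = deg_map.get(rid, 0)
        if d == 0 or not pool:
            continue
        targets = rng_m.choice(pool_arr, size=d, replace=False)
        for t in targets:
            mirna_rows.append({
                "regulator_id": rid, "regulator_class": "miRNA",
                "target_gene": str(t), "source_db": "synthdb", "evidence": "simulated"})
    mirna_table = _interaction_frame(mirna_rows)

    mirna_union = sorted(set(mirna_table["target_gene"])) if len(mirna_table) else []
    outside = sorted(set(pool) - set(mirna_union))
    mirna_union_arr = np.array(mirna_union) if mirna_union else np.array([], dtype=str)
    outside_arr = np.array(outside) if outside else np.array([], dtype=str)

    rng_l = np.random.default_rng([params.seed, _STREAM_INT_LNCRNA])
    lncrna_rows: list[dict] = []
    background_l = [r for r in lncrnas if r not in hub_counts]
    degrees_l = (_sample_degree(rng_l, params.degree_exponent, len(pool), len(background_l))
                 if background_l and pool else np.array([], dtype=int))
    deg_map_l = {rid: int(d) for rid, d in zip(background_l, degrees_l)}
    deg_map_l.update({rid: hub_counts[rid] for rid in lncrnas if rid in hub_counts})
    for rid in lncrnas:
        d = deg_map_l.get(rid, 0)
        if d == 0 or not pool:
            continue
        n_overlap = int(rng_l.binomial(d, params.overlap_fraction))
        n_overlap = min(n_overlap, len(mirna_union))
        n_outside = min(d - n_overlap, len(outside))
        # if one pool ran short, top up from the other
        n_overlap = min(d - n_outside, len(mirna_union))
        chosen: list[str] = []
        if n_overlap:
            chosen.extend(rng_l.choice(mirna_union_arr, size=n_overlap, replace=False))
        if n_outside:
            chosen.extend(rng_l.choice(outside_arr, size=n_outside, replace=False))
        for t in chosen:
            lncrna_rows.append({
                "regulator_id": rid, "regulator_class": "lncRNA",
                "target_gene": str(t), "source_db": "synthdb", "evidence": "simulated"})
    lncrna_table = _interaction_frame(lncrna_rows)
    return mirna_table, lncrna_table


def simulate_pathway(
    n_nodes: int,
    edge_prob: float,
    de_overlay: pd.DataFrame,
    seed: int = 0,
) -> PathwayTopology:
    """Random acyclic signed pathway whose node ids overlap ``de_overlay``.

    Nodes are drawn from the overlay's feature ids (topping up with
    synthetic ids when the table is small); each forward pair (in a random
    topological order) gets an edge with probability ``edge_prob`` and a
    uniform +-1 sign.
    """
    if n_nodes < 1:
        raise ParameterError("n_nodes must be >= 1")
    if not 0.0 <= edge_prob <= 1.0:
        raise ParameterError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng([seed, _STREAM_PATHWAY])
    available = list(dict.fromkeys(de_overlay["feature_id"].astype(str))) \
        if len(de_overlay) else []
    if len(available) >= n_nodes:
        picks = rng.choice(len(available), size=n_nodes, replace=False)
        nodes = [available[i] for i in sorted(picks)]
    else:
        nodes = available + [f"PWGENE{i:03d}" for i in range(1, n_nodes - len(available) + 1)]
    order = rng.permutation(n_nodes)
    rows = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                sign = int(rng.choice([1, -1]))
                rows.append({
                    "source": nodes[order[a]],
                    "target": nodes[order[b]],
                    "weight": sign,
                    "relation": "activation" if sign == 1 else "inhibition",
                })
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "relation"])
    return PathwayTopology(nodes=tuple(nodes), edges=edges)
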