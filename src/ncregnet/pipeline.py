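"""End-to-end pipeline: DE selection -> networks -> ranking -> partition ->
overrepresentation -> pathway impact -> overlay -> exports.

The whole run is driven by a single :class:`PipelineConfig` (YAML or JSON
on disk) and is deterministic given the config, including the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from . import __version__
from .centrality import partition_stats, regulator_degrees, top_k
from .de import select_de
from .enrichment import ora
from .errors import PipelineStageError, ValidationError
from .impact import impact_analysis, regulator_overlay
from .io import (
    export_graphml,
    export_sif,
    read_de_table,
    read_edge_table,
    read_gmt,
    read_pathway,
    write_de_table,
    write_edge_table,
    write_json_report,
    write_network,
    write_pathway,
    _write_tsv,
)
from .network import build_network, merge_networks
from .synth import SynthParams, simulate_de_tables, simulate_interactions, simulate_pathway

log = logging.getLogger("ncregnet")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    fc_linear_min: float = 1.5
    q_max: float = 0.01
    k: int = 10
    tie_rule: str = "lexicographic"
    display: str = "decimal"
    n_boot: int = 1000
    genes_de: str | None = None
    mirna_de: str | None = None
    lncrna_de: str | None = None
    mirna_interactions: str | None = None
    lncrna_interactions: str | None = None
    gmt: str | None = None
    background: str | None = None  # path to a gene list; default: DE-input genes
    pathway: str | None = None
    simulate: dict | None = None

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must hold a mapping")
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        log.error("stage %s: FAILED (%r)", name, exc)
        raise PipelineStageError(name, exc) from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _simulate_inputs(config: PipelineConfig, outdir: Path, prov: dict) -> None:
    """Generate synthetic inputs and point the config at them."""
    sim = dict(config.simulate or {})
    pathway_nodes = sim.pop("pathway_nodes", 0)
    pathway_edge_prob = sim.pop("pathway_edge_prob", 0.3)
    sim.setdefault("seed", config.seed)
    if "planted_hubs" in sim:
        sim["planted_hubs"] = tuple(tuple(h) for h in sim["planted_hubs"])
    params = SynthParams(**sim)
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)

    genes, mirna, lncrna = simulate_de_tables(params)
    de_genes = select_de(genes, config.fc_linear_min, config.q_max)
    mirna_int, lncrna_int = simulate_interactions(params, de_genes["feature_id"])

    write_de_table(genes, indir / "genes_de.tsv", prov)
    write_de_table(mirna, indir / "mirna_de.tsv", prov)
    write_de_table(lncrna, indir / "lncrna_de.tsv", prov)
    write_edge_table(mirna_int, indir / "mirna_interactions.tsv", prov)
    write_edge_table(lncrna_int, indir / "lncrna_interactions.tsv", prov)
    config.genes_de = str(indir / "genes_de.tsv")
    config.mirna_de = str(indir / "mirna_de.tsv")
    config.lncrna_de = str(indir / "lncrna_de.tsv")
    config.mirna_interactions = str(indir / "mirna_interactions.tsv")
    config.lncrna_interactions = str(indir / "lncrna_interactions.tsv")

    if pathway_nodes:
        topology = simulate_pathway(
            pathway_nodes, pathway_edge_prob, de_genes, seed=params.seed)
        write_pathway(topology, indir / "pathway.tsv", prov)
        config.pathway = str(indir / "pathway.tsv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns (and writes) the report."""
    config = replace(config)  # simulation fills in paths on a private copy
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": config.content_hash(), "seed": config.seed,
            "version": __version__}
    report: dict = {"provenance": dict(prov)}

    if config.simulate is not None:
        with _stage("simulate"):
            _simulate_inputs(config, outdir, prov)

    with _stage("read-inputs"):
        genes = read_de_table(config.genes_de)
        mirna = read_de_table(config.mirna_de)
        lncrna = read_de_table(config.lncrna_de)
        mirna_int = read_edge_table(config.mirna_interactions)
        lncrna_int = read_edge_table(config.lncrna_interactions)

    with _stage("de-selection"):
        de_genes = select_de(genes, config.fc_linear_min, config.q_max)
        de_mirna = select_de(mirna, config.fc_linear_min, config.q_max)
        de_lncrna = select_de(lncrna, config.fc_linear_min, config.q_max)
        report["de"] = {
            "thresholds": {"fc_linear_min": config.fc_linear_min, "q_max": config.q_max},
            "n_de_genes": len(de_genes),
            "n_de_mirna": len(de_mirna),
            "n_de_lncrna": len(de_lncrna),
        }

    with _stage("network"):
        net_m = build_network(de_mirna, de_genes, mirna_int)
        net_l = build_network(de_lncrna, de_genes, lncrna_int)
        net = merge_networks(net_m, net_l)
        write_network(net, outdir / "network.tsv", prov)
        export_sif(net, outdir / "network.sif")
        export_graphml(net, outdir / "network.graphml", [de_genes, de_mirna, de_lncrna])
        report["network"] = {
            "n_edges_mirna": net_m.n_edges,
            "n_edges_lncrna": net_l.n_edges,
            "n_edges_merged": net.n_edges,
            "n_targets_merged": len(net.targets()),
        }

    with _stage("ranking"):
        ranking = regulator_degrees(net)
        _write_tsv(ranking.table, outdir / "ranking.tsv", prov)
        top_m = top_k(ranking, config.k, "miRNA", config.tie_rule) \
            if (ranking.table["regulator_class"] == "miRNA").any() else []
        top_l = top_k(ranking, config.k, "lncRNA", config.tie_rule) \
            if (ranking.table["regulator_class"] == "lncRNA").any() else []
        report["ranking"] = {"k": config.k, "tie_rule": config.tie_rule,
                             "top_mirnas": top_m, "top_lncrnas": top_l}

    with _stage("partition"):
        stats = partition_stats(net, top_m, top_l, n_de_genes=len(de_genes))
        report["partition"] = stats.as_dict(display=config.display)
        write_json_report(report["partition"], outdir / "partition.json")

    if config.gmt:
        with _stage("enrichment"):
            collection = read_gmt(config.gmt)
            if config.background:
                background = [
                    line.strip() for line in Path(config.background).read_text().splitlines()
                    if line.strip() and not line.startswith("#")
                ]
            else:
                background = genes["feature_id"].tolist()
            enr = ora(net.targets(), collection, background)
            _write_tsv(enr, outdir / "enrichment.tsv", prov)
            report["enrichment"] = enr.head(10).to_dict(orient="records")

    if config.pathway:
        with _stage("impact"):
            topology = read_pathway(config.pathway)
            result = impact_analysis(
                topology, de_genes, genes["feature_id"].tolist(),
                n_boot=config.n_boot, seed=config.seed)
            report["impact"] = result.as_dict()
            write_json_report(report["impact"], outdir / "impact.json")
        with _stage("overlay"):
            overlay = regulator_overlay(net, topology.nodes)
            _write_tsv(overlay.table, outdir / "overlay.tsv", prov)
            report["overlay"] = {
                "most_regulated": overlay.most_regulated,
                "genes": overlay.table.to_dict(orient="records"),
            }

    with _stage("report"):
        write_json_report(report, outdir / "report.json")
    return report


def configure_logging(json_logs: bool = False, level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    if json_logs:
        class _JsonFormatter(logging.Formatter):
            def format(self, record):
                return json.dumps({
                    "level": record.levelname,
                    "name": record.name,
                    "message": record.getMessage(),
                })
        handler.setFormatter(_JsonFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
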