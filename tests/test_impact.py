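import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ncregnet.errors import ParameterError, SingularTopologyError, ValidationError
from ncregnet.impact import (
    PathwayTopology,
    impact_analysis,
    perturbation_factors,
    regulator_overlay,
)

from conftest import make_de_table, make_network


def topology(edges, nodes=None):
    frame = pd.DataFrame(
        [{"source": s, "target": t, "weight": w, "relation": ""} for s, t, w in edges],
        columns=["source", "target", "weight", "relation"])
    if nodes is None:
        nodes = list(dict.fromkeys([e[0] for e in edges] + [e[1] for e in edges]))
    return PathwayTopology(nodes=tuple(nodes), edges=frame)


def propagate_topological(top, delta_e):
    """Oracle: iterate PF in topological order (acyclic graphs only)."""
    import networkx as nx
    g = top.to_graph()
    n_ds = top.n_downstream
    pf = {}
    for node in nx.topological_sort(g):
        incoming = sum(
            g.edges[u, node]["weight"] / n_ds[u] * pf[u] for u in g.predecessors(node)
        )
        pf[node] = delta_e.get(node, 0.0) + incoming
    return pf


class TestPerturbationFactors:
    def test_edgeless_topology(self):
        top = topology([], nodes=["A", "B", "C"])
        out = perturbation_factors(top, {"A": 2.0}).set_index("gene")
        assert out.loc["A", "pf"] == 2.0
        assert (out["acc"] == 0).all()

    def test_chain_closed_form(self):
        top = topology([("A", "B", 1)])
        out = perturbation_factors(top, {"A": 1.0, "B": 1.0}).set_index("gene")
        assert out.loc["A", "pf"] == pytest.approx(1.0)
        assert out.loc["B", "pf"] == pytest.approx(2.0)
        assert out["acc"].sum() == pytest.approx(1.0)

    def test_fan_closed_form(self):
        top = topology([("A", "B", 1), ("A", "C", 1)])
        out = perturbation_factors(top, {"A": 1.0}).set_index("gene")
        assert out.loc["B", "pf"] == pytest.approx(0.5)
        assert out.loc["C", "pf"] == pytest.approx(0.5)
        assert out["acc"].sum() == pytest.approx(1.0)

    def test_inhibition_flips_sign(self):
        top = topology([("A", "B", -1)])
        out = perturbation_factors(top, {"A": 1.0}).set_index("gene")
        assert out.loc["B", "pf"] == pytest.approx(-1.0)

    def test_singular_feedback_loop_names_cycle(self):
        top = topology([("X", "Y", 1), ("Y", "X", 1)])
        with pytest.raises(SingularTopologyError, match="cycle"):
            perturbation_factors(top, {"X": 1.0})

    def test_sign_symmetry(self):
        rng = np.random.default_rng(7)
        top = _random_dag(rng, 8, 0.4)
        delta = {node: float(rng.normal()) for node in top.nodes}
        plus = perturbation_factors(top, delta)
        minus = perturbation_factors(top, {k: -v for k, v in delta.items()})
        np.testing.assert_allclose(minus["pf"], -plus["pf"], atol=1e-12)
        assert minus["acc"].sum() == pytest.approx(-plus["acc"].sum(), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_linear_solve_matches_topological_propagation(self, seed):
        rng = np.random.default_rng(seed)
        top = _random_dag(rng, 10, 0.35)
        delta = {node: float(rng.normal()) for node in top.nodes
                 if rng.random() < 0.5}
        solved = perturbation_factors(top, delta).set_index("gene")["pf"]
        oracle = propagate_topological(top, delta)
        for node in top.nodes:
            assert solved[node] == pytest.approx(oracle[node], abs=1e-10)


def _random_dag(rng, n_nodes, edge_prob):
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = []
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((nodes[a], nodes[b], int(rng.choice([1, -1]))))
    return topology(edges, nodes=nodes)


class TestPathwayTopology:
    def test_weight_validation(self):
        with pytest.raises(ValidationError, match="weight"):
            topology([("A", "B", 2)])

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValidationError, match="unique"):
            PathwayTopology(nodes=("A", "A"), edges=pd.DataFrame(
                columns=["source", "target", "weight", "relation"]))

    def test_n_downstream_is_out_degree(self):
        top = topology([("A", "B", 1), ("A", "C", 1), ("B", "C", -1)])
        assert top.n_downstream == {"A": 2, "B": 1, "C": 0}


class TestImpactAnalysis:
    @staticmethod
    def toy():
        return topology([("A", "B", 1), ("A", "C", 1), ("B", "D", -1)])

    def test_degenerate_no_de_genes(self):
        de = make_de_table(["Z1"], "gene", log2fc=2.0)
        with pytest.warns(UserWarning, match="degenerate"):
            result = impact_analysis(self.toy(), de, ["A", "B", "C", "D", "Z1"],
                                     n_boot=100, seed=0)
        assert result.ta == 0.0
        assert result.p_nde == 1.0
        assert result.p_pert == 1.0
        assert result.degenerate

    def test_pg_formula(self):
        c = 0.01 * 0.02
        assert c - c * math.log(c) == pytest.approx(1.903e-3, rel=1e-3)

    def test_seed_reproducibility(self):
        de = make_de_table(["A", "B"], "gene", log2fc=[1.5, -2.0])
        measured = ["A", "B", "C", "D"] + [f"X{i}" for i in range(20)]
        r1 = impact_analysis(self.toy(), de, measured, n_boot=1000, seed=42)
        r2 = impact_analysis(self.toy(), de, measured, n_boot=1000, seed=42)
        assert r1.p_pert == r2.p_pert
        assert r1.ta == r2.ta

    def test_ppert_within_mc_interval_of_high_replicate_oracle(self):
        de = make_de_table(["A", "B"], "gene", log2fc=[1.5, -2.0])
        measured = ["A", "B", "C", "D"] + [f"X{i}" for i in range(20)]
        small = impact_analysis(self.toy(), de, measured, n_boot=1000, seed=1)
        big = impact_analysis(self.toy(), de, measured, n_boot=20000, seed=999)
        # 99% binomial CI around the high-replicate estimate at n=1000
        half = 2.576 * math.sqrt(big.p_pert * (1 - big.p_pert) / 1000)
        assert abs(small.p_pert - big.p_pert) <= half + 2 / 1000

    def test_pnde_is_hypergeometric_tail(self):
        from ncregnet.enrichment import hypergeom_tail
        de = make_de_table(["A", "B", "Z1"], "gene", log2fc=1.5)
        measured = ["A", "B", "C", "D", "Z1"] + [f"X{i}" for i in range(15)]
        result = impact_analysis(self.toy(), de, measured, n_boot=100, seed=0)
        assert result.p_nde == pytest.approx(hypergeom_tail(2, 3, 4, 20))

    def test_n_boot_floor(self):
        de = make_de_table(["A"], "gene")
        with pytest.raises(ParameterError):
            impact_analysis(self.toy(), de, ["A"], n_boot=50, seed=0)

    def test_ppert_uniform_under_null(self):
        # draw dE from the bootstrap distribution itself -> pPERT ~ Uniform
        top = _random_dag(np.random.default_rng(3), 6, 0.5)
        rng = np.random.default_rng(12345)
        pperts = []
        for trial in range(200):
            nodes = list(top.nodes)
            picks = rng.choice(len(nodes), size=2, replace=False)
            values = rng.normal(2.0, 0.5, size=2) * rng.choice([-1, 1], size=2)
            de = make_de_table([nodes[i] for i in picks], "gene",
                               log2fc=list(values))
            result = impact_analysis(top, de, nodes, n_boot=199, seed=trial)
            pperts.append(result.p_pert)
        ks = sps.kstest(pperts, "uniform")
        assert ks.pvalue > 1e-3


class TestRegulatorOverlay:
    def test_gene_without_edges_counts_zero(self):
        net = make_network([("miR-a", "miRNA", "G1")])
        result = regulator_overlay(net, ["G1", "G2"])
        row = result.table.set_index("gene").loc["G2"]
        assert (row["n_mirna"], row["n_lncrna"]) == (0, 0)

    def test_zeb1_fixture_counts(self):
        mirnas = ["miR-335-3p", "miR-493-5p", "miR-543", "miR-548h-5p"]
        lncrnas = ["H19", "LINC00313", "LINC00152", "TPTEP1",
                   "LINC00086/SMIM10L2A", "DGCR5"]
        net = make_network(
            [(m, "miRNA", "ZEB1") for m in mirnas]
            + [(l, "lncRNA", "ZEB1") for l in lncrnas]
            + [("miR-335-3p", "miRNA", "EGFR")])
        result = regulator_overlay(net, ["ZEB1", "EGFR", "PDGFRA"])
        row = result.table.set_index("gene").loc["ZEB1"]
        assert (row["n_mirna"], row["n_lncrna"]) == (4, 6)
        assert result.most_regulated == ["ZEB1"]

    def test_nfatc1_fixture_counts(self):
        net = make_network([
            ("TPTEP1", "lncRNA", "NFATC1"),
            ("SERHL", "lncRNA", "NFATC1"),
            ("miR-218-5p", "miRNA", "NFATC1"),
            ("miR-493-5p", "miRNA", "NFATC1"),
        ])
        result = regulator_overlay(net, ["NFATC1", "CDKN2A"])
        row = result.table.set_index("gene").loc["NFATC1"]
        assert row["n_total"] == 4

    def test_no_regulated_gene_means_no_most_regulated(self):
        net = make_network([("miR-a", "miRNA", "G1")])
        result = regulator_overlay(net, ["G2"])
        assert result.most_regulated == []
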