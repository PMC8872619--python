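import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncregnet.centrality import (
    partition_stats,
    partition_stats_from_counts,
    regulator_degrees,
    regulator_similarity,
    top_k,
)
from ncregnet.errors import ConsistencyError, ParameterError

from conftest import make_network


class TestRegulatorDegrees:
    def test_star_degree(self, star_network):
        ranking = regulator_degrees(star_network)
        assert ranking.table.loc[0, "degree"] == 5
        assert ranking.table.loc[0, "rank"] == 1

    def test_hub_and_minor_labels(self):
        net = make_network(
            [("H19", "lncRNA", f"G{i}") for i in range(120)]
            + [("SNHG5", "lncRNA", "G0")])
        table = regulator_degrees(net).table.set_index("regulator_id")
        assert table.loc["H19", "label"] == "hub"      # > 100 targets
        assert table.loc["SNHG5", "label"] == "minor"  # < 20 targets

    def test_degrees_match_group_count_oracle(self):
        rng = np.random.default_rng(4)
        edges = sorted({
            (f"miR-{rng.integers(8)}", "miRNA", f"G{rng.integers(40)}")
            for _ in range(150)
        })
        net = make_network(edges)
        expected = {}
        for reg, _, tgt in edges:
            expected.setdefault(reg, set()).add(tgt)
        table = regulator_degrees(net).table.set_index("regulator_id")
        for reg, targets in expected.items():
            assert table.loc[reg, "degree"] == len(targets)

    def test_zero_degree_regulators_reported(self):
        net = make_network([("miR-a", "miRNA", "G1")])
        net.regulators.loc[0] = ["miR-silent", "miRNA"]
        table = regulator_degrees(net).table.set_index("regulator_id")
        assert table.loc["miR-silent", "degree"] == 0

    def test_ranks_contiguous_and_degrees_non_increasing(self):
        net = make_network([
            ("miR-a", "miRNA", "G1"), ("miR-a", "miRNA", "G2"),
            ("miR-b", "miRNA", "G1"), ("H19", "lncRNA", "G1"),
        ])
        table = regulator_degrees(net).table
        assert list(table["rank"]) == list(range(1, len(table) + 1))
        assert (table["degree"].diff().dropna() <= 0).all()


class TestTopK:
    def test_k_at_least_population_returns_all(self, star_network):
        ranking = regulator_degrees(star_network)
        with pytest.warns(UserWarning, match="exceeds population"):
            assert top_k(ranking, 10) == ["miR-a"]

    def test_tie_break_lexicographic(self):
        net = make_network([
            (r, "miRNA", f"G{i}") for r in ("miR-c", "miR-a", "miR-b")
            for i in range(3)
        ])
        assert top_k(regulator_degrees(net), 2) == ["miR-a", "miR-b"]

    def test_keep_all_ties_matches_full_sort_oracle(self):
        rng = np.random.default_rng(9)
        degrees = {f"miR-{i:02d}": int(rng.integers(1, 6)) for i in range(30)}
        net = make_network([
            (reg, "miRNA", f"G{reg}-{j}")
            for reg, d in degrees.items() for j in range(d)
        ])
        k = 10
        got = top_k(regulator_degrees(net), k, tie_rule="keep-all-ties")
        cutoff = sorted(degrees.values(), reverse=True)[k - 1]
        expected = {r for r, d in degrees.items() if d >= cutoff}
        assert set(got) == expected
        assert len(got) == len(expected)

    def test_invalid_parameters(self, star_network):
        ranking = regulator_degrees(star_network)
        with pytest.raises(ParameterError):
            top_k(ranking, 0)
        with pytest.raises(ParameterError):
            top_k(ranking, 1, tie_rule="random")


class TestPartitionStats:
    def test_published_counts_reproduced(self):
        stats = partition_stats_from_counts(567, 478, 217, 1361)
        assert stats.network_targets == 828
        assert stats.pct_network_of_de == 60.8
        assert stats.pct_m_of_network == 68.5
        assert stats.pct_m_of_de == 41.7
        assert stats.pct_l_of_network == 57.7
        assert stats.pct_l_of_de == 35.1
        assert stats.pct_shared_of_de == 15.9
        assert stats.as_dict("integer")["pct_shared_of_network"] == 26

    def test_disjoint_sets(self):
        stats = partition_stats_from_counts(10, 5, 0, 100)
        assert stats.shared == 0
        assert stats.network_targets == 15

    def test_identical_sets(self):
        stats = partition_stats_from_counts(10, 10, 10, 100)
        assert stats.pct_shared_of_network == 100.0

    def test_consistency_errors(self):
        with pytest.raises(ConsistencyError):
            partition_stats_from_counts(10, 5, 6, 100)  # shared > min
        with pytest.raises(ConsistencyError):
            partition_stats_from_counts(60, 60, 0, 100)  # union > universe

    def test_from_network_counts_distinct_targets(self):
        net = make_network([
            ("miR-a", "miRNA", "G1"), ("miR-a", "miRNA", "G2"),
            ("miR-b", "miRNA", "G2"), ("H19", "lncRNA", "G2"),
            ("H19", "lncRNA", "G3"), ("DGCR5", "lncRNA", "G9"),
        ])
        stats = partition_stats(net, ["miR-a", "miR-b"], ["H19"], n_de_genes=10)
        assert (stats.m_targets, stats.l_targets, stats.shared) == (2, 2, 1)
        assert stats.network_targets == 3

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_inclusion_exclusion_always_holds(self, m, l, s):
        shared = min(s, m, l)
        stats = partition_stats_from_counts(m, l, shared, m + l + 10)
        assert stats.network_targets == m + l - shared
        for name in stats._PCT_FIELDS:
            assert 0.0 <= getattr(stats, name) <= 100.0


class TestPlantedHubRecovery:
    def test_recall_is_one_over_twenty_seeds(self):
        # planted hubs >= 3x the background mean degree must always be the top-k
        from ncregnet.synth import SynthParams, simulate_de_tables, simulate_interactions
        from ncregnet.de import select_de
        from ncregnet.network import build_network

        hubs = tuple((f"miR-hub-{i}", 60 + 5 * i) for i in range(3))
        for seed in range(20):
            params = SynthParams(
                n_genes=600, n_mirna=20, n_lncrna=5, de_fraction=0.4,
                effect_mean=3.0, effect_sd=0.3,
                degree_exponent=3.0, planted_hubs=hubs, seed=seed)
            genes, mirna, _ = simulate_de_tables(params)
            de_genes = select_de(genes)
            mirna_int, _ = simulate_interactions(params, de_genes["feature_id"])
            net = build_network(select_de(mirna), de_genes, mirna_int)
            got = top_k(regulator_degrees(net), len(hubs), "miRNA")
            assert set(got) == {rid for rid, _ in hubs}, f"seed {seed}"


class TestRegulatorSimilarity:
    def test_identical_and_disjoint(self):
        net = make_network([
            ("miR-a", "miRNA", "G1"), ("miR-a", "miRNA", "G2"),
            ("miR-b", "miRNA", "G1"), ("miR-b", "miRNA", "G2"),
            ("miR-c", "miRNA", "G8"),
        ])
        sim = regulator_similarity(net)
        assert sim.loc["miR-a", "miR-b"] == 1.0
        assert sim.loc["miR-a", "miR-c"] == 0.0

    def test_enumerated_jaccard(self):
        net = make_network([
            ("miR-a", "miRNA", g) for g in ("g1", "g2", "g3")
        ] + [("miR-b", "miRNA", g) for g in ("g2", "g3", "g4")])
        sim = regulator_similarity(net)
        assert sim.loc["miR-a", "miR-b"] == pytest.approx(0.5)  # 2/4

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(2)
        edges = sorted({
            (f"miR-{rng.integers(6)}", "miRNA", f"G{rng.integers(15)}")
            for _ in range(40)
        })
        sim = regulator_similarity(make_network(edges))
        assert np.allclose(sim.values, sim.values.T)
        assert np.allclose(np.diag(sim.values), 1.0)
        assert ((sim.values >= 0) & (sim.values <= 1)).all()

    def test_zero_target_regulator_flagged(self):
        net = make_network([("miR-a", "miRNA", "G1")])
        net.regulators.loc[0] = ["miR-silent", "miRNA"]
        with pytest.warns(UserWarning, match="zero-target"):
            sim = regulator_similarity(net)
        assert sim.loc["miR-silent", "miR-a"] == 0.0
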