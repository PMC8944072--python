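"""Inter-module edges, permutation significance, interactors, edge-type test."""

import itertools
import math

import numpy as np
import pytest

from netmod import (
    EdgeTally,
    Network,
    NullModelConfig,
    count_inter_module_edges,
    edge_type_composition_test,
    find_interactors,
    gene_set_connectivity,
    inter_module_significance,
    union_component,
)
from netmod.connectivity import write_connectivity_report, write_interactor_table

from conftest import random_typed_network


class TestCountInterModuleEdges:
    def test_t1_toy_single_functional_bridge(self, t1_toy):
        tally = count_inter_module_edges(t1_toy, {"A", "B"}, {"C", "D"})
        assert tally.total == 1 and tally.functional == 1

    def test_disjoint_components_zero(self, path_plus_pair):
        tally = count_inter_module_edges(path_plus_pair, {"A", "B"}, {"F", "G"})
        assert tally.total == 0

    def test_matches_exhaustive_edge_scan(self):
        net = random_typed_network(100, 0.05, seed=17)
        rng = np.random.default_rng(17)
        nodes = sorted(net.nodes)
        A = set(rng.choice(nodes, size=15, replace=False))
        B = set(rng.choice(nodes, size=20, replace=False))
        tally = count_inter_module_edges(net, A, B)
        Ax, Bx = A - B, B - A
        oracle = {"physical": 0, "functional": 0, "both": 0}
        for u, v, t in net.graph.edges(data="etype"):
            if (u in Ax and v in Bx) or (v in Ax and u in Bx):
                oracle[t] += 1
        assert (tally.physical, tally.functional, tally.both) == (
            oracle["physical"],
            oracle["functional"],
            oracle["both"],
        )

    def test_symmetry(self):
        net = random_typed_network(80, 0.06, seed=23)
        rng = np.random.default_rng(23)
        nodes = sorted(net.nodes)
        A = set(rng.choice(nodes, size=10, replace=False))
        B = set(rng.choice(nodes, size=12, replace=False))
        assert count_inter_module_edges(net, A, B) == count_inter_module_edges(
            net, B, A
        )

    def test_shared_policy_error_names_genes(self, t1_toy):
        with pytest.raises(ValueError, match="B"):
            count_inter_module_edges(
                t1_toy, {"A", "B"}, {"B", "C"}, shared_policy="error"
            )

    def test_tally_invariant(self):
        t = EdgeTally(physical=2, functional=5, both=1)
        assert t.total == 8
        assert t.count("functional", pool_both=True) == 6


class TestInterModuleSignificance:
    def test_add_one_p_at_99_samples(self, t1_toy):
        # planted-adjacent pair in a tiny graph: observed must top all draws
        net = Network()
        # two triangles bridged by many edges in a sparse sea
        for u, v in [("A1", "A2"), ("A2", "A3"), ("A1", "A3"),
                     ("B1", "B2"), ("B2", "B3"), ("B1", "B3")]:
            net.add_typed_edge(u, v, "physical")
        for a in ("A1", "A2", "A3"):
            for b in ("B1", "B2", "B3"):
                net.add_typed_edge(a, b, "functional")
        for i in range(40):  # sparse background
            net.add_typed_edge(f"C{i}", f"D{i}", "functional")
        res = inter_module_significance(
            net,
            {"A1", "A2", "A3"},
            {"B1", "B2", "B3"},
            null=NullModelConfig(method="uniform", n_samples=99, seed=5),
        )
        assert res.observed.total == 9
        assert res.empirical_p == pytest.approx(0.01)

    def test_calibration_under_exchangeable_null(self):
        """Observed pair drawn from the same sampler as the null: p ~ uniform."""
        from netmod.nulls import bins_for, sample_matched_set

        net = random_typed_network(300, 0.02, seed=31)
        cfg = NullModelConfig(n_samples=199, min_bin_size=50, seed=0)
        bins = bins_for(net, cfg)
        rng = np.random.default_rng(99)
        nodes = sorted(net.nodes)
        target_a = set(rng.choice(nodes, size=20, replace=False))
        target_b = set(rng.choice(sorted(set(nodes) - target_a), size=15, replace=False))
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            A = sample_matched_set(bins, target_a, rng)
            B = sample_matched_set(bins, target_b, rng)
            B -= A
            if len(B) < 5:
                continue
            res = inter_module_significance(net, A, B, null=cfg, rng=rng)
            hits += res.empirical_p <= 0.05
        sigma = math.sqrt(n_rep * 0.05 * 0.95)
        assert hits <= n_rep * 0.05 + 3 * sigma

    def test_shared_genes_excluded_before_test(self, t1_toy):
        with pytest.raises(ValueError):
            # exclusion empties one side
            inter_module_significance(
                t1_toy, {"B"}, {"B"}, null=NullModelConfig(n_samples=100, seed=1)
            )


class TestFindInteractors:
    def test_t1_toy_bridge_genes(self, t1_toy):
        table = find_interactors(t1_toy, {"m1": {"A", "B"}, "m2": {"C", "D"}})
        got = set(zip(table.data["gene"], table.data["home_module"]))
        assert got == {("B", "m1"), ("C", "m2")}

    def test_no_cross_edges_empty_table(self, path_plus_pair):
        table = find_interactors(
            path_plus_pair, {"m1": {"A", "B"}, "m2": {"F", "G"}}
        )
        assert len(table.data) == 0

    def test_matches_neighborhood_oracle_three_modules(self):
        net = random_typed_network(90, 0.05, seed=41)
        rng = np.random.default_rng(41)
        nodes = sorted(net.nodes)
        picks = rng.choice(nodes, size=30, replace=False)
        modules = {
            "m1": set(picks[:10]),
            "m2": set(picks[10:20]),
            "m3": set(picks[20:]),
        }
        table = find_interactors(net, modules)
        rows = set(
            zip(table.data["gene"], table.data["home_module"], table.data["target_module"])
        )
        oracle = set()
        for home, hg in modules.items():
            for target, tg in modules.items():
                if home == target:
                    continue
                h, t = hg - tg, tg - hg
                for g in h:
                    if any(v in t for v in net.graph.adj[g]):
                        oracle.add((g, home, target))
        assert rows == oracle

    def test_cross_edge_sums_match_tally(self):
        net = random_typed_network(90, 0.05, seed=43)
        rng = np.random.default_rng(43)
        nodes = sorted(net.nodes)
        A = set(rng.choice(nodes, size=12, replace=False))
        B = set(rng.choice(sorted(set(nodes) - A), size=12, replace=False))
        table = find_interactors(net, {"a": A, "b": B})
        tally = count_inter_module_edges(net, A, B)
        a_to_b = table.data[
            (table.data.home_module == "a") & (table.data.target_module == "b")
        ]["n_cross_edges"].sum()
        assert a_to_b == tally.total

    def test_multi_target_flag(self):
        net = Network()
        net.add_typed_edge("H", "X1", "physical")
        net.add_typed_edge("H", "X2", "physical")
        net.add_typed_edge("H", "H2", "physical")
        table = find_interactors(
            net, {"m1": {"H", "H2"}, "m2": {"X1"}, "m3": {"X2"}}
        )
        h_rows = table.data[table.data.gene == "H"]
        assert h_rows["multi_target"].all() and len(h_rows) == 2

    def test_writer_lists_non_interactors_as_no_module(self, tmp_path, t1_toy):
        modules = {"m1": {"A", "B"}, "m2": {"C", "D"}}
        table = find_interactors(t1_toy, modules)
        write_interactor_table(table, modules, tmp_path / "i.tsv")
        lines = (tmp_path / "i.tsv").read_text().splitlines()[1:]
        rows = [tuple(l.split("\t")) for l in lines]
        assert ("A", "m1", "No module") in rows
        assert ("B", "m1", "m2") in rows


class TestEdgeTypeCompositionTest:
    def test_exact_small_population(self):
        """10 edges, 4 functional; draw 3, see >= 2 functional: P = 40/120."""
        net = Network()
        for i in range(4):
            net.add_typed_edge(f"F{i}", f"G{i}", "functional")
        for i in range(6):
            net.add_typed_edge(f"P{i}", f"Q{i}", "physical")
        observed = EdgeTally(physical=1, functional=2, both=0)
        res = edge_type_composition_test(observed, net)
        # oracle: complete enumeration of all C(10,3) draws
        k_count = sum(
            1
            for combo in itertools.combinations(range(10), 3)
            if sum(1 for e in combo if e < 4) >= 2
        )
        assert res["p_value"] == pytest.approx(k_count / 120)
        assert res["p_value"] == pytest.approx(1 / 3)

    def test_zero_of_type_gives_one(self, t1_toy):
        res = edge_type_composition_test(
            EdgeTally(physical=2, functional=0, both=0), t1_toy
        )
        assert res["p_value"] == 1.0

    def test_drawing_all_edges_gives_one(self, t1_toy):
        counts = t1_toy.edge_type_counts()
        res = edge_type_composition_test(EdgeTally(**counts), t1_toy)
        assert res["p_value"] == pytest.approx(1.0)

    def test_pool_both_changes_population(self, t1_toy):
        obs = EdgeTally(physical=0, functional=1, both=1)
        strict = edge_type_composition_test(obs, t1_toy, pool_both=False)
        pooled = edge_type_composition_test(obs, t1_toy, pool_both=True)
        assert strict["K"] == 2 and pooled["K"] == 3
        assert strict["pool_both"] is False and pooled["pool_both"] is True

    def test_observed_exceeding_population_rejected(self, t1_toy):
        with pytest.raises(ValueError):
            edge_type_composition_test(
                EdgeTally(physical=0, functional=99, both=0), t1_toy
            )


class TestGeneSetConnectivity:
    def test_triangle_is_positively_connected(self):
        net = random_typed_network(60, 0.02, seed=51)
        net.add_typed_edge("T1", "T2", "physical")
        net.add_typed_edge("T2", "T3", "physical")
        net.add_typed_edge("T1", "T3", "physical")
        res = gene_set_connectivity(
            net,
            {"T1", "T2", "T3"},
            null=NullModelConfig(method="uniform", n_samples=500, seed=1),
        )
        assert res.observed_value == 3
        assert res.z_score is not None and res.z_score > 0

    def test_observed_matches_pair_scan_oracle(self):
        net = random_typed_network(100, 0.06, seed=53)
        rng = np.random.default_rng(53)
        genes = set(rng.choice(sorted(net.nodes), size=18, replace=False))
        res = gene_set_connectivity(
            net, genes, null=NullModelConfig(n_samples=100, min_bin_size=30, seed=2)
        )
        oracle = sum(
            1
            for u, v in itertools.combinations(sorted(genes), 2)
            if net.graph.has_edge(u, v)
        )
        assert res.observed_value == oracle

    def test_lcc_statistic_variant(self, path_plus_pair):
        res = gene_set_connectivity(
            path_plus_pair,
            {"A", "B", "C"},
            null=NullModelConfig(method="uniform", n_samples=200, seed=3),
            statistic="lcc_size",
        )
        assert res.observed_value == 3

    def test_requires_two_mapped_genes(self, t1_toy):
        with pytest.raises(ValueError):
            gene_set_connectivity(t1_toy, {"A", "Z9"})

    def test_report_writer(self, tmp_path, path_plus_pair):
        res = gene_set_connectivity(
            path_plus_pair,
            {"A", "B", "C"},
            null=NullModelConfig(method="uniform", n_samples=100, seed=1),
        )
        write_connectivity_report(res, tmp_path / "c.tsv")
        header, row = (tmp_path / "c.tsv").read_text().splitlines()
        assert "empirical_p" in header and row


class TestUnionComponent:
    def test_bridged_modules_span_one_component(self, t1_toy):
        view, ann = union_component(t1_toy, {"m1": {"A", "B"}, "m2": {"C", "D"}})
        assert view.member_nodes == frozenset({"A", "B", "C", "D"})
        assert ann["A"] == ["m1"] and ann["D"] == ["m2"]

    def test_separated_modules_keep_larger(self, path_plus_pair):
        view, _ = union_component(
            path_plus_pair, {"m1": {"A", "B", "C"}, "m2": {"F", "G"}}
        )
        assert view.member_nodes == frozenset({"A", "B", "C"})

    def test_shared_gene_carries_all_labels(self, t1_toy):
        _, ann = union_component(t1_toy, {"m1": {"A", "B"}, "m2": {"B", "C"}})
        assert ann["B"] == ["m1", "m2"]

    def test_equals_induced_lcc_of_union(self):
        from netmod import induced_lcc

        net = random_typed_network(90, 0.04, seed=61)
        rng = np.random.default_rng(61)
        nodes = sorted(net.nodes)
        modules = {
            f"m{i}": set(rng.choice(nodes, size=10, replace=False)) for i in range(3)
        }
        view, _ = union_component(net, modules)
        union = set().union(*modules.values())
        assert view.member_nodes == induced_lcc(net, union).member_nodes
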