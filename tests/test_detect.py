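"""Threshold grid, sweep, and module selection."""

import itertools
import math

import numpy as np
import pytest

from netmod import (
    GeneScoreTable,
    Module,
    Network,
    NoModuleReport,
    NullModelConfig,
    SelectionRule,
    SweepResult,
    SweepRow,
    detect_module,
    make_threshold_grid,
    run_sweep,
    select_module,
)
from netmod.detect import EmptyGridError, write_module, write_sweep_trace

from conftest import random_typed_network


def table_of(ps: dict[str, float], name: str = "t") -> GeneScoreTable:
    return GeneScoreTable.from_records(ps, name)


class TestThresholdGrid:
    def test_cutoffs_admit_cumulative_counts(self):
        t = table_of({"G1": 0.001, "G2": 0.001, "G3": 0.03, "G4": 0.2})
        grid = make_threshold_grid(t, max_threshold=0.05)
        counts = [sum(p < c for p in [0.001, 0.001, 0.03, 0.2]) for c in grid]
        assert counts == [2, 3]

    def test_max_points_one_keeps_largest_cutoff(self):
        t = table_of({"G1": 0.001, "G2": 0.01, "G3": 0.04})
        grid = make_threshold_grid(t, max_threshold=0.05, max_points=1)
        assert len(grid) == 1
        assert sum(p < grid[0] for p in [0.001, 0.01, 0.04]) == 3

    def test_every_grid_member_admissible_and_spacing_sane(self):
        rng = np.random.default_rng(0)
        ps = {f"G{i}": float(p) for i, p in enumerate(rng.random(2000))}
        t = table_of(ps)
        grid = make_threshold_grid(t, max_threshold=1.0, max_points=200)
        assert len(grid) <= 200
        values = np.array(sorted(ps.values()))
        for c in grid:
            # strict cutoff admits at least its own gene
            assert (values < c).sum() >= 1
        # thinning is rank-even: admitted counts step by at most 2x the
        # even quantile stride
        counts = np.array([(values < c).sum() for c in grid])
        stride = len(values) / 200
        assert np.all(np.diff(counts) <= 2 * stride + 1)

    def test_no_admissible_pvalues_raises(self):
        with pytest.raises(EmptyGridError):
            make_threshold_grid(table_of({"G1": 0.5}), max_threshold=0.05)

    def test_strictly_increasing(self):
        rng = np.random.default_rng(1)
        t = table_of({f"G{i}": float(p) for i, p in enumerate(rng.random(100))})
        grid = make_threshold_grid(t, max_threshold=1.0)
        assert np.all(np.diff(grid) > 0)


class TestRunSweep:
    def test_star_graph_exact_null_moments(self, star5):
        """Size-2 subsets of the 5-star: 4/10 contain the hub (LCC 2), so
        the exact uniform null has mean 1.4 and sd sqrt(0.24) = 0.4899."""
        table = table_of(
            {"X": 0.01, "Y1": 0.02, "Y2": 0.3, "Y3": 0.4, "Y4": 0.5}
        )
        null = NullModelConfig(method="uniform", n_samples=20000, seed=2)
        sweep = run_sweep(star5, table, np.array([0.05]), null)
        row = sweep.rows[0]
        assert row.n_genes_below == 2 and row.lcc_size == 2
        # 3-standard-error Monte-Carlo bands around the exact values
        se_mean = 0.4899 / math.sqrt(20000)
        assert row.null_mean == pytest.approx(1.4, abs=3 * se_mean)
        assert row.null_sd == pytest.approx(0.4899, abs=3 * 0.4899 / math.sqrt(2 * 20000))
        assert row.z_score == pytest.approx(1.2247, abs=0.05)

    def test_degenerate_null_flags_z_undefined(self, star5):
        table = table_of({g: 0.01 for g in star5.nodes})
        null = NullModelConfig(method="uniform", n_samples=100, seed=0)
        sweep = run_sweep(star5, table, np.array([0.05]), null)
        row = sweep.rows[0]
        assert row.null_sd == 0.0 and row.z_score is None
        assert row.lcc_size == 5

    def test_lcc_sizes_weakly_increasing(self):
        net = random_typed_network(120, 0.04, seed=3)
        rng = np.random.default_rng(3)
        table = table_of(
            {g: float(rng.random()) for g in net.nodes}
        )
        grid = make_threshold_grid(table, max_threshold=1.0, max_points=25)
        null = NullModelConfig(method="uniform", n_samples=100, seed=1)
        sweep = run_sweep(net, table, grid, null)
        sizes = [r.lcc_size for r in sweep.rows]
        assert sizes == sorted(sizes)

    def test_early_stop_past_hard_cap(self):
        net = random_typed_network(120, 0.2, seed=5)  # dense: LCC grows fast
        rng = np.random.default_rng(5)
        table = table_of({g: float(rng.random()) for g in net.nodes})
        rule = SelectionRule(size_min=2, size_max=10, hard_cap=20)
        grid = make_threshold_grid(table, max_threshold=1.0, max_points=40)
        null = NullModelConfig(method="uniform", n_samples=100, seed=1)
        sweep = run_sweep(net, table, grid, null, rule=rule)
        oversized = [r for r in sweep.rows if r.lcc_size > 20]
        assert len(oversized) <= 1  # at most the row that triggered the stop
        assert len(sweep.rows) < len(grid)

    def test_row_order_invariant_to_table_row_shuffle(self, star5):
        ps = {"X": 0.01, "Y1": 0.02, "Y2": 0.3, "Y3": 0.4, "Y4": 0.5}
        null = NullModelConfig(method="uniform", n_samples=500, seed=9)
        rows1 = run_sweep(star5, table_of(ps), np.array([0.05, 0.45]), null).rows
        shuffled = dict(reversed(list(ps.items())))
        rows2 = run_sweep(star5, table_of(shuffled), np.array([0.05, 0.45]), null).rows
        assert [(r.threshold, r.lcc_size, r.lcc_members) for r in rows1] == [
            (r.threshold, r.lcc_size, r.lcc_members) for r in rows2
        ]

    def test_monte_carlo_matches_exhaustive_enumeration_small_graph(self):
        """Uniform-null moments vs complete C(n,k) enumeration, n=10, k=4."""
        net = random_typed_network(10, 0.3, seed=11)
        nodes = sorted(net.nodes)
        import networkx as nx

        sizes = []
        for comb in itertools.combinations(nodes, 4):
            sub = net.graph.subgraph(comb)
            sizes.append(max(len(c) for c in nx.connected_components(sub)))
        exact_mean = float(np.mean(sizes))
        exact_sd = float(np.std(sizes))
        table = table_of({g: (0.01 if g in nodes[:4] else 0.9) for g in nodes})
        null = NullModelConfig(method="uniform", n_samples=20000, seed=21)
        row = run_sweep(net, table, np.array([0.05]), null).rows[0]
        assert row.null_mean == pytest.approx(
            exact_mean, abs=3 * exact_sd / math.sqrt(20000)
        )
        assert row.null_sd == pytest.approx(
            exact_sd, abs=3 * exact_sd / math.sqrt(2 * 20000), rel=0.05
        )


def sweep_from(rows, name="x"):
    return SweepResult(
        rows=[
            SweepRow(
                threshold=t,
                n_genes_below=size + 5,
                lcc_size=size,
                null_mean=0.0,
                null_sd=1.0,
                z_score=z,
                lcc_members=frozenset(f"G{i}" for i in range(size)),
            )
            for t, z, size in rows
        ],
        dataset_name=name,
        null_config=NullModelConfig(n_samples=100),
    )


class TestSelectModule:
    def test_published_rule_example(self):
        sweep = sweep_from([(0.001, 1.5, 40), (0.010, 2.0, 55), (0.020, 2.6, 150)])
        module = select_module(sweep)
        assert isinstance(module, Module)
        assert module.threshold == 0.010  # first fails z, third fails size

    def test_all_rows_below_z_min_yield_report(self):
        sweep = sweep_from([(0.01, 1.2, 40), (0.02, 1.6, 50)])  # 1.6 not > 1.6
        report = select_module(sweep)
        assert isinstance(report, NoModuleReport)
        assert report.nearest_miss

    def test_tie_break_prefers_smallest_threshold(self):
        sweep = sweep_from([(0.01, 2.0, 40), (0.03, 2.0, 60)])
        module = select_module(sweep)
        assert module.threshold == 0.01

    def test_undefined_z_rows_ineligible(self):
        sweep = sweep_from([(0.01, 2.5, 50)])
        sweep.rows[0].z_score = None
        assert isinstance(select_module(sweep), NoModuleReport)

    def test_exhaustive_conformance_small_grid(self):
        """Brute-force oracle over all sweeps built from a small z/size grid."""
        rule = SelectionRule()
        zs = [1.0, 1.6, 1.7, 2.5]
        sizes = [10, 30, 100, 150]
        combos = list(itertools.product(zs, sizes))
        for picks in itertools.permutations(range(len(combos)), 3):
            rows = [
                (0.01 * (i + 1), combos[p][0], combos[p][1])
                for i, p in enumerate(picks)
            ]
            sweep = sweep_from(rows)
            got = select_module(sweep, rule)
            eligible = [
                (t, z, s)
                for t, z, s in rows
                if z > rule.z_min and rule.size_min <= s <= rule.size_max
            ]
            if not eligible:
                assert isinstance(got, NoModuleReport)
            else:
                best = max(eligible, key=lambda r: (r[1], -r[0]))
                assert isinstance(got, Module)
                assert (got.threshold, got.z_score, got.lcc_size) == best


class TestDetectModule:
    def test_single_subthreshold_gene_gives_no_module(self, star5):
        table = table_of({"X": 0.01, "Y1": 0.9, "Y2": 0.9, "Y3": 0.9, "Y4": 0.9})
        null = NullModelConfig(method="uniform", n_samples=100, seed=1)
        verdict, sweep = detect_module(star5, table, null=null, max_threshold=0.05)
        assert isinstance(verdict, NoModuleReport)

    def test_module_invariants_hold_post_hoc(self):
        import networkx as nx
        from netmod import ScenarioConfig, generate_study_scenario

        sc = generate_study_scenario(
            ScenarioConfig(n_nodes=600, module_sizes=(30, 20, 25), seed=3)
        )
        rule = SelectionRule(size_min=10, size_max=60)
        null = NullModelConfig(n_samples=500, seed=3)
        verdict, _ = detect_module(
            sc.network, sc.tables["exposure"], null=null, rule=rule,
            rng=np.random.default_rng(3),
        )
        if isinstance(verdict, Module):
            sub = sc.network.graph.subgraph(verdict.members)
            assert nx.is_connected(sub)
            assert rule.size_min <= verdict.lcc_size <= rule.size_max
            assert verdict.z_score > rule.z_min
            table = sc.tables["exposure"]
            assert all(table.p_value(g) < verdict.threshold for g in verdict.members)

    def test_writers_produce_parseable_outputs(self, tmp_path, star5):
        table = table_of({"X": 0.01, "Y1": 0.02, "Y2": 0.3, "Y3": 0.4, "Y4": 0.5})
        null = NullModelConfig(method="uniform", n_samples=200, seed=4)
        rule = SelectionRule(size_min=2, size_max=4, z_min=0.5, hard_cap=5)
        verdict, sweep = detect_module(star5, table, null=null, rule=rule)
        write_sweep_trace(sweep, tmp_path / "trace.tsv")
        lines = (tmp_path / "trace.tsv").read_text().splitlines()
        assert lines[0].startswith("threshold\t")
        assert len(lines) == len(sweep.rows) + 1
        if isinstance(verdict, Module):
            genes_path, meta_path = write_module(verdict, tmp_path / "mod")
            assert len(genes_path.read_text().split()) == verdict.lcc_size


def test_selection_rule_validation():
    with pytest.raises(ValueError):
        SelectionRule(size_min=0)
    with pytest.raises(ValueError):
        SelectionRule(size_min=50, size_max=40)
    with pytest.raises(ValueError):
        SelectionRule(size_max=400, hard_cap=300)
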