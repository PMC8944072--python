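"""Synthetic study scenarios: networks, planted modules, p-value tables.

The generator emulates the statistical structure the pipeline assumes: a
scale-free interactome with typed edges, one or more planted *connected*
gene modules whose members carry small p-values, uniform background
p-values, and optional excess edges planted between module pairs. Defaults
mirror the study design the pipeline targets — one exposure dataset plus
two disease datasets over a single interactome, with the exposure module
wired to both disease modules — at a desk scale of 2,000 genes.

All randomness flows through a single ``numpy`` Generator (or a seed),
so scenarios are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import EDGE_TYPES, Network
from .scores import GeneScoreTable

# HumanNet-FN's printed typed-edge composition (118,012 physical, 213,003
# functional, 39,587 both) normalized over the three type counts.
DEFAULT_EDGE_TYPE_PROPS = (118012 / 370602, 213003 / 370602, 39587 / 370602)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-scenario parameters.

    ``module_sizes`` defaults to (50, 37, 64) — one exposure and two
    disease modules at the scale the method targets; ``a`` is the
    Beta(a, 1) shape of planted-gene p-values (a = 0.1 is a strong signal:
    74% of planted genes fall below p = 0.05; a = 1 is exactly the null);
    ``cross_edges`` extra functional edges are planted from the exposure
    module to each disease module. ``triad_p`` is the triad-formation
    probability of the preferential-attachment generator (clustering, and
    with it community structure, vanishes at 0); ``growth_bias`` makes
    module growth conductance-seeking (attachment-fraction exponent) so
    planted modules carry the excess internal density and weak external
    coupling that define a disease module.
    """

    n_nodes: int = 2000
    m_attach: int = 3
    triad_p: float = 1.0
    growth_bias: float = 2.0
    edge_type_props: tuple[float, float, float] = DEFAULT_EDGE_TYPE_PROPS
    module_sizes: tuple[int, ...] = (50, 37, 64)
    a: float = 0.1
    cross_edges: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.edge_type_props) - 1.0) > 1e-9:
            raise ValueError("edge_type_props must sum to 1")
        if not (0 < self.a <= 1):
            raise ValueError("signal shape a must lie in (0, 1]")
        for s in self.module_sizes:
            if not (2 <= s <= self.n_nodes):
                raise ValueError("module sizes must lie in [2, n_nodes]")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")


@dataclass
class SyntheticTruth:
    """Ground truth serialized alongside generated data."""

    modules: dict[str, list[str]]
    cross_edges: dict[str, list[tuple[str, str]]]
    signal_genes: dict[str, list[str]]  # per-dataset planted (signal) genes
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "modules": self.modules,
                    "cross_edges": self.cross_edges,
                    "signal_genes": self.signal_genes,
                    "config": self.config,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            modules=raw["modules"],
            cross_edges={
                k: [tuple(e) for e in v] for k, v in raw["cross_edges"].items()
            },
            signal_genes=raw["signal_genes"],
            config=raw.get("config", {}),
        )


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_network(config: ScenarioConfig, rng: np.random.Generator) -> Network:
    """Preferential-attachment network with typed edges.

    Each new node attaches to ``m_attach`` existing nodes (with triad
    formation at probability ``triad_p``, giving the clustered
    neighborhoods real interactomes show), so the graph is connected by
    construction with ~m·(n−m) edges; every edge draws its type
    independently from the configured proportions.
    """
    seed_int = int(rng.integers(0, 2**31 - 1))
    if config.triad_p > 0:
        g = nx.powerlaw_cluster_graph(
            config.n_nodes, config.m_attach, config.triad_p, seed=seed_int
        )
    else:
        g = nx.barabasi_albert_graph(config.n_nodes, config.m_attach, seed=seed_int)
    width = len(str(config.n_nodes - 1))
    mapping = {i: _gene_name(i, width) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    edges = sorted(g.edges)
    types = rng.choice(
        np.array(EDGE_TYPES), size=len(edges), p=np.array(config.edge_type_props)
    )
    net = Network(name="synthetic")
    net.graph.add_nodes_from(sorted(g.nodes))
    for (u, v), t in zip(edges, types):
        net.add_typed_edge(u, v, str(t))
    return net


def plant_connected_module(
    net: Network,
    size: int,
    rng: np.random.Generator,
    avoid: set[str] | None = None,
    bias: float = 2.0,
    min_density: float = 0.0,
    max_restarts: int = 100,
) -> set[str]:
    """Grow a random connected induced gene set of the requested size.

    Starting from a random node, neighbors of the current set are added
    one at a time until ``size`` is reached, each candidate v drawn with
    probability proportional to c_v * (c_v / deg(v))^bias, where c_v
    counts v's edges into the current set. The attachment-fraction factor
    makes growth conductance-seeking: it prefers candidates most of whose
    edges point into the module, so the planted set is internally dense
    yet weakly tied to the rest of the network — the defining property of
    a module, which uniform frontier growth (spanning-tree-like sets with
    no excess density) cannot produce.
    ``min_density`` (internal edges per spanning-tree edge, i.e. a floor
    of min_density·(size−1) induced edges) triggers regrowth of sets that
    came out too sparse; the densest attempt is kept if the floor is
    never met. Nodes in ``avoid`` are never used (successive modules can
    be grown disjoint); growth that strands itself restarts from a new
    seed node.
    """
    avoid = avoid or set()
    candidates = sorted(net.nodes - avoid)
    if size > len(candidates):
        raise ValueError(f"cannot plant a module of size {size}")
    best: set[str] | None = None
    best_edges = -1
    for _ in range(max_restarts):
        start = candidates[int(rng.integers(len(candidates)))]
        module = {start}
        frontier: dict[str, int] = {}  # candidate -> edges into module
        for v in net.graph.adj[start]:
            if v not in avoid:
                frontier[v] = 1
        n_internal = 0
        while len(module) < size and frontier:
            keys = sorted(frontier)
            c = np.array([frontier[k] for k in keys], dtype=float)
            d = np.array([net.graph.degree[k] for k in keys], dtype=float)
            weights = c * (c / d) ** bias
            pick = keys[int(rng.choice(len(keys), p=weights / weights.sum()))]
            n_internal += frontier.pop(pick)
            module.add(pick)
            for v in net.graph.adj[pick]:
                if v not in module and v not in avoid:
                    frontier[v] = frontier.get(v, 0) + 1
        if len(module) == size:
            if n_internal >= min_density * (size - 1):
                return module
            if n_internal > best_edges:
                best, best_edges = module, n_internal
    if best is not None:
        return best
    raise ValueError(
        f"could not grow a connected module of size {size} in {max_restarts} restarts"
    )


def generate_scores(
    net: Network,
    planted: set[str],
    a: float,
    rng: np.random.Generator,
    dataset_name: str = "synthetic",
) -> GeneScoreTable:
    """Gene p-values: planted genes ~ Beta(a, 1), background ~ Uniform(0, 1).

    Beta(a, 1) has CDF x^a, so detection power is analytic; a = 1 is the
    Uniform null exactly.
    """
    if not (0 < a <= 1):
        raise ValueError("signal shape a must lie in (0, 1]")
    genes = sorted(net.nodes)
    ps = rng.uniform(0.0, 1.0, size=len(genes))
    planted_mask = np.array([g in planted for g in genes])
    if planted_mask.any():
        ps[planted_mask] = rng.beta(a, 1.0, size=int(planted_mask.sum()))
    df = pd.DataFrame({"p_value": ps}, index=pd.Index(genes, name="gene"))
    return GeneScoreTable(df, dataset_name)


def plant_cross_edges(
    net: Network,
    A: set[str],
    B: set[str],
    extra: int,
    rng: np.random.Generator,
) -> tuple[Network, list[tuple[str, str]]]:
    """Add ``extra`` absent A–B pairs as functional edges (new network).

    Candidate pairs run over A\\B × B\\A; planting more edges than absent
    pairs exist is an error. Returns the augmented network and the added
    edges (also recorded in scenario truth files).
    """
    a_only = sorted(A - B)
    b_only = sorted(B - A)
    absent = [
        (u, v) for u in a_only for v in b_only if not net.graph.has_edge(u, v)
    ]
    if extra > len(absent):
        raise ValueError(
            f"requested {extra} cross edges but only {len(absent)} pairs are absent"
        )
    out = net.copy()
    if extra == 0:
        return out, []
    chosen_idx = rng.choice(len(absent), size=extra, replace=False)
    added = [absent[i] for i in sorted(chosen_idx)]
    for u, v in added:
        out.add_typed_edge(u, v, "functional")
    return out, added


@dataclass
class StudyScenario:
    """One network, one score table per dataset, and the planted truth."""

    network: Network
    tables: dict[str, GeneScoreTable]
    truth: SyntheticTruth


DATASET_NAMES = ("exposure", "disease1", "disease2")


def generate_study_scenario(
    config: ScenarioConfig = ScenarioConfig(),
    rng: np.random.Generator | None = None,
) -> StudyScenario:
    """Mirror the study design: exposure + two disease datasets, one PPI.

    Three disjoint connected modules are planted (exposure, disease1,
    disease2); ``config.cross_edges`` extra functional edges are wired
    exposure↔disease1 and exposure↔disease2; each dataset's score table
    carries Beta(a, 1) p-values on its own module and uniform noise
    elsewhere.
    """
    if len(config.module_sizes) != 3:
        raise ValueError("the study scenario requires exactly three module sizes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    net = generate_network(config, rng)
    modules: dict[str, set[str]] = {}
    used: set[str] = set()
    # plant larger modules first: the densest regions go to the modules
    # that need the most internal structure, instead of to whichever
    # dataset happens to be listed first
    by_size = sorted(
        zip(DATASET_NAMES, config.module_sizes), key=lambda x: -x[1]
    )
    for name, size in by_size:
        module = plant_connected_module(
            net,
            size,
            rng,
            avoid=used,
            bias=config.growth_bias,
            min_density=2.0,
            max_restarts=30,
        )
        modules[name] = module
        used |= module
    cross: dict[str, list[tuple[str, str]]] = {}
    for disease in ("disease1", "disease2"):
        net, added = plant_cross_edges(
            net, modules["exposure"], modules[disease], config.cross_edges, rng
        )
        cross[f"exposure-{disease}"] = added
    tables = {
        name: generate_scores(net, modules[name], config.a, rng, dataset_name=name)
        for name in DATASET_NAMES
    }
    truth = SyntheticTruth(
        modules={k: sorted(v) for k, v in modules.items()},
        cross_edges=cross,
        signal_genes={k: sorted(modules[k]) for k in DATASET_NAMES},
        config=asdict(config),
    )
    return StudyScenario(network=net, tables=tables, truth=truth)


def scenario_collection(
    scenario: StudyScenario,
    rng: np.random.Generator,
    n_random_sets: int = 15,
    set_size_range: tuple[int, int] = (20, 80),
):
    """A synthetic GMT-style collection matched to a scenario.

    Contains ``n_random_sets`` random gene sets plus, per planted module,
    one set holding half the module's genes padded with random genes —
    sets a correct enrichment should flag when queried with the module.
    """
    from .enrichment import GeneSetCollection

    genes = sorted(scenario.network.nodes)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    lo, hi = set_size_range
    for i in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        name = f"RANDOM_SET_{i:02d}"
        sets[name] = frozenset(str(g) for g in members)
        descriptions[name] = "random background set"
    for mod_name, members in scenario.truth.modules.items():
        half = sorted(members)[: max(2, len(members) // 2)]
        pad = rng.choice(
            [g for g in genes if g not in set(members)], size=len(half), replace=False
        )
        name = f"PLANTED_{mod_name.upper()}_SET"
        sets[name] = frozenset(half) | frozenset(str(g) for g in pad)
        descriptions[name] = f"half of planted module {mod_name} plus random padding"
    return GeneSetCollection(sets=sets, descriptions=descriptions, name="synthetic")


def write_scenario(
    scenario: StudyScenario, outdir: str | Path, rng: np.random.Generator | None = None
) -> Path:
    """Serialize a scenario so the CLI can consume it without modification.

    Writes the network edge list, one score table per dataset, the truth
    JSON, a synthetic gene-set collection, a disease-gene list (the
    planted disease-module genes), and a ready-to-run pipeline config.
    """
    import yaml

    from .graph import write_edge_list

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edge_list(scenario.network, outdir / "network.tsv")
    for name, table in scenario.tables.items():
        table.write_tsv(outdir / f"scores_{name}.tsv")
    scenario.truth.to_json(outdir / "truth.json")
    seed = scenario.truth.config.get("seed", 0)
    if rng is None:
        rng = np.random.default_rng([int(seed), 977])
    collection = scenario_collection(scenario, rng)
    collection.write_gmt(outdir / "collection.gmt")
    disease_genes = sorted(
        set(scenario.truth.modules["disease1"]) | set(scenario.truth.modules["disease2"])
    )
    with open(outdir / "disease_genes.txt", "w") as fh:
        fh.write("# planted disease-module genes\n")
        for g in disease_genes:
            fh.write(g + "\n")
    config = {
        "seed": int(seed),
        "output_dir": "run",
        "network": {"path": "network.tsv", "dialect": "generic"},
        "scores": [
            {"path": f"scores_{name}.tsv", "name": name} for name in scenario.tables
        ],
        "null_model": {"method": "degree_binned", "n_samples": 10000, "min_bin_size": 100},
        "selection": {"z_min": 1.6, "size_min": 30, "size_max": 100, "hard_cap": 300},
        "enrichment": {
            "collections": ["collection.gmt"],
            "background": "network_lcc",
            "correction": "benjamini_hochberg",
        },
        "disease_gene_lists": ["disease_genes.txt"],
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return outdir
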