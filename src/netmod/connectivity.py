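"""Inter-module connectivity statistics and interactor extraction.

Given two (or more) gene modules on a typed PPI this module tallies the
edges running between them by interaction type, assesses whether that
count exceeds random expectation (jointly resampling degree-matched
disjoint surrogate pairs), extracts *interactors* — genes of one module
with at least one direct edge into another — and tests whether the
cross-edge type composition is biased (hypergeometric draw from the
network-wide edge-type population). A within-set variant scores the
connectivity of an arbitrary gene list (e.g. literature disease genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from . import _kernels
from .graph import ComponentView, Network, induced_lcc
from .nulls import NullModelConfig, bins_for, empirical_p, null_statistics, z_score

logger = logging.getLogger(__name__)

SHARED_POLICIES = ("exclude", "include", "error")


@dataclass(frozen=True)
class EdgeTally:
    """Edge counts partitioned by interaction type."""

    physical: int = 0
    functional: int = 0
    both: int = 0

    @property
    def total(self) -> int:
        return self.physical + self.functional + self.both

    def count(self, etype: str, pool_both: bool = False) -> int:
        base = getattr(self, etype)
        return base + self.both if (pool_both and etype != "both") else base


@dataclass
class ConnectivityResult:
    """Observed statistic vs its randomization null."""

    labels: tuple[str, ...]
    observed: EdgeTally | int
    statistic: str  # "cross_edges", "within_edges", or "lcc_size"
    empirical_p: float
    z_score: float | None
    null_mean: float
    null_sd: float
    null_config: NullModelConfig

    @property
    def observed_value(self) -> int:
        return self.observed.total if isinstance(self.observed, EdgeTally) else self.observed


def _apply_shared_policy(
    A: set[str], B: set[str], shared_policy: str
) -> tuple[set[str], set[str]]:
    if shared_policy not in SHARED_POLICIES:
        raise ValueError(f"unknown shared_policy {shared_policy!r}")
    shared = A & B
    if shared and shared_policy == "error":
        raise ValueError(f"modules share genes: {sorted(shared)}")
    if shared_policy == "include":
        return set(A), set(B)
    return A - B, B - A


def count_inter_module_edges(
    net: Network, A: Iterable[str], B: Iterable[str], shared_policy: str = "exclude"
) -> EdgeTally:
    """Typed tally of edges with one endpoint in A and the other in B.

    Shared genes are excluded from both sides by default so that no gene
    can "link a module to itself"; each unordered edge is counted once.
    """
    A, B = _apply_shared_policy(set(A), set(B), shared_policy)
    counts = {"physical": 0, "functional": 0, "both": 0}
    small, other = (A, B) if len(A) <= len(B) else (B, A)
    seen: set[tuple[str, str]] = set()
    for u in small & net.nodes:
        for v, attrs in net.graph.adj[u].items():
            if v in other:
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen.add(key)
                    counts[attrs["etype"]] += 1
    return EdgeTally(**counts)


def inter_module_significance(
    net: Network,
    A: Iterable[str],
    B: Iterable[str],
    null: NullModelConfig = NullModelConfig(),
    shared_policy: str = "exclude",
    rng: np.random.Generator | None = None,
) -> ConnectivityResult:
    """Permutation test of the cross-edge count between two modules.

    Both modules are resampled jointly per draw: degree-matched surrogate
    sets of the two sizes, disjoint within each draw, neither module
    privileged. The upper-tail add-one empirical p and a z-score against
    the null mean/sd are returned.
    """
    A, B = _apply_shared_policy(set(A) & net.nodes, set(B) & net.nodes, shared_policy)
    if not A or not B:
        raise ValueError("both modules must be nonempty after shared-gene exclusion")
    if rng is None:
        rng = null.rng()
    observed = count_inter_module_edges(net, A, B, shared_policy="exclude")
    bins = bins_for(net, null)
    _, index, _, _ = net.csr()
    idx_a = np.array([index[g] for g in A], dtype=np.int64)
    idx_b = np.array([index[g] for g in B], dtype=np.int64)
    null_counts = null_statistics(
        bins,
        bins.counts_for(idx_a),
        bins.counts_for(idx_b),
        null.n_samples,
        rng,
        _kernels.STAT_CROSS_EDGES,
    )
    p = empirical_p(observed.total, null_counts)
    z, mean, sd = z_score(observed.total, null_counts)
    return ConnectivityResult(
        labels=("A", "B"),
        observed=observed,
        statistic="cross_edges",
        empirical_p=p,
        z_score=z,
        null_mean=mean,
        null_sd=sd,
        null_config=null,
    )


@dataclass
class InteractorTable:
    """Per-(home, target) interactor rows plus pairwise summary counts.

    ``data`` columns: gene, home_module, target_module, n_cross_edges,
    cross_edge_types (comma-joined type counts), multi_target (gene
    connects to more than one foreign module from its home module).
    """

    data: pd.DataFrame
    pair_summary: pd.DataFrame  # home, target, n_interactors, n_cross_edges

    def genes(self) -> set[str]:
        return set(self.data["gene"])


def find_interactors(
    net: Network,
    modules: Mapping[str, Iterable[str]],
    shared_policy: str = "exclude",
) -> InteractorTable:
    """Genes of one module with >= 1 direct edge into another module.

    For every ordered (home, target) module pair, lists the home-module
    genes adjacent to the target module (shared genes handled per
    ``shared_policy``), with cross-edge counts by type; genes reaching
    several foreign modules are flagged.
    """
    if len(modules) < 2:
        raise ValueError("need at least two modules")
    sets = {name: set(genes) & net.nodes for name, genes in modules.items()}
    rows = []
    for home, home_genes in sets.items():
        for target, target_genes in sets.items():
            if home == target:
                continue
            h, t = _apply_shared_policy(home_genes, target_genes, shared_policy)
            for g in sorted(h):
                tally = {"physical": 0, "functional": 0, "both": 0}
                for v, attrs in net.graph.adj[g].items():
                    if v in t:
                        tally[attrs["etype"]] += 1
                n_cross = sum(tally.values())
                if n_cross:
                    rows.append(
                        {
                            "gene": g,
                            "home_module": home,
                            "target_module": target,
                            "n_cross_edges": n_cross,
                            "cross_edge_types": ",".join(
                                f"{k}:{v}" for k, v in tally.items() if v
                            ),
                        }
                    )
    data = pd.DataFrame(
        rows,
        columns=["gene", "home_module", "target_module", "n_cross_edges", "cross_edge_types"],
    )
    if len(data):
        targets_per_gene = data.groupby(["gene", "home_module"])["target_module"].nunique()
        data["multi_target"] = [
            bool(targets_per_gene[(g, h)] > 1)
            for g, h in zip(data["gene"], data["home_module"])
        ]
        pair_summary = (
            data.groupby(["home_module", "target_module"])
            .agg(n_interactors=("gene", "nunique"), n_cross_edges=("n_cross_edges", "sum"))
            .reset_index()
        )
    else:
        data["multi_target"] = pd.Series(dtype=bool)
        pair_summary = pd.DataFrame(
            columns=["home_module", "target_module", "n_interactors", "n_cross_edges"]
        )
    return InteractorTable(data=data, pair_summary=pair_summary)


def write_interactor_table(
    table: InteractorTable,
    modules: Mapping[str, Iterable[str]],
    path: str | Path,
) -> None:
    """Writer mirroring the three-column published layout.

    One row per (gene, home module, target module or "No module"): module
    members with no cross edges at all appear once with target "No module".
    """
    rows = []
    interacting = set(zip(table.data["gene"], table.data["home_module"]))
    for _, r in table.data.iterrows():
        rows.append((r["gene"], r["home_module"], r["target_module"]))
    for home, genes in modules.items():
        for g in sorted(set(genes)):
            if (g, home) not in interacting:
                rows.append((g, home, "No module"))
    rows.sort(key=lambda r: (r[1], r[2], r[0]))
    with open(path, "w") as fh:
        fh.write("gene\thome_module\ttarget_module\n")
        for g, h, t in rows:
            fh.write(f"{g}\t{h}\t{t}\n")


def edge_type_composition_test(
    observed: EdgeTally,
    net: Network,
    type_of_interest: str = "functional",
    pool_both: bool = False,
) -> dict:
    """Hypergeometric upper tail for edge-type bias among drawn edges.

    The population is the network-wide typed edge partition; the draw is
    ``observed.total`` edges of which ``k`` are of the type of interest.
    Whether the hybrid physical+functional class pools with the type of
    interest is an explicit, recorded parameter (``pool_both``).
    """
    if observed.total < 1:
        raise ValueError("need at least one observed edge")
    pop = net.edge_type_counts()
    N = sum(pop.values())
    K = pop[type_of_interest] + (pop["both"] if pool_both and type_of_interest != "both" else 0)
    n = observed.total
    k = observed.count(type_of_interest, pool_both=pool_both)
    if n > N or k > K:
        raise ValueError("observed counts exceed the edge population")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return {
        "type_of_interest": type_of_interest,
        "pool_both": pool_both,
        "k": k,
        "n": n,
        "K": K,
        "N": N,
        "p_value": p,
    }


def gene_set_connectivity(
    net: Network,
    genes: Iterable[str],
    null: NullModelConfig = NullModelConfig(),
    statistic: str = "within_edges",
    rng: np.random.Generator | None = None,
) -> ConnectivityResult:
    """Is a gene set better connected than degree-matched random sets?

    ``statistic`` is the within-set edge count (default) or the induced
    LCC size (``lcc_size``); the null draws degree-matched sets of the
    same mapped size.
    """
    if statistic not in ("within_edges", "lcc_size"):
        raise ValueError(f"unknown statistic {statistic!r}")
    mapped = set(genes) & net.nodes
    if len(mapped) < 2:
        raise ValueError("need at least 2 genes mapped to the network")
    if rng is None:
        rng = null.rng()
    _, index, indptr, indices = net.csr()
    idx = np.array(sorted(index[g] for g in mapped), dtype=np.int64)
    if statistic == "within_edges":
        observed = sum(
            1 for g in mapped for v in net.graph.adj[g] if v in mapped and v > g
        )
        stat_code = _kernels.STAT_WITHIN_EDGES
    else:
        observed = _kernels.induced_lcc_size(indptr, indices, idx)
        stat_code = _kernels.STAT_LCC
    bins = bins_for(net, null)
    null_vals = null_statistics(
        bins, bins.counts_for(idx), None, null.n_samples, rng, stat_code
    )
    p = empirical_p(observed, null_vals)
    z, mean, sd = z_score(observed, null_vals)
    return ConnectivityResult(
        labels=(f"{len(mapped)} genes",),
        observed=int(observed),
        statistic=statistic,
        empirical_p=p,
        z_score=z,
        null_mean=mean,
        null_sd=sd,
        null_config=null,
    )


def union_component(
    net: Network, modules: Mapping[str, Iterable[str]]
) -> tuple[ComponentView, dict[str, list[str]]]:
    """LCC of the union of module gene sets, annotated by module of origin."""
    if not modules:
        raise ValueError("need at least one module")
    union: set[str] = set()
    for genes in modules.values():
        union |= set(genes)
    view = induced_lcc(net, union)
    annotation = {
        g: sorted(name for name, genes in modules.items() if g in set(genes))
        for g in view.member_nodes
    }
    return view, annotation


def write_connectivity_report(result: ConnectivityResult, path: str | Path) -> None:
    """Tab-separated one-row report of a connectivity test."""
    obs = result.observed
    with open(path, "w") as fh:
        if isinstance(obs, EdgeTally):
            fh.write(
                "labels\tstatistic\tobserved_total\tphysical\tfunctional\tboth\t"
                "null_mean\tnull_sd\tz\tempirical_p\tn_samples\tnull_method\n"
            )
            z = f"{result.z_score:.6g}" if result.z_score is not None else "NA"
            fh.write(
                f"{'|'.join(result.labels)}\t{result.statistic}\t{obs.total}\t"
                f"{obs.physical}\t{obs.functional}\t{obs.both}\t"
                f"{result.null_mean:.6g}\t{result.null_sd:.6g}\t{z}\t"
                f"{result.empirical_p:.6g}\t{result.null_config.n_samples}\t"
                f"{result.null_config.method}\n"
            )
        else:
            fh.write(
                "labels\tstatistic\tobserved\tnull_mean\tnull_sd\tz\tempirical_p\t"
                "n_samples\tnull_method\n"
            )
            z = f"{result.z_score:.6g}" if result.z_score is not None else "NA"
            fh.write(
                f"{'|'.join(result.labels)}\t{result.statistic}\t{obs}\t"
                f"{result.null_mean:.6g}\t{result.null_sd:.6g}\t{z}\t"
                f"{result.empirical_p:.6g}\t{result.null_config.n_samples}\t"
                f"{result.null_config.method}\n"
            )
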