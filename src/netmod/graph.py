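"""Typed protein-protein interaction network container and component machinery.

The network is an undirected graph whose nodes are normalized gene
identifiers and whose edges carry one of three interaction types:
``physical``, ``functional``, or ``both`` (physical *and* functional).
Exactly one type is stored per unordered gene pair, so typed-edge counts
partition the edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

EDGE_TYPES = ("physical", "functional", "both")


class EdgeListFormatError(ValueError):
    """Raised when an edge-list file violates the expected format."""


def normalize_gene(identifier: str, casefold: bool = True) -> str:
    """Normalize a gene identifier: strip whitespace, optionally uppercase.

    Case-folding is on by default because gene symbols are conventionally
    upper-case but source files mix conventions; disable it for identifier
    schemes (e.g. Ensembl versioned ids) where case matters.
    """
    identifier = identifier.strip()
    return identifier.upper() if casefold else identifier


def _merge_types(a: str, b: str) -> str:
    """Resolve two type claims for the same gene pair into one type."""
    if a == b:
        return a
    return "both"


@dataclass
class Network:
    """Undirected typed PPI backed by a :class:`networkx.Graph`.

    Edge type lives in the ``etype`` edge attribute. Invariants (no
    self-loops, one record per unordered pair, valid ``etype``) are
    maintained by :meth:`add_typed_edge` and checked by :meth:`validate`.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = "network"

    # CSR adjacency cache for the randomization kernels
    _csr_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)
        self._csr_cache = None

    def add_typed_edge(self, u: str, v: str, etype: str) -> None:
        """Add one typed edge; duplicates are merged (physical+functional→both)."""
        if etype not in EDGE_TYPES:
            raise EdgeListFormatError(f"unknown edge type {etype!r}")
        if u == v:
            raise ValueError(f"self-loop on {u!r} not allowed")
        if self.graph.has_edge(u, v):
            old = self.graph.edges[u, v]["etype"]
            self.graph.edges[u, v]["etype"] = _merge_types(old, etype)
        else:
            self.graph.add_edge(u, v, etype=etype)
        self._csr_cache = None

    def edge_type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EDGE_TYPES}
        for _, _, t in self.graph.edges(data="etype"):
            counts[t] += 1
        return counts

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def validate(self) -> None:
        """Assert the container invariants; raises ``ValueError`` on violation."""
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("network contains a self-loop")
        for u, v, t in self.graph.edges(data="etype"):
            if t not in EDGE_TYPES:
                raise ValueError(f"edge {u}-{v} has invalid type {t!r}")

    def csr(self) -> tuple[list[str], dict[str, int], np.ndarray, np.ndarray]:
        """Return (node order, node→index map, CSR indptr, CSR indices).

        Node order is sorted for determinism; the structure is cached and
        invalidated on mutation.
        """
        if self._csr_cache is None:
            order = sorted(self.graph.nodes)
            index = {g: i for i, g in enumerate(order)}
            n = len(order)
            degs = np.fromiter(
                (self.graph.degree[g] for g in order), dtype=np.int64, count=n
            )
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.cumsum(degs, out=indptr[1:])
            indices = np.empty(int(indptr[-1]), dtype=np.int64)
            fill = indptr[:-1].copy()
            for u, v in self.graph.edges:
                iu, iv = index[u], index[v]
                indices[fill[iu]] = iv
                fill[iu] += 1
                indices[fill[iv]] = iu
                fill[iv] += 1
            self._csr_cache = (order, index, indptr, indices)
        return self._csr_cache

    def copy(self, name: str | None = None) -> "Network":
        return Network(graph=self.graph.copy(), name=name or self.name)


@dataclass(frozen=True)
class ComponentView:
    """A connected component of (an induced subgraph of) a parent network."""

    member_nodes: frozenset[str]
    parent_network: Network

    @property
    def size(self) -> int:
        return len(self.member_nodes)


def load_edge_list(
    path: str | Path,
    dialect: str = "generic",
    physical_path: str | Path | None = None,
    casefold: bool = True,
    id_mapping: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Network:
    """Load a tab-separated typed edge list into a :class:`Network`.

    ``generic`` dialect: columns geneA, geneB, optional edge type (defaults
    to ``functional`` when absent). ``humannet`` dialect: *path* holds the
    functional links and *physical_path* the physical links; pairs present
    in both files are typed ``both``. ``#`` comment lines are skipped,
    self-loops dropped (count logged), duplicate rows collapsed. An optional
    two-column identifier mapping is applied before normalization checks.
    """
    if dialect not in ("generic", "humannet"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = Network(name=name or Path(path).stem)

    def norm(g: str) -> str:
        g = normalize_gene(g, casefold=casefold)
        if id_mapping is not None and g in id_mapping:
            g = normalize_gene(id_mapping[g], casefold=casefold)
        return g

    def read_pairs(p: str | Path, default_type: str) -> None:
        dropped_loops = 0
        with open(p) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise EdgeListFormatError(
                        f"{p}:{lineno}: expected >=2 tab-separated columns"
                    )
                u, v = norm(fields[0]), norm(fields[1])
                etype = default_type
                if dialect == "generic" and len(fields) >= 3 and fields[2].strip():
                    etype = fields[2].strip().lower()
                    if etype not in EDGE_TYPES:
                        raise EdgeListFormatError(
                            f"{p}:{lineno}: unknown edge type {fields[2]!r}"
                        )
                if u == v:
                    dropped_loops += 1
                    net.add_node(u)
                    continue
                net.add_typed_edge(u, v, etype)
        if dropped_loops:
            logger.info("%s: dropped %d self-loop rows", p, dropped_loops)

    if dialect == "generic":
        read_pairs(path, "functional")
    else:
        read_pairs(path, "functional")
        if physical_path is not None:
            read_pairs(physical_path, "physical")
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the network as geneA<TAB>geneB<TAB>type, sorted for determinism."""
    rows = sorted(
        (min(u, v), max(u, v), t) for u, v, t in net.graph.edges(data="etype")
    )
    with open(path, "w") as fh:
        fh.write("# geneA\tgeneB\tedge_type\n")
        for u, v, t in rows:
            fh.write(f"{u}\t{v}\t{t}\n")
    # isolated nodes are not representable in an edge list; note them
    isolated = [g for g in net.graph.nodes if net.graph.degree[g] == 0]
    if isolated:
        logger.info("%d isolated nodes not written to %s", len(isolated), path)


def largest_connected_component(net: Network) -> ComponentView:
    """Largest connected component of the whole network (size 0 if empty)."""
    if net.number_of_nodes() == 0:
        return ComponentView(frozenset(), net)
    members = max(nx.connected_components(net.graph), key=lambda c: (len(c), min(c)))
    return ComponentView(frozenset(members), net)


def induced_lcc(net: Network, genes: Iterable[str]) -> ComponentView:
    """Largest connected component of the subgraph induced by ``genes``.

    Genes absent from the network are silently ignored (count logged);
    an empty intersection gives a size-0 view.
    """
    genes = set(genes)
    present = genes & set(net.graph.nodes)
    missing = len(genes) - len(present)
    if missing:
        logger.debug("induced_lcc: %d query genes absent from network", missing)
    if not present:
        return ComponentView(frozenset(), net)
    sub = net.graph.subgraph(present)
    members = max(nx.connected_components(sub), key=lambda c: (len(c), min(c)))
    return ComponentView(frozenset(members), net)


def export_subnetwork(
    net: Network,
    genes: Iterable[str],
    path_prefix: str | Path,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
) -> tuple[Path, Path]:
    """Export the induced subgraph on ``genes`` to GraphML and a TSV edge list.

    Node annotations (module membership, disease-gene flags, ...) are
    attached as GraphML attributes together with the degree within the
    exported subgraph; genes without an annotation get empty labels with a
    logged warning. Returns the (graphml, tsv) paths.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("export_subnetwork: empty gene set")
    present = sorted(genes & set(net.graph.nodes))
    sub = nx.Graph()
    sub.add_nodes_from(present)
    for u, v, t in net.graph.subgraph(present).edges(data="etype"):
        sub.add_edge(u, v, etype=t)
    ann_keys: list[str] = []
    if annotations:
        ann_keys = sorted({k for v in annotations.values() for k in v})
    n_missing = 0
    for g in present:
        sub.nodes[g]["subnetwork_degree"] = sub.degree[g]
        node_ann = (annotations or {}).get(g)
        if annotations and node_ann is None:
            n_missing += 1
        for k in ann_keys:
            sub.nodes[g][k] = str((node_ann or {}).get(k, ""))
    if n_missing:
        logger.warning("export_subnetwork: %d genes lack annotations", n_missing)

    prefix = Path(path_prefix)
    graphml_path = prefix.with_suffix(".graphml")
    tsv_path = prefix.with_suffix(".tsv")
    nx.write_graphml(sub, graphml_path)
    sub_net = Network(graph=sub, name=f"{net.name}:subnetwork")
    write_edge_list(sub_net, tsv_path)
    return graphml_path, tsv_path
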