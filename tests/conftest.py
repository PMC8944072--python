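"""Shared fixtures: small networks with known structure."""

from __future__ import annotations

import numpy as np
import pytest

from netmod import Network


@pytest.fixture
def t1_toy() -> Network:
    """Path A-B-C-D-E with mixed edge types (the worked toy network)."""
    net = Network(name="t1")
    net.add_typed_edge("A", "B", "physical")
    net.add_typed_edge("B", "C", "functional")
    net.add_typed_edge("C", "D", "both")
    net.add_typed_edge("D", "E", "functional")
    return net


@pytest.fixture
def star5() -> Network:
    """5-node star: hub X with leaves Y1..Y4."""
    net = Network(name="star")
    for leaf in ("Y1", "Y2", "Y3", "Y4"):
        net.add_typed_edge("X", leaf, "physical")
    return net


@pytest.fixture
def path_plus_pair() -> Network:
    """Path A-B-C-D-E plus an isolated pair F-G."""
    net = Network(name="path+pair")
    for u, v in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("F", "G")]:
        net.add_typed_edge(u, v, "functional")
    return net


def random_typed_network(
    n: int, p: float, seed: int, name: str = "random"
) -> Network:
    """Erdős–Rényi-style random network with random edge types."""
    rng = np.random.default_rng(seed)
    net = Network(name=name)
    genes = [f"N{i:03d}" for i in range(n)]
    for g in genes:
        net.add_node(g)
    types = ("physical", "functional", "both")
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_typed_edge(genes[i], genes[j], types[int(rng.integers(3))])
    return net


@pytest.fixture
def random_net_200() -> Network:
    return random_typed_network(200, 0.02, seed=42)
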