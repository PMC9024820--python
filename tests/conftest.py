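"""Shared fixtures and the random-SEM battery used by the property tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ivgin.graphs import DirectedGraph
from ivgin.sem import LinearSEM, NoiseSpec


def random_linear_sem(
    rng: np.random.Generator,
    *,
    min_nodes: int = 4,
    max_nodes: int = 7,
    edge_prob: float = 0.45,
    noise_family: str = "squared_exponential",
) -> LinearSEM:
    """A random small DAG with 0-2 latent nodes and coefficients bounded
    away from zero (magnitudes in [0.5, 2]): the generic, faithful regime
    the population batteries assume."""
    p = int(rng.integers(min_nodes, max_nodes + 1))
    names = [f"V{i}" for i in range(p)]
    order = list(rng.permutation(p))
    edges = [
        (names[order[i]], names[order[j]])
        for i in range(p)
        for j in range(i + 1, p)
        if rng.random() < edge_prob
    ]
    n_latent = int(rng.integers(0, min(3, p - 3) + 1))
    latent = (
        list(rng.choice(names, size=n_latent, replace=False)) if n_latent else []
    )
    graph = DirectedGraph(edges, latent=latent, nodes=names)
    coeffs = {
        e: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0))
        for e in graph.edges
    }
    return LinearSEM(graph, coeffs, NoiseSpec(noise_family))


def pairwise_correlated(sem: LinearSEM, nodes) -> bool:
    cov = sem.population_cov()
    return all(
        abs(cov.loc[a, b]) > 1e-9 for a, b in itertools.combinations(nodes, 2)
    )


def draw_query(rng: np.random.Generator, sem: LinearSEM, *, max_w: int = 1):
    """Random (z, w, x, y) among observed nodes, or None if the graph is too
    small or the variables are not pairwise correlated."""
    obs = list(sem.graph.observed)
    if len(obs) < 3:
        return None
    rng.shuffle(obs)
    x, y, z = obs[:3]
    w_size = int(rng.integers(0, min(max_w, len(obs) - 3) + 1))
    w = frozenset(obs[3 : 3 + w_size])
    if not pairwise_correlated(sem, {x, y, z} | w):
        return None
    return z, w, x, y


@pytest.fixture(scope="session")
def battery_rng_seed() -> int:
    # one fixed stream for all derandomized property batteries
    return 20240512
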