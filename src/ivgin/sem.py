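"""Linear non-Gaussian acyclic structural equation models (LiNGAM-style).

Each node satisfies ``V_i = sum_j b_ij V_j + eps_i`` with mutually
independent noise terms.  The model is fully determined by a
:class:`~ivgin.graphs.DirectedGraph`, one coefficient per edge, and a
:class:`NoiseSpec` per node.  Besides forward sampling, the class exposes the
exact population algebra used by the GIN oracle:

* ``noise_mixing`` — the reduced-form matrix A = (I - B)^-1, whose row v
  gives the loading of every noise term in node v;
* ``population_cov`` — Sigma = A Omega A^T with Omega the diagonal of noise
  variances.

The default noise family is *squared-exponential*: E^2 with E ~ Exp(1),
centered by subtracting its mean 2.  This is a strongly skewed non-Gaussian
distribution with variance 20; it is centered but deliberately not rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .graphs import DirectedGraph, GraphError

__all__ = ["NoiseSpec", "LinearSEM", "as_rng"]

# Variance of each family's natural (unit-parameter) centered form.
_NATURAL_VARIANCE = {
    "gaussian": 1.0,
    "uniform": 1.0 / 12.0,  # U(0,1) centered
    "exponential": 1.0,  # Exp(1) centered
    "squared_exponential": 20.0,  # E^2 - 2, E ~ Exp(1): Var = E[E^4] - 4 = 20
}


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseSpec:
    """Distribution of one structural noise term.

    ``variance`` defaults to the family's natural variance (e.g. 20 for
    squared-exponential); setting it rescales the centered draw.  A custom
    family supplies its own centered ``sampler(rng, n)`` and must state its
    variance and Gaussianity explicitly.
    """

    family: str = "squared_exponential"
    variance: float | None = None
    sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    gaussian: bool | None = None

    def __post_init__(self) -> None:
        if self.family == "custom":
            if self.sampler is None or self.variance is None or self.gaussian is None:
                raise ValueError(
                    "custom noise needs sampler, variance and gaussian flag"
                )
        elif self.family not in _NATURAL_VARIANCE:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.variance is not None and self.variance <= 0:
            raise ValueError("noise variance must be positive")

    @property
    def var(self) -> float:
        if self.variance is not None:
            return float(self.variance)
        return _NATURAL_VARIANCE[self.family]

    @property
    def is_gaussian(self) -> bool:
        if self.family == "custom":
            return bool(self.gaussian)
        return self.family == "gaussian"

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "custom":
            return np.asarray(self.sampler(rng, n), dtype=float)
        if self.family == "gaussian":
            base = rng.standard_normal(n)
        elif self.family == "uniform":
            base = rng.uniform(0.0, 1.0, n) - 0.5
        elif self.family == "exponential":
            base = rng.exponential(1.0, n) - 1.0
        else:  # squared_exponential
            e = rng.exponential(1.0, n)
            base = e * e - 2.0
        return base * np.sqrt(self.var / _NATURAL_VARIANCE[self.family])


class LinearSEM:
    """A linear acyclic SEM over a :class:`DirectedGraph`.

    Parameters
    ----------
    graph : DirectedGraph
    coefficients : mapping (tail, head) -> float, one entry per edge
    noises : a NoiseSpec applied to every node, or a mapping node -> NoiseSpec
    """

    def __init__(
        self,
        graph: DirectedGraph,
        coefficients: Mapping[tuple[str, str], float],
        noises: NoiseSpec | Mapping[str, NoiseSpec] | None = None,
    ) -> None:
        self.graph = graph
        coeffs = {(str(t), str(h)): float(v) for (t, h), v in coefficients.items()}
        if set(coeffs) != set(graph.edges):
            missing = set(graph.edges) - set(coeffs)
            extra = set(coeffs) - set(graph.edges)
            raise GraphError(
                f"coefficients must cover exactly the edges; missing={sorted(missing)}"
                f" extra={sorted(extra)}"
            )
        self.coefficients = coeffs
        if noises is None:
            noises = NoiseSpec()
        if isinstance(noises, NoiseSpec):
            noises = {v: noises for v in graph.nodes}
        self.noises = {v: noises[v] for v in graph.nodes}

    # -- algebra -----------------------------------------------------------
    @property
    def node_order(self) -> tuple[str, ...]:
        return self.graph.nodes

    def coefficient_matrix(self) -> np.ndarray:
        """B with B[i, j] = coefficient of node j in node i's equation."""
        order = self.node_order
        idx = {v: i for i, v in enumerate(order)}
        B = np.zeros((len(order), len(order)))
        for (t, h), b in self.coefficients.items():
            B[idx[h], idx[t]] = b
        return B

    def noise_variances(self) -> np.ndarray:
        return np.array([self.noises[v].var for v in self.node_order])

    def noise_mixing(self) -> pd.DataFrame:
        """A = (I - B)^-1: entry (v, j) is the loading of noise eps_j in the
        reduced form of node v."""
        B = self.coefficient_matrix()
        A = np.linalg.solve(np.eye(len(B)) - B, np.eye(len(B)))
        order = list(self.node_order)
        return pd.DataFrame(A, index=order, columns=order)

    def population_cov(self) -> pd.DataFrame:
        """Exact covariance Sigma = A Omega A^T over *all* nodes."""
        A = self.noise_mixing().to_numpy()
        omega = self.noise_variances()
        sigma = A @ np.diag(omega) @ A.T
        order = list(self.node_order)
        return pd.DataFrame(sigma, index=order, columns=order)

    def cross_cov(self, p_nodes, q_nodes) -> np.ndarray:
        sigma = self.population_cov()
        return sigma.loc[list(p_nodes), list(q_nodes)].to_numpy()

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, seed=0, *, observed_only: bool = True) -> pd.DataFrame:
        """Draw ``n`` i.i.d. rows by propagating noise through A.

        Noise columns are drawn in node order so a fixed seed reproduces the
        exact matrix.  Only observed columns are returned unless
        ``observed_only`` is False.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = as_rng(seed)
        order = self.node_order
        eps = np.column_stack([self.noises[v].draw(rng, n) for v in order])
        A = self.noise_mixing().to_numpy()
        data = eps @ A.T
        df = pd.DataFrame(data, columns=list(order))
        if observed_only:
            df = df[list(self.graph.observed)]
        return df

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"name": v, "latent": v in self.graph.latent} for v in self.node_order
            ],
            "edges": [
                {"tail": t, "head": h, "coefficient": b}
                for (t, h), b in self.coefficients.items()
            ],
            "noises": {
                v: {"family": s.family, "variance": s.var}
                for v, s in self.noises.items()
                if s.family != "custom"
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, spec: dict, *, seed=0) -> "LinearSEM":
        """Build from a plain mapping (e.g. parsed YAML/JSON).

        Edge coefficients may be numbers or the marker ``"random"``, drawn
        uniformly from [-2, -0.5] u [0.5, 2] with the given seed.
        """
        rng = as_rng(seed)
        nodes = [str(d["name"]) for d in spec["nodes"]]
        latent = [str(d["name"]) for d in spec["nodes"] if d.get("latent")]
        edges = [(str(d["tail"]), str(d["head"])) for d in spec["edges"]]
        graph = DirectedGraph(edges, latent=latent, nodes=nodes)
        coeffs = {}
        for d in spec["edges"]:
            val = d.get("coefficient", "random")
            if isinstance(val, str):
                if val != "random":
                    raise ValueError(f"bad coefficient marker {val!r}")
                val = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
            coeffs[(str(d["tail"]), str(d["head"]))] = float(val)
        noises: dict[str, NoiseSpec] = {}
        for v in nodes:
            ns = spec.get("noises", {}).get(v, {})
            noises[v] = NoiseSpec(
                family=ns.get("family", "squared_exponential"),
                variance=ns.get("variance"),
            )
        return cls(graph, coeffs, noises)

    @classmethod
    def from_yaml(cls, path, *, seed=0) -> "LinearSEM":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), seed=seed)
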