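"""Benchmark scenarios and worked-example mechanisms.

Three named scenarios (S1, S2, S3) define the simulation study's generative
setup: treatment X, outcome Y, latent confounders U1 (and U2), and candidate
instruments Z1..Z4 with known ground-truth validity:

* S1 — Z1 -> X, Z2 -> X, Z3 -> X, with U1 confounding Z1, X and Y.
  Z2 and Z3 are valid instruments given the empty set; Z1 is invalid
  (the trek Z1 <- U1 -> Y cannot be blocked by observed variables).
* S2 — S1 plus a second latent U2 -> Z3, U2 -> X, adding an active
  nondirected path between Z3 and X.  Ground truth unchanged.
* S3 — Z1 is valid only conditioning on Z3; Z2 is valid given the empty
  set; Z3 is invalid (direct edge Z3 -> Y and trek Z3 <- U1 -> Y); Z4 is
  invalid (a collider child X -> Z4 <- Y); U2 confounds X and Y.

Edge coefficients are drawn uniformly from [-2, -0.5] u [0.5, 2]; noise
terms are squared-exponential (centered squares of Exp(1) draws).  The
confounding strength between {X, Y} and U1 can be pinned to a level lambda,
and the treatment-outcome edge can be reversed (Y -> X) while keeping the
ground-truth labels — the selection algorithm is symmetric in X and Y.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graphs import DirectedGraph, load_fixture
from .sem import LinearSEM, NoiseSpec, as_rng

__all__ = [
    "ScenarioSpec",
    "get_scenario",
    "make_scenario",
    "reverse_target",
    "fig3_sem",
    "fig8_sem",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = ("S1", "S2", "S3")

# node -> minimal valid conditioning set, or None when the node is not a
# valid instrument for any conditioning set drawn from the observed pool.
_GROUND_TRUTH = {
    "S1": {"Z1": None, "Z2": (), "Z3": ()},
    "S2": {"Z1": None, "Z2": (), "Z3": ()},
    "S3": {"Z1": ("Z3",), "Z2": (), "Z3": None, "Z4": None},
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named benchmark graph with ground-truth instrument labels.

    ``lam`` pins the two confounder coefficients b_XU1 = b_YU1 (sensitivity
    task); ``reversed_target`` flips the X -> Y edge to Y -> X.  Coefficient
    magnitudes are drawn from [coef_low, coef_high] with random sign.
    """

    name: str
    lam: float | None = None
    reversed_target: bool = False
    coef_low: float = 0.5
    coef_high: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not 0 < self.coef_low < self.coef_high:
            raise ValueError("need 0 < coef_low < coef_high")

    @property
    def ground_truth(self) -> dict[str, tuple[str, ...] | None]:
        return dict(_GROUND_TRUTH[self.name])

    @property
    def valid_ivs(self) -> frozenset[str]:
        return frozenset(
            z for z, w in self.ground_truth.items() if w is not None
        )

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(sorted(self.ground_truth))

    @property
    def graph(self) -> DirectedGraph:
        g = load_fixture(self.name.lower())
        if self.reversed_target:
            edges = [("Y", "X") if e == ("X", "Y") else e for e in g.edges]
            g = DirectedGraph(edges, latent=g.latent, nodes=g.nodes)
        return g

    @property
    def target_edge(self) -> tuple[str, str]:
        return ("Y", "X") if self.reversed_target else ("X", "Y")


def get_scenario(name: str, *, lam: float | None = None,
                 reversed_target: bool = False) -> ScenarioSpec:
    return ScenarioSpec(name=name, lam=lam, reversed_target=reversed_target)


def reverse_target(spec: ScenarioSpec) -> ScenarioSpec:
    """Flip the direction of the treatment-outcome edge (an involution)."""
    return replace(spec, reversed_target=not spec.reversed_target)


def _draw_coefficient(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))


def make_scenario(spec: ScenarioSpec, seed=0) -> LinearSEM:
    """Instantiate a scenario as a concrete LinearSEM.

    Coefficients are drawn in the graph's fixed edge order from
    [-coef_high, -coef_low] u [coef_low, coef_high]; if ``spec.lam`` is set,
    the U1 -> X and U1 -> Y coefficients are overridden to lambda *after*
    drawing.  Noise is squared-exponential at every node.
    """
    rng = as_rng(seed)
    g = spec.graph
    coeffs = {
        e: _draw_coefficient(rng, spec.coef_low, spec.coef_high) for e in g.edges
    }
    if spec.lam is not None:
        for head in ("X", "Y"):
            if ("U1", head) in coeffs:
                coeffs[("U1", head)] = float(spec.lam)
    return LinearSEM(g, coeffs, NoiseSpec("squared_exponential"))


# ---------------------------------------------------------------------------
# Worked-example mechanisms (motivating demonstration, untestability example)
# ---------------------------------------------------------------------------

def fig3_sem(subgraph: str = "a", noise: str = "uniform") -> LinearSEM:
    """The two motivating four-node mechanisms.

    Subgraph (a): Z = eps_Z, X = 2 Z + 0.5 U1 + eps_X, Y = X + 2 U1 + eps_Y,
    where Z is a valid instrument.  Subgraph (b) adds Z = U1 + eps_Z,
    making Z invalid through the latent confounder.  ``noise`` selects the
    noise family at every node (the Gaussian/uniform contrast).
    """
    if subgraph not in ("a", "b"):
        raise ValueError("subgraph must be 'a' or 'b'")
    g = load_fixture("fig3a" if subgraph == "a" else "fig3b")
    coeffs = {("Z", "X"): 2.0, ("U1", "X"): 0.5, ("U1", "Y"): 2.0, ("X", "Y"): 1.0}
    if subgraph == "b":
        coeffs[("U1", "Z")] = 1.0
    return LinearSEM(g, coeffs, NoiseSpec(noise))


def fig8_sem(
    lam: float,
    *,
    alpha: float = 2.0,
    beta: float = 1.0,
    gamma: float = 0.5,
    delta: float = 2.0,
    noise: str = "uniform",
) -> LinearSEM:
    """The direct-edge (condition 2b) untestability mechanism:
    X = alpha Z + gamma U1 + eps_X, Y = beta X + delta U1 + lambda Z + eps_Y.

    Even for lambda != 0 (a directed path Z -> Y bypassing X) the surrogate
    of {Y, X} relative to Z carries no eps_Z component, so the GIN condition
    holds although Z is an invalid instrument.
    """
    g = load_fixture("fig8")
    if lam == 0:
        g = g.without_edge("Z", "Y")
    coeffs = {
        ("Z", "X"): alpha,
        ("U1", "X"): gamma,
        ("U1", "Y"): delta,
        ("X", "Y"): beta,
    }
    if lam != 0:
        coeffs[("Z", "Y")] = lam
    return LinearSEM(g, coeffs, NoiseSpec(noise))
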