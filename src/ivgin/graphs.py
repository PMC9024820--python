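"""Directed acyclic graphs with latent nodes and the graphical machinery of
instrumental-variable validity.

A :class:`DirectedGraph` is a DAG over named nodes, each flagged observed or
latent.  On top of it this module provides

* d-separation (:func:`d_separated`),
* exhaustive trek enumeration (:func:`treks_between`) — a *trek* is a path
  containing no collider,
* the classical (conditional) instrument criteria
  (:func:`instrument_criteria_holds`): ``Z`` is a valid instrument for the
  effect of treatment ``x`` on outcome ``y`` given a conditioning set ``w``
  iff ``w`` contains only nondescendants of ``y``, ``w`` d-separates ``z``
  from ``y`` once the ``x -> y`` edge is removed, and ``w`` does *not*
  d-separate ``z`` from ``x``,
* the trek-based graphical characterisation of the IV-GIN condition
  (:func:`ivgin_graphical_criterion`), which is what the population GIN
  oracle in :mod:`ivgin.gin` is provably equivalent to under faithfulness.

Graph fixtures for all worked examples ship as edge-list text files under
``ivgin/data/graphs`` and load via :func:`load_fixture`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import networkx as nx

__all__ = [
    "DirectedGraph",
    "Trek",
    "GraphError",
    "d_separated",
    "treks_between",
    "instrument_criteria_holds",
    "ivgin_graphical_criterion",
    "load_fixture",
    "FIXTURE_NAMES",
]


class GraphError(ValueError):
    """Invalid graph structure or unknown node identifier."""


@dataclass(frozen=True)
class Trek:
    """A collider-free path, stored as a node sequence plus edge orientations.

    ``forward[i]`` is True when the i-th step is the directed edge
    ``nodes[i] -> nodes[i+1]`` and False when it is ``nodes[i] <- nodes[i+1]``.
    """

    nodes: tuple[str, ...]
    forward: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.forward) != len(self.nodes) - 1:
            raise GraphError("orientation list must have one entry per edge")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def source(self) -> str:
        """The causally earliest node: every trek is of the form
        ``nodes[0] <- ... <- source -> ... -> nodes[-1]``."""
        for i, fwd in enumerate(self.forward):
            if fwd:
                return self.nodes[i]
        return self.nodes[-1]


class DirectedGraph:
    """A DAG over observed and latent nodes.

    Parameters
    ----------
    edges : iterable of (tail, head) pairs
    latent : iterable of node names flagged unobserved
    nodes : optional explicit node list (for isolated nodes / fixed order)
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        latent: Iterable[str] = (),
        nodes: Iterable[str] | None = None,
    ) -> None:
        edges = [(str(t), str(h)) for t, h in edges]
        seen: set[tuple[str, str]] = set()
        for t, h in edges:
            if t == h:
                raise GraphError(f"self-loop on {t!r}")
            if (t, h) in seen:
                raise GraphError(f"duplicate edge {t!r} -> {h!r}")
            seen.add((t, h))
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(str(v) for v in nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("edge set induces a directed cycle")
        self._dg = g
        self.latent = frozenset(str(v) for v in latent)
        unknown = self.latent - set(g.nodes)
        if unknown:
            raise GraphError(f"latent nodes not in graph: {sorted(unknown)}")
        self.nodes = tuple(g.nodes)
        self.edges = tuple(edges)

    # -- basic queries -----------------------------------------------------
    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(v for v in self.nodes if v not in self.latent)

    def __contains__(self, node: str) -> bool:
        return node in self._dg

    def parents(self, v: str) -> set[str]:
        self._check_nodes([v])
        return set(self._dg.predecessors(v))

    def children(self, v: str) -> set[str]:
        self._check_nodes([v])
        return set(self._dg.successors(v))

    def descendants(self, v: str) -> set[str]:
        """Strict descendants of ``v`` (``v`` excluded)."""
        self._check_nodes([v])
        return set(nx.descendants(self._dg, v))

    def ancestors(self, v: str) -> set[str]:
        self._check_nodes([v])
        return set(nx.ancestors(self._dg, v))

    def has_directed_path(self, a: str, b: str) -> bool:
        """True iff there is a directed path from ``a`` to ``b`` (including
        the trivial path ``a == b``)."""
        self._check_nodes([a, b])
        return nx.has_path(self._dg, a, b)

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self._dg))

    def without_edge(self, tail: str, head: str) -> "DirectedGraph":
        """A copy with the edge ``tail -> head`` removed.  If the edge is
        absent the graph is returned unchanged (nothing to remove)."""
        if (tail, head) not in set(self.edges):
            return self
        edges = [e for e in self.edges if e != (tail, head)]
        return DirectedGraph(edges, latent=self.latent, nodes=self.nodes)

    def to_networkx(self) -> nx.DiGraph:
        return self._dg.copy()

    def _check_nodes(self, vs: Iterable[str]) -> None:
        for v in vs:
            if v not in self._dg:
                raise GraphError(f"unknown node {v!r}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DirectedGraph({len(self.nodes)} nodes, {len(self.edges)} edges,"
            f" latent={sorted(self.latent)})"
        )

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_edgelist_text(cls, text: str) -> "DirectedGraph":
        """Parse the fixture format: one ``tail<TAB>head`` per line, with an
        optional ``# latent: U1 U2`` header and ``# nodes: ...`` for isolated
        nodes."""
        latent: list[str] = []
        nodes: list[str] | None = None
        edges: list[tuple[str, str]] = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("latent:"):
                    latent += body.split(":", 1)[1].split()
                elif body.lower().startswith("nodes:"):
                    nodes = body.split(":", 1)[1].split()
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise GraphError(f"malformed edge line: {raw!r}")
            edges.append((parts[0], parts[1]))
        return cls(edges, latent=latent, nodes=nodes)

    def to_edgelist_text(self) -> str:
        lines = []
        if self.latent:
            lines.append("# latent: " + " ".join(sorted(self.latent)))
        lines.append("# nodes: " + " ".join(self.nodes))
        lines += [f"{t}\t{h}" for t, h in self.edges]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# d-separation and treks
# ---------------------------------------------------------------------------

def _as_set(x) -> frozenset[str]:
    if isinstance(x, str):
        return frozenset([x])
    return frozenset(x)


def d_separated(g: DirectedGraph, a, b, s=()) -> bool:
    """Pearl's d-separation criterion: True iff every path between ``a`` and
    ``b`` is blocked given ``s``."""
    a, b, s = _as_set(a), _as_set(b), _as_set(s)
    g._check_nodes(a | b | s)
    if (a & b) or (a & s) or (b & s):
        raise GraphError("a, b, s must be pairwise disjoint")
    return nx.is_d_separator(g._dg, set(a), set(b), set(s))


def treks_between(g: DirectedGraph, a: str, b: str) -> list[Trek]:
    """All treks (collider-free paths) between ``a`` and ``b``, oriented from
    ``a`` to ``b``; both endpoints are part of each trek."""
    g._check_nodes([a, b])
    if a == b:
        raise GraphError("trek endpoints must differ")
    skeleton = nx.Graph()
    skeleton.add_nodes_from(g.nodes)
    skeleton.add_edges_from(g.edges)
    directed = set(g.edges)
    treks = []
    for path in nx.all_simple_paths(skeleton, a, b):
        forward = tuple(
            (path[i], path[i + 1]) in directed for i in range(len(path) - 1)
        )
        # collider at interior i: both incident edges point into path[i]
        if any(forward[i - 1] and not forward[i] for i in range(1, len(path) - 1)):
            continue
        treks.append(Trek(tuple(path), forward))
    return treks


# ---------------------------------------------------------------------------
# Instrument criteria (Definition-style) and the IV-GIN graphical criterion
# ---------------------------------------------------------------------------

def instrument_criteria_holds(g: DirectedGraph, z: str, w, x: str, y: str) -> bool:
    """Classical conditional-instrument criteria for ``z`` relative to the
    effect ``x -> y`` given conditioning set ``w``.

    All three conditions are graphical; they are *not* testable from data
    alone (that untestability is exactly what the GIN machinery quantifies).
    """
    w = _as_set(w)
    g._check_nodes({z, x, y} | w)
    if len({z, x, y}) != 3 or w & {z, x, y}:
        raise GraphError("z, x, y must be distinct and excluded from w")
    if w & g.descendants(y):
        return False
    if not d_separated(g.without_edge(x, y), {z}, {y}, w):
        return False
    if d_separated(g, {z}, {x}, w):
        return False
    return True


def _covers_trek(trek: Trek, blockers: frozenset[str]) -> bool:
    """True iff some node of ``blockers`` lies on ``trek`` and is causally no
    later than the trek's Vp endpoint (``trek.nodes[0]``).

    The Vp endpoint itself always qualifies when it is a blocker; any other
    node Vk qualifies iff its trek edge on the Vp side points away from Vk
    (i.e. Vk is causally earlier than Vp along the trek).
    """
    for i, node in enumerate(trek.nodes):
        if node not in blockers:
            continue
        if i == 0 or not trek.forward[i - 1]:
            return True
    return False


def _ivgin_conditions_1_2(
    g: DirectedGraph, z: str, w: frozenset[str], x: str, y: str
) -> str | None:
    """Search for a choke node C making conditions 1-2 of the trek criterion
    hold; returns the witness C or None.

    C ranges over *all* nodes (latent included, and possibly z itself — the
    directed-path case z -> y is covered only by C = z)."""
    p_side = frozenset({x, y}) | w
    q_side = frozenset({z}) | w
    pairs = [
        (vp, vq) for vp in sorted(p_side) for vq in sorted(q_side) if vp != vq
    ]
    trek_cache = {pair: treks_between(g, *pair) for pair in pairs}
    for c in g.nodes:
        if c in w:
            continue
        blockers = frozenset({c}) | w
        if not all(
            _covers_trek(trek, blockers)
            for pair in pairs
            for trek in trek_cache[pair]
        ):
            continue
        if any(
            g.has_directed_path(v, x) or g.has_directed_path(v, y)
            for v in blockers
        ):
            return c
    return None


def ivgin_graphical_criterion(
    g: DirectedGraph, z: str, w, x: str, y: str, *, return_witness: bool = False
):
    """Graphical characterisation of ``[z || w]`` satisfying the IV-GIN
    condition *minimally* (no proper subset of ``w`` also satisfies it).

    Holds iff some node C exists such that (1) every trek between the
    ``{x, y} | w`` side and the ``{z} | w`` side passes through a node of
    ``{C} | w`` causally earlier than (or equal to) its p-side endpoint,
    (2) some node of ``{C} | w`` has a directed path to ``x`` or ``y``, and
    (3) no proper subset of ``w`` satisfies (1)-(2).
    """
    w = _as_set(w)
    g._check_nodes({z, x, y} | w)
    if len({z, x, y}) != 3 or w & {z, x, y}:
        raise GraphError("z, x, y must be distinct and excluded from w")
    witness = _ivgin_conditions_1_2(g, z, w, x, y)
    if witness is None:
        return (False, None) if return_witness else False
    for k in range(len(w)):
        for sub in itertools.combinations(sorted(w), k):
            if _ivgin_conditions_1_2(g, z, frozenset(sub), x, y) is not None:
                return (False, None) if return_witness else False
    return (True, witness) if return_witness else True


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "fig1",
    "fig2",
    "fig3a",
    "fig3b",
    "fig5",
    "fig6",
    "fig7",
    "fig8",
    "s1",
    "s2",
    "s3",
)


def load_fixture(name: str) -> DirectedGraph:
    """Load one of the shipped example graphs by name (see FIXTURE_NAMES)."""
    if name not in FIXTURE_NAMES:
        raise GraphError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = (
        resources.files("ivgin").joinpath(f"data/graphs/{name}.tsv").read_text()
    )
    return DirectedGraph.from_edgelist_text(text)
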