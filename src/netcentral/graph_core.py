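"""Graph construction, canonical families, and the saturation operator.

Graphs are plain :class:`networkx.Graph` objects restricted to the simple
undirected case (no self-loops, no parallel edges).  The canonical families
— star, ring, complete, and their single-edge perturbations — are the
deterministic benchmark topologies used by the numerical battery: the
perturbation of each family is fixed once (which edge is rewired or
removed) so that every result in this package is reproducible without a
random seed.

Node labels produced here are contiguous integers starting at 0.  Arbitrary
hashable labels are accepted everywhere else in the package; they are only
renumbered internally where a dense adjacency matrix is needed.
"""

from __future__ import annotations

import itertools
from typing import Hashable, Iterator, Mapping

import networkx as nx

__all__ = [
    "FAMILIES",
    "enumerate_labeled_graphs",
    "is_saturated",
    "largest_component",
    "make_complete",
    "make_family",
    "make_ring",
    "make_star",
    "perturb_complete",
    "perturb_ring",
    "perturb_star",
    "relabel",
    "saturate",
]

#: family id -> (generator, minimum admissible order)
FAMILIES: dict[str, tuple] = {}


def _family(name: str, min_n: int):
    def deco(fn):
        FAMILIES[name] = (fn, min_n)
        return fn

    return deco


def _check_order(n: int, min_n: int, what: str) -> None:
    if not isinstance(n, (int,)) or isinstance(n, bool):
        raise TypeError(f"{what}: n must be an integer, got {n!r}")
    if n < min_n:
        raise ValueError(f"{what}: requires n >= {min_n}, got n={n}")


@_family("star", 1)
def make_star(n: int) -> nx.Graph:
    """Star graph on ``n`` nodes: node 0 adjacent to every other node.

    The star is the canonical maximally centralized topology; ``n=1`` is the
    degenerate single-node star.
    """
    _check_order(n, 1, "make_star")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((0, i) for i in range(1, n))
    return g


@_family("ring", 3)
def make_ring(n: int) -> nx.Graph:
    """Cycle graph on ``n >= 3`` nodes; every degree equals 2."""
    _check_order(n, 3, "make_ring")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, (i + 1) % n) for i in range(n))
    return g


@_family("complete", 1)
def make_complete(n: int) -> nx.Graph:
    """Complete graph on ``n`` nodes; every node is saturated."""
    _check_order(n, 1, "make_complete")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(itertools.combinations(range(n), 2))
    return g


@_family("perturbed_star", 4)
def perturb_star(n: int) -> nx.Graph:
    """Star with one edge rewired: (0,2) removed, (1,2) added.

    The hub keeps degree ``n-2``; node 2 hangs off leaf 1.  For ``n=6`` this
    is the edge list [(0,1),(0,3),(0,4),(0,5),(1,2)].
    """
    _check_order(n, 4, "perturb_star")
    g = make_star(n)
    g.remove_edge(0, 2)
    g.add_edge(1, 2)
    return g


@_family("perturbed_ring", 4)
def perturb_ring(n: int) -> nx.Graph:
    """Ring with one edge rewired: (0, n-1) removed, (1, n-1) added.

    Degree sequence: one node of degree 1, one of degree 3, the rest 2.
    """
    _check_order(n, 4, "perturb_ring")
    g = make_ring(n)
    g.remove_edge(0, n - 1)
    g.add_edge(1, n - 1)
    return g


@_family("perturbed_complete", 3)
def perturb_complete(n: int) -> nx.Graph:
    """Complete graph with the single edge (0,1) removed."""
    _check_order(n, 3, "perturb_complete")
    g = make_complete(n)
    g.remove_edge(0, 1)
    return g


def make_family(family: str, n: int) -> nx.Graph:
    """Build graph ``family`` at order ``n`` (see :data:`FAMILIES`)."""
    try:
        fn, _ = FAMILIES[family]
    except KeyError:
        raise KeyError(f"unknown graph family {family!r}; known: {sorted(FAMILIES)}")
    return fn(n)


def is_saturated(g: nx.Graph, v: Hashable) -> bool:
    """True iff ``v`` is adjacent to every other node (degree n-1)."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return g.degree(v) == g.number_of_nodes() - 1


def saturate(g: nx.Graph, v: Hashable) -> nx.Graph:
    """Return a copy of ``g`` with node ``v`` connected to all other nodes.

    Saturating an already-saturated node is rejected: the postulates that use
    this operator (P5/P6) are stated for non-saturated targets only.
    """
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    if is_saturated(g, v):
        raise ValueError(f"node {v!r} is already saturated")
    y = g.copy()
    y.add_edges_from((v, u) for u in g.nodes() if u != v and not g.has_edge(v, u))
    return y


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties are broken by the smallest node label contained in the component, so
    the result is deterministic for any input.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("largest_component: empty node set")
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return g.subgraph(comps[0]).copy()


def enumerate_labeled_graphs(n: int) -> Iterator[nx.Graph]:
    """Yield all ``2^(n(n-1)/2)`` labeled simple graphs on nodes 0..n-1.

    Deterministic order: edge pairs in lexicographic order, subsets by
    increasing bitmask.  Capped at ``n=6`` (32768 graphs) — beyond that the
    corpus is no longer desk-scale.
    """
    if not 1 <= n <= 6:
        raise ValueError(f"enumerate_labeled_graphs: 1 <= n <= 6 required, got {n}")
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(1 << len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if mask >> i & 1)
        yield g


def relabel(g: nx.Graph, permutation: Mapping[Hashable, Hashable]) -> nx.Graph:
    """Relabel nodes through a bijection over exactly the nodes of ``g``."""
    if set(permutation) != set(g.nodes()) or len(set(permutation.values())) != len(
        permutation
    ):
        raise ValueError("relabel: mapping must be a bijection on the graph's nodes")
    return nx.relabel_nodes(g, dict(permutation), copy=True)
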