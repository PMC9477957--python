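"""Coloring characterizations of proper forest-based networks.

For a network N let RH(N) be its roots and hybrids and, for any vertex v,
let gamma(v) be the nearest root-or-hybrid ancestor of v (v itself when v
is one).  The undirected graph Gamma(N) on RH(N) has one edge per hybrid
h: {gamma(u'), gamma(v')} for u', v' the parents of h (a loop when the two
coincide).  An *omni-extension* of Gamma(N) adds, for every omnian v (a
vertex all of whose children are hybrids), an edge {gamma(u), h} for some
hybrid child h of v, with u the other parent of h.

An m-rooted network (m >= 2) is proper forest-based iff some
omni-extension admits a proper vertex coloring with m colors such that
(C1) the roots receive m distinct colors and (C2) every hybrid shares its
color with a root from which it is reachable by a directed path whose
hybrids all carry that color.  For m = 2 this reduces to: Gamma(N) has a
bipartite omni-extension.

Only *minimal* omni-extensions (one added edge per omnian) are searched: a
coloring that is proper on a larger extension is proper on any contained
one, and C1/C2 do not depend on the extension, so a witness coloring on
some extension restricts to a witness on a minimal one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx

from .netcore import Network, vertex_roles

__all__ = [
    "GammaGraph",
    "RHColoring",
    "gamma_graph",
    "minimal_omni_extensions",
    "find_C1C2_coloring",
    "is_proper_via_coloring",
    "has_bipartite_omni_extension",
    "is_bipartite",
    "gamma_graph_of_forest",
]

Edge = frozenset  # frozenset of 1 (loop) or 2 vertices


@dataclass(frozen=True)
class GammaGraph:
    """Undirected graph on RH(N); loops permitted (size-1 edges)."""

    vertices: frozenset[str]
    edges: frozenset[frozenset[str]]

    def has_loop(self) -> bool:
        return any(len(e) == 1 for e in self.edges)

    def to_nx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for e in self.edges:
            if len(e) == 1:
                (v,) = e
                g.add_edge(v, v)
            else:
                u, v = e
                g.add_edge(u, v)
        return g

    def is_supergraph_of(self, other: "GammaGraph") -> bool:
        return self.vertices == other.vertices and other.edges <= self.edges


@dataclass(frozen=True)
class RHColoring:
    """A coloring of RH(N); colors are the roots themselves, the root
    sigma(r) = r convention breaking the color-permutation symmetry."""

    color: Mapping[str, str]

    def classes(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for v, c in self.color.items():
            out.setdefault(c, set()).add(v)
        return {c: frozenset(s) for c, s in out.items()}


def gamma_graph(net: Network) -> GammaGraph:
    """Build Gamma(N).  Strict networks pair the two parents of each
    hybrid; in relaxed mode all parent pairs of a higher-indegree hybrid
    contribute edges (the natural generalization)."""
    roles = vertex_roles(net)
    gamma = roles.gamma
    edges: set[frozenset[str]] = set()
    for h in sorted(net.hybrids):
        for u, v in itertools.combinations(net.parents(h), 2):
            edges.add(frozenset({gamma[u], gamma[v]}))
    return GammaGraph(roles.rh_set, frozenset(edges))


def minimal_omni_extensions(net: Network) -> list[GammaGraph]:
    """All distinct omni-extensions obtained by adding exactly one edge
    per omnian (one choice of hybrid child each); Gamma(N) itself when
    there are no omnians."""
    base = gamma_graph(net)
    roles = vertex_roles(net)
    gamma = roles.gamma
    omnians = sorted(roles.omnians)
    if not omnians:
        return [base]
    if net.mode != "strict":
        # "the second parent" of an omnian's hybrid child is ambiguous
        # beyond indegree two
        raise ValueError("omni-extensions of omnian-bearing networks require strict mode")
    per_omnian: list[list[frozenset[str]]] = []
    for v in omnians:
        opts = []
        for h in net.children(v):
            (u,) = [p for p in net.parents(h) if p != v]
            opts.append(frozenset({gamma[u], h}))
        per_omnian.append(opts)
    seen: set[frozenset[frozenset[str]]] = set()
    out: list[GammaGraph] = []
    for combo in itertools.product(*per_omnian):
        edges = base.edges | frozenset(combo)
        if edges not in seen:
            seen.add(edges)
            out.append(GammaGraph(base.vertices, edges))
    return out


def is_bipartite(g: GammaGraph) -> bool:
    if g.has_loop():
        return False
    return nx.is_bipartite(g.to_nx())


def find_C1C2_coloring(
    net: Network, extension: GammaGraph
) -> Optional[RHColoring]:
    """Search for a proper coloring of the omni-extension satisfying C1
    and C2; None when none exists.

    Roots are pre-assigned distinct colors (themselves, in sorted order);
    hybrid colors are filled in by backtracking, pruning on properness,
    with C2 checked on complete assignments by per-color reachability."""
    if net.mode != "strict":
        raise ValueError("coloring search requires a strict network")
    roots = sorted(net.roots)
    m = len(roots)
    if m < 2:
        raise ValueError("coloring characterization needs at least two roots")
    base = gamma_graph(net)
    if not extension.is_supergraph_of(base):
        raise ValueError("extension is not a supergraph of Gamma(N)")
    if extension.has_loop():
        return None

    adj: dict[str, set[str]] = {v: set() for v in extension.vertices}
    for e in extension.edges:
        if len(e) == 2:
            u, v = e
            adj[u].add(v)
            adj[v].add(u)

    color: dict[str, str] = {r: r for r in roots}
    hybrids = sorted(net.hybrids)

    def c2_holds() -> bool:
        for r in roots:
            same = [h for h in hybrids if color[h] == r]
            if not same:
                continue
            # delete hybrids of other colors, test reachability from r
            allowed = set(net.vertices) - {
                h for h in hybrids if color[h] != r
            }
            seen = {r}
            stack = [r]
            while stack:
                u = stack.pop()
                for c in net.children(u):
                    if c in allowed and c not in seen:
                        seen.add(c)
                        stack.append(c)
            if any(h not in seen for h in same):
                return False
        return True

    def rec(i: int) -> bool:
        if i == len(hybrids):
            return c2_holds()
        h = hybrids[i]
        for r in roots:
            if any(color.get(n) == r for n in adj[h]):
                continue
            color[h] = r
            if rec(i + 1):
                return True
            del color[h]
        return False

    # properness among pre-colored roots
    for r in roots:
        if any(color.get(n) == r for n in adj[r] if n in color):
            return None
    if rec(0):
        return RHColoring(dict(color))
    return None


def is_proper_via_coloring(net: Network) -> tuple[bool, Optional[tuple[GammaGraph, RHColoring]]]:
    """Decide proper forest-basedness by the coloring criterion over all
    minimal omni-extensions."""
    for ext in minimal_omni_extensions(net):
        col = find_C1C2_coloring(net, ext)
        if col is not None:
            return True, (ext, col)
    return False, None


def has_bipartite_omni_extension(net: Network) -> bool:
    """2-rooted criterion: true iff some minimal omni-extension of
    Gamma(N) is bipartite.

    Decides proper forest-basedness for strict networks only; relaxed
    networks are accepted as a graph-level diagnostic (their higher-
    indegree hybrids are why the criterion fails to characterize)."""
    if len(net.roots) != 2:
        raise ValueError("bipartite criterion applies to 2-rooted networks")
    return any(is_bipartite(ext) for ext in minimal_omni_extensions(net))


def gamma_graph_of_forest(
    net: Network, component_of: Mapping[str, int]
) -> GammaGraph:
    """Gamma_F(N): edges between root-or-hybrid vertices lying in
    different trees of a (proper) base forest, given the component index
    of each vertex of the embedded forest."""
    rh = vertex_roles(net).rh_set
    edges = {
        frozenset({u, v})
        for u, v in itertools.combinations(sorted(rh), 2)
        if component_of[u] != component_of[v]
    }
    return GammaGraph(rh, frozenset(edges))
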