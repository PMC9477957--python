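"""Core data model for multiply-rooted phylogenetic networks.

A *network* here is a semi-binary, connected, acyclic digraph whose
outdegree-0 vertices carry the leaf labels (the taxon set ``X``) and whose
every root has outdegree at least two.  Networks with more than one root
arise naturally when reticulate events (lateral gene transfer,
introgression) connect separate lineages, each lineage contributing its own
root.  This module provides validation, vertex-role queries (root / tree /
hybrid / leaf, omnians, the nearest root-or-hybrid ancestor), induced
cluster systems, spanning forests and their suppression to phylogenetic
forests, and leaf-label-preserving equivalence.

Vertex identifiers are plain strings; leaf identifiers *are* the labels of
``X``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Network",
    "VertexRoleTable",
    "SpanningForest",
    "PhylogeneticForest",
    "InvalidNetworkError",
    "validate_network",
    "validation_report",
    "vertex_roles",
    "cluster_system",
    "are_equivalent",
    "suppress",
]

Arc = tuple[str, str]


class InvalidNetworkError(ValueError):
    """Raised when a vertex/arc collection violates the network axioms.

    ``violations`` is a list of ``(rule, offender)`` pairs, one per broken
    rule, where ``offender`` names the vertex or arc at fault (or ``None``
    for global failures such as disconnectedness).
    """

    def __init__(self, violations: list[tuple[str, object]]):
        self.violations = violations
        msg = "; ".join(
            f"{rule}: {offender}" if offender is not None else rule
            for rule, offender in violations
        )
        super().__init__(f"invalid network: {msg}")


@dataclass(frozen=True)
class Network:
    """An m-rooted phylogenetic network (validated; construct via
    :func:`validate_network`)."""

    vertices: frozenset[str]
    arcs: frozenset[Arc]
    mode: str = "strict"

    # -- cached adjacency ------------------------------------------------
    def __post_init__(self):
        children: dict[str, tuple[str, ...]] = {v: () for v in self.vertices}
        parents: dict[str, tuple[str, ...]] = {v: () for v in self.vertices}
        for u, v in sorted(self.arcs):
            children[u] = children[u] + (v,)
            parents[v] = parents[v] + (u,)
        object.__setattr__(self, "_children", children)
        object.__setattr__(self, "_parents", parents)

    def children(self, v: str) -> tuple[str, ...]:
        return self._children[v]

    def parents(self, v: str) -> tuple[str, ...]:
        return self._parents[v]

    def indeg(self, v: str) -> int:
        return len(self._parents[v])

    def outdeg(self, v: str) -> int:
        return len(self._children[v])

    @property
    def leaves(self) -> frozenset[str]:
        """The label set X (outdegree-0 vertices; a single-vertex network
        is its own leaf)."""
        return frozenset(v for v in self.vertices if self.outdeg(v) == 0)

    @property
    def roots(self) -> frozenset[str]:
        if len(self.vertices) == 1:
            return frozenset(self.vertices)
        return frozenset(
            v for v in self.vertices if self.indeg(v) == 0
        )

    @property
    def hybrids(self) -> frozenset[str]:
        return frozenset(v for v in self.vertices if self.indeg(v) >= 2)

    @property
    def tree_vertices(self) -> frozenset[str]:
        """Vertices of indegree one, leaves included."""
        return frozenset(v for v in self.vertices if self.indeg(v) == 1)

    @property
    def rh_set(self) -> frozenset[str]:
        return self.roots | self.hybrids

    def is_binary(self) -> bool:
        for v in self.vertices:
            if self.indeg(v) >= 2 and (self.indeg(v) != 2 or self.outdeg(v) != 1):
                return False
            if self.indeg(v) <= 1 and self.outdeg(v) not in (0, 2):
                return False
        return True

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.arcs)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_digraph()))

    def descendants(self, v: str) -> frozenset[str]:
        """All vertices below v, v included."""
        seen = {v}
        stack = [v]
        while stack:
            u = stack.pop()
            for c in self.children(u):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return frozenset(seen)

    def is_arboreal(self) -> bool:
        """True iff the underlying undirected graph is a tree."""
        return len(self.arcs) == len(self.vertices) - 1

    def relabel(self, mapping: Mapping[str, str]) -> "Network":
        """Rename vertices (injective map; identity where omitted)."""
        f = lambda v: mapping.get(v, v)
        return Network(
            frozenset(f(v) for v in self.vertices),
            frozenset((f(u), f(v)) for u, v in self.arcs),
            self.mode,
        )


def validation_report(
    vertices: Iterable[str], arcs: Iterable[Arc], mode: str = "strict"
) -> list[tuple[str, object]]:
    """Check the network axioms; return a list of (rule, offender) pairs,
    empty iff the input is a valid network in the given mode."""
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    vs = set(vertices)
    ars = list(arcs)
    out: list[tuple[str, object]] = []
    seen_arcs: set[Arc] = set()
    for a in ars:
        u, v = a
        vs.add(u)
        vs.add(v)
        if u == v:
            out.append(("loop", a))
        if a in seen_arcs:
            out.append(("parallel_arc", a))
        seen_arcs.add(a)
    if not vs:
        return [("empty_graph", None)]
    if out:  # degenerate arcs make degree bookkeeping meaningless
        return out

    indeg = {v: 0 for v in vs}
    outdeg = {v: 0 for v in vs}
    for u, v in seen_arcs:
        outdeg[u] += 1
        indeg[v] += 1

    g = nx.DiGraph()
    g.add_nodes_from(vs)
    g.add_edges_from(seen_arcs)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        out.append(("cyclic", tuple(e[:2] for e in cyc)))
    if not nx.is_weakly_connected(g):
        out.append(("disconnected", None))

    single = len(vs) == 1
    for v in sorted(vs):
        if outdeg[v] == 0 and indeg[v] >= 2:
            out.append(("leaf_indegree", v))
        if indeg[v] == 0 and not single and outdeg[v] <= 1:
            out.append(("root_outdegree", v))
        if indeg[v] >= 2:
            if mode == "strict" and (indeg[v] != 2 or outdeg[v] != 1):
                out.append(("hybrid_degree", v))
            if mode == "relaxed" and outdeg[v] == 0:
                # covered by leaf_indegree, nothing extra
                pass
        if mode == "strict" and indeg[v] == 1 and outdeg[v] == 1:
            out.append(("unary_tree_vertex", v))
    return out


def validate_network(
    vertices: Iterable[str], arcs: Iterable[Arc], mode: str = "strict"
) -> Network:
    """Build a :class:`Network`, raising :class:`InvalidNetworkError` (with
    the full rule-by-rule report attached) if any axiom fails."""
    vs = set(vertices)
    ars = set(arcs)
    for u, v in ars:
        vs.add(u)
        vs.add(v)
    report = validation_report(vs, ars, mode)
    if report:
        raise InvalidNetworkError(report)
    return Network(frozenset(vs), frozenset(ars), mode)


@dataclass(frozen=True)
class VertexRoleTable:
    """Per-vertex roles, omnian flags and the nearest root-or-hybrid
    ancestor (gamma) of every vertex."""

    role: Mapping[str, str]  # root | leaf | tree | hybrid
    omnian: Mapping[str, bool]
    gamma: Mapping[str, str]
    rh_set: frozenset[str]

    @property
    def omnians(self) -> frozenset[str]:
        return frozenset(v for v, f in self.omnian.items() if f)


def vertex_roles(net: Network) -> VertexRoleTable:
    """Classify every vertex and compute gamma.

    gamma(v) is found by walking the unique tree-vertex parent chain
    upwards until the first root or hybrid; gamma(v) = v for v itself a
    root or hybrid.
    """
    role: dict[str, str] = {}
    single = len(net.vertices) == 1
    for v in net.vertices:
        if net.indeg(v) == 0:
            role[v] = "root"
        elif net.indeg(v) >= 2:
            role[v] = "hybrid"
        elif net.outdeg(v) == 0:
            role[v] = "leaf"
        else:
            role[v] = "tree"
    rh = frozenset(v for v, r in role.items() if r in ("root", "hybrid"))

    hybrids = net.hybrids
    omnian = {
        v: net.outdeg(v) >= 1 and all(c in hybrids for c in net.children(v))
        for v in net.vertices
    }

    gamma: dict[str, str] = {}
    for v in net.vertices:
        u = v
        while u not in rh:
            (u,) = net.parents(u)  # tree vertices have a unique parent
        gamma[v] = u
    return VertexRoleTable(role, omnian, gamma, rh)


def cluster_system(net: Network) -> tuple[dict[str, frozenset[str]], frozenset[frozenset[str]]]:
    """Per-vertex induced clusters and the cluster system C(N).

    cluster(u) is the set of leaves below u (u itself when u is a leaf);
    C(N) is the set of distinct clusters, all non-empty.
    """
    leaves = net.leaves
    cl: dict[str, frozenset[str]] = {}
    for v in reversed(net.topological_order()):
        if v in leaves:
            cl[v] = frozenset({v})
        else:
            acc: set[str] = set()
            for c in net.children(v):
                acc |= cl[c]
            cl[v] = frozenset(acc)
    return cl, frozenset(cl.values())


def are_equivalent(n1: Network, n2: Network) -> bool:
    """Leaf-label-preserving digraph isomorphism.

    True iff there is an isomorphism between the two digraphs that is the
    identity on the shared label set X (VF2 with leaf labels pinned)."""
    if n1.leaves != n2.leaves:
        return False
    if len(n1.vertices) != len(n2.vertices) or len(n1.arcs) != len(n2.arcs):
        return False
    g1, g2 = n1.to_digraph(), n2.to_digraph()
    for g, net in ((g1, n1), (g2, n2)):
        for v in g.nodes:
            g.nodes[v]["label"] = v if v in net.leaves else None
            g.nodes[v]["deg"] = (net.indeg(v), net.outdeg(v))
    nm = nx.algorithms.isomorphism.categorical_node_match(["label", "deg"], [None, None])
    return nx.is_isomorphic(g1, g2, node_match=nm)


# ---------------------------------------------------------------------------
# Spanning forests and phylogenetic forests


@dataclass(frozen=True)
class SpanningForest:
    """A subgraph (V, A') of a host network in which every vertex has
    indegree at most one; each component is a rooted tree (possibly a
    single vertex)."""

    vertices: frozenset[str]
    arcs: frozenset[Arc]

    def __post_init__(self):
        indeg: dict[str, int] = {v: 0 for v in self.vertices}
        for u, v in self.arcs:
            indeg[v] += 1
            if indeg[v] > 1:
                raise ValueError(f"vertex {v!r} has indegree > 1 in forest")

    def components(self) -> list[frozenset[str]]:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.arcs)
        return sorted(
            (frozenset(c) for c in nx.connected_components(g)),
            key=lambda c: min(c),
        )

    def component_index(self) -> dict[str, int]:
        idx: dict[str, int] = {}
        for i, comp in enumerate(self.components()):
            for v in comp:
                idx[v] = i
        return idx

    def leaves(self) -> frozenset[str]:
        outdeg = {v: 0 for v in self.vertices}
        for u, _ in self.arcs:
            outdeg[u] += 1
        return frozenset(v for v in self.vertices if outdeg[v] == 0)


class PhylogeneticForest:
    """A set of leaf-disjoint rooted phylogenetic trees covering a label
    set X, stored canonically: each tree is its hierarchy (the set of
    clusters it induces).

    A phylogenetic forest proper has at least two trees; ``allow_single``
    admits the one-tree variant used for base-tree interoperability.
    """

    def __init__(
        self,
        trees: Iterable[Iterable[Iterable[str]]],
        allow_single: bool = False,
    ):
        canon: set[frozenset[frozenset[str]]] = set()
        for tree in trees:
            canon.add(frozenset(frozenset(c) for c in tree))
        self.trees: frozenset[frozenset[frozenset[str]]] = frozenset(canon)
        if not self.trees:
            raise ValueError("empty forest")
        if len(self.trees) < 2 and not allow_single:
            raise ValueError("a phylogenetic forest needs at least two trees")
        label_sets = [frozenset().union(*t) for t in self.trees]
        union: set[str] = set()
        for ls in label_sets:
            if union & ls:
                raise ValueError("tree leaf sets are not pairwise disjoint")
            union |= ls
        self.label_set: frozenset[str] = frozenset(union)
        for tree, ls in zip(self.trees, label_sets):
            _check_hierarchy_on(tree, ls)

    def __eq__(self, other) -> bool:
        return isinstance(other, PhylogeneticForest) and self.trees == other.trees

    def __hash__(self) -> int:
        return hash(self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __repr__(self) -> str:
        parts = []
        for t in sorted(self.trees, key=lambda t: sorted(map(sorted, t))):
            parts.append("{" + ",".join(sorted("".join(sorted(c)) for c in t)) + "}")
        return f"PhylogeneticForest({'; '.join(parts)})"

    @classmethod
    def trivial(cls, labels: Iterable[str]) -> "PhylogeneticForest":
        """The forest in which every component is a single labelled vertex."""
        labs = sorted(set(labels))
        if len(labs) < 2:
            raise ValueError("trivial forest needs at least two labels")
        return cls([[{x}] for x in labs])


def _check_hierarchy_on(clusters: frozenset[frozenset[str]], labels: frozenset[str]):
    if labels not in clusters:
        raise ValueError("tree hierarchy lacks its full leaf set")
    for x in labels:
        if frozenset({x}) not in clusters:
            raise ValueError("tree hierarchy lacks a trivial cluster")
    for c in clusters:
        if not c or not c <= labels:
            raise ValueError("cluster outside label set")
    for c1, c2 in itertools.combinations(clusters, 2):
        inter = c1 & c2
        if inter and inter != c1 and inter != c2:
            raise ValueError(f"clusters {sorted(c1)} and {sorted(c2)} overlap")


def suppress(forest: SpanningForest, labels: frozenset[str]) -> PhylogeneticForest:
    """Reduce each component of a spanning forest to the phylogenetic tree
    it subdivides, returning the canonical base forest.

    Suppression of subdivision vertices and outdegree-one roots is
    implicit: a tree's hierarchy has one cluster per *branching* point and
    leaf, so unary vertices contribute nothing.  Raises ValueError if some
    component has a leaf outside ``labels`` (the subdivision forest does
    not preserve the host's leaf set)."""
    bad = forest.leaves() - labels
    if bad:
        raise ValueError(f"forest leaves {sorted(bad)} are not labels of X")
    children: dict[str, list[str]] = {v: [] for v in forest.vertices}
    indeg = {v: 0 for v in forest.vertices}
    for u, v in forest.arcs:
        children[u].append(v)
        indeg[v] += 1

    cl: dict[str, frozenset[str]] = {}

    def cluster(v: str) -> frozenset[str]:
        if v not in cl:
            if not children[v]:
                cl[v] = frozenset({v})
            else:
                acc: set[str] = set()
                for c in children[v]:
                    acc |= cluster(c)
                cl[v] = frozenset(acc)
        return cl[v]

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(forest.vertices) * 2 + 100))
    try:
        trees = []
        for comp in forest.components():
            trees.append({cluster(v) for v in comp})
    finally:
        sys.setrecursionlimit(old)
    return PhylogeneticForest(trees, allow_single=True)
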