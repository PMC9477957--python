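"""Cluster systems and the reconstruction of arboreal networks.

Every vertex u of a network induces the cluster C(u) of leaves below it;
the cluster system C(N) collects the distinct clusters.  For *arboreal*
networks (underlying graph a tree) the cluster system characterizes the
network up to a local ambiguity: C(N) is realizable by an arboreal
network iff

* (P1) for each inclusion-maximal cluster C, the clusters inside C form a
  hierarchy containing all trivial clusters on C;
* (P2) the intersection graph of the maximal clusters is connected;
* (P3) the intersection of any two maximal clusters is itself a cluster
  (or empty);

and the realization is unique up to equivalence iff the network has no
*bad arc* (an arc joining two hybrids), which happens iff no three
maximal clusters have equal pairwise non-empty intersections.  Two
arboreal networks share a cluster system iff they become equivalent after
collapsing all bad arcs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .netcore import (
    Arc,
    Network,
    are_equivalent,
    cluster_system,
    validate_network,
)

__all__ = [
    "ClusterSystem",
    "P123Report",
    "is_hierarchy",
    "maximal_clusters",
    "check_P123",
    "build_arboreal_network",
    "bad_arcs",
    "collapse_bad_arcs",
    "is_uniquely_determined",
    "same_clusters_iff_collapse_equivalent",
    "ClusterSystemError",
]


class ClusterSystemError(ValueError):
    """The cluster system does not satisfy the preconditions of the
    arboreal construction (the failed properties are attached)."""

    def __init__(self, report: "P123Report", message: str):
        self.report = report
        super().__init__(message)


@dataclass(frozen=True)
class ClusterSystem:
    """A collection of non-empty subsets (clusters) of a ground set X."""

    ground_set: frozenset[str]
    clusters: frozenset[frozenset[str]]

    def __post_init__(self):
        for c in self.clusters:
            if not c:
                raise ValueError("clusters must be non-empty")
            if not c <= self.ground_set:
                raise ValueError(f"cluster {sorted(c)} outside the ground set")

    @classmethod
    def from_network(cls, net: Network) -> "ClusterSystem":
        _, cs = cluster_system(net)
        return cls(net.leaves, cs)

    @classmethod
    def of(cls, *clusters: Iterable[str], ground_set=None) -> "ClusterSystem":
        cl = frozenset(frozenset(c) for c in clusters)
        gs = frozenset(ground_set) if ground_set is not None else frozenset().union(*cl)
        return cls(gs, cl)

    def has_all_trivial(self) -> bool:
        return all(frozenset({x}) in self.clusters for x in self.ground_set)


def is_hierarchy(cs: ClusterSystem) -> bool:
    """True iff pairwise intersections are nested or disjoint and the
    system contains every trivial cluster and the full ground set."""
    if frozenset(cs.ground_set) not in cs.clusters or not cs.has_all_trivial():
        return False
    for c1, c2 in itertools.combinations(cs.clusters, 2):
        if c1 & c2 not in (c1, c2, frozenset()):
            return False
    return True


def maximal_clusters(cs: ClusterSystem) -> frozenset[frozenset[str]]:
    """The set-inclusion maximal elements C_M of the system."""
    return frozenset(
        c
        for c in cs.clusters
        if not any(c < d for d in cs.clusters)
    )


@dataclass(frozen=True)
class P123Report:
    p1: bool
    p2: bool
    p3: bool
    witnesses: dict = field(default_factory=dict)

    def all_ok(self) -> bool:
        return self.p1 and self.p2 and self.p3


def check_P123(cs: ClusterSystem) -> P123Report:
    """Evaluate the three arboreal realizability properties literally."""
    cm = sorted(maximal_clusters(cs), key=sorted)
    witnesses: dict = {}

    p1 = True
    for c in cm:
        inside = ClusterSystem(
            frozenset(c),
            frozenset(d for d in cs.clusters if d <= c),
        )
        if not is_hierarchy(inside):
            p1 = False
            witnesses["p1"] = tuple(sorted(c))
            break

    ig = nx.Graph()
    ig.add_nodes_from(range(len(cm)))
    for i, j in itertools.combinations(range(len(cm)), 2):
        if cm[i] & cm[j]:
            ig.add_edge(i, j)
    p2 = nx.is_connected(ig) if len(cm) > 0 else True
    if not p2:
        witnesses["p2"] = tuple(
            tuple(sorted(min((cm[i] for i in comp), key=sorted)))
            for comp in nx.connected_components(ig)
        )

    p3 = True
    for c1, c2 in itertools.combinations(cm, 2):
        inter = c1 & c2
        if inter and inter not in cs.clusters:
            p3 = False
            witnesses["p3"] = (tuple(sorted(c1)), tuple(sorted(c2)))
            break

    return P123Report(p1, p2, p3, witnesses)


# ---------------------------------------------------------------------------
# Construction


def _tree_arcs_from_hierarchy(
    clusters: frozenset[frozenset[str]], tag: str
) -> tuple[list[Arc], dict[frozenset[str], str]]:
    """Arcs of the unique rooted tree with the given hierarchy; singleton
    clusters become the labelled leaves, internal vertices get ``tag``-
    prefixed names keyed by their cluster."""
    name: dict[frozenset[str], str] = {}
    for c in clusters:
        if len(c) == 1:
            (x,) = c
            name[c] = x
        else:
            name[c] = f"{tag}:" + "|".join(sorted(c))
    arcs: list[Arc] = []
    for c in clusters:
        if len(c) == 1:
            continue
        # children: maximal proper sub-clusters
        subs = [d for d in clusters if d < c]
        kids = [d for d in subs if not any(d < e for e in subs)]
        for d in kids:
            arcs.append((name[c], name[d]))
    return arcs, name


def build_arboreal_network(cs: ClusterSystem) -> Network:
    """Realize a cluster system satisfying P1-P3 (plus all trivial
    clusters on X) as an arboreal |C_M|-rooted network.

    One tree per maximal cluster is built from its hierarchy; the trees
    are then glued in lexicographic order: each next tree sharing a
    cluster with the network built so far is attached by subdividing the
    incoming arc of the unique non-hybrid vertex carrying the shared
    maximal cluster and identifying.  The result's cluster system equals
    the input."""
    report = check_P123(cs)
    if not report.all_ok() or not cs.has_all_trivial():
        raise ClusterSystemError(
            report, "cluster system fails P1-P3 or lacks trivial clusters"
        )
    cm = sorted(maximal_clusters(cs), key=sorted)
    trees = {}
    for i, c in enumerate(cm):
        inside = frozenset(d for d in cs.clusters if d <= c)
        trees[i] = _tree_arcs_from_hierarchy(inside, f"T{i}")

    if len(cm) == 1:
        arcs, _ = trees[0]
        if not arcs:  # single labelled vertex
            (x,) = cm[0]
            return Network(frozenset({x}), frozenset(), "strict")
        return validate_network((), arcs, "strict")

    done = {0}
    arcs: list[Arc] = list(trees[0][0])
    net_clusters = {c for c in cs.clusters if c <= cm[0]}
    hyb = itertools.count(1)

    def current_clusters() -> dict[str, frozenset[str]]:
        g = nx.DiGraph(arcs)
        cl: dict[str, frozenset[str]] = {}
        for v in reversed(list(nx.topological_sort(g))):
            succ = list(g.successors(v))
            if not succ:
                cl[v] = frozenset({v})
            else:
                cl[v] = frozenset().union(*(cl[c] for c in succ))
        return cl

    while len(done) < len(cm):
        nxt = None
        for j in range(len(cm)):
            if j in done:
                continue
            if any(d <= cm[j] and d in net_clusters for d in cs.clusters):
                nxt = j
                break
        assert nxt is not None, "P2 guarantees an eligible next tree"
        shared = {d for d in cs.clusters if d <= cm[nxt]} & net_clusters
        glue = max(shared, key=lambda d: (len(d), sorted(d)))
        if any(not (d <= glue) for d in shared):
            raise ClusterSystemError(
                report,
                "shared clusters are not nested under a single glue point; "
                "no single attachment realizes this system",
            )
        cl = current_clusters()
        indeg: dict[str, int] = {}
        for u, v in arcs:
            indeg[v] = indeg.get(v, 0) + 1
            indeg.setdefault(u, indeg.get(u, 0))
        candidates = [
            v for v, c in cl.items() if c == glue and indeg.get(v, 0) <= 1
        ]
        assert len(candidates) == 1, "glue vertex must be unique"
        u_i = candidates[0]
        assert indeg.get(u_i, 0) == 1, "glue vertex cannot be a root"
        (in_arc,) = [(a, b) for a, b in arcs if b == u_i]
        w = f"H{next(hyb)}"
        arcs.remove(in_arc)
        arcs.append((in_arc[0], w))
        arcs.append((w, u_i))
        tarcs, tname = trees[nxt]
        v_next = tname[glue]
        # drop everything below v_next in the new tree, redirect its
        # incoming arc to w, keep the rest
        below = {v_next}
        changed = True
        while changed:
            changed = False
            for a, b in tarcs:
                if a in below and b not in below:
                    below.add(b)
                    changed = True
        for a, b in tarcs:
            if a in below:
                continue
            arcs.append((a, w) if b == v_next else (a, b))
        done.add(nxt)
        net_clusters |= {d for d in cs.clusters if d <= cm[nxt]}

    return validate_network((), arcs, "strict")


# ---------------------------------------------------------------------------
# Bad arcs


def bad_arcs(net: Network) -> frozenset[Arc]:
    """Arcs with both end vertices hybrid."""
    h = net.hybrids
    return frozenset((u, v) for u, v in net.arcs if u in h and v in h)


def collapse_bad_arcs(net: Network) -> Network:
    """Comp(N): contract every bad arc.  The result need not be
    semi-binary and is returned as a relaxed-mode graph."""
    bad = bad_arcs(net)
    if not bad:
        return net
    rep: dict[str, str] = {v: v for v in net.vertices}

    def find(x: str) -> str:
        while rep[x] != x:
            x = rep[x]
        return x

    for u, v in bad:
        ru, rv = find(u), find(v)
        if ru != rv:
            rep[ru] = rv
    arcs = set()
    for u, v in net.arcs:
        fu, fv = find(u), find(v)
        if fu != fv:
            arcs.add((fu, fv))
    return validate_network((), arcs, "relaxed")


def _require_arboreal(net: Network) -> None:
    if not net.is_arboreal():
        raise ValueError("operation defined for arboreal networks only")


def is_uniquely_determined(net: Network) -> bool:
    """True iff the arboreal network is the only one (up to equivalence)
    with its cluster system, i.e. iff it has no bad arcs."""
    _require_arboreal(net)
    return not bad_arcs(net)


def same_clusters_iff_collapse_equivalent(
    n1: Network, n2: Network
) -> tuple[bool, bool]:
    """(equal cluster systems?, equivalent after collapsing bad arcs?).

    The two verdicts coincide for arboreal networks on a common label
    set; both are computed independently for diagnostics."""
    _require_arboreal(n1)
    _require_arboreal(n2)
    same_cs = ClusterSystem.from_network(n1) == ClusterSystem.from_network(n2)
    collapse_eq = are_equivalent(collapse_bad_arcs(n1), collapse_bad_arcs(n2))
    return same_cs, collapse_eq
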