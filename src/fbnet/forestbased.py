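"""Forest-based network recognition with certificates.

A network N = (V, A) on X is *forest-based* if some subset A' of A forms a
spanning forest F' = (V, A') (at least two components, every vertex of
indegree at most one) with the same leaf set as N, such that every removed
arc ("contact arc") joins two different trees of F'.  Suppressing the
subdivision vertices of F' yields the *base forest*, a phylogenetic forest
on X.  An m-rooted network is *proper* forest-based if it has a base
forest with exactly m trees.

Recognition is exact exponential search (general recognition complexity is
open); budgets guard the exhaustive oracle.  Three routes are provided:

* :func:`oracle_is_forest_based` — ground-truth enumeration of all
  forest-inducing arc subsets;
* :func:`is_forest_based` — the path-partition criterion: N is
  forest-based iff the trivial forest embeds as a union of vertex-disjoint
  directed paths, one per leaf, with no arc of N joining two
  non-consecutive vertices of a path;
* :func:`arboreal_forest_based` — for networks whose underlying graph is a
  tree, via hybrid sequences and an oriented auxiliary graph.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterator, Optional

from .netcore import (
    Arc,
    Network,
    PhylogeneticForest,
    SpanningForest,
    cluster_system,
    suppress,
    vertex_roles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ContactArcCertificate",
    "PathPartition",
    "oracle_is_forest_based",
    "enumerate_certificates",
    "base_forests",
    "is_forest_based",
    "path_partition_certificate",
    "verify_certificate",
    "hybrid_sequence",
    "arboreal_forest_based",
    "is_proper_forest_based",
    "is_base_forest",
    "is_universal_forest_based",
    "has_forbidden_configuration",
    "ArcBudgetExceeded",
]


class ArcBudgetExceeded(ValueError):
    """The exhaustive oracle was asked to search beyond its arc budget."""


@dataclass(frozen=True)
class ContactArcCertificate:
    """Witness of forest-basedness: the contact arcs I, the spanning
    forest (V, A - I) and its suppressed base forest."""

    contact_arcs: frozenset[Arc]
    spanning_forest: SpanningForest
    base_forest: PhylogeneticForest


@dataclass(frozen=True)
class PathPartition:
    """Witness in the form of the trivial-forest embedding: one successor
    child per non-leaf vertex, whose chosen arcs form vertex-disjoint
    directed paths each ending at a distinct leaf."""

    successor: dict[str, str]

    def paths(self, net: Network) -> list[list[str]]:
        chosen_heads = set(self.successor.values())
        starts = sorted(v for v in net.vertices if v not in chosen_heads)
        out = []
        for s in starts:
            path = [s]
            while path[-1] in self.successor:
                path.append(self.successor[path[-1]])
            out.append(path)
        return out


def _require_decidable(net: Network) -> None:
    if net.mode != "strict":
        raise ValueError("forest-based deciders require a strict network")
    if len(net.leaves) < 2:
        raise ValueError("forest-based is undefined for |X| < 2")


# ---------------------------------------------------------------------------
# Exhaustive oracle


def enumerate_certificates(net: Network) -> Iterator[ContactArcCertificate]:
    """Exhaustively enumerate every subdivision forest of ``net``.

    Equivalent to trying all subsets I of A: a subset can only pass when
    each vertex keeps at most one incoming arc, so the search enumerates,
    per vertex, which incoming arc (if any) survives.  Candidates are
    pruned as soon as a removed arc's endpoints are forced into one
    component or a non-leaf vertex loses all outgoing arcs, and accepted
    when the result is a spanning forest (>= 2 components) with leaf set
    X whose removed arcs all cross components.
    """
    _require_decidable(net)
    leaves = net.leaves
    verts = sorted(net.vertices, key=lambda v: (len(net.parents(v)) == 0, v))
    with_in = [v for v in verts if net.indeg(v) >= 1]

    parent_dsu: dict[str, str] = {v: v for v in net.vertices}

    def find(x: str) -> str:
        while parent_dsu[x] != x:
            x = parent_dsu[x]
        return x

    kept_out = {v: 0 for v in net.vertices}
    undecided_out = {v: net.outdeg(v) for v in net.vertices}
    removed: list[Arc] = []
    kept: list[Arc] = []

    def rec(i: int) -> Iterator[ContactArcCertificate]:
        if i == len(with_in):
            # final crossing check
            for u, v in removed:
                if find(u) == find(v):
                    return
            forest = SpanningForest(net.vertices, frozenset(kept))
            comps = forest.components()
            if len(comps) < 2:
                return
            yield ContactArcCertificate(
                frozenset(removed), forest, suppress(forest, leaves)
            )
            return
        v = with_in[i]
        in_arcs = [(p, v) for p in net.parents(v)]
        for choice in [*in_arcs, None]:
            undo_union: Optional[str] = None
            added_removed = 0
            ok = True
            for a in in_arcs:
                if a is choice:
                    continue
                removed.append(a)
                added_removed += 1
            if choice is not None:
                ru, rv = find(choice[0]), find(choice[1])
                if ru != rv:
                    parent_dsu[ru] = rv
                    undo_union = ru
                kept.append(choice)
            # prune: removed arcs whose endpoints already share a component
            for a in removed[-added_removed:] if added_removed else []:
                if find(a[0]) == find(a[1]):
                    ok = False
                    break
            # prune: tails that just lost their last outgoing arc
            touched = []
            for a in in_arcs:
                t = a[0]
                undecided_out[t] -= 1
                if a is choice:
                    kept_out[t] += 1
                touched.append(t)
                if (
                    ok
                    and t not in leaves
                    and undecided_out[t] == 0
                    and kept_out[t] == 0
                ):
                    ok = False
            if ok:
                yield from rec(i + 1)
            # rollback
            for a in in_arcs:
                t = a[0]
                undecided_out[t] += 1
                if a is choice:
                    kept_out[t] -= 1
            if choice is not None:
                kept.pop()
                if undo_union is not None:
                    parent_dsu[undo_union] = undo_union
            for _ in range(added_removed):
                removed.pop()

    yield from rec(0)


def oracle_is_forest_based(
    net: Network, arc_budget: int = 18
) -> Optional[ContactArcCertificate]:
    """Ground-truth decision by exhaustive search over removal sets.

    Returns the first certificate found, or None when no subdivision
    forest exists.  Refuses networks with more than ``arc_budget`` arcs."""
    _require_decidable(net)
    if len(net.arcs) > arc_budget:
        raise ArcBudgetExceeded(
            f"{len(net.arcs)} arcs exceed the oracle budget of {arc_budget}"
        )
    for cert in enumerate_certificates(net):
        return cert
    return None


def base_forests(net: Network) -> set[PhylogeneticForest]:
    """All base forests of ``net`` (exhaustive; desk-scale networks only)."""
    return {cert.base_forest for cert in enumerate_certificates(net)}


def verify_certificate(net: Network, cert: ContactArcCertificate) -> bool:
    """Independent soundness check of a contact-arc certificate."""
    forest = cert.spanning_forest
    if forest.vertices != net.vertices:
        return False
    if not forest.arcs <= net.arcs:
        return False
    if cert.contact_arcs != net.arcs - forest.arcs:
        return False
    if forest.leaves() != net.leaves:
        return False
    comps = forest.component_index()
    if len(set(comps.values())) < 2:
        return False
    for u, v in cert.contact_arcs:
        if comps[u] == comps[v]:
            return False
    return cert.base_forest == suppress(forest, net.leaves)


# ---------------------------------------------------------------------------
# Path-partition decider


def is_forest_based(net: Network) -> tuple[bool, Optional[PathPartition]]:
    """Decide forest-basedness via the trivial-forest path criterion.

    Searches for one successor child per non-leaf vertex such that the
    chosen arcs have indegree at most one everywhere (hence form
    vertex-disjoint directed paths, one ending at each leaf) and no arc of
    N joins two non-consecutive vertices of one path."""
    _require_decidable(net)
    leaves = net.leaves
    non_leaves = sorted(v for v in net.vertices if v not in leaves)
    chosen: dict[str, str] = {}
    chosen_in: dict[str, int] = {v: 0 for v in net.vertices}

    def chordless(succ: dict[str, str]) -> bool:
        pos: dict[str, tuple[int, int]] = {}
        heads = set(succ.values())
        pid = 0
        for s in sorted(net.vertices):
            if s in heads:
                continue
            v, k = s, 0
            while True:
                pos[v] = (pid, k)
                if v not in succ:
                    break
                v, k = succ[v], k + 1
            pid += 1
        for u, v in net.arcs:
            pu, pv = pos[u], pos[v]
            if pu[0] == pv[0] and pv[1] != pu[1] + 1:
                return False
        return True

    explored = 0

    def rec(i: int) -> Optional[PathPartition]:
        nonlocal explored
        explored += 1
        if i == len(non_leaves):
            succ = dict(chosen)
            if chordless(succ):
                return PathPartition(succ)
            return None
        v = non_leaves[i]
        for c in net.children(v):
            if chosen_in[c] == 1:
                continue
            chosen[v] = c
            chosen_in[c] += 1
            found = rec(i + 1)
            chosen_in[c] -= 1
            del chosen[v]
            if found is not None:
                return found
        return None

    pp = rec(0)
    logger.debug(
        "path-partition search explored %d nodes on %d vertices (%s)",
        explored, len(net.vertices), "found" if pp else "exhausted",
    )
    return (pp is not None), pp


def path_partition_certificate(
    net: Network, pp: PathPartition
) -> ContactArcCertificate:
    """Convert a path partition into the contact-arc certificate of the
    trivial base forest it embeds."""
    kept = frozenset((u, v) for u, v in pp.successor.items())
    forest = SpanningForest(net.vertices, kept)
    contact = net.arcs - kept
    return ContactArcCertificate(contact, forest, suppress(forest, net.leaves))


# ---------------------------------------------------------------------------
# Arboreal networks: hybrid sequences and the oriented auxiliary graph


def _mu_graph(net: Network):
    """Auxiliary graph on the vertices with a hybrid child; one edge per
    hybrid, joining its two parents."""
    import networkx as nx

    hybrids = net.hybrids
    mu = nx.Graph()
    for v in net.vertices:
        if any(c in hybrids for c in net.children(v)):
            mu.add_node(v)
    for g in sorted(hybrids):
        p1, p2 = sorted(net.parents(g))
        mu.add_edge(p1, p2, hybrid=g)
    return mu


def hybrid_sequence(net: Network, h: str) -> Optional[list[str]]:
    """A sequence v1 = h, ..., vk of distinct vertices in which consecutive
    vertices share a hybrid child and vk has a non-hybrid child; None if no
    such sequence exists."""
    import networkx as nx

    hybrids = net.hybrids
    if h not in hybrids:
        raise ValueError(f"{h!r} is not a hybrid vertex")

    def good(v: str) -> bool:
        return any(c not in hybrids for c in net.children(v))

    if good(h):
        return [h]
    mu = _mu_graph(net)
    targets = [v for v in mu.nodes if good(v)]
    best: Optional[list[str]] = None
    for t in sorted(targets):
        if nx.has_path(mu, h, t):
            p = nx.shortest_path(mu, h, t)
            if best is None or len(p) < len(best):
                best = p
    return best


def arboreal_forest_based(
    net: Network,
) -> tuple[bool, ContactArcCertificate | str]:
    """Decide forest-basedness of an arboreal network.

    N is forest-based iff every hybrid admits a hybrid sequence.  When it
    does, the auxiliary graph is oriented so that every sink has a
    non-hybrid child, and the contact arcs are read off the orientation:
    each hybrid drops the incoming arc from the head of its oriented edge.
    Returns (False, witness-hybrid) when some hybrid has no sequence."""
    import networkx as nx

    _require_decidable(net)
    if not net.is_arboreal():
        raise ValueError("network is not arboreal")
    hybrids = net.hybrids
    if not hybrids:
        # a single-rooted arboreal network is a phylogenetic tree
        pp = is_forest_based(net)[1]
        return True, path_partition_certificate(net, pp)

    def good(v: str) -> bool:
        return any(c not in hybrids for c in net.children(v))

    mu = _mu_graph(net)
    comp_of: dict[str, int] = {}
    comps = [sorted(c) for c in nx.connected_components(mu)]
    comps.sort(key=lambda c: c[0])
    for i, c in enumerate(comps):
        for v in c:
            comp_of[v] = i
    comp_target: dict[int, Optional[str]] = {}
    for i, c in enumerate(comps):
        goods = [v for v in c if good(v)]
        comp_target[i] = min(goods) if goods else None

    for h in sorted(hybrids):
        if good(h):
            continue
        if h not in mu or comp_target[comp_of[h]] is None:
            return False, h

    # orient every component toward its target: each non-target vertex
    # points along the unique tree path to the target
    removed: set[Arc] = set()
    for i, c in enumerate(comps):
        t = comp_target[i]
        parent_toward = nx.bfs_predecessors(mu.subgraph(c), t)
        toward = dict(parent_toward)  # vertex -> next hop toward t
        for a, b, data in mu.subgraph(c).edges(data=True):
            g = data["hybrid"]
            head = b if toward.get(a) == b else a
            removed.add((head, g))

    kept = net.arcs - removed
    forest = SpanningForest(net.vertices, frozenset(kept))
    cert = ContactArcCertificate(
        frozenset(removed), forest, suppress(forest, net.leaves)
    )
    assert verify_certificate(net, cert)
    return True, cert


# ---------------------------------------------------------------------------
# Proper forest-basedness and base-forest membership


def is_proper_forest_based(
    net: Network,
) -> tuple[bool, Optional[ContactArcCertificate]]:
    """Decide whether N has a base forest with exactly m = |R(N)| trees.

    A base forest with m trees exists iff one incoming arc can be deleted
    from every hybrid (and nothing else) so that the result keeps leaf set
    X and every deleted arc joins two components: deleting a tree vertex's
    incoming arc, or both arcs of a hybrid, would create an extra root.
    For 2-rooted networks the bipartite omni-extension criterion is run as
    a fast path and cross-checked against the direct search."""
    _require_decidable(net)
    m = len(net.roots)
    if m < 2:
        raise ValueError("proper forest-basedness needs at least two roots")

    verdict, cert = _proper_by_deletion(net)
    if m == 2:
        from .gammacolor import has_bipartite_omni_extension

        fast = has_bipartite_omni_extension(net)
        if fast != verdict:  # pragma: no cover - cross-check failure
            raise AssertionError(
                "bipartite omni-extension criterion disagrees with search"
            )
    return verdict, cert


def _proper_by_deletion(
    net: Network,
) -> tuple[bool, Optional[ContactArcCertificate]]:
    hybrids = sorted(net.hybrids)
    leaves = net.leaves
    if not hybrids:
        return False, None  # connected, no hybrid => single root
    all_parents = [net.parents(h) for h in hybrids]
    for keeps in itertools.product(*all_parents):
        removed = set()
        for h, keep in zip(hybrids, keeps):
            for p in net.parents(h):
                if p != keep:
                    removed.add((p, h))
        kept = net.arcs - removed
        # leaf preservation
        outdeg = {v: 0 for v in net.vertices}
        for u, _ in kept:
            outdeg[u] += 1
        if any(outdeg[v] == 0 for v in net.vertices if v not in leaves):
            continue
        forest = SpanningForest(net.vertices, frozenset(kept))
        comps = forest.component_index()
        if any(comps[u] == comps[v] for u, v in removed):
            continue
        cert = ContactArcCertificate(
            frozenset(removed), forest, suppress(forest, leaves)
        )
        assert len(cert.base_forest) == len(net.roots)
        return True, cert
    return False, None


def is_base_forest(net: Network, forest: PhylogeneticForest) -> bool:
    """True iff ``forest`` is a base forest for ``net``."""
    _require_decidable(net)
    if forest.label_set != net.leaves:
        raise ValueError("forest label set differs from the network's X")
    for cert in enumerate_certificates(net):
        if cert.base_forest == forest:
            return True
    return False


def is_universal_forest_based(net: Network) -> bool:
    """True iff every phylogenetic forest on X is a base forest of N.

    Exhaustive over all forests; guarded to |X| <= 5."""
    from .genfix import enumerate_forests

    _require_decidable(net)
    if len(net.leaves) > 5:
        raise ValueError("universality check is exhaustive; |X| <= 5 only")
    found = base_forests(net)
    return all(f in found for f in enumerate_forests(net.leaves))


def has_forbidden_configuration(net: Network, x: str, y: str) -> bool:
    """Detect the universality-forbidding configuration: a common tree
    vertex or root w with directed paths to both leaves x and y whose
    internal vertices are all hybrids (paths of length >= 1; the chains of
    hybrids may be empty)."""
    if net.mode != "strict":
        raise ValueError("configuration detector requires a strict network")
    if x == y or x not in net.leaves or y not in net.leaves:
        raise ValueError("x and y must be distinct leaves")
    hybrids = net.hybrids
    roles = vertex_roles(net)
    for w in sorted(net.vertices):
        if roles.role[w] not in ("root", "tree"):
            continue
        reach: set[str] = set()
        for c in net.children(w):
            v = c
            while v in hybrids:
                (v,) = net.children(v)
            if v in net.leaves:
                reach.add(v)
        if x in reach and y in reach:
            return True
    return False
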