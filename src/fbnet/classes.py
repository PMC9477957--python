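"""Network class predicates and the tree-based test.

``classify`` evaluates the standard classes directly from their
definitions: *tree-child* (every internal vertex has a non-hybrid child),
*tree-sibling* (every hybrid has a sibling that is a tree vertex),
*reticulation-visible* (every hybrid v is seen by some leaf x: every
root-to-x path passes through v), plus structural flags (tree, binary,
semi-binary, arboreal, single-rooted).

``is_tree_based`` implements the omnian matching criterion for binary
single-rooted networks: N is tree-based iff the bipartite graph between
omnians and hybrids (one edge per arc from an omnian to a hybrid child)
has a matching saturating the omnians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .netcore import Network, vertex_roles

__all__ = ["ClassReport", "classify", "is_tree_based"]


@dataclass(frozen=True)
class ClassReport:
    is_tree: bool
    is_binary: bool
    is_semi_binary: bool
    is_arboreal: bool
    is_tree_child: bool
    is_tree_sibling: bool
    is_reticulation_visible: bool
    is_phylogenetic: bool  # single-rooted

    def flags(self) -> dict[str, bool]:
        return dict(self.__dict__)


def classify(net: Network) -> ClassReport:
    roles = vertex_roles(net)
    hybrids = sorted(net.hybrids)
    leaves = net.leaves
    roots = net.roots

    is_tree = not hybrids and len(roots) == 1
    is_semi_binary = all(
        net.indeg(h) == 2 and net.outdeg(h) == 1 for h in hybrids
    )
    is_binary = net.is_binary()
    is_arboreal = net.is_arboreal()

    internal = [v for v in net.vertices if net.outdeg(v) > 0]
    is_tree_child = all(
        any(c not in net.hybrids for c in net.children(v)) for v in internal
    )

    def has_tree_sibling(v: str) -> bool:
        for p in net.parents(v):
            for s in net.children(p):
                if s != v and net.indeg(s) == 1:
                    return True
        return False

    is_tree_sibling = all(has_tree_sibling(h) for h in hybrids)

    def visible(v: str) -> bool:
        # v is visible iff deleting it cuts every root-to-x path for some x
        rest = set(net.vertices) - {v}
        seen = set(r for r in roots if r != v)
        stack = list(seen)
        while stack:
            u = stack.pop()
            for c in net.children(u):
                if c in rest and c not in seen:
                    seen.add(c)
                    stack.append(c)
        below = net.descendants(v) & leaves
        return any(x not in seen for x in below)

    is_reticulation_visible = all(visible(h) for h in hybrids)

    return ClassReport(
        is_tree=is_tree,
        is_binary=is_binary,
        is_semi_binary=is_semi_binary,
        is_arboreal=is_arboreal,
        is_tree_child=is_tree_child,
        is_tree_sibling=is_tree_sibling,
        is_reticulation_visible=is_reticulation_visible,
        is_phylogenetic=len(roots) == 1,
    )


def is_tree_based(
    net: Network,
) -> tuple[bool, Optional[dict[str, str]]]:
    """Omnian-matching criterion for binary phylogenetic networks.

    Returns (verdict, matching omnian -> hybrid) on success, (False,
    None) otherwise.  Raises on multi-rooted or non-binary input, for
    which the criterion does not apply."""
    if len(net.roots) != 1:
        raise ValueError("tree-based test applies to single-rooted networks")
    if not net.is_binary():
        raise ValueError("tree-based test applies to binary networks")
    roles = vertex_roles(net)
    omnians = sorted(roles.omnians)
    if not omnians:
        return True, {}
    g = nx.Graph()
    for v in omnians:
        g.add_node(("U", v))
    for h in sorted(net.hybrids):
        g.add_node(("H", h))
    for v in omnians:
        for h in net.children(v):
            g.add_edge(("U", v), ("H", h))
    matching = nx.algorithms.bipartite.hopcroft_karp_matching(
        g, top_nodes=[("U", v) for v in omnians]
    )
    pairs = {
        u[1]: h[1]
        for u, h in matching.items()
        if u[0] == "U"
    }
    if len(pairs) == len(omnians):
        return True, pairs
    return False, None
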