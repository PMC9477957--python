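"""Reference fixtures, random network generators and forest enumeration.

The named fixtures are small networks reconstructed from the worked
examples that motivate each construct in this package (a proper
forest-based 2-network, a non-forest-based arboreal network, a cluster
system shared by two non-equivalent networks, coloring examples, a
universal network on three labels, and so on).  Each fixture's documented
facts are re-asserted by the test suite.

Random generation grows a forest of random binary trees and then adds
reticulations along a random topological order, with kind-specific
constraints (tree-child: never create an all-hybrid child set; arboreal:
every reticulation joins two components so the underlying graph stays a
tree).  Identical configurations produce identical networks.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterator, Sequence

from .netcore import Network, PhylogeneticForest, validate_network

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "fixture",
    "fixture_names",
    "enumerate_forests",
    "random_network",
    "fig11_configuration",
]


class GenerationError(RuntimeError):
    """Raised when a generator configuration is infeasible."""


# ---------------------------------------------------------------------------
# Fixtures

_FIXTURES: dict[str, dict] = {
    # 2-rooted proper forest-based network on {1,2,3,4}; based both on the
    # forest {1},{2},cherry(3,4) and on the proper forest of two cherries.
    "fig2": dict(
        mode="strict",
        arcs=[
            ("p1", "v"), ("p1", "h1"), ("v", "1"), ("v", "h2"),
            ("p2", "w"), ("p2", "h2"), ("w", "3"), ("w", "h1"),
            ("h1", "2"), ("h2", "4"),
        ],
    ),
    # arboreal 4-rooted network that is NOT forest-based: one of (h1,h3),
    # (h2,h3) must be a contact arc, making h1 or h2 a forest leaf.
    "fig5": dict(
        mode="strict",
        arcs=[
            ("p1", "1"), ("p1", "h1"), ("p2", "2"), ("p2", "h1"),
            ("p3", "3"), ("p3", "h2"), ("p4", "4"), ("p4", "h2"),
            ("h1", "h3"), ("h2", "h3"), ("h3", "5"),
        ],
    ),
    # arboreal 3-rooted pair with equal cluster systems but not
    # equivalent; bad arcs (h1,h2) and (h2p,h1p) respectively.
    "fig6N": dict(
        mode="strict",
        arcs=[
            ("p1", "1"), ("p1", "a"), ("a", "2"), ("a", "h1"),
            ("p2", "3"), ("p2", "b"), ("b", "4"), ("b", "h1"),
            ("p3", "5"), ("p3", "c"), ("c", "6"), ("c", "h2"),
            ("h1", "h2"), ("h2", "7"),
        ],
    ),
    "fig6Nprime": dict(
        mode="strict",
        arcs=[
            ("p1", "1"), ("p1", "a"), ("a", "2"), ("a", "h1p"),
            ("p2", "3"), ("p2", "b"), ("b", "4"), ("b", "h2p"),
            ("p3", "5"), ("p3", "c"), ("c", "6"), ("c", "h2p"),
            ("h2p", "h1p"), ("h1p", "7"),
        ],
    ),
    # 3-rooted, tree-child (no omnians), forest-based but not proper;
    # Gamma(N) contains the triangle p1, p2, h1.
    "fig7": dict(
        mode="strict",
        arcs=[
            ("p1", "a1"), ("p1", "w1"), ("a1", "1"), ("a1", "h1"),
            ("w1", "2"), ("w1", "g1"),
            ("p2", "a2"), ("p2", "m2"), ("a2", "h1"), ("a2", "w2"),
            ("w2", "g2"), ("w2", "5"), ("m2", "4"), ("m2", "k"),
            ("p3", "7"), ("p3", "m3"), ("m3", "8"), ("m3", "k"),
            ("h1", "t"), ("t", "3"), ("t", "u"),
            ("u", "g2"), ("u", "u2"), ("u2", "g1"), ("u2", "6"),
            ("g1", "9"), ("g2", "10"), ("k", "11"),
        ],
    ),
    # 2-rooted proper forest-based network with omnians {v, w}; Gamma(N)
    # has exactly two minimal omni-extensions, one of which is bipartite.
    "fig8": dict(
        mode="strict",
        arcs=[
            ("p1", "f"), ("p1", "v"), ("f", "1"), ("f", "h2"),
            ("v", "w"), ("v", "g"),
            ("p2", "b"), ("p2", "c"), ("b", "4"), ("b", "w"),
            ("c", "e"), ("c", "5"), ("e", "g"), ("e", "6"),
            ("w", "h2"), ("h2", "3"), ("g", "2"),
        ],
    ),
    # binary 2-rooted universal forest-based network on {1,2,3}: all four
    # phylogenetic forests on X are base forests (found by exhaustive
    # search over small binary networks; re-verified by the test suite).
    "fig10": dict(
        mode="strict",
        arcs=[
            ("p1", "h1"), ("p1", "a"), ("p2", "h2"), ("p2", "h1"),
            ("a", "1"), ("a", "h2"), ("h2", "3"), ("h1", "2"),
        ],
    ),
    # not semi-binary (indeg(h2) = 3); 2 roots; based on a forest with
    # three contact arcs, yet Gamma(N) contains a triangle.
    "fig9": dict(
        mode="relaxed",
        arcs=[
            ("p1", "a"), ("p1", "b"), ("a", "1"), ("a", "h1"),
            ("b", "2"), ("b", "h2"),
            ("p2", "c"), ("p2", "d"), ("c", "3"), ("c", "h1"),
            ("d", "4"), ("d", "h2"),
            ("h1", "e"), ("e", "5"), ("e", "h2"), ("h2", "6"),
        ],
    ),
}

# Ten binary single-rooted exemplars spanning distinct regions of the
# class diagram (tree / tree-child / forest-based / tree-based /
# tree-sibling / reticulation-visible).  The flag pattern each was built
# to realize is re-asserted by the tests; patterns respect the known
# implications (tree-child => forest-based => tree-based; tree-child =>
# tree-sibling and reticulation-visible).
_FIG4: dict[str, tuple[tuple[bool, ...], list[tuple[str, str]]]] = {
    # (tree_child, forest_based, tree_based, tree_sibling, retic_visible)
    "fig4A": ((True, True, True, True, True), [  # a phylogenetic tree
        ("r", "a"), ("r", "b"), ("a", "1"), ("a", "2"), ("b", "3"), ("b", "4"),
    ]),
    "fig4B": ((True, True, True, True, True), [  # tree-child, one hybrid
        ("h1", "2"), ("t0", "3"), ("t0", "h1"), ("t1", "t0"), ("t1", "t3"),
        ("t2", "1"), ("t2", "t1"), ("t3", "4"), ("t3", "h1"),
    ]),
    "fig4C": ((False, True, True, True, True), [
        ("h1", "2"), ("h2", "t1"), ("t0", "1"), ("t0", "3"), ("t1", "4"),
        ("t1", "h1"), ("t2", "t0"), ("t2", "t3"), ("t3", "h2"), ("t3", "t4"),
        ("t4", "h1"), ("t4", "h2"),
    ]),
    "fig4D": ((False, True, True, True, False), [
        ("h1", "h2"), ("h2", "3"), ("t0", "h1"), ("t0", "t4"), ("t1", "t0"),
        ("t1", "t3"), ("t2", "4"), ("t2", "t1"), ("t3", "1"), ("t3", "h1"),
        ("t4", "2"), ("t4", "h2"),
    ]),
    "fig4E": ((False, True, True, False, True), [
        ("h1", "4"), ("h2", "2"), ("t0", "h1"), ("t0", "h2"), ("t1", "t0"),
        ("t1", "t3"), ("t2", "3"), ("t2", "t1"), ("t3", "1"), ("t3", "t4"),
        ("t4", "h1"), ("t4", "h2"),
    ]),
    "fig4F": ((False, True, True, False, False), [
        ("h1", "5"), ("h2", "h1"), ("h3", "1"), ("t0", "2"), ("t0", "3"),
        ("t1", "h2"), ("t1", "t0"), ("t2", "4"), ("t2", "t5"), ("t3", "t2"),
        ("t3", "t4"), ("t4", "h1"), ("t4", "h3"), ("t5", "t1"), ("t5", "t6"),
        ("t6", "h2"), ("t6", "h3"),
    ]),
    "fig4G": ((False, False, True, True, False), [
        ("h1", "t1"), ("h2", "h1"), ("h3", "t0"), ("t0", "3"), ("t0", "5"),
        ("t1", "1"), ("t1", "4"), ("t2", "h1"), ("t2", "t5"), ("t3", "t4"),
        ("t3", "t6"), ("t4", "2"), ("t4", "h2"), ("t5", "h2"), ("t5", "h3"),
        ("t6", "h3"), ("t6", "t2"),
    ]),
    "fig4H": ((False, False, True, False, True), [
        ("h1", "5"), ("h2", "t0"), ("h3", "t2"), ("t0", "3"), ("t0", "4"),
        ("t1", "h1"), ("t1", "h2"), ("t2", "1"), ("t2", "2"), ("t3", "t5"),
        ("t3", "t6"), ("t4", "h1"), ("t4", "h3"), ("t5", "h2"), ("t5", "t1"),
        ("t6", "h3"), ("t6", "t4"),
    ]),
    "fig4I": ((False, False, True, False, False), [
        ("h1", "h2"), ("h2", "4"), ("t0", "1"), ("t0", "t3"), ("t1", "2"),
        ("t1", "t0"), ("t2", "h1"), ("t2", "t1"), ("t3", "3"), ("t3", "t4"),
        ("t4", "h1"), ("t4", "h2"),
    ]),
    "fig4J": ((False, False, False, False, False), [
        ("h1", "2"), ("h2", "h1"), ("h3", "h1"), ("t0", "1"), ("t0", "h2"),
        ("t1", "5"), ("t1", "t4"), ("t2", "t1"), ("t2", "t6"), ("t3", "3"),
        ("t3", "t2"), ("t4", "4"), ("t4", "h3"), ("t5", "h2"), ("t5", "t0"),
        ("t6", "h3"), ("t6", "t5"),
    ]),
}

for _name, (_flags, _arcs) in _FIG4.items():
    _FIXTURES[_name] = dict(mode="strict", arcs=_arcs)


def fig4_expected_flags(name: str) -> dict[str, bool]:
    """The designed (tree_child, forest_based, tree_based, tree_sibling,
    reticulation_visible) pattern of a fig4 exemplar."""
    tc, fb, tb, ts, rv = _FIG4[name][0]
    return dict(
        is_tree_child=tc,
        forest_based=fb,
        tree_based=tb,
        is_tree_sibling=ts,
        is_reticulation_visible=rv,
    )


def fixture(name: str) -> Network:
    """Build a named fixture network."""
    if name.startswith("fig11"):
        raise KeyError("use fig11_configuration(p, q) for the forbidden configuration")
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(sorted(_FIXTURES))}"
        ) from None
    return validate_network((), spec["arcs"], spec["mode"])


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


# ---------------------------------------------------------------------------
# Forest enumeration


def _set_partitions(items: Sequence[str]) -> Iterator[list[list[str]]]:
    """All partitions of ``items`` into non-empty blocks, deterministic
    order; blocks kept sorted."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _trees_on(labels: tuple[str, ...]) -> list[frozenset[frozenset[str]]]:
    """All rooted phylogenetic trees on ``labels`` as hierarchies: no
    unary vertices, roots of outdegree >= 2, not necessarily binary."""
    if len(labels) == 1:
        return [frozenset({frozenset(labels)})]
    out: list[frozenset[frozenset[str]]] = []
    full = frozenset(labels)
    for part in _set_partitions(labels):
        if len(part) < 2:
            continue
        block_trees = [_trees_on(tuple(sorted(b))) for b in part]
        for combo in itertools.product(*block_trees):
            h = {full}
            for t in combo:
                h |= t
            out.append(frozenset(h))
    return out


def enumerate_forests(labels) -> list[PhylogeneticForest]:
    """All phylogenetic forests on a label set (2 <= |labels| <= 6):
    every partition into at least two blocks crossed with every rooted
    phylogenetic tree per block, in deterministic order."""
    labs = tuple(sorted(set(labels)))
    if not 2 <= len(labs) <= 6:
        raise ValueError("forest enumeration supports 2..6 labels")
    out: list[PhylogeneticForest] = []
    for part in _set_partitions(labs):
        if len(part) < 2:
            continue
        block_trees = [_trees_on(tuple(sorted(b))) for b in part]
        for combo in itertools.product(*block_trees):
            out.append(PhylogeneticForest(combo))
    return out


# ---------------------------------------------------------------------------
# Random generation


@dataclass(frozen=True)
class GeneratorConfig:
    n_leaves: int
    n_hybrids: int
    kind: str = "general"  # general | tree_child | arboreal
    seed: int = 0
    n_roots: int | None = None


def _random_binary_tree(
    labels: list[str], rng: random.Random, namer
) -> tuple[str, list[tuple[str, str]]]:
    """Random binary tree on labels; returns (root, arcs)."""
    nodes = list(labels)
    rng.shuffle(nodes)
    arcs: list[tuple[str, str]] = []
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        p = namer()
        arcs.append((p, a))
        arcs.append((p, b))
        nodes.append(p)
    return nodes[0], arcs


def random_network(config: GeneratorConfig) -> Network:
    """Draw a random strict binary network of the requested kind."""
    rng = random.Random(config.seed)
    kind = config.kind
    if kind not in ("general", "tree_child", "arboreal"):
        raise GenerationError(f"unknown kind {config.kind!r}")
    if config.n_leaves < 2:
        raise GenerationError("need at least two leaves")
    labels = [str(i + 1) for i in range(config.n_leaves)]

    if kind == "arboreal":
        return _random_arboreal(labels, config, rng)
    m = config.n_roots if config.n_roots is not None else 1
    if m < 1:
        raise GenerationError("need at least one root")
    if config.n_leaves < 2 * m:
        raise GenerationError("each root needs at least two leaves")
    if m > 1 and config.n_hybrids < m - 1:
        raise GenerationError("need >= m-1 reticulations to connect m roots")

    counter = itertools.count()
    namer = lambda: f"t{next(counter)}"
    rng.shuffle(labels)
    blocks = [labels[i::m] for i in range(m)]
    arcs: list[tuple[str, str]] = []
    comp: dict[str, int] = {}
    for bi, block in enumerate(blocks):
        root, tarcs = _random_binary_tree(sorted(block), rng, namer)
        arcs.extend(tarcs)
        comp[root] = bi
        for u, v in tarcs:
            comp[u] = bi
            comp[v] = bi

    hybrids: set[str] = set()
    hnames = itertools.count(1)
    for k in range(config.n_hybrids):
        bridge = k < m - 1
        for attempt in range(400):
            a1 = rng.choice(arcs)
            a2 = rng.choice(arcs)
            if a1 == a2:
                continue
            if bridge and comp[a1[0]] == comp[a2[0]]:
                continue
            u1, v1 = a1
            u2, v2 = a2
            if kind == "tree_child":
                if v1 in hybrids or v2 in hybrids:
                    continue
                # replacing v2 by a hybrid must leave u2 some non-hybrid
                # child (a hybrid tail has none besides v2)
                siblings = [b for a, b in arcs if a == u2 and b != v2]
                if all(s in hybrids for s in siblings):
                    continue
            if _reaches(arcs, v2, u1):
                continue
            w1 = namer()
            h = f"h{next(hnames)}"
            arcs.remove(a1)
            arcs.remove(a2)
            arcs.extend([(u1, w1), (w1, v1), (u2, h), (h, v2), (w1, h)])
            hybrids.add(h)
            if comp[a1[0]] != comp[a2[0]]:
                old, new = comp[a2[0]], comp[a1[0]]
                for x in list(comp):
                    if comp[x] == old:
                        comp[x] = new
            comp[w1] = comp[u1]
            comp[h] = comp[u1]
            break
        else:
            raise GenerationError(
                f"could not place reticulation {k + 1} for {config}"
            )
    net = validate_network((), arcs, "strict")
    if kind == "tree_child":
        from .netcore import vertex_roles

        assert not vertex_roles(net).omnians
    return net


def _reaches(arcs: list[tuple[str, str]], src: str, dst: str) -> bool:
    if src == dst:
        return True
    adj: dict[str, list[str]] = {}
    for u, v in arcs:
        adj.setdefault(u, []).append(v)
    stack, seen = [src], {src}
    while stack:
        u = stack.pop()
        for v in adj.get(u, ()):
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _random_arboreal(
    labels: list[str], config: GeneratorConfig, rng: random.Random
) -> Network:
    m = config.n_hybrids + 1
    if config.n_roots is not None and config.n_roots != m:
        raise GenerationError("arboreal networks have |R| = n_hybrids + 1")
    if config.n_leaves < m + 1:
        raise GenerationError("arboreal generation needs n_leaves >= n_hybrids + 2")
    rng.shuffle(labels)
    # first block gets >= 2 leaves, the rest >= 1
    sizes = [2] + [1] * (m - 1)
    for _ in range(config.n_leaves - sum(sizes)):
        sizes[rng.randrange(m)] += 1
    blocks, i = [], 0
    for s in sizes:
        blocks.append(sorted(labels[i : i + s]))
        i += s

    counter = itertools.count()
    namer = lambda: f"t{next(counter)}"
    root, arcs = _random_binary_tree(blocks[0], rng, namer)
    arcs = list(arcs)
    hnames = itertools.count(1)
    for block in blocks[1:]:
        p, u = rng.choice(arcs)
        h = f"h{next(hnames)}"
        arcs.remove((p, u))
        arcs.extend([(p, h), (h, u)])
        ph = "#"
        broot, barcs = _random_binary_tree(sorted(block) + [ph], rng, namer)
        for a, b in barcs:
            arcs.append((a, h) if b == ph else (a, b))
    return validate_network((), arcs, "strict")


# ---------------------------------------------------------------------------
# Forbidden configuration host


def fig11_configuration(p: int, q: int) -> Network:
    """A host network containing two hybrid-only chains of lengths p and q
    from a common tree vertex w down to leaves x and y."""
    if p < 0 or q < 0:
        raise ValueError("chain lengths must be non-negative")
    arcs: list[tuple[str, str]] = [("rho", "w")]
    vchain = [f"v{i}" for i in range(p, 0, -1)]  # v_p .. v_1
    uchain = [f"u{j}" for j in range(q, 0, -1)]
    for chain, leaf in ((vchain, "x"), (uchain, "y")):
        prev = "w"
        for node in chain:
            arcs.append((prev, node))
            prev = node
        arcs.append((prev, leaf))
    spine_hybrids = vchain + uchain
    if spine_hybrids:
        arcs.append(("rho", "s1"))
        for i, h in enumerate(spine_hybrids, start=1):
            arcs.append((f"s{i}", h))
            if i < len(spine_hybrids):
                arcs.append((f"s{i}", f"s{i+1}"))
            else:
                arcs.append((f"s{i}", "z"))
    else:
        arcs.append(("rho", "z"))
    return validate_network((), arcs, "strict")
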