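"""Plain-text formats and exports.

The primary on-disk format is a tab-separated arc list (one ``tail<TAB>
head`` per line, ``#`` comments, an optional ``!mode strict|relaxed``
directive), chosen over extended Newick because eNewick is single-rooted
by design.  Multi-rooted eNewick export (one statement per root, hybrids
shared via ``#Hk`` tags) and DOT export (contact arcs dashed) are
conveniences, not the source of truth.
"""

from __future__ import annotations

import re
from typing import Optional

from .clustersys import ClusterSystem
from .forestbased import ContactArcCertificate
from .netcore import Network, validate_network

__all__ = [
    "read_network",
    "write_network",
    "read_network_file",
    "write_network_file",
    "read_clusters",
    "write_clusters",
    "write_enewick",
    "read_enewick",
    "write_dot",
    "ParseError",
]


class ParseError(ValueError):
    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(
            f"line {line}: {message}" if line is not None else message
        )


def read_network(text: str, mode: Optional[str] = None) -> Network:
    """Parse an arc-list document and validate it.

    ``mode`` overrides any ``!mode`` directive; default strict."""
    arcs = []
    doc_mode = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("!mode"):
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("strict", "relaxed"):
                raise ParseError(f"bad mode directive {line!r}", ln)
            doc_mode = parts[1]
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(f"expected 'tail<TAB>head', got {raw!r}", ln)
        arcs.append((parts[0], parts[1]))
    return validate_network((), arcs, mode or doc_mode or "strict")


def write_network(net: Network) -> str:
    """Serialize a network; arcs in lexicographic order (deterministic:
    equal networks give byte-identical documents)."""
    lines = []
    if net.mode != "strict":
        lines.append(f"!mode {net.mode}")
    lines.extend(f"{u}\t{v}" for u, v in sorted(net.arcs))
    return "\n".join(lines) + "\n"


def read_network_file(path, mode: Optional[str] = None) -> Network:
    with open(path) as fh:
        return read_network(fh.read(), mode)


def write_network_file(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_network(net))


def read_clusters(text: str) -> ClusterSystem:
    """One cluster per line, labels comma-separated; duplicates collapse."""
    clusters = set()
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        labels = [x.strip() for x in line.split(",")]
        if any(not x for x in labels):
            raise ParseError("empty label in cluster", ln)
        clusters.add(frozenset(labels))
    if not clusters:
        raise ParseError("no clusters in document")
    return ClusterSystem(frozenset().union(*clusters), frozenset(clusters))


def write_clusters(cs: ClusterSystem) -> str:
    lines = sorted(",".join(sorted(c)) for c in cs.clusters)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Extended Newick


def write_enewick(net: Network) -> str:
    """One semicolon-terminated statement per root; each hybrid carries a
    ``#Hk`` tag shared across statements, its subtree printed at its
    first appearance only."""
    if net.mode != "strict":
        raise ValueError("eNewick export requires a strict network")
    tag = {h: f"#H{i}" for i, h in enumerate(sorted(net.hybrids), start=1)}
    expanded: set[str] = set()

    def render(v: str) -> str:
        if v in tag:
            if v in expanded:
                return tag[v]
            expanded.add(v)
            inner = ",".join(render(c) for c in net.children(v))
            return f"({inner}){tag[v]}"
        if net.outdeg(v) == 0:
            return v
        inner = ",".join(render(c) for c in net.children(v))
        return f"({inner})"

    return "\n".join(render(r) + ";" for r in sorted(net.roots))


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;\s]+")


def read_enewick(text: str) -> Network:
    """Parse the dialect produced by :func:`write_enewick` (one statement
    per root, hybrids glued on shared #H tags)."""
    arcs: list[tuple[str, str]] = []
    counter = [0]
    statements = [s.strip() for s in text.split(";") if s.strip()]

    def parse(tokens: list[str], pos: int) -> tuple[str, int]:
        children: list[str] = []
        if tokens[pos] == "(":
            pos += 1
            while True:
                child, pos = parse(tokens, pos)
                children.append(child)
                if tokens[pos] == ",":
                    pos += 1
                    continue
                if tokens[pos] == ")":
                    pos += 1
                    break
        name = None
        if pos < len(tokens) and tokens[pos] not in "(),;":
            name = tokens[pos]
            pos += 1
        if name is None:
            counter[0] += 1
            name = f"_i{counter[0]}"
        for c in children:
            arcs.append((name, c))
        return name, pos

    for s in statements:
        tokens = _TOKEN.findall(s)
        parse(tokens, 0)
    return validate_network((), set(arcs), "strict")


# ---------------------------------------------------------------------------
# DOT


def write_dot(
    net: Network, certificate: Optional[ContactArcCertificate] = None
) -> str:
    """DOT digraph; certificate contact arcs dashed, forest arcs solid,
    leaves boxed."""
    dashed: frozenset = frozenset()
    if certificate is not None:
        if not certificate.contact_arcs <= net.arcs:
            raise ValueError("certificate arcs are not arcs of the network")
        dashed = certificate.contact_arcs
    lines = ["digraph N {"]
    for v in sorted(net.vertices):
        shape = "box" if v in net.leaves else "ellipse"
        lines.append(f'  "{v}" [shape={shape}];')
    for u, v in sorted(net.arcs):
        style = " [style=dashed]" if (u, v) in dashed else ""
        lines.append(f'  "{u}" -> "{v}"{style};')
    lines.append("}")
    return "\n".join(lines) + "\n"
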