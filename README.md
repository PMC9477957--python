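# fbnet — forest-based phylogenetic networks

`fbnet` is a toolkit for **multiply-rooted phylogenetic networks**:
directed acyclic graphs whose outdegree-0 vertices carry the taxon labels
`X`, whose hybrid vertices (indegree ≥ 2) model reticulate events such as
lateral gene transfer and introgression, and which — unlike classical
phylogenetic networks — may have several roots, one per lineage or
environment. Its focus is the recognition of **forest-based networks**:
networks `N = (V, A)` that can be obtained from a *phylogenetic forest*
(a set of leaf-disjoint rooted trees covering `X`) by adding *contact
arcs* only between different trees. Formally, `N` is forest-based when
some `A' ⊆ A` makes `F' = (V, A')` a spanning forest with leaf set
exactly `L(N)` such that every arc of `A − A'` joins two trees of `F'`;
suppressing the subdivision vertices of `F'` gives the *base forest*. An
`m`-rooted network is **proper** forest-based when some base forest has
exactly `m` trees. This is the natural multi-rooted relative of
tree-based networks, and the right shape for histories in which genes
flow *between* subfamilies — butterfly introgression, inter-niche gene
transfer in microbiomes — rather than within a single tree.

## What the package computes

* **`netcore`** — the `Network` data model with validation (semi-binary
  strict mode and a relaxed mode for higher-indegree hybrids), vertex
  roles, omnians, the nearest root-or-hybrid ancestor `γ_v`, induced
  cluster systems `C(N)`, spanning-forest suppression, and
  label-preserving equivalence.
* **`forestbased`** — three recognition routes with certificates:
  an exhaustive ground-truth oracle over arc subsets; the main decider
  via the *path-partition* criterion (`N` is forest-based iff the
  trivial forest embeds as vertex-disjoint directed paths, one per leaf,
  with no arc of `N` joining two non-consecutive vertices of a path);
  and, for *arboreal* networks (underlying graph a tree), a
  hybrid-sequence criterion with a constructive certificate. Also:
  proper forest-basedness, base-forest membership, universality checking
  (`|X| ≤ 5`), and the forbidden-configuration detector that explains
  why no universal forest-based network exists on four or more leaves.
* **`classes`** — tree-child / tree-sibling / reticulation-visible /
  arboreal predicates, and the omnian-matching tree-based test for
  binary single-rooted networks.
* **`clustersys`** — hierarchies, the three realizability properties
  P1–P3 of a cluster system, reconstruction of an arboreal network from
  its clusters, *bad arcs* (hybrid–hybrid arcs), and the
  collapse-equivalence criterion for when two arboreal networks share a
  cluster system.
* **`gammacolor`** — the graph `Γ(N)` on roots-and-hybrids, minimal
  omni-extensions, and the coloring characterization of proper
  forest-based networks (for two roots: a bipartite omni-extension
  exists iff `N` is proper forest-based).
* **`genfix`** — named reference fixtures, exhaustive enumeration of all
  phylogenetic forests on up to six labels, and seeded random generators
  (general / tree-child / arboreal kinds).
* **`netio` / CLI** — tab-separated arc lists as the primary format,
  cluster files, extended-Newick and DOT export, and the `fbnet`
  command-line tool.

## Worked example

A 2-rooted network with omnians `{v, w}` (fixture `fig8`):

```python
from fbnet import fixture, is_proper_forest_based, vertex_roles
from fbnet.gammacolor import minimal_omni_extensions, is_bipartite

net = fixture("fig8")
print("roots:", sorted(net.roots))
print("omnians:", sorted(vertex_roles(net).omnians))
ok, cert = is_proper_forest_based(net)
print("proper forest-based:", ok)
print("contact arcs:", sorted(cert.contact_arcs))
print("base forest:", cert.base_forest)
exts = minimal_omni_extensions(net)
print("minimal omni-extensions:", len(exts),
      "bipartite:", [is_bipartite(e) for e in exts])
```

prints

```
roots: ['p1', 'p2']
omnians: ['v', 'w']
proper forest-based: True
contact arcs: [('e', 'g'), ('f', 'h2'), ('v', 'w')]
base forest: PhylogeneticForest({1,12,2}; {3,34,3456,4,5,56,6})
minimal omni-extensions: 2 bipartite: [True, False]
```

Deleting the three contact arcs splits the network into two trees, one
per root — a cherry on `{1,2}` and a tree on `{3,4,5,6}` (the base
forest is printed as one hierarchy per tree) — so the network is proper
forest-based. Independently, `Γ(N)` has two minimal omni-extensions and
one of them is bipartite, which certifies the same verdict through the
2-rooted coloring characterization.

The same decisions are available from a shell:

```sh
fbnet fixture fig8 -o fig8.tsv
fbnet proper fig8.tsv          # one-line verdict + JSON report
fbnet clusters fig8.tsv
fbnet enumerate-forests -n 3 --count-only   # prints 4
```

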