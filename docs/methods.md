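# Methods

This note records the model, the algorithmic choices, and the scope of
what the synthetic generators and tests do and do not establish.

## The model

A *network* on a finite label set `X` is a connected directed acyclic
graph with no loops or parallel arcs whose outdegree-0 vertices are
exactly the elements of `X` (each with indegree ≤ 1), with at least one
root and every root of outdegree ≥ 2. Strict mode additionally demands
semi-binarity — every hybrid (indegree ≥ 2) has indegree exactly 2 and
outdegree 1 — and rejects internal tree vertices of outdegree 1 (no
figure-style network exhibits them, and admitting them would make
suppression non-canonical). Relaxed mode lifts the hybrid-degree bound;
it exists to host counterexamples showing that semi-binarity is needed
for the 2-rooted coloring characterization, and the recognition
deciders refuse relaxed inputs.

A *phylogenetic forest* on `X` is a set of ≥ 2 leaf-disjoint rooted
phylogenetic trees covering `X`; a one-tree variant is admitted
internally for base-tree interoperability. Trees are stored canonically
as their hierarchies (sets of clusters), exploiting the classical fact
that a phylogenetic tree is determined up to equivalence by its
hierarchy; this also makes suppression of subdivision vertices implicit
(unary vertices contribute no cluster).

`N` is *forest-based* when a spanning forest `F' = (V, A − I)` with ≥ 2
components and leaf set `L(N)` exists such that every arc of `I` joins
two components; *proper* when some base forest has exactly `|R(N)|`
trees. Forest-basedness is undefined for `|X| = 1` and reported as an
error, not `False`.

## Recognition algorithms

**Exhaustive oracle.** The ground truth enumerates, per vertex, which
incoming arc (if any) survives — exactly the arc subsets that can yield
a forest, since any other subset leaves some vertex with two parents.
Branches are pruned when a removed arc's endpoints are already forced
into one component (components only grow, so this is sound) or when a
non-leaf vertex has lost all outgoing arcs; the crossing condition is
re-checked on completion. A default budget of 18 arcs guards the
interface; callers may raise it explicitly.

**Path-partition decider.** The main decider searches for one successor
child per non-leaf vertex such that chosen arcs have indegree ≤ 1
everywhere (the chosen subgraph is then automatically a union of
vertex-disjoint directed paths, one ending at each leaf) and no arc of
`N` joins two non-consecutive vertices of a path. The state space is
exponential only in the branching choices, far smaller than subsets of
`A`; children are visited in lexicographic order, so results are
deterministic. The chord test runs on complete assignments: positions
along each path are indexed and every arc checked in one pass.

**Arboreal route.** For networks whose underlying graph is a tree, an
auxiliary graph is built on the vertices with a hybrid child, one edge
per hybrid joining its two parents (arboreality makes this a forest and
the edge–hybrid correspondence a bijection). The network is forest-based
iff every hybrid whose child is again a hybrid lies in a component
containing a *good* vertex (one with a non-hybrid child). For the
certificate, each component is oriented toward its lexicographically
least good vertex; every hybrid then drops the incoming arc from the
*head* of its oriented edge. Every sink of the orientation is good, so
leaf preservation holds, and in a tree every removed arc reconnects two
distinct components, so the crossing condition is automatic. The
certificate is re-validated by an independent checker before being
returned.

**Proper forest-basedness.** A base forest with `m = |R(N)|` trees
exists iff one incoming arc can be deleted from every hybrid — and
nothing else — subject to leaf preservation and crossing: deleting a
tree vertex's incoming arc, or both arcs of a hybrid, would create an
extra root and hence an extra component. The decider enumerates these
`2^{|H|}` choices. For `m = 2` the bipartite omni-extension criterion is
also run and the two verdicts compared at run time; a disagreement would
raise immediately.

**Coloring characterization.** `Γ(N)` has vertex set `R(N) ∪ H(N)` and
one edge per hybrid, `{γ(u'), γ(v')}` for its parents `u', v'`, where
`γ(v)` is the nearest root-or-hybrid ancestor (unique because the walk
only passes tree vertices). Only *minimal* omni-extensions — one added
edge per omnian — are searched: a proper coloring of any omni-extension
restricts to a coloring of a minimal one it contains, and conditions C1
(roots get distinct colors) and C2 (every hybrid is reachable from its
color's root through same-colored hybrids) do not mention the extension.
This reduction is not assumed silently: the equivalence test against the
deletion-based decider runs over hundreds of random 2- and 3-rooted
networks in the suite and in the acceptance script. Colors are
canonicalized as the roots themselves (σ(r) = r), removing permutation
symmetry; C2 is recomputed per complete candidate by per-color
reachability, favoring transparency over speed at these sizes.

**Universality.** `N` is universal when every phylogenetic forest on
`X` is a base forest. The check is exhaustive on both sides (all
forests × all spanning forests) and guarded to `|X| ≤ 5`. The
forbidden-configuration detector looks for a root-or-tree vertex with
hybrid-only directed paths to two distinct leaves (chain lengths ≥ 0).
Two facts shape the tests here. First, a vertex whose two leaf children
form a cherry *is* the length-0 configuration. Second, every
forest-based strict network exhibits the configuration somewhere: at a
lowest root-or-tree vertex all internal descendants are hybrids, and if
its hybrid chains merged instead of reaching two distinct leaves, the
trivial-forest path partition would contain a chord. For `|X| = 3` this
coexists with universality (the found universal fixture shows both);
for `|X| ≥ 4` it is exactly what rules universality out, and the
acceptance run confirms that no tested four-leaf network is universal.

## Cluster systems

`check_P123` evaluates literally: (P1) the clusters inside each
inclusion-maximal cluster form a hierarchy with all trivial clusters;
(P2) the intersection graph of the maximal clusters is connected; (P3)
pairwise intersections of maximal clusters are clusters or empty.
`build_arboreal_network` builds one tree per maximal cluster from its
hierarchy and glues trees in lexicographic order of their sorted label
tuples (the first eligible tree sharing a cluster with the current
network is taken), subdividing the incoming arc of the unique non-hybrid
vertex carrying the shared maximal cluster. Repeated gluing at the same
cluster stacks hybrids into chains, which is where *bad arcs*
(hybrid–hybrid arcs) and the reconstruction ambiguity come from.

One boundary case is worth recording: P1–P3 are not quite sufficient.
The system `{{1},{2},{3},{1,2},{1,3},{2,3}}` satisfies all three, yet
three maximal clusters with three *distinct* pairwise non-empty
intersections would need three hybrids while an arboreal 3-rooted
network has exactly two. The constructor detects the symptom — shared
clusters not nested under a single glue point — and raises a specific
error instead of emitting a wrong network. Cluster systems that actually
come from arboreal networks never hit this case, and the round-trip
property (rebuild, compare cluster systems, compare bad-arc collapses)
is exercised on every generated arboreal instance.

Uniqueness (no non-equivalent arboreal network with the same cluster
system) is decided as bad-arc absence and cross-checked by brute force:
all 11 084 strict arboreal networks with ≤ 8 vertices are enumerated
(free trees × edge orientations × leaf labelings), grouped by cluster
system, and partitioned into equivalence classes.

## Generators and fixtures

The random generator draws binary networks: a forest of uniformly
shuffled binary trees (one per root; each root's block has ≥ 2 leaves),
then reticulations added by subdividing two arcs and joining them,
rejecting picks that would create a directed cycle; the first `m − 1`
reticulations bridge components so the result is connected. The
tree-child kind rejects picks that would leave any vertex with an
all-hybrid child set; the arboreal kind instead attaches each further
root's tree through a fresh hybrid placed on an existing arc, which
keeps the underlying graph a tree and realizes `|H| = |R| − 1` by
construction. Identical configurations reproduce identical networks.
Default draw sizes in tests and the acceptance script are 4–8 leaves
and up to 5 hybrids — the scale at which the exhaustive oracles remain
exact companions; the agreement statements proven at this scale are
spot checks of correctness, not asymptotic benchmarks.

What the generator does *not* emulate: branch lengths, non-binary tree
vertices (except those arising in arboreal attachment), biased
reticulation placement, or any likelihood model of real gene flow.
Passing tests therefore certify combinatorial correctness of the
deciders, not inference quality on empirical data.

The named fixtures are small reference networks reconstructed from the
worked examples that motivate each construct: a proper forest-based
2-network on four labels, a non-forest-based arboreal network, a pair of
arboreal networks sharing a cluster system while not being equivalent,
coloring examples with and without bipartite omni-extensions, a
non-semi-binary counterexample, and a universal network on three labels
found by exhaustive search over small binary networks (at two hybrids
there are exactly 24 two-rooted and 324 single-rooted universal
networks; the shipped one is a smallest two-rooted representative). The
ten class-diagram exemplars realize ten distinct flag patterns over
(tree-child, forest-based, tree-based, tree-sibling,
reticulation-visible), all consistent with the implications tree-child ⇒
forest-based ⇒ tree-based (binary, single-rooted) and tree-child ⇒
tree-sibling ∧ reticulation-visible.

## Numerical and engineering choices

* All vertex iteration orders are lexicographic; every search is
  deterministic and certificates are stable across runs.
* Equivalence is leaf-label-pinned digraph isomorphism via VF2 with
  degree-pair pruning.
* Bipartite matching for the tree-based test uses Hopcroft–Karp.
* `Comp(N)` (bad arcs collapsed) is returned as a relaxed-mode graph and
  never re-validated as semi-binary.
* Exit codes in the CLI report only whether the command ran (0) or the
  input was invalid (3); mathematical verdicts live in the JSON report.

## Known limitations

General forest-based recognition complexity is open; the deciders here
are exact exponential searches with explicit budgets and are intended
for desk-scale networks (tens of vertices), not genome-scale inputs.
Overlaid species forests, unrooted forest-based networks and pedigrees
are out of scope.
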