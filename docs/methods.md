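# Methods

## Objects and validation

All graphs are rooted multidigraphs over opaque vertex ids with arcs
`(tail, head, key)`; the integer key disambiguates parallel arcs, which
X-networks allow (folding a MUL-tree with isomorphic sibling subtrees
creates them) and phylogenetic networks forbid.  Constructors are
lenient; `core.validate(obj, kind)` checks the invariants of a requested
kind and reports violations by vertex, so degenerate intermediates (a
fold result with parallel arcs, a pseudo tree with subdivision vertices)
remain first-class values.  Networks require `|X| >= 2`; (pseudo)
MUL-trees accept `|X| >= 1` so that the single-label cherry `(a,a)` — the
canonical MUL-tree that no phylogenetic network exhibits — is a legal
input.

Structural flags follow the standard definitions: *binary* (all
reticulation and internal tree vertices of total degree three, root
outdegree 2), *semi-resolved* (internal tree vertices of outdegree 2;
the root and reticulation indegrees are unconstrained), *compressed*
(every reticulation's child is a tree vertex), *tree-child* /
*tree-sibling* (every non-leaf vertex has a tree-vertex child / every
reticulation has a tree-vertex sibling).

## Canonical forms

MUL-tree isomorphism is decided by AHU-style codes built bottom-up:
`L(x)` for a leaf, `D(code)` for a subdivision vertex, `I(sorted child
codes)` otherwise.  Codes are collision-free by construction (the
grammar is prefix-unambiguous), and the `D` constructor makes
subdivision patterns part of the identity — the "isomorphic as pseudo
MUL-trees" notion the folding calculus needs.  Re-rooting a subtree
drops the `D` at its root only (the incoming arc is gone), which is how
per-vertex subtree codes are defined.

Network isomorphism (bijections preserving arc multiplicities, identity
on leaf labels) uses VF2 on the attributed multidigraph; the test suite
certifies it against a brute-force bijection search on small instances.
Deterministic serialization needs a canonical *labelling*, not just a
decision, so `canon.canonical_order` runs individualization–refinement:
WL-1 colour refinement seeded by root flag, leaf label and degrees,
then branching on the first ambiguous colour class, keeping the
lexicographically smallest certificate.  Worst-case exponential, but
leaf-label anchoring makes refinement essentially discrete at the sizes
this calculus is used at (tens of vertices).

## Unfolding

`U*(N)` is materialized explicitly — every downstream algorithm
(stability, the guide-tree criterion, lifting) wants the whole tree.
Path counts grow exponentially in the number of reticulations, so
unfolding takes a cap (default `10^5` path vertices) and fails loudly
rather than truncating.  The canonical map `f*` (path to its last
vertex, arc to the extending arc) is returned as an explicit morphism
and verified as a folding map in the suites.

## Folding and the guide tree

The fold sequence `tau` follows the classical procedure: find the
maximal inextendible subtree classes (repeated subtrees contained in no
larger non-isomorphic repeated subtree), keep one copy, delete the
others, repair (suppress the orphaned parent, or collapse the root if
its outdegree dropped to one), iterate.  The class chosen at each step
is a pluggable policy — lexicographically smallest canonical form by
default, a seeded random policy for the order-invariance suites.

The guide tree `T†` is *not* built by replaying the sequence.  Replaying
turns out to be order-dependent: which copy of a class survives changes
which "accidental" repeats the deletions create downstream, and
non-isomorphic guide trees (and folds) can result, even though every
variant still satisfies the round trip.  `T†` instead gets a choice-free
characterization, which the implementation computes directly: group the
non-root vertices of `T` by subtree isomorphism class; a class is
**shared** when its copies would receive two or more incoming arcs in
the quotient — that is, when the copies' parents fall into two or more
distinct classes, or one parent holds two or more copies.  Every arc
into a copy of a shared class is subdivided once.  A class repeated
*only because an ancestor class is repeated* keeps a single parent class
and is left alone, which is exactly why the construction terminates in
one layer: the fold never produces two reticulations in a row, so no
subdivision ever needs to sit above another.  The subdivision vertices
over one shared class form one reticulation of `F(T)`; `F(T)` is the
quotient of `T†` by equality of pseudo-subtree codes, with `m` parallel
arcs `[u] -> [v]` where `m = |ch(u') ∩ [v]|` for any representative
(representative-independence is asserted, not assumed).  A root of
outdegree one in the quotient — possible when the input's root has
outdegree one — is collapsed so the result can satisfy the X-network
root condition.

Order invariance of `T†` and `F(T)` is enforced by construction and
*tested* against randomized fold orders; the sequence-based examples
(the repeated-cherry and repeated-leaf trees, and the fixtures) agree
with the direct construction.

## Stability

Three routes, kept deliberately separate in the report:

* `stable_direct` — refold the unfolding and test network isomorphism.
* `stable_by_thm1` — for semi-resolved networks only (`None`
  otherwise): compressed and no pair of distinct non-leaf tree vertices
  with identical child sets.  Leaves are excluded because their child
  sets are all empty; the root is excluded because sharing its full
  child set with a vertex below it would close a directed cycle.
* `stable_by_cor3` — `U*(N)` isomorphic, as a pseudo MUL-tree, to the
  guide tree of `U(N)`.  No resolution restriction.

Identifiable pairs are computed from the full unfolding: for every path
ending at a tree vertex, the canonical form of the corresponding
`U(N)`-subtree is recorded (subdivision vertices skipped on the fly);
two distinct tree vertices sharing a form are identifiable.  This is
exponential in the worst case (capped); on semi-resolved inputs the
child-set route is the polynomial fast path.

One consequence of the canonical fold is worth stating: **tree-child
networks are always stable**.  A reticulation's only child must be a
tree vertex (tree-child implies compressed), and in a compressed network
a minimal identifiable pair must share its full, all-reticulation child
set — impossible under tree-child — so tree-child networks are
irreducible, and compressed irreducible networks refold to themselves,
multifurcations included.  The stability suites assert this; the
separations that do exist (semi-resolved compressed tree-sibling but
unstable — requires a reticulation with three or more parents; binary
stable but not tree-sibling) are found by randomized search with fixed
seeds.

## Fibrations

Morphisms are explicit data (vertex map + arc map), so every theorem in
this layer is checked by verifying certificates: incidence and leaf
conditions for X-morphisms; surjectivity plus exactly-one-lifting-per-
(arc, fibre-vertex) for folding maps (rootedness falls out and is
checked as a derived property); the five local properties for fibre
partitions, reported per property.  Quotients assign each tree arc a
parallel-arc key bijectively per tail, which makes the projection's
unique-lifting property hold by construction when the partition is
LOIP.  Lifting through a folding map is top-down; for non-rooted
morphisms the base point is a parameter (default: smallest subtree code
in the fibre).

## Display and weak display

Brute-force display keeps one incoming arc per reticulation
(2^|Ret| selections on binary networks, bounded at 12 reticulations by
default), prunes dead branches, suppresses, collapses outdeg-1 roots,
and compares against the guest tree by canonical form; the selected
subgraph is returned as the witness.

Weak display fills the boolean table `tau(v, u)` ("some tree vertex at
or below `u` roots a locally separated reconciliation of `T(v)`") over
topological orderings.  A leaf row is true iff the label occurs at or
below `u`; an internal row is true iff some child of `u` is already
true (any non-leaf `u`, the root included — the climb-down disjunct is
exactly the ancestor-monotonicity of `tau`), or two *distinct* children
split the two guest subtrees.  The distinct-pair search uses the
first-element trick to stay `O(k)` per entry, keeping the table fill
within `O(m·n·k)` updates (asserted in the suites).  Backpointers record
the first witness under a deterministic child ordering, so extracted
reconciliations are reproducible; extraction prefers the climb-down
disjunct and descends to leaves along deterministic label-bearing
paths.  Guest trees must be binary — the recursion's split step assumes
two children, and non-binary display semantics (subdivision subgraph
versus refinement) is deliberately out of scope.

The HangLeaves reduction follows the two-pass construction: subdivide
every arc entering a reticulation and hang the five-vertex gadget at the
subdivision vertex (after this, every reticulation's child is a tree
vertex); then, for each original reticulation, pick one of its
(reticulation) siblings — deterministically, by the sorted labels below
it — subdivide the arc to it and hang the gadget there, providing the
tree-sibling.  The output is binary, compressed and tree-sibling (hence
stable) and displays the transformed guest tree iff the input instance
displayed its tree; both facts are asserted per instance in the suites.

## Synthetic data

Generators draw from one explicit `random.Random` and iterate
deterministically ordered containers, so a seed fixes the output across
platforms.  Networks grow from a random binary tree (sequential leaf
attachment) by repeatedly subdividing two arcs and adding a connecting
arc whose head becomes a reticulation; a reachability check keeps the
graph acyclic, the compressed constraint restricts which arcs may host
the new reticulation, and remaining constraints are rejection-sampled.
Two optional moves leave the binary regime: contracting random internal
tree-tree arcs (multifurcations) and "strengthening" a reticulation
with an extra parent (indegree ≥ 3, still semi-resolved).  MUL-trees
are binary trees with random subtree duplications.  The generators
emulate topology only — no branch lengths, no hybridization-rate model,
no taxon-sampling bias — so the suites certify the combinatorial
calculus, not inference behaviour on empirical data.

## Problem sizes and determinism

The test and acceptance suites run on taxon sets of 3–8, up to 5
reticulations, MUL-trees with 1–3 duplications (≤ ~12 leaves): large
enough to exercise nested sharing, parallel arcs, multifurcations and
indegree-3 reticulations, small enough that brute-force oracles
(bijection enumeration, subdivision search, 2^|Ret| display) stay
exact.  `scripts/acceptance.py` recomputes every suite from a single
`--seed`; the counts per suite (30–150 instances) are chosen so the
whole script completes in well under a minute on one CPU.

## Known limitations

* Unfolding-based routines are exponential in reticulation count; the
  cap makes this explicit rather than silent.
* Network canonical labelling and isomorphism have exponential worst
  cases (the problem is GI-hard); at desk scale refinement is discrete.
* Brute-force display is restricted to binary host and guest trees.
* The minimal-reticulation optimality of semi-resolved folds is not
  verified (it would require exhaustive network enumeration).
* Generators are uniform-ish, not uniform, over network space.
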