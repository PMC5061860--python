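# mulfold

Folding and unfolding between **multi-labelled trees (MUL-trees)** and
**rooted phylogenetic networks**.

## The problem

Polyploid and hybrid lineages carry several genome copies, so a gene tree
built from those copies is naturally a *MUL-tree*: a rooted tree whose
leaves are labelled by species, with repeats.  Reticulate evolution is
instead drawn as a *phylogenetic network*: a rooted DAG whose non-root
vertices are tree vertices or reticulations (indegree ≥ 2, outdegree 1),
leaves labelled bijectively by the taxon set *X*.  The two pictures are
connected by a pair of operations:

* **Unfolding** `U(N)` — the vertices of the pseudo MUL-tree `U*(N)` are
  the directed paths of `N` starting at the root, with an arc from π to
  πa for every arc a of `N`; suppressing the indegree-1/outdegree-1
  vertices gives the MUL-tree `U(N)` that `N` *exhibits*.
* **Folding** `F(T)` — repeated subtrees of a MUL-tree `T` are merged:
  a *guide tree* `T†` subdivides every arc that will enter a shared copy,
  and `F(T)` is the quotient of `T†` by the relation identifying vertices
  with isomorphic pseudo-subtrees.  Always `U(F(T)) ≅ T`.

The library implements this calculus end to end, together with the
decision procedures built on it:

* **Stability** — `N` is *stable* when `F(U(N)) ≅ N`.  Three routes are
  implemented and cross-checked: the direct refold; for semi-resolved
  networks the characterization *compressed + no two tree vertices with
  identical child sets*; and, unconditionally, `U*(N) ≅ [U(N)]†`.
* **Graph fibrations** — X-morphisms and folding maps as explicit
  certificates (vertex map + arc map), a verifier for the five-property
  characterization of fibre partitions, quotients with parallel-arc
  multiplicities, and unique lifting of morphisms through folding maps
  (`U*(N)` behaves as a universal cover).
* **Displaying trees** — brute-force subdivision containment
  (NP-complete in general; the HangLeaves reduction turns any instance
  into an equivalent one on a binary, compressed, tree-sibling — hence
  stable — network), and the polynomial *weak display* test
  (`T` displayed by `U(N)`) via an `O(m·n·k)` dynamic program whose
  positive answers convert into locally separated reconciliation maps.
* **Seeded generators** for binary trees, MUL-trees (subtree
  duplications) and constrained networks, backing a fully synthetic test
  suite.

## A worked example

```python
from mulfold import core, canon, treeio, unfold, fold, stability, display

N1 = core.fixture_N1()                  # one reticulation, X = {a, b, c}
print(treeio.write(N1, "enewick").text)
# ((a,(c)#H1),(b,#H1));

T = unfold.unfold(N1)                   # the MUL-tree N1 exhibits
print(treeio.write(T, "mul_newick").text)
# ((a,c),(b,c));                        <- the leaf c appears twice

refolded = fold.fold(T).result          # fold it back up
print(bool(canon.network_isomorphic(refolded, N1)))
# True                                  <- N1 is stable

rep = stability.is_stable(core.fixture_N2())
print(rep.stable_direct, sorted(map(sorted, rep.identifiable)))
# False [['v', 'w']]                    <- N2 refolds to a parallel-arc
#                                          network; v and w are an
#                                          identifiable pair

t = treeio.read("((a,c),b);", "mul_newick")
ok, _ = display.weakly_displays(N1, t)  # polynomial DP
rec = display.reconciliation(N1, t)     # explicit witness
print(ok, {str(a[0]) + "->" + str(a[1]): [f"{x}->{y}" for x, y, _ in p]
           for a, p in sorted(rec.paths.items())})
# True {'v2->v0': ['u->a'], 'v2->v1': ['u->r', 'r->c'],
#       'v4->v2': ['rho->u'], 'v4->v3': ['rho->v', 'v->b']}
```

The reconciliation maps each vertex of the guest tree to a tree vertex
of `N1` and each guest arc to a directed path; sibling paths leave their
common image through distinct arcs (*local separation*), which is exactly
what weak display certifies.

The same operations are available from the shell (decision commands
answer through the exit code):

```bash
mulfold generate --x-size 5 --reticulations 2 --seed 7 > n.enewick
mulfold unfold n.enewick > t.mulnewick
mulfold fold t.mulnewick --out-format enewick
mulfold stable n.enewick && echo stable
```

## File formats

`json_edgelist` is the normative lossless dialect (explicit vertices,
arcs with parallel-arc keys, root, leaf-label map); extended Newick with
`#Hk` hybrid tags and Newick with repeated leaf labels are conveniences.
Writers order vertices canonically, so isomorphic objects serialize to
identical text.  Branch lengths are rejected — the calculus is purely
topological.

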