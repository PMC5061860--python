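"""Unfolding a network into a MUL-tree.

``U*(N)`` is the pseudo MUL-tree whose vertices are the directed paths of
``N`` starting at the root (the empty path is its root), with an arc from
``pi`` to ``pi'`` iff ``pi'`` extends ``pi`` by one arc of ``N``; leaves
are the root-to-leaf paths, labelled by the label of their endpoint.
``U(N)`` is ``U*(N)`` with all indeg-1/outdeg-1 vertices suppressed.  The
map ``f*`` sending each path to its last vertex (and each arc to the
extending arc) is the canonical folding map — the phylogenetic analogue
of the universal cover projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from . import canon
from .core import (
    Arc,
    MULTree,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    XNetwork,
    suppress,
)
from .fibration import XMorphism

#: default cap on the number of U*(N) vertices (path count is exponential
#: in the number of reticulations in the worst case — fail loudly).
DEFAULT_CAP = 10**5

RootPath = Tuple[Arc, ...]


class CapExceeded(RuntimeError):
    def __init__(self, cap: int):
        super().__init__(
            f"unfolding exceeds the cap of {cap} path vertices; "
            "raise `cap` explicitly to proceed"
        )
        self.cap = cap


@dataclass
class UnfoldResult:
    ustar: PseudoMULTree  # vertices are RootPath tuples
    u: MULTree
    fstar: XMorphism  # ustar -> n, path |-> last vertex
    correspondence: Dict[Vertex, Vertex]  # V(u) -> V(ustar) (identity on ids)


def _last_vertex(n: XNetwork, path: RootPath) -> Vertex:
    return n.dag.root if not path else path[-1][1]


def unfold_star(n: XNetwork, cap: int = DEFAULT_CAP) -> UnfoldResult:
    """Materialize ``U*(N)``, ``U(N)`` and the folding map ``f*``."""
    dag = RootedDAG(root=())
    vmap: Dict[Vertex, Vertex] = {(): n.dag.root}
    amap: Dict[Arc, Arc] = {}
    labels: Dict[Vertex, str] = {}
    stack = [()]  # type: list[RootPath]
    count = 1
    while stack:
        pi = stack.pop()
        last = vmap[pi]
        for a in n.dag.out_arcs(last):
            pi2 = pi + (a,)
            count += 1
            if count > cap:
                raise CapExceeded(cap)
            dag.add_vertex(pi2)
            arc = dag.add_arc(pi, pi2)
            vmap[pi2] = a[1]
            amap[arc] = a
            if a[1] in n.leaf_label:
                labels[pi2] = n.leaf_label[a[1]]
            stack.append(pi2)
    ustar = PseudoMULTree(dag, labels)
    sup = suppress(dag)
    u = MULTree(sup, {v: x for v, x in labels.items() if v in sup.g})
    corr = {v: v for v in sup.vertices}
    return UnfoldResult(
        ustar=ustar, u=u, fstar=XMorphism(vmap, amap), correspondence=corr
    )


def unfold(n: XNetwork, cap: int = DEFAULT_CAP) -> MULTree:
    """``U(N)``: the MUL-tree exhibited by ``N``."""
    return unfold_star(n, cap).u


def exhibits(n: XNetwork, t: PseudoMULTree, cap: int = DEFAULT_CAP) -> bool:
    """True iff ``U(N)`` and ``t`` are isomorphic MUL-trees."""
    if n.X != t.X:
        return False
    return canon.multree_isomorphic(unfold(n, cap), t)
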