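"""Folding a MUL-tree into an X-network.

The folding operation repeatedly locates a maximal inextendible
subMUL-tree (one occurring, up to isomorphism, at two or more distinct
vertices and contained in no strictly larger repeated subtree), deletes
all but one copy, and records where the copies were.  The deletions give
a strictly shrinking sequence ``tau : T = T_1, T_2, ...``; replaying the
chosen classes over the original tree as arc subdivisions yields the
guide tree ``T†``; the quotient of ``T†`` by the relation identifying
vertices with isomorphic pseudo-subtrees is ``G(T)``, and ``F(T)`` is its
suppressed form.  ``U(F(T))`` is always isomorphic to ``T``.

For binary input the classical criterion applies: ``F(T)`` is a
phylogenetic network (no parallel arcs) iff no two siblings of ``T`` root
isomorphic subtrees.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from . import canon, fibration
from .core import GraphError, MULTree, PseudoMULTree, Vertex, XNetwork


@dataclass
class FoldStep:
    code: str  # canonical form of the selected maximal inextendible class
    S: Set[Vertex]  # S_v: all roots of isomorphic copies in T_i
    kept: Vertex  # the surviving representative v


@dataclass
class FoldTrace:
    tau: List[MULTree]
    steps: List[FoldStep] = field(default_factory=list)
    guide: Optional[PseudoMULTree] = None
    partition: Optional[fibration.VertexPartition] = None
    quotient: Optional[XNetwork] = None  # G(T) before suppression
    result: Optional[XNetwork] = None  # F(T)


# ---------------------------------------------------------------------------
# inextendible classes
# ---------------------------------------------------------------------------


def inextendible_roots(t: PseudoMULTree) -> Dict[str, Set[Vertex]]:
    """For each subtree shape occurring at >= 2 distinct non-root vertices,
    the full set of root vertices of its copies."""
    codes = canon.rooted_codes(t)
    groups: Dict[str, Set[Vertex]] = {}
    for v in t.tree.vertices:
        if v != t.root:
            groups.setdefault(codes[v], set()).add(v)
    return {c: vs for c, vs in groups.items() if len(vs) >= 2}


def maximal_inextendible(t: PseudoMULTree) -> Set[str]:
    """Inextendible classes not properly contained in a larger,
    non-isomorphic inextendible class."""
    inx = inextendible_roots(t)
    codes = canon.rooted_codes(t)
    dominated: Set[str] = set()
    for c, vs in inx.items():
        rep = next(iter(vs))
        for u in t.tree.descendants(rep):
            cu = codes[u]
            if cu != c and cu in inx:
                dominated.add(cu)
    return set(inx) - dominated


# ---------------------------------------------------------------------------
# the tree sequence tau
# ---------------------------------------------------------------------------


def _remove_copy(work: PseudoMULTree, w: Vertex) -> None:
    """Delete ``T_i(w)`` and its incoming arc, then repair the parent:
    collapse the root if it became outdeg-1, else suppress the parent if
    it became a subdivision vertex."""
    tree = work.tree
    p = tree.parent(w)
    doomed = {w} | tree.descendants(w)
    for v in doomed:
        tree.remove_vertex(v)
        work.leaf_label.pop(v, None)
    if p == tree.root and tree.outdeg(p) == 1:
        (_, child, _), = tree.out_arcs(p)
        tree.remove_vertex(p)
        tree.root = child
    elif tree.indeg(p) == 1 and tree.outdeg(p) == 1:
        (pp, _, _), = tree.in_arcs(p)
        (_, child, _), = tree.out_arcs(p)
        tree.remove_vertex(p)
        tree.add_arc(pp, child)


#: maps {class code -> sorted copy roots} to the chosen (code, kept vertex)
OrderPolicy = Callable[[Dict[str, List[Vertex]]], Tuple[str, Vertex]]


def lexicographic_policy(candidates: Dict[str, List[Vertex]]) -> Tuple[str, Vertex]:
    """Default policy: smallest canonical form, first copy kept."""
    code = min(candidates)
    return code, candidates[code][0]


def seeded_policy(rng: random.Random) -> OrderPolicy:
    """Random (seeded) choice of class and surviving representative —
    exists to exercise the order-invariance of the fold."""

    def policy(candidates: Dict[str, List[Vertex]]) -> Tuple[str, Vertex]:
        code = rng.choice(sorted(candidates))
        return code, rng.choice(candidates[code])

    return policy


def fold_sequence(
    t: MULTree, order_policy: Optional[OrderPolicy] = None
) -> FoldTrace:
    """Compute the MUL-tree sequence ``tau`` with full per-step provenance."""
    policy = order_policy or lexicographic_policy
    work = t.copy()
    trace = FoldTrace(tau=[t.copy()])
    while True:
        groups = inextendible_roots(work)
        if not groups:
            break
        maximal = maximal_inextendible(work)
        candidates = {c: sorted(groups[c], key=str) for c in maximal}
        code, kept = policy(candidates)
        members = candidates[code]
        for w in members:
            if w != kept:
                _remove_copy(work, w)
        trace.steps.append(FoldStep(code=code, S=set(members), kept=kept))
        trace.tau.append(work.copy())
    return trace


# ---------------------------------------------------------------------------
# guide tree and quotient
# ---------------------------------------------------------------------------


def guide_tree(trace: FoldTrace) -> PseudoMULTree:
    """The guide tree ``T†``: the canonical subdivision of ``T``.

    ``T†`` is independent of the order in which maximal inextendible
    classes are processed; it admits a choice-free characterization that
    this function computes directly.  Group the non-root vertices of
    ``T`` by subtree isomorphism class; a class is *shared* when its
    copies would receive two or more incoming arcs in the quotient —
    i.e. when the copies' parents fall into two or more distinct classes,
    or some single parent holds two or more copies.  Every arc into a
    copy of a shared class is subdivided once (the subdivision vertices
    over one class become one reticulation of ``F(T)``).  Classes shared
    only because an ancestor class is shared keep a single parent class
    and are left alone.  Because ``F(T)`` never places two reticulations
    in a row, one layer of subdivisions suffices.
    """
    t = trace.tau[0]
    tg = PseudoMULTree(t.tree.copy(), dict(t.leaf_label))
    codes = canon.rooted_codes(tg)
    groups: Dict[str, List[Vertex]] = {}
    for v in tg.tree.vertices:
        if v != tg.root:
            groups.setdefault(codes[v], []).append(v)
    counter = 0
    for code in sorted(groups):
        members = groups[code]
        parents = [tg.tree.parent(v) for v in members]
        parent_classes = {codes[p] for p in parents}
        multi = len(parents) != len(set(parents))
        if len(parent_classes) >= 2 or multi:
            for v in members:
                (arc,) = tg.tree.in_arcs(v)
                counter += 1
                tg.tree.subdivide(arc, f"sub{counter}")
    return tg


def fold(t: MULTree, order_policy: Optional[OrderPolicy] = None) -> FoldTrace:
    """The complete folding pipeline; ``trace.result`` is ``F(T)``.

    The result is an X-network (it may carry parallel arcs, in which case
    it is not a phylogenetic network).  A root of outdegree one in the
    quotient — possible when the input's root has outdegree one — is
    collapsed so the root condition of X-networks can hold.
    """
    trace = fold_sequence(t, order_policy)
    tg = guide_tree(trace)
    part = fibration.VertexPartition.from_codes(tg)
    q = fibration.quotient(tg, part)
    trace.guide = tg
    trace.partition = part
    trace.quotient = q.pre_suppression
    result = q.network
    dag = result.dag
    while dag.outdeg(dag.root) == 1 and dag.indeg(dag.root) == 0 and len(dag) > 1:
        (_, child, _), = dag.out_arcs(dag.root)
        dag.remove_vertex(dag.root)
        dag.root = child
    trace.result = result
    return trace


def prop1_yields_network(t: MULTree) -> bool:
    """For binary ``T``: no sibling pair roots isomorphic subtrees.

    Equivalent to ``F(T)`` being a phylogenetic network (free of parallel
    arcs); raises on non-binary input, for which the criterion is not
    stated.
    """
    for v in t.tree.vertices:
        if t.tree.outdeg(v) not in (0, 2):
            raise GraphError("the sibling criterion applies to binary MUL-trees only")
    codes = canon.rooted_codes(t)
    for v in t.tree.vertices:
        kids = t.tree.children(v)
        seen: Set[str] = set()
        for c in kids:
            if codes[c] in seen:
                return False
            seen.add(codes[c])
    return True
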