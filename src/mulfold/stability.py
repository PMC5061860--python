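"""Stable networks: F(U(N)) ≅ N, decided by three independent routes.

A phylogenetic network is *stable* when refolding its unfolding gives the
network back.  Besides the direct test, two characterizations are
implemented: for semi-resolved networks, stability is equivalent to being
compressed with no two distinct (non-leaf) tree vertices sharing their
full child set; unconditionally, it is equivalent to ``U*(N)`` being
isomorphic, as a pseudo MUL-tree, to the guide tree ``[U(N)]†``.  Two
tree vertices are *identifiable* when some pair of root paths to them
carries isomorphic subtrees of ``U(N)``; a network with no such pair is
*irreducible*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Set

from . import canon, fold as fold_mod, unfold as unfold_mod
from .core import (
    INTERNAL_TREE,
    LEAF,
    PhylogeneticNetwork,
    Vertex,
    properties,
    vertex_class,
)


@dataclass
class StabilityReport:
    stable_direct: bool
    compressed: bool
    irreducible: bool
    duplicate_child_sets: Set[FrozenSet[Vertex]]
    stable_by_thm1: Optional[bool]  # None when not semi-resolved
    stable_by_cor3: bool
    identifiable: Set[FrozenSet[Vertex]]


def _suppressed_subtree_codes(ur: unfold_mod.UnfoldResult) -> Dict[Vertex, str]:
    """Codes of the U(N)-subtrees, indexed by U*(N) vertices.

    Subdivision vertices of U*(N) are skipped (they vanish in U(N)), so a
    path vertex's code equals the canonical form of the corresponding
    subtree of the suppressed MUL-tree U(N).
    """
    tree = ur.ustar.tree
    codes: Dict[Vertex, str] = {}
    for v in reversed(tree.topological_order()):
        if tree.outdeg(v) == 0:
            codes[v] = f"L({ur.ustar.leaf_label[v]})"
        elif tree.indeg(v) == 1 and tree.outdeg(v) == 1:
            codes[v] = codes[tree.children(v)[0]]
        else:
            kids = sorted(codes[h] for _, h, _ in tree.out_arcs(v))
            codes[v] = "I(" + ",".join(kids) + ")"
    return codes


def identifiable_pairs(
    n: PhylogeneticNetwork, cap: int = unfold_mod.DEFAULT_CAP
) -> Set[FrozenSet[Vertex]]:
    """Unordered pairs of distinct tree vertices carrying isomorphic
    root-path subtrees of U(N)."""
    ur = unfold_mod.unfold_star(n, cap)
    codes = _suppressed_subtree_codes(ur)
    tree_vertices = {
        v
        for v in n.dag.vertices
        if vertex_class(n.dag, v) in (INTERNAL_TREE, LEAF)
    }
    by_code: Dict[str, Set[Vertex]] = {}
    for pi in ur.ustar.tree.vertices:
        if pi == ():
            continue
        v = ur.fstar.vmap[pi]
        if v in tree_vertices:
            by_code.setdefault(codes[pi], set()).add(v)
    pairs: Set[FrozenSet[Vertex]] = set()
    for vs in by_code.values():
        if len(vs) >= 2:
            vs = sorted(vs, key=str)
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    pairs.add(frozenset((vs[i], vs[j])))
    return pairs


def is_irreducible(
    n: PhylogeneticNetwork, cap: int = unfold_mod.DEFAULT_CAP
) -> bool:
    return not identifiable_pairs(n, cap)


def duplicate_child_sets(n: PhylogeneticNetwork) -> Set[FrozenSet[Vertex]]:
    """Pairs of distinct non-leaf tree vertices with identical child sets."""
    internal = [
        v for v in n.dag.vertices if vertex_class(n.dag, v) == INTERNAL_TREE
    ]
    by_children: Dict[FrozenSet[Vertex], Set[Vertex]] = {}
    for v in internal:
        by_children.setdefault(frozenset(n.dag.children(v)), set()).add(v)
    pairs: Set[FrozenSet[Vertex]] = set()
    for vs in by_children.values():
        if len(vs) >= 2:
            vs = sorted(vs, key=str)
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    pairs.add(frozenset((vs[i], vs[j])))
    return pairs


def is_stable(
    n: PhylogeneticNetwork, cap: int = unfold_mod.DEFAULT_CAP
) -> StabilityReport:
    """Full stability report; the three routes agree on semi-resolved input."""
    ur = unfold_mod.unfold_star(n, cap)
    trace = fold_mod.fold(ur.u)
    stable_direct = bool(canon.network_isomorphic(trace.result, n))

    props = properties(n)
    ident = identifiable_pairs(n, cap)
    dup = duplicate_child_sets(n)
    thm1 = (props.compressed and not dup) if props.semi_resolved else None

    guide = fold_mod.guide_tree(fold_mod.fold_sequence(ur.u))
    cor3 = canon.multree_isomorphic(ur.ustar, guide)

    return StabilityReport(
        stable_direct=stable_direct,
        compressed=props.compressed,
        irreducible=not ident,
        duplicate_child_sets=dup,
        stable_by_thm1=thm1,
        stable_by_cor3=cor3,
        identifiable=ident,
    )
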