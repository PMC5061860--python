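"""X-morphisms, folding maps, fibration partitions, quotients and lifting.

This is the graph-fibration machinery of the calculus: a folding map
``f : T -> N`` from a pseudo MUL-tree onto a network is a surjective,
incidence- and label-preserving vertex+arc map with unique arc liftings
(for every arc ``a`` of ``N`` and every ``v`` in the fibre of ``t(a)``
there is exactly one arc of ``T`` at ``v`` mapping to ``a``).  An
equivalence relation on ``V(T)`` is the fibre partition of such a map iff
it satisfies five local properties, the first being the local
out-isomorphism property (LOIP).  Morphisms are explicit data throughout,
so every theorem of the calculus is testable by verifying certificates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import canon
from .core import (
    Arc,
    GraphError,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    XNetwork,
    _suppress_inplace,
)


@dataclass
class XMorphism:
    """Vertex map ``f_V`` plus arc map ``f_A`` (incidence-preserving)."""

    vmap: Dict[Vertex, Vertex]
    amap: Dict[Arc, Arc]


@dataclass
class MorphismReport:
    ok: bool
    violations: List[str] = field(default_factory=list)


@dataclass
class FoldingMapReport:
    ok: bool
    violations: List[str] = field(default_factory=list)
    #: (arc of N, fibre vertex) -> number of liftings found (on violation)
    lifting_counts: Dict[Tuple[Arc, Vertex], int] = field(default_factory=dict)


def verify_x_morphism(
    f: XMorphism, t: PseudoMULTree, n: XNetwork, rooted: bool = False
) -> MorphismReport:
    """Check incidence preservation, the leaf condition and (optionally)
    the root condition."""
    v9n: List[str] = []
    label_to_leaf = {x: v for v, x in n.leaf_label.items()}
    for v in t.tree.vertices:
        if v not in f.vmap:
            v9n.append(f"vertex map not total: {v!r} missing")
    for a in t.tree.arcs:
        if a not in f.amap:
            v9n.append(f"arc map not total: {a!r} missing")
            continue
        fa = f.amap[a]
        if fa not in set(n.dag.arcs):
            v9n.append(f"arc {a!r} maps outside A(N): {fa!r}")
            continue
        if f.vmap.get(a[0]) != fa[0] or f.vmap.get(a[1]) != fa[1]:
            v9n.append(f"incidence violated at arc {a!r} -> {fa!r}")
    for v, x in t.leaf_label.items():
        if f.vmap.get(v) != label_to_leaf.get(x):
            v9n.append(f"leaf {v!r} (label {x}) does not map to the leaf {x} of N")
    if rooted and f.vmap.get(t.root) != n.dag.root:
        v9n.append("root of T does not map to the root of N")
    return MorphismReport(ok=not v9n, violations=v9n)


def verify_folding_map(
    f: XMorphism, t: PseudoMULTree, n: XNetwork
) -> FoldingMapReport:
    """Surjectivity plus the unique-arc-lifting property.

    A valid folding map is necessarily rooted; rootedness is checked here
    as a derived consequence, not assumed.
    """
    base = verify_x_morphism(f, t, n, rooted=False)
    v9n = list(base.violations)
    counts: Dict[Tuple[Arc, Vertex], int] = {}
    if set(f.vmap.values()) != set(n.dag.vertices):
        v9n.append("vertex map is not surjective onto V(N)")
    if set(f.amap.values()) != set(n.dag.arcs):
        v9n.append("arc map is not surjective onto A(N)")
    # liftings: group arcs of T by (tail image ... ) lazily
    by_tail_and_image: Dict[Tuple[Vertex, Arc], int] = {}
    for a, fa in f.amap.items():
        key = (a[0], fa)
        by_tail_and_image[key] = by_tail_and_image.get(key, 0) + 1
    fibres: Dict[Vertex, List[Vertex]] = {}
    for v, fv in f.vmap.items():
        fibres.setdefault(fv, []).append(v)
    for a in n.dag.arcs:
        for v in fibres.get(a[0], ()):
            c = by_tail_and_image.get((v, a), 0)
            if c != 1:
                counts[(a, v)] = c
                v9n.append(
                    f"arc {a!r} has {c} liftings at fibre vertex {v!r} (want 1)"
                )
    return FoldingMapReport(ok=not v9n, violations=v9n, lifting_counts=counts)


# ---------------------------------------------------------------------------
# partitions and quotients
# ---------------------------------------------------------------------------


@dataclass
class VertexPartition:
    blocks: List[Set[Vertex]]

    def block_of(self) -> Dict[Vertex, int]:
        out: Dict[Vertex, int] = {}
        for i, b in enumerate(self.blocks):
            for v in b:
                out[v] = i
        return out

    @staticmethod
    def from_codes(t: PseudoMULTree) -> "VertexPartition":
        """The canonical partition grouping vertices by subtree code
        (the relation ``~`` used by the folding operation)."""
        codes = canon.rooted_codes(t)
        groups: Dict[str, Set[Vertex]] = {}
        for v in t.tree.vertices:
            groups.setdefault(codes[v], set()).add(v)
        return VertexPartition([groups[c] for c in sorted(groups)])


@dataclass
class FibrationReport:
    ok: bool
    properties: Dict[str, bool]
    violations: List[str] = field(default_factory=list)


def partition_is_fibration(
    t: PseudoMULTree, p: VertexPartition
) -> FibrationReport:
    """Check the five properties characterizing fibre partitions.

    (i) LOIP; (ii) subdivision vertices sit in classes of size >= 2 with a
    classmate whose parent is inequivalent; (iii) non-subdivision
    non-root vertices have all classmates' parents equivalent; (iv) leaf
    classes are exactly the label classes; (v) no two distinct classmates
    share a parent (no parallel arcs in the quotient).
    """
    tree = t.tree
    bl = p.block_of()
    if set(bl) != set(tree.vertices):
        raise GraphError("partition does not cover V(T) exactly")
    v9n: List[str] = []
    props = {k: True for k in ("loip", "subdivision", "tree_vertex", "leaf", "parallel")}

    def profile(v: Vertex) -> Dict[int, int]:
        out: Dict[int, int] = {}
        for _, h, _ in tree.out_arcs(v):
            out[bl[h]] = out.get(bl[h], 0) + 1
        return out

    for block in p.blocks:
        it = iter(block)
        v0 = next(it)
        prof0 = profile(v0)
        for v in it:
            if profile(v) != prof0:
                props["loip"] = False
                v9n.append(f"LOIP violated inside block of {v0!r} (at {v!r})")
                break

    def pa(v: Vertex) -> Optional[Vertex]:
        ps = tree.parents(v)
        return ps[0] if len(ps) == 1 else None

    for v in tree.vertices:
        if v == tree.root:
            continue
        block = p.blocks[bl[v]]
        if tree.indeg(v) == 1 and tree.outdeg(v) == 1:
            ok = len(block) >= 2 and any(
                w != v and (pa(w) is None or bl[pa(w)] != bl[pa(v)]) for w in block
            )
            if not ok:
                props["subdivision"] = False
                v9n.append(f"property (ii) violated at subdivision vertex {v!r}")
        else:
            for w in block:
                pw = pa(w)
                if pw is None or pa(v) is None or bl[pw] != bl[pa(v)]:
                    props["tree_vertex"] = False
                    v9n.append(f"property (iii) violated at {v!r} (classmate {w!r})")
                    break
    label_classes = t.label_classes()
    for x, cls in label_classes.items():
        v = next(iter(cls))
        if p.blocks[bl[v]] != cls:
            props["leaf"] = False
            v9n.append(f"property (iv) violated for label {x}")
    for v in tree.vertices:
        if v == tree.root:
            continue
        for w in p.blocks[bl[v]]:
            if w != v and pa(w) is not None and pa(w) == pa(v):
                props["parallel"] = False
                v9n.append(f"property (v) violated: {v!r} and {w!r} share a parent")
                break
        if not props["parallel"]:
            break
    return FibrationReport(ok=not v9n, properties=props, violations=v9n)


class QuotientError(ValueError):
    """Raised when arc multiplicities are representative-dependent or a
    block maps onto itself (the partition is not LOIP)."""


@dataclass
class QuotientResult:
    network: XNetwork  # after suppression
    pre_suppression: XNetwork  # G(T): the raw quotient DAG
    projection: XMorphism  # T -> pre_suppression
    suppressed: List[Vertex]  # vertices of G(T) removed by suppression


def quotient(t: PseudoMULTree, p: VertexPartition) -> QuotientResult:
    """Quotient of ``T`` by a partition: ``m`` parallel arcs ``[u] -> [v]``
    where ``m = |ch(u') ∩ [v]|`` for any representative ``u'`` (checked to
    be representative-independent)."""
    tree = t.tree
    bl = p.block_of()
    if set(bl) != set(tree.vertices):
        raise GraphError("partition does not cover V(T) exactly")
    nblocks = len(p.blocks)
    bid = [f"q{i}" for i in range(nblocks)]

    # per-block child profile; must be identical across representatives
    mult: Dict[Tuple[int, int], int] = {}
    arc_assign: Dict[Arc, Arc] = {}
    dag = RootedDAG(root=bid[bl[tree.root]])
    for i in range(nblocks):
        dag.add_vertex(bid[i])
    for i, block in enumerate(p.blocks):
        profiles = {}
        for u in block:
            prof: Dict[int, int] = {}
            for _, h, _ in tree.out_arcs(u):
                prof[bl[h]] = prof.get(bl[h], 0) + 1
            profiles[u] = prof
        first = next(iter(block))
        for u, prof in profiles.items():
            if prof != profiles[first]:
                raise QuotientError(
                    f"arc multiplicity depends on the representative in block "
                    f"{sorted(map(str, block))}"
                )
        if profiles[first].get(i):
            raise QuotientError(
                f"block {sorted(map(str, block))} has an internal arc "
                "(quotient would contain a loop)"
            )
        for j, m in sorted(profiles[first].items()):
            for k in range(m):
                dag.add_arc(bid[i], bid[j], key=k)
        # assign each tree arc a parallel-arc key, bijectively per tail
        for u in block:
            kids = sorted(tree.out_arcs(u), key=lambda a: (bl[a[1]], str(a[1]), a[2]))
            seen: Dict[int, int] = {}
            for a in kids:
                j = bl[a[1]]
                k = seen.get(j, 0)
                seen[j] = k + 1
                arc_assign[a] = (bid[i], bid[j], k)

    # leaf labels: a block that is a leaf of the quotient must be a label class
    labels: Dict[Vertex, str] = {}
    for i, block in enumerate(p.blocks):
        if dag.outdeg(bid[i]) == 0:
            labs = {t.leaf_label.get(v) for v in block}
            if len(labs) != 1 or None in labs:
                raise QuotientError(
                    f"leaf block {sorted(map(str, block))} carries labels {labs}"
                )
            labels[bid[i]] = labs.pop()

    pre = XNetwork(dag.copy(), dict(labels))
    proj = XMorphism({v: bid[bl[v]] for v in tree.vertices}, arc_assign)
    sup = dag.copy()
    before = set(sup.vertices)
    _suppress_inplace(sup)
    suppressed = sorted(before - set(sup.vertices), key=str)
    net = XNetwork(sup, {v: x for v, x in labels.items() if v in sup.g})
    return QuotientResult(
        network=net, pre_suppression=pre, projection=proj, suppressed=suppressed
    )


# ---------------------------------------------------------------------------
# lifting (Theorem-4-style path lifting)
# ---------------------------------------------------------------------------


def lift(
    g: XMorphism,
    f: XMorphism,
    t_prime: PseudoMULTree,
    t: PseudoMULTree,
    n: XNetwork,
    base_point: Optional[Vertex] = None,
) -> XMorphism:
    """Lift ``g : T' -> N`` through the folding map ``f : T -> N``.

    Built top-down: the root of ``T'`` is sent to a vertex of the fibre
    ``f^{-1}(g(rho_{T'}))`` (the unique ``rho_T`` when ``g`` is rooted;
    otherwise ``base_point`` or the fibre member with the smallest
    subtree code), and every arc is lifted through the unique lifting at
    the current image.  The contract ``f ∘ lift(g, f) = g`` holds exactly.
    """
    # unique-lifting index for f: (vertex of T, arc of N) -> arc of T
    lift_index: Dict[Tuple[Vertex, Arc], Arc] = {}
    for a, fa in f.amap.items():
        key = (a[0], fa)
        if key in lift_index:
            raise GraphError("f does not have unique liftings (not a folding map)")
        lift_index[key] = a

    g_root_image = g.vmap[t_prime.root]
    fibre = sorted((v for v, fv in f.vmap.items() if fv == g_root_image), key=str)
    if not fibre:
        raise GraphError("empty fibre over the image of the root of T'")
    if base_point is not None:
        if f.vmap.get(base_point) != g_root_image:
            raise GraphError("base_point is not in the fibre over g(root)")
        start = base_point
    elif g_root_image == n.dag.root:
        roots = [v for v in fibre if v == t.root]
        start = roots[0] if roots else fibre[0]
    else:
        codes = canon.rooted_codes(t)
        start = min(fibre, key=lambda v: (codes[v], str(v)))

    vmap: Dict[Vertex, Vertex] = {t_prime.root: start}
    amap: Dict[Arc, Arc] = {}
    order = t_prime.tree.topological_order()
    for v in order:
        for a in t_prime.tree.out_arcs(v):
            ga = g.amap[a]
            key = (vmap[v], ga)
            if key not in lift_index:
                raise GraphError(
                    f"no lifting of {ga!r} at {vmap[v]!r}: f is not a folding map "
                    "over the image of g"
                )
            ta = lift_index[key]
            amap[a] = ta
            vmap[a[1]] = ta[1]
    return XMorphism(vmap, amap)
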