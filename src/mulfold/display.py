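"""Displaying and weakly displaying trees in networks.

A network *displays* a tree when some subgraph is a subdivision of the
tree — NP-complete to decide even on stable networks, which the
HangLeaves reduction makes concrete by turning any display instance into
an equivalent one on a binary, compressed, tree-sibling (hence stable)
network.  A tree is *weakly displayed* by ``N`` when ``U(N)`` displays
it; this is decidable in ``O(m·n·k)`` time by a dynamic program over a
boolean table ``tau(v, u)`` ("does some tree vertex at or below ``u``
root a locally separated reconciliation of ``T(v)``?"), and a positive
answer converts into an explicit locally separated reconciliation map by
following backpointers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from . import canon
from .core import (
    Arc,
    GraphError,
    INTERNAL_TREE,
    LEAF,
    MULTree,
    PhylogeneticNetwork,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    XNetwork,
    _suppress_inplace,
    vertex_class,
)

DEFAULT_RET_BOUND = 12
RET = "reticulation"


def _check_binary_tree(t: PseudoMULTree) -> None:
    for v in t.tree.vertices:
        if t.tree.outdeg(v) not in (0, 2):
            raise GraphError("a binary tree is required (outdegrees 0 or 2)")


# ---------------------------------------------------------------------------
# brute-force display
# ---------------------------------------------------------------------------


def _clean_to_tree(dag: RootedDAG, labels: Dict[Vertex, str]) -> PseudoMULTree:
    """Prune dead branches, suppress, and collapse outdeg-1 roots."""
    dag = dag.copy()
    changed = True
    while changed:
        changed = False
        for v in list(dag.vertices):
            if v in dag and v not in labels and dag.outdeg(v) == 0:
                dag.remove_vertex(v)
                changed = True
        _suppress_inplace(dag)
        while dag.outdeg(dag.root) == 1 and len(dag) > 1:
            (_, child, _), = dag.out_arcs(dag.root)
            dag.remove_vertex(dag.root)
            dag.root = child
            changed = True
    return PseudoMULTree(dag, {v: x for v, x in labels.items() if v in dag.g})


def displays_bruteforce(
    n: PhylogeneticNetwork,
    t: PseudoMULTree,
    ret_bound: int = DEFAULT_RET_BOUND,
) -> Tuple[bool, Optional[XNetwork]]:
    """Enumerate one-parent selections at every reticulation.

    Keeping one incoming arc per reticulation and cleaning the remains
    yields every tree the network displays; returns the first selection
    (pre-cleaning) whose cleaned tree is isomorphic to ``t``.
    """
    _check_binary_tree(t)
    rets = sorted(
        (v for v in n.dag.vertices if vertex_class(n.dag, v) == RET),
        key=str,
    )
    if len(rets) > ret_bound:
        raise GraphError(
            f"{len(rets)} reticulations exceed the brute-force bound {ret_bound}"
        )
    if n.X != t.X:
        return False, None
    target = canon.canonical_form(t)
    choices = [sorted(n.dag.in_arcs(r)) for r in rets]
    removable = {a for opts in choices for a in opts}
    for pick in itertools.product(*choices):
        drop = removable - set(pick)
        sel = RootedDAG(
            [a for a in n.dag.arcs if a not in drop],
            vertices=n.dag.vertices,
            root=n.dag.root,
        )
        cleaned = _clean_to_tree(sel, n.leaf_label)
        if canon.canonical_form(cleaned) == target:
            witness = XNetwork(sel, dict(n.leaf_label))
            return True, witness
    return False, None


def displays_in_multree(mt: PseudoMULTree, t: PseudoMULTree) -> bool:
    """Does the MUL-tree contain a subgraph that is a subdivision of ``t``?

    Straightforward memoized search over host-tree vertices (leaves of
    ``t`` matched to same-labelled leaves; branches land in disjoint host
    subtrees) — the independent oracle for the weak-display DP.
    """
    _check_binary_tree(t)
    if not (t.X <= mt.X):
        return False
    host = mt.tree
    emb_memo: Dict[Tuple[Vertex, Vertex], bool] = {}
    reach_memo: Dict[Tuple[Vertex, Vertex], bool] = {}

    def emb(v: Vertex, w: Vertex) -> bool:
        key = (v, w)
        if key not in emb_memo:
            if t.tree.outdeg(v) == 0:
                emb_memo[key] = mt.leaf_label.get(w) == t.leaf_label[v]
            else:
                v1, v2 = t.tree.children(v)
                kids = host.children(w)
                a = [c for c in kids if reach(v1, c)]
                b = [c for c in kids if reach(v2, c)]
                emb_memo[key] = bool(a and b and len(set(a) | set(b)) >= 2)
        return emb_memo[key]

    def reach(v: Vertex, w: Vertex) -> bool:
        key = (v, w)
        if key not in reach_memo:
            reach_memo[key] = emb(v, w) or any(
                reach(v, c) for c in host.children(w)
            )
        return reach_memo[key]

    return reach(t.root, mt.root)


# ---------------------------------------------------------------------------
# weak display dynamic program
# ---------------------------------------------------------------------------


@dataclass
class DPTable:
    tau: Dict[Tuple[Vertex, Vertex], int]
    back: Dict[Tuple[Vertex, Vertex], Tuple]
    m: int  # |V(T)|
    n: int  # |V(N)|
    k: int  # max outdegree in N
    updates: int = 0


def weakly_displays(
    n: PhylogeneticNetwork, t: PseudoMULTree
) -> Tuple[bool, DPTable]:
    """Fill ``tau`` over topological orderings; answer ``tau(rho_T, rho_N)``.

    ``tau(v, u) = 1`` iff ``u`` is a non-leaf with ``tau(v, u') = 1`` for
    some child ``u'``, or two distinct children ``u1 != u2`` of ``u``
    satisfy ``tau(v1, u1) = tau(v2, u2) = 1`` (for a leaf ``v`` labelled
    ``x``: iff ``u`` is the leaf ``x`` or ``x`` lies below ``u``).
    """
    _check_binary_tree(t)
    dag = n.dag
    order_n = list(reversed(dag.topological_order()))  # leaves first
    order_t = list(reversed(t.tree.topological_order()))
    at_or_below: Dict[Vertex, Set[str]] = {}
    for u in order_n:
        s: Set[str] = set()
        if u in n.leaf_label:
            s.add(n.leaf_label[u])
        for c in dag.children(u):
            s |= at_or_below[c]
        at_or_below[u] = s

    table = DPTable(
        tau={},
        back={},
        m=len(t.tree),
        n=len(dag),
        k=max((dag.outdeg(u) for u in dag.vertices), default=0),
    )
    tau = table.tau
    for v in order_t:
        is_leaf = t.tree.outdeg(v) == 0
        if not is_leaf:
            v1, v2 = sorted(t.tree.children(v), key=str)
        for u in order_n:
            val = 0
            bp: Optional[Tuple] = None
            if is_leaf:
                val = int(t.leaf_label[v] in at_or_below[u])
            else:
                kids = sorted(dag.children(u), key=str)
                table.updates += max(len(kids), 1)
                for c in kids:
                    if tau[(v, c)]:
                        val, bp = 1, ("down", c)
                        break
                if not val:
                    a = [c for c in kids if tau[(v1, c)]]
                    b = [c for c in kids if tau[(v2, c)]]
                    pair = _distinct_pair(a, b)
                    if pair:
                        val, bp = 1, ("split", v1, pair[0], v2, pair[1])
            tau[(v, u)] = val
            if bp is not None:
                table.back[(v, u)] = bp
    ans = bool(tau[(t.root, dag.root)])
    return ans, table


def _distinct_pair(a: List[Vertex], b: List[Vertex]) -> Optional[Tuple[Vertex, Vertex]]:
    if not a or not b:
        return None
    if a[0] != b[0]:
        return a[0], b[0]
    if len(b) >= 2:
        return a[0], b[1]
    if len(a) >= 2:
        return a[1], b[0]
    return None


# ---------------------------------------------------------------------------
# reconciliation maps
# ---------------------------------------------------------------------------


@dataclass
class ReconciliationMap:
    r: Dict[Vertex, Vertex]  # V(T) -> V_tr(N)
    paths: Dict[Arc, List[Arc]]  # arc of T -> directed path in N


@dataclass
class ReconciliationReport:
    ok: bool
    locally_separated: bool
    violations: List[str] = field(default_factory=list)


def reconciliation(
    n: PhylogeneticNetwork, t: PseudoMULTree
) -> Optional[ReconciliationMap]:
    """Extract a locally separated reconciliation from the DP backpointers
    (None when ``t`` is not weakly displayed)."""
    ok, table = weakly_displays(n, t)
    if not ok:
        return None
    dag = n.dag
    at_or_below: Dict[Vertex, Set[str]] = {}
    for u in reversed(dag.topological_order()):
        s: Set[str] = set()
        if u in n.leaf_label:
            s.add(n.leaf_label[u])
        for c in dag.children(u):
            s |= at_or_below[c]
        at_or_below[u] = s

    rmap: Dict[Vertex, Vertex] = {}
    paths: Dict[Arc, List[Arc]] = {}

    def first_arc(u: Vertex, c: Vertex) -> Arc:
        ks = sorted(k for tt, h, k in dag.out_arcs(u) if h == c)
        return (u, c, ks[0])

    def descend(v: Vertex, u: Vertex) -> List[Arc]:
        """Fill the map below ``v``; return the entry path u -> r(v)."""
        if t.tree.outdeg(v) == 0:
            x = t.leaf_label[v]
            entry: List[Arc] = []
            cur = u
            while n.leaf_label.get(cur) != x:
                nxt = next(
                    c for c in sorted(dag.children(cur), key=str)
                    if x in at_or_below[c]
                )
                entry.append(first_arc(cur, nxt))
                cur = nxt
            rmap[v] = cur
            return entry
        bp = table.back[(v, u)]
        if bp[0] == "down":
            return [first_arc(u, bp[1])] + descend(v, bp[1])
        _, v1, u1, v2, u2 = bp
        rmap[v] = u
        for vi, ui in ((v1, u1), (v2, u2)):
            (arc_t,) = [a for a in t.tree.out_arcs(v) if a[1] == vi]
            paths[arc_t] = [first_arc(u, ui)] + descend(vi, ui)
        return []

    descend(t.root, dag.root)
    return ReconciliationMap(r=rmap, paths=paths)


def verify_reconciliation(
    rec: ReconciliationMap, t: PseudoMULTree, n: PhylogeneticNetwork
) -> ReconciliationReport:
    """Check the reconciliation axioms plus local separation."""
    v9n: List[str] = []
    dag = n.dag
    arcs_n = set(dag.arcs)
    v_tr = {dag.root} | {
        v for v in dag.vertices if vertex_class(dag, v) in (INTERNAL_TREE, LEAF)
    }
    label_to_leaf = {x: v for v, x in n.leaf_label.items()}
    for v in t.tree.vertices:
        if v not in rec.r:
            v9n.append(f"r not total: {v!r} missing")
        elif rec.r[v] not in v_tr:
            v9n.append(f"r({v!r}) = {rec.r[v]!r} is not a tree vertex or the root")
    for v, x in t.leaf_label.items():
        if rec.r.get(v) != label_to_leaf.get(x):
            v9n.append(f"leaf {v!r} (label {x}) does not map to the leaf {x}")
    for a in t.tree.arcs:
        if a not in rec.paths:
            v9n.append(f"no path recorded for arc {a!r}")
            continue
        p = rec.paths[a]
        for arc in p:
            if arc not in arcs_n:
                v9n.append(f"path for {a!r} uses non-arc {arc!r}")
        for x, y in zip(p, p[1:]):
            if x[1] != y[0]:
                v9n.append(f"path for {a!r} is not chained at {x!r} -> {y!r}")
        start = p[0][0] if p else rec.r.get(a[0])
        end = p[-1][1] if p else rec.r.get(a[0])
        if start != rec.r.get(a[0]) or end != rec.r.get(a[1]):
            v9n.append(
                f"path for {a!r} runs {start!r} -> {end!r}, expected "
                f"{rec.r.get(a[0])!r} -> {rec.r.get(a[1])!r}"
            )
    sep = True
    for v in t.tree.vertices:
        kid_arcs = t.tree.out_arcs(v)
        if len(kid_arcs) < 2:
            continue
        firsts = []
        for a in kid_arcs:
            p = rec.paths.get(a)
            if not p:
                sep = False
                v9n.append(f"sibling path for {a!r} is empty")
            else:
                firsts.append(p[0])
        if len(firsts) != len(set(firsts)):
            sep = False
            v9n.append(f"sibling paths below {v!r} share an initial arc")
    ok = not v9n
    return ReconciliationReport(ok=ok, locally_separated=ok and sep, violations=v9n)


# ---------------------------------------------------------------------------
# HangLeaves and the stable-instance reduction
# ---------------------------------------------------------------------------


def hang_leaves(
    n: XNetwork,
    r: PseudoMULTree,
    v: Vertex,
    names: Optional[Tuple[str, str, str, str, str]] = None,
) -> Tuple[XNetwork, PseudoMULTree]:
    """Attach the five-vertex gadget at ``v`` in the network and its
    four-vertex counterpart to the tree.

    Adds to ``N``: vertices ``x_v, x'_v, p_v, q_v, rho_v`` and arcs
    ``(rho_v, rho_N), (rho_v, p_v), (p_v, q_v), (v, q_v), (p_v, x'_v),
    (q_v, x_v)`` (``q_v`` becomes a new reticulation, ``rho_v`` the new
    root).  Adds to ``R``: ``x_v, x'_v, rho_v, p_v`` and arcs
    ``(rho_v, rho_R), (rho_v, p_v), (p_v, x_v), (p_v, x'_v)``.
    """
    if v not in n.dag:
        raise GraphError(f"vertex {v!r} not in network")
    if names is None:
        names = (f"x[{v}]", f"x'[{v}]", f"p[{v}]", f"q[{v}]", f"rho[{v}]")
    xv, xv2, pv, qv, rhov = names
    if {xv, xv2} & (n.X | r.X):
        raise GraphError(f"labels {xv!r}/{xv2!r} collide with existing taxa")
    n2, r2 = n.copy(), r.copy()
    for g, new in ((n2.dag, (xv, xv2, pv, qv, rhov)), (r2.tree, (xv, xv2, rhov, pv))):
        for u in new:
            if u in g:
                raise GraphError(f"vertex name {u!r} already in use")
            g.add_vertex(u)
    nd = n2.dag
    nd.add_arc(rhov, nd.root)
    nd.add_arc(rhov, pv)
    nd.add_arc(pv, qv)
    nd.add_arc(v, qv)
    nd.add_arc(pv, xv2)
    nd.add_arc(qv, xv)
    nd.root = rhov
    n2.leaf_label[xv] = xv
    n2.leaf_label[xv2] = xv2
    rd = r2.tree
    rd.add_arc(rhov, rd.root)
    rd.add_arc(rhov, pv)
    rd.add_arc(pv, xv)
    rd.add_arc(pv, xv2)
    rd.root = rhov
    r2.leaf_label[xv] = xv
    r2.leaf_label[xv2] = xv2
    return n2, r2


def stable_instance(
    n: PhylogeneticNetwork, t: PseudoMULTree
) -> Tuple[PhylogeneticNetwork, PseudoMULTree]:
    """Reduce a display instance to one on a stable network.

    Two passes: first subdivide every arc entering a reticulation and
    hang the gadget at the subdivision vertex (making every reticulation
    child a tree vertex); then, for each original reticulation, pick one
    of its (reticulation) siblings, subdivide the arc to it and hang the
    gadget there (providing the tree-sibling).  The output network is
    binary, compressed and tree-sibling — hence stable — and displays the
    output tree iff ``n`` displays ``t``.
    """
    n2: XNetwork = n.copy()
    t2: PseudoMULTree = t.copy()
    orig_rets = [
        v for v in n.dag.vertices if vertex_class(n.dag, v) == RET
    ]
    counter = 0

    def gadget(at: Vertex) -> None:
        nonlocal n2, t2, counter
        counter += 1
        names = (
            f"x{counter}", f"x{counter}p", f"p{counter}", f"q{counter}",
            f"rho{counter}",
        )
        n2, t2 = hang_leaves(n2, t2, at, names=names)

    step1_arcs = [a for a in n2.dag.arcs if a[1] in orig_rets]
    sub = 0
    for a in sorted(step1_arcs):
        sub += 1
        ve = f"ve{sub}"
        n2.dag.subdivide(a, ve)
        gadget(ve)

    for rv in sorted(orig_rets, key=str):
        # parents of rv are now the step-1 subdivision vertices
        cands = []
        for p in n2.dag.parents(rv):
            for s in n2.dag.children(p):
                if s != rv:
                    below = sorted(
                        n2.leaf_label[w]
                        for w in ({s} | n2.dag.descendants(s))
                        if w in n2.leaf_label
                    )
                    cands.append(((tuple(below), str(s)), p, s))
        _, ps, s = min(cands)
        sub += 1
        vs = f"vs{sub}"
        (arc,) = [a for a in n2.dag.out_arcs(ps) if a[1] == s]
        n2.dag.subdivide(arc, vs)
        gadget(vs)

    return PhylogeneticNetwork(n2.dag, n2.leaf_label), t2
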