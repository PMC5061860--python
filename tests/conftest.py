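"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's canonical-code machinery:
isomorphism is decided by backtracking over explicit vertex bijections,
and path counts by direct enumeration, so they can certify the fast
implementations on small instances.
"""

from __future__ import annotations

import itertools
from typing import Dict, List

import pytest

from mulfold.core import (
    FIXTURES,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    XNetwork,
)


@pytest.fixture
def N1():
    return FIXTURES["N1"]()


@pytest.fixture
def N2():
    return FIXTURES["N2"]()


@pytest.fixture
def M1():
    return FIXTURES["M1"]()


@pytest.fixture
def M2():
    return FIXTURES["M2"]()


@pytest.fixture
def M3():
    return FIXTURES["M3"]()


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _arc_mult(dag: RootedDAG) -> Dict[tuple, int]:
    out: Dict[tuple, int] = {}
    for t, h, _ in dag.arcs:
        out[(t, h)] = out.get((t, h), 0) + 1
    return out


def bruteforce_network_isomorphic(n1: XNetwork, n2: XNetwork) -> bool:
    """Backtracking search over all label-respecting vertex bijections."""
    d1, d2 = n1.dag, n2.dag
    v1 = sorted(d1.vertices, key=str)
    v2 = sorted(d2.vertices, key=str)
    if len(v1) != len(v2) or len(d1.arcs) != len(d2.arcs):
        return False
    if sorted(n1.leaf_label.values()) != sorted(n2.leaf_label.values()):
        return False
    m1, m2 = _arc_mult(d1), _arc_mult(d2)
    lab1 = n1.leaf_label
    lab2 = n2.leaf_label

    def extend(mapping: Dict[Vertex, Vertex], used: set, i: int) -> bool:
        if i == len(v1):
            return True
        a = v1[i]
        for b in v2:
            if b in used:
                continue
            if (a in lab1) != (b in lab2):
                continue
            if a in lab1 and lab1[a] != lab2[b]:
                continue
            if d1.indeg(a) != d2.indeg(b) or d1.outdeg(a) != d2.outdeg(b):
                continue
            ok = True
            for c, bc in mapping.items():
                if m1.get((a, c), 0) != m2.get((b, bc), 0):
                    ok = False
                    break
                if m1.get((c, a), 0) != m2.get((bc, b), 0):
                    ok = False
                    break
            if ok:
                mapping[a] = b
                used.add(b)
                if extend(mapping, used, i + 1):
                    return True
                del mapping[a]
                used.discard(b)
        return False

    return extend({}, set(), 0)


def bruteforce_tree_isomorphic(t1: PseudoMULTree, t2: PseudoMULTree) -> bool:
    """Recursive matching over all child permutations (no codes involved)."""

    def match(a: Vertex, b: Vertex) -> bool:
        la, lb = t1.leaf_label.get(a), t2.leaf_label.get(b)
        if la != lb:
            return False
        ca = t1.tree.children(a)
        cb = t2.tree.children(b)
        if len(ca) != len(cb):
            return False
        if not ca:
            return True
        for perm in itertools.permutations(cb):
            if all(match(x, y) for x, y in zip(ca, perm)):
                return True
        return False

    return match(t1.root, t2.root)


def count_root_leaf_paths(n: XNetwork) -> int:
    """Number of directed root-to-leaf paths, by direct recursion."""
    dag = n.dag
    memo: Dict[Vertex, int] = {}

    def f(v: Vertex) -> int:
        if v not in memo:
            arcs = dag.out_arcs(v)
            memo[v] = 1 if not arcs else sum(f(h) for _, h, _ in arcs)
        return memo[v]

    return f(dag.root)


def count_all_root_paths(n: XNetwork) -> int:
    """Number of directed paths starting at the root (incl. the empty one)."""
    dag = n.dag
    memo: Dict[Vertex, int] = {}

    def f(v: Vertex) -> int:  # paths starting at v
        if v not in memo:
            memo[v] = 1 + sum(f(h) for _, h, _ in dag.out_arcs(v))
        return memo[v]

    return f(dag.root)


def relabel_vertices(n: XNetwork, prefix: str = "z") -> XNetwork:
    """Same network, fresh opaque vertex ids (labels untouched)."""
    order = sorted(n.dag.vertices, key=str)
    ren = {v: f"{prefix}{i}" for i, v in enumerate(order)}
    dag = RootedDAG(
        [(ren[t], ren[h], k) for t, h, k in n.dag.arcs],
        vertices=ren.values(),
        root=ren[n.dag.root],
    )
    return type(n)(dag, {ren[v]: x for v, x in n.leaf_label.items()})


def relabel_tree(t: PseudoMULTree, prefix: str = "z") -> PseudoMULTree:
    order = sorted(t.tree.vertices, key=str)
    ren = {v: f"{prefix}{i}" for i, v in enumerate(order)}
    dag = RootedDAG(
        [(ren[a], ren[b], k) for a, b, k in t.tree.arcs],
        vertices=ren.values(),
        root=ren[t.root],
    )
    return type(t)(dag, {ren[v]: x for v, x in t.leaf_label.items()})
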