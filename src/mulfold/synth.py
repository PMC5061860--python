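"""Seeded random generators for trees, MUL-trees and networks.

Every generator draws exclusively from one explicitly passed
:class:`random.Random` (or an integer seed), never from global state, and
iterates over deterministically ordered containers, so identical seeds
give isomorphic outputs across platforms.  Networks are grown from a
random binary tree by repeatedly subdividing two arcs and connecting the
subdivision vertices (the new head becomes a reticulation); acyclicity is
guaranteed by a reachability check before each insertion, and remaining
constraint predicates are enforced by rejection sampling.
"""

from __future__ import annotations

import random
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .core import (
    MULTree,
    PhylogeneticNetwork,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    properties,
    validate,
)
from .core import FIXTURES  # re-export: the named fixture registry

KNOWN_CONSTRAINTS = frozenset(
    {"binary", "compressed", "tree_child", "tree_sibling", "semi_resolved"}
)


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts ``max_tries``."""


def _as_rng(seed: int | random.Random) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def random_binary_tree(x: Iterable[str], seed: int | random.Random) -> MULTree:
    """Random rooted binary phylogenetic tree on ``x`` (2|x|-1 vertices).

    Sequential random leaf attachment: each new leaf subdivides a random
    arc (or is paired with the old root under a fresh root).  Leaf ids
    equal their labels.
    """
    rng = _as_rng(seed)
    labels = sorted(set(x))
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    dag = RootedDAG(root="i0")
    nxt = 1
    for leaf in labels[:2]:
        dag.add_vertex(leaf)
        dag.add_arc("i0", leaf)
    for leaf in labels[2:]:
        spots = sorted(dag.arcs) + [None]  # None = above the root
        spot = rng.choice(spots)
        v = f"i{nxt}"
        nxt += 1
        if spot is None:
            dag.add_vertex(v)
            dag.add_arc(v, dag.root)
            dag.root = v
        else:
            dag.subdivide(spot, v)
        dag.add_vertex(leaf)
        dag.add_arc(v, leaf)
    return MULTree(dag, {l: l for l in labels})


def _contract_some(
    dag: RootedDAG, rng: random.Random, prob: float
) -> None:
    """Randomly contract internal tree-tree arcs (creates multifurcations)."""
    for a in sorted(dag.arcs):
        p, u, _ = a
        if a not in set(dag.arcs) or u not in dag or p not in dag:
            continue
        if dag.indeg(u) != 1 or dag.outdeg(u) < 2:
            continue
        if p != dag.root and not (dag.indeg(p) == 1 and dag.outdeg(p) >= 2):
            continue
        if set(dag.children(u)) & set(dag.children(p)):
            continue  # contraction would create a parallel arc
        if rng.random() >= prob:
            continue
        kids = dag.out_arcs(u)
        dag.remove_vertex(u)
        for _, h, _ in kids:
            dag.add_arc(p, h)


def random_network(
    x_size: Optional[int] = None,
    reticulations: int = 0,
    constraints: Iterable[str] = (),
    seed: int | random.Random = 0,
    max_tries: int = 400,
    labels: Optional[Sequence[str]] = None,
    contraction_prob: float = 0.0,
    strengthen: int = 0,
) -> PhylogeneticNetwork:
    """Random phylogenetic network satisfying the requested constraints.

    ``constraints`` is a subset of {binary, compressed, tree_child,
    tree_sibling, semi_resolved}.  Construction is binary; with
    ``contraction_prob > 0`` (and neither binary nor semi_resolved
    requested) random internal arcs are contracted to produce
    multifurcations, and each of the ``strengthen`` moves gives a random
    existing reticulation one extra parent (indegree >= 3, which keeps
    the network semi-resolved but not binary).
    """
    constraints = frozenset(constraints)
    unknown = constraints - KNOWN_CONSTRAINTS
    if unknown:
        raise ValueError(f"unknown constraints: {sorted(unknown)}")
    rng = _as_rng(seed)
    if labels is None:
        if x_size is None or x_size < 2:
            raise ValueError("need x_size >= 2 or an explicit label list")
        labels = [f"t{i}" for i in range(x_size)]
    compressed = "compressed" in constraints
    keep_binary = constraints & {"binary", "semi_resolved"}

    for _ in range(max_tries):
        t = random_binary_tree(labels, rng)
        dag = t.tree
        ok = True
        for _i in range(reticulations):
            placed = False
            for _try in range(60):
                arcs = sorted(dag.arcs)
                a1, a2 = rng.choice(arcs), rng.choice(arcs)
                if a1 == a2:
                    continue
                p1, c1 = a1[0], a1[1]
                p2, c2 = a2[0], a2[1]
                if compressed:
                    # the new reticulation must not touch an existing one
                    if dag.outdeg(p2) == 1 or (
                        dag.indeg(c2) >= 2 and dag.outdeg(c2) == 1
                    ):
                        continue
                if c2 == p1 or p1 in dag.descendants(c2):
                    continue  # the connecting arc would close a cycle
                u1, u2 = f"s{len(dag)}a", f"s{len(dag)}b"
                dag.subdivide(a1, u1)
                dag.subdivide(a2, u2)
                dag.add_arc(u1, u2)
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        for _s in range(strengthen):
            rets = sorted(
                v for v in dag.vertices
                if dag.indeg(v) >= 2 and dag.outdeg(v) == 1
            )
            if not rets:
                break  # nothing to strengthen on a reticulation-free draw
            placed = False
            if rets:
                for _try in range(60):
                    r = rng.choice(rets)
                    a1 = rng.choice(sorted(dag.arcs))
                    if a1[1] == r:
                        continue
                    if compressed and dag.outdeg(a1[0]) == 1:
                        continue  # would put a reticulation below one
                    if a1[0] == r or a1[0] in dag.descendants(r):
                        continue  # new arc would close a cycle
                    u1 = f"s{len(dag)}a"
                    dag.subdivide(a1, u1)
                    dag.add_arc(u1, r)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        if contraction_prob > 0 and not keep_binary:
            _contract_some(dag, rng, contraction_prob)
        net = PhylogeneticNetwork(dag, {l: l for l in labels})
        if not validate(net, "phylo_network").ok:
            continue
        props = properties(net)
        if all(getattr(props, c) for c in constraints):
            return net
    raise GenerationError(
        f"could not satisfy {sorted(constraints)} with {reticulations} "
        f"reticulations on {len(labels)} taxa in {max_tries} tries"
    )


def random_multree(
    x: Iterable[str],
    dup: int = 0,
    seed: int | random.Random = 0,
    contraction_prob: float = 0.0,
) -> MULTree:
    """Random MUL-tree: a binary tree with ``dup`` subtree duplications.

    Each duplication copies the subtree at a random non-root vertex
    (fresh vertex ids, same labels) and reattaches the copy beside a
    random arc.  ``dup = 0`` gives a phylogenetic tree; positive
    ``contraction_prob`` yields non-binary trees.
    """
    rng = _as_rng(seed)
    t = random_binary_tree(x, rng)
    dag = t.tree
    fresh = [0]

    def copy_subtree(v: Vertex) -> Vertex:
        fresh[0] += 1
        tag = f"c{fresh[0]}"
        keep = sorted({v} | dag.descendants(v), key=str)
        ren = {u: f"{tag}_{u}" for u in keep}
        arcs = [a for a in dag.arcs if a[0] in ren and a[1] in ren]
        for u in keep:
            dag.add_vertex(ren[u])
            if u in t.leaf_label:
                t.leaf_label[ren[u]] = t.leaf_label[u]
        for a in arcs:
            dag.add_arc(ren[a[0]], ren[a[1]])
        return ren[v]

    for _ in range(dup):
        cands = sorted(v for v in dag.vertices if v != dag.root)
        v = rng.choice(cands)
        croot = copy_subtree(v)
        spot = rng.choice(sorted(a for a in dag.arcs if not a[1].startswith(f"c{fresh[0]}_")))
        fresh[0] += 1
        s = f"s{fresh[0]}"
        dag.subdivide(spot, s)
        dag.add_arc(s, croot)
    if contraction_prob > 0:
        _contract_some(dag, rng, contraction_prob)
    t.leaf_label = {v: x for v, x in t.leaf_label.items() if v in dag.g}
    return t
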