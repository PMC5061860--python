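"""Canonical forms and isomorphism tests.

Isomorphism of (pseudo) MUL-trees is decided through AHU-style canonical
codes: a leaf labelled ``x`` gets code ``L(x)``, a subdivision
(indeg-1/outdeg-1) vertex gets ``D(<child code>)`` and every other vertex
``I(<sorted multiset of children codes>)``.  Two (pseudo) MUL-trees are
isomorphic — in the label-respecting digraph sense — iff their root codes
are equal; the ``D`` constructor makes subdivision patterns part of the
identity, which is exactly the "isomorphic as pseudo MUL-trees" notion the
folding calculus relies on.

Networks are compared with an exact multidigraph isomorphism test anchored
at leaf labels (the witness bijection is the identity on X), and
canonically labelled by individualization–refinement for deterministic
serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .core import PseudoMULTree, RootedDAG, Vertex, XNetwork


# ---------------------------------------------------------------------------
# MUL-tree codes
# ---------------------------------------------------------------------------


def subtree_codes(t: PseudoMULTree) -> Dict[Vertex, str]:
    """Code of every vertex in the context of the whole tree (bottom-up)."""
    tree = t.tree
    codes: Dict[Vertex, str] = {}
    for v in reversed(tree.topological_order()):
        if tree.outdeg(v) == 0:
            label = t.leaf_label.get(v)
            if label is None:
                raise ValueError(f"leaf {v!r} is unlabelled")
            codes[v] = f"L({label})"
        elif tree.indeg(v) == 1 and tree.outdeg(v) == 1:
            codes[v] = f"D({codes[tree.children(v)[0]]})"
        else:
            kids = sorted(codes[h] for _, h, _ in tree.out_arcs(v))
            codes[v] = "I(" + ",".join(kids) + ")"
    return codes


def rooted_codes(t: PseudoMULTree) -> Dict[Vertex, str]:
    """Code of the standalone subtree ``T(v)`` for every vertex.

    Differs from :func:`subtree_codes` only at subdivision vertices: once
    ``v`` is re-rooted its incoming arc is gone, so the ``D`` rule no
    longer applies at ``v`` itself (but still does below it).
    """
    codes = subtree_codes(t)
    out = dict(codes)
    tree = t.tree
    for v in tree.vertices:
        if v != tree.root and tree.indeg(v) == 1 and tree.outdeg(v) == 1:
            out[v] = "I(" + codes[tree.children(v)[0]] + ")"
    return out


def canonical_form(t: PseudoMULTree, v: Optional[Vertex] = None) -> str:
    """Canonical code of ``T(v)`` (whole tree when ``v`` is None or the root)."""
    if v is None:
        v = t.root
    return rooted_codes(t)[v]


def multree_isomorphic(t1: PseudoMULTree, t2: PseudoMULTree) -> bool:
    """Label-respecting digraph isomorphism of (pseudo) MUL-trees."""
    return canonical_form(t1) == canonical_form(t2)


# ---------------------------------------------------------------------------
# network isomorphism
# ---------------------------------------------------------------------------


@dataclass
class NetworkIsoResult:
    isomorphic: bool
    witness: Optional[Dict[Vertex, Vertex]]
    reason: str = ""

    def __bool__(self) -> bool:
        return self.isomorphic


def _attributed(n: XNetwork) -> nx.MultiDiGraph:
    g = n.dag.g.copy()
    for v in g.nodes:
        g.nodes[v]["label"] = n.leaf_label.get(v)
    g.nodes[n.dag.root]["is_root"] = True
    return g


def network_isomorphic(n1: XNetwork, n2: XNetwork) -> NetworkIsoResult:
    """Exact isomorphism of X-networks with witness.

    The bijection must preserve arc multiplicities and be the identity on
    leaf labels.  Different taxon sets short-circuit (reported distinctly
    from structural non-isomorphism).
    """
    if n1.X != n2.X:
        return NetworkIsoResult(False, None, "different taxon sets")
    g1, g2 = _attributed(n1), _attributed(n2)
    nm = nxiso.categorical_node_match(["label", "is_root"], [None, None])
    matcher = nxiso.MultiDiGraphMatcher(g1, g2, node_match=nm)
    if matcher.is_isomorphic():
        return NetworkIsoResult(True, dict(matcher.mapping))
    return NetworkIsoResult(False, None, "not isomorphic")


# ---------------------------------------------------------------------------
# canonical labelling (individualization–refinement)
# ---------------------------------------------------------------------------


def _initial_colors(n: XNetwork) -> Dict[Vertex, Tuple]:
    dag = n.dag
    return {
        v: (
            v == dag.root,
            n.leaf_label.get(v),
            dag.indeg(v),
            dag.outdeg(v),
        )
        for v in dag.vertices
    }


def _refine(dag: RootedDAG, colors: Dict[Vertex, int]) -> Dict[Vertex, int]:
    """Iterated colour refinement on a multidigraph (WL-1, both directions)."""
    g = dag.g
    while True:
        sigs = {}
        for v in g.nodes:
            out_sig = sorted(colors[h] for _, h, _ in g.out_edges(v, keys=True))
            in_sig = sorted(colors[t] for t, _, _ in g.in_edges(v, keys=True))
            sigs[v] = (colors[v], tuple(out_sig), tuple(in_sig))
        ranks = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        new = {v: ranks[sigs[v]] for v in g.nodes}
        if len(set(new.values())) == len(set(colors.values())):
            return new
        colors = new


def _certificate_from_order(n: XNetwork, order: List[Vertex]) -> str:
    idx = {v: i for i, v in enumerate(order)}
    arcs = sorted((idx[t], idx[h]) for t, h, _ in n.dag.arcs)
    labels = sorted((idx[v], x) for v, x in n.leaf_label.items())
    return repr((arcs, labels, idx[n.dag.root]))


def canonical_order(n: XNetwork) -> List[Vertex]:
    """A vertex ordering invariant under isomorphism (identity on labels).

    Individualization–refinement: refine colours; while a colour class has
    more than one vertex, individualize each candidate in turn and keep
    the branch with the lexicographically smallest certificate.  Worst
    case exponential, but leaf-label anchoring makes refinement discrete
    on the object sizes this calculus is used at.
    """
    init = _initial_colors(n)
    ranks = {c: i for i, c in enumerate(sorted(set(init.values()), key=repr))}
    colors = {v: ranks[init[v]] for v in n.dag.vertices}

    best: List[Tuple[str, List[Vertex]]] = []

    def search(colors: Dict[Vertex, int]) -> Tuple[str, List[Vertex]]:
        colors = _refine(n.dag, colors)
        classes: Dict[int, List[Vertex]] = {}
        for v, c in colors.items():
            classes.setdefault(c, []).append(v)
        ambiguous = [c for c, vs in classes.items() if len(vs) > 1]
        if not ambiguous:
            order = [v for v, _ in sorted(colors.items(), key=lambda kv: kv[1])]
            return _certificate_from_order(n, order), order
        c = min(ambiguous)
        ncol = max(colors.values()) + 1
        results = []
        for v in classes[c]:
            branch = dict(colors)
            branch[v] = ncol
            results.append(search(branch))
        return min(results, key=lambda r: r[0])

    cert, order = search(colors)
    return order


def network_certificate(n: XNetwork) -> str:
    """Complete isomorphism invariant: equal iff networks are isomorphic."""
    return _certificate_from_order(n, canonical_order(n))
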