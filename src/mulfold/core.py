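"""Graph data model for rooted DAGs, X-networks and (pseudo) MUL-trees.

The objects here follow the standard definitions from the theory of
phylogenetic networks: an *X-network* is a rooted DAG (parallel arcs
allowed) whose non-root vertices are either reticulations (indegree >= 2,
outdegree 1) or tree vertices (indegree 1, outdegree != 1), with leaves
labelled bijectively by a taxon set ``X``.  A *MUL-tree* is a rooted tree
whose leaves carry labels from ``X`` with multiplicity; a *pseudo*
MUL-tree additionally allows subdivision (indegree-1/outdegree-1)
vertices.

Vertices are opaque hashable ids (strings in practice); arcs are
``(tail, head, key)`` triples where ``key`` disambiguates parallel arcs.
Constructors are deliberately lenient — validity is checked explicitly by
:func:`validate`, so that degenerate intermediates (e.g. foldings with
parallel arcs) remain representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Optional, Set, Tuple

import networkx as nx

Vertex = Hashable
Arc = Tuple[Vertex, Vertex, int]


class GraphError(ValueError):
    """Raised for structurally impossible requests (missing vertex etc.)."""


class RootedDAG:
    """A rooted directed multigraph (acyclicity is *validated*, not forced).

    Thin wrapper around :class:`networkx.MultiDiGraph` exposing the
    vocabulary of the field (children, reticulations, suppression) with
    stable vertex ids.
    """

    def __init__(
        self,
        arcs: Iterable[Tuple[Vertex, Vertex]] | Iterable[Arc] = (),
        vertices: Iterable[Vertex] = (),
        root: Optional[Vertex] = None,
    ) -> None:
        g = nx.MultiDiGraph()
        g.add_nodes_from(vertices)
        for a in arcs:
            if len(a) == 3:
                t, h, k = a
                g.add_edge(t, h, key=k)
            else:
                t, h = a
                g.add_edge(t, h, key=self._fresh_key(g, t, h))
        self.g = g
        if root is None:
            sources = [v for v in g.nodes if g.in_degree(v) == 0]
            if len(sources) != 1:
                raise GraphError(
                    f"cannot infer root: {len(sources)} indegree-0 vertices"
                )
            root = sources[0]
        elif root not in g.nodes:
            g.add_node(root)
        self.root: Vertex = root

    # -- basic accessors -------------------------------------------------
    @staticmethod
    def _fresh_key(g: nx.MultiDiGraph, t: Vertex, h: Vertex) -> int:
        if g.has_edge(t, h):
            return max(g[t][h]) + 1
        return 0

    @property
    def vertices(self) -> List[Vertex]:
        return list(self.g.nodes)

    @property
    def arcs(self) -> List[Arc]:
        return [(t, h, k) for t, h, k in self.g.edges(keys=True)]

    def __contains__(self, v: Vertex) -> bool:
        return v in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def indeg(self, v: Vertex) -> int:
        return self.g.in_degree(v)

    def outdeg(self, v: Vertex) -> int:
        return self.g.out_degree(v)

    def children(self, v: Vertex) -> List[Vertex]:
        """Distinct children of ``v`` (``ch(v)``)."""
        return list(self.g.successors(v))

    def parents(self, v: Vertex) -> List[Vertex]:
        return list(self.g.predecessors(v))

    def parent(self, v: Vertex) -> Vertex:
        ps = self.parents(v)
        if len(ps) != 1:
            raise GraphError(f"vertex {v!r} has {len(ps)} distinct parents")
        return ps[0]

    def out_arcs(self, v: Vertex) -> List[Arc]:
        return [(t, h, k) for t, h, k in self.g.out_edges(v, keys=True)]

    def in_arcs(self, v: Vertex) -> List[Arc]:
        return [(t, h, k) for t, h, k in self.g.in_edges(v, keys=True)]

    def leaves(self) -> List[Vertex]:
        return [v for v in self.g.nodes if self.g.out_degree(v) == 0]

    def descendants(self, v: Vertex) -> Set[Vertex]:
        return nx.descendants(self.g, v)

    def is_below(self, v: Vertex, w: Vertex) -> bool:
        """True iff ``v`` is strictly below ``w`` (directed path w -> v)."""
        return v != w and nx.has_path(self.g, w, v)

    def topological_order(self) -> List[Vertex]:
        return list(nx.topological_sort(self.g))

    # -- mutation helpers (used by the construction modules) -------------
    def add_vertex(self, v: Vertex) -> None:
        self.g.add_node(v)

    def add_arc(self, t: Vertex, h: Vertex, key: Optional[int] = None) -> Arc:
        if key is None:
            key = self._fresh_key(self.g, t, h)
        self.g.add_edge(t, h, key=key)
        return (t, h, key)

    def remove_arc(self, a: Arc) -> None:
        self.g.remove_edge(*a)

    def remove_vertex(self, v: Vertex) -> None:
        self.g.remove_node(v)

    def copy(self) -> "RootedDAG":
        new = object.__new__(RootedDAG)
        new.g = self.g.copy()
        new.root = self.root
        return new

    def subdivide(self, a: Arc, new_vertex: Vertex) -> None:
        """Replace arc ``a = (t, h, k)`` by ``t -> new_vertex -> h``."""
        t, h, _ = a
        self.remove_arc(a)
        self.add_vertex(new_vertex)
        self.add_arc(t, new_vertex)
        self.add_arc(new_vertex, h)


@dataclass
class XNetwork:
    """A rooted DAG with leaves labelled bijectively by X (parallel arcs ok)."""

    dag: RootedDAG
    leaf_label: Dict[Vertex, str]

    @property
    def X(self) -> Set[str]:
        return set(self.leaf_label.values())

    @property
    def root(self) -> Vertex:
        return self.dag.root

    def copy(self) -> "XNetwork":
        return XNetwork(self.dag.copy(), dict(self.leaf_label))

    def label_classes(self) -> Dict[str, Set[Vertex]]:
        out: Dict[str, Set[Vertex]] = {}
        for v, x in self.leaf_label.items():
            out.setdefault(x, set()).add(v)
        return out


class PhylogeneticNetwork(XNetwork):
    """X-network without parallel arcs (the common biological object)."""


@dataclass
class PseudoMULTree:
    """Rooted tree with totally (not necessarily injectively) labelled leaves."""

    tree: RootedDAG
    leaf_label: Dict[Vertex, str]

    @property
    def X(self) -> Set[str]:
        return set(self.leaf_label.values())

    @property
    def root(self) -> Vertex:
        return self.tree.root

    def copy(self) -> "PseudoMULTree":
        return type(self)(self.tree.copy(), dict(self.leaf_label))

    def label_classes(self) -> Dict[str, Set[Vertex]]:
        out: Dict[str, Set[Vertex]] = {}
        for v, x in self.leaf_label.items():
            out.setdefault(x, set()).add(v)
        return out


class MULTree(PseudoMULTree):
    """Pseudo MUL-tree with no subdivision (indeg-1/outdeg-1) vertices."""


@dataclass
class PropertyReport:
    binary: bool
    semi_resolved: bool
    compressed: bool
    tree_child: bool
    tree_sibling: bool
    has_parallel_arcs: bool
    is_tree: bool


@dataclass
class ValidationReport:
    ok: bool
    violations: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# classification & validation
# ---------------------------------------------------------------------------

ROOT = "root"
RETICULATION = "reticulation"
INTERNAL_TREE = "internal_tree"
LEAF = "leaf"


def vertex_class(dag: RootedDAG, v: Vertex) -> str:
    """Classify ``v`` as root / reticulation / internal_tree / leaf."""
    if v not in dag:
        raise GraphError(f"vertex {v!r} not in graph")
    ind, outd = dag.indeg(v), dag.outdeg(v)
    if v == dag.root and ind == 0:
        return ROOT
    if outd == 1 and ind >= 2:
        return RETICULATION
    if ind == 1 and outd == 0:
        return LEAF
    if ind == 1 and outd >= 2:
        return INTERNAL_TREE
    raise GraphError(
        f"vertex {v!r} (indeg {ind}, outdeg {outd}) fits no vertex class"
    )


def _dag_violations(dag: RootedDAG) -> List[str]:
    out = []
    if not nx.is_directed_acyclic_graph(dag.g):
        out.append("graph contains a directed cycle")
        return out
    sources = [v for v in dag.g.nodes if dag.indeg(v) == 0]
    if sources != [dag.root] and set(sources) != {dag.root}:
        out.append(f"indegree-0 vertices {sources!r} != root {dag.root!r}")
    reachable = {dag.root} | nx.descendants(dag.g, dag.root)
    missing = set(dag.g.nodes) - reachable
    if missing:
        out.append(f"vertices not reachable from root: {sorted(map(str, missing))}")
    return out


def validate(obj: XNetwork | PseudoMULTree, kind: str) -> ValidationReport:
    """Check the invariants of the requested ``kind``; report, never raise.

    kind: one of ``x_network``, ``phylo_network``, ``mul_tree``,
    ``pseudo_mul_tree``.
    """
    dag = obj.dag if isinstance(obj, XNetwork) else obj.tree
    labels = obj.leaf_label
    v9n = _dag_violations(dag)
    leaves = set(dag.leaves())

    if kind in ("x_network", "phylo_network"):
        if dag.outdeg(dag.root) < 2:
            v9n.append("root outdegree < 2")
        for v in dag.vertices:
            if v == dag.root:
                continue
            ind, outd = dag.indeg(v), dag.outdeg(v)
            if ind == 1 and outd == 1:
                v9n.append(f"vertex {v!r} has indegree 1 and outdegree 1")
            elif not ((outd == 1 and ind >= 2) or (ind == 1 and outd != 1)):
                v9n.append(
                    f"vertex {v!r} (indeg {ind}, outdeg {outd}) is neither a "
                    "reticulation nor a tree vertex"
                )
        unlabelled = leaves - set(labels)
        if unlabelled:
            v9n.append(f"unlabelled leaves: {sorted(map(str, unlabelled))}")
        nonleaf = set(labels) - leaves
        if nonleaf:
            v9n.append(f"labelled non-leaves: {sorted(map(str, nonleaf))}")
        lab = [labels[v] for v in leaves & set(labels)]
        if len(set(lab)) != len(lab):
            v9n.append("leaf labelling is not injective")
        if len(set(lab)) < 2:
            v9n.append("|X| < 2")
        if kind == "phylo_network":
            for t, h, k in dag.arcs:
                if k != 0:
                    v9n.append(f"parallel arc ({t!r}, {h!r})")
    elif kind in ("mul_tree", "pseudo_mul_tree"):
        for v in dag.vertices:
            if v != dag.root and dag.indeg(v) != 1:
                v9n.append(f"vertex {v!r} has indegree {dag.indeg(v)} != 1")
        unlabelled = leaves - set(labels)
        if unlabelled:
            v9n.append(f"unlabelled leaves: {sorted(map(str, unlabelled))}")
        nonleaf = set(labels) - leaves
        if nonleaf:
            v9n.append(f"labelled non-leaves: {sorted(map(str, nonleaf))}")
        if kind == "mul_tree":
            for v in dag.vertices:
                if v != dag.root and dag.indeg(v) == 1 and dag.outdeg(v) == 1:
                    v9n.append(f"vertex {v!r} has indegree 1 and outdegree 1")
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return ValidationReport(ok=not v9n, violations=v9n)


def properties(n: XNetwork) -> PropertyReport:
    """Structural flags of a valid X-network (binary, compressed, ...)."""
    dag = n.dag
    classes = {v: vertex_class(dag, v) for v in dag.vertices}
    rets = [v for v, c in classes.items() if c == RETICULATION]
    internal = [v for v, c in classes.items() if c == INTERNAL_TREE]
    binary = (
        dag.outdeg(dag.root) == 2
        and all(dag.indeg(v) == 2 for v in rets)
        and all(dag.outdeg(v) == 2 for v in internal)
    )
    semi_resolved = all(dag.outdeg(v) == 2 for v in internal)
    compressed = all(
        classes[dag.children(v)[0]] in (INTERNAL_TREE, LEAF) for v in rets
    )
    tree_child = all(
        any(classes[c] in (INTERNAL_TREE, LEAF) for c in dag.children(v))
        for v in dag.vertices
        if dag.outdeg(v) > 0
    )

    def has_tree_sibling(r: Vertex) -> bool:
        sibs = {
            c
            for p in dag.parents(r)
            for c in dag.children(p)
            if c != r
        }
        return any(classes[s] in (INTERNAL_TREE, LEAF) for s in sibs)

    tree_sibling = all(has_tree_sibling(r) for r in rets)
    has_parallel = any(k != 0 for _, _, k in dag.arcs)
    return PropertyReport(
        binary=binary,
        semi_resolved=semi_resolved,
        compressed=compressed,
        tree_child=tree_child,
        tree_sibling=tree_sibling,
        has_parallel_arcs=has_parallel,
        is_tree=not rets and not has_parallel,
    )


# ---------------------------------------------------------------------------
# suppression & restriction
# ---------------------------------------------------------------------------


def suppress(dag: RootedDAG) -> RootedDAG:
    """Iteratively replace every indeg-1/outdeg-1 vertex by an arc.

    Confluent rewriting; suppressing a vertex between ``u`` and ``w`` that
    are already adjacent creates a parallel arc (fresh key).  Leaves and
    their labels are untouched (labels live outside the DAG).
    """
    out = dag.copy()
    _suppress_inplace(out)
    return out


def _suppress_inplace(dag: RootedDAG) -> None:
    queue = [
        v
        for v in dag.vertices
        if v != dag.root and dag.indeg(v) == 1 and dag.outdeg(v) == 1
    ]
    while queue:
        v = queue.pop()
        if v not in dag or not (
            v != dag.root and dag.indeg(v) == 1 and dag.outdeg(v) == 1
        ):
            continue
        (p, _, _), = dag.in_arcs(v)
        (_, c, _), = dag.out_arcs(v)
        dag.remove_vertex(v)
        dag.add_arc(p, c)


def subtree(t: PseudoMULTree, v: Vertex) -> PseudoMULTree:
    """The pseudo subMUL-tree ``T(v)`` (v becomes the root; labels restricted)."""
    if v == t.root:
        raise GraphError("subtree is defined at non-root vertices only")
    if v not in t.tree:
        raise GraphError(f"vertex {v!r} not in tree")
    keep = {v} | t.tree.descendants(v)
    sub = RootedDAG(
        [a for a in t.tree.arcs if a[0] in keep and a[1] in keep],
        vertices=keep,
        root=v,
    )
    labels = {u: x for u, x in t.leaf_label.items() if u in keep}
    return PseudoMULTree(sub, labels)


def restrict_below(n: PhylogeneticNetwork, u: Vertex) -> PhylogeneticNetwork:
    """``N(u)``: restrict to ``u`` and everything below, then suppress.

    ``u`` must be the root or a tree vertex (leaves included); reticulations
    that lose all but one parent become suppressible and are suppressed.
    """
    if u not in n.dag:
        raise GraphError(f"vertex {u!r} not in network")
    if u != n.dag.root and vertex_class(n.dag, u) == RETICULATION:
        raise GraphError("restrict_below is defined at tree vertices and the root")
    keep = {u} | n.dag.descendants(u)
    sub = RootedDAG(
        [a for a in n.dag.arcs if a[0] in keep and a[1] in keep],
        vertices=keep,
        root=u,
    )
    _suppress_inplace(sub)
    labels = {v: x for v, x in n.leaf_label.items() if v in sub.g}
    return PhylogeneticNetwork(sub, labels)


# ---------------------------------------------------------------------------
# named fixtures (arc lists are normative for the whole test suite)
# ---------------------------------------------------------------------------


def tree_as_network(t: PseudoMULTree) -> PhylogeneticNetwork:
    """View a phylogenetic tree (injective labels, no subdivisions) as a
    (reticulation-free) phylogenetic network."""
    return PhylogeneticNetwork(t.tree.copy(), dict(t.leaf_label))


def network_as_multree(n: XNetwork) -> MULTree:
    """View a reticulation-free network as a MUL-tree."""
    if any(n.dag.indeg(v) > 1 for v in n.dag.vertices):
        raise GraphError("network has reticulations; unfold it instead")
    return MULTree(n.dag.copy(), dict(n.leaf_label))


def fixture_N1() -> PhylogeneticNetwork:
    """Binary, compressed, tree-child network on {a,b,c} with one reticulation."""
    dag = RootedDAG(
        [("rho", "u"), ("rho", "v"), ("u", "a"), ("u", "r"),
         ("v", "b"), ("v", "r"), ("r", "c")],
        root="rho",
    )
    return PhylogeneticNetwork(dag, {"a": "a", "b": "b", "c": "c"})


def fixture_N2() -> PhylogeneticNetwork:
    """Binary, compressed, non-tree-sibling network with ch(v) = ch(w)."""
    dag = RootedDAG(
        [("rho", "v"), ("rho", "w"), ("v", "r1"), ("v", "r2"),
         ("w", "r1"), ("w", "r2"), ("r1", "a"), ("r2", "b")],
        root="rho",
    )
    return PhylogeneticNetwork(dag, {"a": "a", "b": "b"})


def fixture_M1() -> MULTree:
    """((a,c),(b,c)) — leaves a, c, b, c."""
    dag = RootedDAG(
        [("rho", "p"), ("rho", "q"), ("p", "a"), ("p", "c1"),
         ("q", "b"), ("q", "c2")],
        root="rho",
    )
    return MULTree(dag, {"a": "a", "c1": "c", "b": "b", "c2": "c"})


def fixture_M2() -> MULTree:
    """((a,b),(a,b)) — two identical cherries."""
    dag = RootedDAG(
        [("rho", "p"), ("rho", "q"), ("p", "a1"), ("p", "b1"),
         ("q", "a2"), ("q", "b2")],
        root="rho",
    )
    return MULTree(dag, {"a1": "a", "b1": "b", "a2": "a", "b2": "b"})


def fixture_M3() -> MULTree:
    """(a,a) — the cherry with both leaves labelled a (no network exhibits it)."""
    dag = RootedDAG([("rho", "a1"), ("rho", "a2")], root="rho")
    return MULTree(dag, {"a1": "a", "a2": "a"})


FIXTURES = {
    "N1": fixture_N1,
    "N2": fixture_N2,
    "M1": fixture_M1,
    "M2": fixture_M2,
    "M3": fixture_M3,
}
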