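"""Readers and writers for the three interchange formats.

* ``enewick`` — extended Newick for networks: reticulations are written
  with ``#Hk`` hybrid tags and merged by tag on reading; a parent that
  references ``#Hk`` twice encodes parallel arcs.  Branch lengths are
  deliberately rejected (the calculus is purely topological).
* ``mul_newick`` — Newick with repeated leaf labels, for MUL-trees.
* ``json_edgelist`` — the normative lossless dialect: explicit vertex
  list, arc list with parallel-arc keys, root id and leaf-label map.

Writers order vertices canonically (AHU codes for trees,
individualization–refinement for networks), so isomorphic objects
serialize to identical text in ``json_edgelist`` and ``mul_newick``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

from . import canon
from .core import (
    MULTree,
    PhylogeneticNetwork,
    PseudoMULTree,
    RootedDAG,
    Vertex,
    XNetwork,
    _suppress_inplace,
    validate,
)

FORMATS = ("enewick", "mul_newick", "json_edgelist")

ReadResult = Union[XNetwork, MULTree, PseudoMULTree]


@dataclass
class SerializedForm:
    text: str
    format: str


class ParseError(ValueError):
    def __init__(self, msg: str, pos: Optional[int] = None):
        super().__init__(msg if pos is None else f"{msg} (at position {pos})")
        self.pos = pos


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Newick tokenizer / parser (shared by enewick and mul_newick)
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[^(),;#:\s]+")


class _Parser:
    def __init__(self, text: str, hybrids_allowed: bool):
        self.text = text
        self.i = 0
        self.hybrids_allowed = hybrids_allowed
        self.nodes: List[dict] = []  # {'name', 'tag', 'children': [idx]}

    def error(self, msg: str):
        raise ParseError(msg, self.i)

    def skip_ws(self):
        while self.i < len(self.text) and self.text[self.i].isspace():
            self.i += 1

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.i] if self.i < len(self.text) else ""

    def parse(self) -> int:
        root = self.parse_node()
        if self.peek() != ";":
            self.error("expected ';'")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            self.error("trailing characters after ';'")
        return root

    def parse_node(self) -> int:
        children: List[int] = []
        if self.peek() == "(":
            self.i += 1
            children.append(self.parse_node())
            while self.peek() == ",":
                self.i += 1
                children.append(self.parse_node())
            if self.peek() != ")":
                self.error("expected ')'")
            self.i += 1
        name = None
        self.skip_ws()
        m = _NAME_RE.match(self.text, self.i)
        if m:
            name = m.group(0)
            self.i = m.end()
        tag = None
        if self.peek() == "#":
            if not self.hybrids_allowed:
                self.error("hybrid tags are not allowed in this format")
            m = re.compile(r"#H?(\d+)").match(self.text, self.i)
            if not m:
                self.error("malformed hybrid tag")
            tag = m.group(1)
            self.i = m.end()
        if self.peek() == ":":
            self.error(
                "branch lengths are not supported (topological formats only)"
            )
        self.nodes.append({"name": name, "tag": tag, "children": children})
        return len(self.nodes) - 1


def _read_enewick(text: str) -> XNetwork:
    p = _Parser(text, hybrids_allowed=True)
    root_idx = p.parse()
    expanded: Dict[str, int] = {}  # hybrid tag -> node index carrying children
    for i, nd in enumerate(p.nodes):
        if nd["tag"] is not None and nd["children"]:
            if nd["tag"] in expanded:
                raise ParseError(
                    f"hybrid #H{nd['tag']} has children at two occurrences"
                )
            expanded[nd["tag"]] = i

    def vid(i: int) -> str:
        nd = p.nodes[i]
        if nd["tag"] is not None:
            return f"#H{nd['tag']}"  # '#' cannot occur in names: no collision
        return nd["name"] if nd["name"] else f"v{i}"

    names_seen: Dict[str, int] = {}
    for nd in p.nodes:
        if nd["tag"] is None and nd["name"]:
            names_seen[nd["name"]] = names_seen.get(nd["name"], 0) + 1
    dup = [n for n, c in names_seen.items() if c > 1]
    if dup:
        raise ParseError(f"duplicate vertex names {dup} (not hybrid-tagged)")

    name_of: Dict[str, str] = {}
    for i, nd in enumerate(p.nodes):
        if nd["name"]:
            prev = name_of.get(vid(i))
            if prev and prev != nd["name"]:
                raise ParseError(
                    f"hybrid #H{nd['tag']} named inconsistently ({prev}/{nd['name']})"
                )
            name_of[vid(i)] = nd["name"]

    dag = RootedDAG(root=vid(root_idx))
    for i in range(len(p.nodes)):
        dag.add_vertex(vid(i))
    for i, nd in enumerate(p.nodes):
        for c in nd["children"]:
            dag.add_arc(vid(i), vid(c))
    _suppress_inplace(dag)
    labels: Dict[Vertex, str] = {}
    for v in dag.leaves():
        if v not in name_of:
            raise ParseError(f"leaf {v!r} has no label")
        labels[v] = name_of[v]
    net = XNetwork(dag, labels)
    rep_v = validate(net, "x_network")
    if not rep_v.ok:
        raise FormatError(
            "parsed graph is not an X-network: " + "; ".join(rep_v.violations)
        )
    if all(k == 0 for _, _, k in dag.arcs):
        return PhylogeneticNetwork(dag, labels)
    return net


def _read_mul_newick(text: str) -> MULTree:
    p = _Parser(text, hybrids_allowed=False)
    root_idx = p.parse()
    dag = RootedDAG(root=f"v{root_idx}")
    labels: Dict[Vertex, str] = {}
    for i, nd in enumerate(p.nodes):
        dag.add_vertex(f"v{i}")
        for c in nd["children"]:
            dag.add_arc(f"v{i}", f"v{c}")
    for i, nd in enumerate(p.nodes):
        if not nd["children"]:
            if not nd["name"]:
                raise ParseError(f"unlabelled leaf (node {i})")
            labels[f"v{i}"] = nd["name"]
    t = MULTree(dag, labels)
    rep = validate(t, "mul_tree")
    if not rep.ok:
        raise FormatError(
            "parsed tree is not a MUL-tree: " + "; ".join(rep.violations)
        )
    return t


# ---------------------------------------------------------------------------
# JSON edge-list
# ---------------------------------------------------------------------------

_KINDS = {
    "x_network": XNetwork,
    "phylo_network": PhylogeneticNetwork,
    "mul_tree": MULTree,
    "pseudo_mul_tree": PseudoMULTree,
}


def _read_json(text: str) -> ReadResult:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e}")
    for key in ("kind", "vertices", "root", "arcs", "leaf_labels"):
        if key not in data:
            raise ParseError(f"missing key {key!r}")
    kind = data["kind"]
    if kind not in _KINDS:
        raise ParseError(f"unknown kind {kind!r}")
    dag = RootedDAG(
        [(t, h, k) for t, h, k in data["arcs"]],
        vertices=data["vertices"],
        root=data["root"],
    )
    obj = _KINDS[kind](dag, dict(data["leaf_labels"]))
    rep = validate(obj, kind)
    if not rep.ok:
        raise FormatError(f"invalid {kind}: " + "; ".join(rep.violations))
    return obj


def _tree_canonical_order(t: PseudoMULTree) -> List[Vertex]:
    codes = canon.subtree_codes(t)
    order: List[Vertex] = []

    def visit(v: Vertex) -> None:
        order.append(v)
        for c in sorted(t.tree.children(v), key=lambda u: (codes[u], str(u))):
            visit(c)

    visit(t.root)
    return order


def _kind_of(obj: ReadResult) -> str:
    if isinstance(obj, PhylogeneticNetwork):
        return "phylo_network"
    if isinstance(obj, XNetwork):
        return "x_network"
    if isinstance(obj, MULTree):
        return "mul_tree"
    return "pseudo_mul_tree"


def _write_json(obj: ReadResult) -> str:
    if isinstance(obj, XNetwork):
        order = canon.canonical_order(obj)
        dag, labels = obj.dag, obj.leaf_label
    else:
        order = _tree_canonical_order(obj)
        dag, labels = obj.tree, obj.leaf_label
    ren = {v: f"n{i}" for i, v in enumerate(order)}
    arcs = sorted((ren[t], ren[h], k) for t, h, k in dag.arcs)
    data = {
        "kind": _kind_of(obj),
        "vertices": [f"n{i}" for i in range(len(order))],
        "root": ren[dag.root],
        "arcs": [list(a) for a in arcs],
        "leaf_labels": {ren[v]: x for v, x in labels.items()},
    }
    return json.dumps(data, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Newick writers
# ---------------------------------------------------------------------------


def _write_mul_newick(t: PseudoMULTree) -> str:
    rep = validate(t, "mul_tree")
    if not rep.ok:
        raise FormatError(
            "only MUL-trees can be written as mul_newick (use json_edgelist): "
            + "; ".join(rep.violations)
        )
    codes = canon.subtree_codes(t)

    def emit(v: Vertex) -> str:
        kids = sorted(t.tree.children(v), key=lambda u: (codes[u], str(u)))
        if not kids:
            return t.leaf_label[v]
        return "(" + ",".join(emit(c) for c in kids) + ")"

    return emit(t.root) + ";"


def _write_enewick(n: XNetwork) -> str:
    rep = validate(n, "x_network")
    if not rep.ok:
        raise FormatError(
            "only X-networks can be written as enewick: "
            + "; ".join(rep.violations)
        )
    order = canon.canonical_order(n)
    pos = {v: i for i, v in enumerate(order)}
    dag = n.dag
    hybrids = {
        v: i + 1
        for i, v in enumerate(
            sorted((v for v in dag.vertices if dag.indeg(v) >= 2), key=pos.get)
        )
    }
    expanded = set()

    def emit(v: Vertex) -> str:
        tag = f"#H{hybrids[v]}" if v in hybrids else ""
        if v in hybrids and v in expanded:
            return tag
        expanded.add(v)
        label = n.leaf_label.get(v, "")
        arcs = sorted(dag.out_arcs(v), key=lambda a: (pos[a[1]], a[2]))
        if not arcs:
            return f"{label}{tag}"
        inner = ",".join(emit(h) for _, h, _ in arcs)
        return f"({inner}){label}{tag}"

    return emit(dag.root) + ";"


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read(s: SerializedForm | str, format: Optional[str] = None) -> ReadResult:
    """Parse ``s`` (a :class:`SerializedForm`, or text plus ``format``)."""
    if isinstance(s, SerializedForm):
        text, fmt = s.text, s.format
    else:
        text, fmt = s, format
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r} (choose from {FORMATS})")
    if fmt == "enewick":
        return _read_enewick(text)
    if fmt == "mul_newick":
        return _read_mul_newick(text)
    return _read_json(text)


def write(obj: ReadResult, format: str = "json_edgelist") -> SerializedForm:
    """Serialize deterministically (isomorphic objects -> identical text
    in ``json_edgelist`` and ``mul_newick``)."""
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r} (choose from {FORMATS})")
    if format == "enewick":
        if not isinstance(obj, XNetwork):
            raise FormatError("enewick encodes X-networks; use mul_newick/json")
        return SerializedForm(_write_enewick(obj), format)
    if format == "mul_newick":
        if isinstance(obj, XNetwork):
            raise FormatError("mul_newick encodes MUL-trees; use enewick/json")
        return SerializedForm(_write_mul_newick(obj), format)
    return SerializedForm(_write_json(obj), format)
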