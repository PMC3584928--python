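"""Dated species trees.

A :class:`DatedTree` is a rooted tree whose branch lengths are in million
years (Ma).  Node ages are measured backward from the present (tips of an
ultrametric tree sit at age 0).  The root may carry an edge of its own: the
*stem* branch, which here represents the interval between the horizontal
acquisition of the gene and the first speciation of the sampled clade.
Events are addressed by branch, and every branch is identified by the id of
the node below it; the stem branch is therefore identified by the root id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import dendropy

__all__ = ["Node", "DatedTree", "TreeError", "read_dated_tree", "write_dated_tree"]

#: absolute tolerance (Ma) for declaring all tips contemporaneous
ULTRAMETRIC_TOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or unsupported trees."""


@dataclass
class Node:
    id: str
    label: Optional[str]
    parent: Optional["Node"] = None
    children: list["Node"] = field(default_factory=list)
    #: length of the edge above this node (Ma); for the root this is the
    #: stem length and may be None (no stem).
    length: Optional[float] = None
    age: float = 0.0

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id!r}, age={self.age:.3g})"


class DatedTree:
    """Rooted, dated phylogeny with node ages in Ma."""

    def __init__(self, root: Node, stem_length: Optional[float] = None):
        self.root = root
        if stem_length is not None:
            root.length = stem_length
        self._index()
        self._compute_ages()

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, stem_length: Optional[float] = None) -> "DatedTree":
        """Parse a Newick string (branch lengths in Ma) into a DatedTree.

        Internal node labels are kept as node ids when present; unlabeled
        internal nodes get deterministic preorder ids ``N1, N2, ...``.
        A branch length on the outermost clade becomes the stem length.
        """
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        counter = [0]
        used: set[str] = set()

        def convert(dnode) -> Node:
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise TreeError("leaf without a label")
                nid = dnode.taxon.label
            elif dnode.label:
                nid = dnode.label
            else:
                counter[0] += 1
                nid = f"N{counter[0]}"
                while nid in used:
                    counter[0] += 1
                    nid = f"N{counter[0]}"
            if nid in used:
                raise TreeError(f"duplicate node id {nid!r}")
            used.add(nid)
            node = Node(id=nid, label=nid, length=dnode.edge.length)
            for child in dnode.child_nodes():
                cnode = convert(child)
                cnode.parent = node
                node.children.append(cnode)
            return node

        root = convert(dtree.seed_node)
        for node in _preorder(root):
            if node is not root and node.length is None:
                raise TreeError(f"branch above {node.id!r} has no length")
            if node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length above {node.id!r}")
        if stem_length is not None:
            root.length = stem_length
        return cls(root)

    # ------------------------------------------------------------------
    # indexing / ages
    # ------------------------------------------------------------------
    def _index(self) -> None:
        self._preorder = list(_preorder(self.root))
        self._by_id = {n.id: n for n in self._preorder}
        if len(self._by_id) != len(self._preorder):
            raise TreeError("duplicate node ids")
        self._preorder_rank = {n.id: i for i, n in enumerate(self._preorder)}

    def _compute_ages(self) -> None:
        depth: dict[str, float] = {self.root.id: 0.0}
        for node in self._preorder[1:]:
            depth[node.id] = depth[node.parent.id] + float(node.length)
        maxdepth = max((depth[t.id] for t in self.leaves()), default=0.0)
        for node in self._preorder:
            node.age = maxdepth - depth[node.id]
        self.ultrametric = all(abs(t.age) <= ULTRAMETRIC_TOL for t in self.leaves())
        for tip in self.leaves():
            if abs(tip.age) <= ULTRAMETRIC_TOL:
                tip.age = 0.0

    # ------------------------------------------------------------------
    # accessors
    # ------------------------------------------------------------------
    def __getitem__(self, node_id: str) -> Node:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TreeError(f"no node {node_id!r} in tree") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._by_id

    def preorder(self) -> Iterator[Node]:
        return iter(self._preorder)

    def postorder(self) -> Iterator[Node]:
        return reversed(self._preorder)

    def leaves(self) -> list[Node]:
        return [n for n in self._preorder if n.is_leaf()]

    @property
    def taxa(self) -> list[str]:
        return [n.id for n in self.leaves()]

    @property
    def stem_length(self) -> Optional[float]:
        return self.root.length

    @stem_length.setter
    def stem_length(self, value: Optional[float]) -> None:
        self.root.length = value

    @property
    def root_age(self) -> float:
        return self.root.age

    @property
    def top_age(self) -> float:
        """Age of the oldest point on the tree (top of the stem, if any)."""
        return self.root.age + (self.root.length or 0.0)

    def preorder_rank(self, node_id: str) -> int:
        return self._preorder_rank[node_id]

    def branch_interval(self, node_id: str) -> tuple[float, float]:
        """(younger age, older age) of the branch above ``node_id``."""
        node = self[node_id]
        if node is self.root:
            if node.length is None:
                raise TreeError("root has no stem branch")
            return node.age, node.age + node.length
        return node.age, node.parent.age

    def branch_length(self, node_id: str) -> float:
        lo, hi = self.branch_interval(node_id)
        return hi - lo

    def branches(self, include_stem: bool = True) -> list[str]:
        """Branch ids in preorder (stem first if present and requested)."""
        out = []
        for node in self._preorder:
            if node is self.root:
                if include_stem and node.length is not None:
                    out.append(node.id)
            else:
                out.append(node.id)
        return out

    def require_ultrametric(self) -> None:
        if not self.ultrametric:
            raise TreeError(
                "tree is not ultrametric (tips at unequal ages); "
                "time profiles need a dated, ultrametric tree"
            )

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """Serialize with exact (shortest round-trip) float formatting."""

        def fmt(node: Node) -> str:
            if node.is_leaf():
                s = node.id
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.id
            if node.length is not None:
                s += f":{float(node.length)!r}"
            return s

        return fmt(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, DatedTree):
            return NotImplemented
        a = [(n.id, n.parent.id if n.parent else None, n.length) for n in self._preorder]
        b = [(n.id, n.parent.id if n.parent else None, n.length) for n in other._preorder]
        return a == b


def _preorder(root: Node) -> Iterator[Node]:
    stack = [root]
    while stack:
        node = stack.pop()
        yield node
        stack.extend(reversed(node.children))


def read_dated_tree(path) -> DatedTree:
    """Read a Newick file (single tree, branch lengths in Ma)."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise TreeError(f"empty tree file: {path}")
    return DatedTree.from_newick(text)


def write_dated_tree(tree: DatedTree, path) -> None:
    tree.write(path)
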