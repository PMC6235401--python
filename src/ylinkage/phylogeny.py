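"""Rooted phylogenies for linkage analysis.

Trees are read from strict rooted Newick (dendropy does the tokenizing) and
converted into a small explicit node structure.  The conversion buys three
things the downstream parsimony code depends on:

* a *canonical child order* (children sorted by the lexically smallest tip
  name in their subtree), which makes every traversal — and therefore every
  tie-break in ancestral-state assignment — deterministic;
* stable, human-readable node identifiers (tip name for leaves, internal
  label when the Newick carries one, ``N<k>`` in canonical preorder
  otherwise) used in event logs and reports;
* validation of the invariants the pipeline assumes: a single root, unique
  non-empty tip names, finite non-negative branch lengths.

Branch lengths, when present, are interpreted as millions of years (Myr)
throughout the package.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional, Sequence

import dendropy


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid rooted tree."""


class Node:
    """One node of a rooted phylogeny.

    ``length`` is the length of the branch *above* the node (to its parent),
    in Myr; ``None`` when the tree carries no branch lengths.  The root's
    length is ignored.
    """

    __slots__ = ("name", "length", "parent", "children", "id")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.id: str = ""

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id or self.name!r})"


class Phylogeny:
    """A validated rooted tree with canonical node order and stable ids."""

    def __init__(self, root: Node):
        self.root = root
        self._canonicalize()
        self._validate()
        self._tips = {n.name: n for n in self.root_postorder() if n.is_leaf}
        self._by_id = {n.id: n for n in self.preorder()}

    # -- construction helpers ------------------------------------------------

    def _canonicalize(self) -> None:
        anchor: dict[int, str] = {}
        for node in self.root_postorder():
            if node.is_leaf:
                anchor[id(node)] = node.name or ""
            else:
                node.children.sort(key=lambda c: anchor[id(c)])
                anchor[id(node)] = anchor[id(node.children[0])]
        k = 0
        for node in self.preorder():
            if node.is_leaf:
                node.id = node.name or ""
            elif node.name:
                node.id = node.name
            else:
                node.id = f"N{k}"
            k += 1

    def _validate(self) -> None:
        names = [n.name for n in self.root_postorder() if n.is_leaf]
        if any(not n for n in names):
            raise NewickParseError("tree contains an unnamed tip")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip names: {sorted(dupes)}")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is not None and (
                not math.isfinite(node.length) or node.length < 0
            ):
                raise NewickParseError(
                    f"invalid branch length {node.length!r} above node {node.id or node.name!r}"
                )

    # -- traversal -----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def root_postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    postorder = root_postorder

    def edges(self) -> Iterator[tuple[Node, Node]]:
        """(parent, child) pairs in canonical preorder of the child."""
        for node in self.preorder():
            if node.parent is not None:
                yield node.parent, node

    # -- queries -------------------------------------------------------------

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.preorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tip(self, name: str) -> Node:
        return self._tips[name]

    def node_by_id(self, node_id: str) -> Node:
        return self._by_id[node_id]

    def mrca(self, names: Sequence[str]) -> Node:
        """Most recent common ancestor of a set of tip names."""
        if not names:
            raise ValueError("mrca() needs at least one tip name")
        missing = [n for n in names if n not in self._tips]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        paths = []
        for name in names:
            path = []
            node: Optional[Node] = self._tips[name]
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        anc = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                anc = level[0]
            else:
                break
        return anc

    def clade_tips(self, node: Node) -> set[str]:
        return {n.name for n in _subtree(node) if n.is_leaf}

    @property
    def has_branch_lengths(self) -> bool:
        return all(c.length is not None for _, c in self.edges())

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (Myr); raises if any are missing."""
        if not self.has_branch_lengths:
            raise ValueError("tree has missing branch lengths")
        return sum(c.length for _, c in self.edges())

    # -- serialization -------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.name:
                    s += node.name
            if node.parent is not None and node.length is not None:
                s += f":{_fmt_len(node.length)}"
            return s

        return fmt(self.root) + ";"


def _subtree(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _fmt_len(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick expression into a :class:`Phylogeny`.

    Raises :class:`NewickParseError` on unbalanced parentheses, duplicate or
    empty tip names, and negative or non-finite branch lengths, naming the
    offending token where possible.
    """
    if not isinstance(text, str) or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        node = Node(name=name, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Phylogeny(convert(dtree.seed_node))


def write_newick(tree: Phylogeny) -> str:
    """Serialize a tree in canonical form (round-trips with parse_newick)."""
    return tree.to_newick()
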