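"""Rooted phylogenetic trees: data model, Newick I/O, shapes and enumeration.

The central object is :class:`RootedPhyloTree`, a rooted tree with labelled
leaves and optional positive edge lengths, edges directed away from the root.
An optional *stem* edge above the root is stored as a flagged length (never as
an extra vertex); it is excluded from diversity sums by default.

Unlabelled binary *tree shapes* (:class:`TreeShape`) are kept in a canonical
recursive encoding so that two shapes are isomorphic iff their encodings are
equal.  Exhaustive enumerators for shapes (Wedderburn–Etherington) and for
labelled binary trees (``(2n-3)!!`` of them) double as oracles for the
probabilistic modules.
"""

from __future__ import annotations

import json
from typing import Iterator, Optional, Sequence


class TreeError(ValueError):
    """Base class for tree-model errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class ValidationError(TreeError):
    """Tree violates a structural invariant (labels, lengths, degrees)."""


class Node:
    """A vertex; the edge *above* a non-root vertex is identified with it."""

    __slots__ = ("label", "children", "parent", "length", "horizontal")

    def __init__(self, label=None, length=None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length
        # True if the edge above this node is a "new species" (horizontal)
        # edge in an evolutionary tree; None when the distinction is unset.
        self.horizontal: Optional[bool] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, length={self.length})"


class RootedPhyloTree:
    """Rooted tree with labelled leaves and optional positive edge lengths.

    Parameters
    ----------
    root : Node
        Root vertex; its ``length`` attribute, if set, is interpreted as the
        stem edge length (stored on ``stem_length``).
    stem_length : float, optional
        Length of the stem edge above the root.  ``None`` means no stem.
    binary : bool
        If True, every interior vertex must have out-degree exactly 2.
    allow_zero_lengths : bool
        Permit zero-length edges (used only by the FD→PD reconstruction,
        which needs non-negative rather than strictly positive lengths).
    """

    def __init__(self, root: Node, stem_length=None, binary: bool = False,
                 allow_zero_lengths: bool = False):
        if root.length is not None and stem_length is None:
            stem_length = root.length
            root.length = None
        self.root = root
        self.stem_length = stem_length
        self.binary_flag = binary
        self.allow_zero_lengths = allow_zero_lengths
        self.validate()

    # -- structure -----------------------------------------------------

    def validate(self) -> None:
        seen_labels = set()
        count = 0
        for v in self.preorder():
            count += 1
            if v.is_leaf:
                if not v.label:
                    raise ValidationError("leaf with empty label")
                if v.label in seen_labels:
                    raise ValidationError(f"duplicate leaf label {v.label!r}")
                seen_labels.add(v.label)
            else:
                if len(v.children) < 2:
                    raise ValidationError(
                        "interior vertex with out-degree < 2")
                if self.binary_flag and len(v.children) != 2:
                    raise ValidationError(
                        "non-binary vertex in a binary-flagged tree")
                for c in v.children:
                    if c.parent is not v:
                        raise ValidationError("inconsistent parent pointer")
            if v is not self.root and v.length is not None:
                if v.length < 0 or (v.length == 0
                                    and not self.allow_zero_lengths):
                    raise ValidationError(
                        f"non-positive length on edge above {v.label or 'an interior vertex'}")
        # one traversal visited each vertex exactly once by construction
        self._n_vertices = count

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(v.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [v for v in self.preorder() if v.is_leaf]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(v.label for v in self.leaves())

    @property
    def n(self) -> int:
        return sum(1 for v in self.preorder() if v.is_leaf)

    def edges(self) -> Iterator[Node]:
        """Edges identified by their child vertex (stem excluded)."""
        for v in self.preorder():
            if v is not self.root:
                yield v

    def is_binary(self) -> bool:
        return all(len(v.children) in (0, 2) for v in self.preorder())

    def has_lengths(self) -> bool:
        return all(v.length is not None for v in self.edges())

    def find_leaf(self, label) -> Node:
        for v in self.preorder():
            if v.is_leaf and v.label == label:
                return v
        raise TreeError(f"unknown leaf {label!r}")

    def copy(self) -> "RootedPhyloTree":
        def rec(v: Node) -> Node:
            w = Node(v.label, v.length)
            w.horizontal = v.horizontal
            for c in v.children:
                w.add(rec(c))
            return w
        return RootedPhyloTree(rec(self.root), stem_length=self.stem_length,
                               binary=self.binary_flag,
                               allow_zero_lengths=self.allow_zero_lengths)

    # -- queries --------------------------------------------------------

    def clade(self, edge: Node) -> frozenset:
        """Leaf labels below ``edge`` (the set C_T(e))."""
        if edge is self.root:
            raise TreeError("the stem is not an edge of the tree proper")
        found = any(edge is v for v in self.preorder())
        if not found:
            raise TreeError("edge does not belong to this tree")
        labels = []
        stack = [edge]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                labels.append(v.label)
            stack.extend(v.children)
        return frozenset(labels)

    def path_to_leaf(self, label) -> list[Node]:
        """Edges (child-vertex handles) from the root down to leaf ``label``."""
        leaf = self.find_leaf(label)
        path = []
        v = leaf
        while v is not self.root:
            path.append(v)
            v = v.parent
        path.reverse()
        return path

    def depth(self, label) -> int:
        """Number of edges between the root and the leaf (stem excluded)."""
        return len(self.path_to_leaf(label))

    def total_length(self, include_stem: bool = False):
        tot = sum(v.length for v in self.edges())
        if include_stem and self.stem_length is not None:
            tot += self.stem_length
        return tot

    # -- Newick ---------------------------------------------------------

    def to_newick(self, include_lengths: bool = True,
                  decimals: Optional[int] = None) -> str:
        def fmt(x):
            if decimals is not None:
                return f"{float(x):.{decimals}f}"
            if isinstance(x, float):
                return repr(x)
            return str(x)

        def rec(v: Node) -> str:
            if v.is_leaf:
                s = str(v.label)
            else:
                s = "(" + ",".join(rec(c) for c in v.children) + ")"
            if include_lengths and v is not self.root and v.length is not None:
                s += ":" + fmt(v.length)
            return s

        s = rec(self.root)
        if include_lengths and self.stem_length is not None:
            s += ":" + fmt(self.stem_length)
        return s + ";"

    def __repr__(self):  # pragma: no cover
        return f"RootedPhyloTree(n={self.n})"


_LABEL_FORBIDDEN = set("(),:;")


def read_newick(text: str, binary: bool = False) -> RootedPhyloTree:
    """Parse a rooted Newick string.

    Interior node labels are accepted and ignored.  A branch length on the
    outermost group becomes the stem length.  Errors report the character
    offset; non-positive branch lengths and duplicate leaf labels are
    rejected.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickParseError("missing terminating ';'", len(text))
    s = s[:-1]
    pos = 0
    n_chars = len(s)

    def parse_label_length(node: Node, interior: bool):
        nonlocal pos
        start = pos
        while pos < n_chars and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        label = s[start:pos].strip()
        if label and not interior:
            node.label = label
        if pos < n_chars and s[pos] == ":":
            pos += 1
            lstart = pos
            while pos < n_chars and s[pos] not in _LABEL_FORBIDDEN:
                pos += 1
            try:
                node.length = float(s[lstart:pos])
            except ValueError:
                raise NewickParseError("invalid branch length", lstart)

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < n_chars and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_clade())
                if pos >= n_chars:
                    raise NewickParseError("unbalanced parentheses", pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"unexpected character {s[pos]!r}", pos)
            parse_label_length(node, interior=True)
        else:
            parse_label_length(node, interior=False)
            if node.label is None:
                raise NewickParseError("empty leaf label", pos)
        return node

    root = parse_clade()
    if pos != n_chars:
        raise NewickParseError(f"trailing characters {s[pos:]!r}", pos)
    try:
        return RootedPhyloTree(root, binary=binary)
    except ValidationError:
        raise


def write_newick(tree: RootedPhyloTree, **kwargs) -> str:
    return tree.to_newick(**kwargs)


# ---------------------------------------------------------------------------
# Tree shapes


class TreeShape:
    """Canonical form of an unlabelled rooted binary tree shape.

    The encoding is recursive: a leaf is ``()`` and an interior vertex is the
    pair of its children's encodings sorted lexicographically.  Equality of
    encodings is equivalence of shapes.  A *symmetry vertex* is an interior
    vertex whose two child encodings are equal; ``s`` counts them (the root
    included when its two child subtrees are isomorphic, which is the
    convention fixed by the five-leaf worked example with s=3).
    """

    __slots__ = ("encoding", "n")

    def __init__(self, encoding: tuple):
        self.encoding = encoding
        self.n = _count_leaves(encoding)

    def __eq__(self, other):
        return isinstance(other, TreeShape) and self.encoding == other.encoding

    def __hash__(self):
        return hash(self.encoding)

    def __lt__(self, other):
        return self.encoding < other.encoding

    @property
    def symmetry_count(self) -> int:
        """s(τ): number of interior vertices with isomorphic child subtrees."""
        def rec(enc):
            if not enc:
                return 0
            a, b = enc
            return (1 if a == b else 0) + rec(a) + rec(b)
        return rec(self.encoding)

    def descendant_counts(self) -> list[int]:
        """n_τ(v) = (#descendant leaves − 1) for every interior vertex v."""
        out = []

        def rec(enc) -> int:
            if not enc:
                return 1
            k = rec(enc[0]) + rec(enc[1])
            out.append(k - 1)
            return k

        rec(self.encoding)
        return out

    def to_newick(self) -> str:
        def rec(enc):
            if not enc:
                return ""
            return "(" + rec(enc[0]) + "," + rec(enc[1]) + ")"
        return (rec(self.encoding) or "()") + ";"

    def stats_json(self) -> str:
        return json.dumps({
            "n": self.n,
            "symmetry_vertices": self.symmetry_count,
            "descendant_counts": sorted(self.descendant_counts()),
        })

    def __repr__(self):  # pragma: no cover
        return f"TreeShape(n={self.n}, s={self.symmetry_count})"


def _count_leaves(enc: tuple) -> int:
    if not enc:
        return 1
    return _count_leaves(enc[0]) + _count_leaves(enc[1])


def shape_of(tree: RootedPhyloTree) -> TreeShape:
    """Canonical shape of a binary tree; invariant under relabelling and
    child reordering."""
    if not tree.is_binary():
        raise TreeError("shape_of requires a binary tree")

    def rec(v: Node) -> tuple:
        if v.is_leaf:
            return ()
        a, b = (rec(c) for c in v.children)
        return (a, b) if a <= b else (b, a)

    return TreeShape(rec(tree.root))


def enumerate_shapes(n: int) -> list[TreeShape]:
    """All distinct binary rooted shapes on ``n`` leaves (1 ≤ n ≤ 20).

    Counts follow the Wedderburn–Etherington numbers 1, 1, 1, 2, 3, 6, 11, …
    """
    if not 1 <= n <= 20:
        raise TreeError("enumerate_shapes supports 1 <= n <= 20")
    return [TreeShape(e) for e in _shape_encodings(n)]


_SHAPE_CACHE: dict[int, list[tuple]] = {1: [()]}


def _shape_encodings(n: int) -> list[tuple]:
    if n not in _SHAPE_CACHE:
        out = set()
        for i in range(1, n // 2 + 1):
            for a in _shape_encodings(i):
                for b in _shape_encodings(n - i):
                    out.add((a, b) if a <= b else (b, a))
        _SHAPE_CACHE[n] = sorted(out)
    return _SHAPE_CACHE[n]


def enumerate_labeled_trees(labels: Sequence) -> list[RootedPhyloTree]:
    """All rooted binary phylogenetic trees on the given labels (2 ≤ n ≤ 8).

    Built by sequential attachment: the k-th leaf can be grafted onto any of
    the 2k−3 edges of a (k−1)-leaf tree or above its root, giving the
    ``(2n−3)!!`` distinct trees.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise TreeError("need at least two labels")
    if n > 8:
        raise TreeError("refusing n > 8: (2n-3)!! trees is too many")
    if len(set(labels)) != n:
        raise TreeError("labels must be distinct")

    first = Node()
    first.add(Node(labels[0]))
    first.add(Node(labels[1]))
    trees = [first]
    for label in labels[2:]:
        nxt = []
        for t in trees:
            n_spots = len(_attachment_spots(t))
            for i in range(n_spots):
                t2 = _copy_node(t)
                spot = _attachment_spots(t2)[i]
                nxt.append(_graft(t2, spot, label))
        trees = nxt
    return [RootedPhyloTree(t, binary=True) for t in trees]


def _copy_node(v: Node) -> Node:
    w = Node(v.label, v.length)
    for c in v.children:
        w.add(_copy_node(c))
    return w


def _preorder_nodes(root: Node) -> list[Node]:
    out = []
    stack = [root]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(reversed(v.children))
    return out


def _attachment_spots(root: Node) -> list[Node]:
    # every vertex, root included: attaching "above the root" creates a new root
    return _preorder_nodes(root)


def _graft(root: Node, spot: Node, label) -> Node:
    new_internal = Node()
    leaf = Node(label)
    if spot is root:
        new_internal.add(root)
        new_internal.add(leaf)
        root.parent = new_internal
        return new_internal
    parent = spot.parent
    idx = parent.children.index(spot)
    new_internal.add(spot)
    new_internal.add(leaf)
    new_internal.parent = parent
    parent.children[idx] = new_internal
    return root


# convenience wrappers matching the documented operation names ------------


def clade(tree: RootedPhyloTree, edge: Node) -> frozenset:
    return tree.clade(edge)


def path_to_leaf(tree: RootedPhyloTree, label) -> list[Node]:
    return tree.path_to_leaf(label)


def depth(tree: RootedPhyloTree, label) -> int:
    return tree.depth(label)


def double_factorial(m: int) -> int:
    """m!! for odd/even m ≥ −1 (with (−1)!! = 1)."""
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out
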