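"""Unrooted phylogenetic trees: structure, Newick I/O, bipartitions.

Trees are stored with an arbitrary internal traversal root (degree 3 for
binary unrooted trees with >= 3 leaves); under the time-reversible models
used here the likelihood does not depend on that choice, and the Newick
serialization's rooting is cosmetic.  Bipartition support values (integer
percent) live on the child node of each internal edge.
"""

from __future__ import annotations

from typing import Iterator

from .errors import NewickParseError


class Node:
    """Tree node.  ``length`` is the branch length to the parent in
    substitutions/site (None only at the traversal root)."""

    __slots__ = ("label", "children", "parent", "length", "support")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.support: int | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"Node({self.label!r})" if self.is_leaf else f"Node(<{len(self.children)} children>)"


class Tree:
    """A tree rooted for traversal at ``root``; semantically unrooted."""

    def __init__(self, root: Node):
        self.root = root
        self.log_likelihood: float | None = None

    # ---------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Internal edges: child node is itself internal (n_taxa - 3 of
        them in a binary unrooted tree)."""
        return [n for n in self.edges() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # --------------------------------------------------------- copy
    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length)
            m.support = n.support
            for c in n.children:
                m.add(clone(c))
            return m

        t = Tree(clone(self.root))
        t.log_likelihood = self.log_likelihood
        return t

    # ------------------------------------------------------ reroot
    def rerooted_at(self, target_label_or_node) -> "Tree":
        """Copy of the tree re-hung at an internal node (or at the parent
        of the named leaf).  Topology and branch lengths are untouched;
        only the traversal root moves."""
        t = self.copy()
        if isinstance(target_label_or_node, Node):
            # locate the corresponding node in the copy by path
            path = []
            n = target_label_or_node
            while n.parent is not None:
                path.append(n.parent.children.index(n))
                n = n.parent
            node = t.root
            for i in reversed(path):
                node = node.children[i]
        else:
            node = next(n for n in t.postorder() if n.label == target_label_or_node)
        if node.is_leaf:
            node = node.parent
        # walk up from node, reversing each parent link; the length of
        # edge (chain[i], chain[i+1]) moves from chain[i] to chain[i+1]
        chain = []
        n = node
        while n is not None:
            chain.append(n)
            n = n.parent
        lengths = [n.length for n in chain]
        for i in range(len(chain) - 1):
            par, child = chain[i + 1], chain[i]
            par.children.remove(child)
            child.add(par)
            par.length = lengths[i]
        node.parent = None
        node.length = None
        return Tree(node)

    # ------------------------------------------------- bipartitions
    def bipartitions(self) -> set[frozenset[str]]:
        """Normalized leaf-set splits of the internal edges.

        Each internal edge splits the leaves in two; the side not
        containing the lexicographically smallest leaf label is the
        canonical representative.
        """
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        below: dict[Node, frozenset[str]] = {}
        out: set[frozenset[str]] = set()
        for n in self.postorder():
            if n.is_leaf:
                below[n] = frozenset([n.label])
            else:
                below[n] = frozenset().union(*(below[c] for c in n.children))
                if n.parent is not None:
                    side = below[n] if anchor not in below[n] else all_leaves - below[n]
                    if 1 < len(side) < len(all_leaves) - 1:
                        out.add(side)
        return out

    def rf_distance(self, other: "Tree") -> int:
        """Robinson-Foulds distance (symmetric bipartition difference)."""
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            raise ValueError("trees have different leaf sets")
        return len(self.bipartitions() ^ other.bipartitions())

    # -------------------------------------------------------- newick
    def to_newick(self, include_support: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                body = _escape(n.label)
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if include_support and n.support is not None and n.parent is not None:
                    body += str(int(n.support))
            if n.length is not None:
                body += f":{n.length:.6g}"
            return body

        return fmt(self.root) + ";"


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, path, include_support: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(include_support=include_support) + "\n")


def parse_newick(text: str) -> Tree:
    """Recursive-descent Newick parser; raises :class:`NewickParseError`
    with the failing character offset.  Internal-node labels that parse
    as integers are stored as bootstrap supports."""
    s = text.strip()
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def parse_label() -> str:
        nonlocal pos
        if peek() == "'":
            pos += 1
            out = []
            while True:
                if pos >= len(s):
                    raise NewickParseError("unterminated quoted label", pos)
                ch = s[pos]
                if ch == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(ch)
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_length() -> float | None:
        nonlocal pos
        if peek() != ":":
            return None
        pos += 1
        start = pos
        while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            raise NewickParseError(f"bad branch length {s[start:pos]!r}", start) from None

    def parse_clade() -> Node:
        nonlocal pos
        if peek() == "(":
            pos += 1
            node = Node()
            while True:
                node.add(parse_clade())
                if peek() == ",":
                    pos += 1
                    continue
                if peek() == ")":
                    pos += 1
                    break
                raise NewickParseError("expected ',' or ')'", pos)
            label = parse_label()
            if label:
                try:
                    node.support = int(label)
                except ValueError:
                    node.label = label
            node.length = parse_length()
            return node
        label = parse_label()
        if not label:
            raise NewickParseError("expected a leaf label or '('", pos)
        node = Node(label)
        node.length = parse_length()
        return node

    root = parse_clade()
    if peek() != ";":
        raise NewickParseError("expected ';' at end of tree", pos)
    pos += 1
    if s[pos:].strip():
        raise NewickParseError("trailing content after ';'", pos)
    return Tree(root)


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())
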