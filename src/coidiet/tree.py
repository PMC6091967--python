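"""Rooted phylogenetic trees with branch lengths and jplace edge numbers.

The tree container is deliberately small: the placement machinery needs
parent links, per-edge branch lengths, stable edge numbering and cheap
copying, and the jplace dialect of newick (``{edge_num}`` tokens after
branch lengths) is not handled by general-purpose newick readers.
Plain newick (with quoted labels and bracket comments) is accepted too.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional

from .errors import FormatError, ValidationError

__all__ = ["TreeNode", "PhyloTree", "read_newick", "write_newick"]


class TreeNode:
    __slots__ = ("name", "length", "children", "parent", "edge_num")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length  # branch length of the edge above this node
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        self.edge_num: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name!r} {kind} len={self.length}>"


class PhyloTree:
    """A rooted tree; one root, unique leaf labels, branch lengths >= 0."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def edges(self) -> list[TreeNode]:
        """Every non-root node stands for the edge joining it to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def node_by_edge_num(self, edge_num: int) -> TreeNode:
        for node in self.postorder():
            if node.edge_num == edge_num:
                return node
        raise KeyError(f"no edge numbered {edge_num}")

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == label:
                return leaf
        raise KeyError(label)

    # -- editing -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            new.edge_num = node.edge_num
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def prune_to(self, keep: set[str]) -> list[str]:
        """Drop leaves not in *keep*, collapsing unary nodes (lengths add).

        Returns the labels that were removed.
        """
        removed = [lab for lab in self.leaf_labels() if lab not in keep]

        def rebuild(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.name in keep:
                    out = TreeNode(node.name, node.length)
                    return out
                return None
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                only = kids[0]
                # collapse the unary node: its length accrues to the child
                if node.length is not None or only.length is not None:
                    only.length = (node.length or 0.0) + (only.length or 0.0)
                return only
            new = TreeNode(node.name, node.length)
            for k in kids:
                new.add_child(k)
            return new

        new_root = rebuild(self.root)
        if new_root is None:
            raise ValidationError("pruning removed every leaf")
        new_root.parent = None
        self.root = new_root
        return removed

    def validate(self) -> None:
        labels = self.leaf_labels()
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValidationError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.edges():
            if node.length is not None and node.length < 0:
                raise ValidationError(f"negative branch length on {node.name!r}")


# ---------------------------------------------------------------------------
# newick reading / writing
# ---------------------------------------------------------------------------

def read_newick(text: str, edge_numbers: bool = False) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Accepts the jplace dialect in which every branch may carry a
    ``{edge_num}`` token after its length. Bracketed comments ``[...]``
    are skipped; labels may be single-quoted.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n:
            c = text[pos]
            if c.isspace():
                pos += 1
            elif c == "[":  # comment
                end = text.find("]", pos)
                if end == -1:
                    raise FormatError("unterminated [comment] in newick")
                pos = end + 1
            else:
                break

    def parse_label() -> Optional[str]:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            end = pos + 1
            out = []
            while end < n:
                if text[end] == "'":
                    if end + 1 < n and text[end + 1] == "'":
                        out.append("'")
                        end += 2
                        continue
                    break
                out.append(text[end])
                end += 1
            else:
                raise FormatError("unterminated quoted label in newick")
            pos = end + 1
            return "".join(out)
        start = pos
        while pos < n and text[pos] not in "(),:;[]{}":
            pos += 1
        label = text[start:pos].strip()
        return label or None

    def parse_suffix(node: TreeNode) -> None:
        """Optional ':length' and '{edge_num}' after a label/subtree."""
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos] in "+-.eE" or text[pos].isdigit()):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise FormatError(f"bad branch length at offset {start}") from None
        skip_ws()
        if pos < n and text[pos] == "{":
            end = text.find("}", pos)
            if end == -1:
                raise FormatError("unterminated {edge_num} token in newick")
            try:
                node.edge_num = int(text[pos + 1:end])
            except ValueError:
                raise FormatError(f"bad edge number {text[pos + 1:end]!r}") from None
            pos = end + 1

    def parse_clade() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if pos < n and text[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= n:
                    raise FormatError("unbalanced parentheses in newick")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {text[pos]!r} at offset {pos}")
            node.name = parse_label()
        else:
            node.name = parse_label()
            if node.name is None:
                raise FormatError(f"expected a label at offset {pos}")
        parse_suffix(node)
        return node

    root = parse_clade()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise FormatError("newick string must end with ';'")
    pos += 1
    skip_ws()
    if pos != n:
        raise FormatError("trailing characters after ';' in newick")
    tree = PhyloTree(root)
    tree.validate()
    if edge_numbers:
        nums = sorted(e.edge_num for e in tree.edges())
        if None in nums or nums != list(range(len(nums))):
            raise FormatError("edge numbers do not form a contiguous 0-based set")
    return tree


def _fmt_label(label: str) -> str:
    if any(c in label for c in "(),:;[]{}' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, edge_numbers: bool = False) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            s = _fmt_label(node.name or "")
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                s += _fmt_label(node.name)
        if node.length is not None:
            s += f":{node.length!r}"
        if edge_numbers and node.parent is not None:
            if node.edge_num is None:
                raise ValidationError("edge numbers requested but not assigned")
            s += f"{{{node.edge_num}}}"
        return s

    return render(tree.root) + ";"
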