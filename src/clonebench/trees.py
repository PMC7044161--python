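"""Rooted tip-labelled trees with duplicate labels, plus Newick I/O.

Tree-distance computations here need multifurcating rooted trees whose tips
may share labels (several inferred clones can map to one true clone), which
rules out parsers built around unique taxon namespaces; the minimal Newick
grammar is therefore parsed directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["LabeledTree", "parse_newick", "tip_tree_from_clone_phylogeny"]


@dataclass(frozen=True)
class LabeledTree:
    """Rooted tree: integer node ids, ``parent`` child->parent map, tip labels."""

    root: int
    parent: Mapping[int, int]
    labels: Mapping[int, str]  # tip node -> label (duplicates allowed)
    internal_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "parent", dict(self.parent))
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "internal_labels", dict(self.internal_labels))
        for n in self.parent:
            cur, seen = n, {n}
            while cur != self.root:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError("cycle in tree")
                seen.add(cur)

    @property
    def nodes(self) -> list:
        return [self.root] + sorted(self.parent)

    def children(self, node: int) -> list:
        return sorted(c for c, p in self.parent.items() if p == node)

    @property
    def tips(self) -> list:
        parents = set(self.parent.values())
        return [n for n in self.nodes if n not in parents]

    def depth(self, node: int) -> int:
        """Edges between the root and ``node``."""
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    def root_path(self, node: int) -> list:
        path = [node]
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        return path[::-1]

    def mrca(self, nodes) -> int:
        nodes = list(nodes)
        common = set(self.root_path(nodes[0]))
        for n in nodes[1:]:
            common &= set(self.root_path(n))
        return max(common, key=self.depth)

    def tipset(self, node: int) -> frozenset:
        """Labels of the tips descending from ``node`` (multiset collapsed)."""
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            kids = self.children(n)
            if not kids:
                out.append(self.labels.get(n, str(n)))
            else:
                stack.extend(kids)
        return frozenset(out)

    def label_tips(self) -> dict:
        """Map label -> list of tip nodes carrying it."""
        out: dict = {}
        for t in self.tips:
            out.setdefault(self.labels.get(t, str(t)), []).append(t)
        return out

    # -- editing ----------------------------------------------------------

    def relabel(self, label_map: Mapping[str, str]) -> "LabeledTree":
        return LabeledTree(
            self.root, self.parent,
            {t: label_map.get(l, l) for t, l in self.labels.items()},
            self.internal_labels)

    def keep_tips(self, tips_to_keep) -> "LabeledTree":
        """Prune to a tip subset, suppressing unary internal nodes."""
        keep = set(tips_to_keep)
        bad = set(self.tips) - keep
        parent = dict(self.parent)
        labels = {t: l for t, l in self.labels.items() if t in keep}
        for t in bad:
            parent.pop(t, None)
        changed = True
        while changed:
            changed = False
            nodes = [self.root] + list(parent)
            kids: dict = {}
            for c, p in parent.items():
                kids.setdefault(p, []).append(c)
            for n in list(parent):
                if n in labels:
                    continue
                ch = kids.get(n, [])
                if len(ch) == 0:
                    parent.pop(n)
                    changed = True
                elif len(ch) == 1:
                    parent[ch[0]] = parent[n]
                    parent.pop(n)
                    changed = True
        # suppress a unary root
        root = self.root
        kids = [c for c, p in parent.items() if p == root]
        while len(kids) == 1 and kids[0] not in labels:
            new_root = kids[0]
            parent.pop(new_root)
            root = new_root
            kids = [c for c, p in parent.items() if p == root]
        return LabeledTree(root, parent, labels)

    # -- newick -----------------------------------------------------------

    def to_newick(self) -> str:
        def render(node: int) -> str:
            kids = self.children(node)
            if not kids:
                return _quote(self.labels.get(node, str(node)))
            inner = ",".join(render(c) for c in kids)
            lbl = self.internal_labels.get(node, "")
            return f"({inner}){_quote(lbl) if lbl else ''}"
        return render(self.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in "(),:;' \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_newick(text: str) -> LabeledTree:
    """Parse a rooted Newick string; duplicate tip labels are preserved."""
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    pos = 0
    counter = [0]
    parent: dict = {}
    labels: dict = {}
    internal_labels: dict = {}

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    def read_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'" and pos + 1 < len(s) and s[pos + 1] == "'":
                    out.append("'")
                    pos += 2
                elif s[pos] == "'":
                    pos += 1
                    break
                else:
                    out.append(s[pos])
                    pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def skip_length() -> None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            while pos < len(s) and s[pos] not in "(),;":
                pos += 1

    def parse_clade() -> int:
        nonlocal pos
        node = new_node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                child = parse_clade()
                parent[child] = node
                if pos < len(s) and s[pos] == ",":
                    pos += 1
                    continue
                break
            if pos >= len(s) or s[pos] != ")":
                raise ValueError(f"unbalanced parentheses in newick near {pos}")
            pos += 1
            lbl = read_label()
            if lbl:
                internal_labels[node] = lbl
        else:
            lbl = read_label()
            labels[node] = lbl
        skip_length()
        return node

    root = parse_clade()
    if pos != len(s):
        raise ValueError(f"trailing characters in newick: {s[pos:]!r}")
    return LabeledTree(root, parent, labels, internal_labels)


def tip_tree_from_clone_phylogeny(tree, include_germline: bool = True,
                                  label_map: Mapping | None = None) -> LabeledTree:
    """Turn a clone phylogeny into a tip-labelled tree.

    Every clone (including ancestral, internal clones) becomes a tip: an
    internal clone node contributes a pendant tip attached at its position,
    mirroring how a taxon tree over clone genotypes represents persisting
    ancestors.  Nodes carrying several merged clone labels contribute one
    tip per label.  The germline becomes a tip labelled ``Normal`` attached
    at the root.
    """
    label_map = dict(label_map or {})
    counter = [0]
    parent: dict = {}
    labels: dict = {}

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    node_of: dict = {}
    for clone in tree.nodes:
        n = new_node()
        node_of[clone] = n
        if clone != tree.root_id:
            parent[n] = node_of[tree.parent_of[clone]]
    kids_count = {c: len(tree.children(c)) for c in tree.nodes}
    for clone in tree.nodes:
        clone_labels = list(tree.labels_of(clone))
        if clone == tree.root_id:
            if not include_germline:
                continue
            clone_labels = [l for l in clone_labels if True]
        if kids_count[clone] == 0 and len(clone_labels) == 1:
            labels[node_of[clone]] = label_map.get(clone_labels[0],
                                                   str(clone_labels[0]))
            continue
        for lbl in clone_labels:
            t = new_node()
            parent[t] = node_of[clone]
            labels[t] = label_map.get(lbl, str(lbl))
    return LabeledTree(node_of[tree.root_id], parent, labels)
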