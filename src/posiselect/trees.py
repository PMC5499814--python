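"""Unrooted species trees with branch lengths and a marked foreground branch.

Internally a tree is stored in rooted form, but the root is a basal
multifurcation carrying no branch length, so the object represents an
unrooted tree: every non-root node corresponds to exactly one branch (the
edge above it), identified by the set of leaf labels below it.  Branch
lengths are in expected substitutions per codon.  Newick parsing is
delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.postorder() if n.is_leaf)

    def copy(self) -> "Node":
        return Node(self.name, self.length, [c.copy() for c in self.children])


def split_key(split: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical (orientation-free) identifier of the branch cutting off `split`."""
    comp = all_leaves - split
    a, _ = sorted((split, comp), key=lambda s: (len(s), tuple(sorted(s))))
    return a


class SpeciesTree:
    """Unrooted phylogeny over species labels.

    Parameters
    ----------
    root : Node
        Root of the internal rooted representation; a degree-2 root
        (conventional rooted Newick) is merged into a basal trifurcation.
    foreground : str | Iterable[str] | None
        Branch to test: a terminal species name, or the set of leaf labels
        below an internal branch.
    """

    def __init__(self, root: Node, foreground=None):
        self.root = root
        self._unroot()
        names = [n.name for n in self.root.postorder() if n.is_leaf]
        if len(names) != len(set(names)):
            raise ValueError("leaf labels are not unique")
        self.leaves = frozenset(names)
        if any(n.length < 0 for n in self.root.postorder()):
            raise ValueError("negative branch length")
        self.foreground: Optional[frozenset] = None
        if foreground is not None:
            self.set_foreground(foreground)

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, foreground=None) -> "SpeciesTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)

        def conv(dn) -> Node:
            return Node(
                name=dn.taxon.label.replace(" ", "_") if dn.taxon is not None else None,
                length=float(dn.edge.length) if dn.edge.length is not None else 0.0,
                children=[conv(c) for c in dn.child_nodes()],
            )

        return cls(conv(dt.seed_node), foreground=foreground)

    @classmethod
    def read(cls, path, foreground=None) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), foreground=foreground)

    def _unroot(self):
        root = self.root
        root.length = 0.0
        while len(root.children) == 2:
            a, b = root.children
            keep = a if not a.is_leaf else b
            if keep.is_leaf:  # 2-taxon tree: keep the degree-2 root
                break
            other = b if keep is a else a
            other.length += keep.length
            root.children = keep.children + [other]
            root.name = keep.name

    def copy(self) -> "SpeciesTree":
        t = SpeciesTree(self.root.copy())
        t.foreground = self.foreground
        return t

    def _parents(self) -> dict:
        return {id(c): p for p in self.root.postorder() for c in p.children}

    # -- branches ------------------------------------------------------

    def branches(self) -> dict[frozenset, Node]:
        """Map leafset-below → node, for every branch (non-root node)."""
        out = {}
        for node in self.root.postorder():
            if node is not self.root:
                out[node.leaf_names()] = node
        return out

    def splits(self) -> set[frozenset]:
        """Canonical non-trivial splits (internal branches)."""
        return {
            split_key(s, self.leaves)
            for s in self.branches()
            if 1 < len(s) < len(self.leaves) - 1
        }

    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)

    def scaled(self, factor: float) -> "SpeciesTree":
        t = self.copy()
        for n in t.root.postorder():
            if n is not t.root:
                n.length *= factor
        return t

    # -- rerooting ------------------------------------------------------

    def _reroot_at(self, target: Node):
        """Make an internal node the (multifurcating) root."""
        if target is self.root:
            return
        parents = self._parents()
        path = [target]
        while path[-1] is not self.root:
            path.append(parents[id(path[-1])])
        lens = [n.length for n in path]
        for i in range(len(path) - 1):
            path[i + 1].children.remove(path[i])
        for i in range(len(path) - 1):
            path[i].children.append(path[i + 1])
            path[i + 1].length = lens[i]
        target.length = 0.0
        self.root = target
        self._collapse_unary()

    def _collapse_unary(self):
        def fix(node: Node) -> Node:
            node.children = [fix(c) for c in node.children]
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                return child
            return node

        self.root = fix(self.root)
        self.root.length = 0.0

    # -- foreground / sister -------------------------------------------

    def set_foreground(self, foreground):
        target = (frozenset([foreground]) if isinstance(foreground, str)
                  else frozenset(foreground))
        unknown = target - self.leaves
        if unknown:
            raise ValueError(f"foreground species not in tree: {sorted(unknown)}")
        if target == self.leaves:
            raise ValueError("foreground cannot be the whole leaf set")
        if target not in self.branches():
            comp = self.leaves - target
            node = self.branches().get(comp)
            if node is None:
                raise ValueError(f"no branch corresponds to clade {sorted(target)}")
            if node.is_leaf:
                raise ValueError(
                    "foreground of all-but-one species is ambiguous; "
                    "test the terminal branch instead")
            self._reroot_at(node)
            if target not in self.branches():  # pragma: no cover - safety net
                raise ValueError(f"cannot orient clade {sorted(target)}")
        self.foreground = target

    def foreground_node(self) -> Node:
        if self.foreground is None:
            raise ValueError("no foreground branch set")
        return self.branches()[self.foreground]

    def sister_species(self, foreground=None) -> frozenset:
        """Leaf labels of the sister clade of the foreground branch (the other
        subtrees hanging off the node where the tested branch attaches)."""
        if foreground is not None:
            self.set_foreground(foreground)
        node = self.foreground_node()
        parent = self._parents()[id(node)]
        return frozenset().union(
            *[c.leaf_names() for c in parent.children if c is not node]
        )

    # -- restriction ---------------------------------------------------

    def restricted(self, species: Iterable[str]) -> "SpeciesTree":
        """Tree pruned to a subset of species (branch lengths summed through
        collapsed unary nodes)."""
        keep = frozenset(species)
        missing = keep - self.leaves
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return node.copy() if node.name in keep else None
            kids = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].length += node.length
                return kids[0]
            return Node(node.name, node.length, kids)

        new_root = prune(self.root)
        if new_root is None or new_root.is_leaf:
            raise ValueError("fewer than 2 species left after restriction")
        new_root.length = 0.0
        t = SpeciesTree(new_root)
        if self.foreground is not None:
            fg = self.foreground & keep
            if fg and fg != keep:
                try:
                    t.set_foreground(fg)
                except ValueError:
                    pass
        return t

    # -- I/O -----------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            if node is self.root:
                return f"({inner});"
            return f"({inner}):{node.length:.10g}"

        return fmt(self.root)

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self):
        return f"SpeciesTree({len(self.leaves)} taxa, foreground={self.foreground})"
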