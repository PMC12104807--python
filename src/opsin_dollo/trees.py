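"""Rooted species-tree hypotheses with named internal nodes.

The package ships the two competing placements of Xenacoelomorpha as
cladograms over five terminal clades:

* ``nephrozoa`` — Xenacoelomorpha sister to all remaining Bilateria
  (Protostomia + Deuterostomia, together "Nephrozoa");
* ``xenambulacraria`` — Xenacoelomorpha sister to Ambulacraria, nested
  inside Deuterostomia.

Branch lengths are ignored throughout: the parsimony argument is purely
topological.  Trees must be binary and rooted; Cnidaria is the outgroup
in both builtins, so the root is the Cnidaria–Bilateria (eumetazoan)
ancestor.  Newick parsing and serialisation are delegated to dendropy;
the wrapper keeps a name-indexed view with parent/child pointers, which
is what the Dollo engine needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import dendropy

__all__ = ["CladeTree", "TreeError", "builtin_tree", "read_tree", "write_tree", "BUILTIN_NEWICK"]

BUILTIN_NEWICK = {
    "nephrozoa": (
        "(Cnidaria,(Xenacoelomorpha,(Protostomia,(Chordata,Ambulacraria)"
        "Deuterostomia)Nephrozoa)Bilateria)Eumetazoa;"
    ),
    "xenambulacraria": (
        "(Cnidaria,(Protostomia,((Ambulacraria,Xenacoelomorpha)Xenambulacraria,"
        "Chordata)Deuterostomia)Bilateria)Eumetazoa;"
    ),
}

#: Node carrying the "ancestral bilaterian" repertoire queries in both builtins.
BILATERIAN_ANCESTOR = "Bilateria"


class TreeError(ValueError):
    """Malformed or unsupported species tree."""


@dataclass
class _Node:
    name: str
    parent: str | None
    children: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class CladeTree:
    """Rooted binary cladogram with uniquely named nodes.

    Every node (terminal or internal) is addressed by its name; the edge
    above a node is identified by the node's name, so "a loss on branch X"
    means a loss on the edge leading into node X.
    """

    def __init__(self, root: str, nodes: dict[str, _Node], labels: dict[str, str] | None = None):
        self.root = root
        self._nodes = nodes
        #: designated nodes of interest, e.g. {"bilaterian_ancestor": "Bilateria"}
        self.labels = labels or {}
        self._validate()
        self._leaf_cache: dict[str, frozenset[str]] = {}

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "CladeTree":
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from None
        nodes: dict[str, _Node] = {}
        # First pass: collect names, auto-naming unlabeled internals by
        # postorder index (n1, n2, ...) with a warning.
        auto_idx = 0
        names: dict[int, str] = {}
        for nd in dtree.postorder_node_iter():
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon else nd.label
                if not name:
                    raise TreeError("leaf without a name")
            else:
                name = nd.label
                if not name:
                    auto_idx += 1
                    name = f"n{auto_idx}"
                    warnings.warn(
                        f"unlabeled internal node auto-named {name!r} (postorder index)",
                        stacklevel=2,
                    )
            name = name.replace(" ", "_")
            if name in {v for v in names.values()}:
                raise TreeError(f"duplicate node name {name!r}")
            names[id(nd)] = name
        root_name = None
        for nd in dtree.preorder_node_iter():
            name = names[id(nd)]
            parent = names[id(nd.parent_node)] if nd.parent_node is not None else None
            nodes[name] = _Node(name, parent)
            if parent is None:
                root_name = name
            else:
                nodes[parent].children.append(name)
        assert root_name is not None
        labels = {}
        if BILATERIAN_ANCESTOR in nodes:
            labels["bilaterian_ancestor"] = BILATERIAN_ANCESTOR
        return cls(root_name, nodes, labels)

    def to_newick(self) -> str:
        def render(name: str) -> str:
            node = self._nodes[name]
            if node.is_leaf:
                return name
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){name}"

        return render(self.root) + ";"

    def _validate(self) -> None:
        if self.root not in self._nodes:
            raise TreeError(f"root {self.root!r} not among nodes")
        for node in self._nodes.values():
            if node.children and len(node.children) != 2:
                raise TreeError(
                    f"node {node.name!r} has {len(node.children)} children; "
                    "only binary rooted trees are supported"
                )

    # -- queries -------------------------------------------------------

    @property
    def leaves(self) -> list[str]:
        return [n for n in self.postorder() if self._nodes[n].is_leaf]

    @property
    def node_names(self) -> list[str]:
        return list(self._nodes)

    @property
    def internal_names(self) -> list[str]:
        return [n for n in self.postorder() if not self._nodes[n].is_leaf]

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def parent(self, name: str) -> str | None:
        return self._node(name).parent

    def children(self, name: str) -> list[str]:
        return list(self._node(name).children)

    def is_leaf(self, name: str) -> bool:
        return self._node(name).is_leaf

    def _node(self, name: str) -> _Node:
        try:
            return self._nodes[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}; have {sorted(self._nodes)}") from None

    def postorder(self, start: str | None = None) -> list[str]:
        out: list[str] = []

        def walk(name: str) -> None:
            for c in self._nodes[name].children:
                walk(c)
            out.append(name)

        walk(start or self.root)
        return out

    def subtree_leaves(self, name: str) -> frozenset[str]:
        """Terminal clades descending from (or equal to) ``name``."""
        if name not in self._leaf_cache:
            node = self._node(name)
            if node.is_leaf:
                self._leaf_cache[name] = frozenset({name})
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= self.subtree_leaves(c)
                self._leaf_cache[name] = frozenset(acc)
        return self._leaf_cache[name]

    def path_to_root(self, name: str) -> list[str]:
        """Nodes from ``name`` up to and including the root."""
        out = [name]
        cur = self._node(name)
        while cur.parent is not None:
            out.append(cur.parent)
            cur = self._nodes[cur.parent]
        return out

    def is_ancestor_or_equal(self, anc: str, desc: str) -> bool:
        return anc in self.path_to_root(desc)

    def lca(self, names: Iterable[str]) -> str:
        """Last common ancestor of one or more named nodes."""
        names = list(names)
        if not names:
            raise ValueError("lca of empty node set")
        paths = [self.path_to_root(n) for n in names]
        common = set(paths[0])
        for p in paths[1:]:
            common &= set(p)
        # deepest common node = first along any leaf-to-root path
        for node in paths[0]:
            if node in common:
                return node
        raise AssertionError("rooted tree must have a common ancestor")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CladeTree):
            return NotImplemented
        return self.to_newick() == other.to_newick()

    def __repr__(self) -> str:
        return f"CladeTree({self.to_newick()!r})"


def builtin_tree(name: str) -> CladeTree:
    """Return one of the packaged species-tree hypotheses.

    ``nephrozoa`` places Xenacoelomorpha as sister to Protostomia +
    Deuterostomia; ``xenambulacraria`` nests it beside Ambulacraria inside
    Deuterostomia.  Both are rooted on Cnidaria and label the Bilateria
    node as the bilaterian ancestor.
    """
    try:
        newick = BUILTIN_NEWICK[name]
    except KeyError:
        raise KeyError(
            f"unknown hypothesis {name!r}; choose from {sorted(BUILTIN_NEWICK)}"
        ) from None
    return CladeTree.from_newick(newick)


def read_tree(path: str | Path) -> CladeTree:
    """Read a rooted, internally labelled Newick tree."""
    return CladeTree.from_newick(Path(path).read_text())


def write_tree(tree: CladeTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
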