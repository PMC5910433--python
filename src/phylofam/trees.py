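"""Rooted-tree containers shared across the pipeline.

Two kinds of trees appear throughout: the *species tree* (the organismal
phylogeny on which events are mapped) and *gene trees* (one per protein
family, leaves labeled ``species|protein_id``).  Both are held as plain
linked :class:`TreeNode` structures; Newick reading/writing is delegated to
dendropy.  :class:`SpeciesTree` wraps a tree with postorder indexing, parent
and depth arrays, and LCA queries, which is the coordinate system used by
reconciliation and Dollo mapping.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

__all__ = [
    "TreeNode",
    "SpeciesTree",
    "parse_newick",
    "to_newick",
    "split_gene_label",
    "make_gene_label",
]

GENE_LABEL_SEP = "|"


class TreeNode:
    """A node of a rooted tree: label, branch length, children, parent."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length)
        for child in self.children:
            clone.add(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add(_from_dendropy(dchild))
    return node


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` tree (via dendropy)."""
    dtree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        suppress_leaf_node_taxa=True,  # duplicate labels validated by callers
    )
    return _from_dendropy(dtree.seed_node)


def _to_dendropy(root: TreeNode, lengths: bool) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: TreeNode, dnode: dendropy.Node) -> None:
        if node.is_leaf:
            dnode.taxon = taxa.new_taxon(node.label or "")
        else:
            dnode.label = node.label
        if lengths and node.length is not None:
            dnode.edge.length = node.length
        for child in node.children:
            dchild = dnode.new_child()
            build(child, dchild)

    build(root, dtree.seed_node)
    return dtree


def to_newick(root: TreeNode, lengths: bool = True) -> str:
    """Serialize a tree as a one-line Newick string with internal labels."""
    dtree = _to_dendropy(root, lengths)
    out = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
        unquoted_underscores=True,
    )
    return out.strip()


def split_gene_label(label: str) -> tuple[str, str]:
    """Split a gene-tree leaf label ``species|protein_id`` -> (species, protein)."""
    species, sep, protein = label.partition(GENE_LABEL_SEP)
    if not sep or not species or not protein:
        raise ValueError(
            f"gene leaf label {label!r} is not of the form 'species|protein_id'"
        )
    return species, protein


def make_gene_label(species: str, protein_id: str) -> str:
    return f"{species}{GENE_LABEL_SEP}{protein_id}"


class SpeciesTree:
    """A rooted binary species tree with postorder indexing and LCA queries.

    Nodes are referred to by their postorder index everywhere downstream
    (event tallies, Dollo histories).  Leaf labels must be unique; unnamed
    internal nodes are assigned stable labels ``N1..N{n-1}`` in postorder.
    Branches are identified by their *child* node: "the branch to X" is the
    species-tree edge whose lower endpoint is X.  The root, having no parent
    edge, identifies the pre-root branch for orthogroup gains mapped at the
    root.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: list[TreeNode] = list(root.postorder())
        n_leaves = sum(1 for n in self.nodes if n.is_leaf)
        if n_leaves < 2:
            raise ValueError("species tree must have at least 2 leaves")
        for node in self.nodes:
            if node.children and len(node.children) != 2:
                raise ValueError(
                    "species tree must be binary; node "
                    f"{node.label!r} has {len(node.children)} children"
                )
        # stable labels for unnamed internal nodes
        counter = 1
        seen: set[str] = set()
        for node in self.nodes:
            if not node.is_leaf and not node.label:
                while f"N{counter}" in seen:
                    counter += 1
                node.label = f"N{counter}"
                counter += 1
            if node.label in seen:
                raise ValueError(f"duplicate node label {node.label!r}")
            seen.add(node.label)

        self._index_of = {id(n): i for i, n in enumerate(self.nodes)}
        self.label_to_index = {n.label: i for i, n in enumerate(self.nodes)}
        self.root_index = self._index_of[id(root)]
        self.parent = [-1] * len(self.nodes)
        for i, node in enumerate(self.nodes):
            for child in node.children:
                self.parent[self._index_of[id(child)]] = i
        self.depth = [0] * len(self.nodes)
        for node in root.preorder():
            i = self._index_of[id(node)]
            if self.parent[i] >= 0:
                self.depth[i] = self.depth[self.parent[i]] + 1
        self.leaf_indices = [i for i, n in enumerate(self.nodes) if n.is_leaf]
        self.leaf_labels = [self.nodes[i].label for i in self.leaf_indices]
        # species present under each node
        self.leafset_under: list[frozenset[str]] = [frozenset()] * len(self.nodes)
        for i, node in enumerate(self.nodes):  # postorder: children first
            if node.is_leaf:
                self.leafset_under[i] = frozenset([node.label])
            else:
                acc: frozenset[str] = frozenset()
                for child in node.children:
                    acc |= self.leafset_under[self._index_of[id(child)]]
                self.leafset_under[i] = acc

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        return cls(parse_newick(newick))

    def to_newick(self, lengths: bool = True) -> str:
        return to_newick(self.root, lengths=lengths)

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def index(self, label: str) -> int:
        try:
            return self.label_to_index[label]
        except KeyError:
            raise KeyError(f"species {label!r} not found in species tree") from None

    def label(self, index: int) -> str:
        return self.nodes[index].label

    def children_of(self, index: int) -> list[int]:
        return [self._index_of[id(c)] for c in self.nodes[index].children]

    def lca(self, i: int, j: int) -> int:
        """Lowest common ancestor of two node indices (walk-up; trees are small)."""
        while i != j:
            if self.depth[i] < self.depth[j]:
                j = self.parent[j]
            elif self.depth[j] < self.depth[i]:
                i = self.parent[i]
            else:
                i = self.parent[i]
                j = self.parent[j]
        return i

    def lca_many(self, indices) -> int:
        it = iter(indices)
        try:
            acc = next(it)
        except StopIteration:
            raise ValueError("lca_many of empty set") from None
        for i in it:
            acc = self.lca(acc, i)
        return acc

    def is_ancestor_or_equal(self, anc: int, desc: int) -> bool:
        while self.depth[desc] > self.depth[anc]:
            desc = self.parent[desc]
        return desc == anc

    def edges_on_path(self, anc: int, desc: int) -> int:
        """Number of species-tree edges from ``anc`` down to ``desc``."""
        if not self.is_ancestor_or_equal(anc, desc):
            raise ValueError(
                f"{self.label(anc)} is not ancestral to {self.label(desc)}"
            )
        return self.depth[desc] - self.depth[anc]

    def edges(self) -> list[tuple[int, int]]:
        """All (parent_index, child_index) edges, in child-postorder order."""
        return [
            (self.parent[i], i) for i in range(len(self.nodes)) if self.parent[i] >= 0
        ]
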