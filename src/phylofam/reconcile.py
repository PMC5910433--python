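"""Gene-tree / species-tree reconciliation by LCA mapping.

Each gene-tree node is mapped to the lowest species-tree node containing
all species under it (the most-parsimonious reconciliation map).  An
internal node is a *duplication* when its mapping coincides with that of at
least one child; otherwise it is a speciation.  Losses are counted per
gene-tree edge from the number of species-tree edges skipped between the
parent's and the child's mapping: for the edge from ``v`` to child ``c``
with ``k`` species-tree edges between ``M(v)`` and ``M(c)``, the edge
implies ``k - 1`` losses when ``v`` is a speciation and ``k`` when it is a
duplication.  Losses above the gene-tree root are not counted (nothing is
known about pre-root history).

For unrooted gene trees, :func:`root_by_dl` evaluates every rooting and
keeps the one minimizing duplications + losses (the usual duplication/loss
cost with unit costs), with a deterministic postorder tie-break.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .trees import SpeciesTree, TreeNode, split_gene_label

__all__ = ["Reconciliation", "lca_map", "reconcile", "root_by_dl", "enumerate_rootings"]

DUPLICATION = "duplication"
SPECIATION = "speciation"


@dataclass
class Reconciliation:
    """A reconciled gene tree: mapping, event labels, per-edge losses."""

    gene_root: TreeNode
    stree: SpeciesTree
    mapping: dict[int, int]  # id(gene node) -> species node index
    events: dict[int, str]  # id(internal gene node) -> 'duplication'|'speciation'
    losses: dict[int, int] = field(default_factory=dict)  # id(node) -> losses on edge above it
    n_duplications: int = 0
    n_losses: int = 0

    def species_of(self, node: TreeNode) -> int:
        return self.mapping[id(node)]

    def event_of(self, node: TreeNode) -> str:
        return self.events[id(node)]

    def is_duplication(self, node: TreeNode) -> bool:
        return self.events.get(id(node)) == DUPLICATION

    @property
    def cost(self) -> int:
        """Unit-cost duplication/loss score of this (rooted) reconciliation."""
        return self.n_duplications + self.n_losses

    def duplication_branches(self) -> Counter:
        """Species-node index -> number of duplication nodes mapped there."""
        return Counter(
            self.mapping[id(n)]
            for n in self.gene_root.postorder()
            if self.events.get(id(n)) == DUPLICATION
        )

    def to_frame(self, gene_tree_id: str = "gt0"):
        import pandas as pd

        rows = []
        for i, node in enumerate(self.gene_root.postorder()):
            rows.append(
                (
                    gene_tree_id,
                    i,
                    node.label if node.is_leaf else "",
                    self.events.get(id(node), "leaf"),
                    self.stree.label(self.mapping[id(node)]),
                    self.losses.get(id(node), 0),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_tree_id", "node_id", "leaf", "event",
                "species_node", "losses_on_parent_edge",
            ],
        )


def _check_gene_tree(gtree: TreeNode) -> None:
    for node in gtree.postorder():
        if node.children and len(node.children) != 2:
            raise ValueError(
                f"gene tree must be binary (node with {len(node.children)} children)"
            )


def lca_map(gtree: TreeNode, stree: SpeciesTree) -> dict[int, int]:
    """Map every gene-tree node to its species-tree LCA (keyed by id(node))."""
    _check_gene_tree(gtree)
    mapping: dict[int, int] = {}
    for node in gtree.postorder():
        if node.is_leaf:
            species, _ = split_gene_label(node.label)
            try:
                mapping[id(node)] = stree.index(species)
            except KeyError:
                raise KeyError(
                    f"gene-tree leaf {node.label!r}: species {species!r} "
                    "not in the species tree"
                ) from None
        else:
            l, r = node.children
            mapping[id(node)] = stree.lca(mapping[id(l)], mapping[id(r)])
    return mapping


def reconcile(gtree: TreeNode, stree: SpeciesTree) -> Reconciliation:
    """Reconcile a rooted binary gene tree with the rooted species tree."""
    mapping = lca_map(gtree, stree)
    events: dict[int, str] = {}
    losses: dict[int, int] = {}
    n_dup = 0
    n_loss = 0
    for node in gtree.postorder():
        if node.is_leaf:
            continue
        mv = mapping[id(node)]
        is_dup = any(mapping[id(c)] == mv for c in node.children)
        events[id(node)] = DUPLICATION if is_dup else SPECIATION
        if is_dup:
            n_dup += 1
        for c in node.children:
            k = stree.edges_on_path(mv, mapping[id(c)])
            edge_losses = k if is_dup else k - 1
            losses[id(c)] = edge_losses
            n_loss += edge_losses
    return Reconciliation(
        gene_root=gtree,
        stree=stree,
        mapping=mapping,
        events=events,
        losses=losses,
        n_duplications=n_dup,
        n_losses=n_loss,
    )


# ---------------------------------------------------------------------------
# DL-optimal rooting
# ---------------------------------------------------------------------------

def _unrooted_adjacency(gtree: TreeNode):
    """Adjacency of the unrooted topology; a degree-2 root is suppressed.

    Returns (adjacency dict keyed by id, node lookup, edge list).  Edges are
    listed in postorder of the input tree (the deterministic tie-break
    order) as unordered id pairs.
    """
    nodes = {id(n): n for n in gtree.postorder()}
    adj: dict[int, list[int]] = {id(n): [] for n in gtree.postorder()}
    for n in gtree.postorder():
        for c in n.children:
            adj[id(n)].append(id(c))
            adj[id(c)].append(id(n))
    if len(gtree.children) == 2:  # suppress the rooted-input root
        a, b = (id(c) for c in gtree.children)
        for x, y in ((a, b), (b, a)):
            adj[x].remove(id(gtree))
            adj[x].append(y)
        del adj[id(gtree)]
        del nodes[id(gtree)]
    edges: list[tuple[int, int]] = []
    seen: set[frozenset] = set()
    for n in gtree.postorder():
        if id(n) not in adj:
            continue
        for m in adj[id(n)]:
            key = frozenset((id(n), m))
            if key not in seen:
                seen.add(key)
                edges.append((id(n), m))
    return adj, nodes, edges


def _orient(adj, nodes, at: int, away_from: int) -> TreeNode:
    node = nodes[at]
    out = TreeNode(label=node.label if node.is_leaf else None)
    for nb in adj[at]:
        if nb != away_from:
            out.add(_orient(adj, nodes, nb, at))
    return out


def enumerate_rootings(gtree: TreeNode):
    """Yield one rooted binary tree per edge of the unrooted topology.

    The input may be rooted (degree-2 root, which is suppressed) or carry a
    basal trifurcation (the usual unrooted representation).  Rootings are
    yielded in a deterministic postorder edge order.
    """
    adj, nodes, edges = _unrooted_adjacency(gtree)
    if len(nodes) == 1:
        yield gtree.copy()
        return
    for a, b in edges:
        root = TreeNode()
        root.add(_orient(adj, nodes, a, b))
        root.add(_orient(adj, nodes, b, a))
        yield root


def root_by_dl(gtree: TreeNode, stree: SpeciesTree) -> TreeNode:
    """Root an (un)rooted gene tree at the edge minimizing duplications + losses.

    Every rooting (one per edge of the unrooted topology) is reconciled and
    the first rooting attaining the minimal cost in the deterministic edge
    order is returned.  Branch lengths are not preserved (topology only).
    """
    n_leaves = sum(1 for n in gtree.postorder() if n.is_leaf)
    if n_leaves < 3:
        return gtree.copy()
    best: TreeNode | None = None
    best_cost = None
    for rooted in enumerate_rootings(gtree):
        cost = reconcile(rooted, stree).cost
        if best_cost is None or cost < best_cost:
            best, best_cost = rooted, cost
    assert best is not None
    return best
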