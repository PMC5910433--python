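"""Ortholog coding, Dollo parsimony, and per-branch event tallies.

A reconciled gene tree decomposes into *orthogroups* by cutting at
duplication nodes: two leaves share an orthogroup exactly when the path
between them contains no duplication node.  Each orthogroup's origin is the
species mapping of the topmost gene-tree node of its component (so a
lineage surviving in one clade but originating deeper generates Dollo
losses elsewhere); an ``origin_mode='lca'`` switch restricts the origin to
the LCA of the represented species instead.

Dollo parsimony then places a single gain at the origin and the minimal set
of losses explaining the presence pattern: a species-tree node is present
iff it descends from (or is) the gain node and its subtree retains at least
one represented species; losses sit on the present->absent edges.  Gains,
duplication nodes, and Dollo losses are tallied per species-tree branch and
the ancestral gene content (number of orthogroups present) is read off each
internal node — the quantities comparative studies draw on the organismal
phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reconcile import Reconciliation
from .trees import SpeciesTree, TreeNode, split_gene_label

__all__ = [
    "Orthogroup",
    "DolloHistory",
    "EventHistory",
    "extract_orthogroups",
    "dollo_reconstruct",
    "tally_branch_events",
    "cluster_presence_summary",
]


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    family_id: str
    members: tuple[str, ...]  # gene leaf labels species|protein
    species: frozenset[str]
    origin: int  # species-tree node index

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DolloHistory:
    og_id: str
    gain: int  # species-tree node index
    present: np.ndarray  # bool per species-tree node index
    loss_edges: tuple[int, ...]  # child node index of each lost edge

    @property
    def n_losses(self) -> int:
        return len(self.loss_edges)


def extract_orthogroups(
    recon: Reconciliation,
    family_id: str = "fam0",
    origin_mode: str = "reconciled",
) -> list[Orthogroup]:
    """Cut a reconciled gene tree at duplication nodes into orthogroups.

    Deleting every duplication node (with its incident edges) leaves
    components; each component containing leaves is one orthogroup.  With
    ``origin_mode='reconciled'`` the origin is the species mapping of the
    component's topmost (shallowest) node; with ``'lca'`` it is the species
    LCA of the members.
    """
    if origin_mode not in ("reconciled", "lca"):
        raise ValueError("origin_mode must be 'reconciled' or 'lca'")
    stree = recon.stree
    root = recon.gene_root

    # union-find over non-duplication adjacency
    parent_uf: dict[int, int] = {}

    def find(x: int) -> int:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent_uf[rx] = ry

    nodes = list(root.postorder())
    for n in nodes:
        parent_uf[id(n)] = id(n)
    for n in nodes:
        if recon.is_duplication(n):
            continue
        for c in n.children:
            if not recon.is_duplication(c):
                union(id(n), id(c))

    # gather components in a deterministic order (preorder depth)
    depth: dict[int, int] = {id(root): 0}
    for n in root.preorder():
        for c in n.children:
            depth[id(c)] = depth[id(n)] + 1
    comp_nodes: dict[int, list[TreeNode]] = {}
    for n in root.preorder():  # preorder => first node of a component is topmost
        comp_nodes.setdefault(find(id(n)), []).append(n)

    out: list[Orthogroup] = []
    k = 0
    for comp in comp_nodes.values():
        leaves = [n for n in comp if n.is_leaf]
        if not leaves:
            continue  # a bare duplication node between components
        topmost = min(comp, key=lambda n: depth[id(n)])
        members = tuple(sorted(n.label for n in leaves))
        species = frozenset(split_gene_label(m)[0] for m in members)
        if origin_mode == "reconciled":
            origin = recon.species_of(topmost)
        else:
            origin = stree.lca_many(stree.index(sp) for sp in species)
        out.append(
            Orthogroup(
                og_id=f"{family_id}.og{k}",
                family_id=family_id,
                members=members,
                species=species,
                origin=origin,
            )
        )
        k += 1
    return out


def dollo_reconstruct(og: Orthogroup, stree: SpeciesTree) -> DolloHistory:
    """Single-gain / minimal-loss history of one orthogroup on the species tree."""
    present_leaves = {stree.index(sp) for sp in og.species}
    for leaf in present_leaves:
        if not stree.is_ancestor_or_equal(og.origin, leaf):
            raise ValueError(
                f"orthogroup {og.og_id}: origin {stree.label(og.origin)} is not "
                f"ancestral to represented species {stree.label(leaf)}"
            )
    present = np.zeros(len(stree), dtype=bool)
    # postorder: a node is present iff under-or-at the gain and its subtree
    # retains at least one represented species
    retains = np.zeros(len(stree), dtype=bool)
    for i, node in enumerate(stree.nodes):
        if node.is_leaf:
            retains[i] = i in present_leaves
        else:
            retains[i] = any(retains[c] for c in stree.children_of(i))
    for i in range(len(stree)):
        present[i] = retains[i] and stree.is_ancestor_or_equal(og.origin, i)
    loss_edges = tuple(
        child
        for parent, child in stree.edges()
        if present[parent] and not present[child]
    )
    return DolloHistory(
        og_id=og.og_id, gain=og.origin, present=present, loss_edges=loss_edges
    )


@dataclass
class EventHistory:
    """Per-branch gains/duplications/losses and per-node ancestral content.

    Branches are identified by their child species-tree node; the root row
    holds orthogroup gains at the root.  ``ancestral`` is the number of
    orthogroups present at each node — the reconstructed gene content of
    internal nodes and the observed orthogroup richness of the leaves.
    """

    stree: SpeciesTree
    gains: np.ndarray
    duplications: np.ndarray
    losses: np.ndarray
    ancestral: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": [self.stree.label(i) for i in range(len(self.stree))],
                "is_leaf": [n.is_leaf for n in self.stree.nodes],
                "gains": self.gains,
                "duplications": self.duplications,
                "losses": self.losses,
                "ancestral_orthogroups": self.ancestral,
            }
        )

    def species_specific_duplications(self) -> dict[str, int]:
        return {
            self.stree.label(i): int(self.duplications[i])
            for i in self.stree.leaf_indices
        }

    def check_leaf_identity(self) -> None:
        """Dollo bookkeeping: path gains - path losses = leaf orthogroup count."""
        for leaf in self.stree.leaf_indices:
            gains = losses = 0
            i = leaf
            while i >= 0:
                gains += int(self.gains[i])
                if i != self.stree.root_index:
                    losses += int(self.losses[i])
                i = self.stree.parent[i]
            if gains - losses != int(self.ancestral[leaf]):
                raise AssertionError(
                    f"Dollo identity violated at {self.stree.label(leaf)}: "
                    f"{gains} gains - {losses} losses != {self.ancestral[leaf]}"
                )


def tally_branch_events(
    histories: Sequence[tuple[Orthogroup, DolloHistory]],
    recons: Iterable[Reconciliation],
    stree: SpeciesTree,
) -> EventHistory:
    """Aggregate orthogroup gains, duplication nodes, and Dollo losses per branch."""
    n = len(stree)
    gains = np.zeros(n, dtype=int)
    losses = np.zeros(n, dtype=int)
    dups = np.zeros(n, dtype=int)
    ancestral = np.zeros(n, dtype=int)
    for og, hist in histories:
        gains[hist.gain] += 1
        for child in hist.loss_edges:
            losses[child] += 1
        ancestral += hist.present.astype(int)
    for rec in recons:
        for snode, count in rec.duplication_branches().items():
            dups[snode] += count
    out = EventHistory(
        stree=stree, gains=gains, duplications=dups, losses=losses, ancestral=ancestral
    )
    out.check_leaf_identity()
    return out


def cluster_presence_summary(clusters, focal_species: Iterable[str]) -> dict:
    """Classify clusters by species composition relative to a focal set.

    Classes: ``absent_from_focal`` (no focal species), ``specific_to_focal``
    (all members from a single focal species; reported per species),
    ``shared_only_by_focal`` (members from >=2 focal species and nothing
    else), and ``mixed`` (focal and non-focal members together).  The class
    counts partition the cluster set.
    """
    focal = set(focal_species)
    counts = {
        "total": len(clusters.clusters),
        "absent_from_focal": 0,
        "specific_to_focal": {sp: 0 for sp in sorted(focal)},
        "shared_only_by_focal": 0,
        "mixed": 0,
    }
    for cid in clusters.clusters:
        sp = clusters.species_of_cluster(cid)
        inter = sp & focal
        if not inter:
            counts["absent_from_focal"] += 1
        elif sp <= focal:
            if len(sp) == 1:
                counts["specific_to_focal"][next(iter(sp))] += 1
            else:
                counts["shared_only_by_focal"] += 1
        else:
            counts["mixed"] += 1
    return counts
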