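"""End-to-end orchestration: gene trees -> reconciliation -> orthogroups ->
Dollo histories -> per-branch event tallies.

Families too small for meaningful tree inference are handled without one:
a single protein is one orthogroup originating at its species; two or
three proteins get a trivial topology (the single cherry, or the
duplication/loss-optimal rooted triplet).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

from .orthogroups import (
    DolloHistory,
    EventHistory,
    Orthogroup,
    dollo_reconstruct,
    extract_orthogroups,
    tally_branch_events,
)
from .reconcile import Reconciliation, reconcile, root_by_dl
from .trees import SpeciesTree, TreeNode, split_gene_label

__all__ = ["FamilyAnalysis", "trivial_gene_tree", "analyze_families"]


@dataclass
class FamilyAnalysis:
    """The pipeline products for a collection of families on one species tree."""

    stree: SpeciesTree
    reconciliations: dict[str, Reconciliation]
    orthogroups: list[Orthogroup]
    histories: list[tuple[Orthogroup, DolloHistory]]
    events: EventHistory

    @property
    def n_duplications(self) -> int:
        return sum(r.n_duplications for r in self.reconciliations.values())

    @property
    def n_dollo_losses(self) -> int:
        return sum(h.n_losses for _, h in self.histories)


def trivial_gene_tree(
    leaf_labels: Sequence[str], stree: SpeciesTree
) -> Optional[TreeNode]:
    """Build a tree for a 2- or 3-protein family (None for a single protein).

    Two proteins form the single cherry; for three proteins all three rooted
    triplet topologies are reconciled and the duplication/loss-cheapest one
    is kept (ties broken by enumeration order over sorted labels).
    """
    labels = sorted(leaf_labels)
    if len(labels) == 1:
        return None
    if len(labels) == 2:
        root = TreeNode()
        for lab in labels:
            root.add(TreeNode(lab))
        return root
    if len(labels) != 3:
        raise ValueError("trivial_gene_tree handles at most 3 proteins")
    best, best_cost = None, None
    for pair in combinations(range(3), 2):
        cherry = TreeNode()
        outgroup = next(i for i in range(3) if i not in pair)
        for i in pair:
            cherry.add(TreeNode(labels[i]))
        root = TreeNode()
        root.add(cherry)
        root.add(TreeNode(labels[outgroup]))
        cost = reconcile(root, stree).cost
        if best_cost is None or cost < best_cost:
            best, best_cost = root, cost
    return best


def analyze_families(
    gene_trees: Mapping[str, Optional[TreeNode]],
    stree: SpeciesTree,
    origin_mode: str = "reconciled",
    root_mode: str = "given",
    singletons: Mapping[str, str] | None = None,
) -> FamilyAnalysis:
    """Run reconciliation, ortholog coding, and Dollo mapping over families.

    ``gene_trees`` maps family id -> rooted gene tree; ``root_mode='dl'``
    re-roots each tree at its duplication/loss-optimal edge first.
    ``singletons`` maps family id -> the single member's leaf label for
    families without a tree; each becomes one orthogroup originating at its
    species.
    """
    if root_mode not in ("given", "dl"):
        raise ValueError("root_mode must be 'given' or 'dl'")
    recons: dict[str, Reconciliation] = {}
    orthogroups: list[Orthogroup] = []
    for fam_id in sorted(gene_trees):
        tree = gene_trees[fam_id]
        if tree is None:
            continue
        if root_mode == "dl":
            tree = root_by_dl(tree, stree)
        rec = reconcile(tree, stree)
        recons[fam_id] = rec
        orthogroups.extend(
            extract_orthogroups(rec, family_id=fam_id, origin_mode=origin_mode)
        )
    if singletons:
        for fam_id in sorted(singletons):
            label = singletons[fam_id]
            species, _ = split_gene_label(label)
            orthogroups.append(
                Orthogroup(
                    og_id=f"{fam_id}.og0",
                    family_id=fam_id,
                    members=(label,),
                    species=frozenset([species]),
                    origin=stree.index(species),
                )
            )
    histories = [(og, dollo_reconstruct(og, stree)) for og in orthogroups]
    events = tally_branch_events(histories, recons.values(), stree)
    return FamilyAnalysis(
        stree=stree,
        reconciliations=recons,
        orthogroups=orthogroups,
        histories=histories,
        events=events,
    )
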