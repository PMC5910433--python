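"""Synthetic data with known truth for exercising the whole pipeline.

The generators emulate the inputs a comparative gene-family study starts
from, at desk scale and with every event recorded:

* a rooted, ultrametric species tree from a pure-birth (Yule) process;
* per-family gene duplication/loss histories simulated as independent
  continuous-time birth-death processes along each species-tree branch,
  with the genealogy of the surviving copies returned as the gene tree and
  every event (including those on lineages that later went extinct) kept in
  a :class:`SimTruth` record;
* an all-vs-all protein hit table in which within-family scores dominate
  between-family noise, mimicking a BLAST tabular report;
* protein annotation tables with a term deliberately over-represented in a
  chosen set of clusters, plus signal-peptide flags and lengths, for the
  enrichment and secreted-protein statistics.

All generators are pure functions of their seeds (numpy PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import SpeciesTree, TreeNode, make_gene_label

__all__ = [
    "SimEvent",
    "SimTruth",
    "SimulatedFamily",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_families",
    "synthesize_hit_table",
    "synthesize_annotations",
    "HIT_COLUMNS",
]

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


@dataclass(frozen=True)
class SimEvent:
    """A single true event: kind ('duplication'|'loss'), species branch, time.

    ``branch`` is the label of the species-tree node the branch leads into;
    ``time`` is measured from the top of that branch.
    """

    kind: str
    branch: str
    time: float


@dataclass
class SimTruth:
    """Ground truth for one simulated family."""

    events: list[SimEvent]
    copy_number: dict[str, int]
    extinct: bool

    def per_branch(self, kind: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ev in self.events:
            if ev.kind == kind:
                counts[ev.branch] = counts.get(ev.branch, 0) + 1
        return counts

    @property
    def n_duplications(self) -> int:
        return sum(1 for e in self.events if e.kind == "duplication")

    @property
    def n_losses(self) -> int:
        return sum(1 for e in self.events if e.kind == "loss")


@dataclass
class SimulatedFamily:
    family_id: str
    tree: Optional[TreeNode]  # None iff extinct
    truth: SimTruth
    proteins: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_proteins(self) -> int:
        return sum(len(v) for v in self.proteins.values())

    def protein_ids(self) -> list[str]:
        out: list[str] = []
        for sp in sorted(self.proteins):
            out.extend(self.proteins[sp])
        return out


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, seed: int = 0
) -> SpeciesTree:
    """Simulate an ultrametric rooted binary tree under a pure-birth process.

    Starting from two lineages at the root, waiting times are exponential
    with rate ``k * birth_rate`` for ``k`` extant lineages and a uniformly
    chosen lineage splits at each event; after the (n-1)-th split the tree is
    extended by one more exponential waiting time so terminal branches have
    positive length.  Leaves are named ``S1..Sn`` in left-to-right order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []  # (leaf node, birth time)
    for _ in range(2):
        active.append((root.add(TreeNode()), 0.0))
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (len(active) * birth_rate))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = t - born
        active.append((node.add(TreeNode()), t))
        active.append((node.add(TreeNode()), t))
    t += rng.exponential(1.0 / (n_species * birth_rate))
    for node, born in active:
        node.length = t - born

    k = 1
    for leaf in root.preorder():
        if leaf.is_leaf:
            leaf.label = f"S{k}"
            k += 1
    return SpeciesTree(root)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

class _GNode:
    """Node of the full (unpruned) lineage tree produced by the simulation."""

    __slots__ = ("kind", "snode", "time", "children")

    def __init__(self, kind: str, snode: int, time: float):
        self.kind = kind  # 'dup' | 'spec' | 'tip' | 'lost'
        self.snode = snode
        self.time = time  # absolute time from the species root
        self.children: list["_GNode"] = []


def simulate_gene_family(
    stree: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    root_copies: int = 1,
    seed: int = 0,
    family_id: str = "fam0",
) -> SimulatedFamily:
    """Simulate one gene family along the species tree.

    Each gene lineage evolves independently along each species branch,
    duplicating at ``dup_rate`` and dying at ``loss_rate`` (exponential
    waiting times); lineages surviving to an internal species node enter
    both child branches.  The returned gene tree is the genealogy of the
    surviving leaves (extinct lineages pruned, unary nodes suppressed);
    ``SimTruth.events`` records *every* event, also those on lineages whose
    descendants all died.  A fully extinct family is flagged and has no tree.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if root_copies < 1:
        raise ValueError("root_copies must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[SimEvent] = []
    total = dup_rate + loss_rate

    # absolute time at the top of the branch into each node
    node_start = [0.0] * len(stree)
    node_end = [0.0] * len(stree)
    for node in stree.root.preorder():
        i = stree.label_to_index[node.label]
        p = stree.parent[i]
        if p < 0:
            node_start[i] = node_end[i] = 0.0
        else:
            node_start[i] = node_end[i] = node_end[p]
            if node.length is not None:
                node_end[i] = node_start[i] + node.length

    def speciate(snode: int, time: float) -> _GNode:
        node = _GNode("spec" if stree.children_of(snode) else "tip", snode, time)
        for child in stree.children_of(snode):
            node.children.append(evolve(child, node_start[child]))
        return node

    def evolve(snode: int, t: float) -> _GNode:
        """One lineage entering the branch into ``snode`` at absolute time t."""
        while True:
            if total > 0:
                dt = rng.exponential(1.0 / total)
            else:
                dt = np.inf
            if t + dt >= node_end[snode]:
                return speciate(snode, node_end[snode])
            t += dt
            if total > 0 and rng.random() < dup_rate / total:
                events.append(
                    SimEvent("duplication", stree.label(snode), t - node_start[snode])
                )
                node = _GNode("dup", snode, t)
                node.children.append(evolve(snode, t))
                node.children.append(evolve(snode, t))
                return node
            events.append(
                SimEvent("loss", stree.label(snode), t - node_start[snode])
            )
            return _GNode("lost", snode, t)

    roots = [speciate(stree.root_index, 0.0) for _ in range(root_copies)]

    # prune extinct lineages, suppress unary nodes
    def prune(g: _GNode) -> Optional[_GNode]:
        if g.kind == "lost":
            return None
        if g.kind == "tip":
            return g
        kept = [c for c in (prune(c) for c in g.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        g.children = kept
        return g

    surviving = [g for g in (prune(r) for r in roots) if g is not None]

    copy_number = {sp: 0 for sp in stree.leaf_labels}
    proteins: dict[str, list[str]] = {sp: [] for sp in stree.leaf_labels}

    if not surviving:
        truth = SimTruth(events=events, copy_number=copy_number, extinct=True)
        return SimulatedFamily(family_id, None, truth, proteins)

    # join multiple surviving root lineages under root duplication nodes
    g = surviving[0]
    for other in surviving[1:]:
        joined = _GNode("dup", stree.root_index, 0.0)
        joined.children = [g, other]
        g = joined

    counter = 0

    def to_tree(node: _GNode, parent_time: float) -> TreeNode:
        nonlocal counter
        if node.kind == "tip":
            sp = stree.label(node.snode)
            pid = f"{family_id}.{counter}"
            counter += 1
            copy_number[sp] += 1
            proteins[sp].append(pid)
            return TreeNode(make_gene_label(sp, pid), length=node.time - parent_time)
        t = TreeNode(length=node.time - parent_time)
        for child in node.children:
            t.add(to_tree(child, node.time))
        return t

    tree = to_tree(g, 0.0)
    tree.length = None
    truth = SimTruth(events=events, copy_number=copy_number, extinct=False)
    return SimulatedFamily(family_id, tree, truth, proteins)


def simulate_families(
    stree: SpeciesTree,
    n_families: int,
    dup_rate: float,
    loss_rate: float,
    root_copies: int = 1,
    seed: int = 0,
) -> list[SimulatedFamily]:
    """Simulate ``n_families`` independent families with per-family substreams."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_families)
    return [
        simulate_gene_family(
            stree,
            dup_rate,
            loss_rate,
            root_copies=root_copies,
            seed=int(child_seeds[i]),
            family_id=f"fam{i}",
        )
        for i in range(n_families)
    ]


def planted_families(
    n_families: int = 10,
    n_proteins: int = 200,
    n_species: int = 10,
    prefix: str = "fam",
) -> list[SimulatedFamily]:
    """Families of known membership for planted-partition clustering tests.

    Proteins are dealt round-robin across families and species; no
    evolutionary history is attached (the truth here is the partition
    itself, not an event list).
    """
    if n_proteins < n_families:
        raise ValueError("need at least one protein per family")
    species = [f"S{i + 1}" for i in range(n_species)]
    out = []
    for fi in range(n_families):
        size = n_proteins // n_families + (1 if fi < n_proteins % n_families else 0)
        proteins: dict[str, list[str]] = {sp: [] for sp in species}
        for j in range(size):
            sp = species[(fi + j) % n_species]
            proteins[sp].append(f"{prefix}{fi}.{j}")
        copy_number = {sp: len(v) for sp, v in proteins.items()}
        truth = SimTruth(events=[], copy_number=copy_number, extinct=False)
        out.append(SimulatedFamily(f"{prefix}{fi}", None, truth, proteins))
    return out


# ---------------------------------------------------------------------------
# hit table
# ---------------------------------------------------------------------------

def _evalue_from_bitscore(bitscore: np.ndarray | float) -> np.ndarray | float:
    # deterministic monotone transform; only ordering and cutoff behavior matter
    return 1e3 * np.power(2.0, -np.asarray(bitscore, dtype=float) / 4.0)


def synthesize_hit_table(
    families: Sequence[SimulatedFamily],
    within_score: tuple[float, float] = (500.0, 50.0),
    noise_prob: float = 0.0,
    noise_score: tuple[float, float] = (40.0, 8.0),
    length_range: tuple[int, int] = (150, 600),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build a synthetic all-vs-all hit table (BLAST tabular + qlen/slen).

    Every ordered within-family pair (including self-hits) receives a
    high-bitscore, near-full-coverage hit; each ordered between-family pair
    receives a low-score, partial-coverage hit with probability
    ``noise_prob``.  E-values are a fixed monotone decreasing transform of
    the bitscore.  Returns the hit table and the drawn protein lengths.
    """
    if not 0 <= noise_prob < 1:
        raise ValueError("noise_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)

    label_of: dict[str, str] = {}  # protein id -> full species|protein label
    fam_of: dict[str, int] = {}
    all_proteins: list[str] = []
    for fi, fam in enumerate(families):
        for sp in sorted(fam.proteins):
            for pid in fam.proteins[sp]:
                label = make_gene_label(sp, pid)
                all_proteins.append(label)
                fam_of[label] = fi
                label_of[pid] = label
    lengths = {
        p: int(rng.integers(length_range[0], length_range[1] + 1))
        for p in all_proteins
    }

    rows: list[tuple] = []

    def emit(q: str, s: str, bitscore: float, cov: float, pident: float) -> None:
        bitscore = round(max(bitscore, 25.0), 1)
        qlen, slen = lengths[q], lengths[s]
        aln = max(1, int(round(cov * min(qlen, slen))))
        mism = int(round(aln * (1 - pident / 100.0)))
        rows.append(
            (
                q, s, round(pident, 1), aln, mism, 0,
                1, min(aln, qlen), 1, min(aln, slen),
                float(_evalue_from_bitscore(bitscore)), bitscore,
                qlen, slen,
            )
        )

    for fam in families:
        members = [label_of[p] for p in fam.protein_ids()]
        for q in members:
            for s in members:
                if q == s:
                    emit(q, s, rng.normal(*within_score) * 1.2, 1.0, 100.0)
                else:
                    emit(
                        q, s,
                        rng.normal(*within_score),
                        rng.uniform(0.9, 1.0),
                        rng.uniform(60.0, 99.0),
                    )
    if noise_prob > 0:
        for q in all_proteins:
            for s in all_proteins:
                if fam_of[q] != fam_of[s] and rng.random() < noise_prob:
                    emit(
                        q, s,
                        rng.normal(*noise_score),
                        rng.uniform(0.1, 0.4),
                        rng.uniform(20.0, 35.0),
                    )

    return pd.DataFrame(rows, columns=HIT_COLUMNS), lengths


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def synthesize_annotations(
    clusters,
    planted_term: str,
    target_clusters: Iterable,
    background_term_rate: float = 0.05,
    sp_rate: float = 0.3,
    length_range: tuple[int, int] = (80, 600),
    n_decoy_terms: int = 20,
    decoy_rate: float = 0.1,
    seed: int = 0,
):
    """Annotation table with ``planted_term`` planted in ``target_clusters``.

    All proteins of a target cluster carry the planted term; every other
    protein carries it with probability ``background_term_rate``.  A pool of
    decoy terms is sprinkled uniformly so enrichment has a term universe to
    correct over.  Signal-peptide flags are Bernoulli(``sp_rate``) and
    lengths uniform on ``length_range``.
    """
    from .stats import AnnotationTable
    from .trees import split_gene_label

    rng = np.random.default_rng(seed)
    target = set(target_clusters)
    unknown = target - set(clusters.clusters)
    if unknown:
        raise ValueError(f"unknown cluster ids in target_clusters: {sorted(unknown)}")

    decoys = [f"D{i:03d}" for i in range(n_decoy_terms)]
    records = []
    for cid in sorted(clusters.clusters):
        for label in sorted(clusters.clusters[cid]):
            species, _ = split_gene_label(label)
            terms = set()
            if cid in target or rng.random() < background_term_rate:
                terms.add(planted_term)
            for d in decoys:
                if rng.random() < decoy_rate:
                    terms.add(d)
            records.append(
                {
                    "protein_id": label,
                    "species": species,
                    "length": int(rng.integers(length_range[0], length_range[1] + 1)),
                    "signal_peptide": bool(rng.random() < sp_rate),
                    "terms": frozenset(terms),
                }
            )
    df = pd.DataFrame.from_records(records).set_index("protein_id", drop=False)
    return AnnotationTable(df)
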