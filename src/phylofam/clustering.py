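"""Protein-family clustering from all-vs-all similarity hits.

The hit table is BLAST tabular output (the 12 standard columns) with query
and subject lengths appended, i.e. the equivalent of
``-outfmt "6 std qlen slen"``; sequence lengths are required because the
edge weight combines the bitscore with alignment coverage.  Hits are merged
into an undirected weighted graph and partitioned with the Markov Cluster
(MCL) algorithm at a configurable inflation (2.0 by default, the standard
granularity for protein families).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .simulate import HIT_COLUMNS
from .trees import split_gene_label

__all__ = [
    "ClusterSet",
    "MCLConvergenceWarning",
    "validate_hit_table",
    "read_hit_table",
    "edge_weight",
    "build_similarity_graph",
    "mcl_cluster",
]


class MCLConvergenceWarning(UserWarning):
    """Raised (as a warning) when MCL stops at max_iter without converging."""


@dataclass
class ClusterSet:
    """A partition of proteins into families.

    ``clusters`` maps cluster id (0..k-1) to the set of protein labels;
    ids are deterministic: clusters sorted by (size descending, smallest
    member label), then renumbered.
    """

    clusters: dict[int, frozenset[str]]
    inflation: float
    converged: bool = True
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_proteins(self) -> int:
        return sum(len(v) for v in self.clusters.values())

    def assignment(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cid, members in self.clusters.items():
            for m in members:
                out[m] = cid
        return out

    def species_of_cluster(self, cid: int) -> frozenset[str]:
        return frozenset(split_gene_label(m)[0] for m in self.clusters[cid])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.clusters):
            for label in sorted(self.clusters[cid]):
                sp, pid = split_gene_label(label)
                rows.append((cid, label, sp))
        return pd.DataFrame(rows, columns=["cluster_id", "protein_id", "species"])

    @classmethod
    def from_assignment(
        cls, assignment: dict[str, int], inflation: float = float("nan")
    ) -> "ClusterSet":
        groups: dict[int, set[str]] = {}
        for label, cid in assignment.items():
            groups.setdefault(cid, set()).add(label)
        ordered = sorted(
            groups.values(), key=lambda s: (-len(s), min(s))
        )
        return cls(
            clusters={i: frozenset(s) for i, s in enumerate(ordered)},
            inflation=inflation,
        )


# ---------------------------------------------------------------------------
# hit table
# ---------------------------------------------------------------------------

def validate_hit_table(hits: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    bad = hits.index[
        (hits.qstart > hits.qend)
        | (hits.sstart > hits.send)
        | (hits.bitscore <= 0)
        | (hits.evalue < 0)
        | (hits.qlen <= 0)
        | (hits.slen <= 0)
    ]
    if len(bad):
        raise ValueError(f"malformed hit rows at lines {list(bad[:5])}")
    return hits


def read_hit_table(path) -> pd.DataFrame:
    """Read a BLAST tabular TSV with qlen/slen appended (outfmt '6 std qlen slen')."""
    try:
        hits = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, header=None)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"cannot parse hit table {path}: {exc}") from exc
    return validate_hit_table(hits)


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def _directional_weight(bitscore, length, qlen, slen) -> float:
    if qlen <= 0 or slen <= 0:
        raise ValueError("qlen and slen must be positive")
    qcov = min(1.0, length / qlen)
    scov = min(1.0, length / slen)
    return bitscore * (qcov + scov) / 2.0


def edge_weight(hit_forward, hit_reverse=None) -> float:
    """Similarity weight for one unordered protein pair.

    Each direction contributes ``bitscore * (qcov + scov) / 2`` with
    coverages ``alignment_length/qlen`` and ``alignment_length/slen``
    clamped to [0, 1]; the weight is the mean over available directions.
    """
    w = _directional_weight(
        hit_forward["bitscore"], hit_forward["length"],
        hit_forward["qlen"], hit_forward["slen"],
    )
    if hit_reverse is None:
        return w
    w2 = _directional_weight(
        hit_reverse["bitscore"], hit_reverse["length"],
        hit_reverse["qlen"], hit_reverse["slen"],
    )
    return (w + w2) / 2.0


def build_similarity_graph(
    hits: pd.DataFrame,
    evalue_cutoff: float = 10.0,
    extra_proteins=None,
) -> nx.Graph:
    """Merge directed hits into an undirected weighted similarity graph.

    Hits above the E-value cutoff and self-hits are dropped.  When several
    HSPs exist for the same directed pair, the highest-bitscore one is used.
    ``extra_proteins`` registers proteins absent from the hit table (they
    become isolated nodes and, downstream, singleton clusters).
    """
    validate_hit_table(hits)
    graph = nx.Graph()
    for q in hits["query"]:
        graph.add_node(q)
    for s in hits["subject"]:
        graph.add_node(s)
    if extra_proteins is not None:
        for p in extra_proteins:
            graph.add_node(p)

    kept = hits[(hits.evalue <= evalue_cutoff) & (hits["query"] != hits.subject)]
    if len(kept) == 0:
        return graph
    # best HSP per directed pair
    best = (
        kept.sort_values("bitscore", ascending=False)
        .drop_duplicates(subset=["query", "subject"], keep="first")
    )
    directed: dict[tuple[str, str], pd.Series] = {
        (r["query"], r.subject): r for _, r in best.iterrows()
    }
    done: set[frozenset] = set()
    for (q, s), row in directed.items():
        key = frozenset((q, s))
        if key in done:
            continue
        done.add(key)
        rev = directed.get((s, q))
        graph.add_edge(q, s, weight=edge_weight(row, rev))
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune_threshold: float = 1e-8,
) -> ClusterSet:
    """Partition a similarity graph with the Markov Cluster algorithm.

    Self-loops are added with weight equal to the maximum incident edge
    weight (1 for isolated nodes), columns are normalized to a stochastic
    matrix, and expansion (matrix squaring) alternates with inflation
    (entrywise power, column renormalization) until the largest entry change
    falls below ``tol``.  Entries below ``prune_threshold`` are zeroed each
    round.  Clusters are the connected components of the non-zero structure
    of the attractor matrix; ids are deterministic (size-descending, then
    smallest member label).
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    n = len(nodes)
    if n == 0:
        return ClusterSet(clusters={}, inflation=inflation)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("edge weights must be nonnegative")
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    loop = M.max(axis=0)
    loop[loop <= 0] = 1.0
    np.fill_diagonal(M, loop)
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations",
            MCLConvergenceWarning,
        )

    structure = (M + M.T) > 0
    n_comp, labels = connected_components(structure, directed=False)
    groups: dict[int, set[str]] = {}
    for v, lab in zip(nodes, labels):
        groups.setdefault(int(lab), set()).add(v)
    ordered = sorted(groups.values(), key=lambda s: (-len(s), min(s)))
    return ClusterSet(
        clusters={i: frozenset(s) for i, s in enumerate(ordered)},
        inflation=inflation,
        converged=converged,
        params={
            "max_iter": max_iter,
            "tol": tol,
            "prune_threshold": prune_threshold,
        },
    )
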