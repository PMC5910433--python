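"""Downstream statistics: term enrichment, 2x2 exact tests, secreted-protein
filtering, presence percentages, and copy-number PCA.

Enrichment follows the classic over-representation scheme: for a term with
``K`` carriers among ``N`` population units and ``k`` among ``n`` sampled
units, the raw p-value is the hypergeometric upper tail P(X >= k), and
Bonferroni correction multiplies by the number of testable terms (those
with at least one population carrier).  Units may be proteins or clusters;
a cluster carries the union of its members' terms, counted once.

The small-secreted-protein (SSP) filter keeps proteins with a predicted
signal peptide and a whole-protein length of 80-300 aa inclusive — the
length window conventionally used to call candidate effectors in fungal
genomes.

Copy-number PCA centers each family column (optionally also scaling to
unit variance) and decomposes by SVD, with a deterministic sign convention
(the largest-magnitude loading of each component is positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "PcaResult",
    "hypergeom_enrichment",
    "cluster_terms",
    "fisher_exact_2x2",
    "ssp_filter",
    "presence_percent",
    "proteome_percent",
    "copy_number_pca",
]

SSP_MIN_LEN = 80
SSP_MAX_LEN = 300


class AnnotationTable:
    """Protein annotations: term set, signal-peptide flag, length, species.

    Backed by a DataFrame indexed by protein id with columns ``protein_id``,
    ``species``, ``length`` (aa, > 0), ``signal_peptide`` (bool) and
    ``terms`` (frozenset of identifiers).
    """

    COLUMNS = ["protein_id", "species", "length", "signal_peptide", "terms"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns: {missing}")
        if (df["length"] <= 0).any():
            raise ValueError("protein lengths must be positive")
        if df["protein_id"].duplicated().any():
            raise ValueError("duplicate protein ids in annotation table")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def proteins(self) -> list[str]:
        return list(self.df["protein_id"])

    def term_map(self) -> dict[str, frozenset]:
        return dict(zip(self.df["protein_id"], self.df["terms"]))

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype={"terms": str}, keep_default_na=False)
        df["signal_peptide"] = df["signal_peptide"].astype(str).str.lower().isin(
            ["1", "true", "yes"]
        )
        df["terms"] = [
            frozenset(t for t in str(ts).split(";") if t) for ts in df["terms"]
        ]
        df = df.set_index("protein_id", drop=False)
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["signal_peptide"] = out["signal_peptide"].astype(int)
        out["terms"] = [";".join(sorted(t)) for t in out["terms"]]
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # sample successes
    n: int  # sample size
    K: int  # population successes
    N: int  # population size
    p_raw: float
    p_bonferroni: float
    m: int  # number of terms tested


def cluster_terms(
    clusters, annotations: AnnotationTable
) -> dict[int, frozenset]:
    """Term set of each cluster: the union of its members' terms."""
    term_map = annotations.term_map()
    out: dict[int, frozenset] = {}
    for cid, members in clusters.clusters.items():
        acc: set = set()
        for m in members:
            acc |= term_map.get(m, frozenset())
        out[cid] = frozenset(acc)
    return out


def hypergeom_enrichment(
    sample: Iterable,
    population: Iterable,
    term_sets: Mapping,
    term_universe: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of terms in ``sample`` vs ``population``.

    ``term_sets`` maps each unit id (protein or cluster) to its term set.
    Terms with zero population carriers are untestable and excluded from the
    Bonferroni factor ``m``.  Results are sorted by adjusted p-value with a
    term-id tie-break.
    """
    sample = set(sample)
    population = set(population)
    if not sample <= population:
        raise ValueError("sample must be a subset of population")
    N, n = len(population), len(sample)

    pop_counts: dict[str, int] = {}
    sam_counts: dict[str, int] = {}
    for unit in population:
        for term in term_sets.get(unit, ()):  # units without terms contribute nothing
            pop_counts[term] = pop_counts.get(term, 0) + 1
            if unit in sample:
                sam_counts[term] = sam_counts.get(term, 0) + 1
    terms = set(pop_counts)
    if term_universe is not None:
        terms &= set(term_universe)
    m = len(terms)

    results = []
    for term in sorted(terms):
        K = pop_counts[term]
        k = sam_counts.get(term, 0)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        results.append(
            EnrichmentResult(
                term=term, k=k, n=n, K=K, N=N,
                p_raw=p, p_bonferroni=min(1.0, p * m), m=m,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.p_raw, r.term))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term, r.k, r.n, r.K, r.N, r.p_raw, r.p_bonferroni)
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p_raw", "p_bonferroni"],
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table must contain at least one observation")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def ssp_filter(annotations: AnnotationTable) -> tuple[set[str], float]:
    """Small secreted proteins: signal peptide and length in [80, 300] aa.

    Returns the protein-id set and the proteome fraction as a percentage
    rounded to 0.1%.
    """
    df = annotations.df
    mask = (
        df["signal_peptide"]
        & (df["length"] >= SSP_MIN_LEN)
        & (df["length"] <= SSP_MAX_LEN)
    )
    ids = set(df.loc[mask, "protein_id"])
    fraction = proteome_percent(len(ids), len(df)) if len(df) else 0.0
    return ids, fraction


def proteome_percent(found: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (reporting convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return math.floor(1000.0 * found / total + 0.5) / 10.0


def presence_percent(found: int, searched: int) -> int:
    """Integer percentage, rounded half-up (e.g. 93 of 127 -> 73)."""
    if searched <= 0:
        raise ValueError("searched must be positive")
    if not 0 <= found <= searched:
        raise ValueError("found must be within [0, searched]")
    return int(math.floor(100.0 * found / searched + 0.5))


@dataclass
class PcaResult:
    scores: pd.DataFrame  # genomes x components
    loadings: pd.DataFrame  # families x components
    variance_fraction: np.ndarray  # per component, over *all* components

    def variance_percent(self, component: int) -> float:
        return float(self.variance_fraction[component] * 100.0)


def copy_number_pca(
    profile: pd.DataFrame, n_components: Optional[int] = None, scale: bool = False
) -> PcaResult:
    """PCA of a genomes x families copy-number matrix.

    Columns are centered (and scaled to unit variance when ``scale=True``,
    constant columns dropped); the decomposition is by SVD and the variance
    fraction of component i is sigma_i^2 over the sum across all
    components.  Signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    if profile.shape[0] < 2 or profile.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genomes and 2 families")
    if profile.index.duplicated().any() or profile.columns.duplicated().any():
        raise ValueError("duplicate genome or family labels")
    X = profile.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    cols = profile.columns
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        X = X[:, keep] / sd[keep]
        cols = cols[keep]
    if not np.any(np.abs(X) > 0):
        raise ValueError("copy-number matrix is constant; PCA undefined")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2
    frac = var / var.sum()
    k = len(S) if n_components is None else min(n_components, len(S))
    # deterministic sign: largest-|loading| positive per component
    for i in range(len(S)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U * S
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores[:, :k], index=profile.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=cols, columns=comp_names),
        variance_fraction=frac,
    )
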