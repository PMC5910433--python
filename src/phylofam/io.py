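"""Readers and writers for the pipeline's plain-text interchange formats.

Hit tables are BLAST tabular TSV with qlen/slen appended (see
``clustering``); clusters, annotations, orthogroups and event tallies are
simple TSV; trees are Newick; proteomes are FASTA with ``species|protein``
headers (synthetic sequences, since no amino-acid evolution is modeled).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .orthogroups import DolloHistory, EventHistory, Orthogroup
from .simulate import SimulatedFamily
from .trees import SpeciesTree, make_gene_label

AA = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "write_hit_table",
    "write_clusters",
    "read_clusters",
    "write_orthogroups",
    "write_events",
    "write_truth",
    "write_proteome_fasta",
]


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False)


def write_clusters(clusters: ClusterSet, path) -> None:
    clusters.to_frame().to_csv(path, sep="\t", index=False)


def read_clusters(path) -> ClusterSet:
    df = pd.read_csv(path, sep="\t")
    return ClusterSet.from_assignment(
        dict(zip(df["protein_id"], df["cluster_id"]))
    )


def write_orthogroups(
    histories: list[tuple[Orthogroup, DolloHistory]], stree: SpeciesTree, path
) -> None:
    rows = []
    for og, hist in histories:
        for member in og.members:
            rows.append(
                (og.og_id, og.family_id, member, stree.label(og.origin), hist.n_losses)
            )
    pd.DataFrame(
        rows,
        columns=["orthogroup_id", "family_id", "protein_id", "origin_node", "n_losses"],
    ).to_csv(path, sep="\t", index=False)


def write_events(events: EventHistory, path) -> None:
    events.to_frame().to_csv(path, sep="\t", index=False)


def write_truth(families: list[SimulatedFamily], path) -> None:
    rows = []
    for fam in families:
        for ev in fam.truth.events:
            rows.append((fam.family_id, ev.kind, ev.branch, round(ev.time, 6)))
        if fam.truth.extinct:
            rows.append((fam.family_id, "extinct", "", ""))
    pd.DataFrame(
        rows, columns=["family_id", "event_kind", "branch_id", "time"]
    ).to_csv(path, sep="\t", index=False)


def write_proteome_fasta(
    proteins: Mapping[str, list[str]],
    lengths: Mapping[str, int],
    path,
    seed: int = 0,
) -> None:
    """Write per-species protein FASTA with random (placeholder) sequences."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for species in sorted(proteins):
            for pid in proteins[species]:
                label = make_gene_label(species, pid)
                length = int(lengths.get(label, 200))
                seq = "".join(rng.choice(list(AA), size=length))
                fh.write(f">{label}\n{seq}\n")
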