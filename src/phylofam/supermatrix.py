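"""Single-copy cluster selection and supermatrix assembly.

Clusters in which every represented species contributes exactly one protein
and at least ``min_species`` species are represented are the phylogenomic
markers; their (externally computed) alignments are trimmed with a strict
gap-column filter, alignments shorter than ``min_len`` columns are dropped,
and the survivors are concatenated into a species x sites supermatrix with
a partition table.  A neighbor-joining tree on p-distances, midpoint
rooted, stands in for external maximum-likelihood inference when no species
tree is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Sequence

import pandas as pd

from .clustering import ClusterSet
from .trees import SpeciesTree, split_gene_label

__all__ = [
    "Alignment",
    "Supermatrix",
    "select_single_copy",
    "filter_gap_columns",
    "concatenate",
    "nj_tree",
]

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """An amino-acid multiple alignment: parallel (species, sequence) pairs."""

    species: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if len(self.species) != len(self.seqs):
            raise ValueError("species and seqs must be parallel")
        if len(self.species) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        species, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            # headers may be bare species or species|protein
            name = rec.id.split("|")[0]
            species.append(name)
            seqs.append(str(rec.seq).upper())
        return cls(tuple(species), tuple(seqs))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp, seq in zip(self.species, self.seqs):
                fh.write(f">{sp}\n{seq}\n")


@dataclass
class Supermatrix:
    """Concatenated alignment over a species universe plus a partition table."""

    species: tuple[str, ...]
    rows: dict[str, str]
    partitions: pd.DataFrame  # family_id, start, end (1-based inclusive)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sp in self.species:
                fh.write(f">{sp}\n{self.rows[sp]}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.species)} {self.width}\n")
            for sp in self.species:
                fh.write(f"{sp}  {self.rows[sp]}\n")


def select_single_copy(
    clusters: ClusterSet,
    species_universe: Iterable[str],
    min_species: int = 25,
) -> list[int]:
    """Clusters with exactly one protein per represented species, in >= min_species species."""
    universe = set(species_universe)
    if min_species > len(universe):
        raise ValueError("min_species exceeds the species universe")
    selected = []
    for cid in sorted(clusters.clusters):
        per_species: dict[str, int] = {}
        for label in clusters.clusters[cid]:
            sp, _ = split_gene_label(label)
            per_species[sp] = per_species.get(sp, 0) + 1
        if not set(per_species) <= universe:
            continue
        if all(v == 1 for v in per_species.values()) and len(per_species) >= min_species:
            selected.append(cid)
    return selected


def filter_gap_columns(aln: Alignment) -> Alignment:
    """Drop every column containing at least one gap (strict trimming policy)."""
    keep = [
        j for j in range(aln.length) if all(seq[j] != GAP for seq in aln.seqs)
    ]
    seqs = tuple("".join(seq[j] for j in keep) for seq in aln.seqs)
    return Alignment(aln.species, seqs)


class EmptySupermatrixError(ValueError):
    pass


def concatenate(
    alignments: Sequence[tuple[str, Alignment]],
    species_universe: Iterable[str],
    min_len: int = 50,
    trim: bool = True,
) -> Supermatrix:
    """Concatenate per-family alignments into a supermatrix.

    Alignments are gap-column trimmed (unless ``trim=False``), those shorter
    than ``min_len`` columns are excluded, and survivors are concatenated in
    family-id order.  Species missing from a partition are gap-filled across
    it.
    """
    universe = tuple(sorted(set(species_universe)))
    parts: list[tuple[str, Alignment]] = []
    for fam_id, aln in sorted(alignments, key=lambda t: t[0]):
        if not set(aln.species) <= set(universe):
            extra = set(aln.species) - set(universe)
            raise ValueError(f"alignment {fam_id}: species outside universe: {extra}")
        if trim:
            aln = filter_gap_columns(aln)
        if aln.length >= min_len:
            parts.append((fam_id, aln))
    if not parts:
        raise EmptySupermatrixError(
            f"no alignment of length >= {min_len} columns survives filtering"
        )
    rows = {sp: [] for sp in universe}
    records = []
    pos = 1
    for fam_id, aln in parts:
        lookup = dict(zip(aln.species, aln.seqs))
        for sp in universe:
            rows[sp].append(lookup.get(sp, GAP * aln.length))
        records.append((fam_id, pos, pos + aln.length - 1))
        pos += aln.length
    return Supermatrix(
        species=universe,
        rows={sp: "".join(chunks) for sp, chunks in rows.items()},
        partitions=pd.DataFrame(records, columns=["family_id", "start", "end"]),
    )


def nj_tree(matrix: Supermatrix) -> SpeciesTree:
    """Neighbor-joining tree on p-distances, midpoint rooted.

    The p-distance of a species pair is the fraction of differing residues
    over their mutually non-gap columns; a pair with no comparable column is
    an error.  Negative NJ branch lengths are clamped to zero before
    midpoint rooting.  Ties are made deterministic by ordering species
    alphabetically.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    species = sorted(matrix.species)
    if len(species) < 3:
        raise ValueError("nj_tree needs at least 3 species")
    n = len(species)
    dist = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = matrix.rows[species[i]], matrix.rows[species[j]]
            comparable = diffs = 0
            for x, y in zip(a, b):
                if x != GAP and y != GAP:
                    comparable += 1
                    if x != y:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"species pair ({species[i]}, {species[j]}) shares no "
                    "non-gap column; distance undefined"
                )
            dist[i][j] = dist[j][i] = diffs / comparable
    dm = DistanceMatrix(dist, ids=species)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    rooted = tree.root_at_midpoint()
    buf = StringIO()
    rooted.write(buf, format="newick")
    return SpeciesTree.from_newick(buf.getvalue())
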