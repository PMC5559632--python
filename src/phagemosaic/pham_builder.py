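"""Group protein sequences into phamilies (phams).

A pham is a set of genes whose protein products are related by sequence
similarity; phages are later compared by which phams they carry rather than
by nucleotide alignment. Here relatedness is measured alignment-free as the
Jaccard index of amino-acid k-mer sets, and phams are the connected
components of the graph joining genes whose similarity reaches a threshold
(single linkage, so relatedness is transitive across a family). The metric
and its defaults (k=4, threshold 0.5) are this package's own documented
choice; published pham tables built with other tools will not be reproduced
gene-for-gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

from .io_tables import GeneRecord, ValidationError

__all__ = [
    "Pham",
    "PhamSummary",
    "protein_similarity",
    "build_phams",
    "pham_summary",
    "assign_pham_ids",
]


class SimilarityUndefinedError(ValueError):
    """A sequence is too short for the requested k-mer length."""


@dataclass(frozen=True)
class Pham:
    """One phamily: a non-empty set of gene ids sharing related proteins."""

    pham_id: int
    member_gene_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)

    @property
    def is_orpham(self) -> bool:
        return self.size == 1


@dataclass(frozen=True)
class PhamSummary:
    n_genes: int
    n_phams: int
    mean_pham_size: float
    n_orphams: int


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    if len(seq) < k:
        raise SimilarityUndefinedError(
            f"sequence of length {len(seq)} is shorter than k={k}"
        )
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def protein_similarity(a: str, b: str, k: int = 4) -> float:
    """Jaccard index of the two proteins' k-mer sets; 1.0 for identical sequences."""
    ka, kb = _kmer_set(a, k), _kmer_set(b, k)
    inter = len(ka & kb)
    union = len(ka | kb)
    return inter / union


def build_phams(
    genes: Sequence[GeneRecord], k: int = 4, threshold: float = 0.5
) -> list[Pham]:
    """Partition genes into phams by single-linkage k-mer-Jaccard clustering.

    Two genes are joined whenever their protein similarity is >= ``threshold``;
    phams are the connected components of that graph. Pham ids are assigned
    1..N in order of each component's lexicographically smallest gene id, so
    the output is independent of input order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if not genes:
        return []
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene_id in input")

    kmers = {g.gene_id: _kmer_set(g.translation, k) for g in genes}
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    # Inverted k-mer index keeps the candidate set far below all-pairs.
    index: dict[str, list[str]] = {}
    for gid in sorted(ids):
        for kmer in kmers[gid]:
            index.setdefault(kmer, []).append(gid)
    candidates: set[tuple[str, str]] = set()
    for members in index.values():
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                candidates.add((a, b) if a < b else (b, a))
    for a, b in candidates:
        ka, kb = kmers[a], kmers[b]
        if len(ka & kb) / len(ka | kb) >= threshold:
            graph.add_edge(a, b)

    components = sorted(
        (frozenset(c) for c in nx.connected_components(graph)), key=min
    )
    return [Pham(i + 1, comp) for i, comp in enumerate(components)]


def assign_pham_ids(
    genes: Iterable[GeneRecord], phams: Sequence[Pham]
) -> list[GeneRecord]:
    """Return copies of ``genes`` with ``pham_id`` filled from ``phams``."""
    lookup = {gid: p.pham_id for p in phams for gid in p.member_gene_ids}
    out = []
    for g in genes:
        pid = lookup.get(g.gene_id)
        out.append(GeneRecord(g.gene_id, g.genome_id, g.start, g.end, g.strand,
                              g.translation, pham_id=pid))
    return out


def pham_summary(phams: Sequence[Pham]) -> PhamSummary:
    """Summary counts of a pham partition (gene count, pham count, orphams)."""
    all_genes: list[str] = []
    for p in phams:
        all_genes.extend(p.member_gene_ids)
    if len(set(all_genes)) != len(all_genes):
        raise ValidationError("phams overlap: not a partition")
    n_genes = len(all_genes)
    n_phams = len(phams)
    if n_phams == 0:
        return PhamSummary(0, 0, 0.0, 0)
    mean = float(Fraction(n_genes, n_phams))
    n_orphams = sum(1 for p in phams if p.is_orpham)
    return PhamSummary(n_genes, n_phams, mean, n_orphams)
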