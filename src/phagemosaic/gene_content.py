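"""Gene content dissimilarity (GCD) and gap statistics for phage populations.

Each genome is reduced to the set of distinct phams it carries (presence /
absence; within-genome duplicates collapse). For two genomes with pham sets
A and B sharing S = |A ∩ B| phams,

    GCD = 1 - (S/|A| + S/|B|) / 2

so 0 means identical gene content and 1 means no shared phams. The
MaxGCDGap of a phage ranks its GCD values against every other genome from
largest to smallest — with the self-comparison value 0 anchoring the end of
the list — takes consecutive differences (GCD gaps), and reports the
largest. It measures the biggest discontinuity in that phage's genetic
relationships without requiring any prior cluster assignment: a phage with
no close relatives has a MaxGCDGap approaching 1, while a member of a tight
cluster embedded in a continuum has a small one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import GeneRecord, ValidationError

__all__ = [
    "PhamProfile",
    "GCDMatrix",
    "GapProfile",
    "profiles_from_genes",
    "gcd",
    "gcd_matrix",
    "gap_profile",
    "max_gcd_gap_all",
    "band_statistics",
    "host_set_sharing",
]


@dataclass(frozen=True)
class PhamProfile:
    """Per-genome set of distinct pham ids."""

    genome_id: str
    pham_set: frozenset[int]


@dataclass
class GCDMatrix:
    """Symmetric pairwise gene-content-dissimilarity matrix with labels."""

    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if len(set(self.genome_ids)) != n:
            raise ValidationError("duplicate genome_id in matrix labels")
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("GCD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("GCD matrix diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValidationError("GCD values must lie in [0, 1]")

    def index_of(self, genome_id: str) -> int:
        try:
            return self.genome_ids.index(genome_id)
        except ValueError:
            raise KeyError(f"genome {genome_id!r} not in matrix") from None

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])


@dataclass(frozen=True)
class GapProfile:
    """One phage's magnitude-ranked GCD vector and its consecutive gaps.

    ``ranked_gcds`` is sorted descending and includes the self-comparison
    value 0 as its final element, so the gap between a phage's closest
    relative and itself is counted; ``max_gap_pair`` names the two neighbours
    (self allowed) flanking the maximal gap.
    """

    genome_id: str
    ranked_gcds: tuple[float, ...]
    neighbor_ids: tuple[str, ...]
    gaps: tuple[float, ...]
    max_gap: float
    max_gap_pair: tuple[str, str]


def profiles_from_genes(genes: Iterable[GeneRecord]) -> list[PhamProfile]:
    """Collapse pham-annotated genes into per-genome presence/absence profiles."""
    sets: dict[str, set[int]] = {}
    for g in genes:
        if g.pham_id is None:
            raise ValidationError(f"gene {g.gene_id!r} has no pham assignment")
        sets.setdefault(g.genome_id, set()).add(g.pham_id)
    return [PhamProfile(gid, frozenset(s)) for gid, s in sorted(sets.items())]


def gcd(a: PhamProfile, b: PhamProfile) -> float:
    """Gene content dissimilarity between two pham profiles."""
    if not a.pham_set or not b.pham_set:
        raise ValidationError("GCD is undefined for an empty pham profile")
    s = len(a.pham_set & b.pham_set)
    return 1.0 - (s / len(a.pham_set) + s / len(b.pham_set)) / 2.0


def gcd_matrix(profiles: Sequence[PhamProfile]) -> GCDMatrix:
    """All pairwise GCD values for a population of pham profiles."""
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles for a GCD matrix")
    ids = [p.genome_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate genome_id among profiles")
    n = len(profiles)
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = gcd(profiles[i], profiles[j])
    return GCDMatrix(ids, values)


def gap_profile(genome_id: str, matrix: GCDMatrix) -> GapProfile:
    """Ranked GCD list, consecutive gaps, and MaxGCDGap for one genome.

    Ties in GCD value are ordered by neighbour genome id; equal values yield
    zero gaps, so tie order never changes the gap values themselves.
    """
    if len(matrix.genome_ids) < 2:
        raise ValidationError("gap profile needs a matrix with >= 2 genomes")
    i = matrix.index_of(genome_id)
    others = [
        (float(matrix.values[i, j]), matrix.genome_ids[j])
        for j in range(len(matrix.genome_ids))
        if j != i
    ]
    # Descending by value; ties stably by genome id.
    others.sort(key=lambda t: (-t[0], t[1]))
    ranked = [v for v, _ in others] + [0.0]
    neighbors = [g for _, g in others] + [genome_id]
    gaps = [ranked[k] - ranked[k + 1] for k in range(len(ranked) - 1)]
    k_max = int(np.argmax(gaps))
    return GapProfile(
        genome_id=genome_id,
        ranked_gcds=tuple(ranked),
        neighbor_ids=tuple(neighbors),
        gaps=tuple(gaps),
        max_gap=gaps[k_max],
        max_gap_pair=(neighbors[k_max], neighbors[k_max + 1]),
    )


def max_gcd_gap_all(matrix: GCDMatrix) -> dict[str, float]:
    """MaxGCDGap for every genome in the matrix."""
    return {g: gap_profile(g, matrix).max_gap for g in matrix.genome_ids}


@dataclass(frozen=True)
class BandStatistics:
    """Counts of pairwise comparisons falling inside a GCD band [lo, hi]."""

    lo: float
    hi: float
    n_pairs_total: int
    n_pairs_in_band: int
    fraction_in_band: float
    participating_genomes: frozenset[str]
    participating_groups: frozenset[str] = field(default_factory=frozenset)


def band_statistics(
    matrix: GCDMatrix,
    lo: float = 0.3,
    hi: float = 0.7,
    group_of: Mapping[str, str] | None = None,
) -> BandStatistics:
    """How many pairwise comparisons fall in the GCD band [lo, hi] (inclusive).

    ``group_of`` optionally maps genome ids to cluster/singleton labels so the
    participating groups can be reported alongside participating genomes.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"band bounds must satisfy 0 <= lo < hi <= 1, got {lo}, {hi}")
    n = len(matrix.genome_ids)
    total = n * (n - 1) // 2
    in_band = 0
    participants: set[str] = set()
    for i, j in combinations(range(n), 2):
        v = matrix.values[i, j]
        if lo <= v <= hi:
            in_band += 1
            participants.add(matrix.genome_ids[i])
            participants.add(matrix.genome_ids[j])
    groups: set[str] = set()
    if group_of is not None:
        groups = {group_of[g] for g in participants if g in group_of}
    return BandStatistics(
        lo=lo,
        hi=hi,
        n_pairs_total=total,
        n_pairs_in_band=in_band,
        fraction_in_band=in_band / total if total else 0.0,
        participating_genomes=frozenset(participants),
        participating_groups=frozenset(groups),
    )


def host_set_sharing(
    profiles_by_host: Mapping[str, Sequence[PhamProfile]],
) -> dict[frozenset[str], int]:
    """Exclusive Venn-region pham counts across host groups.

    For every non-empty subset of hosts, counts the phams present in at least
    one genome of every host in the subset and absent from all genomes of
    every host outside it. Region counts sum to the total number of distinct
    phams.
    """
    if len(profiles_by_host) < 2:
        raise ValidationError("host sharing needs at least 2 host groups")
    seen_ids: set[str] = set()
    union_by_host: dict[str, frozenset[int]] = {}
    for host, profiles in profiles_by_host.items():
        if not profiles:
            raise ValidationError(f"host group {host!r} is empty")
        ids = {p.genome_id for p in profiles}
        if ids & seen_ids:
            raise ValidationError("a genome_id appears under more than one host")
        seen_ids |= ids
        union_by_host[host] = frozenset().union(*(p.pham_set for p in profiles))

    all_phams = frozenset().union(*union_by_host.values())
    regions: dict[frozenset[str], int] = {}
    for pham in all_phams:
        present = frozenset(h for h, u in union_by_host.items() if pham in u)
        regions[present] = regions.get(present, 0) + 1
    return regions
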