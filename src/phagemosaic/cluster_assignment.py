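"""Cluster assignment by shared gene content, ANI-based subdivision, and
genometric summaries.

Two phages belong to the same cluster when each is linked — directly or
through intermediates — to at least one other member with which it shares at
least 35% of its genes, i.e. GCD <= 0.65 by default. That rule is exactly
single linkage, so clusters are the connected components of the share graph;
components of size 1 are singletons. Subdivision of a cluster into
subclusters uses average nucleotide identity (ANI) computed by a fragment
method: the query is cut into fixed windows, each window is aligned to its
best match in the subject by edit distance, and windows at >= 70% identity
count as aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import edlib
import networkx as nx

from .io_tables import SINGLETON, GenomeRecord, ValidationError
from .gene_content import GCDMatrix

__all__ = [
    "ClusterResult",
    "ANIResult",
    "GenometricsSummary",
    "assign_clusters",
    "compute_ani",
    "mean_ani",
    "assign_subclusters",
    "genometrics_summary",
]


@dataclass(frozen=True)
class ClusterResult:
    """Cluster membership for a genome set.

    ``assignment`` maps every genome to a cluster label (``C1``, ``C2``, ...)
    or ``SINGLETON``; ``clusters`` lists the multi-member components.
    """

    assignment: dict[str, str]
    clusters: list[frozenset[str]]
    threshold_gcd: float


@dataclass(frozen=True)
class ANIResult:
    """Directional fragment-ANI of a query against a subject genome."""

    ani_percent: float | None
    aligned_fraction: float


def assign_clusters(
    matrix: GCDMatrix,
    threshold_gcd: float = 0.65,
    rule: str = "gcd",
    profiles: Sequence | None = None,
) -> ClusterResult:
    """Group genomes into clusters by shared gene content.

    With the default ``rule='gcd'`` an edge joins two genomes iff their GCD
    is <= ``threshold_gcd``; clusters are the connected components (so
    membership requires closeness to at least one other member, not to
    all). Components of size 1 are labelled ``SINGLETON``; the rest get
    deterministic labels ``C1, C2, ...`` ordered by each component's
    smallest genome id.

    ``rule='per_genome'`` is the alternative reading of "shares 35% of its
    genes": an edge joins A and B when the shared phams reach
    ``1 - threshold_gcd`` of **either** genome's own pham count. It needs
    the pham ``profiles`` and is not the default.
    """
    if not 0.0 < threshold_gcd < 1.0:
        raise ValueError(f"threshold_gcd must be in (0, 1), got {threshold_gcd}")
    if rule not in ("gcd", "per_genome"):
        raise ValueError(f"unknown clustering rule {rule!r}")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.genome_ids)
    n = len(matrix.genome_ids)
    if rule == "per_genome":
        if profiles is None:
            raise ValueError("rule='per_genome' requires the pham profiles")
        by_id = {p.genome_id: p.pham_set for p in profiles}
        min_shared = 1.0 - threshold_gcd
        for i, j in combinations(range(n), 2):
            a = by_id[matrix.genome_ids[i]]
            b = by_id[matrix.genome_ids[j]]
            s = len(a & b)
            if s / len(a) >= min_shared or s / len(b) >= min_shared:
                graph.add_edge(matrix.genome_ids[i], matrix.genome_ids[j])
    else:
        for i, j in combinations(range(n), 2):
            if matrix.values[i, j] <= threshold_gcd:
                graph.add_edge(matrix.genome_ids[i], matrix.genome_ids[j])
    components = sorted((frozenset(c) for c in nx.connected_components(graph)), key=min)
    assignment: dict[str, str] = {}
    clusters: list[frozenset[str]] = []
    for comp in components:
        if len(comp) == 1:
            assignment[next(iter(comp))] = SINGLETON
        else:
            clusters.append(comp)
    for idx, comp in enumerate(clusters, start=1):
        for g in comp:
            assignment[g] = f"C{idx}"
    return ClusterResult(assignment=assignment, clusters=clusters,
                         threshold_gcd=threshold_gcd)


def compute_ani(
    a: str,
    b: str,
    fragment_bp: int = 1000,
    min_identity: float = 0.7,
) -> ANIResult:
    """Fragment-based average nucleotide identity of ``a`` against ``b``.

    ``a`` is cut into consecutive full windows of ``fragment_bp``; each window
    is aligned to its best-matching location in ``b`` (edit distance, infix
    alignment). Windows reaching ``min_identity`` count as aligned;
    ``ani_percent`` is the mean identity of aligned windows on the 0-100
    scale, or ``None`` when nothing aligns. The measure is directional; see
    :func:`mean_ani` for the symmetric report.
    """
    if len(a) < fragment_bp or len(b) < fragment_bp:
        raise ValueError(
            f"both sequences must be >= fragment_bp={fragment_bp}; "
            f"got {len(a)} and {len(b)} (use a smaller fragment)"
        )
    n_frag = len(a) // fragment_bp
    identities = []
    n_aligned = 0
    for i in range(n_frag):
        frag = a[i * fragment_bp : (i + 1) * fragment_bp]
        res = edlib.align(frag, b, mode="HW", task="distance")
        identity = 1.0 - res["editDistance"] / fragment_bp
        if identity >= min_identity:
            n_aligned += 1
            identities.append(identity)
    aligned_fraction = n_aligned / n_frag
    ani = 100.0 * sum(identities) / n_aligned if n_aligned else None
    return ANIResult(ani_percent=ani, aligned_fraction=aligned_fraction)


def mean_ani(a: str, b: str, fragment_bp: int = 1000,
             min_identity: float = 0.7) -> ANIResult:
    """Mean of the two directional fragment-ANI measurements."""
    fwd = compute_ani(a, b, fragment_bp, min_identity)
    rev = compute_ani(b, a, fragment_bp, min_identity)
    anis = [x.ani_percent for x in (fwd, rev) if x.ani_percent is not None]
    return ANIResult(
        ani_percent=sum(anis) / len(anis) if anis else None,
        aligned_fraction=(fwd.aligned_fraction + rev.aligned_fraction) / 2.0,
    )


def assign_subclusters(
    cluster_members: Sequence[GenomeRecord],
    cluster_label: str = "C1",
    ani_percent_cut: float = 95.0,
    min_aligned: float = 0.5,
    fragment_bp: int = 1000,
) -> dict[str, str]:
    """Subdivide one cluster into subclusters by ANI connectivity.

    An edge joins two members iff their mean ANI is >= ``ani_percent_cut``
    with mean aligned fraction >= ``min_aligned``. When the cluster holds
    together as one component it is reported undivided (label = cluster
    label); otherwise components get ``<cluster>1, <cluster>2, ...`` by
    smallest member id.
    """
    for rec in cluster_members:
        if rec.sequence is None:
            raise ValidationError(f"genome {rec.genome_id!r} carries no sequence")
    graph = nx.Graph()
    graph.add_nodes_from(r.genome_id for r in cluster_members)
    for x, y in combinations(cluster_members, 2):
        res = mean_ani(x.sequence, y.sequence, fragment_bp=fragment_bp)
        if (res.ani_percent is not None and res.ani_percent >= ani_percent_cut
                and res.aligned_fraction >= min_aligned):
            graph.add_edge(x.genome_id, y.genome_id)
    components = sorted((frozenset(c) for c in nx.connected_components(graph)), key=min)
    if len(components) == 1:
        return {g: cluster_label for g in components[0]}
    out: dict[str, str] = {}
    for idx, comp in enumerate(components, start=1):
        for g in comp:
            out[g] = f"{cluster_label}{idx}"
    return out


@dataclass(frozen=True)
class GenometricsSummary:
    """Headline statistics of a phage-profile metadata table."""

    n_genomes: int
    min_length_bp: int
    max_length_bp: int
    min_gc_percent: float
    max_gc_percent: float
    n_clusters: int
    n_clustered: int
    n_singletons: int
    n_clusters_with_subclusters: int
    n_groups: int
    dtr_lengths: tuple[int, ...]


def genometrics_summary(records: Sequence[GenomeRecord]) -> GenometricsSummary:
    """Summarize a metadata table: extrema, cluster counts, DTR lengths.

    Subcluster labels are normalized to their base cluster (A15 -> A) before
    counting; a cluster counts as subdivided when its members carry at least
    two distinct subcluster labels.
    """
    if not records:
        raise ValidationError("cannot summarize an empty record list")
    lengths = [r.length_bp for r in records]
    gcs = [r.gc_percent for r in records if r.gc_percent is not None]
    base_clusters: set[str] = set()
    subclusters_of: dict[str, set[str]] = {}
    n_singletons = 0
    for r in records:
        if r.cluster_label is None:
            raise ValidationError(f"genome {r.genome_id!r} has no cluster label")
        if r.is_singleton:
            n_singletons += 1
            continue
        base_clusters.add(r.cluster_label)
        if r.subcluster_label is not None:
            subclusters_of.setdefault(r.cluster_label, set()).add(r.subcluster_label)
    n_clusters = len(base_clusters)
    n_clustered = len(records) - n_singletons
    n_subdivided = sum(1 for subs in subclusters_of.values() if len(subs) >= 2)
    dtrs = tuple(sorted({r.end_type.n for r in records if r.end_type.kind == "dtr"}))
    return GenometricsSummary(
        n_genomes=len(records),
        min_length_bp=min(lengths),
        max_length_bp=max(lengths),
        min_gc_percent=min(gcs) if gcs else 0.0,
        max_gc_percent=max(gcs) if gcs else 0.0,
        n_clusters=n_clusters,
        n_clustered=n_clustered,
        n_singletons=n_singletons,
        n_clusters_with_subclusters=n_subdivided,
        n_groups=n_clusters + n_singletons,
        dtr_lengths=dtrs,
    )
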