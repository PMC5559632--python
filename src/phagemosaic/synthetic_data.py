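"""Seeded generator of synthetic mosaic phage populations with ground truth.

The generator emulates the population structure that gene-content methods
are built to detect: clusters of related phages drawing most genes from a
cluster-specific core pool, plus a single accessory pool shared across the
whole population through horizontal gene transfer (HGT), plus per-genome
private orphams. One knob, ``hgt_rate``, moves the population from fully
discrete clusters (rate 0: within-cluster GCD 0, between-cluster GCD 1 when
retention is 1) toward a continuum of relatedness.

For every pham one random ancestor protein (80-400 aa) is drawn and each
member gene receives an independently mutated copy (per-site substitution at
``protein_family_mutation``), so pham construction can be tested against the
planted families. Nucleotide genomes are uniform-random background into
which operator motifs (with controlled substitution counts) and att cores
shared with a synthetic host are planted; every plant is recorded in the
exported truth.

All randomness flows from one integer seed; identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import GeneRecord, GenomeRecord
from .site_finder import CONSENSUS_PRESETS, reverse_complement

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "simulate_population",
    "emit_genome_sequences",
    "export_truth",
    "read_truth",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


class SimConfigError(ValueError):
    """The simulation config cannot produce a valid population."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic phage population.

    Defaults describe the well-separated regime used throughout the test
    suite: 4 clusters of 5 genomes, 40 core phams per cluster retained with
    probability 0.9, a 200-pham accessory pool drawn at ``hgt_rate`` 0.02,
    about one private orpham per genome, and 2% per-site protein divergence
    within a family.
    """

    n_clusters: int = 4
    genomes_per_cluster: int | tuple[int, ...] = 5
    core_phams_per_cluster: int = 40
    core_retention: float = 0.9
    accessory_pool_size: int = 200
    hgt_rate: float = 0.02
    orpham_rate: float = 1.0
    protein_family_mutation: float = 0.02
    genome_length_bp: int = 20000
    host_length_bp: int = 40000
    n_planted_motifs: int = 5
    motif_mismatch_distribution: dict[int, int] = field(default_factory=dict)
    motif_consensus: str = CONSENSUS_PRESETS["KatherineG"]
    att_core_lengths: tuple[int, ...] = (37,)
    seed: int = 0

    def per_cluster_counts(self) -> list[int]:
        if isinstance(self.genomes_per_cluster, int):
            return [self.genomes_per_cluster] * self.n_clusters
        counts = list(self.genomes_per_cluster)
        if len(counts) != self.n_clusters:
            raise SimConfigError("genomes_per_cluster list length != n_clusters")
        return counts

    def validate(self) -> None:
        for name in ("core_retention", "hgt_rate", "protein_family_mutation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be a probability, got {v}")
        if min(self.n_clusters, self.core_phams_per_cluster) < 0 or self.orpham_rate < 0:
            raise SimConfigError("counts and rates must be non-negative")
        if (self.core_retention == 0.0 and self.hgt_rate == 0.0
                and self.orpham_rate == 0.0):
            raise SimConfigError("config guarantees empty genomes")
        if self.motif_mismatch_distribution:
            if any(s < 0 or s > len(self.motif_consensus)
                   for s in self.motif_mismatch_distribution):
                raise SimConfigError("motif substitution counts out of range")


@dataclass
class SimTruth:
    """Planted ground truth: cluster labels, pham families, motif and att loci."""

    true_cluster_of: dict[str, int]
    pham_of_gene: dict[str, int]
    motif_positions: list[tuple[str, int, str, int]]
    att_core_loci: list[tuple[int, int, int]]  # (phage 1-based start, host start, length)


# _AA is alphabetically sorted, which _mutate_protein's searchsorted relies on.
_AA_ARR = np.frombuffer(_AA.encode(), dtype=np.uint8)
_NT_ARR = np.frombuffer(_NT.encode(), dtype=np.uint8)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA_ARR[rng.integers(0, len(_AA), size=length)]).decode()


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        cur = np.searchsorted(_AA_ARR, arr[hit])
        # Draw among the 19 alternatives, skipping the current residue.
        alt = rng.integers(0, len(_AA) - 1, size=hit.size)
        alt += alt >= cur
        arr[hit] = _AA_ARR[alt]
    return bytes(arr).decode()


def simulate_population(
    config: SimConfig,
) -> tuple[list[GenomeRecord], list[GeneRecord], SimTruth]:
    """Draw a population of genomes with planted cluster structure.

    Each genome's pham set is its cluster core (each core pham kept with
    probability ``core_retention``), plus accessory-pool phams each drawn
    with probability ``hgt_rate``, plus ~Poisson(``orpham_rate``) private
    orphams. Genes are laid head-to-tail with 50-bp spacers; translations are
    per-member mutated copies of each pham's ancestor protein.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.per_cluster_counts()

    next_pham = 1
    core_pools: list[list[int]] = []
    for _ in range(config.n_clusters):
        core_pools.append(list(range(next_pham, next_pham + config.core_phams_per_cluster)))
        next_pham += config.core_phams_per_cluster
    accessory_pool = list(range(next_pham, next_pham + config.accessory_pool_size))
    next_pham += config.accessory_pool_size

    ancestors: dict[int, str] = {}

    def ancestor(pham: int) -> str:
        if pham not in ancestors:
            ancestors[pham] = _random_protein(rng, int(rng.integers(80, 401)))
        return ancestors[pham]

    genomes: list[GenomeRecord] = []
    genes: list[GeneRecord] = []
    truth = SimTruth({}, {}, [], [])
    gene_counter = 0
    for c in range(config.n_clusters):
        for g in range(counts[c]):
            genome_id = f"sim_c{c + 1:02d}_g{g + 1:02d}"
            phams = [p for p in core_pools[c] if rng.random() < config.core_retention]
            phams += [p for p in accessory_pool if rng.random() < config.hgt_rate]
            n_orphams = int(rng.poisson(config.orpham_rate))
            orphams = list(range(next_pham, next_pham + n_orphams))
            next_pham += n_orphams
            phams += orphams
            if not phams:  # rare empty draw; give it one private orpham
                phams = [next_pham]
                next_pham += 1
            truth.true_cluster_of[genome_id] = c + 1
            pos = 101
            for pham in phams:
                gene_counter += 1
                gene_id = f"{genome_id}_gene{gene_counter:05d}"
                protein = _mutate_protein(
                    rng, ancestor(pham), config.protein_family_mutation
                )
                start, end = pos, pos + 3 * len(protein) - 1
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneRecord(gene_id, genome_id, start, end, strand, protein))
                truth.pham_of_gene[gene_id] = pham
                pos = end + 51
            genomes.append(
                GenomeRecord(genome_id=genome_id, host_genus="Synthetica",
                             host_species="simulata",
                             length_bp=max(config.genome_length_bp, pos + 100))
            )
    return genomes, genes, truth


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return bytes(_NT_ARR[rng.integers(0, 4, size=length)]).decode()


def _plant(seq: list[str], pos0: int, insert: str) -> None:
    seq[pos0 : pos0 + len(insert)] = list(insert)


def _substitute(rng: np.random.Generator, motif: str, n_sub: int) -> str:
    out = list(motif)
    for i in rng.choice(len(motif), size=n_sub, replace=False):
        alternatives = _NT.replace(out[i], "")
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def emit_genome_sequences(
    genomes: Sequence[GenomeRecord],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[list[GenomeRecord], str]:
    """Fill genome sequences with random background plus planted sites.

    Motifs (with the configured substitution counts, random strands) are
    planted at non-overlapping positions in the first genome, and one att
    core per configured length is copied between the first genome and the
    returned synthetic host sequence. Background bases flanking each att
    plant are forced to differ between phage and host so the planted core is
    maximal at exactly its planted length. All plants are appended to
    ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    out: list[GenomeRecord] = []
    host = list(_random_nt(rng, config.host_length_bp))

    mismatch_counts: list[int] = []
    if config.motif_mismatch_distribution:
        for n_sub, count in sorted(config.motif_mismatch_distribution.items()):
            mismatch_counts += [n_sub] * count
    else:
        mismatch_counts = [0] * config.n_planted_motifs

    for idx, genome in enumerate(genomes):
        length = genome.length_bp or config.genome_length_bp
        seq = list(_random_nt(rng, length))
        if idx == 0:
            occupied: list[tuple[int, int]] = []

            def place(width: int) -> int:
                for _ in range(1000):
                    p = int(rng.integers(0, length - width))
                    if all(p + width + 1 <= s or p >= e + 1 for s, e in occupied):
                        occupied.append((p, p + width))
                        return p
                raise SimConfigError("plants exceed genome capacity")

            motif = config.motif_consensus
            for n_sub in mismatch_counts:
                p = place(len(motif))
                variant = _substitute(rng, motif, n_sub)
                strand = "+" if rng.random() < 0.5 else "-"
                _plant(seq, p, variant if strand == "+" else reverse_complement(variant))
                truth.motif_positions.append((genome.genome_id, p + 1, strand, n_sub))

            for core_len in config.att_core_lengths:
                core = _random_nt(rng, core_len)
                p = place(core_len)
                h = int(rng.integers(1, config.host_length_bp - core_len - 1))
                _plant(seq, p, core)
                _plant(host, h, core)
                # Force mismatching flanks so the shared segment is maximal
                # at exactly core_len.
                for ph_flank, host_flank in ((p - 1, h - 1), (p + core_len, h + core_len)):
                    if 0 <= ph_flank < length and 0 <= host_flank < len(host):
                        choices = _NT.replace(seq[ph_flank], "")
                        host[host_flank] = choices[rng.integers(3)]
                truth.att_core_loci.append((p + 1, h + 1, core_len))
        out.append(replace(genome, sequence="".join(seq), gc_percent=None))
    return out, "".join(host)


def export_truth(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the planted truth as a TSV bundle; see :func:`read_truth`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clusters": out_dir / "truth_clusters.tsv",
        "phams": out_dir / "truth_phams.tsv",
        "motifs": out_dir / "truth_motifs.tsv",
        "att_cores": out_dir / "truth_att_cores.tsv",
    }
    pd.DataFrame(
        sorted(truth.true_cluster_of.items()), columns=["genome_id", "cluster"]
    ).to_csv(paths["clusters"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.pham_of_gene.items()), columns=["gene_id", "pham"]
    ).to_csv(paths["phams"], sep="\t", index=False)
    pd.DataFrame(
        truth.motif_positions, columns=["genome_id", "start", "strand", "n_substitutions"]
    ).to_csv(paths["motifs"], sep="\t", index=False)
    pd.DataFrame(
        truth.att_core_loci, columns=["phage_start", "host_start", "length"]
    ).to_csv(paths["att_cores"], sep="\t", index=False)
    return paths


def read_truth(out_dir: str | Path) -> SimTruth:
    """Read back a truth bundle written by :func:`export_truth`."""
    out_dir = Path(out_dir)
    clusters = pd.read_csv(out_dir / "truth_clusters.tsv", sep="\t")
    phams = pd.read_csv(out_dir / "truth_phams.tsv", sep="\t")
    motifs = pd.read_csv(out_dir / "truth_motifs.tsv", sep="\t")
    atts = pd.read_csv(out_dir / "truth_att_cores.tsv", sep="\t")
    return SimTruth(
        true_cluster_of=dict(zip(clusters.genome_id, clusters.cluster.astype(int))),
        pham_of_gene=dict(zip(phams.gene_id, phams.pham.astype(int))),
        motif_positions=[
            (r.genome_id, int(r.start), r.strand, int(r.n_substitutions))
            for r in motifs.itertuples()
        ],
        att_core_loci=[
            (int(r.phage_start), int(r.host_start), int(r.length))
            for r in atts.itertuples()
        ],
    )
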