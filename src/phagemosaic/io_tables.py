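"""Readers and writers for the formats the pipeline consumes and emits.

Genome sequences travel as FASTA, gene annotations as GFF3 or a plain TSV
gene table, phage metadata as a TSV modelled on the published profile table,
and distance matrices as TSV or as a Nexus ``DISTANCES`` block for network
software. All downstream modules consume only the record types defined here.

External coordinates are 1-based inclusive throughout (GFF3/GenBank
convention); host attachment-site coordinates printed in descending order
are stored as ``(min, max)`` plus an orientation flag.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "EndType",
    "GenomeRecord",
    "GeneRecord",
    "AttTableRow",
    "FormatError",
    "ValidationError",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_gene_table",
    "read_metadata_table",
    "read_att_table",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_nexus_distances",
    "gc_percent_of",
    "table1_path",
    "table2_path",
]

SINGLETON = "SINGLETON"
INTERGENIC = "INTERGENIC"

#: IUPAC nucleotide one-letter codes accepted in genome sequences.
IUPAC_NT = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """A file violates the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a documented invariant."""


def gc_percent_of(sequence: str) -> float:
    """GC content on the 0-100 scale.

    Computed as ``100 * (G+C) / (A+C+G+T)``; ambiguous bases are excluded
    from both numerator and denominator.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return 0.0
    return 100.0 * gc / (gc + at)


@dataclass(frozen=True)
class EndType:
    """Physical genome-end architecture of a packaged phage chromosome.

    ``kind`` is one of ``three_prime_ext`` / ``five_prime_ext`` (single-strand
    extension of ``n`` bases), ``dtr`` (direct terminal repeat of ``n`` bp),
    ``circularly_permuted``, or ``unknown``.
    """

    kind: str
    n: int | None = None

    KINDS = ("three_prime_ext", "five_prime_ext", "circularly_permuted", "dtr", "unknown")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown end type kind {self.kind!r}")
        if self.kind in ("three_prime_ext", "five_prime_ext", "dtr") and (
            self.n is None or self.n <= 0
        ):
            raise ValidationError(f"end type {self.kind!r} needs a positive size")


_END_EXT_RE = re.compile(r"^([35])\s*[′'’]\s*(\d+)-base\s+ext\.?$")
_END_DTR_RE = re.compile(r"^([\d,]+)-bp\s+DTR$")


def parse_end_type(text: str) -> EndType:
    """Parse a printed genome-end description.

    Recognizes e.g. ``3′ 10-base ext.``, ``5′ 16-base ext.``, ``Cir. Perm``,
    ``1,182-bp DTR`` and ``?``. Unrecognized strings are recorded as
    ``unknown`` with a warning rather than an error.
    """
    t = text.strip()
    if t in ("?", ""):
        return EndType("unknown")
    m = _END_EXT_RE.match(t)
    if m:
        kind = "three_prime_ext" if m.group(1) == "3" else "five_prime_ext"
        return EndType(kind, int(m.group(2)))
    if t.lower().startswith("cir"):
        return EndType("circularly_permuted")
    m = _END_DTR_RE.match(t)
    if m:
        return EndType("dtr", int(m.group(1).replace(",", "")))
    warnings.warn(f"unparseable genome-end description {text!r}; recording as unknown")
    return EndType("unknown")


def split_cluster_label(label: str) -> tuple[str, str | None]:
    """Split a printed cluster column entry into (cluster, subcluster).

    Trailing digits denote a subcluster: ``CS2`` -> (``CS``, ``CS2``),
    ``A15`` -> (``A``, ``A15``). ``Singleton`` maps to (``SINGLETON``, None).
    """
    t = label.strip()
    if t.lower() == "singleton":
        return SINGLETON, None
    base = t.rstrip("0123456789")
    if not base:
        raise ValidationError(f"cluster label {label!r} has no letter prefix")
    if base == t:
        return t, None
    return base, t


@dataclass
class GenomeRecord:
    """One phage genome: identity, optional sequence, and profile metadata."""

    genome_id: str
    host_genus: str = ""
    host_species: str = ""
    host_strain: str = ""
    sequence: str | None = None
    length_bp: int = 0
    gc_percent: float | None = None
    end_type: EndType = field(default_factory=lambda: EndType("unknown"))
    cluster_label: str | None = None
    subcluster_label: str | None = None
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - IUPAC_NT
            if bad:
                raise FormatError(
                    f"record {self.genome_id!r}: non-IUPAC characters {sorted(bad)}"
                )
            if self.length_bp and self.length_bp != len(self.sequence):
                raise ValidationError(
                    f"record {self.genome_id!r}: length_bp {self.length_bp} != "
                    f"sequence length {len(self.sequence)}"
                )
            self.length_bp = len(self.sequence)
            recomputed = gc_percent_of(self.sequence)
            if self.gc_percent is None:
                self.gc_percent = recomputed
            elif abs(self.gc_percent - recomputed) > 0.15:
                raise ValidationError(
                    f"record {self.genome_id!r}: stored GC {self.gc_percent} "
                    f"disagrees with recomputed {recomputed:.2f}"
                )
        if self.gc_percent is not None and not 0.0 <= self.gc_percent <= 100.0:
            raise ValidationError(f"record {self.genome_id!r}: GC% out of [0, 100]")
        if self.subcluster_label is not None:
            base = self.subcluster_label.rstrip("0123456789")
            if self.cluster_label is None or base != self.cluster_label:
                raise ValidationError(
                    f"record {self.genome_id!r}: subcluster {self.subcluster_label!r} "
                    f"does not extend cluster {self.cluster_label!r}"
                )

    @property
    def is_singleton(self) -> bool:
        return self.cluster_label == SINGLETON


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene with its protein translation.

    Coordinates are 1-based inclusive on the genome named by ``genome_id``;
    ``pham_id`` is filled in by pham construction and is ``None`` until then.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    translation: str
    pham_id: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.translation:
            raise ValidationError(f"gene {self.gene_id!r}: empty translation")


@dataclass(frozen=True)
class AttTableRow:
    """One host attachment-site (attB) table row.

    ``host_start <= host_end`` always; ``orientation`` is ``reverse`` when the
    source printed the coordinate pair in descending order (minus-strand site).
    """

    site_id: str
    trna_label: str
    locus_tag: str
    host_start: int
    host_end: int
    orientation: str
    phage_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phage_names:
            raise ValidationError(f"att site {self.site_id!r} lists no phages")
        if self.host_start > self.host_end:
            raise ValidationError(f"att site {self.site_id!r}: start > end after normalization")

    @property
    def overlaps_trna(self) -> bool:
        return self.trna_label != INTERGENIC


# ---------------------------------------------------------------------------
# FASTA

def read_genome_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a genome FASTA into records with derived length and GC content."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(genome_id=rec.id, sequence=seq))
    if not seen:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_genome_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqs = []
    for r in records:
        if r.sequence is None:
            raise ValidationError(f"record {r.genome_id!r} carries no sequence")
        seqs.append(SeqRecord(Seq(r.sequence), id=r.genome_id, description=""))
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene tables

_TSV_GENE_COLUMNS = ["gene_id", "genome_id", "start", "end", "strand", "translation"]


def read_gene_table(
    path: str | Path,
    dialect: str = "tsv",
    genomes: Sequence[GenomeRecord] | None = None,
) -> list[GeneRecord]:
    """Read gene annotations from a TSV gene table or a GFF3 file.

    The TSV dialect has columns ``gene_id, genome_id, start, end, strand,
    translation``. GFF3 rows must carry a ``translation`` attribute; the
    seqid column names the genome. When ``genomes`` is supplied, gene
    coordinates are validated against genome lengths.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(_TSV_GENE_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"gene table missing columns {sorted(missing)}")
        genes = [
            GeneRecord(
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                translation=row.translation,
            )
            for row in df.itertuples()
        ]
    elif dialect == "gff3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")

    if genomes is not None:
        lengths = {g.genome_id: g.length_bp for g in genomes}
        for gene in genes:
            L = lengths.get(gene.genome_id)
            if L is not None and gene.end > L:
                raise ValidationError(
                    f"gene {gene.gene_id!r} ends at {gene.end}, beyond "
                    f"genome {gene.genome_id!r} length {L}"
                )
    return genes


def _read_gff3(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"GFF3 line does not have 9 columns: {line[:60]!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            attr_map = {}
            for item in attrs.split(";"):
                if "=" in item:
                    key, val = item.split("=", 1)
                    attr_map[key.strip()] = val.strip()
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            translation = attr_map.get("translation")
            if gene_id is None or translation is None:
                raise FormatError(
                    f"GFF3 feature on {seqid!r} lacks ID or translation attribute"
                )
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    translation=translation,
                )
            )
    return genes


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "genome_id": g.genome_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "translation": g.translation,
            }
            for g in genes
        ],
        columns=_TSV_GENE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged metadata fixtures

_DATA_DIR = Path(__file__).parent / "data"


def table1_path() -> Path:
    """Path to the packaged phage-profile metadata fixture (79 genomes)."""
    return _DATA_DIR / "table1_gordonia.tsv"


def table2_path() -> Path:
    """Path to the packaged host attB-site fixture (13 sites)."""
    return _DATA_DIR / "table2_attB.tsv"


def _split_host(text: str) -> tuple[str, str]:
    t = text.strip()
    if t.startswith("G. "):
        return "Gordonia", t[3:]
    parts = t.split(None, 1)
    if len(parts) == 2:
        return parts[0], parts[1]
    return t, ""


def read_metadata_table(path: str | Path | None = None) -> list[GenomeRecord]:
    """Read a phage-profile metadata TSV (defaults to the packaged fixture).

    Expected columns: ``name, host_species, strain, cluster, length_bp,
    gc_percent, end_type, accession``. The cluster column encodes subclusters
    by trailing digits; ``Singleton`` rows become cluster ``SINGLETON``.
    """
    if path is None:
        path = table1_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "host_species", "strain", "cluster", "length_bp",
                "gc_percent", "end_type", "accession"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        cluster, subcluster = split_cluster_label(row.cluster)
        genus, species = _split_host(row.host_species)
        records.append(
            GenomeRecord(
                genome_id=row.name,
                host_genus=genus,
                host_species=species,
                host_strain=row.strain,
                length_bp=int(str(row.length_bp).replace(",", "")),
                gc_percent=float(row.gc_percent),
                end_type=parse_end_type(row.end_type),
                cluster_label=cluster,
                subcluster_label=subcluster,
                accession=row.accession,
            )
        )
    return records


_COORD_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")


def read_att_table(path: str | Path | None = None) -> list[AttTableRow]:
    """Read an attB-site TSV (defaults to the packaged fixture).

    Descending coordinate pairs (minus-strand sites) are normalized to
    ``(min, max)`` with ``orientation='reverse'``.
    """
    if path is None:
        path = table2_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows: list[AttTableRow] = []
    seen: set[str] = set()
    for row in df.itertuples():
        if row.site_id in seen:
            raise ValidationError(f"duplicate att site id {row.site_id!r}")
        seen.add(row.site_id)
        m = _COORD_RE.match(row.coordinates.strip())
        if not m:
            raise FormatError(f"unparseable coordinates {row.coordinates!r}")
        a, b = int(m.group(1)), int(m.group(2))
        trna = row.trna.strip()
        rows.append(
            AttTableRow(
                site_id=row.site_id,
                trna_label=INTERGENIC if trna.lower() == "intergenic" else trna,
                locus_tag=row.locus_tag,
                host_start=min(a, b),
                host_end=max(a, b),
                orientation="reverse" if a > b else "forward",
                phage_names=tuple(p.strip() for p in row.phages.split(",") if p.strip()),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Matrix IO

def _check_symmetric(labels: Sequence[str], values) -> None:
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] != len(labels):
        raise ValidationError("matrix shape does not match its labels")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("matrix is not symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValidationError("matrix diagonal is not zero")


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write a symmetric labelled matrix as TSV (labels in first row/column)."""
    _check_symmetric(matrix.genome_ids, matrix.values)
    df = pd.DataFrame(matrix.values, index=matrix.genome_ids, columns=matrix.genome_ids)
    df.to_csv(path, sep="\t", index_label="genome_id", float_format="%.12g")


def read_matrix_tsv(path: str | Path):
    """Read a matrix written by :func:`write_matrix_tsv`; round-trip exact to 1e-10."""
    from .gene_content import GCDMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    return GCDMatrix(genome_ids=labels, values=df.to_numpy(dtype=float))


def _nexus_label(label: str) -> str:
    if re.search(r"\s", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_distances(matrix, path: str | Path) -> None:
    """Emit a Nexus DISTANCES block (triangle=both, labelled) for network tools."""
    labels = list(matrix.genome_ids)
    if not labels:
        raise ValidationError("cannot write a Nexus distances block with no taxa")
    _check_symmetric(labels, matrix.values)
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={n};\n")
        fh.write("    TAXLABELS " + " ".join(_nexus_label(x) for x in labels) + ";\nEND;\n\n")
        fh.write("BEGIN DISTANCES;\n")
        fh.write(f"    DIMENSIONS NTAX={n};\n")
        fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n")
        fh.write("    MATRIX\n")
        for i, label in enumerate(labels):
            row = " ".join(f"{matrix.values[i][j]:.10f}" for j in range(n))
            fh.write(f"        {_nexus_label(label)} {row}\n")
        fh.write("    ;\nEND;\n")
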