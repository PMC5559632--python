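"""Degenerate operator-motif scanning and attachment-site core discovery.

Temperate Cluster A-type phages regulate lysogeny through a repressor that
binds many short asymmetric operator sites ("stoperators") scattered
intergenically across the genome. The scanner reports every window on either
strand within a fixed Hamming distance (substitutions only, no indels) of a
consensus; the three published 13/14-base consensus strings ship as named
presets.

Integration of a tyrosine-integrase phage joins an attP site in the phage to
an attB site in the host chromosome through an identical "common core"
segment, typically 20-40 bp and often overlapping a host tRNA gene. Cores
are found as maximal exact common substrings between a phage and a host
sequence, in both phage orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .io_tables import GeneRecord, GenomeRecord, ValidationError

__all__ = [
    "MotifHit",
    "AttCore",
    "CONSENSUS_PRESETS",
    "scan_consensus",
    "intergenic_filter",
    "find_att_cores",
    "annotate_trna_overlap",
    "reverse_complement",
]

#: Published repressor-binding consensus strings, used verbatim as presets.
#: The Phlei string is 14 bases as printed.
CONSENSUS_PRESETS: dict[str, str] = {
    "Che12": "GGTGGTTGTCAAG",
    "Phlei": "GCTTGGGTGTCAAG",
    "KatherineG": "GGGGATTGTCAAG",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One consensus match: 1-based leftmost coordinate on the forward strand.

    ``matched_seq`` is the site read 5'->3' on the hit strand; ``intergenic``
    is ``None`` until :func:`intergenic_filter` annotates it.
    """

    genome_id: str
    start: int
    strand: str
    matched_seq: str
    n_mismatches: int
    intergenic: bool | None = None


@dataclass(frozen=True)
class AttCore:
    """A maximal shared core between a phage and a host sequence.

    Coordinates are 1-based inclusive in each sequence's own forward frame;
    ``orientation`` is ``reverse`` when the core matches the reverse
    complement of the phage segment. ``long_core`` flags cores exceeding the
    configured maximum length (they are reported whole, never truncated).
    """

    core_seq: str
    phage_start: int
    phage_end: int
    host_start: int
    host_end: int
    orientation: str
    long_core: bool = False
    trna_overlap: bool | None = None
    trna_locus: str | None = None

    @property
    def length(self) -> int:
        return len(self.core_seq)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _hamming_scan(seq_arr: np.ndarray, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """(0-based start, mismatches) for every window within max_mm of pattern.

    Ambiguous genome bases (anything outside ACGT) always count as mismatches.
    """
    k = len(pattern)
    n = seq_arr.size
    if n < k:
        return []
    mm = np.zeros(n - k + 1, dtype=np.int32)
    for i, base in enumerate(pattern):
        mm += seq_arr[i : n - k + 1 + i] != _BASE_CODE[base]
    starts = np.nonzero(mm <= max_mm)[0]
    return [(int(s), int(mm[s])) for s in starts]


def scan_consensus(
    genome: GenomeRecord,
    consensus: str,
    max_mismatch: int = 2,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Find all windows within ``max_mismatch`` substitutions of a consensus.

    Both strands are scanned by default; a minus-strand hit is reported at
    the leftmost forward-strand coordinate of its window, with ``matched_seq``
    read on the minus strand. Overlapping hits are all reported; output is
    sorted by start, then strand.
    """
    consensus = consensus.upper()
    if len(consensus) < 6:
        raise ValueError("consensus must be at least 6 bases")
    if set(consensus) - set("ACGT"):
        raise ValueError(f"consensus contains non-ACGT characters: {consensus!r}")
    if max_mismatch >= len(consensus):
        raise ValueError("max_mismatch must be smaller than the consensus length")
    if genome.sequence is None:
        raise ValidationError(f"genome {genome.genome_id!r} carries no sequence")
    seq = genome.sequence
    arr = _encode(seq)
    k = len(consensus)
    hits: list[MotifHit] = []
    for start0, n_mm in _hamming_scan(arr, consensus, max_mismatch):
        hits.append(
            MotifHit(genome.genome_id, start0 + 1, "+", seq[start0 : start0 + k], n_mm)
        )
    if both_strands:
        # A minus-strand site reads as revcomp(consensus) on the forward strand.
        for start0, n_mm in _hamming_scan(arr, reverse_complement(consensus), max_mismatch):
            hits.append(
                MotifHit(
                    genome.genome_id,
                    start0 + 1,
                    "-",
                    reverse_complement(seq[start0 : start0 + k]),
                    n_mm,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def intergenic_filter(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneRecord],
    drop_genic: bool = False,
) -> list[MotifHit]:
    """Annotate hits as intergenic (no base inside any gene; any overlap counts).

    All genes must belong to the scanned genome(s). With ``drop_genic`` the
    genic hits are removed instead of annotated.
    """
    by_genome: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append((g.start, g.end))
    hit_genomes = {h.genome_id for h in hits}
    unknown = {g for g in by_genome if g not in hit_genomes} if hits else set()
    if unknown:
        raise ValidationError(f"genes reference genomes not in the hit list: {sorted(unknown)}")
    out: list[MotifHit] = []
    for h in hits:
        k = len(h.matched_seq)
        h_start, h_end = h.start, h.start + k - 1
        genic = any(
            h_start <= g_end and g_start <= h_end
            for g_start, g_end in by_genome.get(h.genome_id, [])
        )
        if genic and drop_genic:
            continue
        out.append(replace(h, intergenic=not genic))
    return out


def find_att_cores(
    phage_seq: str,
    host_seq: str,
    min_len: int = 20,
    max_len: int = 40,
) -> list[AttCore]:
    """Maximal exact common substrings between a phage and a host sequence.

    Both orientations of the phage are searched. Every maximal shared
    segment of length >= ``min_len`` is reported once per (phage locus, host
    locus) pair; segments beyond ``max_len`` carry ``long_core=True``. Sorted
    by descending length, then coordinates.
    """
    if min_len < 12:
        raise ValueError("min_len must be >= 12")
    if max_len < min_len:
        raise ValueError("max_len must be >= min_len")
    phage_seq, host_seq = phage_seq.upper(), host_seq.upper()
    if len(phage_seq) < min_len or len(host_seq) < min_len:
        raise ValueError(f"both sequences must be at least min_len={min_len} long")

    host_index: dict[str, list[int]] = {}
    for j in range(len(host_seq) - min_len + 1):
        host_index.setdefault(host_seq[j : j + min_len], []).append(j)

    cores: list[AttCore] = []
    lp = len(phage_seq)
    for orientation, query in (("same", phage_seq), ("reverse", reverse_complement(phage_seq))):
        for i in range(len(query) - min_len + 1):
            positions = host_index.get(query[i : i + min_len])
            if not positions:
                continue
            for j in positions:
                # Report each maximal match once: only from its left edge.
                if i > 0 and j > 0 and query[i - 1] == host_seq[j - 1]:
                    continue
                length = min_len
                while (i + length < len(query) and j + length < len(host_seq)
                       and query[i + length] == host_seq[j + length]):
                    length += 1
                if orientation == "same":
                    p_start, p_end = i + 1, i + length
                else:
                    p_start, p_end = lp - (i + length) + 1, lp - i
                cores.append(
                    AttCore(
                        core_seq=query[i : i + length],
                        phage_start=p_start,
                        phage_end=p_end,
                        host_start=j + 1,
                        host_end=j + length,
                        orientation=orientation,
                        long_core=length > max_len,
                    )
                )
    cores.sort(key=lambda c: (-c.length, c.phage_start, c.host_start, c.orientation))
    return cores


def annotate_trna_overlap(
    cores: Sequence[AttCore],
    host_features: Sequence[tuple[str, str, int, int]],
) -> list[AttCore]:
    """Mark cores whose host interval intersects (>= 1 bp) a tRNA feature.

    ``host_features`` rows are ``(locus_tag, type, start, end)`` with 1-based
    inclusive coordinates; on ties the first tRNA by coordinate wins.
    """
    trnas = sorted(
        ((start, end, locus) for locus, ftype, start, end in host_features
         if ftype.lower() == "trna"),
    )
    out: list[AttCore] = []
    for core in cores:
        locus: str | None = None
        for start, end, tag in trnas:
            if core.host_start <= end and start <= core.host_end:
                locus = tag
                break
        out.append(replace(core, trna_overlap=locus is not None, trna_locus=locus))
    return out
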