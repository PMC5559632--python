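"""Stoperator consensus scanning and attP/attB common-core discovery."""

import math

import numpy as np
import pytest
from scipy.stats import binom

from phagemosaic.io_tables import GeneRecord, GenomeRecord
from phagemosaic.site_finder import (
    CONSENSUS_PRESETS,
    annotate_trna_overlap,
    find_att_cores,
    intergenic_filter,
    reverse_complement,
    scan_consensus,
)

CONSENSUS = CONSENSUS_PRESETS["KatherineG"]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def genome(seq, gid="phage1"):
    return GenomeRecord(genome_id=gid, sequence=seq)


def plant(seq, pos0, insert):
    return seq[:pos0] + insert + seq[pos0 + len(insert):]


def substituted(rng, motif, n_sub):
    out = list(motif)
    for i in rng.choice(len(motif), size=n_sub, replace=False):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def brute_force_scan(seq, consensus, max_mm):
    """Oracle: per-window character comparison on both strands."""
    hits = []
    k = len(consensus)
    rc = reverse_complement(consensus)
    for pattern, strand in ((consensus, "+"), (rc, "-")):
        for start0 in range(len(seq) - k + 1):
            window = seq[start0 : start0 + k]
            mm = sum(1 for a, b in zip(window, pattern) if a != b)
            if mm <= max_mm:
                hits.append((start0 + 1, strand, mm))
    return sorted(hits)


class TestScanConsensus:
    def test_exact_planted_hit(self):
        rng = np.random.default_rng(0)
        seq = plant(random_seq(rng, 2000), 99, CONSENSUS)
        hits = [h for h in scan_consensus(genome(seq), CONSENSUS) if h.start == 100]
        assert hits and hits[0].strand == "+" and hits[0].n_mismatches == 0

    def test_three_substitutions_not_reported(self):
        rng = np.random.default_rng(1)
        variant = substituted(rng, CONSENSUS, 3)
        seq = plant(random_seq(rng, 2000), 499, variant)
        hits = scan_consensus(genome(seq), CONSENSUS, max_mismatch=2)
        assert not any(h.start == 500 for h in hits)

    def test_reverse_complement_hit_on_minus_strand(self):
        rng = np.random.default_rng(2)
        seq = plant(random_seq(rng, 2000), 299, reverse_complement(CONSENSUS))
        hits = [h for h in scan_consensus(genome(seq), CONSENSUS) if h.start == 300]
        assert hits and hits[0].strand == "-"
        assert hits[0].matched_seq == CONSENSUS

    def test_strand_symmetry_under_genome_reversal(self):
        rng = np.random.default_rng(3)
        seq = plant(plant(random_seq(rng, 3000), 99, CONSENSUS),
                    1999, reverse_complement(CONSENSUS))
        k = len(CONSENSUS)
        L = len(seq)
        fwd = scan_consensus(genome(seq), CONSENSUS)
        rev = scan_consensus(genome(reverse_complement(seq), gid="phage1"), CONSENSUS)
        mapped = sorted((L - h.start - k + 2, {"+": "-", "-": "+"}[h.strand],
                         h.n_mismatches) for h in rev)
        assert mapped == sorted((h.start, h.strand, h.n_mismatches) for h in fwd)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 10_000)
        for pos, n_sub in ((1000, 0), (3000, 1), (5000, 2), (7000, 3)):
            seq = plant(seq, pos, substituted(rng, CONSENSUS, n_sub))
        hits = scan_consensus(genome(seq), CONSENSUS, max_mismatch=2)
        assert sorted((h.start, h.strand, h.n_mismatches) for h in hits) == \
            brute_force_scan(seq, CONSENSUS, 2)

    def test_planted_recall_and_background_rate(self):
        """<=2 substitutions always found, 3 never; background near binomial."""
        rng = np.random.default_rng(6)
        n_bg = 200_000
        seq = random_seq(rng, n_bg)
        planted = {}
        for i, n_sub in enumerate([0, 1, 1, 2, 2, 2, 3, 3]):
            pos0 = 1000 + i * 500
            seq = plant(seq, pos0, substituted(rng, CONSENSUS, n_sub))
            planted[pos0 + 1] = n_sub
        hits = scan_consensus(genome(seq), CONSENSUS, max_mismatch=2)
        starts = {h.start for h in hits if h.strand == "+"}
        for pos, n_sub in planted.items():
            assert (pos in starts) == (n_sub <= 2)
        # Background: windows within 2 mismatches of a 13-mer, both strands.
        k = len(CONSENSUS)
        p_hit = float(binom.cdf(2, k, 0.75))
        n_windows = 2 * (n_bg - k + 1)
        expected = n_windows * p_hit
        sd = math.sqrt(n_windows * p_hit * (1 - p_hit))
        n_background = len(hits) - sum(1 for s in planted.values() if s <= 2)
        assert abs(n_background - expected) <= 3 * sd + 1

    def test_ambiguous_consensus_rejected(self):
        with pytest.raises(ValueError):
            scan_consensus(genome("ACGT" * 100), "GGGGANNGTCAAG")

    def test_presets_are_verbatim(self):
        assert CONSENSUS_PRESETS["Che12"] == "GGTGGTTGTCAAG"
        assert CONSENSUS_PRESETS["Phlei"] == "GCTTGGGTGTCAAG"  # 14 bases as printed
        assert CONSENSUS_PRESETS["KatherineG"] == "GGGGATTGTCAAG"


class TestIntergenicFilter:
    def make_hit(self, start, k=13):
        return scan_consensus(
            genome(plant("A" * 400, start - 1, CONSENSUS), gid="p1"),
            CONSENSUS, both_strands=False,
        )[0]

    def gene(self, start, end):
        return GeneRecord("g1", "p1", start, end, "+", "M")

    def test_hit_inside_gene_is_genic(self):
        annotated = intergenic_filter([self.make_hit(100)], [self.gene(50, 200)])
        assert annotated[0].intergenic is False

    def test_hit_between_genes_is_intergenic(self):
        annotated = intergenic_filter([self.make_hit(100)], [self.gene(200, 300)])
        assert annotated[0].intergenic is True

    def test_one_base_overlap_counts_as_genic(self):
        hit = self.make_hit(100)  # covers 100..112
        annotated = intergenic_filter([hit], [self.gene(112, 150)])
        assert annotated[0].intergenic is False
        annotated = intergenic_filter([hit], [self.gene(113, 150)])
        assert annotated[0].intergenic is True

    def test_drop_genic_removes_hits(self):
        hits = [self.make_hit(100)]
        assert intergenic_filter(hits, [self.gene(50, 200)], drop_genic=True) == []


def dp_common_substrings(a, b, min_len):
    """O(n*m) dynamic-programming oracle for maximal common substrings.

    Returns {(a_start_1based, b_start_1based, length)} of maximal matches.
    """
    import numpy as np

    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    out = set()
    for i in range(len(a)):
        cur = np.zeros(len(b) + 1, dtype=np.int32)
        cur[1:] = np.where(arr_b == arr_a[i], prev[:-1] + 1, 0)
        # A run ending at (i, j) is maximal if it cannot extend to (i+1, j+1).
        if i + 1 < len(a):
            ext = np.zeros(len(b) + 1, dtype=bool)
            ext[:-1] = arr_b == arr_a[i + 1]
            ends = np.nonzero((cur >= min_len) & ~ext)[0]
        else:
            ends = np.nonzero(cur >= min_len)[0]
        for j in ends:
            length = int(cur[j])
            out.add((i - length + 2, int(j) - length + 1, length))
        prev = cur
    return out


class TestFindAttCores:
    def test_planted_37bp_core(self):
        rng = np.random.default_rng(10)
        core = random_seq(rng, 37)
        # Mismatching flanks keep the shared segment maximal at exactly 37 bp.
        phage = plant(random_seq(rng, 3000), 499, "A" + core + "A")
        host = plant(random_seq(rng, 5000), 1999, "C" + core + "C")
        cores = find_att_cores(phage, host)
        top = cores[0]
        assert top.length == 37
        assert top.core_seq == core
        assert (top.phage_start, top.host_start) == (501, 2001)
        assert top.orientation == "same"
        assert not top.long_core

    def test_below_min_len_not_reported(self):
        rng = np.random.default_rng(11)
        core = random_seq(rng, 19)
        phage = plant(random_seq(rng, 1000), 100, core)
        host = plant(random_seq(rng, 1000), 500, core)
        assert [c for c in find_att_cores(phage, host, min_len=20)
                if c.core_seq == core] == []

    def test_reverse_orientation_core_found(self):
        rng = np.random.default_rng(12)
        core = random_seq(rng, 30)
        phage = plant(random_seq(rng, 2000), 699, "A" + reverse_complement(core) + "A")
        host = plant(random_seq(rng, 2000), 299, "C" + core + "C")
        hits = [c for c in find_att_cores(phage, host) if c.length >= 30]
        assert hits and hits[0].orientation == "reverse"
        assert hits[0].host_start == 301
        assert (hits[0].phage_start, hits[0].phage_end) == (701, 730)

    def test_long_core_flagged_not_truncated(self):
        rng = np.random.default_rng(13)
        core = random_seq(rng, 60)
        phage = plant(random_seq(rng, 1000), 99, "A" + core + "A")
        host = plant(random_seq(rng, 1000), 399, "C" + core + "C")
        top = find_att_cores(phage, host, min_len=20, max_len=40)[0]
        assert top.length == 60 and top.long_core

    @pytest.mark.parametrize("seed", [14, 15])
    def test_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        phage = random_seq(rng, 3000)
        host = random_seq(rng, 4000)
        for pos_p, pos_h, n in ((200, 700, 24), (1500, 2500, 31)):
            seg = random_seq(rng, n)
            phage = plant(phage, pos_p, seg)
            host = plant(host, pos_h, seg)
        got = {
            (c.phage_start, c.host_start, c.length)
            for c in find_att_cores(phage, host, min_len=20)
            if c.orientation == "same"
        }
        assert got == dp_common_substrings(phage, host, 20)
        got_rev = {
            (c.phage_start, c.host_start, c.length)
            for c in find_att_cores(phage, host, min_len=20)
            if c.orientation == "reverse"
        }
        Lp = len(phage)
        oracle_rev = {
            (Lp - i - length + 2, j, length)
            for i, j, length in dp_common_substrings(reverse_complement(phage), host, 20)
        }
        assert got_rev == oracle_rev

    def test_role_symmetry(self):
        rng = np.random.default_rng(16)
        seg = random_seq(rng, 26)
        a = plant(random_seq(rng, 1500), 300, seg)
        b = plant(random_seq(rng, 1500), 900, seg)
        fwd = {(c.phage_start, c.host_start, c.length, c.orientation)
               for c in find_att_cores(a, b)}
        swapped = {(c.host_start, c.phage_start, c.length, c.orientation)
                   for c in find_att_cores(b, a)}
        assert {x for x in fwd if x[3] == "same"} == {x for x in swapped if x[3] == "same"}

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            find_att_cores("ACGTACGTACGT", "ACGT" * 100, min_len=20)


class TestAnnotateTrnaOverlap:
    def core_at(self, start, end):
        from phagemosaic.site_finder import AttCore

        return AttCore("A" * (end - start + 1), 1, end - start + 1, start, end, "same")

    FEATURES = [("trnA", "tRNA", 1000, 1075), ("genX", "CDS", 2000, 2900)]

    def test_core_inside_trna(self):
        (core,) = annotate_trna_overlap([self.core_at(1010, 1040)], self.FEATURES)
        assert core.trna_overlap and core.trna_locus == "trnA"

    def test_core_in_feature_free_region_intergenic(self):
        (core,) = annotate_trna_overlap([self.core_at(5000, 5030)], self.FEATURES)
        assert core.trna_overlap is False and core.trna_locus is None

    def test_non_trna_feature_does_not_count(self):
        (core,) = annotate_trna_overlap([self.core_at(2100, 2130)], self.FEATURES)
        assert core.trna_overlap is False

    def test_one_bp_boundary(self):
        (just_out,) = annotate_trna_overlap([self.core_at(970, 999)], self.FEATURES)
        assert just_out.trna_overlap is False
        (just_in,) = annotate_trna_overlap([self.core_at(970, 1000)], self.FEATURES)
        assert just_in.trna_overlap is True
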