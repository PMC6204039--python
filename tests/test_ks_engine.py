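import math
import random

import numpy as np
import pytest

from wgdtrace import ks_engine as K
from wgdtrace.formats_io import CdsRecord

from oracles import ng86_brute

SENSE = K.SENSE_CODONS


def _rec(gid, seq):
    return CdsRecord(gene_id=gid, species=gid.split("_")[0], sequence=seq)


class TestProteinAlignment:
    def test_identical_sequences_gapless(self):
        aln = K.align_proteins_global("MKVA", "MKVA")
        assert aln.seq_a == aln.seq_b == "MKVA"

    def test_single_gap_opposite_k(self):
        aln = K.align_proteins_global("MKV", "MV")
        assert aln.seq_a == "MKV"
        assert aln.seq_b == "M-V"

    def test_symmetry_under_swap(self):
        a, b = "MKVLLY", "MKLY"
        f = K.align_proteins_global(a, b)
        r = K.align_proteins_global(b, a)
        assert (f.seq_a.replace("-", ""), f.seq_b.replace("-", "")) == (a, b)
        assert (r.seq_a.replace("-", ""), r.seq_b.replace("-", "")) == (b, a)

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            K.align_proteins_global("MKX1", "MK")


class TestBackTranslate:
    def test_gapless_is_codon_chunking(self):
        a, b = _rec("S_a", "ATGAAAGTT"), _rec("S_b", "ATGAAAGTA")
        aln = K.align_proteins_global(a.protein, b.protein)
        ca = K.back_translate(aln, a, b)
        assert ca.codons_a == ("ATG", "AAA", "GTT")
        assert ca.codons_b == ("ATG", "AAA", "GTA")

    def test_gap_column_bookkeeping(self):
        a, b = _rec("S_a", "ATGAAA"), _rec("S_b", "ATGAAACTT")
        aln = K.ProteinAlignment(seq_a="MK-", seq_b="MKL")
        ca = K.back_translate(aln, a, b)
        assert ca.codons_a[2] == "---"
        assert ca.codons_b[2] == "CTT"

    def test_translation_mismatch_raises(self):
        a, b = _rec("S_a", "ATGAAA"), _rec("S_b", "ATGAAA")
        aln = K.ProteinAlignment(seq_a="MR", seq_b="MK")  # a does not encode MR
        with pytest.raises(ValueError, match="column"):
            K.back_translate(aln, a, b)


def _codon_aln(codons_a, codons_b):
    return K.CodonAlignment(gene_a="S_a", gene_b="S_b",
                            codons_a=tuple(codons_a), codons_b=tuple(codons_b))


class TestNg86Counts:
    def test_fourfold_identity(self):
        c = K.ng86_counts(_codon_aln(["GCT"] * 6, ["GCT"] * 6))
        assert c.S == pytest.approx(6.0)
        assert c.N == pytest.approx(12.0)
        assert (c.Sd, c.Nd) == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        c = K.ng86_counts(_codon_aln(["GCT"] * 6, ["GCT"] * 5 + ["GCC"]))
        assert c.Sd == pytest.approx(1.0)
        assert c.Nd == pytest.approx(0.0)

    def test_two_difference_codon_matches_pathway_average(self):
        # TTT (Phe) vs GTA (Val): both orders enumerated explicitly
        c = K.ng86_counts(_codon_aln(["TTT"], ["GTA"]))
        s_brute, n_brute, sd_brute, nd_brute = ng86_brute(["TTT"], ["GTA"])
        assert c.Sd == pytest.approx(sd_brute)
        assert c.Nd == pytest.approx(nd_brute)

    def test_gap_columns_skipped(self):
        c = K.ng86_counts(_codon_aln(["GCT", "---", "GCT"], ["GCT", "AAA", "GCC"]))
        assert c.L == 2

    def test_all_columns_skipped_raises(self):
        with pytest.raises(ValueError):
            K.ng86_counts(_codon_aln(["---"], ["AAA"]))

    def test_oracle_equivalence_small_random(self):
        rng = random.Random(42)
        for _ in range(100):
            n = rng.randint(1, 5)
            ca = [rng.choice(SENSE) for _ in range(n)]
            cb = [rng.choice(SENSE) for _ in range(n)]
            s, nn, sd, nd = ng86_brute(ca, cb)
            got = K.ng86_counts(_codon_aln(ca, cb))
            assert got.S == pytest.approx(s, abs=1e-9)
            assert got.N == pytest.approx(nn, abs=1e-9)
            assert got.Sd == pytest.approx(sd, abs=1e-9)
            assert got.Nd == pytest.approx(nd, abs=1e-9)


class TestKsEstimate:
    def test_zero_difference_zero_ks(self):
        a = _rec("S_a", "GCT" * 6)
        est = K.ks_estimate(K.NgCounts(S=6, N=12, Sd=0, Nd=0, L=6), a, a)
        assert est.ks == 0.0

    def test_closed_form_value(self):
        a = _rec("S_a", "GCT" * 6)
        est = K.ks_estimate(K.NgCounts(S=6, N=12, Sd=1, Nd=0, L=6), a, a)
        assert est.p_s == pytest.approx(1 / 6)
        assert est.ks == pytest.approx(-0.75 * math.log(1 - 4 / 3 * (1 / 6)))
        assert est.ks == pytest.approx(0.1885, abs=5e-4)

    def test_saturation_sentinel(self):
        a = _rec("S_a", "GCT" * 6)
        est = K.ks_estimate(K.NgCounts(S=10, N=20, Sd=8, Nd=0, L=10), a, a)
        assert est.saturated
        assert not math.isfinite(est.ks)

    def test_degenerate_counts_raise(self):
        a = _rec("S_a", "GCT" * 6)
        with pytest.raises(ValueError):
            K.ks_estimate(K.NgCounts(S=0, N=18, Sd=0, Nd=0, L=6), a, a)

    def test_symmetric_under_pair_swap(self):
        a = _rec("S_a", "GCTGCAACGCCTTCTGGG")
        b = _rec("S_b", "GCCGCGACGCCATCAGGA")
        assert K.ks_pair(a, b).ks == K.ks_pair(b, a).ks

    def test_monotone_in_sd(self):
        a = _rec("S_a", "GCT" * 10)
        prev = -1.0
        for sd in range(0, 7):
            ks = K.ks_estimate(K.NgCounts(S=10, N=20, Sd=sd, Nd=0, L=10), a, a).ks
            assert ks > prev
            prev = ks


class TestGc3AndFilter:
    def test_gc3_fraction(self):
        # codon third positions T, G, A -> one of three is G/C
        assert K.gc3("GCTGCGGCA") == pytest.approx(1 / 3)
        assert K.gc3("GCGGCC") == pytest.approx(1.0)

    def _est(self, ga, gb, ks, g3):
        return K.KsEstimate(gene_a=ga, gene_b=gb, ks=ks, ka=0.1, p_s=0.1,
                            p_n=0.05, gc3=g3, flags=frozenset())

    def test_ks_above_max_excluded(self):
        kept, rej = K.filter_ks_pairs([self._est("Aa_1", "Aa_2", 2.3, 0.5)])
        assert kept == []
        assert rej[0][1] == "KS_GT_MAX"

    def test_gc3_rule_only_for_flagged_taxa(self):
        grassy = self._est("Orysa_1", "Orysa_2", 0.5, 0.80)
        other = self._est("Vitvi_1", "Vitvi_2", 0.5, 0.80)
        kept, rej = K.filter_ks_pairs([grassy, other],
                                      gc3_taxa={"Orysa", "Sorbi"})
        assert [e.gene_a for e in kept] == ["Vitvi_1"]
        assert rej[0][1] == "GC3_HIGH"

    def test_empty_input(self):
        assert K.filter_ks_pairs([]) == ([], [])


class TestSimulatedRecovery:
    def test_ks_within_three_binomial_se_of_truth(self, benchmark_sim):
        """NG86 Ks of simulated pairs tracks the true synonymous distance."""
        _, truth, seqs = benchmark_sim
        checked = 0
        for p in truth.paralog_pairs("A"):
            if checked >= 40:
                break
            d = p["distance"]
            if d > 1.0:
                continue
            est = K.ks_pair(seqs[p["gene_a"]], seqs[p["gene_b"]])
            L = 300.0
            p_true = 0.75 * (1 - math.exp(-4 * d / 3))
            se_p = math.sqrt(p_true * (1 - p_true) / L)
            se_d = se_p / (1 - 4 * p_true / 3)
            assert abs(est.ks - d) <= 3 * se_d
            checked += 1
        assert checked >= 30
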