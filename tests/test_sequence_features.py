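import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txpred._tables import SENSE_CODONS
from txpred.adaptation import ContextPSSM, build_context_pssm
from txpred.io_formats import TranscriptRecord
from txpred.sequence_features import (
    atg_context_scores, codon_and_pair_features, codon_usage_arrays,
    composition_features, count_atg, find_sorfs, find_uorfs, length_features,
)

from .oracles import scan_sorfs, scan_uorfs

sense_codon = st.sampled_from(SENSE_CODONS)
random_orf = st.lists(sense_codon, min_size=1, max_size=40).map(
    lambda inner: "ATG" + "".join(inner) + "TAA"
)
utr_seq = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestLengths:
    def test_ratios_forced_by_arithmetic(self):
        rec = TranscriptRecord("g", "ACGT", "ATGAAATAA", "")
        f = length_features(rec)
        assert f["TRANSCRIPT.length.ratio_utr5_orf"] == pytest.approx(4 / 9)
        assert f["ORF.length.codons"] == 3
        assert f["UTR3.length.nt"] == 0
        assert f["TRANSCRIPT.length.ratio_utr3_orf"] == 0


class TestComposition:
    def test_gc_and_overlapping_atg_count(self):
        rec = TranscriptRecord("g", "ATGATG", "ATGC" * 24 + "ATGTAA", "")
        f = composition_features(rec)
        assert f["UTR5.composition.n_atg"] == 2
        assert f["UTR5.composition.gc"] == pytest.approx(1 / 3)

    def test_overlapping_scan_counts_shared_prefix(self):
        assert count_atg("ATGATGATG") == 3
        assert count_atg("ATATGG") == 1

    def test_short_orf_window_truncates_to_whole_segment(self):
        rec = TranscriptRecord("g", "", "ATGAAATAA", "")
        f = composition_features(rec)
        assert f["ORF.composition.first30c.gc"] == f["ORF.composition.gc"]


class TestCodonUsage:
    def test_two_codon_gene_frequencies(self):
        f = codon_and_pair_features("ATGAAATAA")
        assert f["ORF.codon.ATG"] == pytest.approx(0.5)
        assert f["ORF.codon.AAA"] == pytest.approx(0.5)
        assert f["ORF.codon_pair.ATG_AAA"] == pytest.approx(1.0)
        assert f["ORF.aa.M"] == pytest.approx(0.5)
        assert f["ORF.aa.K"] == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(random_orf)
    def test_frequency_families_sum_to_one(self, orf):
        codon, aa, cpair, apair = codon_usage_arrays(orf)
        for arr in (codon, aa, cpair, apair):
            assert arr.sum() == pytest.approx(1.0, abs=1e-12)

    def test_internal_stop_excluded_from_sense_frequencies(self):
        codon, _, _, _ = codon_usage_arrays("ATGTAAAAATAA")
        assert codon.sum() == pytest.approx(1.0)
        names = dict(zip(SENSE_CODONS, codon))
        assert names["ATG"] == pytest.approx(0.5)
        assert names["AAA"] == pytest.approx(0.5)


class TestUorfs:
    @pytest.mark.parametrize(
        "utr5, count, dist",
        [
            ("ATGTAA", 1, 6),          # uORF by construction
            ("ATGAAA", 0, 6),          # ATG without in-frame UTR stop
            ("CCATGCCTAACC", 0, 10),   # TAA at 7 is frame-shifted: no uORF
            ("CCATGCCCTAACC", 1, 11),  # ATG at 2, TAA in frame at 8
            ("CCCCCC", 0, 7),          # no ATG: sentinel length+1
        ],
    )
    def test_examples(self, utr5, count, dist):
        assert find_uorfs(utr5) == (count, dist)

    def test_stop_in_orf_flag_extends_search(self):
        # ATG at the very 3' end of the UTR; the stop falls inside the ORF
        utr5, orf = "CCCATG", "ATGTAAAAATAA"
        assert find_uorfs(utr5)[0] == 0
        assert find_uorfs(utr5, allow_stop_in_orf=True, orf=orf)[0] == 1

    @settings(max_examples=60, deadline=None)
    @given(utr_seq)
    def test_matches_bruteforce_scan(self, utr5):
        assert find_uorfs(utr5)[0] == scan_uorfs(utr5)

    @settings(max_examples=30, deadline=None)
    @given(utr_seq)
    def test_prepending_nucleotides_respects_start_anchor(self, utr5):
        # distances are measured to the START codon: prepending C's (which
        # cannot create an ATG) leaves an existing first-ATG distance alone
        # and grows the no-ATG sentinel by exactly N
        base = find_uorfs(utr5)[1]
        grown = find_uorfs("C" * 7 + utr5)[1]
        if "ATG" in utr5:
            assert grown == base
        else:
            assert grown == base + 7


class TestSorfs:
    def test_no_alternative_atg_defaults(self):
        f = find_sorfs("ATGAAATAA")
        assert f["ORF.init.n_sorf_f1"] == 0
        assert f["ORF.init.first_alt_atg_dist"] == 10  # len + 1 sentinel

    def test_shifted_orf_with_inframe_stop(self):
        # ATG at offset 4 (frame 1) with TAA at offset 7 in its frame
        orf = "ATGGATGTAACCTAA"
        f = find_sorfs(orf)
        assert f["ORF.init.n_sorf_f1"] == 1
        assert f["ORF.init.first_alt_atg_dist"] == 4

    @settings(max_examples=60, deadline=None)
    @given(random_orf)
    def test_matches_bruteforce_scan(self, orf):
        f = find_sorfs(orf)
        n1, n2 = scan_sorfs(orf)
        assert (f["ORF.init.n_sorf_f1"], f["ORF.init.n_sorf_f2"]) == (n1, n2)

    @settings(max_examples=30, deadline=None)
    @given(random_orf)
    def test_reported_first_alternative_is_an_atg(self, orf):
        d = find_sorfs(orf)["ORF.init.first_alt_atg_dist"]
        if d <= len(orf) - 3:
            assert orf[int(d) : int(d) + 3] == "ATG"


class TestContextScores:
    def _uniform_pssm(self):
        return ContextPSSM(logodds=np.zeros((9, 4)),
                           background=np.full(4, 0.25))

    def test_uniform_pssm_scores_zero(self):
        rec = TranscriptRecord("g", "ACGTACGTAC", "ATGAAATAA", "ACGT")
        f = atg_context_scores(rec, self._uniform_pssm())
        assert all(v == 0.0 for v in f.values())

    def test_single_alternative_best_equals_mean(self, tiny_records):
        pssm = build_context_pssm(tiny_records[:20])
        rec = TranscriptRecord("g", "CCCCCCCCC", "ATGCCCATGGATTAA", "CCC")
        f = atg_context_scores(rec, pssm)
        assert f["ORF.init.best_rel_context"] == pytest.approx(
            f["ORF.init.mean_rel_context"])

    def test_segment_without_alternatives_defaults_to_zero(self, tiny_records):
        pssm = build_context_pssm(tiny_records[:20])
        rec = TranscriptRecord("g", "CCCCCC", "ATGCCCTAA", "CCCC")
        f = atg_context_scores(rec, pssm)
        assert f["UTR5.init.best_rel_context"] == 0.0
        assert f["UTR3.init.mean_rel_context"] == 0.0
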