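import inspect

import numpy as np
import pytest

from txpred._tables import DEFAULT_TRNA_COPIES, SENSE_CODONS
from txpred.adaptation import (
    CodonWeights, build_context_pssm, cai_weights_from_reference, gene_index,
    gene_index_matrix, codon_count_matrix, scheme_a_reference_selection,
    scheme_b_optimize, tai_weights_from_copy_numbers,
)
from txpred.io_formats import TranscriptRecord

NO_WOBBLE = {"G:T": 1.0, "I:C": 1.0, "I:A": 1.0, "T:G": 1.0}


def _w(weights, codon):
    return weights.as_dict()[codon]


class TestTaiWeights:
    def test_perfect_match_anticodon_normalizes_to_one(self):
        w = tai_weights_from_copy_numbers({"AAA": 5}, s_params=NO_WOBBLE)
        assert _w(w, "TTT") == 1.0

    def test_scale_invariance_under_copy_doubling(self):
        base = tai_weights_from_copy_numbers()
        doubled = tai_weights_from_copy_numbers(
            {a: 2 * c for a, c in DEFAULT_TRNA_COPIES.items()})
        assert np.allclose(base.w, doubled.w)

    def test_toy_table_hand_computation(self):
        # Watson-Crick anticodons for TTT/TTC/TTA/CTT with copies 5,5,10,1
        copies = {"AAA": 5, "GAA": 5, "TAA": 10, "AAG": 1}
        w = tai_weights_from_copy_numbers(copies, s_params=NO_WOBBLE)
        assert _w(w, "TTT") == pytest.approx(0.5)
        assert _w(w, "TTC") == pytest.approx(0.5)
        assert _w(w, "TTA") == pytest.approx(1.0)
        assert _w(w, "CTT") == pytest.approx(0.1)

    def test_wobble_contributes_at_reduced_efficiency(self):
        # codon TTT read by WC anticodon AAA and by GAA at (1 - 0.41)
        w = tai_weights_from_copy_numbers({"AAA": 5, "GAA": 5},
                                          s_params={**NO_WOBBLE, "G:T": 0.41})
        expected = (5 + 0.59 * 5) / 5  # before max-normalization
        assert _w(w, "TTT") / _w(w, "TTC") == pytest.approx(expected)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            tai_weights_from_copy_numbers({"AAA": 0})

    def test_zero_weights_imputed_into_unit_interval(self):
        w = tai_weights_from_copy_numbers({"AAA": 5}, s_params=NO_WOBBLE)
        assert np.all(w.w > 0) and np.all(w.w <= 1)


class TestGeneIndex:
    def test_all_unit_weights_give_index_one(self):
        w = CodonWeights(np.ones(61), "reference_set")
        assert gene_index("ATGAAATAA", w) == 1.0

    def test_two_codon_geometric_mean(self):
        vals = np.ones(61)
        vals[SENSE_CODONS.index("AAA")] = 0.25
        w = CodonWeights(vals, "reference_set")
        assert gene_index("ATGAAATAA", w) == pytest.approx(0.5)

    def test_invariant_to_codon_order(self):
        rng = np.random.default_rng(0)
        w = CodonWeights(rng.uniform(0.1, 1.0, 61) / 1.0, "reference_set")
        w.w /= w.w.max()
        a = gene_index("ATGAAACCCGGGTAA", w)
        b = gene_index("ATGGGGCCCAAATAA", w)
        assert a == pytest.approx(b)

    def test_matrix_form_matches_scalar_form(self):
        rng = np.random.default_rng(1)
        w = rng.uniform(0.2, 1.0, 61)
        w /= w.max()
        cw = CodonWeights(w, "reference_set")
        orfs = ["ATGAAACCCTAA", "ATGGGGTAA"]
        counts = codon_count_matrix(orfs)
        mat = gene_index_matrix(counts, w)
        assert mat == pytest.approx([gene_index(o, cw) for o in orfs])


class TestCaiWeights:
    def test_single_synonym_reference(self):
        # reference uses only AAA for Lys: AAA gets 1, AAG the pseudocount ratio
        w = cai_weights_from_reference(["ATGAAAAAATAA"])
        assert _w(w, "AAA") == 1.0
        assert _w(w, "AAG") == pytest.approx(0.5 / 2.0)

    def test_count_ratio_three_to_one(self):
        w = cai_weights_from_reference(["ATGAAAAAAAAAAAGTAA"])
        assert _w(w, "AAG") == pytest.approx(1 / 3)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValueError):
            cai_weights_from_reference([])


class TestSchemeAReferenceSelection:
    def test_full_fraction_returns_all(self, tiny_records):
        tai = tai_weights_from_copy_numbers()
        ref = scheme_a_reference_selection(tiny_records, tai, 1.0)
        assert len(ref) == len(tiny_records)

    def test_top_fraction_selects_highest_tai(self, tiny_records):
        tai = tai_weights_from_copy_numbers()
        ref = scheme_a_reference_selection(tiny_records, tai, 0.2)
        chosen = {r.gene_id for r in ref}
        scores = {r.gene_id: gene_index(r.orf, tai) for r in tiny_records}
        cutoff = min(scores[g] for g in chosen)
        assert all(scores[g] <= cutoff or g in chosen for g in scores)

    def test_rejects_expression_trained_weights(self, tiny_records):
        w = CodonWeights(np.ones(61), "train_optimized")
        with pytest.raises(ValueError, match="expression-free"):
            scheme_a_reference_selection(tiny_records, w, 0.5)

    def test_scheme_a_interface_never_accepts_expression(self):
        """Scheme-A constructors have no parameter that could carry
        expression measurements — the no-leakage guarantee is structural."""
        from txpred.extract import ExtractConfig, extract_features
        for fn in (tai_weights_from_copy_numbers, cai_weights_from_reference,
                   scheme_a_reference_selection, build_context_pssm,
                   extract_features):
            params = set(inspect.signature(fn).parameters)
            assert not params & {"expression", "mrna", "train_mrna", "y"}, fn
        assert not {f.name for f in
                    ExtractConfig.__dataclass_fields__.values()} & {
                        "expression", "mrna"}


class TestSchemeBOptimize:
    def _setup(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        w_true = rng.uniform(0.2, 1.0, 61)
        w_true /= w_true.max()
        codons = np.array(SENSE_CODONS)
        orfs = ["ATG" + "".join(codons[rng.integers(0, 61, 60)]) + "TAA"
                for _ in range(n)]
        counts = codon_count_matrix(orfs)
        mrna = gene_index_matrix(counts, w_true)
        return w_true, orfs, mrna

    def test_zero_sweeps_is_a_no_op(self):
        _, orfs, mrna = self._setup()
        w0 = tai_weights_from_copy_numbers()
        w, _ = scheme_b_optimize(w0, orfs, mrna, max_sweeps=0)
        assert np.allclose(w.w, w0.w / w0.w.max())

    def test_starting_at_truth_keeps_perfect_rank_agreement(self):
        # mRNA generated exactly as the gene index under known weights:
        # the optimizer can never fall below the objective at the truth
        w_true, orfs, mrna = self._setup()
        w0 = CodonWeights(w_true, "reference_set")
        _, achieved = scheme_b_optimize(w0, orfs, mrna, max_sweeps=10)
        assert achieved >= 1.0 - 1e-9

    def test_ascent_improves_substantially_from_generic_start(self):
        from scipy.stats import spearmanr
        w_true, orfs, mrna = self._setup()
        counts = codon_count_matrix(orfs)
        w0 = tai_weights_from_copy_numbers()
        start = spearmanr(gene_index_matrix(counts, w0.w), mrna).statistic
        _, achieved = scheme_b_optimize(w0, orfs, mrna, max_sweeps=30)
        assert achieved >= start  # monotone ascent
        assert achieved >= start + 0.2  # and a real climb, not a plateau

    def test_leakage_guard_rejects_heldout_ids(self):
        _, orfs, mrna = self._setup(n=20)
        w0 = tai_weights_from_copy_numbers()
        ids = [f"g{i}" for i in range(20)]
        with pytest.raises(ValueError, match="leakage"):
            scheme_b_optimize(w0, orfs, mrna, train_ids=ids,
                              forbidden_ids=["g3"])


class TestContextPssm:
    def test_background_equal_frequencies_give_zero_matrix(self):
        # every window position uniform over ACGT -> log-odds identically 0
        recs = [TranscriptRecord("g" + b, b * 6, "ATG" + b * 3 + "TAA", "")
                for b in "ACGT"]
        pssm = build_context_pssm(recs)
        assert np.allclose(pssm.logodds, 0.0)

    def test_single_gene_pseudocounted_one_hot(self):
        rec = TranscriptRecord("g", "AAAAAA", "ATGCCCTAA", "")
        pssm = build_context_pssm([rec])
        # upstream positions saw A once: freq (1+1)/(1+4) = 0.4, others 0.2
        # pooled background: 6 A + 3 C over 9 -> A: 7/13
        assert pssm.logodds[0, 0] == pytest.approx(np.log(0.4 / (7 / 13)))
        assert pssm.logodds[0, 1] == pytest.approx(np.log(0.2 / (4 / 13)))

    def test_conserved_position_has_maximal_weight(self, tiny_records):
        pssm = build_context_pssm(tiny_records)
        # scoring a sequence can only reward the observed-majority base
        assert pssm.logodds.shape == (9, 4)
        col = pssm.logodds[2]  # -4 position
        assert col.max() >= col.min()

    def test_out_of_sequence_positions_contribute_zero(self):
        rec = TranscriptRecord("g", "", "ATGCCCTAA", "")
        pssm = build_context_pssm([TranscriptRecord("t", "ACGTAC",
                                                    "ATGAAATAA", "")])
        upstream_only = sum(
            pssm.logodds[k, "ACGT".index(c)]
            for k, c in zip(range(6, 9), "CCC"))
        assert pssm.score(rec.transcript, 0) == pytest.approx(upstream_only)
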