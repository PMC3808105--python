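"""Per-gene indices against hand computations and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonforge.codon_metrics import (CAIReference, CodonCountTable, aromo,
                                      cai, composition, count_codons, enc,
                                      expected_enc, gene_indices, gravy,
                                      indices_table, load_cai_reference,
                                      rscu, rscu_matrix)
from codonforge.genetic_code import AminoAcidScales, informative_codons
from codonforge.orf_io import ORFRecord


def _orf(seq, oid="o"):
    return ORFRecord(id=oid, genome_id="g", start=0, end=len(seq),
                     strand="+", seq=seq)


def _counts(d, oid="t"):
    return CodonCountTable(orf_id=oid, counts=d, total_codons=sum(d.values()))


# --- independent oracle: a literal, self-contained transcription of
# Wright's estimator (per-family F averaged per degeneracy class),
# sharing no code with the implementation under test.
def enc_oracle(counts_by_codon, code):
    F_by_class = {}
    for aa, fam in code.synonymous_families.items():
        k = len(fam)
        if k == 1:
            continue
        ns = [counts_by_codon.get(c, 0) for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        S = sum((x / n) ** 2 for x in ns)
        F_by_class.setdefault(k, []).append((n * S - 1) / (n - 1))
    mean = {k: sum(v) / len(v) for k, v in F_by_class.items()}
    if 3 not in mean and 2 in mean and 4 in mean:
        mean[3] = (mean[2] + mean[4]) / 2
    val = 2 + 9 / mean[2] + 1 / mean[3] + 5 / mean[4] + 3 / mean[6]
    return min(val, 61.0)


class TestCountCodons:
    def test_basic_counts(self, code):
        c = count_codons("ATGAAAAAA", code)
        assert c.counts == {"ATG": 1, "AAA": 2}
        assert c.total_codons == 3

    def test_terminal_stop_trimmed(self, code):
        c = count_codons("ATGTAA", code)
        assert c.counts == {"ATG": 1}

    def test_internal_stop_rejected(self, code):
        with pytest.raises(ValueError, match="non-sense codon"):
            count_codons("ATGTAAAAA", code)

    def test_frame_error(self, code):
        with pytest.raises(ValueError, match="divisible by 3"):
            count_codons("ATGA", code)

    def test_long_orf_total(self, code, small_corpus):
        orfs, _ = small_corpus
        c = count_codons(orfs[0], code)
        assert c.total_codons == len(orfs[0].seq) // 3 - 1  # stop trimmed


class TestRSCU:
    def test_uniform_usage_is_all_ones(self, code):
        counts = _counts({c: 3 for c in informative_codons(code)})
        vals = rscu(counts, code)
        assert all(v == pytest.approx(1.0) for v in vals.values())

    def test_two_fold_hand_case(self, code):
        vals = rscu(_counts({"TTT": 4}), code)
        assert vals["TTT"] == pytest.approx(2.0)
        assert vals["TTC"] == pytest.approx(0.0)

    def test_six_fold_hand_case(self, code):
        fam = code.synonymous_families["L"]
        vals = rscu(_counts({fam[0]: 6}), code)
        assert vals[fam[0]] == pytest.approx(6.0)
        assert all(vals[c] == pytest.approx(0.0) for c in fam[1:])

    def test_unobserved_family_is_undefined_not_zero(self, code):
        vals = rscu(_counts({"TTT": 4}), code)
        assert vals["GGG"] is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_family_sums_equal_degeneracy(self, code, seed):
        rng = np.random.default_rng(seed)
        counts = _counts({c: int(rng.integers(0, 20))
                          for c in informative_codons(code)})
        vals = rscu(counts, code)
        for aa, fam in code.synonymous_families.items():
            if len(fam) == 1:
                continue
            got = [vals[c] for c in fam]
            if all(v is not None for v in got):
                assert sum(got) == pytest.approx(len(fam))


class TestENC:
    def test_even_usage_reaches_61(self, code):
        counts = _counts({c: 50 for c in code.sense_codons})
        assert enc(counts, code) == pytest.approx(61.0)

    def test_one_codon_per_family_is_20(self, code):
        counts = _counts({fam[0]: 30 for fam in code.synonymous_families.values()})
        assert enc(counts, code) == pytest.approx(20.0)

    def test_matches_independent_oracle_on_toy_gene(self, code):
        # fixed 30-codon toy gene
        d = {"TTT": 3, "TTC": 1, "CTG": 4, "CTT": 2, "ATT": 2, "ATC": 1,
             "GTT": 3, "GTG": 1, "GCC": 2, "GCA": 2, "AAA": 3, "AAG": 1,
             "CGT": 2, "AGA": 2, "GGG": 1}
        counts = _counts(d)
        assert enc(counts, code) == pytest.approx(enc_oracle(d, code), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_oracle_on_random_genes(self, code, seed):
        rng = np.random.default_rng(seed)
        d = {c: int(rng.integers(0, 15)) for c in code.sense_codons}
        got = enc(_counts(d), code)
        if got is not None:
            assert got == pytest.approx(enc_oracle(d, code), abs=1e-10)

    def test_permutation_within_family_invariance(self, code):
        fam = code.synonymous_families["A"]  # 4-fold
        base = {c: 30 for c in code.sense_codons}
        a = dict(base, **{fam[0]: 10, fam[1]: 50})
        b = dict(base, **{fam[0]: 50, fam[1]: 10})
        assert enc(_counts(a), code) == pytest.approx(enc(_counts(b), code))

    def test_monotone_decrease_with_skew(self, code):
        # one-parameter skew: move mass onto the first codon of each family
        values = []
        for skew in (0.0, 0.25, 0.5, 0.75):
            d = {}
            for fam in code.synonymous_families.values():
                k = len(fam)
                if k == 1:
                    d[fam[0]] = 120
                    continue
                extra = int(120 * skew)
                d[fam[0]] = 120 // k + extra
                for c in fam[1:]:
                    d[c] = 120 // k
            values.append(enc(_counts(d), code))
        assert values == sorted(values, reverse=True)
        assert values[0] > values[-1]

    def test_sparse_gene_undefined(self, code):
        assert enc(_counts({"TTT": 1}), code) is None


class TestExpectedENC:
    @pytest.mark.parametrize("s,val", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form_points(self, s, val):
        assert expected_enc(s) == pytest.approx(val)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    def test_curve_maximum_against_dense_grid(self):
        # the curve peaks where the direct evaluation peaks
        grid = np.linspace(0, 1, 20001)
        vals = np.array([2 + s + 29 / (s ** 2 + (1 - s) ** 2) for s in grid])
        s_star = grid[vals.argmax()]
        assert expected_enc(s_star) >= expected_enc(s_star - 0.01)
        assert expected_enc(s_star) >= expected_enc(s_star + 0.01)
        assert vals.max() == pytest.approx(expected_enc(s_star))


class TestCAI:
    def test_all_optimal_is_one(self, code):
        ref = load_cai_reference()
        optimal = {c: 5 for c, w in ref.w.items() if w == 1.0}
        assert cai(_counts(optimal), ref, code) == pytest.approx(1.0)

    def test_single_codon_value(self, code):
        ref = CAIReference("toy", {"TTT": 0.25, "TTC": 1.0})
        assert cai(_counts({"TTT": 7}), ref, code) == pytest.approx(0.25)

    def test_mixed_gene_matches_log_sum_oracle(self, code):
        ref = load_cai_reference()
        d = {"TTT": 3, "TTC": 2, "CTG": 5, "CTA": 1, "GGT": 4, "ATG": 2}
        expect = math.exp(sum(
            cnt * math.log(ref.w[c]) for c, cnt in d.items() if c != "ATG"
        ) / (sum(d.values()) - 2))
        assert cai(_counts(d), ref, code) == pytest.approx(expect, abs=1e-12)

    def test_atg_tgg_excluded(self, code):
        ref = load_cai_reference()
        assert cai(_counts({"ATG": 5, "TGG": 3}), ref, code) is None

    def test_length_invariance_at_fixed_frequencies(self, code):
        ref = load_cai_reference()
        d = {"TTT": 2, "CTG": 3, "GGT": 1}
        short = cai(_counts(d), ref, code)
        long = cai(_counts({c: 10 * n for c, n in d.items()}), ref, code)
        assert short == pytest.approx(long)


class TestProteinIndices:
    def test_gravy_poly_ile(self, code):
        scales = AminoAcidScales()
        assert gravy(_counts({"ATT": 12}), code) == pytest.approx(
            scales.hydropathy["I"])

    def test_gravy_midpoint(self, code):
        scales = AminoAcidScales()
        mid = (scales.hydropathy["I"] + scales.hydropathy["R"]) / 2
        assert gravy(_counts({"ATT": 5, "CGT": 5}), code) == pytest.approx(mid)

    def test_gravy_manual_sum(self, code):
        scales = AminoAcidScales()
        d = {"ATT": 2, "CGT": 3, "GGT": 1, "TTT": 2, "TGG": 2}  # I2 R3 G1 F2 W2
        expect = (2 * 4.5 + 3 * -4.5 + 1 * -0.4 + 2 * 2.8 + 2 * -0.9) / 10
        assert gravy(_counts(d), code) == pytest.approx(expect)

    @pytest.mark.parametrize("d,val", [
        ({"TTT": 2, "TAT": 2, "TGG": 2}, 1.0),   # F/Y/W only
        ({"GCT": 5, "AAA": 5}, 0.0),             # no aromatics
        ({"TTT": 1, "GCT": 9}, 0.1),             # 1 in 10
    ])
    def test_aromo(self, code, d, val):
        assert aromo(_counts(d), code) == pytest.approx(val)


class TestComposition:
    def test_all_g(self, code):
        comp = composition("GGGGGGGGG", code)
        assert comp["gc"] == 1.0 and comp["g3s"] == 1.0
        assert comp["a3s"] == comp["t3s"] == comp["c3s"] == 0.0

    def test_manual_tally(self, code):
        # ATG CGC TTA: GC over 9 nt = 4/9; synonymous thirds: CGC->C, TTA->A
        comp = composition("ATGCGCTTA", code)
        assert comp["gc"] == pytest.approx(4 / 9)
        assert comp["c3s"] == pytest.approx(0.5)
        assert comp["a3s"] == pytest.approx(0.5)
        assert comp["gc3s"] == pytest.approx(0.5)
        # GC12: pos1 bases A,C,T -> 1/3; pos2 bases T,G,T -> 1/3
        assert comp["gc12"] == pytest.approx(1 / 3)

    def test_gc12_saturated_first_two_positions(self, code):
        # GC at every 1st/2nd position, AT at every 3rd
        comp = composition("GCAGGTCCA", code)
        assert comp["gc12"] == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_third_position_fractions_sum_to_one(self, code, seed):
        rng = np.random.default_rng(seed)
        codons = [c for c in code.sense_codons]
        seq = "".join(rng.choice(codons, size=60))
        comp = composition(seq, code)
        if comp["gc3s"] is not None:
            total = comp["a3s"] + comp["t3s"] + comp["c3s"] + comp["g3s"]
            assert total == pytest.approx(1.0)
            assert comp["gc3s"] == pytest.approx(comp["c3s"] + comp["g3s"])


class TestGeneIndices:
    def test_uniform_usage_orf(self, code):
        seq = "".join(c * 3 for c in informative_codons(code)) + "TAA"
        gi = gene_indices(_orf(seq), code)
        assert gi.enc == pytest.approx(61.0)
        assert all(v == pytest.approx(1.0) for v in gi.rscu.values())

    def test_single_codon_per_family_orf(self, code):
        seq = "".join(fam[0] * 6 for fam in code.synonymous_families.values()) + "TAA"
        gi = gene_indices(_orf(seq), code)
        assert gi.enc == pytest.approx(20.0)

    def test_corpus_recovers_generator_truth(self, code, small_corpus):
        orfs, truth = small_corpus
        idx = indices_table(orfs, code)
        err = (idx["GC3s"] - truth.per_gene["effective_gc3s"]).abs().mean()
        assert err < 0.05
        # expression-weighted selection raises CAI
        r = np.corrcoef(idx["CAI"], truth.per_gene["expression_weight"])[0, 1]
        assert r > 0.5
        rg = np.corrcoef(idx["GRAVY"], truth.per_gene["target_gravy"])[0, 1]
        assert rg > 0.8

    def test_rscu_matrix_shape_and_range(self, code, small_corpus):
        orfs, _ = small_corpus
        Y = rscu_matrix(orfs, code)
        assert Y.shape == (len(orfs), 59)
        assert (Y.to_numpy() >= 0).all()
        C = rscu_matrix(orfs, code, values="counts")
        assert int(C.to_numpy().sum()) == sum(
            count_codons(o, code).total_codons
            - count_codons(o, code).counts.get("ATG", 0)
            - count_codons(o, code).counts.get("TGG", 0)
            for o in orfs)
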