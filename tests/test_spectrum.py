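"""Substitution classes, context flags, group tests, coding effects."""
import math
from itertools import product

import numpy as np
import pytest

from crossonc import spectrum as sp
from crossonc import synthetic as syn
from crossonc.model import SUBSTITUTION_CLASSES, SpectrumProfile, VariantRecord

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def fisher_two_sided_enumeration(table) -> float:
    """Independent oracle: two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def _rec(ref, alt, five="A", three="A", depth=100, sample="s"):
    return VariantRecord(sample, "chr1", 100, ref, alt, depth, five, three)


class TestCoverageFilter:
    @pytest.mark.parametrize(
        "depth,kept", [(29, False), (30, True), (300, True), (301, False)]
    )
    def test_inclusive_bounds(self, depth, kept):
        out = sp.filter_by_coverage([_rec("C", "T", depth=depth)])
        assert (len(out) == 1) == kept

    def test_simulated_out_of_range_share_removed(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=3000, seed=1)
        kept = sp.filter_by_coverage(recs)
        assert 0.85 < len(kept) / len(recs) < 0.95  # nominal 90%


class TestCollapseClass:
    def test_purine_reference_collapses_by_complement(self):
        assert sp.collapse_class("G", "A") == ("C>T", True)

    def test_transversion_flagged(self):
        assert sp.collapse_class("C", "A") == ("C>A", False)

    def test_all_twelve_pairs_map_onto_six_classes_twice(self):
        hits: dict[str, int] = {}
        for ref, alt in product("ACGT", repeat=2):
            if ref == alt:
                continue
            cls, _ = sp.collapse_class(ref, alt)
            hits[cls] = hits.get(cls, 0) + 1
        assert set(hits) == set(SUBSTITUTION_CLASSES)
        assert all(v == 2 for v in hits.values())


class TestContext:
    def test_c_with_3prime_g_is_cpg(self):
        assert sp.annotate_context(_rec("C", "A", three="G"))["is_CpG"] is True

    def test_g_with_5prime_c_is_cpg_via_strand_symmetry(self):
        assert sp.annotate_context(_rec("G", "T", five="C"))["is_CpG"] is True

    def test_n_flank_gives_unknown(self):
        assert sp.annotate_context(_rec("C", "A", three="N"))["is_CpG"] is None

    def test_exhaustive_flank_table_matches_hand_enumeration(self):
        for ref in "ACGT":
            for five in "ACGT":
                for three in "ACGT":
                    alt = next(b for b in "ACGT" if b != ref)
                    got = sp.annotate_context(_rec(ref, alt, five=five, three=three))
                    if ref == "C":
                        expect_cpg, expect_tpc = three == "G", five == "T"
                    elif ref == "G":
                        expect_cpg, expect_tpc = five == "C", three == "A"
                    else:
                        expect_cpg = expect_tpc = False
                    assert got["is_CpG"] == expect_cpg, (ref, five, three)
                    assert got["is_TpC"] == expect_tpc, (ref, five, three)


class TestSpectrum:
    def test_single_record_gives_unit_fraction(self):
        s = sp.spectrum([_rec("C", "T")])
        assert s.fractions.loc["s", "C>T"] == 1.0
        assert s.transition_fraction.loc["s"] == 1.0

    def test_empty_sample_flagged_not_crashing(self):
        s = sp.spectrum([])
        assert s.counts.empty

    def test_fractions_sum_to_one_and_ti_tv_partition(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=500, seed=2)
        s = sp.spectrum(recs)
        assert s.fractions.loc["s"].sum() == pytest.approx(1.0)
        assert (s.transition_fraction + s.transversion_fraction).loc["s"] == pytest.approx(1.0)

    def test_invariant_under_reverse_complementation(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS, cpg_transversion_mult=2.0)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=800, seed=3)
        rc = [
            VariantRecord(r.sample_id, r.chrom, r.pos, _COMP[r.ref], _COMP[r.alt],
                          r.depth, _COMP[r.three_prime], _COMP[r.five_prime])
            for r in recs
        ]
        a, b = sp.spectrum(recs), sp.spectrum(rc)
        assert np.array_equal(a.counts.values, b.counts.values)
        assert np.array_equal(a.cpg_counts.values, b.cpg_counts.values)

    def test_cpg_subset_never_exceeds_totals(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS, cpg_transversion_mult=3.0)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=400, seed=4)
        s = sp.spectrum(recs)
        assert (s.cpg_counts.values <= s.counts.values).all()


class TestCpgComparison:
    def test_identical_proportions_give_unit_odds(self):
        recs_a = [_rec("C", "A", three="G", sample="p")] * 5 + [
            _rec("C", "T", three="G", sample="p")
        ] * 5
        recs_b = [_rec("C", "A", three="G", sample="n")] * 5 + [
            _rec("C", "T", three="G", sample="n")
        ] * 5
        res = sp.compare_cpg_transversions(recs_a, recs_b)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_p_matches_enumeration_oracle(self):
        recs_a = [_rec("C", "A", three="G", sample="p")] * 10 + [
            _rec("C", "T", three="G", sample="p")
        ] * 90
        recs_b = [_rec("C", "A", three="G", sample="n")] * 40 + [
            _rec("C", "T", three="G", sample="n")
        ] * 60
        res = sp.compare_cpg_transversions(recs_a, recs_b)
        assert res.table.tolist() == [[10, 90], [40, 60]]
        assert res.p_value == pytest.approx(
            fisher_two_sided_enumeration([[10, 90], [40, 60]]), rel=1e-9
        )

    def test_empty_margin_returns_p_one_with_warning(self):
        recs_a = [_rec("C", "T", three="G", sample="p")] * 3
        recs_b = [_rec("C", "T", three="G", sample="n")] * 3
        with pytest.warns(UserWarning, match="empty margin"):
            res = sp.compare_cpg_transversions(recs_a, recs_b)
        assert res.p_value == 1.0

    def test_multiplier_difference_detected_with_power(self, small_genome):
        # 3x CpG transversion odds in one group, 2000 variants per group
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            pos = SpectrumProfile(syn.DEFAULT_CLASS_PROBS, cpg_transversion_mult=3.0)
            neg = SpectrumProfile(syn.DEFAULT_CLASS_PROBS, cpg_transversion_mult=1.0)
            recs, _ = syn.simulate_variants(
                small_genome, {"p": pos, "n": neg}, n_variants=2000, seed=100 + rep
            )
            res = sp.compare_cpg_transversions(
                [r for r in recs if r.sample_id == "p"],
                [r for r in recs if r.sample_id == "n"],
            )
            hits += res.p_value < 0.05
        assert hits / n_rep > 0.8


class TestCodingEffect:
    def test_synonymous_change(self):
        kind, label = sp.classify_coding_effect("GAA", 2, "A", "G")
        assert kind == "synonymous" and label == "EE"

    def test_glutamate_to_lysine_matches_the_e233k_pattern(self):
        kind, label = sp.classify_coding_effect("GAA", 0, "G", "A", residue_index=233)
        assert kind == "missense" and label == "E233K"

    def test_stop_gain_is_nonsense(self):
        kind, label = sp.classify_coding_effect("TAC", 2, "C", "A", residue_index=12)
        assert kind == "nonsense" and label == "Y12*"

    def test_minus_strand_bases_complemented(self):
        # genomic C>T on the minus strand is a coding G>A
        kind, label = sp.classify_coding_effect("GAA", 0, "C", "T", residue_index=1,
                                                strand="-")
        assert kind == "missense" and label == "E1K"

    def test_codon_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="not ref"):
            sp.classify_coding_effect("GAA", 0, "T", "C")
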