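"""Generator behaviour: determinism, truth implantation, spectra, synteny."""
import numpy as np
import pandas as pd
import pytest

from crossonc import synthetic as syn
from crossonc.model import CnaTruth, SpectrumProfile, TruthSegment


class TestMakeGenome:
    def test_probe_density_matches_requested_spacing(self):
        g = syn.make_genome(n_chrom=1, chrom_len=10_000_000, gene_count=5,
                            probe_spacing=5_500, seed=0)
        n = len(g.probes["chr1"])
        assert abs(n - 10_000_000 / 5_500) < 0.05 * n  # ~1818 probes

    def test_deterministic_under_fixed_seed(self):
        a = syn.make_genome(n_chrom=2, chrom_len=500_000, gene_count=4, seed=9)
        b = syn.make_genome(n_chrom=2, chrom_len=500_000, gene_count=4, seed=9)
        for c in ("chr1", "chr2"):
            assert np.array_equal(a.probes[c], b.probes[c])
        assert [(g.id, g.start) for g in a.genes] == [(g.id, g.start) for g in b.genes]

    def test_genes_within_bounds_and_counted_per_chromosome(self):
        g = syn.make_genome(n_chrom=2, chrom_len=1_000_000, gene_count=10, seed=1)
        assert len(g.genes) == 20
        for gene in g.genes:
            assert 0 <= gene.start < gene.end <= 1_000_000

    def test_impossible_packing_raises(self):
        with pytest.raises(ValueError, match="impossible packing"):
            syn.make_genome(n_chrom=1, chrom_len=100_000, gene_count=10,
                            gene_length=20_000, seed=0)


class TestSimulateAcgh:
    def test_zero_noise_probes_carry_exact_amplitudes(self, small_genome, amp_truth):
        profs = syn.simulate_acgh(small_genome, amp_truth, noise_sd=0.0, seed=0)
        chr1 = next(p for p in profs if p.chrom == "chr1")
        inside = (chr1.positions >= 200_000) & (chr1.positions < 420_000)
        assert np.all(chr1.log2ratio[inside] == 1.0)
        assert np.all(chr1.log2ratio[~inside] == 0.0)

    def test_null_truth_mean_near_zero(self, small_genome):
        profs = syn.simulate_acgh(small_genome, CnaTruth("t", []), noise_sd=0.2, seed=3)
        vals = np.concatenate([p.log2ratio for p in profs])
        assert abs(vals.mean()) < 4 * 0.2 / np.sqrt(len(vals))

    def test_truth_outside_genome_rejected(self, small_genome):
        bad = CnaTruth("t", [TruthSegment("chr1", 900_000, 1_100_000, 1.0, "amp")])
        with pytest.raises(ValueError, match="outside genome"):
            syn.simulate_acgh(small_genome, bad, seed=0)

    def test_focal_amplicon_covers_all_its_genes(self):
        # a ~9.9 Mb amplicon on a 63-gene chromosome: every gene midpoint inside
        g = syn.make_genome(n_chrom=1, chrom_len=9_950_000, gene_count=63,
                            gene_length=20_000, seed=5)
        seg = TruthSegment("chr1", 0, 9_950_000, 1.0, "amp")
        assert sum(seg.start <= gene.midpoint < seg.end for gene in g.genes) == 63


class TestSimulateExpression:
    def _copy_matrix(self, genome, amped, samples):
        ids = [g.id for g in genome.genes]
        m = pd.DataFrame(0.0, index=pd.Index(ids, name="gene_id"), columns=samples)
        m.loc[amped] = 1.0
        return m

    def test_zero_coupling_decouples_expression(self, small_genome):
        samples = [f"s{i}" for i in range(40)]
        ids = [g.id for g in small_genome.genes]
        copy = pd.DataFrame(
            np.random.default_rng(1).choice([0.0, 1.0], size=(len(ids), 40)),
            index=pd.Index(ids, name="gene_id"), columns=samples,
        )
        expr = syn.simulate_expression(small_genome, copy, set(ids), coupling=0.0, seed=2)
        flat_c = copy.values.ravel()
        flat_e = np.log2(expr.values).ravel()
        assert abs(np.corrcoef(flat_c, flat_e)[0, 1]) < 0.1

    def test_unit_coupling_zero_noise_doubles_expression(self, small_genome):
        copy = self._copy_matrix(small_genome, [small_genome.genes[0].id], ["s1"])
        expr = syn.simulate_expression(
            small_genome, copy, {small_genome.genes[0].id}, sd=0.0, coupling=1.0, seed=0
        )
        base = expr.iloc[1, 0]  # non-driver at baseline
        assert expr.loc[small_genome.genes[0].id, "s1"] == pytest.approx(2 * base)

    def test_driver_shift_recovered_over_many_samples(self, small_genome):
        samples = [f"s{i}" for i in range(100)]
        driver = small_genome.genes[0].id
        copy = self._copy_matrix(small_genome, [driver], samples)
        expr = syn.simulate_expression(small_genome, copy, {driver}, sd=0.5,
                                       coupling=1.0, seed=3)
        shift = np.log2(expr.loc[driver]).mean() - 5.0
        assert shift == pytest.approx(1.0, abs=4 * 0.5 / np.sqrt(100))

    def test_unknown_driver_id_rejected(self, small_genome):
        copy = self._copy_matrix(small_genome, [], ["s1"])
        with pytest.raises(ValueError, match="unknown driver"):
            syn.simulate_expression(small_genome, copy, {"nope"}, seed=0)


class TestSimulateVariants:
    def test_pure_ct_profile_emits_only_ct_pairs(self, small_genome):
        probs = {c: 0.0 for c in syn.SUBSTITUTION_CLASSES}
        probs["C>T"] = 1.0
        prof = SpectrumProfile(probs)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=200, seed=4)
        assert all((r.ref, r.alt) in {("C", "T"), ("G", "A")} for r in recs)

    def test_class_fractions_follow_profile_within_3_sigma(self, small_genome):
        p = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        prof = SpectrumProfile(dict(zip(syn.SUBSTITUTION_CLASSES, p)))
        n = 10_000
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=n, seed=6)
        from crossonc.spectrum import collapse_class

        counts = {c: 0 for c in syn.SUBSTITUTION_CLASSES}
        for r in recs:
            counts[collapse_class(r.ref, r.alt)[0]] += 1
        for cls, pi in zip(syn.SUBSTITUTION_CLASSES, p):
            sigma = np.sqrt(n * pi * (1 - pi))
            assert abs(counts[cls] - n * pi) < 3 * sigma

    def test_coverage_filter_is_exercised(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS)
        recs, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=2000, seed=7)
        out = sum(1 for r in recs if not 30 <= r.depth <= 300)
        assert 0.05 < out / len(recs) < 0.15

    def test_deterministic_under_fixed_seed(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS)
        a, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=50, seed=8)
        b, _ = syn.simulate_variants(small_genome, {"s": prof}, n_variants=50, seed=8)
        assert a == b

    def test_flanks_match_reference_sequence(self, small_genome):
        prof = SpectrumProfile(syn.DEFAULT_CLASS_PROBS)
        recs, seqs = syn.simulate_variants(small_genome, {"s": prof}, n_variants=100, seed=9)
        strings = syn.sequences_to_str(seqs)
        for r in recs[:50]:
            s = strings[r.chrom]
            assert s[r.pos] == r.ref
            assert s[r.pos - 1] == r.five_prime
            assert s[r.pos + 1] == r.three_prime


class TestSyntenyScenario:
    def test_gene_split_matches_the_two_region_design(self):
        sc = syn.make_synteny_scenario(n_genes=398, seed=0)
        assert sc.n_region_a == 210
        assert sc.n_region_b == 188
        assert len(sc.driver_ids) == 125
        assert (sc.human_genes["status"] == 1).all()
        assert sum(g.chrom == "chr13" for g in sc.dog_genes) == 210
        assert sum(g.chrom == "chr29" for g in sc.dog_genes) == 188

    def test_zero_driver_fraction_leaves_region_a_empty(self):
        sc = syn.make_synteny_scenario(n_genes=40, driver_fraction=0.0,
                                       human_region_len=2_000_000, seed=1)
        assert sc.driver_ids == []
        assert sc.truth.segments == []

    def test_projection_round_trip_recovers_human_interval(self):
        from crossonc.driver_passenger import project_region

        sc = syn.make_synteny_scenario(n_genes=40, human_region_len=2_000_000, seed=2)
        block_a = sc.blocks[0]
        sub = (block_a.human_chrom, 100_000, min(400_000, block_a.human_end))
        fwd, gaps = project_region(sub, sc.blocks)
        assert not gaps
        back_total = []
        for piece in fwd:
            back, g2 = project_region(
                (piece.chrom, piece.start, piece.end), sc.blocks, direction="dog_to_human"
            )
            assert not g2
            back_total.extend((b.start, b.end) for b in back)
        covered = sorted(back_total)
        assert covered[0][0] == sub[1] and covered[-1][1] == sub[2]

    def test_truth_segments_cover_exactly_the_driver_genes(self):
        sc = syn.make_synteny_scenario(n_genes=60, human_region_len=3_000_000, seed=3)
        drivers = set(sc.driver_ids)
        for g in sc.dog_genes:
            inside = any(
                s.chrom == g.chrom and s.start <= g.midpoint < s.end
                for s in sc.truth.segments
            )
            assert inside == (g.id in drivers)
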