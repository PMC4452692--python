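"""Expression classification, concordance, t-tests, and Hotelling T^2."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossonc import expression as ex
from crossonc.model import GeneCnaMatrix


def _gene_cna(status: np.ndarray, samples, genes=None) -> GeneCnaMatrix:
    n_genes, n_samples = status.shape
    idx = pd.Index(genes or [f"g{i}" for i in range(n_genes)], name="gene_id")
    st = pd.DataFrame(status, index=idx, columns=samples)
    amp = pd.DataFrame(status.astype(float), index=idx, columns=samples)
    meta = pd.DataFrame({"chrom": "chr1", "start": 0, "end": 1000}, index=idx)
    return GeneCnaMatrix(st, amp, meta)


class TestFilterExpressed:
    def test_all_zero_gene_dropped_and_boundary_kept(self):
        m = pd.DataFrame({"s1": [0.0, 1.0, 0.5], "s2": [0.0, 0.2, 0.4]},
                         index=["dead", "boundary", "low"])
        kept = ex.filter_expressed(m, min_fpkm=1.0, min_samples=1)
        assert list(kept.index) == ["boundary"]

    def test_known_expressed_fraction_recovered(self):
        rng = np.random.default_rng(0)
        n = 500
        expressed = rng.random(n) < 0.4
        vals = np.where(expressed[:, None], 5.0, 0.1) * np.ones((n, 3))
        m = pd.DataFrame(vals, columns=["a", "b", "c"])
        assert len(ex.filter_expressed(m)) == int(expressed.sum())


class TestClassifyExpression:
    def test_identical_values_classify_normal(self):
        samples = [f"s{i}" for i in range(6)]
        m = pd.DataFrame(7.0, index=["g0"], columns=samples)
        cna = _gene_cna(np.zeros((1, 6), int), samples)
        calls = ex.classify_expression(m, cna)
        assert (calls["level"] == "normal").all()

    def test_extreme_outlier_called_high(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(9)]
        vals = 2 ** rng.normal(5, 0.5, 9)
        vals[8] = 2 ** (5 + 10 * 0.5)
        m = pd.DataFrame([vals], index=["g0"], columns=samples)
        status = np.zeros((1, 9), int)
        status[0, 8] = 1  # the outlier sample is amplified, others diploid
        calls = ex.classify_expression(m, _gene_cna(status, samples))
        assert calls.set_index("sample_id").loc["s8", "level"] == "high"

    def test_too_few_diploid_references_unclassifiable(self):
        samples = ["s0", "s1", "s2"]
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=samples)
        status = np.array([[0, 0, 1]])
        calls = ex.classify_expression(m, _gene_cna(status, samples))
        assert (calls["level"] == "unclassifiable").all()

    def test_leave_one_out_calibration_for_reference_samples(self):
        # diploid samples judged against intervals excluding themselves:
        # outlier rate stays near alpha rather than collapsing to zero
        rng = np.random.default_rng(2)
        n_genes, n_ref = 400, 9
        samples = [f"s{i}" for i in range(n_ref)]
        m = pd.DataFrame(2 ** rng.normal(5, 1, (n_genes, n_ref)), columns=samples)
        m.index = [f"g{i}" for i in range(n_genes)]
        calls = ex.classify_expression(m, _gene_cna(np.zeros((n_genes, n_ref), int),
                                                    samples, genes=list(m.index)))
        rate = float((calls["level"] != "normal").mean())
        assert 0.02 < rate < 0.09  # nominal 0.05


class TestConcordance:
    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(8)]
        n = 60
        status = rng.choice([-1, 0, 1], size=(n, 8), p=[0.2, 0.6, 0.2])
        status[:, :4] = 0  # keep enough diploid references per gene
        m = pd.DataFrame(2 ** rng.normal(5, 1, (n, 8)), columns=samples,
                         index=[f"g{i}" for i in range(n)])
        cna = _gene_cna(status, samples, genes=list(m.index))
        table = ex.concordance_table(ex.classify_expression(m, cna), cna)
        for col in table.columns:
            total = table[col].sum()
            assert total == 0 or total == pytest.approx(100.0, abs=0.01)

    def test_no_cnas_populates_only_unchanged(self):
        samples = [f"s{i}" for i in range(5)]
        rng = np.random.default_rng(4)
        m = pd.DataFrame(2 ** rng.normal(5, 1, (10, 5)), columns=samples,
                         index=[f"g{i}" for i in range(10)])
        cna = _gene_cna(np.zeros((10, 5), int), samples, genes=list(m.index))
        table = ex.concordance_table(ex.classify_expression(m, cna), cna)
        assert table["Del"].sum() == 0 and table["Amp"].sum() == 0
        assert table["unchanged"].sum() == pytest.approx(100.0, abs=0.01)

    def test_coupled_amplification_skews_high_fraction(self):
        # driver-style coupling: amplified samples expressed 2x higher
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(12)]
        n = 80
        status = np.zeros((n, 12), int)
        status[:, 8:] = rng.choice([0, 1], size=(n, 4), p=[0.3, 0.7])
        log2e = rng.normal(5, 0.3, (n, 12)) + 1.0 * status
        m = pd.DataFrame(2.0 ** log2e, columns=samples, index=[f"g{i}" for i in range(n)])
        cna = _gene_cna(status, samples, genes=list(m.index))
        table = ex.concordance_table(ex.classify_expression(m, cna), cna)
        assert table.loc["high", "Amp"] > table.loc["high", "unchanged"]


class TestDifferentialExpression:
    def test_identical_groups_yield_no_hits(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(2 ** rng.normal(5, 1, (200, 8)),
                         columns=[f"s{i}" for i in range(8)])
        res = ex.differential_expression_ttest(m, [f"s{i}" for i in range(4)],
                                               [f"s{i}" for i in range(4, 8)])
        assert int(res["significant"].sum()) == 0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        vals = 2 ** rng.normal(5, 0.5, (50, 8))
        m = pd.DataFrame(vals, columns=[f"s{i}" for i in range(8)],
                         index=[f"g{i}" for i in range(50)])
        m.loc["g0", [f"s{i}" for i in range(4)]] *= 2 ** 5
        res = ex.differential_expression_ttest(m, [f"s{i}" for i in range(4)],
                                               [f"s{i}" for i in range(4, 8)])
        assert bool(res.loc["g0", "significant"])
        assert res.loc["g0", "direction"] == 1

    def test_null_false_call_rate_controlled(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(2 ** rng.normal(5, 1, (5000, 10)),
                         columns=[f"s{i}" for i in range(10)])
        res = ex.differential_expression_ttest(m, [f"s{i}" for i in range(5)],
                                               [f"s{i}" for i in range(5, 10)], fdr=0.1)
        # under the global null, BH keeps false calls near zero
        assert int(res["significant"].sum()) <= 5


class TestHotelling:
    def test_identical_groups_give_zero_statistic(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(20, 2))
        res = ex.hotelling_concordance(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_one_dimension_reduces_to_squared_t(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, size=(15, 1))
        b = rng.normal(0.8, 1, size=(12, 1))
        res = ex.hotelling_concordance(a, b)
        t, p = stats.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert res.t2 == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_coupled_vs_uncoupled_features_separate(self):
        # driver-like genes: expression tracks copy number; passengers do not
        rng = np.random.default_rng(11)
        n = 100
        copy = rng.uniform(0.4, 1.2, n)
        dcg = np.column_stack([copy, 5 + copy + rng.normal(0, 0.3, n)])
        copy_b = rng.uniform(0.4, 1.2, n)
        pcg = np.column_stack([copy_b, 5 + rng.normal(0, 0.3, n)])
        res = ex.hotelling_concordance(dcg, pcg)
        assert res.p_value < 0.05

    def test_singular_covariance_raises_helpful_error(self):
        a = np.ones((5, 2))
        b = np.ones((5, 2)) * 2
        with pytest.raises(np.linalg.LinAlgError, match="jitter"):
            ex.hotelling_concordance(a, b)
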