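import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from stressmir.diffexpr import (
    DERecord,
    bh_fdr,
    call_de,
    count_test,
    expression_matrix,
    log2_fold_change,
    normalize,
    run_all_comparisons,
    run_comparison,
)


def brute_force_two_sided_p(ct: int, total_t: int, cc: int, total_c: int) -> float:
    """Independent oracle: explicit binomial tail summation."""
    n = ct + cc
    if n == 0:
        return 1.0
    q = total_t / (total_t + total_c)
    pmf = [math.comb(n, k) * q ** k * (1 - q) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: ct + 1])
    upper = sum(pmf[ct:])
    return min(1.0, 2.0 * min(lower, upper))


class TestNormalize:
    def test_reads_per_million(self):
        assert normalize(50, 10 ** 6) == pytest.approx(50.0)

    def test_zero_count_floored_for_ratios(self):
        assert normalize(0, 10 ** 6, zero_tpm=0.01) == pytest.approx(0.01)
        assert normalize(0, 10 ** 6) == 0.0

    def test_full_library(self):
        assert normalize(10 ** 6, 10 ** 6) == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(5, 0)


class TestLog2FoldChange:
    @pytest.mark.parametrize("t,c,expected", [
        (100.0, 25.0, 2.0),
        (7.5, 7.5, 0.0),
        (10.0, 0.01, math.log2(1000)),
    ])
    def test_values(self, t, c, expected):
        assert log2_fold_change(t, c) == pytest.approx(expected)


class TestCountTest:
    def test_balanced_split_is_not_significant(self):
        assert count_test(5, 1000, 5, 1000) == pytest.approx(1.0)

    def test_extreme_split_closed_form(self):
        assert count_test(20, 1000, 0, 1000) == pytest.approx(2 * 0.5 ** 20)

    def test_double_zero_degenerate(self):
        assert count_test(0, 1000, 0, 1000) == 1.0

    def test_matches_brute_force_tail_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            total_t = int(rng.integers(10 ** 3, 10 ** 6))
            total_c = int(rng.integers(10 ** 3, 10 ** 6))
            ct = int(rng.integers(0, 200))
            cc = int(rng.integers(0, 200))
            if ct + cc > 200:
                cc = 200 - ct
            got = count_test(ct, total_t, cc, total_c)
            want = brute_force_two_sided_p(ct, total_t, cc, total_c)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    @settings(derandomize=True, max_examples=40)
    @given(ct=st.integers(0, 50), cc=st.integers(0, 50),
           tt=st.integers(100, 10 ** 6), tc=st.integers(100, 10 ** 6))
    def test_symmetry_under_label_swap(self, ct, cc, tt, tc):
        assert count_test(ct, tt, cc, tc) == pytest.approx(
            count_test(cc, tc, ct, tt))


class TestBhFdr:
    def test_worked_example(self):
        fdr = bh_fdr([0.0001, 0.01, 0.03])
        assert fdr == pytest.approx([0.0003, 0.015, 0.03])

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.random(100)
        ours = bh_fdr(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=30)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_p_and_bounded(self, ps):
        fdr = bh_fdr(ps)
        assert np.all(fdr >= np.asarray(ps) - 1e-12)
        assert np.all(fdr <= 1.0)


def record(log2fc, fdr, count_t=10, count_c=10):
    return DERecord(mirna="m", treatment="AS", control="CK",
                    count_t=count_t, count_c=count_c, tpm_t=1.0, tpm_c=1.0,
                    log2fc=log2fc, p_value=fdr, fdr=fdr)


class TestCallDe:
    @pytest.mark.parametrize("log2fc,fdr,expected", [
        (1.0, 1e-6, "ns"),       # boundary excluded: threshold is strict
        (2.5, 1e-6, "up"),
        (-3.66411747, 1e-4, "down"),
        (2.5, 0.001, "ns"),      # FDR boundary excluded
        (0.5, 1e-9, "ns"),
    ])
    def test_thresholds(self, log2fc, fdr, expected):
        rec = call_de([record(log2fc, fdr)])[0]
        assert rec.call == expected

    def test_absent_when_zero_everywhere(self):
        rec = call_de([record(0.0, 1.0, count_t=0, count_c=0)])[0]
        assert rec.call == "absent"


class TestComparisons:
    def counts(self):
        return pd.DataFrame(
            {"CK": [100, 5, 0, 50], "AS": [400, 5, 30, 45]},
            index=["m1", "m2", "m3", "m4"])

    def test_swap_negates_log2fc_and_keeps_p(self):
        c = self.counts()
        totals = {"CK": 10 ** 5, "AS": 10 ** 5}
        fwd = run_comparison(c, "AS", "CK", totals)
        rev = run_comparison(c, "CK", "AS", totals)
        for f, r in zip(fwd, rev):
            assert f.log2fc == pytest.approx(-r.log2fc)
            assert f.p_value == pytest.approx(r.p_value)

    def test_fdr_dominates_p(self):
        for rec in run_comparison(self.counts(), "AS", "CK"):
            assert rec.fdr >= rec.p_value - 1e-15

    def test_expression_matrix_shape_and_mask(self):
        c = self.counts()
        c["AS2"] = [90, 6, 1, 55]
        de = run_all_comparisons(c, "CK", {"CK": 10 ** 5, "AS": 10 ** 5,
                                           "AS2": 10 ** 5})
        lfc, mask = expression_matrix(de)
        assert lfc.shape == (4, 2)
        assert bool(mask.loc["m3"].any())  # zero count in CK -> masked

    def test_identical_rows_cluster_adjacently(self):
        c = pd.DataFrame({"CK": [10, 80, 10], "AS": [40, 20, 40],
                          "AS2": [40, 20, 40]},
                         index=["a", "far", "b"])
        de = run_all_comparisons(c, "CK")
        lfc, _ = expression_matrix(de)
        order = list(lfc.index)
        assert abs(order.index("a") - order.index("b")) == 1


class TestErrorRates:
    def test_null_data_rarely_called(self):
        """No planted fold change: essentially nothing passes FDR<0.001."""
        rng = np.random.default_rng(123)
        n = 1000
        mu = rng.lognormal(4.0, 1.0, size=n)
        counts = pd.DataFrame({
            "CK": rng.poisson(mu), "AS": rng.poisson(mu)})
        de = run_comparison(counts, "AS", "CK",
                            {"CK": 10 ** 6, "AS": 10 ** 6})
        frac = np.mean([r.call in ("up", "down") for r in de])
        assert frac <= 0.005
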