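from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cgishift.io_formats import CgiClass, ExpressionMatrix, GeneModel, GenomicInterval
from cgishift.shift_stats import (
    Status,
    all_pairs_shift,
    classify_status,
    distribution_shift,
    fold_change_fractions,
    net_expression_change,
    normalize_counts,
    paired_strata_test,
    rank_sum_test,
    reference_profile,
)


def enumeration_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating every rank split."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # untied inputs only
    n, m = len(x), len(y)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n * (n + m + 1) / 2
    count = total = 0
    for comb in combinations(range(1, n + m + 1), n):
        w = sum(comb)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestRankSum:
    def test_identical_distributions_p_one(self):
        x = np.arange(1.0, 20.0)
        assert rank_sum_test(x, x) == 1.0

    def test_all_tied_contract(self):
        assert rank_sum_test(np.ones(5), np.ones(7)) == 1.0

    def test_separated_triples_exact(self):
        # U = 0; 2 of C(6,3)=20 splits are as extreme -> p = 0.1
        p = rank_sum_test(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n,m", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4)])
    def test_exact_path_equals_full_enumeration(self, n, m, rng):
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = vals[:n], vals[n:]
            assert rank_sum_test(x, y) == pytest.approx(
                enumeration_rank_sum_p(x, y), abs=1e-12
            )

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            x, y = rng.normal(size=50), rng.normal(size=50)
            rejections += rank_sum_test(x, y) < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestDistributionShift:
    def test_identical_sample_p_one_score_zero(self):
        v = np.array([0.0, 5, 10, 20, 0, 3])
        p, score = distribution_shift(v, v)
        assert p == 1.0 and score == 0.0

    def test_genes_zero_in_both_excluded(self):
        s = np.array([0.0, 1, 2])
        r = np.array([0.0, 2, 1])
        p, _ = distribution_shift(s, r)
        # identical value sets after exclusion -> p = 1
        assert p == 1.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            distribution_shift(np.zeros(3), np.zeros(3))


class TestNetExpressionChange:
    def test_identical_zero(self):
        v = np.array([1.0, 10, 100])
        assert net_expression_change(v, v) == 0.0

    def test_uniform_tenfold_is_fifty(self):
        r = np.full(20, 10.0)
        s = np.full(20, 100.0)
        assert net_expression_change(s, r, pseudocount=0.0) == pytest.approx(50.0)

    def test_antisymmetry(self, rng):
        a = rng.lognormal(3, 1, 200)
        b = rng.lognormal(3, 1, 200)
        assert net_expression_change(a, b) == pytest.approx(
            -net_expression_change(b, a), abs=1e-12
        )

    def test_matches_sorted_curve_area_oracle(self, rng):
        """dAUC equals the difference of areas under the two sorted log
        curves drawn on a 0-10 scaled plot, x100/(10*10) rescaled."""
        for _ in range(20):
            a = rng.lognormal(2, 1, 150)
            b = rng.lognormal(2, 1, 150)
            pc = 1.0
            la, lb = np.log10(np.sort(a) + pc), np.log10(np.sort(b) + pc)
            log_max = np.log10(max(a.max(), b.max()) + pc)
            # both axes scaled to 0..10; rectangle rule with dx = 10/n
            ya, yb = 10 * la / log_max, 10 * lb / log_max
            dx = 10.0 / la.size
            oracle = (ya.sum() * dx - yb.sum() * dx)  # area difference, 0-100
            assert net_expression_change(a, b) == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            net_expression_change(
                np.array([0.0, 0.1]), np.array([0.05, 0.0]), pseudocount=0.5
            )


class TestNormalizeCounts:
    def _matrix(self, arr, ids=None):
        ids = ids or [f"s{i}" for i in range(arr.shape[1])]
        meta = pd.DataFrame(
            {"age_group": "young", "sex": "F", "tissue": "t",
             "total_mapped_reads": 1_000_000},
            index=ids,
        )
        values = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                              columns=ids)
        return ExpressionMatrix(values, meta)

    def test_identical_columns_unit_factors(self):
        arr = np.tile(np.array([[5], [10], [20]]), (1, 2))
        norm = normalize_counts(self._matrix(arr))
        np.testing.assert_allclose(norm.values["s0"], norm.values["s1"])
        np.testing.assert_allclose(norm.values["s0"], arr[:, 0])

    def test_doubled_column_equalized(self):
        arr = np.array([[5, 10], [10, 20], [20, 40]])
        norm = normalize_counts(self._matrix(arr))
        np.testing.assert_allclose(
            norm.values["s0"].to_numpy(), norm.values["s1"].to_numpy()
        )

    def test_factors_match_pydeseq2(self, rng):
        arr = rng.poisson(50, size=(200, 6)).astype(float)
        arr[arr == 0] = 1
        m = self._matrix(arr)
        norm = normalize_counts(m)
        from pydeseq2.preprocessing import deseq2_norm

        expected, _ = deseq2_norm(pd.DataFrame(arr.T))
        np.testing.assert_allclose(
            norm.values.to_numpy(), np.asarray(expected).T, rtol=1e-10
        )

    def test_all_zero_sample_rejected(self):
        arr = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(self._matrix(arr))


class TestReferenceProfile:
    def test_single_young_sample_is_that_column(self, toy_bulk_matrix):
        ref = reference_profile(toy_bulk_matrix, ["s1"])
        np.testing.assert_allclose(ref.values, toy_bulk_matrix.values["s1"])

    def test_odd_count_median(self, toy_bulk_matrix):
        ref = reference_profile(toy_bulk_matrix, ["s1", "s2", "s3"])
        assert ref.values["gA"] == 12  # median of (10, 20, 12)

    def test_matches_sorting_oracle(self, rng):
        values = pd.DataFrame(
            rng.random((100, 8)), index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(8)],
        )
        meta = pd.DataFrame(
            {"age_group": "young", "sex": "F", "tissue": "t",
             "total_mapped_reads": 1}, index=values.columns,
        )
        m = ExpressionMatrix(values, meta)
        ref = reference_profile(m, list(values.columns))
        arr = np.sort(values.to_numpy(), axis=1)
        oracle = (arr[:, 3] + arr[:, 4]) / 2  # mean of middle two, n=8
        np.testing.assert_allclose(ref.values.to_numpy(), oracle)

    def test_unknown_sample_rejected(self, toy_bulk_matrix):
        with pytest.raises(ValueError, match="unknown"):
            reference_profile(toy_bulk_matrix, ["nope"])


class TestClassifyStatus:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.7, Status.AFFECTED), (0.1, Status.UNAFFECTED),
         (0.3, Status.INTERMEDIATE)],
    )
    def test_threshold_rule(self, score, expected):
        assert classify_status(score).status is expected

    @given(st.floats(0, 10, allow_nan=False))
    def test_monotone_in_score(self, score):
        order = {Status.UNAFFECTED: 0, Status.INTERMEDIATE: 1, Status.AFFECTED: 2}
        lower = classify_status(score).status
        higher = classify_status(score + 0.5).status
        assert order[higher] >= order[lower]

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_status(0.3, t_affected=0.2, t_unaffected=0.4)


class TestAllPairsShift:
    def _group(self, n, sex, depths, prefix):
        ids = [f"{prefix}{i}" for i in range(n)]
        rng = np.random.default_rng(hash(prefix) % 2**31)
        values = pd.DataFrame(
            rng.poisson(30, size=(50, n)).astype(float) + 1.0,
            index=[f"g{i}" for i in range(50)], columns=ids,
        )
        meta = pd.DataFrame(
            {"age_group": "x", "sex": sex, "tissue": "t",
             "total_mapped_reads": depths},
            index=ids,
        )
        return ExpressionMatrix(values, meta, layer="normalized")

    def test_depth_ratio_boundary(self):
        a = self._group(1, ["F"], [10_000_000], "a")
        b_excl = self._group(1, ["F"], [16_000_000], "b")
        b_incl = self._group(1, ["F"], [15_000_000], "c")
        table, excluded = all_pairs_shift(a, b_excl)
        assert excluded == [("a0", "b0")] and table.empty
        table, excluded = all_pairs_shift(a, b_incl)  # 1.5x exactly: kept
        assert excluded == [] and not table.empty

    def test_pair_count_per_sex_split(self):
        a = self._group(4, ["F"] * 2 + ["M"] * 2, [1e7] * 4, "a")
        b = self._group(3, ["F", "M", "M"], [1e7] * 3, "b")
        table, _ = all_pairs_shift(a, b)
        # F: 2x1 pairs, M: 2x2 pairs -> 6 pairs x 1 stratum ('all')
        assert len(table) == 6
        assert set(table["stratum"]) == {"all"}

    def test_y_chromosome_genes_dropped(self):
        a = self._group(1, ["F"], [1e7], "a")
        b = self._group(1, ["F"], [1e7], "b")
        genes = [
            GeneModel.from_interval(
                f"g{i}",
                GenomicInterval("chrY" if i < 10 else "chr1", 100, 300, "+"),
            )
            for i in range(50)
        ]
        table, _ = all_pairs_shift(a, b, genes=genes)
        assert table["n_genes"].iloc[0] <= 40


class TestPairedStrataTest:
    def test_symmetric_differences_half(self):
        p = paired_strata_test([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert p == pytest.approx(0.5)

    def test_matches_textbook_t(self):
        d = np.array([1.0, 2.0, 3.0])
        from scipy import stats

        t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        expected = float(stats.t.sf(t, df=2))
        assert paired_strata_test(d, np.zeros(3)) == pytest.approx(expected)

    def test_negative_differences_above_half(self):
        assert paired_strata_test([-1.0, -2.0, -3.5], [0.0, 0.0, 0.0]) > 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_strata_test([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])


class TestFoldChangeFractions:
    def test_exact_doubling_counts_as_up(self):
        r = np.array([1.0, 2.0, 5.0])
        assert fold_change_fractions(2 * r, r) == (100.0, 0.0)

    def test_identical_is_zero_zero(self):
        r = np.array([1.0, 2.0, 5.0])
        assert fold_change_fractions(r, r) == (0.0, 0.0)

    def test_matches_brute_force(self, rng):
        s = rng.lognormal(1, 1, 300)
        r = rng.lognormal(1, 1, 300)
        up, down = fold_change_fractions(s, r, fold=2)
        assert up == pytest.approx(100 * np.mean(s >= 2 * r))
        assert down == pytest.approx(100 * np.mean(r >= 2 * s))

    def test_fold_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            fold_change_fractions(np.ones(3), np.ones(3), fold=1.0)
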