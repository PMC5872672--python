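"""Frequencies, chi-square, Kruskal-Wallis, and the closed-form odds ratio."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from nafldscore import (
    GenotypeCounts,
    allele_frequency,
    genotype_count_table,
    kruskal_wallis,
    odds_ratio_2x2,
    pearson_chi2,
)
from nafldscore.errors import DegenerateInputError

counts_st = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda t: sum(t) > 0)


class TestAlleleFrequency:
    @pytest.mark.parametrize(
        "counts, expected_rounded",
        [
            ((20, 44, 43), 0.61),  # cirrhosis PNPLA3: 130/214
            ((90, 0, 0), 0.0),
            ((0, 0, 50), 1.0),
            ((30, 36, 27), 0.48),  # NAFLD PNPLA3: 90/186
            ((53, 30, 7), 0.24),  # healthy PNPLA3: 44/180
        ],
    )
    def test_reported_frequencies(self, counts, expected_rounded):
        res = allele_frequency(GenotypeCounts(*counts))
        assert res.rounded == pytest.approx(expected_rounded)
        assert res.n_alleles == 2 * sum(counts)

    def test_exact_value(self):
        res = allele_frequency(GenotypeCounts(20, 44, 43))
        assert res.maf == pytest.approx(130 / 214, abs=1e-15)

    def test_empty_counts_error(self):
        with pytest.raises(DegenerateInputError):
            allele_frequency(GenotypeCounts(0, 0, 0))

    @given(counts_st)
    def test_swapping_homozygotes_complements_maf(self, counts):
        a, h, m = counts
        maf = allele_frequency(GenotypeCounts(a, h, m)).maf
        swapped = allele_frequency(GenotypeCounts(m, h, a)).maf
        assert maf + swapped == pytest.approx(1.0, abs=1e-12)


class TestGenotypeCountTable:
    def test_group_columns_match_margins(self, study_cohort):
        table = genotype_count_table(
            study_cohort, "rs738409", group_order=["healthy", "nafld", "cirrhosis"]
        )
        assert list(table["nafld"]) == [30, 36, 27]
        assert list(table["healthy"]) == [53, 30, 7]
        assert list(table["cirrhosis"]) == [20, 44, 43]

    def test_dichotomized_pools_carriers(self, study_cohort):
        table = genotype_count_table(
            study_cohort,
            "rs58542926",
            group_order=["healthy", "nafld", "cirrhosis"],
            dichotomize=True,
        )
        assert list(table["healthy"]) == [79, 11]
        assert list(table["cirrhosis"]) == [79, 28]
        assert list(table.index) == ["CC", "CT/TT"]

    def test_one_subject_per_class(self, study_cohort):
        from tests.conftest import make_cohort

        cohort = make_cohort(
            [
                {"group": "healthy", "rs738409": g}
                for g in ("CC", "CG", "GG")
            ]
            + [{"group": "nafld", "rs738409": g} for g in ("CC", "CG", "GG")]
        )
        table = genotype_count_table(cohort, "rs738409")
        assert list(table["healthy"]) == [1, 1, 1]

    def test_empty_group_named(self, study_cohort):
        with pytest.raises(DegenerateInputError, match="ghost"):
            genotype_count_table(
                study_cohort, "rs738409", group_order=["healthy", "ghost"]
            )


class TestPearsonChi2:
    def test_identical_columns_statistic_zero(self):
        res = pearson_chi2([[10, 20], [5, 10], [15, 30]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_worked_2x2(self):
        res = pearson_chi2([[10, 20], [20, 10]])
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1

    def test_matches_scipy_on_3x3_genotype_table(self, study_cohort):
        table = genotype_count_table(
            study_cohort, "rs4880", group_order=["healthy", "nafld", "cirrhosis"]
        ).to_numpy()
        mine = pearson_chi2(table)
        stat, p, df, _ = chi2_contingency(table, correction=False)
        assert mine.statistic == pytest.approx(stat, abs=1e-10)
        assert mine.p_value == pytest.approx(p, abs=1e-10)
        assert mine.df == df

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi2([[0, 0], [5, 10]])

    def test_sparse_expected_warns_but_computes(self):
        with pytest.warns(UserWarning, match="chi-square approximation"):
            res = pearson_chi2([[1, 30], [2, 40]])
        assert res.statistic >= 0

    @given(
        st.lists(
            st.tuples(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40)),
            min_size=2,
            max_size=4,
        ),
        st.integers(2, 5),
    )
    def test_permutation_and_scaling_invariance(self, rows, multiplier):
        import warnings

        table = np.array(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse tables are fine here
            base = pearson_chi2(table).statistic
            permuted = pearson_chi2(table[::-1, ::-1]).statistic
            scaled = pearson_chi2(table * multiplier).statistic
        assert permuted == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert scaled == pytest.approx(base * multiplier, rel=1e-9, abs=1e-12)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        h, _ = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(27 / 7, rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        a, b = [1.0, 2.5, 7.0], [0.5, 3.0, 9.0, 11.0]
        h1, _ = kruskal_wallis(a, b)
        h2, _ = kruskal_wallis(np.exp(a), np.exp(b))
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_group_error(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis([1, 2], [])


class TestOddsRatio2x2:
    def test_carrier_contrast_from_genotype_table(self):
        # cirrhosis vs healthy TM6SF2 carriers: 28/79 vs 11/79
        or_value, lo, hi = odds_ratio_2x2(28, 11, 79, 79)
        assert or_value == pytest.approx(28 / 11, rel=1e-12)
        assert lo < or_value < hi

    def test_null_table(self):
        or_value, lo, hi = odds_ratio_2x2(10, 10, 10, 10)
        assert or_value == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_behaviour(self):
        with pytest.raises(DegenerateInputError):
            odds_ratio_2x2(5, 0, 3, 7)
        or_value, lo, hi = odds_ratio_2x2(5, 0, 3, 7, correction=True)
        assert np.isfinite([or_value, lo, hi]).all()

    @given(
        st.tuples(*[st.integers(1, 50)] * 4)
    )
    def test_swap_inverts(self, cells):
        a, b, c, d = cells
        or1, lo1, hi1 = odds_ratio_2x2(a, b, c, d)
        or2, lo2, hi2 = odds_ratio_2x2(b, a, d, c)
        assert or1 * or2 == pytest.approx(1.0, rel=1e-9)
        assert lo1 * hi2 == pytest.approx(1.0, rel=1e-9)

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    def test_unit_or_iff_zero_chi2(self, cells):
        a, b, c, d = cells
        or_value, _, _ = odds_ratio_2x2(a, b, c, d)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = pearson_chi2([[a, b], [c, d]]).statistic
        if abs(or_value - 1) < 1e-12:
            assert stat == pytest.approx(0.0, abs=1e-9)
        if stat < 1e-12:
            assert or_value == pytest.approx(1.0, abs=1e-6)
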