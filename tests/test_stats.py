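"""Contingency-table tests: published crosstabs, closed forms, and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats as sps

import hetrank as hr
from hetrank.stats import chi2_sf


def table(counts, **kw):
    return hr.ContingencyTable.from_counts(counts, **kw)


class TestContingencyTable:
    def test_rejects_negative_fractional_or_empty(self):
        with pytest.raises(ValueError):
            table([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            table([[1.5, 1], [2, 3]])
        with pytest.raises(ValueError):
            table([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            table([[1, 2, 3]])

    def test_frame_round_trip_keeps_labels(self):
        t = table([[1, 2], [3, 4]], row_labels=("a", "b"), col_labels=("x", "y"))
        f = t.to_frame()
        assert list(f.index) == ["a", "b"] and list(f.columns) == ["x", "y"]


class TestPearsonChi2:
    def test_marker_by_her2_crosstab(self):
        with pytest.warns(UserWarning, match="expected count"):
            res = hr.pearson_chi2(table([[11, 4], [3, 7]]))
        assert res.statistic == pytest.approx(4.5725, abs=1e-4)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0325, abs=5e-4)
        assert round(res.p_value, 3) == 0.032

    def test_tumor_location_crosstab(self):
        res = hr.pearson_chi2(table([[62, 37], [40, 11]]))
        assert res.df == 1
        assert round(res.p_value, 3) == 0.049

    def test_three_level_her2_crosstab(self):
        with pytest.warns(UserWarning):
            res = hr.pearson_chi2(table([[54, 24], [9, 4], [2, 3]]))
        assert res.df == 2
        assert round(res.p_value, 3) == 0.396

    def test_perfect_independence(self):
        res = hr.pearson_chi2(table([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="empty row or column"):
            hr.pearson_chi2(table([[5, 5], [0, 0]]))

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.lists(st.integers(1, 30), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_invariant_to_transposition_and_permutation(self, rows):
        import warnings

        t = np.array(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small random tables trip the <5 caveat
            base = hr.pearson_chi2(table(t)).statistic
            assert hr.pearson_chi2(table(t.T)).statistic == pytest.approx(base, rel=1e-12)
            perm = t[np.random.default_rng(0).permutation(t.shape[0])]
            assert hr.pearson_chi2(table(perm)).statistic == pytest.approx(base, rel=1e-12)

    def test_agrees_with_scipy(self):
        import warnings

        for counts in ([[11, 4], [3, 7]], [[62, 37], [40, 11]], [[54, 24], [9, 4], [2, 3]]):
            expected = sps.chi2_contingency(counts, correction=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = hr.pearson_chi2(table(counts))
            assert res.statistic == pytest.approx(expected.statistic, rel=1e-12)
            assert res.p_value == pytest.approx(expected.pvalue, rel=1e-10)


class TestChi2Tail:
    def test_df2_closed_form(self):
        for x in np.linspace(0.01, 40, 37):
            assert chi2_sf(x, 2) == pytest.approx(math.exp(-x / 2), abs=1e-12)

    def test_df1_erfc_closed_form(self):
        for x in np.linspace(0.01, 30, 23):
            assert chi2_sf(x, 1) == pytest.approx(special.erfc(math.sqrt(x / 2)), abs=1e-12)

    def test_monotone_decreasing_in_statistic(self):
        for df in (1, 2, 5):
            vals = [chi2_sf(x, df) for x in np.linspace(0, 50, 101)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


def _fisher_oracle(counts):
    """Two-sided p by direct hypergeometric summation (scipy pmf route)."""
    a, b = counts[0]
    c, d = counts[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-7)].sum())


class TestFisherExact:
    def test_marker_by_her2_crosstab(self):
        res = hr.fisher_exact_2x2(table([[11, 4], [3, 7]]))
        assert res.p_value == pytest.approx(0.0486, abs=5e-5)

    def test_extreme_diagonal_table(self):
        res = hr.fisher_exact_2x2(table([[5, 0], [0, 5]]))
        assert res.p_value == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_modal_table_gives_p_one(self):
        assert hr.fisher_exact_2x2(table([[3, 3], [3, 3]])).p_value == pytest.approx(1.0)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError):
            hr.fisher_exact_2x2(table([[1, 2], [3, 4], [5, 6]]))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            hr.fisher_exact_2x2(table([[0, 0], [3, 4]]))

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_matches_hypergeometric_enumeration_oracle(self, a, b, c, d):
        counts = [[a, b], [c, d]]
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        res = hr.fisher_exact_2x2(table(counts))
        assert res.p_value == pytest.approx(_fisher_oracle(counts), abs=1e-10)
        assert res.p_value == pytest.approx(
            sps.fisher_exact(counts).pvalue, abs=1e-9
        )


class TestCrosstab:
    def test_marker_vs_her2_from_reference_cohort(self, scored_table2):
        tab, n_excl = hr.crosstab(
            scored_table2[0],
            "her2_status",
            "category",
            col_order=("hypo-intense", "intermediate", "hyper-intense"),
        )
        assert n_excl == 0
        merged, _ = hr.crosstab(
            scored_table2[0],
            "category",
            "her2_status",
            merge_rows=(hr.HYPO, hr.INTERMEDIATE),
            merged_label="hypo/intermediate",
            row_order=("hypo/intermediate", hr.HYPER),
            col_order=("negative", "positive"),
        )
        assert merged.counts.tolist() == [[11, 3], [4, 7]]

    def test_conditional_fractions(self, scored_table2):
        tab, _ = hr.crosstab(
            scored_table2[0],
            "her2_status",
            "category",
            merge_rows=None,
            row_order=("negative", "positive"),
        )
        frame = tab.to_frame()
        pos = frame.loc["positive"]
        neg = frame.loc["negative"]
        assert pos["hyper-intense"] / pos.sum() == pytest.approx(0.70)
        assert (neg["hypo-intense"] + neg["intermediate"]) / neg.sum() == pytest.approx(
            11 / 15
        )

    def test_missing_dropped_and_counted(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"x": ["a", "a", "b", "b", None], "y": ["u", "v", "u", "v", "u"]}
        )
        tab, n_excl = hr.crosstab(frame, "x", "y")
        assert n_excl == 1
        assert tab.counts.sum() == 4

    def test_keep_missing_as_level_reproduces_three_row_table(self):
        import pandas as pd

        rows = (
            [("negative", "low")] * 54 + [("negative", "high")] * 24
            + [("positive", "low")] * 9 + [("positive", "high")] * 4
            + [(None, "low")] * 2 + [(None, "high")] * 3
        )
        frame = pd.DataFrame(rows, columns=["her2_status", "marker"])
        tab, n_excl = hr.crosstab(
            frame,
            "her2_status",
            "marker",
            keep_missing_as_level=True,
            row_order=("negative", "positive", "Unspecified"),
            col_order=("low", "high"),
        )
        assert n_excl == 0
        assert tab.counts.tolist() == [[54, 24], [9, 4], [2, 3]]
        with pytest.warns(UserWarning):
            assert round(hr.pearson_chi2(tab).p_value, 3) == 0.396

    def test_single_level_margin_rejected(self):
        import pandas as pd

        frame = pd.DataFrame({"x": ["a"] * 5, "y": ["u", "v", "u", "v", "u"]})
        with pytest.raises(ValueError, match="fewer than 2"):
            hr.crosstab(frame, "x", "y")

    def test_unknown_column_rejected(self, scored_table2):
        with pytest.raises(KeyError):
            hr.crosstab(scored_table2[0], "category", "nope")
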