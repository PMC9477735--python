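"""The screen statistic: Fisher test, BH adjustment, ratio and hit calls."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hapscreen as hs
from hapscreen.enrichment_stats import GeneContingency
from hapscreen.errors import (
    DegenerateTableError,
    FormatError,
    InvalidInputError,
)

from conftest import run_pipeline


def fisher_oracle(a, b, c, d):
    """Exact integer-arithmetic enumeration of the minimum-likelihood rule.

    All point probabilities share the denominator C(n, k), so tables are
    compared by their integer numerators — no floating point at all.
    """
    r1, r2, k = a + b, c + d, a + c
    lo, hi = max(0, k - r2), min(k, r1)
    weights = {x: comb(r1, x) * comb(r2, k - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    numerator = sum(w for w in weights.values() if w <= observed)
    return numerator / comb(r1 + r2, k)


class TestFisherTwoSided:
    def test_identical_proportions_give_one(self):
        assert hs.fisher_two_sided(5, 95, 5, 95) == 1.0

    def test_two_table_support_enumeration(self):
        # margins (1,1): both admissible tables have probability 1/2
        assert hs.fisher_two_sided(1, 0, 0, 1) == 1.0

    def test_frozen_enumeration_value(self):
        # support x in 0..3, weights (120, 450, 450, 120); observed x=3
        assert hs.fisher_two_sided(3, 7, 0, 10) == pytest.approx(
            4 / 19, abs=1e-12
        )

    def test_empty_population_rejected(self):
        with pytest.raises(DegenerateTableError):
            hs.fisher_two_sided(0, 0, 1, 5)

    @settings(max_examples=300, deadline=None)
    @given(
        a=st.integers(0, 40),
        b=st.integers(0, 40),
        c=st.integers(0, 40),
        d=st.integers(0, 40),
    )
    def test_matches_exact_enumeration(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        assert hs.fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(0, 60),
        b=st.integers(0, 60),
        c=st.integers(0, 60),
        d=st.integers(0, 60),
    )
    def test_population_and_category_swap_symmetry(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = hs.fisher_two_sided(a, b, c, d)
        assert p == pytest.approx(hs.fisher_two_sided(c, d, a, b), rel=1e-12)
        assert p == pytest.approx(hs.fisher_two_sided(b, a, d, c), rel=1e-12)

    def test_matches_scipy_on_screen_scale_tables(self):
        """Independent cross-check at realistic totals (~1e3..1e6)."""
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(200):
            b = int(rng.integers(100, 1_000_000))
            d = int(rng.integers(100, 1_000_000))
            a = int(rng.integers(0, 400))
            c = int(rng.integers(0, 400))
            expected = fisher_exact([[a, b], [c, d]]).pvalue
            # both routes use float log-pmfs; agreement is limited by
            # log-gamma rounding at margins of order 1e6
            assert hs.fisher_two_sided(a, b, c, d) == pytest.approx(
                expected, rel=5e-7, abs=1e-300
            )


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert hs.benjamini_hochberg([0.04]) == pytest.approx([0.04])

    def test_equal_ps_unchanged(self):
        assert hs.benjamini_hochberg([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_hand_applied_step_up(self):
        adjusted = hs.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            hs.benjamini_hochberg([0.5, 0.0])
        with pytest.raises(InvalidInputError):
            hs.benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60
        )
    )
    def test_matches_statsmodels_and_is_monotone(self, p_values):
        from statsmodels.stats.multitest import multipletests

        adjusted = hs.benjamini_hochberg(p_values)
        _, expected, _, _ = multipletests(p_values, method="fdr_bh")
        assert adjusted == pytest.approx(expected, rel=1e-12)
        p = np.asarray(p_values)
        assert np.all(adjusted >= p) and np.all(adjusted <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40),
        st.floats(0.01, 0.2),
    )
    def test_rejections_equal_classic_step_up_rule(self, p_values, alpha):
        """{p_adj < alpha} must equal the textbook step-up rejection set."""
        p = np.asarray(p_values)
        adjusted = hs.benjamini_hochberg(p)
        m = p.size
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        below = np.nonzero(sorted_p < alpha * np.arange(1, m + 1) / m)[0]
        classic = set(order[: below[-1] + 1]) if below.size else set()
        assert set(np.nonzero(adjusted < alpha)[0]) == classic

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, size=50)
        perm = rng.permutation(50)
        assert hs.benjamini_hochberg(p)[perm] == pytest.approx(
            hs.benjamini_hochberg(p[perm])
        )


class TestMutationRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((10, 90, 10, 90), 1.0),
            ((20, 80, 5, 95), 4.0),
            ((0, 100, 5, 95), 0.0),
            ((3, 97, 0, 100), math.inf),
        ],
    )
    def test_examples(self, table, expected):
        assert hs.mutation_ratio(*table) == expected

    def test_undefined_for_zero_combined(self):
        assert math.isnan(hs.mutation_ratio(0, 10, 0, 10))

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(1, 500),
        b=st.integers(0, 500),
        c=st.integers(1, 500),
        d=st.integers(0, 500),
    )
    def test_population_swap_inverts_ratio(self, a, b, c, d):
        product = hs.mutation_ratio(a, b, c, d) * hs.mutation_ratio(c, d, a, b)
        assert product == pytest.approx(1.0, rel=1e-12)


class TestAnalyzeScreen:
    def test_single_null_gene(self):
        (result,) = hs.analyze_screen([GeneContingency("g", 5, 95, 5, 95)])
        assert result.p == result.p_adj == 1.0
        assert result.direction == hs.NO_DIRECTION
        assert result.combined == 10

    def test_strong_hit_called_with_direction(self, hit_config):
        results = run_pipeline(hs.simulate_screen(hit_config))
        top = results[0]
        assert top.gene_id == "gene050"
        assert top.p_adj < 0.05
        assert top.direction == hs.POSITIVE_REGULATOR
        assert results == sorted(results, key=lambda r: (r.p_adj, r.gene_id))

    def test_null_screen_false_positive_fraction(self, null_config):
        """Empirical screen-wide FP fraction at p_adj < 0.05 under the null."""
        fractions = []
        for seed in range(5):
            results = run_pipeline(
                hs.simulate_screen(null_config.replace(seed=100 + seed))
            )
            fractions.append(
                np.mean([r.p_adj < 0.05 for r in results])
            )
        standard_error = 0.05 / math.sqrt(len(fractions))
        assert np.mean(fractions) <= 0.05 + 2 * standard_error

    def test_untestable_genes_excluded(self):
        tables = [
            GeneContingency("seen", 2, 98, 3, 97),
            GeneContingency("unseen", 0, 100, 0, 100),
        ]
        results = hs.analyze_screen(tables)
        assert [r.gene_id for r in results] == ["seen"]

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            hs.analyze_screen([])


class TestResultIO:
    def make_results(self):
        tables = [
            GeneContingency("gene_inf", 3, 97, 0, 100),
            GeneContingency("gene_mid", 10, 90, 12, 88),
            GeneContingency("gene_low", 0, 100, 9, 91),
        ]
        return hs.analyze_screen(tables)

    def test_write_results_row_count_and_inf(self, tmp_path):
        results = self.make_results()
        path = hs.write_results(results, tmp_path / "results.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(results)
        inf_line = next(l for l in lines if l.startswith("gene_inf"))
        assert "\tinf\t" in inf_line

    def test_supplementary_table_column_order(self, tmp_path):
        # published layout: low-bin counts precede high-bin counts
        path = tmp_path / "supp.tsv"
        path.write_text(
            "gene\tlow\tlow_other\thigh\thigh_other\tP\tFDR\n"
            "GENE1\t10\t990\t50\t950\t0.001\t0.01\n"
        )
        tables, frame = hs.read_supplementary_table(path)
        (table,) = tables
        assert (table.a, table.b, table.c, table.d) == (50, 950, 10, 990)
        assert frame.loc[0, "p_adj"] == 0.01

    def test_non_integer_count_is_format_error(self, tmp_path):
        path = tmp_path / "supp.tsv"
        path.write_text(
            "gene\tlow\tlow_other\thigh\thigh_other\tP\tFDR\n"
            "GENE1\t1.5\t990\t50\t950\t0.001\t0.01\n"
        )
        with pytest.raises(FormatError, match="low_in_gene"):
            hs.read_supplementary_table(path)

    def test_counts_round_trip_through_write_results(self, tmp_path):
        results = self.make_results()
        path = hs.write_results(results, tmp_path / "results.tsv")
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        by_gene = {r.gene_id: r for r in results}
        for row in frame.itertuples(index=False):
            r = by_gene[row.gene_id]
            assert (row.a, row.b, row.c, row.d) == (r.a, r.b, r.c, r.d)

    def test_fishtail_coordinates_map_inf_to_axis_max(self):
        results = self.make_results()
        coords = hs.fishtail_coordinates(results)
        finite_max = max(
            r.ratio for r in results if math.isfinite(r.ratio) and r.ratio > 0
        )
        row = coords.set_index("gene_id").loc["gene_inf"]
        assert row["ratio"] == finite_max
        assert set(coords.columns) >= {"gene_id", "combined", "ratio"}
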