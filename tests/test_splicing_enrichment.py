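import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from splicemre.est_classification import classify_all
from splicemre.formats_io import (
    ESTAlignment,
    ESTDataset,
    LibraryAnnotation,
    MRESite,
)
from splicemre.splicing_enrichment import (
    ContingencyTable,
    EnrichmentSettings,
    build_tables,
    enrich_mre,
    fisher_exact,
    fraction_regulated,
)


def oracle_fisher(a, b, c, d):
    """Exhaustive hypergeometric enumeration in exact integer arithmetic.

    Applies the same minimum-likelihood two-tail rule (tolerance factor
    1 + 1e-7, evaluated exactly on the integer weights).
    """
    N, K, n = a + b + c + d, a + c, a + b
    if K == 0 or K == N or n == 0 or n == N:
        return Fraction(1), Fraction(1), Fraction(1)
    kmin, kmax = max(0, n - (N - K)), min(n, K)
    weights = {k: math.comb(K, k) * math.comb(N - K, n - k) for k in range(kmin, kmax + 1)}
    total = sum(weights.values())
    wa = weights[a]
    p_left = Fraction(sum(w for k, w in weights.items() if k <= a), total)
    p_right = Fraction(sum(w for k, w in weights.items() if k >= a), total)
    p_two = Fraction(
        sum(w for w in weights.values() if w * 10_000_000 <= wa * 10_000_001),
        total,
    )
    return p_left, p_right, p_two


class TestFisherExact:
    def test_worked_example_tails_are_exact_fractions(self):
        r = fisher_exact(ContingencyTable(3, 7, 6, 1))
        assert r.p_left == pytest.approx(708 / 19448, rel=1e-12)
        assert r.p_right == pytest.approx(19412 / 19448, rel=1e-12)

    def test_symmetric_table(self):
        r = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert r.p_left == pytest.approx(r.p_right, rel=1e-12)
        assert r.p_twotail == pytest.approx(1.0, rel=1e-12)

    def test_extreme_table_single_term(self):
        r = fisher_exact(ContingencyTable(0, 10, 10, 0))
        assert r.p_left == pytest.approx(1 / math.comb(20, 10), rel=1e-12)

    def test_degenerate_margins_give_one(self):
        assert fisher_exact(ContingencyTable(0, 0, 3, 4)) == (1.0, 1.0, 1.0)
        assert fisher_exact(ContingencyTable(0, 3, 0, 4)) == (1.0, 1.0, 1.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            pl, pr, pt = fisher_exact(ContingencyTable(a, b, c, d))
            ol, orr, ot = oracle_fisher(a, b, c, d)
            assert pl == pytest.approx(float(ol), rel=1e-12)
            assert pr == pytest.approx(float(orr), rel=1e-12)
            assert pt == pytest.approx(float(ot), rel=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if min(a + c, b + d, a + b, c + d) == 0:
                continue
            table = [[a, b], [c, d]]
            pl, pr, pt = fisher_exact(ContingencyTable(a, b, c, d))
            assert pl == pytest.approx(
                scipy.stats.fisher_exact(table, "less")[1], rel=1e-9
            )
            assert pr == pytest.approx(
                scipy.stats.fisher_exact(table, "greater")[1], rel=1e-9
            )
            assert pt == pytest.approx(
                scipy.stats.fisher_exact(table, "two-sided")[1], rel=1e-7
            )

    @given(st.tuples(*[st.integers(min_value=0, max_value=15)] * 4))
    def test_row_and_column_swap_duality(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        base = fisher_exact(ContingencyTable(a, b, c, d))
        rows = fisher_exact(ContingencyTable(c, d, a, b))
        cols = fisher_exact(ContingencyTable(b, a, d, c))
        assert base.p_left == pytest.approx(rows.p_right, rel=1e-10)
        assert base.p_right == pytest.approx(rows.p_left, rel=1e-10)
        assert base.p_left == pytest.approx(cols.p_right, rel=1e-10)
        assert base.p_twotail == pytest.approx(rows.p_twotail, rel=1e-10)
        assert base.p_twotail == pytest.approx(cols.p_twotail, rel=1e-10)

    @given(st.tuples(*[st.integers(min_value=0, max_value=15)] * 4))
    def test_hypergeometric_tail_identity(self, cells):
        a, b, c, d = cells
        N = a + b + c + d
        K, n = a + c, a + b
        if N == 0 or K == 0 or K == N or n == 0 or n == N:
            return
        pl, pr, _ = fisher_exact(ContingencyTable(a, b, c, d))
        pa = math.comb(K, a) * math.comb(N - K, n - a) / math.comb(N, n)
        assert pl + pr - pa == pytest.approx(1.0, abs=1e-10)


class TestBuildTables:
    def test_worked_example_brain_table(self, worked_example):
        ests, mre, libraries = worked_example
        classified = classify_all(ests, mre, libraries)
        tables = {t: tab for t, _, tab in build_tables(classified, libraries)}
        assert tables["brain"] == ContingencyTable(3, 7, 6, 1)
        assert "liver" not in tables  # both liver ESTs are configuration I
        # excluded ESTs appear in no cell of any stratum
        total = sum(tab.a + tab.b for tab in tables.values())
        assert total == 17

    def test_single_tissue_has_empty_margin(self, worked_example):
        ests, mre, libraries = worked_example
        brain_only = [e for e in ests if e.library_id == "brain-lib"]
        classified = classify_all(brain_only, mre, libraries)
        ((tissue, _, tab),) = build_tables(classified, libraries)
        assert tissue == "brain"
        assert (tab.c, tab.d) == (0, 0)

    def test_histology_stratification_with_all_normal(self, worked_example):
        ests, mre, libraries = worked_example
        classified = classify_all(ests, mre, libraries)
        tables = build_tables(classified, libraries, stratify_histology=True)
        assert {stratum for _, stratum, _ in tables} == {"normal"}


def _planted_dataset(focal_free, focal_cont, other_free, other_cont):
    """Single-block ESTs spanning / gap ESTs skipping the MRE at [100, 120)."""
    libs = [LibraryAnnotation("f-lib", "focal"), LibraryAnnotation("o-lib", "other")]
    ests = []

    def add(n, lib, blocks, tag):
        for i in range(n):
            ests.append(
                ESTAlignment(f"{tag}{i}", "G1", lib, tuple(blocks))
            )

    add(focal_cont, "f-lib", [(0, 400)], "fc")
    add(focal_free, "f-lib", [(0, 90), (130, 400)], "ff")
    add(other_cont, "o-lib", [(0, 400)], "oc")
    add(other_free, "o-lib", [(0, 90), (130, 400)], "of")
    mre = MRESite("G1:s1", "G1", "miR-1", 100, 120)
    return ests, mre, libs


class TestEnrichMre:
    def test_homogeneous_proportions_never_regulated(self):
        ests, mre, libs = _planted_dataset(5, 5, 0, 0)
        # add a second tissue with identical proportions
        more = [
            ESTAlignment(f"x{i}", "G1", "o-lib", ((0, 400),)) for i in range(5)
        ] + [
            ESTAlignment(f"y{i}", "G1", "o-lib", ((0, 90), (130, 400)))
            for i in range(5)
        ]
        results, call = enrich_mre(ests + more, mre, libs)
        assert all(r.p_twotail == pytest.approx(1.0) for r in results)
        assert not call.is_regulated

    def test_planted_extreme_tissue_detected(self):
        ests, mre, libs = _planted_dataset(0, 15, 15, 15)
        results, call = enrich_mre(ests, mre, libs)
        focal = next(r for r in results if r.tissue == "focal")
        expected = math.comb(30, 15) / math.comb(45, 15)
        assert focal.p_left == pytest.approx(expected, rel=1e-10)
        assert call.is_regulated
        assert call.significant_tissues[0][2] == "left"

    def test_tissue_below_est_threshold_untested(self):
        ests, mre, libs = _planted_dataset(0, 9, 15, 15)
        results, call = enrich_mre(ests, mre, libs)
        focal = next(r for r in results if r.tissue == "focal")
        assert not focal.tested
        assert all(t != "focal" for t, _, _ in call.significant_tissues)

    def test_gene_below_est_threshold_untested(self):
        ests, mre, libs = _planted_dataset(2, 2, 2, 2)
        results, call = enrich_mre(ests, mre, libs)
        assert results == [] and not call.tested and not call.is_regulated


class TestFractionRegulated:
    def test_identical_intervals_collapse_to_one_site(self):
        ests, mre, libs = _planted_dataset(0, 15, 15, 15)
        twin = MRESite("G1:s1b", "G1", "miR-99", 100, 120)
        data = ESTDataset(alignments=ests, libraries=libs)
        result = fraction_regulated([mre, twin], data)
        assert result.n_unique == 1
        assert result.fraction == 1.0

    def test_fraction_arithmetic(self):
        ests, mre, libs = _planted_dataset(8, 7, 15, 15)  # balanced, null-ish
        data = ESTDataset(alignments=ests, libraries=libs)
        other = MRESite("G1:s2", "G1", "miR-2", 200, 220)  # inside every block
        result = fraction_regulated([mre, other], data)
        assert result.n_tested == 2
        assert result.fraction == result.n_regulated / 2

    def test_empty_catalog_is_error(self):
        data = ESTDataset(alignments=[], libraries=[])
        with pytest.raises(ValueError, match="empty"):
            fraction_regulated([], data)

    def test_no_testable_site_is_error(self):
        ests, mre, libs = _planted_dataset(2, 2, 2, 2)
        data = ESTDataset(alignments=ests, libraries=libs)
        with pytest.raises(ValueError, match="testable"):
            fraction_regulated([mre], data)


class TestTypeIError:
    def test_null_rejection_rate_is_conservative(self):
        """Per-tissue two-tailed rejection at alpha 0.05 on null tables with
        >= 10 informative ESTs per tissue stays within Monte-Carlo bounds."""
        rng = np.random.default_rng(2024)
        n_tables = 2000
        rejections = 0
        for _ in range(n_tables):
            free = rng.binomial(15, 0.5, size=2)
            tab = ContingencyTable(
                int(free[0]), 15 - int(free[0]), int(free[1]), 15 - int(free[1])
            )
            if fisher_exact(tab).p_twotail < 0.05:
                rejections += 1
        rate = rejections / n_tables
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_tables)
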