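"""Contingency tables, the exact test, BH adjustment, and the full analysis."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from darkproteome import enrichment
from darkproteome.types import (
    AnnotationEntry,
    AnnotationField,
    ContingencyTable,
    Direction,
    EnrichmentConfig,
)

from conftest import make_protein


def _universe(n, n_dark, annotated_dark, annotated_nondark, ann):
    """n proteins, the first n_dark labelled dark; the first annotated_* of
    each class carry the annotation."""
    prots, labels = [], {}
    for i in range(n):
        acc = f"P{i}"
        is_dark = i < n_dark
        idx_in_class = i if is_dark else i - n_dark
        quota = annotated_dark if is_dark else annotated_nondark
        p = make_protein(acc, 10)
        if idx_in_class < quota:
            p.annotations.append(ann)
        prots.append(p)
        labels[acc] = is_dark
    return prots, labels


ANN = AnnotationEntry(AnnotationField.DE, "FUNCTION", "secreted")


class TestBuildTables:
    def test_hand_counted_table(self):
        prots, labels = _universe(10, 4, annotated_dark=3, annotated_nondark=1, ann=ANN)
        tables = enrichment.build_tables(prots, labels)
        assert tables[ANN] == ContingencyTable(3, 1, 1, 5)

    def test_annotation_held_by_all(self):
        prots, labels = _universe(10, 4, 4, 6, ANN)
        assert enrichment.build_tables(prots, labels)[ANN] == ContingencyTable(4, 0, 6, 0)

    def test_duplicate_annotation_counts_once_per_protein(self):
        prots, labels = _universe(4, 2, 1, 1, ANN)
        prots[0].annotations.append(ANN)  # same annotation twice on one protein
        tables = enrichment.build_tables(prots, labels)
        assert tables[ANN].dark_with == 1

    def test_missing_label_rejected(self):
        prots, labels = _universe(4, 2, 1, 1, ANN)
        del labels["P3"]
        with pytest.raises(ValueError, match="P3"):
            enrichment.build_tables(prots, labels)


def brute_force_fisher_p(a, b, c, d):
    """Exhaustive enumeration of all tables with the observed margins, in
    exact integer weights (independent of the implementation's loop)."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    tables = [
        (x, r1 - x, c1 - x, r2 - (c1 - x))
        for x in range(0, r1 + 1)
        if 0 <= c1 - x <= r2
    ]
    weight = lambda t: math.comb(r1, t[0]) * math.comb(r2, t[2])
    w_obs = weight((a, b, c, d))
    return sum(weight(t) for t in tables if weight(t) <= w_obs) / math.comb(n, c1)


class TestFisherExact:
    def test_symmetric_table(self):
        p, odds = enrichment.fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert p == 1.0 and odds == 1.0

    def test_cross_table_against_enumeration(self):
        p, odds = enrichment.fisher_exact(ContingencyTable(8, 2, 2, 8))
        assert p == pytest.approx(brute_force_fisher_p(8, 2, 2, 8), abs=1e-15)
        assert odds == 16.0

    def test_infinite_odds_ratio_handled(self):
        p, odds = enrichment.fisher_exact(ContingencyTable(4, 0, 6, 2))
        assert odds == math.inf and 0 <= p <= 1

    def test_degenerate_margin(self):
        p, odds = enrichment.fisher_exact(ContingencyTable(4, 0, 6, 0))
        assert p == 1.0 and odds == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            enrichment.fisher_exact(ContingencyTable(0, 0, 0, 0))

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_agrees_with_scipy(self, a, b, c, d):
        """Independent cross-check against scipy's implementation."""
        if a + b + c + d == 0:
            return
        p, _ = enrichment.fisher_exact(ContingencyTable(a, b, c, d))
        p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_scipy, abs=1e-10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj, ranks = enrichment.bh_adjust([0.01, 0.02, 0.03])
        assert adj.tolist() == pytest.approx([0.03, 0.03, 0.03])
        assert ranks.tolist() == [1, 2, 3]

    def test_single_value(self):
        adj, _ = enrichment.bh_adjust([1.0])
        assert adj.tolist() == [1.0]

    def test_ties_share_rank(self):
        adj, ranks = enrichment.bh_adjust([0.5, 0.5])
        assert adj.tolist() == pytest.approx([0.5, 0.5])
        assert ranks.tolist() == [1, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enrichment.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_never_below_raw(self, pvals):
        adj, _ = enrichment.bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (adj >= p - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestEnrich:
    def test_planted_overrepresentation_recovered(self):
        prots, labels = _universe(2000, 500, annotated_dark=200, annotated_nondark=40, ann=ANN)
        [res] = enrichment.enrich(prots, labels)
        assert res.annotation == ANN
        assert res.direction is Direction.over
        assert res.odds_ratio > 1
        assert res.p_adjusted <= 0.01

    def test_excluded_subcategory_never_tested(self):
        sim = AnnotationEntry(AnnotationField.DE, "SIMILARITY", "Belongs to family X")
        prots, labels = _universe(2000, 500, 200, 40, sim)
        assert enrichment.enrich(prots, labels) == []

    def test_families_corrected_separately(self):
        # identical counts in DE and FT: same adjusted p within each family
        de = AnnotationEntry(AnnotationField.DE, "FUNCTION", "x")
        ft = AnnotationEntry(AnnotationField.FT, "transmem", "Helical")
        prots, labels = _universe(400, 100, 60, 10, de)
        for p in prots:
            if de in p.annotations:
                p.annotations.append(ft)
        results = enrichment.enrich(prots, labels)
        by_field = {r.annotation.field: r for r in results}
        assert set(by_field) == {AnnotationField.DE, AnnotationField.FT}
        assert by_field[AnnotationField.DE].p_adjusted == pytest.approx(
            by_field[AnnotationField.FT].p_adjusted
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment.enrich([], {})

    def test_output_sorted_by_adjusted_p(self):
        a1 = AnnotationEntry(AnnotationField.DE, "FUNCTION", "strong")
        a2 = AnnotationEntry(AnnotationField.DE, "FUNCTION", "weak")
        prots, labels = _universe(600, 150, 120, 20, a1)
        for i, p in enumerate(prots):
            is_dark = labels[p.accession]
            idx = i if is_dark else i - 150
            if (is_dark and idx < 60) or (not is_dark and idx < 60):
                p.annotations.append(a2)
        results = enrichment.enrich(prots, labels, EnrichmentConfig(alpha=0.5))
        adj = [r.p_adjusted for r in results]
        assert adj == sorted(adj)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(alpha=1.5)
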