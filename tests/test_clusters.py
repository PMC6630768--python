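"""Gene ordering, longest dark runs, permutation p-values, cluster summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from darkproteome import clusters
from darkproteome.types import ChromosomeOrder, LinkTable


def loci_frame(rows):
    return pd.DataFrame(rows, columns=["accession", "chromosome", "central_position"])


def order_of(labels):
    return ChromosomeOrder("c", [(f"P{i}", i * 10, bool(v)) for i, v in enumerate(labels)])


def brute_force_longest(labels):
    """Longest all-dark window, checked over every window (oracle)."""
    n = len(labels)
    best = 0
    for i in range(n):
        for j in range(i, n):
            if all(labels[i : j + 1]):
                best = max(best, j - i + 1)
    return best


class TestBuildOrder:
    def test_duplicate_protein_keeps_first_occurrence(self):
        loci = loci_frame([("P1", "chr1", 100), ("P1", "chr1", 900), ("P2", "chr1", 500)])
        order = clusters.build_order(loci, {"P1": True, "P2": False})["chr1"]
        assert [(a, p) for a, p, _ in order.entries] == [("P1", 100), ("P2", 500)]

    def test_empty_chromosome_absent(self):
        assert clusters.build_order(loci_frame([]), {}) == {}

    def test_position_tie_broken_lexicographically(self):
        loci = loci_frame([("PB", "chr1", 100), ("PA", "chr1", 100)])
        order = clusters.build_order(loci, {"PA": True, "PB": True})["chr1"]
        assert [a for a, _, _ in order.entries] == ["PA", "PB"]

    def test_deduplication_never_increases_run_length(self):
        labels = {"P1": True, "P2": True, "P3": False}
        base = loci_frame([("P1", "chr1", 1), ("P2", "chr1", 2), ("P3", "chr1", 3)])
        with_dup = pd.concat(
            [base, loci_frame([("P1", "chr1", 4)])], ignore_index=True
        )
        run_base = clusters.longest_run(clusters.build_order(base, labels)["chr1"])[0]
        run_dup = clusters.longest_run(clusters.build_order(with_dup, labels)["chr1"])[0]
        assert run_dup <= run_base


class TestLongestRun:
    def test_direct_scan(self):
        length, members = clusters.longest_run(order_of([1, 1, 0, 1, 1, 1]))
        assert length == 3 and members == ["P3", "P4", "P5"]

    def test_all_non_dark_gives_zero(self):
        assert clusters.longest_run(order_of([0, 0, 0])) == (0, [])

    def test_leftmost_run_on_ties(self):
        _, members = clusters.longest_run(order_of([1, 1, 0, 1, 1]))
        assert members == ["P0", "P1"]

    @given(st.lists(st.booleans(), min_size=1, max_size=15))
    @settings(deadline=None, derandomize=True)
    def test_equals_window_oracle(self, labels):
        assert clusters.longest_run(order_of(labels))[0] == brute_force_longest(labels)


class TestPermutationPvalue:
    def test_all_dark_gives_p_one(self):
        assert clusters.permutation_pvalue(order_of([1, 1, 1]), 100, seed=0) == 1.0

    def test_run_zero_gives_p_one(self):
        assert clusters.permutation_pvalue(order_of([0, 0, 0]), 100, seed=0) == 1.0

    def test_planted_long_run_is_rare(self):
        rng = np.random.default_rng(3)
        labels = (rng.random(500) < 0.05).tolist()
        labels[100:110] = [True] * 10
        p = clusters.permutation_pvalue(order_of(labels), 1000, seed=1)
        assert p <= 0.005

    def test_seeded_and_reproducible(self):
        order = order_of((np.arange(50) % 7 == 0).tolist())
        p1 = clusters.permutation_pvalue(order, 500, seed=11)
        p2 = clusters.permutation_pvalue(order, 500, seed=11)
        assert p1 == p2

    def test_p_on_the_grid(self):
        order = order_of((np.arange(40) % 5 == 0).tolist())
        p = clusters.permutation_pvalue(order, 200, seed=2)
        assert 0.0 <= p <= 1.0 and round(p * 200) == pytest.approx(p * 200)

    def test_empty_or_invalid_rejected(self):
        with pytest.raises(ValueError):
            clusters.permutation_pvalue(ChromosomeOrder("c", []), 100)
        with pytest.raises(ValueError):
            clusters.permutation_pvalue(order_of([1]), 0)


class TestCompositionBias:
    def test_direct_count(self):
        assert clusters.composition_bias("CCCCS") == pytest.approx(80.0)

    def test_homopolymer(self):
        assert clusters.composition_bias("QQQQQQ") == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clusters.composition_bias("")


class TestFindDarkClusters:
    def _setup(self):
        loci = loci_frame(
            [("P1", "chr1", 10), ("P2", "chr1", 20), ("P3", "chr1", 30), ("P4", "chr1", 40)]
        )
        labels = {"P1": False, "P2": True, "P3": True, "P4": False}
        return loci, labels

    def test_member_summaries(self):
        loci, labels = self._setup()
        links = LinkTable([("P2", "P3", 800), ("P2", "P9", 900)])
        seqs = {"P2": "CCCCS", "P3": "AAAA"}
        [res] = clusters.find_dark_clusters(
            loci, labels, links=links, sequences=seqs, seed=0
        )
        assert res.run_length == 2 and res.run_members == ["P2", "P3"]
        by_acc = {m.accession: m for m in res.members}
        assert by_acc["P2"].binds == 1  # only the within-cluster partner counts
        assert by_acc["P2"].bias_pct == pytest.approx(80.0)
        assert by_acc["P3"].length == 4

    def test_missing_sequence_leaves_bias_absent(self):
        loci, labels = self._setup()
        [res] = clusters.find_dark_clusters(
            loci, labels, sequences={"P2": "CCCCS"}, lengths={"P3": 7}, seed=0
        )
        by_acc = {m.accession: m for m in res.members}
        assert by_acc["P3"].bias_pct is None and by_acc["P3"].length == 7

    def test_isolated_proteins_bind_nothing(self):
        loci, labels = self._setup()
        [res] = clusters.find_dark_clusters(loci, labels, links=LinkTable([]), seed=0)
        assert all(m.binds == 0 for m in res.members)

    def test_results_independent_of_chromosome_insertion_order(self):
        loci, labels = self._setup()
        loci2 = pd.concat(
            [loci_frame([("P5", "chr2", 5)]), loci], ignore_index=True
        )
        labels2 = dict(labels, P5=True)
        res_multi = {
            r.chromosome: r.p_perm
            for r in clusters.find_dark_clusters(loci2, labels2, seed=4)
        }
        [res_single] = clusters.find_dark_clusters(loci, labels, seed=4)
        assert res_multi["chr1"] == res_single.p_perm
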