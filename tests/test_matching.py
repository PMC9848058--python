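import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sciber import (
    fisher_one_sided,
    match_clusters,
    overlap_table,
    putative_matches,
)
from sciber.markers import MarkerSet
from sciber.matching import MatchedPair


def _ms(genes, cluster_id=1, batch="q"):
    return MarkerSet(batch, cluster_id, list(genes),
                     [0.01] * len(genes), h=max(len(genes), 1))


def hypergeom_tail_oracle(a, b, c, d):
    """Exact upper-tail P[X >= a] by rational-arithmetic summation."""
    M, n, N = a + b + c + d, a + c, a + b
    total = Fraction(0)
    for k in range(a, min(n, N) + 1):
        total += Fraction(math.comb(n, k) * math.comb(M - n, N - k),
                          math.comb(M, N))
    return float(total)


class TestOverlapTable:
    def test_identical_sets(self):
        genes = [f"g{i}" for i in range(5)]
        assert overlap_table(_ms(genes), _ms(genes), p=20) == (5, 0, 0, 15)

    def test_disjoint_sets(self):
        a = _ms([f"g{i}" for i in range(3)])
        b = _ms([f"h{i}" for i in range(4)])
        assert overlap_table(a, b, p=20) == (0, 3, 4, 13)

    def test_random_sets_match_set_oracle(self, rng):
        panel = [f"g{i}" for i in range(40)]
        for _ in range(20):
            q = set(rng.choice(panel, size=8, replace=False))
            r = set(rng.choice(panel, size=12, replace=False))
            a, b, c, d = overlap_table(_ms(q), _ms(r), p=40)
            assert a == len(q & r)
            assert b == len(q - r)
            assert c == len(r - q)
            assert d == 40 - len(q | r)

    def test_stray_gene_rejected_when_panel_given(self):
        with pytest.raises(ValueError, match="not in panel"):
            overlap_table(_ms(["gX"]), _ms(["g0"]), p=10, panel={"g0", "g1"})


class TestFisherOneSided:
    def test_empty_draw_gives_one(self):
        assert fisher_one_sided((0, 0, 3, 7)) == 1.0

    def test_single_most_extreme_table(self):
        # panel of 10, both sets size 2, identical: P = 1 / C(10,2) = 1/45
        assert fisher_one_sided((2, 0, 0, 8)) == pytest.approx(1 / 45, abs=1e-15)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided((1, -1, 2, 3))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(0, 60)] * 4))
    def test_matches_exact_tail_sum(self, table):
        assert fisher_one_sided(table) == pytest.approx(
            hypergeom_tail_oracle(*table), abs=1e-12
        )


class TestMatchClusters:
    def test_identical_marker_sets_give_bijection(self):
        panel = 100
        sets = [[f"g{10 * k + i}" for i in range(10)] for k in range(3)]
        q = [_ms(s, cluster_id=k + 1, batch="q") for k, s in enumerate(sets)]
        r = [_ms(s, cluster_id=k + 1, batch="r") for k, s in enumerate(sets)]
        pairs = match_clusters(q, r, p=panel)
        assert [(pr.query_cluster, pr.ref_cluster) for pr in pairs] == [
            (1, 1), (2, 2), (3, 3)
        ]
        assert all(pr.overlap == 10 for pr in pairs)

    def test_zero_overlap_cluster_still_paired(self):
        q = [_ms(["g0", "g1"], 1, "q")]
        r = [_ms(["g5", "g6"], 1, "r"), _ms(["g7"], 2, "r")]
        pairs = match_clusters(q, r, p=50)
        assert len(pairs) == 1
        assert pairs[0].overlap == 0
        assert pairs[0].p_value > 0.05  # weak match, destined for discard

    def test_untestable_sets_yield_no_pair(self):
        q = [
            _ms(["g0"], 1, "q"),
            MarkerSet("q", 2, [], [], h=5, untestable=True),
        ]
        r = [_ms(["g0"], 1, "r")]
        pairs = match_clusters(q, r, p=10)
        assert [pr.query_cluster for pr in pairs] == [1]

    def test_no_testable_reference_rejected(self):
        q = [_ms(["g0"], 1, "q")]
        r = [MarkerSet("r", 1, [], [], h=5, untestable=True)]
        with pytest.raises(ValueError, match="reference"):
            match_clusters(q, r, p=10)

    def test_many_to_one_allowed(self):
        shared = [f"g{i}" for i in range(10)]
        q = [_ms(shared, 1, "q"), _ms(shared, 2, "q")]
        r = [_ms(shared, 1, "r")]
        pairs = match_clusters(q, r, p=100)
        assert [pr.ref_cluster for pr in pairs] == [1, 1]

    def test_table_margins_consistent(self, rng):
        panel = [f"g{i}" for i in range(60)]
        q = [_ms(rng.choice(panel, 10, replace=False), 1, "q")]
        r = [_ms(rng.choice(panel, 15, replace=False), 1, "r")]
        (pr,) = match_clusters(q, r, p=60)
        a, b, c, d = pr.table
        assert a == pr.overlap
        assert a + b == 10 and a + c == 15 and a + b + c + d == 60


class TestPutativeMatches:
    def _pairs(self, pvals):
        return [
            MatchedPair("q", i + 1, i + 1, overlap=5,
                        table=(5, 5, 5, 85), p_value=p)
            for i, p in enumerate(pvals)
        ]

    def test_half_of_four_pairs(self):
        out = putative_matches(self._pairs([0.4, 0.1, 0.9, 0.2]), omega=0.5)
        assert [pr.putative for pr in out] == [False, True, False, True]

    def test_omega_one_keeps_all(self):
        out = putative_matches(self._pairs([0.5, 0.5, 0.5]), omega=1.0)
        assert all(pr.putative for pr in out)

    def test_at_least_one_putative(self):
        out = putative_matches(self._pairs([0.9, 0.8, 0.7]), omega=0.01)
        assert sum(pr.putative for pr in out) == 1

    def test_invalid_omega_rejected(self):
        pairs = self._pairs([0.5])
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                putative_matches(pairs, omega=bad)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_decreasing_omega_never_adds_a_pair(self, pvals):
        pairs = self._pairs(pvals)
        selected = {}
        for omega in (0.9, 0.6, 0.3):
            out = putative_matches(pairs, omega=omega)
            selected[omega] = {pr.query_cluster for pr in out if pr.putative}
        assert selected[0.3] <= selected[0.6] <= selected[0.9]

    def test_input_order_preserved_and_input_untouched(self):
        pairs = self._pairs([0.3, 0.1])
        out = putative_matches(pairs, omega=0.5)
        assert [pr.query_cluster for pr in out] == [1, 2]
        assert all(not pr.putative for pr in pairs)
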