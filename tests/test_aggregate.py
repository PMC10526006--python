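"""Rank aggregation, normalization, percentile and tau-b checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbdhub.aggregate import (
    RankList,
    kendall_tau_b,
    minmax,
    percentile_rank,
    ulara,
)
from lbdhub.pathscore import MetapathSchema

from conftest import tau_b_oracle


def _list(tag, scores):
    return RankList(MetapathSchema.parse(f"OUT:{tag}"), dict(scores))


def _descending(tag, n):
    return _list(tag, {f"C{i:07d}": (n - i) / n for i in range(n)})


def _ascending(tag, n):
    return _list(tag, {f"C{i:07d}": (i + 1) / n for i in range(n)})


class TestUlara:
    def test_identical_lists_share_weight_equally(self):
        lists = [_descending(t, 10) for t in ("A", "B", "C")]
        result = ulara(lists)
        assert all(w == pytest.approx(1 / 3, abs=1e-9) for w in result.weights.values())
        order = sorted(result.relevance, key=result.relevance.get, reverse=True)
        assert order == sorted(lists[0].scores, key=lists[0].scores.get, reverse=True)

    def test_single_list_gets_all_weight(self):
        lst = _descending("A", 6)
        result = ulara([lst])
        assert list(result.weights.values()) == [pytest.approx(1.0)]
        for cui, score in lst.scores.items():
            assert result.relevance[cui] == pytest.approx(score)

    def test_reversed_voter_downweighted(self, rng):
        """One contrarian among four agreeing voters gets the smallest weight."""
        for trial in range(20):
            n = int(rng.integers(10, 30))
            agree = [_descending(t, n) for t in ("A", "B", "C", "D")]
            contrarian = _ascending("E", n)
            result = ulara(agree + [contrarian])
            weights = {str(s): w for s, w in result.weights.items()}
            w_rev = weights["OUT:E"]
            assert w_rev < 1 / 5
            assert all(w_rev < weights[f"OUT:{t}"] for t in "ABCD")

    def test_weights_nonnegative_and_sum_to_one(self, rng):
        for _ in range(10):
            n_lists = int(rng.integers(1, 6))
            n = int(rng.integers(3, 15))
            lists = [
                _list(
                    f"P{j}",
                    {f"C{i:07d}": float(rng.random()) for i in range(n)},
                )
                for j in range(n_lists)
            ]
            result = ulara(lists)
            w = np.array(list(result.weights.values()))
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert all(0.0 <= v <= 1.0 for v in result.relevance.values())

    def test_permutation_equivariance(self):
        lists = [
            _list("A", {"C0000001": 0.9, "C0000002": 0.5, "C0000003": 0.1}),
            _list("B", {"C0000001": 0.8, "C0000002": 0.1, "C0000003": 0.4}),
        ]
        mapping = {"C0000001": "C0000007", "C0000002": "C0000005", "C0000003": "C0000006"}
        renamed = [
            RankList(l.schema, {mapping[c]: s for c, s in l.scores.items()})
            for l in lists
        ]
        r1, r2 = ulara(lists), ulara(renamed)
        assert [w for w in r1.weights.values()] == pytest.approx(
            [w for w in r2.weights.values()]
        )
        for old, new in mapping.items():
            assert r1.relevance[old] == pytest.approx(r2.relevance[new])

    def test_partial_lists_cover_the_union_universe(self):
        full = _descending("A", 5)
        partial = _list("B", {"C0000004": 1.0})
        result = ulara([full, partial])
        assert set(result.relevance) == set(full.scores) | set(partial.scores)
        # a node missing from a list contributes HeteSim 0 there, so its
        # relevance is bounded by the weight of the lists that rank it
        w_b = result.weights[partial.schema]
        assert result.relevance["C0000004"] <= (
            (1 - w_b) * full.scores["C0000004"] + w_b * 1.0 + 1e-12
        )

    def test_zero_lists_rejected(self):
        with pytest.raises(ValueError):
            ulara([])


class TestMinmax:
    def test_basic(self):
        assert minmax([2, 4, 6]) == pytest.approx([0.0, 0.5, 1.0])

    def test_all_equal_maps_to_half(self):
        assert minmax([5, 5]) == pytest.approx([0.5, 0.5])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax([])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        scores=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
        a=st.floats(0.1, 100),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, scores, a, b):
        direct = minmax(scores)
        shifted = minmax([a * s + b for s in scores])
        assert np.allclose(direct, shifted, atol=1e-6)


class TestPercentileRank:
    def test_counting_definition_example(self):
        assert percentile_rank([10, 20, 30]) == pytest.approx(
            [16.67, 50.0, 83.33], abs=0.01
        )

    def test_all_equal_is_fifty(self):
        assert percentile_rank([7, 7, 7, 7]) == pytest.approx([50.0] * 4)

    def test_maximum_of_distinct(self):
        n = 17
        pct = percentile_rank(list(range(n)))
        assert pct[-1] == pytest.approx(100 * (n - 0.5) / n)

    def test_matches_counting_oracle(self, rng):
        scores = rng.integers(0, 10, size=40).astype(float)
        pct = percentile_rank(scores)
        for i, s in enumerate(scores):
            less = (scores < s).sum()
            equal = (scores == s).sum()
            assert pct[i] == pytest.approx(100 * (less + 0.5 * equal) / len(scores))

    def test_invariant_under_minmax(self, rng):
        scores = rng.random(100)
        assert percentile_rank(scores) == pytest.approx(
            percentile_rank(minmax(scores))
        )


class TestKendallTauB:
    def test_identical_is_one(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_reversed_tie_free_is_minus_one(self):
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_single_swap_example(self):
        # pairs: 5 concordant, 1 discordant -> 4/6
        assert kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            2 / 3, abs=1e-4
        )

    def test_matches_exhaustive_pair_count_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 200))
            x = rng.integers(0, 20, size=n).astype(float)  # many ties
            y = rng.integers(0, 20, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert kendall_tau_b(x, y) == pytest.approx(
                tau_b_oracle(x, y), abs=1e-10
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b([1], [2])
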