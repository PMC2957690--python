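from collections import Counter
from itertools import product

import numpy as np
import pytest

from iddcomp.clustering import ClusterMatch, ClusterProfile
from iddcomp.pfam import (
    PfamCatalog,
    cooccurring_pfams,
    distinct_cooccurrence_count,
    permutation_test,
    pfam_expected_count,
)


def _prof(cid, members):
    return ClusterProfile(
        cluster_id=cid, member_ids=members, mean=np.full(20, 0.05), std=np.zeros(20)
    )


class TestCatalog:
    def test_cluster_aggregation_via_segments(self):
        cat = PfamCatalog.from_pairs([("p1", "X"), ("p1", "X"), ("p2", "Y")])
        clusters = [_prof(0, ["p1:1-40", "p2:5-60"]), _prof(1, ["p1:80-120"])]
        counts = cat.cluster_counts(clusters)
        assert counts[0] == Counter({"X": 2, "Y": 1})
        assert counts[1] == Counter({"X": 2})  # multi-IDD protein appears in both

    def test_per_protein_once(self):
        cat = PfamCatalog.from_pairs([("p1", "X"), ("p1", "X")])
        counts = cat.cluster_counts([_prof(0, ["p1:1-40"])], per_protein_once=True)
        assert counts[0] == Counter({"X": 1})


class TestExpectedCount:
    def test_direct_arithmetic(self):
        counts = {
            0: Counter({"p": 10, "q": 10}),  # N^c = 20
            1: Counter({"q": 180}),
        }
        assert pfam_expected_count("p", 0, counts) == pytest.approx(1.0)

    def test_empty_cluster(self):
        counts = {0: Counter({"p": 5}), 1: Counter()}
        assert pfam_expected_count("p", 1, counts) == 0.0

    def test_single_cluster_holds_everything(self):
        counts = {0: Counter({"p": 7, "q": 3})}
        assert pfam_expected_count("p", 0, counts) == pytest.approx(7.0)

    def test_unknown_cluster_is_error(self):
        with pytest.raises(KeyError):
            pfam_expected_count("p", 9, {0: Counter({"p": 1})})


class TestCooccurrence:
    def test_both_sides_rule(self):
        counts_a = {0: Counter({"X": 5, "Y": 2})}
        counts_b = {1: Counter({"X": 3})}
        matches = [ClusterMatch(0, 1, 1.0)]
        recs = cooccurring_pfams(matches, counts_a, counts_b)
        assert [r.pfam_id for r in recs] == ["X"]
        (r,) = recs
        assert (r.count_a, r.total_a, r.count_b, r.total_b) == (5, 7, 3, 3)

    def test_min_total_excludes_single_occurrences(self):
        counts_a = {0: Counter({"Z": 1})}
        counts_b = {1: Counter({"Z": 1})}
        recs = cooccurring_pfams([ClusterMatch(0, 1, 1.0)], counts_a, counts_b)
        assert recs == []

    def test_min_total_satisfied_by_one_set(self):
        counts_a = {0: Counter({"Z": 1}), 2: Counter({"Z": 1})}  # set total 2
        counts_b = {1: Counter({"Z": 1})}
        recs = cooccurring_pfams([ClusterMatch(0, 1, 1.0)], counts_a, counts_b)
        assert [r.pfam_id for r in recs] == ["Z"]

    def test_distinct_count_matches_brute_force(self, rng):
        pfams = list("UVWXYZ")
        counts_a = {
            i: Counter(rng.choice(pfams, size=rng.integers(0, 6))) for i in range(4)
        }
        counts_b = {
            i: Counter(rng.choice(pfams, size=rng.integers(0, 6))) for i in range(4)
        }
        matches = [ClusterMatch(i, int(rng.integers(0, 4)), 1.0) for i in range(4)]
        got = distinct_cooccurrence_count(matches, counts_a, counts_b)
        totals_a = Counter()
        totals_b = Counter()
        for c in counts_a.values():
            totals_a.update(c)
        for c in counts_b.values():
            totals_b.update(c)
        brute = set()
        for m in matches:
            for p in set(counts_a[m.cluster_a]) & set(counts_b[m.cluster_b]):
                if totals_a[p] >= 2 or totals_b[p] >= 2:
                    brute.add(p)
        assert got == len(brute)


class TestPermutationTest:
    def _toy(self):
        counts_a = {
            0: Counter({"X": 2, "Y": 1}),
            1: Counter({"Y": 2}),
            2: Counter({"Z": 2}),
        }
        counts_b = {
            0: Counter({"X": 2}),
            1: Counter({"Y": 2, "Z": 1}),
            2: Counter({"W": 2}),
        }
        matches = [ClusterMatch(0, 0, 1.0), ClusterMatch(1, 1, 1.0), ClusterMatch(2, 2, 1.0)]
        return matches, counts_a, counts_b

    def test_zero_observed_gives_p_one(self):
        counts_a = {0: Counter({"X": 5})}
        counts_b = {0: Counter({"Y": 5})}
        null = permutation_test([ClusterMatch(0, 0, 1.0)], counts_a, counts_b, n_reps=50, seed=1)
        assert null.observed == 0 and null.p_value == 1.0

    def test_degenerate_single_pair(self):
        counts_a = {0: Counter({"X": 2})}
        counts_b = {0: Counter({"X": 2})}
        null = permutation_test([ClusterMatch(0, 0, 1.0)], counts_a, counts_b, n_reps=50, seed=1)
        assert null.p_value == 1.0  # every replicate reproduces the observed pairing

    def test_matches_exhaustive_enumeration(self):
        """Empirical tail fraction agrees with the exact 27-pairing enumeration."""
        matches, counts_a, counts_b = self._toy()
        sets_a = {k: set(v) for k, v in counts_a.items()}
        sets_b = {k: set(v) for k, v in counts_b.items()}
        totals_a = Counter()
        totals_b = Counter()
        for c in counts_a.values():
            totals_a.update(c)
        for c in counts_b.values():
            totals_b.update(c)

        def eligible(p):
            return totals_a[p] >= 2 or totals_b[p] >= 2

        def count(pairing):
            co = set()
            for ca, cb in zip(range(3), pairing):
                co |= {p for p in sets_a[ca] & sets_b[cb] if eligible(p)}
            return len(co)

        observed = count((0, 1, 2))
        exact_counts = [count(p) for p in product(range(3), repeat=3)]
        exact_p = sum(1 for c in exact_counts if c >= observed) / len(exact_counts)

        n_reps = 4000
        null = permutation_test(matches, counts_a, counts_b, n_reps=n_reps, seed=13)
        assert null.observed == observed
        se = (exact_p * (1 - exact_p) / n_reps) ** 0.5
        assert abs(null.p_value - exact_p) <= 3 * se

    def test_without_replacement_pairing(self):
        matches, counts_a, counts_b = self._toy()
        null = permutation_test(
            matches, counts_a, counts_b, n_reps=100, seed=5, with_replacement=False
        )
        assert 0 < null.p_value <= 1.0

    def test_invalid_reps(self):
        matches, counts_a, counts_b = self._toy()
        with pytest.raises(ValueError):
            permutation_test(matches, counts_a, counts_b, n_reps=0, seed=1)
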