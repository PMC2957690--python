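import math

import numpy as np
import pytest

from iddcomp.alphabet import AA_INDEX
from iddcomp.clustering import (
    ClusterProfile,
    cluster,
    cluster_similarity,
    cutoff_scan,
    match_clusters,
)
from iddcomp.composition import frequency_vector, pair_similarity

from conftest import make_seqs, random_seqs


def _profile(cid, means, stds=None, members=("m",)):
    mean = np.zeros(20)
    for aa, v in means.items():
        mean[AA_INDEX[aa]] = v
    std = np.zeros(20)
    for aa, v in (stds or {}).items():
        std[AA_INDEX[aa]] = v
    return ClusterProfile(cluster_id=cid, member_ids=list(members), mean=mean, std=std)


class TestCluster:
    def test_identical_compositions_merge(self):
        profs = cluster(make_seqs(["ACAC", "CACA"]), cutoff=0.05)
        assert len(profs) == 1 and profs[0].size == 2

    def test_separated_compositions_split(self):
        # d(A,A)=0; d(A,C)=1-e^-100 ~ 1 > 0.15
        profs = cluster(make_seqs(["AAAA", "AAA", "CCCC"]), cutoff=0.15)
        assert sorted(p.size for p in profs) == [1, 2]
        assert profs[0].member_ids == ["s0", "s1"]  # largest cluster gets id 0

    def test_zero_cutoff_gives_singletons(self, rng):
        seqs = random_seqs(rng, 8)
        profs = cluster(seqs, cutoff=0.0)
        assert len(profs) == len(seqs)

    def test_partition_property(self, rng):
        seqs = random_seqs(rng, 25)
        profs = cluster(seqs, cutoff=0.15)
        members = [m for p in profs for m in p.member_ids]
        assert sorted(members) == sorted(s.id for s in seqs)

    def test_profile_mean_and_std(self):
        profs = cluster(make_seqs(["AAAA", "AACC"]), cutoff=1.0)
        (p,) = profs
        assert p.mean[AA_INDEX["A"]] == pytest.approx(0.75)
        assert p.std[AA_INDEX["A"]] == pytest.approx(0.25)  # population std
        assert p.mean.sum() == pytest.approx(1.0)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            cluster(make_seqs(["AAAA"]), cutoff=1.5)

    def test_singleton_input(self):
        (p,) = cluster(make_seqs(["ACDE"]), cutoff=0.15)
        assert p.size == 1 and (p.std == 0).all()


class TestClusterSimilarity:
    def test_self_similarity_is_one(self, rng):
        seqs = random_seqs(rng, 10)
        (p,) = cluster(seqs, cutoff=1.0)
        assert cluster_similarity(p, p) == pytest.approx(1.0, abs=1e-15)

    def test_hand_evaluated_example(self):
        # each exponent -0.01/0.02; numerator 2 e^-0.5, denominator 2
        ca = _profile(0, {"A": 0.6, "C": 0.4}, {"A": 0.1, "C": 0.1})
        cb = _profile(1, {"A": 0.5, "C": 0.5}, {"A": 0.1, "C": 0.1})
        assert cluster_similarity(ca, cb) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_singletons_fall_back_to_pairwise(self):
        a, b = make_seqs(["AAAAG", "AACCG"])
        (pa,) = cluster([a], cutoff=0.15)
        (pb,) = cluster([b], cutoff=0.15)
        expected = pair_similarity(frequency_vector(a), frequency_vector(b), w=0.1)
        assert cluster_similarity(pa, pb, fallback_w=0.1) == pytest.approx(expected, rel=1e-12)


class TestMatchClusters:
    def test_copies_match_perfectly(self):
        set_a = [_profile(i, {"A": 0.5 + 0.05 * i, "C": 0.5 - 0.05 * i}) for i in range(3)]
        set_b = [_profile(i + 10, {"A": 0.5 + 0.05 * i, "C": 0.5 - 0.05 * i}) for i in range(3)]
        matches = match_clusters(set_a, set_b)
        assert [(m.cluster_a, m.cluster_b) for m in matches] == [(0, 10), (1, 11), (2, 12)]
        assert all(m.score == pytest.approx(1.0) for m in matches)

    def test_single_b_cluster_takes_all(self):
        set_a = [_profile(0, {"A": 1.0}), _profile(1, {"C": 1.0})]
        set_b = [_profile(7, {"G": 1.0})]
        assert [m.cluster_b for m in match_clusters(set_a, set_b)] == [7, 7]

    def test_tie_breaks_to_lowest_b_id(self):
        set_a = [_profile(0, {"A": 1.0})]
        set_b = [_profile(5, {"C": 1.0}), _profile(2, {"C": 1.0})]
        assert match_clusters(set_a, set_b)[0].cluster_b == 2

    def test_matches_brute_force(self, rng):
        def rand_prof(cid):
            return ClusterProfile(
                cluster_id=cid,
                member_ids=[f"m{cid}"],
                mean=rng.dirichlet(np.ones(20)),
                std=rng.uniform(0, 0.05, size=20),
            )

        set_a = [rand_prof(i) for i in range(5)]
        set_b = [rand_prof(i) for i in range(5)]
        got = match_clusters(set_a, set_b)
        for ca, m in zip(set_a, got):
            scores = {cb.cluster_id: cluster_similarity(ca, cb) for cb in set_b}
            assert scores[m.cluster_b] == max(scores.values())

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            match_clusters([], [_profile(0, {"A": 1.0})])


class TestCutoffScan:
    def test_monotone_non_increasing(self, rng):
        seqs = random_seqs(rng, 15)
        df = cutoff_scan(seqs, [0.0, 0.05, 0.15, 0.5, 1.0])
        ns = df["n_clusters"].tolist()
        assert ns == sorted(ns, reverse=True)
        assert ns[0] == 15  # distinct compositions stay apart at cutoff 0
        assert ns[-1] == 1


def test_archetype_recovery_single_seed():
    """Planted archetypes are recovered at the standard 0.15 cutoff."""
    from sklearn.metrics import adjusted_rand_score

    from iddcomp.synthetic import default_config, generate

    cfg = default_config(seed=42)
    cfg.n_per_archetype_a = 30
    cfg.n_per_archetype_b = 0
    set_a, _ = generate(cfg)
    profs = cluster(set_a.proteins, cutoff=0.15)
    truth = [set_a.archetype_of[p.id] for p in set_a.proteins]
    pred_of = {m: p.cluster_id for p in profs for m in p.member_ids}
    pred = [pred_of[p.id] for p in set_a.proteins]
    truth_codes = [hash(t) for t in truth]
    assert adjusted_rand_score(truth_codes, pred) >= 0.9
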