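"""Pfam-domain co-occurrence across matched cluster pairs.

Each clustered IDD segment contributes its parent protein's Pfam domains to
its cluster, giving a per-cluster multiset of domain occurrences. Under a
uniform-allocation null, the expected count of domain p in cluster c is

    Nexp_{p,c} = Ntot_p * N^c / sum_c N^c

with Ntot_p the total occurrences of p over all clusters and N^c the number
of domain occurrences in cluster c.

A domain "co-occurs" in a matched cluster pair when it is present (count >= 1)
on both sides; analysis is restricted to domains occurring more than once in
at least one of the two sets. The headline statistic is the number of distinct
co-occurring domains over all matched pairs; its significance is assessed by
replacing the similarity-maximizing matching with uniformly random pairings
and integrating the tail of the resulting null distribution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .clustering import ClusterMatch, ClusterProfile
from .io import segment_parent


@dataclass
class PfamCatalog:
    """Protein -> Pfam assignments, aggregatable per IDD cluster."""

    assignments: dict[str, list[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PfamCatalog":
        out: dict[str, list[str]] = {}
        for pid, pfam in pairs:
            out.setdefault(pid, []).append(pfam)
        return cls(assignments=out)

    def cluster_counts(
        self, clusters: Sequence[ClusterProfile], per_protein_once: bool = False
    ) -> dict[int, Counter]:
        """Aggregate domain occurrences per cluster.

        A protein contributes its domains to the cluster of each of its IDD
        segments (member ids are ``"<protein>:<start>-<end>"``; bare protein
        ids are also accepted). ``per_protein_once`` collapses repeated
        domain instances within one protein to a single occurrence.
        """
        out: dict[int, Counter] = {}
        for c in clusters:
            counts: Counter[str] = Counter()
            for mid in c.member_ids:
                pid = segment_parent(mid)
                domains = self.assignments.get(pid, [])
                if per_protein_once:
                    domains = sorted(set(domains))
                counts.update(domains)
            out[c.cluster_id] = counts
        return out


@dataclass(frozen=True)
class CooccurrenceRecord:
    pfam_id: str
    cluster_a: int
    cluster_b: int
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    oe_a: float  # observed/expected in cluster_a
    oe_b: float


@dataclass(frozen=True)
class PermutationNull:
    replicate_counts: list[int]
    observed: int
    p_value: float


def _set_totals(cluster_counts: Mapping[int, Counter]) -> tuple[Counter, int]:
    tot: Counter[str] = Counter()
    for c in cluster_counts.values():
        tot.update(c)
    return tot, sum(tot.values())


def pfam_expected_count(
    pfam_id: str, cluster_id: int, cluster_counts: Mapping[int, Counter]
) -> float:
    """Expected occurrences of a domain in one cluster under uniform allocation."""
    if cluster_id not in cluster_counts:
        raise KeyError(f"unknown cluster {cluster_id}")
    totals, grand = _set_totals(cluster_counts)
    if grand == 0:
        raise ValueError("catalog aggregates to zero domain occurrences")
    n_c = sum(cluster_counts[cluster_id].values())
    return totals[pfam_id] * n_c / grand


def _eligible(
    totals_a: Counter, totals_b: Counter, min_total: int
) -> set[str]:
    keys = set(totals_a) | set(totals_b)
    return {p for p in keys if totals_a[p] >= min_total or totals_b[p] >= min_total}


def cooccurring_pfams(
    matches: Sequence[ClusterMatch],
    counts_a: Mapping[int, Counter],
    counts_b: Mapping[int, Counter],
    min_total: int = 2,
) -> list[CooccurrenceRecord]:
    """Domains present on both sides of a matched cluster pair.

    Only domains whose set-level total is >= ``min_total`` in set A or set B
    are considered. One record per distinct (domain, matched pair).
    """
    totals_a, grand_a = _set_totals(counts_a)
    totals_b, grand_b = _set_totals(counts_b)
    eligible = _eligible(totals_a, totals_b, min_total)
    out: list[CooccurrenceRecord] = []
    for m in matches:
        ca, cb = counts_a[m.cluster_a], counts_b[m.cluster_b]
        na, nb = sum(ca.values()), sum(cb.values())
        for p in sorted(set(ca) & set(cb) & eligible):
            exp_a = totals_a[p] * na / grand_a
            exp_b = totals_b[p] * nb / grand_b
            out.append(
                CooccurrenceRecord(
                    pfam_id=p,
                    cluster_a=m.cluster_a,
                    cluster_b=m.cluster_b,
                    count_a=ca[p],
                    total_a=na,
                    count_b=cb[p],
                    total_b=nb,
                    oe_a=ca[p] / exp_a if exp_a > 0 else float("nan"),
                    oe_b=cb[p] / exp_b if exp_b > 0 else float("nan"),
                )
            )
    return out


def distinct_cooccurrence_count(
    matches: Sequence[ClusterMatch],
    counts_a: Mapping[int, Counter],
    counts_b: Mapping[int, Counter],
    min_total: int = 2,
) -> int:
    """Number of distinct domains that co-occur in any matched pair."""
    records = cooccurring_pfams(matches, counts_a, counts_b, min_total=min_total)
    return len({r.pfam_id for r in records})


def permutation_test(
    matches: Sequence[ClusterMatch],
    counts_a: Mapping[int, Counter],
    counts_b: Mapping[int, Counter],
    n_reps: int = 9000,
    seed: int = 0,
    min_total: int = 2,
    with_replacement: bool = True,
) -> PermutationNull:
    """Random-pairing null for the distinct co-occurring-domain count.

    Each replicate re-pairs every set-A cluster with a uniformly random set-B
    cluster (with replacement by default, mirroring the many-to-one observed
    matching) and recounts distinct co-occurring domains. The p-value is the
    empirical tail fraction of replicates at or above the observed count.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not matches or not counts_a or not counts_b:
        raise ValueError("need at least one cluster on each side")
    totals_a, _ = _set_totals(counts_a)
    totals_b, _ = _set_totals(counts_b)
    eligible = _eligible(totals_a, totals_b, min_total)
    a_ids = [m.cluster_a for m in matches]
    b_ids = sorted(counts_b)
    sets_a = {cid: frozenset(counts_a[cid]) & eligible for cid in counts_a}
    sets_b = {cid: frozenset(counts_b[cid]) & eligible for cid in counts_b}
    observed = len(
        set().union(*(sets_a[m.cluster_a] & sets_b[m.cluster_b] for m in matches))
    )
    rng = np.random.default_rng(seed)
    if not with_replacement and len(a_ids) > len(b_ids):
        raise ValueError("without-replacement pairing needs |B| >= |A|")
    counts: list[int] = []
    for _ in range(n_reps):
        if with_replacement:
            picks = rng.integers(0, len(b_ids), size=len(a_ids))
        else:
            picks = rng.permutation(len(b_ids))[: len(a_ids)]
        co: set[str] = set()
        for ca, k in zip(a_ids, picks):
            co |= sets_a[ca] & sets_b[b_ids[k]]
        counts.append(len(co))
    tail = sum(1 for c in counts if c >= observed)
    return PermutationNull(
        replicate_counts=counts, observed=observed, p_value=tail / n_reps
    )
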