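"""Exhaustive short-motif enumeration and enrichment against an independence model.

Motifs of length n (2-5) are counted as overlapping windows within each
sequence (windows never span sequence boundaries). The expectation for a
motif under residue independence is

    ev(a1..an) = N(n) * prod_i p(a_i)

where p(a) is the pooled single-residue background frequency of the dataset
and N(n) = sum over sequences of max(0, len - n + 1) is the total number of
windows. Observed/expected ratios, their natural-log histogram, and a
two-set over-representation table are derived from these counts. Motifs seen
fewer than ``min_count`` times (default 10) are statistically uninformative
and are excluded from histograms and tables.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS


@dataclass(frozen=True)
class BackgroundComposition:
    """Pooled single-residue frequencies p(a) of a dataset."""

    p: np.ndarray  # shape (20,), sums to 1

    def of(self, aa: str) -> float:
        return float(self.p[AA_INDEX[aa]])


@dataclass(frozen=True)
class MotifStats:
    motif: str
    observed: int
    expected: float
    ratio: float | None  # None when expected == 0
    log_ratio: float | None  # ln(ratio); None when observed == 0 or ratio is None


@dataclass(frozen=True)
class OverrepresentationRow:
    motif: str
    ratio_a: float
    ratio_b: float | None  # None renders as "--" (motif absent from set B)
    cross_ratio: float | None  # ratio_a / ratio_b; None when ratio_b is 0/None


def background(seqs: Sequence) -> BackgroundComposition:
    """Pooled residue frequencies over a whole sequence set."""
    counts = Counter()
    for s in seqs:
        counts.update(s.residues)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty dataset")
    p = np.zeros(20)
    for a, n in counts.items():
        p[AA_INDEX[a]] = n / total
    return BackgroundComposition(p=p)


def count_motifs(seqs: Sequence, n: int) -> dict[str, int]:
    """Overlapping occurrence counts of every observed length-n motif."""
    if n < 2:
        raise ValueError("motif length must be >= 2")
    counts: Counter[str] = Counter()
    for s in seqs:
        r = s.residues
        for i in range(len(r) - n + 1):
            counts[r[i : i + n]] += 1
    return dict(counts)


def total_windows(seqs: Sequence, n: int) -> int:
    """N(n): the number of length-n windows in the dataset."""
    return sum(max(0, len(s.residues) - n + 1) for s in seqs)


def expected_count(motif: str, bg: BackgroundComposition, total_windows: int) -> float:
    """Independence expectation ``N(n) * prod p(a_i)`` for one motif."""
    prod = 1.0
    for a in motif:
        prod *= bg.of(a)
    return total_windows * prod


def motif_stats(
    seqs: Sequence,
    n: int,
    bg: BackgroundComposition | None = None,
    include_unobserved: bool = False,
) -> list[MotifStats]:
    """Observed/expected statistics for length-n motifs of a set.

    By default only observed motifs are returned; ``include_unobserved=True``
    enumerates all 20**n motifs (practical for n <= 3).
    """
    if bg is None:
        bg = background(seqs)
    observed = count_motifs(seqs, n)
    nw = total_windows(seqs, n)
    if include_unobserved:
        motifs = ["".join(t) for t in product(AMINO_ACIDS, repeat=n)]
    else:
        motifs = sorted(observed)
    out = []
    for m in motifs:
        obs = observed.get(m, 0)
        ev = expected_count(m, bg, nw)
        ratio = obs / ev if ev > 0 else None
        log_ratio = math.log(ratio) if ratio else None
        out.append(MotifStats(motif=m, observed=obs, expected=ev, ratio=ratio, log_ratio=log_ratio))
    return out


def log_ratio_histogram(
    stats: Sequence[MotifStats], min_count: int = 10, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ln(observed/expected) over motifs with >= min_count hits.

    Returns ``(bin_edges, counts)``; empty (with a warning) when every motif
    is excluded.
    """
    vals = np.array(
        [s.log_ratio for s in stats if s.observed >= min_count and s.log_ratio is not None]
    )
    if vals.size == 0:
        warnings.warn("no motifs retained after the minimum-count filter")
        return np.array([]), np.array([])
    counts, edges = np.histogram(vals, bins=n_bins)
    return edges, counts


def overrepresented(
    set_a_stats: Sequence[MotifStats],
    set_b_stats: Sequence[MotifStats],
    min_count: int = 10,
    min_cross_ratio: float = 1.25,
) -> list[OverrepresentationRow]:
    """Motifs over-represented in set A relative to set B.

    A motif is reported when its set-A observed count is >= ``min_count`` and
    either it never occurs in set B (cross-ratio undefined, rendered "--") or
    the quotient of the two observed/expected ratios is >= ``min_cross_ratio``.
    Rows sort by cross-ratio descending, with the undefined rows first.
    """
    b_by_motif = {s.motif: s for s in set_b_stats}
    rows: list[OverrepresentationRow] = []
    for sa in set_a_stats:
        if sa.observed < min_count or sa.ratio is None:
            continue
        sb = b_by_motif.get(sa.motif)
        ratio_b = sb.ratio if sb is not None and sb.ratio is not None else 0.0
        if ratio_b == 0.0:
            rows.append(
                OverrepresentationRow(
                    motif=sa.motif, ratio_a=sa.ratio, ratio_b=None, cross_ratio=None
                )
            )
        else:
            cross = sa.ratio / ratio_b
            if cross >= min_cross_ratio:
                rows.append(
                    OverrepresentationRow(
                        motif=sa.motif, ratio_a=sa.ratio, ratio_b=ratio_b, cross_ratio=cross
                    )
                )
    rows.sort(
        key=lambda r: (0 if r.cross_ratio is None else 1, -(r.cross_ratio or 0.0), r.motif)
    )
    return rows
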