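"""Amino-acid composition vectors and the Gaussian composition similarity.

The composition of sequence ``i`` is the 20-vector ``f_i(a) = N(a) / len_i``.
Two compositions are compared with an alignment-free Gaussian score

    Sim_ij = sum_a [f_i(a) + f_j(a)] * exp(-((f_i(a) - f_j(a)) / w)^2)
             -----------------------------------------------------------
                          sum_a [f_i(a) + f_j(a)]

with width ``w = 0.1`` by default. The exponential terms are weighted by the
summed frequencies so abundant residues dominate and zero counts do not; no
pseudo-counts are needed. The score is 1 for identical compositions and
strictly positive otherwise; ``Dist = 1 - Sim`` is the pseudo-distance used
for clustering. The denominator always evaluates to 2 for valid frequency
vectors but is computed rather than hard-coded.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS

DEFAULT_WIDTH = 0.1


@dataclass(frozen=True)
class AminoAcidFrequency:
    """Per-residue frequencies of one sequence (exact counts over length)."""

    freqs: np.ndarray  # shape (20,), indexed by alphabetical one-letter order
    source_id: str
    length: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,):
            raise ValueError("frequency vector must have 20 components")
        if not np.isclose(f.sum(), 1.0, atol=1e-9):
            raise ValueError("frequencies must sum to 1")
        object.__setattr__(self, "freqs", f)


@dataclass(frozen=True)
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in (0, 1]


@dataclass(frozen=True)
class ScoreHistogram:
    """Histogram of pairwise scores on the 0-20 display scale (50 bins)."""

    bin_edges: np.ndarray  # 51 edges spanning [0, 20]
    counts: np.ndarray  # 50 non-negative integers
    normalized: np.ndarray  # counts / counts.sum()


@dataclass(frozen=True)
class AbundanceHistogram:
    """Across-set histogram of one residue's per-sequence abundance (%)."""

    amino_acid: str
    bin_edges: np.ndarray
    normalized: np.ndarray


def frequency_vector(seq) -> AminoAcidFrequency:
    """Exact composition vector ``f(a) = N(a)/len`` of a sequence record."""
    residues = seq.residues
    if not residues:
        raise ValueError(f"empty sequence {seq.id!r}")
    counts = Counter(residues)
    f = np.zeros(20)
    for a, n in counts.items():
        f[AA_INDEX[a]] = n
    f /= len(residues)
    return AminoAcidFrequency(freqs=f, source_id=seq.id, length=len(residues))


def frequency_matrix(seqs: Sequence) -> tuple[list[str], np.ndarray]:
    """Stack composition vectors of many sequences into an (n, 20) matrix."""
    vecs = [frequency_vector(s) for s in seqs]
    return [v.source_id for v in vecs], np.array([v.freqs for v in vecs])


def _as_array(f) -> np.ndarray:
    return f.freqs if isinstance(f, AminoAcidFrequency) else np.asarray(f, dtype=float)


def similarity_denominator(fi, fj) -> float:
    """The normalizing term ``sum_a [f_i(a) + f_j(a)]`` (2 for valid vectors)."""
    return float((_as_array(fi) + _as_array(fj)).sum())


def pair_similarity(fi, fj, w: float = DEFAULT_WIDTH) -> float:
    """Gaussian composition similarity of two frequency vectors, in (0, 1]."""
    if w <= 0:
        raise ValueError("Gaussian width w must be positive")
    a, b = _as_array(fi), _as_array(fj)
    weight = a + b
    num = float((weight * np.exp(-(((a - b) / w) ** 2))).sum())
    return num / float(weight.sum())


def pair_distance(fi, fj, w: float = DEFAULT_WIDTH) -> float:
    """Pseudo-distance ``1 - Sim``; 0 iff the compositions are identical."""
    return 1.0 - pair_similarity(fi, fj, w=w)


def similarity_from_matrix(F: np.ndarray, w: float = DEFAULT_WIDTH) -> np.ndarray:
    """All-against-all Gaussian similarity for an (n, 20) composition matrix."""
    if w <= 0:
        raise ValueError("Gaussian width w must be positive")
    F = np.asarray(F, dtype=float)
    diff = F[:, None, :] - F[None, :, :]
    ssum = F[:, None, :] + F[None, :, :]
    num = (ssum * np.exp(-((diff / w) ** 2))).sum(axis=-1)
    den = ssum.sum(axis=-1)
    return num / den


def all_vs_all(seqs: Sequence, w: float = DEFAULT_WIDTH) -> SimilarityMatrix:
    """Full symmetric pairwise-similarity matrix for a set of sequences."""
    if len(seqs) < 2:
        raise ValueError("all_vs_all needs at least 2 sequences")
    ids, F = frequency_matrix(seqs)
    values = similarity_from_matrix(F, w=w)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values)


def score_histogram(m: SimilarityMatrix, scale: float = 20.0, n_bins: int = 50) -> ScoreHistogram:
    """Bin the off-diagonal pairwise scores on the 0-20 display scale.

    Each unordered pair (i < j) contributes once; the score shown is
    ``scale * Sim`` so identical compositions land at exactly 20. The
    right-most bin is closed, so a score of exactly 20 is counted.
    """
    n = len(m.ids)
    if n < 2:
        raise ValueError("need at least one off-diagonal pair")
    iu = np.triu_indices(n, k=1)
    scores = m.values[iu] * scale
    counts, edges = np.histogram(scores, bins=n_bins, range=(0.0, scale))
    total = counts.sum()
    return ScoreHistogram(
        bin_edges=edges, counts=counts, normalized=counts / total
    )


def abundance_histograms(
    seqs: Sequence, bin_width_pct: float = 1.0
) -> list[AbundanceHistogram]:
    """Per-residue histograms of abundance (% of sequence length) across a set.

    Returns 20 histograms, one per amino acid, each normalized to sum to 1.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    _, F = frequency_matrix(seqs)
    pct = F * 100.0
    n_bins = int(round(100.0 / bin_width_pct))
    out = []
    for k, aa in enumerate(AMINO_ACIDS):
        counts, edges = np.histogram(pct[:, k], bins=n_bins, range=(0.0, 100.0))
        total = counts.sum()
        if total == 0:
            warnings.warn(f"no abundance mass for {aa}")
            norm = counts.astype(float)
        else:
            norm = counts / total
        out.append(AbundanceHistogram(amino_acid=aa, bin_edges=edges, normalized=norm))
    return out
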