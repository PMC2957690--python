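# Methods

## The similarity model

Sequences are represented only by their amino-acid composition: for sequence
*i*, `f_i(a) = N(a) / len_i` over the 20 standard residues, computed as exact
rational counts with no pseudo-counts. The pairwise score

```
Sim_ij = Σ_a (f_i + f_j) exp(-((f_i - f_j)/w)²)  /  Σ_a (f_i + f_j)
```

is a weighted mean of per-residue Gaussian agreements: the weight `f_i + f_j`
makes abundant residues dominate, so the many zero entries of short-sequence
compositions cannot swamp the score. The denominator is identically 2 for any
two valid frequency vectors; we compute it rather than hard-code it, both for
transparency and so the identity can be asserted in tests. The width `w`
(default 0.1) sets how large a per-residue frequency difference still counts
as agreement; at 0.1 most realistic pairs land in the 0.5–1 range, and the
score is strictly increasing in `w` for fixed non-identical vectors.
`Dist = 1 − Sim` is only a pseudo-distance (the triangle inequality is not
guaranteed), which is sufficient for agglomerative clustering. For display,
scores are scaled linearly to 0–20 (identical compositions score exactly 20)
and binned into 50 equal windows with the right-most bin closed.

## Shuffled null sets

The null hypothesis "this set is a random draw from its own residue pool" is
materialized by concatenating the set, applying one uniform permutation
(Fisher–Yates, equivalent to repeated sampling without replacement but O(N)),
and cutting the permuted string back into the original lengths in the
original order. Sequence count, the length multiset (in order), and pooled
per-residue counts are conserved exactly, and tests assert this exactly, not
approximately. The seed is a required parameter and is recorded in the run
manifest. Within-sequence shuffling and k-mer-preserving shuffles are out of
scope: the null deliberately destroys all per-sequence composition structure.

## Clustering and cluster matching

IDDs are clustered by average linkage (UPGMA) on `Dist`, with the dendrogram
cut at height 0.15: by the UPGMA merge rule the cutoff bounds the average
pairwise distance within any flat cluster. Cluster ids are assigned by
decreasing size, ties by first-member input order, so runs are deterministic;
the ids are an arbitrary labelling and carry no meaning across datasets.

A cluster is profiled by the per-residue mean ⟨f(a)⟩ and the *population*
standard deviation σ(a) of its members' compositions — population rather than
sample so that singleton clusters have the well-defined value σ = 0. Two
profiles are compared with the Gaussian form using per-residue squared width
σ_a(a)² + σ_b(a)²; where that sum is zero the pairwise default width (0.1)
is substituted, which makes the cluster score degrade gracefully to the
pairwise score for singleton clusters. Cross-set matching assigns each set-A
cluster its argmax-similarity set-B partner independently (many-to-one
allowed; several A clusters may share a B partner), ties to the lowest set-B
id.

## Motif enrichment

Motifs of length 2–5 are counted as overlapping windows that never span
sequence boundaries, so the total count for length n is exactly
`N(n) = Σ max(0, len − n + 1)` — the normalization under which the
independence expectation `ev = N(n) Π p(aᵢ)` sums to `N(n)` over all 20ⁿ
motifs. The background p(a) is pooled over the set being analysed. Motifs
observed fewer than 10 times are excluded from ln(observed/expected)
histograms and over-representation tables as statistically uninterpretable.
The two-set table reports motifs whose set-A count is ≥ 10 and whose
ratio-of-ratios is at least 1.25 (configurable; motifs entirely absent from
set B are reported with a `--` sentinel and sort first). Occurrences within
one sequence and across sequences are not distinguished.

## Pfam co-occurrence and the permutation test

Each clustered segment contributes its parent protein's Pfam domains to its
cluster (a protein with several IDDs therefore appears in several clusters;
by default each domain *instance* counts, with a per-protein-once option).
A domain co-occurs in a matched pair when present on both sides; analysis is
restricted to domains occurring more than once in at least one set's
aggregate. The headline statistic is the number of distinct co-occurring
domains across all matched pairs. Its null distribution is obtained by
replacing the similarity-maximizing matching with uniformly random pairings —
sampled with replacement to mirror the many-to-one structure of the observed
matching (a without-replacement option exists) — and the p-value is the
plain empirical tail fraction of replicates at or above the observed count,
so it is never exactly 0. Tests verify the empirical p against exhaustive
enumeration of all pairings on a 3×3 toy catalog, and its calibration
(p > 0.05 in the large majority of runs) on data whose labels are detached
from cluster structure.

## Synthetic data

The generator emulates the structure the analysis assumes rather than protein
evolution. Each synthetic protein is one fully disordered segment: lengths
are `30 + Gamma(shape 4, mean 270)`; per-sequence compositions are Dirichlet
draws centred on one of four archetypes (E-rich, P/S-rich, Q-rich, K-rich —
a disorder-biased background mixed 80:20 with a residue spike), concentration
1000; residues are then iid draws, adding realistic multinomial
within-sequence noise. Pfam-style labels are planted per archetype with
probability 0.6 over a Poisson(0.3) uniform background of 20 label types.
The archetype tightness and length law were fixed by a one-off design
simulation so that within-archetype average composition distance (~0.09) sits
clearly below the 0.15 clustering cutoff and between-archetype distance
(~0.34) clearly above it — the "well-separated archetypes" regime in which
cluster recovery is a meaningful check. A `generate_null` variant permutes
each protein's label bundle across proteins of the same set, preserving label
marginals exactly while destroying any association with composition, which is
the calibration input for the permutation test.

What the generator does **not** emulate: homology and phylogenetic
correlation between sequences, position-dependent structure (real IDD motifs
are not iid draws), realistic Pfam domain architecture, or the 40%-identity
redundancy filtering applied to real datasets. Passing tests on synthetic
data therefore demonstrate correctness of the machinery and its calibration
under the stated model, not performance on real proteomes.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline reruns with the same seeds are byte-identical (floats are
  written with a fixed `%.6g` format; the manifest contains no timestamps).
- Overlapping disorder intervals are passed through unmerged; coordinate
  handling is 1-based inclusive in all files.
- Non-standard residues (B, J, O, U, X, Z, `*`, gaps) are removed at parse
  time with a logged per-record count, not rejected: the composition math is
  defined only over the 20 standard symbols and removal keeps length
  bookkeeping simple.
- Problem sizes in tests (e.g. 120–200 sequences per set, 500–9000
  permutation replicates) are chosen so the full suite runs in well under a
  minute of compute per check while keeping Monte-Carlo error far from the
  asserted margins.

## Known limitations

- `Dist` is not metric, so UPGMA merge heights are heuristic; other linkages
  are deliberately not offered.
- The over-representation threshold (1.25) and the abundance-histogram bin
  width (1 %) are labelled conventions, exposed in configuration and not
  asserted by tests.
- Cluster indices are deterministic but arbitrary; they will not agree
  between datasets or with any external numbering.
- Disorder prediction, redundancy reduction, and Pfam assignment are input
  contracts, not computations; the pipeline's conclusions are conditional on
  their quality.
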