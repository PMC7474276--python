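# Methods

This note documents the models behind `pairmotif`, the parameters that
matter, the numerical choices, what the synthetic benchmark does and does not
establish, and the points where the design was genuinely open.

## Motif model and match p-values

A motif is a letter-probability matrix f over {A, C, G, T}: f_{b,i} is the
probability of base b at position i. For scanning, frequencies are converted
to log-odds against a 0-order background π:

    s(b, i) = log2( (f_{b,i} + c·π_b) / (1 + c) / π_b )

with an additive pseudocount c (default 0.001, configurable) so that zero
frequencies stay finite; per-position scores are additionally clamped below
at `score_floor` (default −32 bits), which only matters at c = 0. The
pseudocount is used **only** for scanning — information content is always
computed from the raw frequencies with the entropy convention 0·log₂0 = 0 and
no pseudocount.

A window's match p-value is the exact tail probability of its score under the
background. Per-position scores are rounded to a grid of width `granularity`
(default 1e-3 log-odds units) and the per-position score distributions are
convolved by dynamic programming; windows are then scored on the same integer
grid, so the looked-up tail is exact for the discretized score (verified in
the tests against exhaustive enumeration over all 4^w windows for w ≤ 6). The
background defaults to uniform for reproducibility; the 0-order composition
of the scanned promoter set is available via `background="promoters"`.

Both strands are scanned by default. The minus strand is scored with the
reverse-complement matrix at the same forward coordinates and has its own
null table, which matters only for strand-asymmetric backgrounds. Windows
containing N (including windows of truncated promoters that would overhang)
score p = 1. A candidate exists at every (position, strand); no p-value
threshold is applied before hit selection — selection itself provides the
stringency.

## Binomial promoter score

Hits are selected greedily in ascending p-value order (ties: start, then +
strand first), discarding hits whose interval intersects an already selected
hit regardless of strand, up to `max_k` = 5. For each k ≤ |selected|, p_k is
the geometric mean of the k best p-values and the score is P(X ≥ k) with
X ~ Binomial(N, p_k); the minimal score wins, smallest k on ties. A hitless
promoter (or one shorter than the motif) scores 1 with k\* = 0.

**Trial count N.** The published description fixes only "a 1-kb promoter". We
set N = (L − w + 1) × (2 if both strands), the number of candidate placements
actually scanned in a promoter of (possibly truncated) length L; this keeps
truncated promoters comparable. `trials=<int>` reproduces a literal fixed
reading (e.g. 1000).

## Motif index

For each motif the n = 5000 lowest-scoring (best) promoters are "containing"
the motif; ties at the boundary are broken by gene id so runs are
bit-reproducible; the n-th member's score is the motif's threshold. When the
universe has ≤ n promoters every promoter is a member and the threshold is
the maximum score — a degenerate regime in which every pair count equals the
universe and no enrichment is detectable, so scaled-down analyses should
scale n with the universe (the synthetic plans default to n/universe = 20%,
mirroring 5000 of the ~27k nuclear-gene promoters at genome scale).

## Overlap resolution and colocalization

For promoters in both motifs' indexes, every intersecting pair of recorded
hits is evaluated: the genomic intersection is mapped to motif-local
positions (mirrored for minus-strand hits) and each motif's information
content over those positions is summed. If either motif's overlap IC
*exceeds* 4 bits (strictly; IC = 4 is retained), **both** participating hits
are removed — the symmetric reading of an ambiguous rule, chosen because it
keeps colocalization symmetric in the pair (the asymmetric alternative would
make the outcome depend on pair order). Binomial scores are then recomputed
from the remaining hits with k re-optimized and N unchanged; a motif left
hitless rescores to 1 and cannot pass. The pair colocalizes iff both
recomputed scores are ≤ their motifs' thresholds. Removal depends only on
the IC, never on the overlap length.

## Enrichment testing

Pair-positive counts are tested with the upper-tail hypergeometric
P(X ≥ x | M, K, N): universe size M, pair-positive promoters K, gene-set size
N (after dropping — and logging — genes without a promoter). All unordered
pairs of distinct motifs are tested; homotypic pairs are off by default
(`include_self_pairs` enables them; they require ≥ 2 non-overlapping
instances to ever count). Bonferroni multiplies by the number of pairs tested
for that gene set, capped at 1; significance is adjusted P < 0.05. The test
is enrichment-only (one-tailed upper), the natural reading for
over-representation. Gene-set equalization takes the top K genes of each
larger set, K the smallest set's size, and refuses unranked sets.

## Synthetic worlds

`PlantingPlan` defaults restate the benchmark: 5000 i.i.d. uniform-composition
promoters of 1000 bp; a library of 80 random width-8 motifs whose columns put
probability 0.92 on a random dominant base; the first two motifs planted
together in 200 promoters, two sampled instances of each per promoter at
non-overlapping random positions and strands; a 300-gene set with 150
pair-positive members; indexes of n = 1000 (20% of the universe).

Design rationale (fixed a priori by power analysis, not tuned on outcomes):

- *Motif strength / multiplicity*: with 0.92-dominant columns, roughly half
  of sampled instances are consensus-exact and scan near the null's extreme
  tail; two instances per promoter put the per-motif detection probability
  high enough that the planted pair's in-set count dwarfs its null
  expectation by > 10 standard deviations.
- *Library size 80*: pairs that share one planted motif ("leakage" pairs,
  2×78 = 156 of 3160) are genuinely enriched through single-motif enrichment
  times chance co-membership — a property of the pair test itself, not a bug.
  80 motifs keep such pairs below 5% of all non-planted pairs even if every
  one of them reaches significance.
- *Negative control world*: 2000 promoters, 8 motifs, n = 50. The small
  index makes pair co-membership counts K of order 1–5, where the discrete
  hypergeometric support cannot reach the Bonferroni threshold unless nearly
  all K positives are drawn — so 100 random 300-gene sets are expected to
  produce zero significant pairs, matching the published negative control at
  a scale where per-set Bonferroni alone would not suffice over 100
  repetitions.

What the generator does **not** emulate: nucleotide autocorrelation, CpG/TA
periodicity, promoter-length variation, shared binding-site clustering
between unrelated motifs, and correlated gene sets. A green benchmark
therefore establishes the statistical machinery end-to-end, not performance
on real genomes.

## Numerical and determinism notes

- All tie-breaks are total and documented: hits by (p, start, strand),
  index membership by (score, gene id), k\* by smallest k, result rows by
  (gene set, adjusted p, raw p, motif pair).
- Binomial and hypergeometric tails come from `scipy.stats` (`binom.sf`,
  `hypergeom.sf`); both are validated against direct summation/enumeration
  oracles in the tests.
- Serialized floats use `%.10g` (indexes) and 6 decimals (matrices); reruns
  with identical inputs are byte-identical, and manifests carry a parameter
  hash plus input checksums that the `pairs` stage verifies.
- The index TSV stores each hit as start:end:strand:p; the raw log-odds score
  is not round-tripped (downstream stages only use intervals and p-values).

## Known limitations

- 0-order background only; no higher-order Markov models.
- One promoter per gene (gene-level 5' end); no isoform-aware TSSs, no
  masking of overlapping upstream genes (fixed windows by design).
- The hypergeometric pair test does not condition on single-motif
  enrichment, so pairs containing one strongly enriched motif can reach
  significance without genuine pairing — at genome scale this is diluted by
  the large Bonferroni m, but it should be kept in mind when reading pair
  heatmaps.
- Bonferroni only; no FDR alternative. No distance or order constraints
  between paired hits beyond overlap handling.
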