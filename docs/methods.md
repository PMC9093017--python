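# Methods

## Problem setting

The package addresses sequence–function mapping across orthologous odorant
receptors: a small panel of species (≈14) with aligned receptor protein
sequences (reference length ≈397 residues) and odor-evoked spike counts
(≈21 odorants per receptor, single-sensillum recordings). The questions are
(i) which alignment columns determine the response profile, (ii) how well a
new species' response profile can be predicted from its sequence, (iii) how
stable the identified column set is to the species panel, and (iv) whether
the columns cluster spatially in the receptor structure.

## Position score

For receptors *i*, *j*, the response distance is the mean absolute spike
difference over odorants measured in both:
`D(i,j) = mean_o |r_i(o) − r_j(o)|` (spikes). Pairs sharing no measured
odorant have undefined distance and contribute nothing.

For an alignment column *c*, receptor pairs split into matched (identical
residue) and mismatched sets; pairs with a gap or unknown residue `X` at *c*
are excluded from both (no evidence either way). The score is

```
S(c) = mean_{mismatched} D − mean_{matched} D        [spikes]
```

A column is *eligible* when it has at least one matched and one mismatched
informative pair (a stricter minimum is configurable). Eligible columns are
ranked by descending score; ties break by smaller reference residue index,
then smaller column index, so output is deterministic. The top *K* = 20
(configurable) is the response-determining set.

Properties (all tested): the score is invariant to receptor/odorant
ordering, invariant to adding a constant to any odorant's responses, and
scales linearly with a positive rescaling of all responses. Its unit is
spikes — how much farther apart two receptors' response profiles are when
they differ at the column.

Pair non-independence is deliberately not corrected: the 91 pairs of 14
receptors are phylogenetically correlated, which inflates effective
certainty but does not bias the ranking itself.

## Leave-one-species-out prediction

For each held-out receptor: the top-*K* columns are re-ranked on the
remaining receptors only (no information leak), and each odorant response is
predicted as a convex combination of training responses,

```
pred(o) = Σ_j w_j r_j(o) / Σ_j w_j ,   w_j = sim(h, j)^α
```

where `sim(h, j)` is the fraction of top-*K* columns (both residues non-gap)
at which held-out *h* and training receptor *j* agree. Two refinements make
this kernel informative rather than degenerate:

- **Score weighting** (default on): each column contributes to `sim` in
  proportion to the positive part of its ranking score. Without this, the
  many marginal columns inside the top-*K* dilute the few strongly
  determining ones; measured on the planted-signal benchmark, the unweighted
  kernel leaves the predictor nearly indistinguishable from its own shuffled
  control.
- **Sharpening exponent α = 10** (default). Similarities across a small
  ortholog panel are tightly clustered (≈0.3–1.0), so a linear kernel
  (α = 1) gives near-uniform weights and the weighted mean collapses toward
  the panel average — which is exactly what the shuffled control computes, so
  model and control coincide by construction. α of order 10 lets receptors
  that match at the determining columns dominate (0.9¹⁰ ≈ 0.35 relative
  weight) without reducing to a strict nearest-neighbor rule. Both knobs are
  exposed; `alpha=1, score_weighted=False` recovers the plain fraction-of-
  identity predictor.

Odorants missing in some training receptors use the remaining ones; if every
available response carries zero weight, the unweighted mean of available
responses is used; odorants with no training response give a missing
prediction, excluded from averages and counted in the report.

**Shuffled control.** Training response rows are randomly reassigned to the
training sequences (uniform permutation), the same predictor is re-run, and
`D_ctrl` is the mean absolute error over shuffles (default 1000). This
preserves the response distribution and the predictor's functional form
while destroying the sequence–response linkage. When the shuffle budget
reaches (n_train)!, all permutations are enumerated exactly once, so the
estimate equals the exact permutation average (tested against explicit
enumeration). Per-receptor random streams derive from
`SeedSequence([seed, crc32(receptor_id)])` and training receptors are
processed in sorted order, making every result independent of input record
order — a stream keyed on the receptor *position* would not be.

Headline summaries: `mean D_pred`, `mean D_ctrl`, and the improvement
`100·(D_ctrl − D_pred)/D_ctrl`. Because the overall ratio and the mean of
per-receptor ratios differ in general, both are reported
(`improvement_percent`, `improvement_percent_receptor_mean`).

## Jackknife robustness

Each species is removed in turn (sequence and response row) and the top-*K*
recomputed. Reported: per-exclusion retention `|recalculated ∩ original|`,
its mean, the frequency of each column across recalculated sets, and whether
the *K* most frequent columns match the original set (frequency ties break
by full-dataset score, then reference index). A caveat the synthetic
benchmark makes explicit: any two reductions share 78 of the 91 receptor
pairs, so even sequence-independent (pure-noise) responses yield mean
retention around 17.7/20. High retention alone is therefore weak evidence of
signal; the informative check is the *decrease* of retention with noise,
which the tests assert on a balanced all-planted configuration.

## Structural neighborhood enrichment

A neighborhood is every residue whose α-carbon lies within radius *r*
(default 15 Å, boundary inclusive, seed included at distance 0) of a seed
residue's α-carbon. The α-carbon is the conventional residue proxy; residues
lacking one are skipped with a warning. Overlap with the top-*K* set is
tested with an upper-tail hypergeometric probability `P(X ≥ k)` for
population *N* (protein length), *K* successes, *n* draws — computed in
log-space (`gammaln` + `logsumexp`) so tails far below double-precision
underflow of the factorials remain accurate; the implementation is verified
against exact integer enumeration for every parameter combination with
N ≤ 25 and against an independent library survival function. The expected
overlap `n·K/N` is reported alongside. A counts-only entry point
(`enrichment_from_counts`) evaluates the test from printed `(N, K, n, k)`
without any structure file. Union tests recompute `n`, `k` and `p` on the
union of two neighborhoods.

The test is one-tailed (over-representation) and conditions on the observed
neighborhood size; it makes no correction for the spatial autocorrelation of
a protein chain, matching the standard usage it reproduces.

## Synthetic benchmark

`GeneratorConfig` defaults define the study conditions: 14 receptors,
reference length 397, 21 odorants, 5 planted determinant positions, 40
variable background positions, per-receptor substitution probability 0.3
(two-letter alphabet per variable column: ancestral + one alternative,
redrawn until the column is actually variable), effect scale τ = 30 spikes,
measurement noise σ = 5 spikes, response baseline 28.78 spikes. Responses
are additive — baseline + Σ over planted positions of a per-(position,
residue, odorant) effect ~ N(0, τ²) + noise — with no epistasis. The first
receptor is the reference and keeps the ungapped ancestral sequence, so
columns coincide with reference numbering. `min_variant_count ≥ 2` builds
balanced panels in which no single species removal can silence a column —
the configuration under which jackknife retention is provably exact at zero
noise. The structure generator emits a straight α-carbon chain at 3.8 Å
spacing; `cluster_planted` relocates planted residues into a 10 Å-diameter
ball around a chosen seed so the enrichment test has true spatial signal.
Everything is deterministic given the seed, with independent spawned
sub-streams per generator.

What the benchmark does *not* emulate: phylogenetic correlation among
sequences (no tree-based simulation), empirical odorant panel structure,
receptor-specific response variances, indel-rich alignments (a single
optional gap column only), and epistasis between determinant positions.
Passing tests therefore demonstrate correctness and statistical behavior of
the machinery under an additive independent-substitution model, not
performance on real ortholog panels.

## Numerical and edge-case choices

- All residue/column indices are 1-based; reporting uses reference
  numbering (columns where the reference is gapped are "unmapped" and lose
  tie-break priority).
- Percent pairwise identity: matches / columns where at least one of the
  pair is non-gap; both-gap columns excluded; `X` matches nothing, itself
  included. In column scoring, by contrast, `X` is treated like a gap
  (excluded): an unknown residue is no evidence of match *or* mismatch.
- Distance exactly equal to the neighborhood radius counts as inside.
- Deterministic output everywhere: sorted JSON keys, floats at 6
  significant digits, fixed tie-breaks.
- Degenerate inputs raise typed errors: no shared odorants
  (`UndefinedDistanceError`), no eligible column (`RankingError`), fewer
  than 3 receptors for ranking / 4 for jackknife / 2 training receptors for
  prediction (`InsufficientDataError`).

## Problem sizes used in the test suite

The statistical tests run the generator at its default 14 × 397 × 21 scale:
planted-position recovery over 20 seeds, leave-one-out improvement over 10
seeds (1000 shuffles) plus a 20-seed null calibration (500 shuffles),
jackknife stability over 10 seeds per noise level, and a 100-seed
false-positive calibration of the enrichment test. The whole suite completes
in well under a minute on one CPU.

## Known limitations

- The pairwise-identity denominator and the shuffled-control construction
  are reconstructions of standard practice; other conventions (ungapped-
  overlap denominators, position-shuffle controls) would give slightly
  different numbers.
- The score treats receptor pairs as independent; closely related species
  contribute correlated pairs.
- The prediction kernel's exponent trades bias for variance; the default is
  tuned to panel-scale similarity spreads, and very small panels may prefer
  smaller α.
- Jackknife retention is an optimistic stability measure (see above).
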