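# Methods

## The network model

The object of study is a simple signed bipartite graph G = (U, V, E):
cancer types U, miRNAs V, and at most one edge per (cancer, miRNA) pair,
signed UP or DOWN. Edges are literature-style dysregulation calls, not
quantitative expression values; all downstream statistics are counting
statistics on this graph. Identifiers are treated as opaque strings
(lower-cased, whitespace-trimmed) — no alias resolution against miRNA
registries is attempted, because curated edge lists mix precursor and
mature naming conventions and silent merging would corrupt degrees.

Duplicate reports for the same (cancer, miRNA) pair with the same sign
collapse to one edge. Conflicting signs are an error by default, with
`first` and `majority` policies as explicit opt-ins: conflicting
evidence is a curation problem, and silently resolving it would bias
every sign-dependent statistic downstream.

Coordinates are held 1-based inclusive (the GFF3 convention, which is how
miRNA annotation is distributed); BED input is converted on read and
written back 0-based half-open.

## Module mining

Transactions are cancer types, items are miRNAs; a transaction is the set
of miRNAs dysregulated in that cancer. By default items carry no sign
(`sign_mode="any"`), because observed modules mix up- and downregulated
members; sign-stratified mining is available. Support is a *fraction* of
transactions — the natural reading of fractional thresholds like 0.3 —
with raw counts reported alongside.

Frequent itemsets come from the classic level-wise search: candidates of
size k are joined from frequent (k−1)-itemsets sharing a prefix and pruned
when any (k−1)-subset is infrequent (downward closure). Transaction sets
are kept as integer bitmasks so support counting is a popcount. Rule
generation grows consequents: single-item consequents first, then merged
level by level, pruning any consequent whose subset already failed the
confidence threshold (confidence is anti-monotone in the consequent for a
fixed itemset). The itemset lattice is capped at 6 items by default
(configurable); realistic modules are far smaller. All orderings are
deterministic (size, then lexicographic; ranking by confidence desc,
support desc, itemset size desc, then lexicographic), so results are
identical across runs and platforms.

## Tissue bias

For cancer u with n_up/n_down signed edges, the majority percentage is
100·max(n_up, n_down)/(n_up+n_down), **truncated** (not rounded) to two
decimals via integer arithmetic — the convention under which 10/11 prints
as 90.90 and 9/11 as 81.81. Ties report "Mixed" at 50.00.

The bias test is Fisher's exact test on [[n_up, n_down], [bg_up, bg_down]],
where the background row pools every other cancer's edges. Sidedness
defaults to two-sided with the point-probability rule (sum of all tables,
at fixed margins, no more probable than the observed one), matching the
default of the standard statistical platforms; `greater`/`less` are
options. The odds ratio is the conditional maximum-likelihood estimate
(flagged as such in the result). No multiple-testing correction is applied
across cancers; the report lists every cancer and leaves filtering to the
user. Hub/module significance is deliberately *not* computed here — that
belongs to the randomization null below, keeping this module purely
descriptive counting plus one exact test.

## Randomization nulls

The default null (`cancer-degree`) resamples, for each cancer
independently, its d partners uniformly without replacement from all
miRNAs, reattaching the cancer's own multiset of signs in shuffled order.
Each cancer's degree and sign composition are preserved exactly — so
tissue-level bias survives under the null — while miRNA degrees vary
freely, which is what makes hub significance non-trivial. A second mode
(`double-swap`) applies sign-preserving double edge swaps and preserves
*both* degree sequences exactly; it is shipped for sensitivity analysis
(note that under it any single miRNA's degree is constant, so it is the
wrong null for hub degrees and the interesting one for joint statistics
like rule support).

Empirical p-values use the add-one estimator p = (b+1)/(n+1) with b the
number of null replicates at least as extreme as the observation. With n
replicates p can never be smaller than 1/(n+1); the floor is carried in
the result so reports cannot overstate significance (a 1,000-replicate
test bottoms out at p ≈ 0.001, never at analytic-looking bounds like
1e-16). Permutation tests recompute the statistic on a compact
array representation of the network (per-cancer partner and sign arrays)
rather than rebuilding full network objects per replicate; the public
single-network rewiring functions use the same code path. One master seed
plus per-test sub-seeds derived by hashing (master, test-name) keep every
substream stable when tests are added.

## Neighbor clusters

Two miRNAs are neighbors when their loci lie within 50 kb. Operationally:
per chromosome (strand-agnostic by default; strand is never part of the
published cluster definitions we model), loci sorted by start are chained
whenever max(0, next.start − running_max_end) ≤ max_gap; maximal chains of
≥ 2 loci are clusters. Tracking the running maximum end makes the sweep
exactly single-linkage even with nested or overlapping loci.
Start-to-start distance is available as an option. Gap-based single
linkage is the common operational definition of miRNA clusters; the
threshold is a parameter (`max_gap`, default 50,000 bp) precisely so the
robustness of any downstream claim can be checked across definitions
(20/50/100 kb are exercised in the tests).

A cancer is "co-dysregulation positive" for a direction iff **some single
cluster** contributes ≥ 2 members linked to that cancer with that
direction (the stricter same-cluster reading; the statistic is the
fraction of positive cancers). Members without edges, or edges without
loci, are tolerated and logged — they simply cannot contribute.
Significance uses the cancer-degree null with per-cancer sign retention,
so the null keeps each tissue's sign composition while scrambling which
miRNAs — and hence which genomic neighbors — it touches.

## Synthetic data

The generator emulates a curated pan-cancer dysregulation corpus at its
natural scale: 30 cancer types × 200 miRNAs, background density 0.05
(mean cancer degree 10, mean miRNA degree 1.5 — the sparse regime where
a literature network lives), per-cancer sign bias 0.5 unless specified.
Planted structure overwrites background edges so ground truth is exact and
checked at generation time:

- **modules** (size m, k carrier cancers, fixed or sampled U/D pattern);
  defaults in tests use m = 3, k = 10 so the planted support 10/30 sits
  just above the 0.3 threshold — the hardest recoverable case;
- **hubs** topped up to a target degree, optionally sign-homogeneous
  (default planted degree 12 against a background mean of 1.5);
- **neighbor pairs**: each of the planted pairs is co-reported in a cancer
  with probability 0.3, the second member copying the first's sign with
  probability ρ (default 0.9). With ten pairs this yields observed
  co-down fractions around 0.7–0.85, the regime reported for real
  corpora, against a null fraction near 0.03.

Loci: planted pair members are placed 1–45,000 bp apart; every other locus
is placed uniformly per chromosome with a rejection check enforcing
pairwise gaps > 50 kb (loud failure if the budget is exhausted), so the
background contributes no clusters. Loci are 80 bp, the precursor scale.

What the generator does **not** emulate: heavy-tailed real degree
distributions, correlated study coverage (popular miRNAs are measured more
often), chromosomal clustering beyond the planted pairs, or real miRBase
coordinates and names. Passing recovery tests therefore demonstrates
correctness of the machinery under controlled conditions, not performance
on any real corpus.

## Numerical and design choices

- Support/confidence comparisons are plain float `>=` against thresholds;
  counts are exact integers, and thresholds like 0.3 at n = 30 fall on
  exact values, so no tolerance is needed.
- Percentage truncation is integer arithmetic ((100·max·100)//total /100) —
  no float rounding can flip a printed digit.
- Exact-test p-values delegate to scipy's `fisher_exact`; the test suite
  holds them to 1e-9 against exhaustive rational enumeration on all 2×2
  tables with total ≤ 40.
- Double-swap rejection sampling caps attempts at 100 per requested swap
  (plus a constant); networks near complete bipartite simply keep their
  forced configuration.
- Degenerate inputs fail loudly: empty transaction databases (support
  undefined), all-zero contingency tables, empty null-value lists, cancers
  with degree exceeding the miRNA universe, duplicate loci names.
- Pipeline bundles are written to a temporary directory and renamed into
  place, so a failed stage never leaves a partial bundle; the manifest
  (config echo, seed, versions, input/output SHA-256) reproduces a bundle
  bit-for-bit.

## Problem sizes in the shipped checks

Test and acceptance workloads are sized to be decisive yet desk-scale:
oracle equivalence on ≤ 12-item databases and 2×2 tables with total ≤ 40;
100 seeded generator replicates for module/hub/cluster recovery (199
permutation replicates each); 200 replicates at 99 permutations for null
calibration; the acceptance script uses 999 permutations and 50 recovery
replicates. These sizes were chosen as the smallest that make the 95%
recovery and ±3·SE calibration bounds meaningful.

## Known limitations

- The cancer-degree null conditions only on cancer degrees; if real miRNA
  degree heterogeneity matters for a claim, use `double-swap` for joint
  statistics (it cannot test single-miRNA degrees, which it fixes).
- Rule mining is exhaustive under the thresholds; very dense networks with
  low support thresholds can explode combinatorially (the `max_len` cap
  bounds this).
- Identifier opacity means the same biological locus reported under two
  names is two nodes.
- The empirical p floor means 1,000 replicates can never certify
  significance beyond p ≈ 0.001; raise `n_permutations` when smaller
  bounds are required.
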