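# Methods

## Model and procedure

sigconn scores an up/down tag-set query against a database of ranked
drug-perturbation profiles.  The units of analysis are:

* **Instance** — one treatment experiment reduced to a permutation of the
  probe universe: rank 1 is the probe most up-regulated by treatment, rank n
  the most down-regulated.  Ranks are the persisted unit; because the KS
  statistic consumes ranks only, scoring is invariant to any monotone
  normalisation of the underlying expression values.
* **Signature** — disjoint, ordered up and down tag sets, built either from a
  differential-expression table (disease signature) or from treated/control
  expression matrices (drug signature).

### Per-instance score

For one tag set with sorted ranks `V(1) < … < V(t)` in a list of length `n`,
the signed KS enrichment is

    a  = max_{j=1..t} ( j/t − V(j)/n )
    b  = max_{j=1..t} ( V(j)/n − (j−1)/t )
    es = a  if a ≥ b  else  −b .

`a` and `b` are both ≥ 0 (the j = t and j = 1 terms are non-negative), so
`|es| ≤ 1`.  The exact tie `a = b` resolves deterministically to the positive
branch; both deviations are kept in the result object so tie cases are
auditable.

The bidirectional raw score is `s = es_up − es_down` when the two statistics
have opposite strict signs or either is exactly 0, and `s = 0` (a *null*
instance) when they share a strict sign: a query whose up and down genes are
pushed the same way by a treatment carries no directional information.  A
zero on one side does not null the score — nulling a measure-zero case would
discard information.  For one-sided queries the sign convention of the
bidirectional formula is kept: `s = +es_up` (up-only) or `s = −es_down`
(down-only).  This preserves the engine's antisymmetry — swapping the two tag
sets negates every nonzero `s` — for every query shape.

### Scaling

Connectivity scores are `c = s/p_max` for positive `s` and `c = −s/q_min` for
negative `s`, where `p_max` / `q_min` are the extreme raw scores over *all*
instances of the database for the given query (not per compound).  This makes
`c` comparable across compounds, bounds it in [−1, 1], and guarantees the
extreme instances attain ±1.  `c` depends on `s` only through positive
rescaling.

### Group statistics

Instances are grouped by compound × cell line by default (plain compound
grouping available).  Per group:

* **similarity mean** — mean of member `c`.  Null (s = 0) members are included
  in the denominator by default, consistent with reporting the statistic over
  *all* arrays of a compound; a toggle excludes them (the non-null count is
  always reported).
* **enrichment** — the KS statistic of the group's 1-based positions within
  all N instances ordered by descending `c`.
* **p-value** — empirical: the fraction of uniform random same-size subsets of
  1..N whose enrichment is at least as extreme as observed.  Default
  100,000 draws; subsets are drawn without replacement within a draw, draws
  independent, from a single seeded generator.  When C(N, group size) ≤
  100,000 the exact enumeration over all subsets replaces sampling (same cost,
  exact answer).  "At least as extreme" defaults to the *signed* reading
  (same sign, |es| at least as large); an *absolute* reading (|es| alone) is
  available.  p may be exactly 0 in sampling mode — it is reported verbatim,
  as empirical p-values conventionally are — with an optional
  (count+1)/(n_perm+1) pseudo-count mode.
* **rank** — lexicographic on (p ascending, |enrichment| descending,
  |similarity mean| descending, group key).

### Numerical and tie-break choices

* Amplitude ties when ranking a profile break lexicographically by probe
  identifier, making rankings platform-independent.
* Ties in `c` when positioning instances for group enrichment break by the
  md5 hash of the instance identifier, not the identifier itself.  This
  matters: on a null database roughly half the instances tie at `c = 0`, and
  instance identifiers typically share a compound prefix, so a lexicographic
  tie-break would place a compound's instances adjacently inside the tie
  block and fabricate group enrichment from nothing (empirically ~19% of
  null groups reached p < 0.05 that way).  The hash keeps the ordering fully
  deterministic while decorrelating it from group membership; with it the
  null p-value distribution is calibrated.
* Groups of equal size share one sampled permutation null per query.  The
  draws are independent of every observed statistic, so p-values are
  unbiased; the sharing is what makes the 100,000-draw default affordable on
  databases with many same-size compound groups.
* Query tags absent from the probe universe are dropped with a logged count
  rather than raising — cross-platform signatures never overlap completely.
  Only a query with *no* overlapping tag errors out.
* Result TSVs print floats at 6 significant digits through a fixed formatter,
  so identical seed + inputs give byte-identical files.

### Permutation-tail choice and calibration

The signed tail is one-sided and direction-aware: under the null its p-value
is uniform only on [0, P(same sign)] ≈ [0, ½], so ~10% of null groups fall
below 0.05 by construction.  That is the intended behaviour for a directional
screen, but it is not the right instrument for checking engine calibration.
Calibration is therefore assessed under the absolute tail, whose null p-value
is uniform on [0, 1]; the null-database benchmark (200 no-effect groups)
checks both the fraction of groups below 0.05 (99% binomial band around 0.05:
[0.01, 0.10]) and a KS goodness-of-fit against Uniform(0, 1) at α = 0.01.

## Signature construction

* **Disease signatures**: genes with q ≤ threshold enter the side given by
  the sign of their log2 fold change (zero excluded); each side is ordered by
  |log2fc| descending (ties by gene id) and optionally truncated to its
  strongest `top_k` genes.  Output sizes are monotone in both knobs.
* **Probe mapping** is a pure many-to-many table join with optional
  case-folding (mouse → human symbol convention); no ortholog inference.
  Unmapped genes are dropped and counted; a probe reached from both sides is
  removed from both and counted as a conflict — the conservative resolution
  that preserves disjointness, with counts exposed for audit.
* **Drug signatures**: per-probe amplitude is the difference of sample means
  on the (assumed log-scale) matrices, with a log-ratio-of-linear-means mode
  behind a switch.  Selection is by rank counts (top K = bottom K = 50 by
  default) or by absolute amplitude cutoffs; reference-database threshold
  conventions vary, so the rule is configuration, and the provenance records
  which rule produced a signature.

## Synthetic databases

The generator emulates the statistical shape of a perturbation reference
database.  Per probe a baseline `b_g ~ N(baseline_mean, baseline_sd²)`; per
instance of compound k, `control = b_g + ε` and `treated = b_g + effect_{k,g}
+ ε'` with `ε, ε' ~ N(0, σ²)` i.i.d., so the ranked amplitude is
`effect + noise(sd σ√2)` and the baseline cancels — the paired-profiling
design.  Planted compounds carry `effect = ±δ` on disjoint random up/down
sets of t/2 probes each; null compounds carry none.  Queries targeting a
planted compound are built concordantly (sets copied; the compound scores
positively, self-retrieval) or oppositionally (sets swapped; the compound
scores negatively, the disease-vs-therapeutic configuration).

Defaults are the benchmark conditions used throughout the tests: G = 1000
probes, K = 50 compounds × m = 4 instances, t = 100 tags, δ = 2, σ = 1,
baseline mean 7 and sd 1 (a typical log2 microarray intensity scale), one
oppositional plant.  Benchmark sizes (100 seeds for recovery; K = 200 null
groups with n_perm = 10,000 for calibration) keep each benchmark within
seconds on one CPU while leaving the binomial/GoF bands meaningful.

Reproducibility: one master seed; the baseline, each planted tag set and each
instance's noise use generator sub-streams derived deterministically from
(seed, role, index), so regeneration is byte-identical regardless of order.

What the generator does **not** emulate: batch and cell-line covariance,
probe-level affinity effects, correlated gene modules, dose–response
structure, or heavy-tailed expression noise.  Passing the planted-recovery
and calibration benchmarks shows the scoring engine is correct and
calibrated under clean Gaussian conditions; it does not certify performance
on real arrays, where signature quality and cross-platform mapping dominate.

## MOA inference

A second-order query runs the ordinary engine with a drug's own signature;
hits are flagged "similar"/"oppositional" by the sign of the similarity mean.
The class tally counts annotation labels over the *distinct* compounds among
the top-k hits (a compound hit in two cell lines counts once; multi-label
compounds count once per label; unannotated hits pool under "unannotated").
Annotation matching is case-insensitive after whitespace normalisation,
because public annotation tables are inconsistent.  The optional
over-representation p is the hypergeometric upper tail of the class count in
k draws from the database's compound background — an extension beyond the
descriptive tally, and marked as such in outputs.

## Known limitations

* The scaling extremes are query-relative, so `c` values are not comparable
  across different queries, only across compounds within one query.
* The group enrichment treats instances as exchangeable; plate, batch or
  cell-line structure in a real database violates that and is not modelled.
* Specificity-style statistics (how unusual a connectivity is across many
  queries) and weighted rank statistics are out of scope; the non-null count
  is the only null-instance summary reported.
* Empirical p-values are reported raw, without multiple-testing adjustment;
  at n_perm = 100,000 the resolution floor is 10⁻⁵ (0 below it).
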