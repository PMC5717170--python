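# Methods

## Model and procedure

IPP quantifies the association between one gene's expression and
right-censored survival by exhausting the threshold choice that a
conventional log-rank analysis fixes in advance. Patients are sorted by the
gene's expression (ascending; ties broken by sample id so the order is
deterministic). For every pair of group sizes (i, j) with i + j ≤ N the top
i patients form the high-expression group and the bottom j the low group;
the N − i − j patients between the thresholds are excluded from that
element. Each element is a standard two-group log-rank test summarised as a
signed z-score

    Z_ij = -(O_H - E_H) / sqrt(V),

with O_H the observed events in the high group, E_H = Σ_t d_t n_Ht / n_t
its expectation over the pooled distinct event times, and
V = Σ_t d_t (n_Ht/n_t)(1 − n_Ht/n_t)(n_t − d_t)/(n_t − 1) the
hypergeometric variance with tie correction. The minus sign makes Z
negative when high expressers are at higher risk. The IPP score is the
arithmetic mean of all N(N−1)/2 elements; its sign classifies the gene as
adverse (< 0), favorable (> 0) or unrelated (= 0).

Assumptions worth stating: the log-rank test assumes non-informative
censoring and is most powerful under proportional hazards; IPP inherits
both. Averaging over all partitions trades the single-threshold test's
sensitivity at one split for stability across splits — neighbouring matrix
elements share most of their patients and are strongly correlated, so the
score is *not* a mean of independent z-scores and its null spread must be
obtained by simulation (see below), not from a N(0, 1/√(#elements)) rule.

## Conventions and numerical choices

* **Risk sets and ties.** All subjects with observed time ≥ t are at risk
  at t; censorings tied with events at the same time are processed after
  the events. Tied *expression* values do not collapse partitions: the
  deterministic (expression, sample id) order defines the groups and all
  N(N−1)/2 elements are always evaluated, keeping the score's denominator
  fixed. The invariant-gene pre-filter (below) bounds how often heavily
  tied genes reach the scorer.
* **Degenerate elements.** When V = 0 (no events in the element's pooled
  group, or risk sets of size ≤ 1 at every event time) the element
  contributes Z = 0 but still counts in the denominator.
* **Exact antisymmetry.** The per-time numerator is evaluated as the
  integer cross-term (d_H n_L − d_L n_H)/n — algebraically identical to
  d_H − d n_H/n — and the variance through the symmetric product n_H n_L.
  With these forms, swapping the group labels negates z *bit-exactly*, and
  negating a gene's (tie-free) expression negates its IPP score bit-exactly;
  the score averages its entries with `math.fsum`, which is correctly
  rounded and therefore independent of enumeration order.
* **Incremental evaluation.** Scoring all partitions naively costs an
  O(N log N) sort plus an O(N) table walk per element. The compiled kernel
  instead fixes the high-group size i, builds the integer per-event-time
  risk tables once, and updates them in O(N) as the low group grows by one
  patient; only the floating-point statistic is recomputed per element,
  from exact integer tables, in ascending time order. Results are identical
  to independent per-element evaluation (tested to 1e−12, observed 0.0) at
  roughly two orders of magnitude less wall time; a 250-patient gene scores
  in ~10 ms.
* **Top-fraction count.** ceil(fraction · G) with a 1e−9 guard so that
  binary-float artifacts cannot inflate the count (5% of 100 is 5; 5% of
  11,123 is 557). Boundary ties in |score| are broken by gene id.

## Cohort handling

Expression and clinical TSVs are inner-joined on sample id; samples without
a valid (time, event) pair are dropped, times ≤ 0 with a logged warning.
Outputs are sorted by sample id for bit-reproducible runs. Subtypes follow
the receptor definitions luminal = ER+/PR+ (HER2 not consulted),
HER2-enriched = ER−/PR−/HER2+, triple-negative = ER−/PR−/HER2−; a sample
with any required status unknown joins no subtype — the alternative
(guessing) would contaminate subtype-specific scores. Cohorts below 20
patients are excluded by default. The invariant-gene filter drops genes
whose modal expression value — compared after rounding to 6 significant
digits, which is scale-robust and deterministic — covers strictly more than
half the samples (configurable); such genes cannot support informative
partitions. Five-level CNA calls collapse onto deletion / normal /
amplification, and mutation grouping places any sample with at least one
consequence-type record for the gene in the mutation group.

## Cross-dataset integration

Per-dataset scores are combined with Liptak's weighted method,
combined = Σ w_d S_d / √(Σ w_d²) with w_d = √n_d, the standard
sample-size weighting for Stouffer-type combination. Scores are combined on
their native scale by default; an optional hook divides each dataset's
scores by a supplied null SD first (useful because the null spread of the
IPP score depends on the dataset's N), but no variance model is imposed by
default. Genes absent from any contributing dataset are excluded with a
warning rather than imputed.

## Baselines and comparison machinery

The conventional baseline scores a gene by one log-rank z at the mean or
median threshold (high group strictly above the threshold; an empty side
yields a degenerate z = 0 with a warning). Shared-gene counting takes each
dataset's top 5% by |score| and keeps genes present in ≥ 5 datasets;
outcome-relation consistency tallies, per gene, the number of datasets with
a negative and with a positive score (exact zeros count to neither side and
are logged — they have probability zero with continuous data but must be
defined). The difference between two shared-gene counts over the same
universe is tested with a pooled two-proportion z-test, one-tailed; the
pooled-variance variant is the package's choice among the test family.
Resampling robustness draws bootstrap (with replacement) or subsample
(without) cohorts, rescores all genes per draw, and reports the per-gene
mean resampled score, the per-gene ratio mean/full — undefined and excluded
when |full| < 0.05, since near-zero denominators make the ratio
meaningless; the threshold is configurable — and the Pearson correlation
between the full and mean-resampled score vectors.

## Synthetic cohorts

The null generator emulates "virtual patients": Bernoulli(0.5) events,
Uniform(0, 10) follow-up, and expression that is a random permutation of
ranks. Because IPP is rank-invariant in expression, any exchangeable null
law induces the same score distribution, so these choices are
consequence-free for IPP itself (they do matter for the mean-threshold
baseline, whose split depends on the expression values; the generator is
configurable for that reason). The planted-signal generator draws
standard-normal expression and exponential event times with patient mean
baseline_scale · exp(−Σ β_g x_g) under uniform censoring on
(0, censor_horizon] — the simplest proportional-hazards model in which
β > 0 is adverse and β < 0 favorable by construction. Defaults
(baseline_scale 5, horizon 10) give ≈ 55–60% observed events, typical of
the breast-cancer follow-up settings the package targets. All randomness
derives from one seed through counter-based Philox streams keyed per gene,
so each gene's expression is reproducible regardless of generation order.

What the synthetic cohorts do *not* emulate: microarray noise structure,
batch effects, correlated co-expression modules, non-proportional hazards,
or informative censoring. Passing recovery tests therefore demonstrates
correctness of the scoring machinery and its comparative sensitivity under
clean proportional-hazards signal, not performance on any real cohort.

## Problem sizes used in validation

The package's own validation runs at desk scale: oracle equivalence of the
incremental scorer against naive per-partition enumeration on 200 random
cohorts of up to 30 patients; null calibration with 500 replicates at
cohort sizes 20, 100 and 250 (the full simulation supports 10,000
replicates over sizes 20–250 via `ipp null`); sign recovery over 100 seeds
at |β| = 2, n = 100; and top-5% recovery of 5 planted genes among 200 nulls
over 50 seeds at n = 120. Multi-cohort quantities that require the original
21 public microarray datasets (shared-gene and consistency counts across
cohorts) are exercised on synthetic data and, for the published counts,
through their self-contained arithmetic.

## Known limitations

* Exhaustive partitioning is O(N³)-ish per gene even with incremental
  tables; genome-wide scoring of cohorts with thousands of patients is
  feasible but not instant (~10 ms per gene at N = 250, growing cubically).
* Only the two-group log-rank statistic is supported inside the matrix; no
  stratified or weighted (Fleming–Harrington) variants, and no Cox
  adjustment for covariates.
* Liptak combination without standardisation treats per-dataset IPP scores
  as comparable despite their N-dependent null spread; the null-SD hook
  exists but is off by default.
* The one-sided log-rank tests for CNA/mutation groups require the caller
  to state the compared pair and direction; the package does not guess a
  pairing among deletion/normal/amplification.
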