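# Methods

## Problem setting

`poolseq` models a cost-reduced design for finding rare, highly penetrant
single-nucleotide variants in a candidate-gene panel across large
case–control cohorts: instead of sequencing each sample, DNA from `K = 20`
diploid samples is mixed per pool, each sample is placed in exactly **two**
pools, and the pools are sequenced deeply.  A heterozygous variant private
to one sample then surfaces at an expected allele fraction of
`1 / (2K) = 2.5%` in exactly that sample's two pools; two allele copies in a
pool (a homozygote, or two carriers sharing a pool) give `2 / (2K) = 5%`.
Because no two samples share the same unordered pool pair, the pair acts as
a barcode and the carrier of a singleton variant is recovered by
intersecting the pools in which the variant was detected.

## Pool design

`build_design` uses greedy randomized pairing: for each sample an unused
pool pair is drawn among pools with free slots, weighted by the product of
free slots (this keeps occupancy balanced and makes dead ends rare even for
fully saturated designs such as 480 samples in 48 pools of 20); dead ends
restart with the next seed-derived stream.  Any injective,
capacity-respecting assignment is equivalent for decoding, so no attempt is
made at combinatorial-design optimality (Steiner systems etc. are out of
scope).  Feasibility requires `2·n_samples ≤ n_pools·pool_size` and
`n_samples ≤ C(n_pools, 2)`; infeasible requests raise an error naming the
violated constraint.  Case and control cohorts receive independent designs.

## Synthetic pileups

The simulator produces count-level evidence directly; read-level artifacts
of alignment (FASTQ/BAM, mapping error, indel realignment) are deliberately
out of scope.  Per pool and targeted site:

* **depth** — rounded normal, truncated below at a floor.  Defaults: mean
  2396×, SD 574×, floor 400× for cases; mean 3428×, SD 660× for controls.
  A two-parameter model is sufficient at this scale and reproduces the
  regime in which essentially all sites exceed 400×.
* **alt reads** — binomial with success probability
  `p = f·(1−ε) + ε/3`, where `f = c/(2K)` is the diluted carrier fraction
  (`c` planted allele copies in the pool) and `ε` the per-base substitution
  error rate, split evenly over the three non-reference bases.  Default
  `ε = 10⁻³`: at depth ~2400 this makes error-derived alt reads appear at
  more than half of all pool–site–allele combinations, reproducing the
  "false positives nearly everywhere" regime that motivates the filter
  stack, while keeping 1% allele fractions detectable.
* **base quality / strand** — true-variant evidence draws mean BQ from
  N(30, 3) and forward-strand fraction from N(0.5, 0.05); error-derived
  evidence draws BQ from N(10, 4) and strand fraction from N(0.5, 0.25).
  The two BQ distributions deliberately bracket the BQ > 15 filter so its
  behaviour is testable from both sides.

`inject_artifacts` plants additional artifact entries at random sites in
random single pools at a configurable per pool-site rate.  Artifacts are
*defined* as filter-disqualified evidence: each one draws mean BQ from the
artifact distribution truncated below 15 and/or a strand fraction outside
[0.2, 0.8] (level 0.95, mirrored to either strand), while its allele
fraction is drawn inside the callable 1–8% window so that only the quality
filters can reject it.  A companion list of injected artifacts supports
specificity scoring.

What passing tests on these synthetics do **not** show: performance on real
pooled reads, where error is context-dependent and correlated across sites,
base-quality distributions are not Gaussian, and coverage is not independent
across pools.  The generator's purpose is to exercise the decision logic in
the stated regime, not to emulate an instrument.

## Candidate scoring and filters

Candidates are scored with a Phred-scaled binomial likelihood ratio,

    score = 10·log₁₀[ Binom(k | n, f̂) / Binom(k | n, ε/3) ],
    f̂ = max(k/n, ε/3),

clipped below at 0 (`k` alt reads of `n`).  This self-contained score plays
the role a low-fraction somatic caller would play as candidate generator;
the discriminating work is done by the filter stack:

* score > 5 (strict) — "Phred over 5";
* mean base quality > 15 (strict);
* forward-strand fraction within [0.20, 0.80] (inclusive keep-band);
* allele fraction within [0.01, 0.10] (inclusive): below 1% is
  indistinguishable from error, above 10% implies ≥ 3 copies in one pool —
  too common to be a highly penetrant rare variant;
* depth < 1000× flags the call for manual review but does **not** exclude
  it; reports list review calls separately.

Each filter is a pure per-call predicate, so filters commute and excluded
calls are retained with explanatory flags.  A per-reason exclusion ledger
(each excluded call tallied once under its highest-priority flag) plus
survivors always equals the candidate total.  The scoring `ε` defaults to
the simulation `ε` but is an independent knob, since a real-data user would
estimate it from data.

## Decoding

Surviving calls are grouped by variant; the supporting pool set is matched
against the design.  Exactly two pools forming an assigned pair →
`unique` carrier.  Larger patterns → exhaustive search for the smallest
sample set whose pool pairs exactly cover the pattern (`multi_carrier` if
the minimal cover is unique, `ambiguous` if several tie).  One pool, or no
cover of ≤ 3 samples → `undecodable`.  The 3-carrier cap follows from the
10% allele-fraction ceiling, which already rejects ≥ 3 copies per pool
upstream.  Observed fractions are converted to copy estimates by
`round(f · 2K)` (halves up), so a 5% two-pool variant is reported as one
homozygous carrier with 2 copies rather than two carriers.  Ambiguous and
undecodable variants are reported, never dropped: they are the method's
failure modes and are measured in simulation.

## Prioritization

The cascade applies, in order: a region filter (exonic consequences and
splice-affecting positions within ±6 bp; deeper intronic excluded), a
rarity filter (maximum population frequency across databases ≤ 1/1000,
strictly interpreted, and never observed homozygous — a frequency of 1/945
therefore fails), and tier assignment: known functionally validated
variants → `known_pathogenic`; nonsense, frameshift or canonical-splice →
`likely_pathogenic`; missense with Condel > 0.522 **and** CADD > 20 →
`likely_pathogenic`; all other survivors → `rare_RSV`.  Gene constraint
(pLI > 0.50 and missense Z > 0) is attached as a metadata flag rather than
a gate: making it a filter would change carrier counts, and the criteria
treat it as interpretive context.  Missing annotation excludes
conservatively with reason `unannotated`.  Annotation is consumed from a
flat table — one max-frequency column stands in for the per-database
columns, since the rule needs only the maximum — and is never fetched live.

## Burden statistics

Carrier tables count distinct individuals with ≥ 1 qualifying variant per
cohort.  The headline statistic is the ratio of carrier proportions
`(a/n_a)/(b/n_b)` (displayed half-away-from-zero to 2 decimals), with the
classical odds ratio reported alongside under its own label; on tables of
this shape the two differ (48/463 vs 31/480: proportion ratio 1.61, odds
ratio 1.67), and the proportion ratio is the statistic the per-table
published values follow from.  Significance uses a two-sided Fisher exact
test computed by full enumeration of the hypergeometric support under the
minimum-likelihood convention (a small relative tolerance guards
floating-point ties); an independent reference implementation pins it in
the tests.  No covariate adjustment or multiple-testing correction is
applied.

## Evaluation

`evaluate` scores a simulated run against the planted truth.  Sensitivity
counts a planted variant as detected only when a decoded record with the
same variant key reports **exactly** the true carrier set; it is reported
as a whole-number percentage (6/7 → 86%) and stored unrounded.  The
specificity proxy is the number of injected artifacts surviving the filter
stack (0 expected).  The report also carries the decoding ambiguity rate
and the filter ledger, whose conservation is asserted on every run.

## Problem sizes and numerical choices

Default end-to-end runs use the full study geometry (463 + 480 samples, 48
pools of 20 per cohort) over a compact synthetic panel of one 40-bp "exon"
per candidate gene (600 targeted sites) — large enough to produce tens of
thousands of error-derived candidates per cohort while keeping a full run
in seconds.  The matched-regime sensitivity experiment plants 60 singleton
heterozygotes; the dilution calibration uses 100 singletons observed in 200
carrier pools and checks the empirical mean against 2.5% (and 5% for two
copies) within three Monte-Carlo standard errors, with `ε = 0` so the check
isolates the dilution arithmetic.  All randomness flows from explicit
seeds through `numpy.random.default_rng`; identical configuration and seed
give byte-identical output tables.

## Known limitations

* Indels, multi-allelic decomposition beyond independent per-alt treatment,
  and mapping/base-quality recalibration are out of scope.
* Decoding is combinatorial, not probabilistic; it does not weigh call
  scores when covers tie, and designs with > 2 replicates per sample are
  unsupported.
* The simulator's independence assumptions (across sites, pools, strands)
  are optimistic relative to real sequencing error.
* Printed-count statistics reproduce published tables from their counts;
  per-gene counts from the original cohorts depend on the original reads
  and annotations and are not reproducible here.
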