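# poolseq

Rare-variant discovery from **pooled DNA sequencing** of candidate-gene
panels in case–control cohorts.

Sequencing every sample of a large cohort is expensive; mixing DNA from
*K* = 20 diploid samples per pool and placing each sample in exactly **two**
pools cuts the number of libraries by an order of magnitude while keeping
variants assignable to individuals.  A heterozygous singleton then appears
at an expected allele fraction of 1/(2·20) = **2.5%** of the reads in
exactly its carrier's two pools (two allele copies → 5%), and the unordered
pool pair — unique per sample by construction — identifies the carrier.
The price is that at pooled depths of ~2400×, sequencing error produces
alt-allele candidates at nearly every targeted position, so calling hinges
on an aggressive, well-characterized filter stack.

`poolseq` implements the full workflow for anyone studying or teaching this
design — statistical geneticists screening candidate genes in severe
early-onset phenotypes, or methodologists probing where overlapping-pool
decoding breaks:

* **design** — two-replicate overlapping pool designs with validated
  invariants (injective pool pairs, capacity limits);
* **simulate** — synthetic per-pool pileup count tables with planted
  variants, normal-truncated coverage (default 2396× ± 574, floor 400×),
  binomial error noise (ε = 10⁻³), and injected low-quality / strand-biased
  artifacts, plus a ground-truth table;
* **call** — a Phred-scaled binomial likelihood-ratio score
  `10·log₁₀[L(k|n, f̂)/L(k|n, ε/3)]` with the filter stack: score > 5,
  mean base quality > 15, forward-strand fraction in [0.20, 0.80], allele
  fraction in [1%, 10%], and a manual-review flag below 1000×;
* **decode** — carrier assignment by minimal exact cover of the supporting
  pool set against the design (unique / multi-carrier / ambiguous /
  undecodable), with allele-copy estimates `round(f·2K)`;
* **prioritize** — exonic/splice ±6 region filter, ≤ 1/1000 frequency and
  no-database-homozygote rarity filter, then tiering: loss-of-function or
  damaging missense (Condel > 0.522 **and** CADD > 20) → likely pathogenic;
  functionally validated → known pathogenic; gene constraint
  (pLI > 0.50, missense Z > 0) attached as metadata;
* **burden** — distinct-carrier tables, carrier-proportion ratio, classical
  odds ratio, and a two-sided Fisher exact test by hypergeometric
  enumeration.

See `docs/methods.md` for the model, its assumptions and its limits.

## Worked example

Published carrier counts are inputs to the burden statistics — e.g. 23 of
463 patients versus 8 of 480 controls carrying likely pathogenic variants:

```python
>>> from poolseq.burden import CarrierTable, burden_result
>>> r = burden_result(CarrierTable(23, 463, 8, 480))
>>> round(r.ratio, 2), round(r.odds_ratio, 2), round(r.p_two_sided, 4)
(2.98, 3.08, 0.0055)
>>> r.pct_a, r.pct_b
(4.97, 1.67)
```

The carrier-proportion ratio (2.98) says patients are three times as likely
as controls to carry a qualifying variant; the classical odds ratio (3.08)
is reported alongside under its own name.

A full simulated run at study scale (463 + 480 samples, 48 pools of 20 per
cohort, 25 + 20 planted variants over a 600-site toy panel):

```python
>>> from poolseq.pipeline import RunConfig, run_pipeline
>>> from poolseq.simulate import ErrorModel
>>> res = run_pipeline(RunConfig(seed=7, error=ErrorModel(artifact_rate=0.002)))
>>> res.cases.report.to_dict()
{'n_planted': 25, 'n_detected_correct': 25, 'sensitivity': 1.0,
 'sensitivity_percent': 100, 'n_artifacts': 44, 'n_artifacts_surviving': 0,
 'ambiguity_rate': 0.0,
 'ledger': {'low_score': 42173, 'low_bq': 4041, 'strand_bias': 119,
            'fraction_out_of_range': 387, 'survivors': 50}, 'applicable': True}
```

The ledger shows the regime the filters exist for: ~46 000 error-derived
candidates are rejected, all 44 injected artifacts among them, while all 25
planted variants survive and decode to their exact carriers (50 surviving
calls = 25 variants × 2 pools).

The same stages run from the shell:

```sh
poolseq design --cohort cases --samples 463 --pools 48 --pool-size 20 \
    --seed 7 -o design.tsv
poolseq simulate --design design.tsv --regions targets.bed \
    --variants variants.yaml --seed 7 -o pileups.tsv --truth truth.tsv
poolseq call --pileups pileups.tsv --error-rate 1e-3 -o calls.tsv
poolseq decode --calls calls.tsv --design design.tsv -o decoded.vcf
poolseq prioritize --decoded decoded.vcf.tsv --annotations ann.tsv \
    --constraint constraint.tsv -o prioritized.tsv
poolseq burden --table 48,463,31,480
poolseq run --config run.yaml -o out/   # everything at once
```

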