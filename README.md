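# mtsomatic

Somatic mitochondrial DNA analysis for clonally transmissible tumours that
periodically capture mtDNA from their hosts. The package covers the full
desk-scale analysis:

* **Reference model** (`mtsomatic.reference`) — circular mtDNA reference with
  gene annotations, excluded regions/sites, circular triplet censuses on
  either strand, and codon-level consequence annotation under the vertebrate
  mitochondrial genetic code (NCBI table 2).
* **Call tables** (`mtsomatic.calls`) — variant calls with full filter
  evidence (strand counts, base/mapping-quality summaries, read-end flags,
  REP, caller support) in a TSV or VCF-4.2 INFO-key dialect, gzip
  transparent; per-sample coverage summaries.
* **Filters** (`mtsomatic.filters`) — substitution post-processing rules
  (base-quality fraction, mean mapping quality, read-end support, indel
  proximity with REP extension, repeat-region and site exclusions, strand
  representation) with a rescue list that can only override the
  indel-proximity rule; indel strand-support and caller-support rules;
  recurrence/back-mutation flagging.
* **Somatic classification** (`mtsomatic.classify`) — germline vs somatic
  separation with matched hosts (VAF-0.9 rule, low-coverage-host checks) or
  per-tumour VAF cutoffs without hosts; tumour-fraction estimation from
  tumour-unique homoplasmic variants; VAF normalization; the four per-clade
  variant classes (clade-defining germline, somatic, conservative-somatic,
  potential-somatic).
* **Mutation spectrum** (`mtsomatic.spectrum`) — 96 pyrimidine-context
  classes per strand, observed/expected normalization against the genome
  triplet census, with presentation-rounding and strict modes.
* **Selection inference** (`mtsomatic.selection`) — two-sample KS tests on
  normalized VAF distributions (truncating vs other variants; exact p for
  small samples) and a context-dependent Poisson dN/dS with 192
  substitution-in-context rates, per-coefficient likelihood-ratio tests and
  profile-likelihood confidence intervals. The single light-strand gene is
  excluded.
* **Clade timing** (`mtsomatic.timing`) — time since each mtDNA capture from
  mean somatic burden under three calibrations (nuclear reference clade,
  cell divisions, external per-year rate), with and without potential-
  somatic variants.
* **Copy number / qPCR** (`mtsomatic.copynumber`) — copies per cell from the
  coverage ratio formula, high-coverage exclusion, and standard-curve
  relative-input arithmetic.
* **Haplotype nomenclature** (`mtsomatic.haplotypes`) — host haplogroup
  assignment from diagnostic-variant definitions, hierarchical tumour
  naming with the five-level/serial-suffix rules, donor-haplotype
  reconstruction.
* **Synthetic data** (`mtsomatic.simulate`) — seeded generator for
  reference genomes and cohorts: clade structure from distinct donor
  haplotypes, Poisson somatic accumulation under a strand-biased context
  spectrum, consequence-specific selection, heteroplasmy, host
  contamination, binomial read support. Output is a drop-in fixture for the
  pipeline, with a per-variant truth table.

## CLI

```sh
# generate a synthetic fixture directory
mtsomatic simulate --seed 1 --out fixtures/demo

# run the complete pipeline and write all reports
mtsomatic run-all --input fixtures/demo --out reports/demo

# individual stages (each prints a JSON digest)
mtsomatic filter    --input fixtures/demo
mtsomatic classify  --input fixtures/demo
mtsomatic spectrum  --input fixtures/demo --presentation-rounding
mtsomatic selection --input fixtures/demo
mtsomatic timing    --input fixtures/demo
mtsomatic copynum   --input fixtures/demo
mtsomatic haplotype --input fixtures/demo
```

Thresholds can be overridden with `--config config.yaml`; every numeric
default (base-quality fraction 1/3 over BQ 25, mapping quality 21, 15 bp
read ends, 10 bp indel proximity, repeat region 16129–16430, VAF 0.9,
20X/300X coverage bounds, VAF cutoffs 0.5/0.6, 460-year calibration,
1000-generation rule with 4/20-day bounds, 0.025/year rate, ploidy 2) lives
in `mtsomatic.defaults`.

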