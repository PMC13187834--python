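# uvmut

Analysis pipeline for genome-wide UV mutagenesis experiments in
photolyase-expressing yeast: mutation-accumulation cohorts are passaged
through repeated UV exposures, whole-genome sequenced, and compared across
strains that express a CPD photolyase, a 6–4PP photolyase, both, or neither.
Because each photolyase removes exactly one photoproduct class before it can
mutate, subtracting a photolyase strain's mutation spectrum from the
no-photolyase control attributes mutation classes to cyclobutane pyrimidine
dimers (CPDs), 6–4 photoproducts, or photolyase-resistant *atypical*
photoproducts such as the thymine–adenine photoproduct.

The package is aimed at researchers analyzing such cohorts (or building
simulated ones to validate methods). It provides:

- **Variant filtering** — per-isolate VCF input with the cohort QC rules:
  depth ≥ 10 reads, allele fraction ≥ 45%, mitochondrial exclusion, and
  removal of identical mutations recurring in > 2 isolates of a passaging
  replicate (pre-existing, not UV-induced). Adjacent SNVs merge into doublet
  substitutions (DBS); every removal is audited.
- **Spectra** — per-isolate SBS-96 matrices (pyrimidine-centric trinucleotide
  classes, `A[C>T]G`) and DBS matrices on the 78 canonical doublet classes
  (`CC>TT`, `AC>TT`, …), with per-class mean ± SEM and per-isolate totals.
- **Attribution** — per-class fold reductions between strains with Welch's
  unequal-variance t-tests; classification of each class on the
  (fold<sub>CPD</sub>, fold<sub>6–4PP</sub>) plane into CPD-dominant /
  6-4PP-dominant / mixed / atypical; Mann–Whitney replicate concordance; and
  mutagenic potential = attributed mutations ÷ total induced lesions.
- **Strand asymmetry** — NTS/TS assignment inside genes, trinucleotide-
  normalized NTS/TS ratios, 1-df chi-squared tests with Bonferroni
  correction, and re-expression of *reverse-asymmetric* classes on the
  lesion strand (the inference that T>A in NTA reflects A>T at TA
  photoproducts on the complementary strand).
- **Lesion quantification** — alkaline-gel densitometry: ladder calibration
  (log-linear size ↔ migration), intensity-median fragment size, and the
  Poisson fragment correction φ = 1.678 / median-size, with no-enzyme
  background subtraction.
- **Synthetic data** — a generator that emulates the whole experiment
  (genome, genes, photoproduct channels with configurable repair and
  transcription-coupled strand bias, depth/AF noise, recurrent contaminants,
  gel lane profiles) with a ground-truth table for every emitted mutation.

## The core quantities

For a mutation class *c* compared between control and photolyase strains:

```
fold_reduction(c) = mean mutations/isolate, control / mean mutations/isolate, treated
normalized NTS/TS(c) = (n_NTS / a_NTS) / (n_TS / a_TS)
```

where `a_NTS`, `a_TS` are the abundances of *c*'s trinucleotide context on
each strand across gene bodies. Lesion loads come from Poisson fragment
analysis of gel lanes, and mutagenic potential combines the two:

```
φ = 1.678 / (intensity-median fragment size, kb)      [per strand, per kb]
total lesions = φ_net × haploid kb × ploidy × 2 strands
% mutagenic   = 100 × attributed mutations / total lesions
```

## Worked example

`examples/photoproduct_attribution.py` runs the attribution arithmetic with
the cohort medians and gel lesion densities from the photolyase passaging
study (no-PL medians 652/694 and CPD-PL medians 264/285 mutations per
isolate across two replicates; 1.26 CPDs/kb and 0.26 non-CPD
photoproducts/kb; 12 070 kb haploid genome, diploid cells):

```
CPDs: 398.5 attributed mutations / 60833 induced CPDs = 0.66% mutagenic
6-4PP + atypical: 274.5 / 12553 = 2.19% mutagenic
```

i.e. CPDs cause most UV mutations in aggregate, yet fewer than 1% of
individual CPDs become mutations, and non-CPD photoproducts are ~3× more
mutagenic per lesion. The other examples cover cohort simulation + spectra
(`simulate_and_spectra.py`), strand asymmetry and the atypical-photoproduct
inference (`strand_asymmetry.py`), and gel-based lesion quantification
(`gel_lesion_quantification.py`).

A thin CLI orchestrates the stages on files
(`uvmut simulate`, `uvmut run --config run.yaml`, `uvmut filter`,
`uvmut spectra`, `uvmut lesions`); every stage writes a TSV and the run
report echoes every parameter that affects a number.

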