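# Methods

This note documents the models, conventions and numerical choices behind
`uvmut`, and what the synthetic-data generator does and does not emulate.

## Mutation-class encoding

SNVs are encoded pyrimidine-centrically: a change whose reference base is a
purine is reverse complemented together with its flanking bases, giving 6
substitution types × 16 trinucleotide contexts (SBS-96, labels `A[C>T]G`).
Doublets collapse onto ten canonical reference dinucleotides
{AC, AT, CC, CG, CT, GC, TA, TC, TG, TT}; exactly one of a non-palindromic
dinucleotide and its reverse complement is canonical, and for palindromic
references (AT, CG, GC, TA) the lexicographically smaller of the two
equivalent alt readings labels the class, giving 78 classes. Trinucleotide
windows containing N are uncountable: the variant is excluded from spectra
and recorded in the audit rather than silently dropped.

Coordinates are 0-based half-open everywhere inside the package; VCF
(1-based) and GFF3 (1-based inclusive) are converted at the I/O edge. A
variant whose reference allele disagrees with the genome raises a hard
error, since that almost always signals a genome-build mismatch rather than
a bad record.

## Filtering

Thresholds are inclusive (depth ≥ 10, allele fraction ≥ 45%), pinning the
boundary behavior by test. Allele fractions are rounded to 6 decimals on
read because VCF floats are single precision (0.45 would otherwise arrive
as 0.44999998 and fail its own boundary). The recurrence rule pools all
strains within a passaging replicate, keys on exact
(contig, position, ref, alt) and counts *distinct isolates*; a site seen in
more than two isolates loses all its records in that replicate.
Cross-replicate recurrence is not filtered. The filters are applied in the
documented order — site predicates, then recurrence — because the
recurrence count depends on which records are present; the suite asserts
idempotence and audit conservation (every input record lands in "kept" or
exactly one removal bucket).

Doublet calling merges exactly two adjacent filtered SNVs of one isolate;
runs of three or more adjacent SNVs are multi-nucleotide events, excluded
from both SBS and DBS spectra but audited. Length-2 MNV records from the
caller are accepted directly as doublet candidates, so both calling styles
are supported.

## Spectra and summaries

Matrices are isolates × classes; the isolate row set can be fixed from the
sample sheet so zero-mutation isolates keep zero rows (they matter for
means). SEM uses the n−1 sample standard deviation and is undefined (NaN)
below two isolates. The median of an even-sized group is the mean of the
two central values.

## Attribution

Welch's unequal-variance t-test is implemented directly (statistic,
Welch–Satterthwaite degrees of freedom, two-sided p) and cross-checked
against SciPy to 1e-10 in the suite. Zero variance in both groups is
degenerate: equal constants give p = 1, unequal constants p = 0, with a flag
so tables can mark the row. Fold reductions with a zero treated mean are
reported as ∞ with the control mean retained — this genuinely occurs for
rare classes in double-photolyase isolates. No multiple-testing correction
is applied to fold tables (Bonferroni is reserved for the asymmetry
chi-squared tests, matching how such cohorts are conventionally analyzed);
the per-class count threshold (default 70 cumulative control mutations,
configurable per comparison) limits the table to classes with usable signal.

The Mann–Whitney U test used for replicate concordance computes the exact
tie-aware permutation distribution of the rank sum (by subset-count dynamic
programming, equivalent to enumerating all partitions) for combined n ≤ 20,
and the tie-corrected normal approximation with continuity correction above
that. Two-sided exact p is 2 × min(P(≤ u), P(≥ u)) capped at 1.

Photoproduct classification partitions the (fold_CPD, fold_6-4PP) plane
with thresholds defaulting to 2.0: a threshold crossed on one axis only
gives CPD-dominant or 6-4PP-dominant, both give mixed, neither gives
atypical. The 2.0 default is this package's choice, surfaced as a
parameter; the underlying experimental shading is qualitative.

Attribution of mutation counts uses per-replicate median totals, averaged
across replicates within each strain, control minus treated; with no
treated strain the control average itself is the attribution (residual
mutagenesis read against a zero baseline). Mutagenic potential multiplies
lesions/kb by haploid genome size, ploidy and 2 strands — gel
quantification measures lesions per strand — and divides attributed
mutations by that total.

## Strand asymmetry

The non-transcribed strand (NTS) is the gene's annotated coding strand; the
transcribed strand (TS) is its template. A mutation whose canonical
pyrimidine lies on the coding strand is an NTS mutation. Positions covered
by genes on both strands are ambiguous and excluded, both from assignment
and from the strand censuses, as are doublets whose reference dinucleotide
is palindromic (their strand is undecidable). Intergenic mutations are
excluded from the analysis.

Counts are normalized by the strand-specific abundance of the class's
context across gene bodies; the chi-squared null splits each class's total
proportionally to those abundances (a 50:50 mode exists for sensitivity
analysis; whether the original normalization used abundance-weighted or
equal expectations is not decidable from the text, so abundance-weighted —
the stricter reading of "normalized by occurrence" — is the default). The
Bonferroni divisor is the number of classes passing the count threshold
(default 50 genic mutations) in the invocation. Reverse-asymmetric classes
(ratio < 1 and significant) are re-expressed on the complementary strand —
`T[T>A]A` becomes `T[A>T]A` — to name the putative lesion-strand change.

## Lesion quantification

Ladder calibration interpolates log10(size) linearly against migration
through the band knots, extrapolating linearly beyond the outermost bands.
The HindIII-λ band sizes (23130…564 bp) ship as an editable default. The
lane median is the migration at which cumulative intensity crosses half the
lane total, interpolated linearly between samples.

Under random (Poisson) breakage at φ per kb, fragment lengths are
exponential with mean 1/φ, but gel intensity is mass-weighted: the
length-biased distribution is gamma with shape 2, whose median is
≈ 1.6783/φ. The default correction therefore estimates φ = 1.6783 /
(median-intensity size in kb); `correction=1.0` gives the naive reciprocal
for comparability with analyses whose exact convention is unknown. The
no-enzyme lane's frequency is subtracted to remove background cutting; a
negative net floors to 0 with a flag.

The estimator assumes fragments ≪ strand length. At φ = 1.26/kb on 50 kb
strands recovery is within ~2%; at φ = 0.1/kb the mean fragment approaches
the strand length and truncation biases the raw estimate by ~15–20%, so
low-φ validations use proportionally longer strands. Real preparations,
whose input DNA is itself heterogeneous and much longer than 1/φ in the
measured lanes, sit in the well-behaved regime.

## Synthetic-data generator

The generator emulates the passaging experiment at desk scale: a random
genome (default 200 kb, GC 0.38, ~yeast-like) with non-overlapping genes on
both strands covering most of the sequence; photoproduct channels that
deposit lesions Poisson-distributed over their target-dinucleotide
occurrences on both strands across 15 passages; per-strain photolyase
repair as binomial thinning of a channel; transcription-coupled repair as a
further 1/f survival of template-strand lesions inside gene bodies
(default f = 4; asymmetry validations use 10); channel-specific substitution
outcomes, including AC>TT doublets; Poisson depth (mean 50) and Gaussian
allele-fraction noise (0.5 ± 0.02, clipped); and shared contaminant SNVs
injected into three isolates per replicate to exercise the recurrence
filter. Default channel rates make CPDs responsible for ~60% of the
no-photolyase burden so the CPD-photolyase strain retains ~40% of it,
mirroring the reported strain ratios; per-isolate totals (~400 at default
size) are set by the 200 kb genome, a deliberate scale-down of the
genome-wide experiment.

Not modeled: replication/translesion mechanics (each surviving lesion
converts directly to a mutation with the channel's outcome distribution),
selection during passaging, sequencing reads, chromatin or expression-level
repair heterogeneity, and real genome composition. Passing recovery tests
therefore demonstrates correctness of the *statistics* — spectrum
construction, normalization, thinning arithmetic, estimator inversion — not
fidelity of mutagenesis biochemistry.

Gel simulation places Poisson breaks uniformly on fixed-length strands
(default 50 kb, 10⁴ strands), bins fragment masses onto the calibrated
migration axis (400 bins), and emits an enzyme lane (lesions + background)
and a no-enzyme lane (background only).

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy.random.default_rng`);
identical configs produce byte-identical VCFs, tables and reports, and the
pipeline is idempotent. Validation problem sizes — 120–200 kb genomes, 4–24
isolates per strain, 10⁴ gel strands — were chosen so every recovery
property has comfortable statistical power (3 SE margins, 10–15% relative
tolerances) while the full suite runs in seconds.
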