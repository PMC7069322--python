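# Methods

## The coverage-ratio statistic

The core of the package is a two-sample read-depth comparison on a shared
assembly. Illumina reads of a focal and a comparison individual are mapped
to the same reference and their per-base depth is summed in fixed genomic
bins (default b = 1,000 bp). For each bin the statistic is

    r = e / (e + s·a)

where e is the focal sample's binned coverage, a the comparison sample's,
and s a library-size correction applied to the comparison sample. Under
equal copy number and corrected library sizes, E[r] = 0.5. A segment whose
copy number in the comparison sample is c_a against c_e focal copies has
expectation r = c_e / (c_e + c_a): a comparison-side doubling (2 vs 4
copies) gives r = 1/3, a comparison-side deletion pushes r above 0.5. The
per-segment fold estimate is the inverse map, fold = (1 − r)/r, reported as
a comparison:focal coverage fold; translating a fold into an absolute copy
number (duplication vs triplication, heterozygous vs homozygous) is left
to the user, because coverage alone cannot distinguish those layouts.

At ~30× depth and 1-kb bins the binomial-type noise of r is tiny (sd
≈ 0.002 per bin at r = 0.5), which is why simple thresholding segments
cleanly. Defaults: bins with r ≤ 0.40 or r ≥ 0.60 are deviant, runs may
bridge up to 2 non-deviant bins, and a call needs at least 5 deviant bins.
At Poisson 30× a neutral bin crosses either threshold with probability far
below 10⁻³, so false segments of ≥ 5 bins are effectively impossible while
a true twofold segment of 5 kb is still called. All thresholds are exposed
as configuration.

### Library-size correction

Two modes are provided because real pipelines differ in what "corrected
for library size" means:

* `totals` — s = (focal library total)/(comparison library total). Literal,
  but biased when large CNVs or sex-linked scaffolds contribute unequally
  to the two totals.
* `median-recenter` (default) — s is chosen so the genome-wide median of r
  is exactly 0.5, i.e. s = median(e/a) over bins with both counts positive.
  Robust as long as more than half of the genome is copy-neutral, which is
  the operating assumption of the whole method.

The two modes differ by approximately (CNV bin fraction) × (relative copy
excess); on mostly-neutral genomes they agree to within a percent or two.

### Masking

Bins with combined corrected coverage below `min_combined` (default 10)
are masked and excluded from medians, folds and segmentation; a 0/0 bin
has no defined ratio and is never imputed.

## Z-scaffold assignment

Birds have ZZ males and ZW females, so a male:female comparison shows
twofold male coverage on Z-linked sequence and equal coverage on
autosomes. Per scaffold the package reports the median over informative
bins of e/(s·a) — the median rather than the mean so that a CNV embedded
in an autosomal scaffold cannot drag the scaffold into the Z band — and
classifies scaffolds by disjoint fold intervals: Z for folds in [1.6, 2.6],
autosome for [0.8, 1.25], ambiguous otherwise. The bands are the package's
own choice (no published fold window exists for this rule); they are wide
enough to absorb residual library miscorrection yet separated so a call
never flips between classes by noise alone at ≥ 100 informative bins.
Ambiguous is retained as an explicit outcome rather than forcing binary
calls, since scaffold-level misassignment is a documented failure mode of
the twofold rule. Scaffolds shorter than `min_len` (default 10 kb) or with
fewer than `min_bins` (default 10) informative bins are not classified.
W-chromosome detection is out of scope: the same comparison cannot see
sequence absent from the male reference individual.

## Assembly metrics

N50 is the length of the scaffold at which the descending cumulative
length first reaches ≥ 50% of the assembly total, L50 the number of
scaffolds up to and including it; N75/L75 are analogous at 75%. Ties use
the first-crossing rule: when the cumulative sum hits the threshold
exactly at a scaffold boundary, that scaffold is counted. NG50 replaces
the assembly total with an external genome size and is undefined (reported
as null) when the assembly never reaches half that size. Genome size may
be supplied directly in bp or as a haploid C-value in pg, converted at
0.978 Gbp per pg with rounding deferred to reporting (1.73 pg → 1.69 Gbp,
1.53 pg → 1.50 Gbp, mean 1.59 Gbp). The scaffold length filter defaults to
≥ 500 bp inclusive and is configurable. GC% excludes N bases from its
denominator (ambiguity codes other than N count toward length but not GC);
N% is relative to total length. This choice is documented here because
published metric tables rarely state it.

## GC profiling and exon recovery

Gene models are reduced to 5'UTR, CDS and 3'UTR intervals; per gene the
regions of one kind are concatenated, GC% computed with N bases excluded,
and mean ± sample sd (ddof = 1) taken across genes. Strand is handled by
reverse-complementing minus-strand regions — irrelevant to GC but kept so
exported sequences are in transcript orientation.

Exon recovery asks whether each first-exon sequence can be located in an
assembly. "Recovered" is operationalized as a local alignment covering at
least `min_cov` = 0.8 of the exon at `min_ident` = 0.9 identity, on either
strand. Implementation: a fast infix edit-distance screen (edlib, full
exon against each scaffold) accepts near-full-length matches; candidates
that fail it fall back to an explicit local alignment
(Bio.Align.PairwiseAligner, match +1, mismatch −2, gap open −2.5, extend
−0.5), from which coverage is the aligned query span and identity the
fraction of identical columns. The decision is monotone in both
thresholds. Both thresholds are configurable because "sequenced" has no
unique definition; the defaults reflect what a practitioner would accept
as the same exon. Recovery of an empty GC class is reported as undefined
(NaN), never 0%.

GC classes are the five conventional bins ≥70, 60–69, 50–59, 40–49 and
<40 percent, with inclusive lower bounds (69.99 falls in 60–69).

## qPCR relative quantification

A standard curve is the ordinary least-squares fit of Ct on log₁₀ starting
copies over a dilution series of at least three levels; the slope m gives
the amplification efficiency E = 10^(−1/m) − 1, so m = −3.3219
cycles/decade is a perfect doubling (E = 100%). Unknowns are quantified
absolutely on their own assay's curve and the target:control copy ratio is
reported per sample with mean ± sd per group. Replicate QC: a sample is
discarded when any two replicates differ by more than 0.3 Ct (the exact
boundary passes; the pairwise-maximum generalizes the duplicate rule to
n replicates). QC failures are retained in the per-sample output with an
exclusion reason but never enter summaries. A ΔCt shortcut mode
(ratio = 2^−(Ct_target − Ct_control), perfect-efficiency assumption, no
standards needed) is available for quick checks; the curve mode is the
default and the faithful procedure.

## The synthetic-data generator

The simulator reproduces the statistical structure the analyses assume,
not raw reads. Per-bin coverage is drawn with mean μ = φ·c·b, where φ is
the per-copy per-base depth (default 15, putting the diploid focal sample
at ~30×, the order of a typical short-read genome project), c the local
copy number (autosomes 2; Z: 2 male / 1 female; planted CNV segments as
specified, with bp-weighted means for bins straddling a segment boundary —
the situation of a gene lying across a duplication edge), and b the bin
width. `dispersion = 0` gives Poisson counts; `dispersion > 0` gives
negative-binomial counts with variance μ(1 + dispersion·μ), reflecting the
overdispersion of real mapped coverage. The comparison sample's counts are
multiplied by a library-scale factor to emulate unequal library sizes.
Scaffold sequences are i.i.d. with controllable GC (default 42%, a typical
avian genome-wide value). Exon sets are generated with exact GC counts
inside each requested class; Ct tables are produced by inverting a
standard curve at implied copy numbers plus Gaussian cycle noise.

All randomness derives from one integer seed through named
`SeedSequence` streams, so outputs are bit-identical across runs and
independent per scaffold/sample.

What the simulator does **not** model — and therefore what passing tests
do not demonstrate about real data: mappability and repeat-induced
coverage holes, GC-dependent coverage bias (the very bias the exon-recovery
analysis quantifies in real assemblies), read-level artifacts (duplicates,
adapters, chimeras), alignment ambiguity between paralogs, and qPCR
inhibition or efficiency drift between plates. The recovery guarantees
shown on simulated data (perfect Z classification at ≥ 100 kb and 30×,
exact single-call recovery of a 200-kb planted duplication) are
best-case: they establish that the statistics and the thresholds are
internally consistent, not that real libraries are this clean.

## Problem sizes used in the shipped checks

The calibration checks run on 10 scaffolds of 1 Mb (10⁴ bins) for the
neutral median and the planted-duplication signature, and on 20 seeds of a
6-scaffold, 100-kb-per-scaffold genome for Z classification — sizes at
which the Monte-Carlo error of the checked quantities is an order of
magnitude below the asserted tolerances.

## Known limitations

* The CNV caller is a thresholding segmenter; it will fragment segments
  whose true ratio hovers at a threshold and has no explicit significance
  model. It replaces what was historically a visual scan, and inherits the
  visual scan's resolution (one bin).
* `median-recenter` normalization assumes a mostly copy-neutral genome; on
  a genome where most bins are deviant it converges to the wrong center.
* Fold estimates conflate copy number with mapping efficiency differences
  between libraries; orthogonal validation (e.g. qPCR, as implemented
  here) is the intended companion.
* Exon recovery depends on alignment scoring; extremely GC-rich exons with
  many short repeats can align ambiguously, and the reported per-class
  percentages depend on the chosen coverage/identity thresholds.
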