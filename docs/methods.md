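# Methods

## The accumulation model

Each MA line is modeled as a single lineage bottlenecked to one selfing
individual per generation. Under that regime a new mutation either is
lost or fixes homozygous within a couple of generations, and selection
has almost no purchase; the package therefore models every surviving
mutation as *instantly fixed homozygous* in its line. Heterozygous
segregation and drift inside the one-individual bottleneck are not
modeled — the detection criteria score only homozygous line-specific
variants, so transient heterozygosity is invisible to every downstream
quantity. Consequently the generation stamp attached to each simulated
mutation is uniform over 1..G and is bookkeeping only: with neutral
instant fixation, origin time does not affect the final genotype matrix.

Per line, the number of mutations of each type is Poisson(μ·L·G) with
independent draws across lines; positions are uniform over non-N sites
with a configurable minimum same-line spacing (`min_spacing`, default 1
= no exact collisions). SNV classes are drawn from a 6-class
strand-collapsed spectrum; the class is drawn *first* and a position
with a compatible reference base is then rejection-sampled, which makes
the empirical class frequencies converge to the configured spectrum on a
genome of any GC content (conditioning a class on a uniformly drawn site
would skew the realized spectrum by base composition). Indel lengths are
geometric with mean `indel_length_mean` (support ≥ 1 bp); inserted
sequence is uniform random; deletions carry their VCF anchor base.

Cross-contamination is emulated by copying a configurable fraction of
one line's mutations into a second line, which is what a physical sample
swap/mixture looks like after homozygous genotype calling.

## The genotyping emulator, and what it does not emulate

`emulate_calling` draws a whole-genome per-line depth track
DP ~ Poisson(`coverage_mean`) and emits one VCF record per truth
mutation: carrier alt-homozygous, everyone else reference-homozygous,
with three noise channels — `missing_rate` (genotype dropped to ./.),
`het_miscall_rate` (a non-carrier miscalled 0/1, which exercises
criterion iii), and a clamped-normal GQ around `gq_mean`. The depth
track doubles as the callable-length input.

Deliberately not emulated: read-level errors, alignment and mapping
bias, indel realignment ambiguity, GC-dependent coverage, and linked
error modes of real callers. Passing tests on synthetic data therefore
demonstrate that the *filtering, rate, spectrum and error-rate
arithmetic* is correct under the stated genotype-level noise model —
not that any particular caller achieves these error rates on real reads.
For real data the package consumes the caller's VCF as-is and applies
the criteria to all records as given (no hidden pre-filtering).

## Detection thresholds

Defaults (all configurable, all serialized into the report for
provenance): focal alternative homozygote DP ≥ 5 and GQ > 20; uniqueness
of the alt-homozygous line at the site; no heterozygote in any other
line; ≥ 10 reference-homozygous lines with DP > 5; linkage window 100 bp
with *both* members of a same-line pair removed. The DP asymmetry
(focal ≥ 5 vs support > 5) is deliberate and preserved from the
published procedure. Missing genotypes count toward neither the
heterozygote veto nor the support count. Multi-allelic sites are judged
jointly: a second alt-homozygous line disqualifies the site even for a
different alt allele, and a het for any alt vetoes. Equal-length
multi-base substitutions (MNVs) are not scored. Groups need at least
11 active lines, otherwise the support criterion is unsatisfiable and
configuration fails loudly.

The linkage window value is a package choice: physical distance is used
(not read-backed linkage), with 100 bp as the default radius within
which two same-line candidates are mutually suspicious; the motivating
observation is that closely spaced candidate pairs are where indel
annotation ambiguity concentrates.

## Contamination screening

Shared alternative-homozygote loci are counted per line pair over loci
where *every* line has DP > 5 and fewer than 30% of lines are
alt-homozygous (the latter removes background heterozygosity/ancestral
polymorphism from the comparison; the eligible-locus set is therefore
identical for all pairs and stored once). Outlier pairs are flagged at
median + k·max(1.4826·MAD, 1) over all pair counts (k = 5). The floor of
one count on the MAD scale matters: in a clean panel most pairs share
zero loci, MAD is 0, and a raw MAD rule would flag every pair with a
single shared locus. All-equal counts yield no flags. Flagging is a
screen, not a verdict — flagged lines are listed for manual exclusion
via the group configuration, mirroring how contaminated lines are
removed in practice.

## Rates and confidence intervals

A position is callable when strictly more than half of the group's
active lines have DP > 5 there; the rate denominator is
G × callable_length. Candidates outside the callable mask are excluded
from numerators and reported, keeping numerator and denominator
consistent (and the estimator exactly unbiased on synthetic data, which
the test suite verifies by comparing estimates to realized planted
rates). The group CI is 1.96·SD/√n across lines by default, with a ±SD
option; the output labels which was used, because published "±" values
in this literature are not always derivable from one convention.
Fold changes are max(mean)/min(mean), rounded half away from zero at the
requested precision.

## Spectra and consequences

SNVs collapse onto six classes keyed by the purine-strand substitution;
transitions are A:T>G:C and G:C>A:T. The AT bias is defined here as the
composition-normalized flux ratio
[(G:C>A:T + G:C>T:A)/n_GC] / [(A:T>G:C + A:T>C:G)/n_AT] — the rate per
G:C site of gaining A:T over the rate per A:T site of gaining G:C.
Published AT-bias columns in MA studies often omit their normalization;
this package's definition is stated so its values are interpretable, and
it is not claimed to reproduce any externally printed AT-bias value.
Triplet contexts are pyrimidine-centered (purine-centered triplets are
reverse-complemented); contig-edge SNVs go to an explicit edge bucket so
context marginals always reconcile with the 6-class spectrum.

Coding consequences are computed by codon translation on the
CDS-containing frame (strand- and phase-aware, spliced across CDS
segments). `coding` is true only for missense/synonymous/stop_gained
SNVs — the convention of consequence-string matching used by the
published analysis, under which coding *indels* (frameshift/inframe
terms) do not count as coding; indels overlapping a CDS instead carry
`genic=True` and an `in_cds` flag. Stop-loss is folded into missense.
When several genes overlap a site the most severe consequence wins;
genes whose CDS length is not a multiple of 3 are skipped for
consequence with a warning (the site stays genic).

## Statistics

Wilcoxon rank-sum: exact null distribution when the combined sample size
is ≤ 20 with no ties; otherwise normal approximation with tie and
continuity correction (the R `wilcox.test` convention). F-test:
F = var(x)/var(y), two-sided p = 2·min(CDF, SF). Fisher r×c tables use
a fixed-margin Monte-Carlo p-value (default n_mc = 100,000, seeded,
reported as (hits+1)/(n_mc+1)) rather than the network algorithm — for
6×2 spectrum tables and half-dozen length bins this is accurate to the
Monte-Carlo error and reproducible bit-for-bit; the 2×2 case is exact
(probability-mass two-sided criterion). P-values are reported raw by
default, matching common practice in MA studies; a Benjamini–Hochberg
helper exists for pairwise-comparison reports. Indel length tables
default to bins 1, 2, 3, 4, 5–9, 10+ when binned tests are requested.

## Error-rate harness

Planted mutations go only where no detected mutation lies within 200 bp,
pairwise ≥ 200 bp apart, away from contig ends, with deletion lengths
capped below the flank so edits can never interact. Edits are applied
right-to-left per contig, and an original↔edited coordinate liftover is
emitted (identity on round trip for every planted anchor; positions
inside deleted segments map to None).

Against an edited reference every sample is alternative-homozygous at a
planted site, so re-detection is per sample — alt-hom with DP ≥ 5 and
GQ > 20, the focal-call thresholds of the main filter — not the six
line-specific criteria (which require the variant to be unique to one
line and cannot apply when all lines differ from the reference).
Matching: SNVs by exact locus and base change; indels by same type
within [planted−5, planted] ("5 bp upstream"), nearest first, each
detected variant consumed at most once. "Covered" means the sample has
DP > 5 at the planted anchor, consistent with the callable rule; the FN
rate is (covered ∧ undetected)/covered per type per sample. The built-in
re-detection emulator can be replaced by any external caller through the
file interface (edited FASTA out, candidate TSV in).

## Problem sizes and numerical choices

Desk-scale defaults are a 1 Mb founder at 42% GC, 20 lines, 100
generations, and rates 100× the observed per-site per-generation values
(SNV 2.23×10⁻⁷, insertion 2.90×10⁻⁸, deletion 4.51×10⁻⁸), giving ~27
mutations per line — enough signal for every statistic while keeping a
full multi-seed recovery suite under a minute; the uninflated rates are
available by setting `mu_*` directly. The default spectrum has
transition mass 0.55 (ts/tv ≈ 1.2), shaped like observed nematode MA
spectra; the default indel length mean is 3 bp. Parameter-recovery
checks run 10 replicate experiments at μ_SNV = 1×10⁻⁷,
μ_ins = 2×10⁻⁸, μ_del = 3×10⁻⁸ with 30× coverage and no genotyping
noise, with planting spaced beyond the linkage window so criterion (vi)
cannot remove true mutations. At these sizes the pooled SNV count is
~2,000 (relative Poisson SE 2.2%) while pooled insertions are ~400
(SE 5%) — recovery bands tighter than these sampling SEs test the
Poisson draw, not the estimator, which is why the suite also asserts the
sharper property that estimates equal realized planted rates exactly.

All randomness flows through `numpy.random.default_rng` seeded from a
single integer plus a stage tag, so founder, accumulation, emulation and
annotation are independently reproducible; VCF output is byte-identical
under a fixed seed.

## Known limitations

- No read-level simulation: FASTQ/alignment artifacts, mapping bias and
  caller-specific error models are out of scope; the emulator's noise is
  genotype-level.
- The fixed-on-origin homozygosity model is a simplification; per-
  generation heterozygosity dynamics are not represented.
- Indels are assumed left-aligned by the upstream caller; the package
  does not re-normalize alleles.
- The contamination flag rule is a robust screen with an invented
  threshold, intended to shortlist pairs for manual review, not to
  adjudicate contamination.
- Consequence classification is codon-level only: no splice-site,
  UTR-subtype or frameshift annotation.
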