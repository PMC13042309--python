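# malines — mutation-accumulation line analysis

`malines` analyzes **mutation-accumulation (MA) experiments**: panels of
isogenic lines (e.g. selfing nematode lineages) propagated for ~100
generations through a single-individual bottleneck, then whole-genome
sequenced together. Because each generation passes through one selfing
hermaphrodite, new mutations fix essentially free of selection, and a
homozygous variant unique to one line can be read as a germline mutation
that arose during the experiment. The package is written for researchers
who have a multi-sample VCF (GT/DP/GQ per line), a reference FASTA and a
GFF3 annotation — or who want to validate such a pipeline end to end on
synthetic data before touching real sequencing.

## What it computes

**Detection.** A site yields a line-specific accumulated mutation iff
(i) exactly one homozygous genotype class is shared by more than one
line (the ancestral state); (ii) the alternative homozygote occurs in
exactly one line with DP ≥ 5; (iii) no other line is heterozygous for
any alt; (iv) ≥ 10 lines are reference-homozygous with DP > 5; (v) the
focal GQ > 20; (vi) no second candidate of the same line lies within the
linkage window (default 100 bp; both members of such a pair are
removed). Cross-contaminated line pairs are screened by counting shared
alternative-homozygote loci over well-covered sites and flagging robust
outliers.

**Rates.** The per-line rate for each mutation type is

    μ̂ = n / (G · L_callable),

where G is the generation count and L_callable the number of positions
at which more than half of the group's lines have DP > 5 — the same
depth rule as the detection criteria, so numerator and denominator refer
to the same genome. Group summaries report the mean rate ± 1.96·SEM
across lines (±SD optional), transition/transversion ratio,
composition-normalized AT bias, coding/noncoding and genic/intergenic
ratios, and indel length distributions.

**Statistics.** Wilcoxon rank-sum on per-line rates (exact for small
tie-free samples), two-sided F-test on rate variances, Fisher's exact
test on spectrum/length tables (exact 2×2; fixed-margin Monte Carlo for
r×c).

**Error rates.** False negatives are measured by planting random
SNVs/indels into the reference (≥ 200 bp from any detected mutation),
re-detecting against the edited reference, and scoring recall (SNVs must
match locus and allele; indels match same-type variants ≤ 5 bp
upstream). The false-positive rate is the fraction of
alternative-homozygote loci carried only by a sequenced ancestral line.

**Synthetic experiments.** `malines.simulate` generates a founder
genome, Poisson mutation accumulation per line (6-class SNV spectrum,
geometric indel lengths, optional cross-contamination), and a genotyping
emulator producing a multi-sample VCF plus a per-site depth track — so
every stage above is testable with known ground truth.

## Worked example

Simulate a 20-line, 100-generation experiment on a 1 Mb genome at
μ_SNV = 1×10⁻⁷, μ_ins = 2×10⁻⁸, μ_del = 3×10⁻⁸ per site per generation
(desk-scale rates), then detect and quantify:

```sh
ma-lines simulate --seed 7 --genome-length 1000000 \
    --mu-snv 1e-7 --mu-ins 2e-8 --mu-del 3e-8 --out sim
# -> simulated 296 mutations across 20 lines -> sim

ma-lines filter --vcf sim/calls.vcf --group-config groups.cfg --out candidates.tsv
# -> op50: 296 candidates

ma-lines rates --candidates candidates.tsv --depth-track sim/depth.npz \
    --group-config groups.cfg --group op50 --out rates.tsv
# -> callable 1000000 bp; mean SNV rate 1e-07 +/- 1.49e-08 (sem);
#    0 candidates outside mask

ma-lines spectra --candidates candidates.tsv --genome sim/founder.fa \
    --gff sim/genes.gff3 --out spectra
# -> ts/tv = 1.151
```

Under noiseless 30× coverage the filter recovers all 296 planted
mutations and nothing else, and the estimated group-mean SNV rate
(1×10⁻⁷, CI half-width 1.49×10⁻⁸ from between-line Poisson scatter)
reproduces the planted parameter. `groups.cfg` is a flat key-value file
mapping each sample to its group and each group to its generation count;
`candidates.tsv` lists each mutation's contig, position, line, type,
alleles and (optionally) coding consequence.

A full multi-group run — simulation, filtering, contamination
screening, rates, spectra and pairwise statistics in one report
directory — is `ma-lines report --config run.cfg --out report/`.

## Layout

- `src/malines/io.py` — FASTA/VCF/GFF3/TSV readers & writers, genotype matrix, group config
- `src/malines/simulate.py` — founder genome, accumulation model, genotyping emulator
- `src/malines/filtering.py` — detection criteria (i)–(vi), sharing matrix, contamination flags
- `src/malines/rates.py` — callable mask, per-line rates, group summaries, fold changes
- `src/malines/spectra.py` — 6-class spectrum, ts/tv, AT bias, triplet context, consequences, indel lengths
- `src/malines/stats.py` — Wilcoxon, variance F-test, Fisher exact / Monte Carlo
- `src/malines/errors.py` — planting plans, reference editing + liftover, FN/FP scoring
- `src/malines/pipeline.py`, `cli.py` — orchestration and the `ma-lines` command
- `docs/methods.md` — model assumptions, parameter choices, numerical details
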