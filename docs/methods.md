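# Methods

## The analysis in one paragraph

`poolfst` re-implements, as a tested pipeline, a pooled exon-enriched
population-genomics workflow for *Aedes aegypti*-style studies: replicate
pooled libraries are sequenced per collection site, per-site allele
coverages ("readcounts") are filtered for depth and replicate
concordance, every surviving SNP is annotated by its position within a
gene model, and genetic diversity within and between collections is
summarized by expected heterozygosity (H_exp), a per-SNP / per-gene F_ST
estimator, and distribution-level comparisons (0.01-bin histograms,
per-bin heterogeneity chi-square LOD profiles, 1% tails). Because raw
sequencing data are not shipped, a synthetic generator produces readcount
tables with known population structure, which makes every stage runnable
and lets parameter-recovery checks close the loop.

## Estimators

For SNP *s* compared between collections *i* and *j*, with p̂ the
frequency of the tracked (reference) allele computed from read coverage,
p̄ the pooled coverage-weighted frequency over both collections, and
n_i, n_j the numbers of mosquitoes pooled:

    α(i,s) = 2 p̂_i (1 − p̂_i)                          (= H_exp)
    b_s   = [n_i α(i,s) + n_j α(j,s)] / (n_i + n_j − 1)
    a_s   = [4 n_i (p̂_i − p̄)² + 4 n_j (p̂_j − p̄)² − b_s] / (2 [2 n_i n_j/(n_i+n_j)])
    F_ST(s) = a_s / (a_s + b_s)
    F_ST(g) = Σ a_s / Σ (a_s + b_s)     over the gene's m SNPs

Properties the implementation is validated against:

* fixed difference (p̂_i = 1, p̂_j = 0) gives b_s = 0 and F_ST = 1;
* identical intermediate frequencies give a_s < 0 and F_ST ≤ 0, which is
  why histograms start at −0.05;
* F_ST ≤ 1 always, and sites with a_s + b_s = 0 are undefined and
  excluded from gene sums;
* a gene's value is the ratio of sums, never the mean of per-SNP ratios;
* an independently written transcription of the same equations agrees to
  1e−12 on 1,000 random sites (dual-implementation oracle in the tests).

Bi-allelic reduction: p̂ is reference coverage over reference + alternate
coverage; the alternate allele is the most common pooled non-reference
allele (ties to the lexicographically smallest token); further alleles
contribute only to *nid*, the count of segregating nucleotides/indels.
n_i counts all mosquitoes whose reads enter the summed counts, i.e.
replicates × individuals-per-replicate once replicates are summed.

Per-SNP F_ST means stratified by gene region / mutation type /
consequence are computed over every site with any alternate coverage.
At high depth most such sites carry only one or two miscalled reads, so
stratified means sit much closer to zero than per-gene medians; this
mirrors what happens when a permissive caller's output is averaged
per-SNP and is not an artifact of the stratification.

## Filters

* **Trim**: a site needs ≥ 15 reads *in each library* (applied per
  replicate before summing). Sites above 2,000 reads are treated as
  putative repetitive DNA and excluded by default; proportional
  truncation to exactly 2,000 (largest-remainder rounding) is available
  as `cap_policy="truncate"` for users who prefer to keep them.
* **Replicate concordance**: for each site present in every replicate of
  a collection, the k×nid table of allele counts is tested with a plain
  Pearson heterogeneity chi-square, no continuity correction, on
  (k−1)(nid−1) degrees of freedom — nid−1 for the usual replicate pair.
  Sites with p < α are discarded; α defaults to 0.05 with no
  multiple-testing correction (the screen is per-SNP by design) and is
  configurable. Monomorphic sites (nid = 1) are trivially retained; a
  zero-coverage replicate discards the site; tables with any expected
  cell < 1 are retained with a logged flag rather than tested, since the
  chi-square approximation is meaningless there. Indel alleles are
  full-fledged allele tokens and contribute to nid.
* **Intersections**: a collection's SNP set is the intersection of its
  replicates with counts summed; a comparison's universe is the
  intersection of the two collections' sets.

Two code paths implement the same semantics — per-site `SiteCounts`
functions and a vectorized pandas path used on multi-million-site tables
— and the test suite asserts their agreement on random libraries. The
vectorized path can represent at most one insertion and one deletion
token per site; the per-site path has no such limit.

## Annotation

Gene models come from a GTF + FASTA pair. Introns are the gaps between
exons; UTRs are exonic sequence outside the CDS; the 5′NTR and 3′NTR are
fixed 600 bp non-transcribed windows flanking the transcript span,
strand-aware, truncated (and flagged) at contig edges rather than
dropped. Codon positions are computed on the coding strand from CDS
frames; coding consequences compare the translated reference and mutated
codons under the standard genetic code, with nonsense changes counted as
replacement (the classification is binary). Transcripts whose CDS length
is not a multiple of 3, or whose frames are inconsistent, keep region
calls but never receive consequence calls. Mutation types: purine↔purine
and pyrimidine↔pyrimidine changes are transitions, other base changes
transversions, and `+SEQ`/`-SEQ` tokens insertions/deletions.

SNPIDs order sites hierarchically: chromosome assignment (1, 2, 3,
unmapped — parsed from the supercontig naming convention
`sc0012_chr2`), supercontig order, gene position within the supercontig,
and offset within the gene window, encoded as
`(gene rank + 1)·10⁶ + offset`. A position inside no gene window is
untracked; a position inside two genes' windows is tracked once per gene
(duplicated records), matching the gene-centric coordinate scheme. Where
a gene has several transcripts, gene-level reports use the longest
complete-CDS transcript; per-transcript classification remains available
(`Annotator(..., canonical=False)`).

## Distribution comparisons

Per-gene statistics are binned at width 0.01 (F_ST from −0.05 to 1.0,
H_exp from 0 to 1.0), left-closed right-open, out-of-range values clamped
into the end bins with a warning so counts always conserve totals. For k
distributions, each bin yields a k×2 table (genes in the bin vs genes
elsewhere) tested with a Pearson chi-square on k−1 degrees of freedom;
LOD is defined as −log10(p), so the customary LOD = 3 cutoff corresponds
to p = 10⁻³ per bin. The per-bin k×2 construction (rather than one
omnibus k×B test) is what makes LOD a profile along the abscissa. Bins
empty in every distribution get LOD = 0 by convention; p-values are
floored at 1e−300 before the logarithm.

Tails take the extreme floor(1% · genes) of the ranked per-gene values,
ties at the cutoff broken by gene id; each collection's tail is taken on
its own gene set. Co-occurrence tallies count how many union genes
appear in exactly 1, 2, …, k tails, with "percent unique" the
whole-percent share appearing in exactly one. Summary tables report
mean, SD (ddof = 1), median, the modal 0.01-bin midpoint (a continuous
statistic has no exact mode), and 5%/95% quantiles by linear
interpolation (nearest-rank by flag).

Gene-wise comparisons of two collections' per-gene values report counts
of genes where one exceeds the other, the whole-percent share, the mean
difference, and a two-sided paired t-test on shared-genes − 1 degrees of
freedom; identical vectors report t = 0, p = 1.

## The synthetic generator

The generator emulates the twelve-library design: four collection sites,
two with dual replicate pools per sex (12 mosquitoes each), two with
dual mixed-sex pools (14 and 22 mosquitoes). Its statistical model:

* **Reference**: `n_genes` transcripts (default 24 in the package;
  analysis drivers use up to 600) laid out on supercontigs of four genes
  each, assigned cyclically to chromosomes 1/2/3/unmapped, strands
  alternating. Each transcript has 60 bp UTRs and either one CDS or two
  CDS exons split by a 90 bp intron, with CDS length a multiple of 3.
  Capture targets (BED) cover CDS only, mirroring an exon-capture
  design, though simulated coverage spans whole gene windows so that
  NTR/intron strata are populated.
* **Frequencies**: a site segregates with probability
  `polymorphic_fraction` (default 0.05 — of the order of the observed
  polymorphic fractions once low-frequency error alleles are counted);
  its ancestral alternate frequency is uniform on `ancestral_maf_range`
  (default 0.05–0.5). Each *population* draws a Balding–Nichols
  frequency Beta(p(1−θ)/θ, (1−p)(1−θ)/θ), reducing to p at θ = 0; the
  Beta's mean is p and variance θ·p(1−p), so θ is the expected F_ST and
  gives the recovery checks a known target. Collections sharing a
  `population` (female/male pools of one site) share that draw, with an
  optional second per-chromosome Balding–Nichols split between them
  (`sex_theta_by_chromosome`) used to plant chromosome-specific
  between-sex divergence.
* **Pools and reads**: the pool allele count is one binomial draw of
  2 × (all mosquitoes in the collection) chromosomes — replicates are
  technical samples of the same pool, so the concordance screen is
  calibrated (pass rate ≈ 1 − α, verified). Read depth per site is
  negative-binomial (mean `coverage_mean`, size `coverage_dispersion`;
  variance μ + μ²/k) rather than Poisson so the coverage cap is
  exercised realistically; a `repeat_fraction` of sites get a 10–100×
  depth multiplier shared across libraries, emulating repetitive DNA.
  Nucleotide reads miscall with probability `error_rate` uniformly onto
  the other three bases; indel reads do not miscall. A fraction
  `indel_rate` of segregating sites carry an indel alternate allele.
* **Determinism**: one integer seed; `SeedSequence(seed)` is split into
  three child streams (reference, frequencies, readcounts), and the
  readcount stream serves libraries in declared order, so all output
  files are byte-identical across reruns.

What the generator does **not** model — and hence what passing tests do
not demonstrate about real data: linkage disequilibrium (sites are
independent), capture bias and off-target decay, unequal DNA
contributions of individual mosquitoes to a pool, mapping artifacts, and
base-quality structure (readcounts are assumed already quality-filtered).

## Calibration experiments and problem sizes

`experiments.theta_recovery_study` simulates two populations (24
mosquitoes per collection pool, 100× coverage, error rate 0.001) at
θ ∈ {0.05, 0.1, 0.2, 0.4} with 60 genes of 300 bp, writes the readcount
files, and runs the full pipeline on them. The genome-wide median
per-gene F_ST is monotone in θ and lands within ±0.05 of θ at θ = 0.2
(observed ≈ 0.20). `experiments.sex_divergence_study` plants θ = 0.3
between sexed pools on chromosome 1 only (600 genes of 150 bp over
chromosomes 1–3) and reproduces the qualitative signature: the
chromosome-1 between-sex F_ST distribution shifts right with per-bin
LOD ≫ 3 in the three-chromosome heterogeneity test, while the
chromosome-2-vs-3 comparison stays below 3. These problem sizes are the
package's default experiment scale; they are deliberately modest so that
the whole suite runs on a laptop in minutes, and all counts scale with
the configuration.

## Numerical and policy choices that were genuinely open

* **Cap policy**: the 2,000-read cap exists to avoid repetitive DNA, so
  the default excludes capped sites outright; literal truncation is a
  flag.
* **Concordance α**: 0.05, per-SNP, uncorrected, configurable.
* **Gene H_exp universe**: gene means average over *all* retained sites
  (monomorphic included, contributing 0), which produces the
  near-zero-shifted gene H_exp distributions typical of mostly
  monomorphic exomes; polymorphic-only averaging is a flag
  (`gene_hexp(..., polymorphic_only=True)`).
* **nid for the concordance test** pools nucleotides and indels; testing
  nucleotides only would also be defensible but is not the default.
* **Multi-transcript genes** are reported per canonical transcript by
  default; per-transcript reporting is retained because the right
  granularity depends on the downstream question.
* **LOD definition**: −log10 of the per-bin heterogeneity p-value; the
  term is used loosely in this literature and this definition makes the
  LOD = 3 cutoff a p = 10⁻³ screen.
* **Tie-breaks**: alternate-allele ties go to the lexicographically
  smallest token; tail ties at the cutoff go to the smaller gene id.

## Known limitations

The estimator corrects for sampling mosquitoes into pools but not for
the read-sampling layer on top; at depths well above 2N this extra
variance is small (the recovery study shows ≈ +0.001–0.005 at θ = 0.2)
but it biases F_ST upward at low coverage. Per-SNP stratified means are
sensitive to the error rate, as noted above. The synthetic annotation
exercises the common gene shapes (both strands, single- and two-exon
CDS, edge-truncated NTRs) but not exotic ones (trans-splicing,
frame-shifted isoform nests). The vectorized path collapses multiple
insertion tokens at one site into one column.
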