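# Methods

## Scope and model

`rrbsdiff` implements a reduced-representation bisulfite sequencing (RRBS)
differential-methylation workflow for a three-condition design: a parental
drug-sensitive line (S), its resistant derivative (R), and the resistant
line after a demethylating treatment (RC), with two biological replicates
each. The analysis proceeds in fixed stages:

1. **Coverage filtering.** Per-sample call tables are filtered at a
   minimum read coverage (default 10 for testing, 3 for descriptive
   statistics; both thresholds are inclusive). An optional high-coverage
   percentile cut guards against PCR duplicates.
2. **Uniting.** CpGs covered at or above the cutoff in *every* sample form
   the tested universe. By default the two strands of a CpG (forward call
   at p, reverse call at p+1) are pooled before filtering, since CpG
   methylation is symmetric; destranding can be disabled.
3. **Per-unit differential testing.** Units are single CpGs or fixed
   genome-aligned tiles of width 200 bp (1000 bp supported for
   visualisation-scale tracks). The methylation difference is
   100 x (pooled test proportion − pooled reference proportion).
   The default test is the likelihood-ratio test of a binomial logistic
   regression on the group indicator. With one binary covariate the MLE
   fitted probabilities are the group-pooled proportions, so the LRT
   statistic reduces to a closed form (a G-test on the pooled 2x2 table),
   which we compute vectorised and refer to chi-square(1); equality with
   per-unit GLM fits is asserted in the test suite. Complete separation (a
   group pooled at exactly 0% or 100%) falls back to the two-sided Fisher
   exact test, and `method=fisher` makes Fisher the primary test.
   Multiple testing is controlled by Benjamini–Hochberg over all tested
   units of a comparison. Significance cutoffs: q < 0.01 with
   |diff| >= 25 percentage points for CpGs (inclusive) and |diff| > 25
   (strict) for tiles — the two rules are deliberately different.
4. **DMR construction.** Significant CpGs (DMCs) are binned onto the
   200-bp genome grid; each occupied window records its DMC count and the
   unweighted mean of DMC differences. This table is united with the
   significant 200-bp tiles; where a window has both, the region
   difference is the average of the two analyses, else the single value.
   Windows where the two analyses disagree in sign are flagged discordant
   and excluded from significance (averaging opposite signs would
   manufacture a small meaningless difference). A window is a significant
   DMR when |averaged difference| >= 25 and it holds more than 3 DMCs
   (i.e. >= 4). Tile-only windows remain rows of the table but can never
   pass, lacking DMCs.
5. **Reversion classification.** Windows significant in both comparisons
   with opposite signs are `reverted_hyper` (hypermethylated R vs S,
   demethylated RC vs R) or `reverted_hypo` (mirror); one-sided windows
   are `resistance_only` / `treatment_only`; same-sign windows are
   `concordant`. The labels partition the window universe.
6. **Summaries.** Hypo/hyper fractions of significant DMRs; the fraction
   of treatment-demethylated windows that were resistance-hypermethylated
   (the "reversion overlap"); per-chromosome percentages of demethylated
   DMCs against tested CpGs, each with the pooled percentage of all other
   chromosomes; and hotspot loci obtained by chaining same-direction
   significant windows with gaps <= 1 kb.
7. **Annotation.** Feature labels use whole-DMR overlap with precedence
   promoter > exon > intron > intergenic, where a promoter is the
   strand-agnostic ±1000 bp window around the TSS (clipped at the
   chromosome start). CpG-island labels use the DMR midpoint with
   precedence island > shore > open sea; shores default to 2 kb flanks
   (community convention — configurable). Midpoint assignment avoids
   double-labelling 200-bp windows that straddle island edges. Any >= 1 bp
   overlap with a candidate cis-regulatory element (cCRE) sets the cCRE
   flag; the element class from BED column 4 is carried along. Gene-class
   breakdowns count each gene once however many DMRs hit it.

## Coordinate conventions

Call tables are 1-based (both supported dialects are); all interval work
is 0-based half-open. Conversion happens only in `rrbsdiff.io`. Windows
are genome-aligned, `[k*200, (k+1)*200)`, step = width (no sliding):
region boundaries that fall on the 200 grid follow from this choice.

## Synthetic data generator

The generator exists so that every stage is exercisable without any
external download. It emulates:

* **Genome geometry** — three autosome-like chromosomes (700, 700,
  650 kb) of CpG-depleted background (85% of background CpG dinucleotides
  removed) with 30 CpG islands each (1.0–1.8 kb, GC-rich, CpG
  observed/expected near 1), and one 250-kb chromosome that is a tandem
  array of a single 2-kb CpG-dense repeat unit — the stand-in for an
  rDNA-like repeat array confined to one chromosome. The total (~2.3 Mb)
  keeps a full run interactive while leaving >10k assayable CpGs.
* **RRBS enrichment** — in-silico MspI digestion (cut C^CGG) with 40–220
  bp size selection (typical RRBS; configurable). Only CpGs inside
  retained fragments appear in call tables, so background CpGs are
  sparsely assayed and islands densely — as in a real library.
* **Methylation landscape** — background CpG means from a bimodal
  mixture (35% Beta(1,19), low mode near 0.05; 50% Beta(18,2), high mode
  near 0.9; 15% uniform mid-range), giving the bimodal per-sample
  profiles characteristic of RRBS.
* **Planted truth** — grid-aligned regions per class with per-condition
  means: reversion (0.2, 0.8, 0.3) for (S, R, RC), resistance-only
  (0.2, 0.8, 0.8), treatment-only (0.7, 0.7, 0.2) or (0.3, 0.3, 0.8).
  The reversion means give planted differences of about +60/−50 points,
  the scale of the published worked examples. Defaults plant 16
  reversion, 9+6 treatment-only and 10 resistance-only 600-bp regions on
  autosomal islands, plus the whole repeat array as one reversion region,
  so treatment demethylation concentrates there and the chromosome-level
  contrast has the shape reported for repeat-array loci.
* **Counts** — coverage per strand cytosine is negative binomial
  (mean 23, size 20 — mild overdispersion; the 21–25x range is the
  reported scale for this assay), methylated counts are beta-binomial
  with overdispersion rho = 0.02 shared by replicates (rho = 0 gives pure
  binomial for calibration work). Bisulfite conversion is assumed
  perfect; a conversion-error parameter is a noted extension point.

One integer seed fixes genome, truth and all six tables; datasets are
written with per-file SHA-256 checksums in a manifest.

**What the generator does not emulate:** read-level artefacts (sequencing
error, mapping bias, incomplete conversion), chromosome-scale methylation
gradients, copy-number effects on the array, or biological covariates.
Passing recovery tests therefore demonstrates correctness of the
statistical chain under the stated count model, not performance on real
libraries.

## Evaluation choices

A planted reversion window counts as *recoverable ground truth* only if
it lies fully inside a planted region and contains at least four CpGs of
the size-selected universe: with fewer assayable CpGs the >= 4-DMC rule
is unsatisfiable for any method, so including such windows would measure
the assay's footprint rather than the pipeline. Sensitivity and false
discovery proportion are computed against this set.

The chromosome-distribution denominator is the number of *tested* CpGs
per chromosome (all units that entered the differential test). Covered
CpGs or called DMCs are alternative denominators; tested CpGs is the
choice exposed as the default because it is the universe on which the
calls were made.

The 83%-hypomethylated / 64%-overlap summary statistics are exercised by
a dedicated no-array scenario planting 64 reversion, 36 treatment-hypo
and 21 treatment-hyper regions (planted proportions 100/121 = 82.6%
demethylated, 64/100 overlap); the default dataset instead concentrates
reversion on the repeat array, which drives both fractions near 1 there
by construction.

## Numerical notes

* Binomial log-likelihoods use the 0·log 0 = 0 convention; LRT statistics
  are clipped at 0 before the chi-square tail.
* The methylated-read count is recovered from percentage columns by
  round-half-up; a freqC+freqT sum check with 0.5 tolerance rejects
  corrupt files. Written tables carry 6-decimal percentages, which makes
  write-then-read bit-exact for counts and coordinates.
* Pearson correlations are computed on per-site methylation percentages;
  zero-variance samples yield flagged NaN entries rather than silent
  propagation.
* BH q-values are monotone in p-rank by construction
  (statsmodels `multipletests`).
* Problem sizes used by the test suite and the acceptance script: the
  default ~2.3 Mb genome (about 10.7k assayable CpGs), 10 null runs of
  20,000 CpGs, and 200 random 2x2 tables for the Fisher oracle — sizes
  chosen so a complete run stays interactive on one CPU.

## Known limitations

* No overdispersion correction in the test itself (the logistic LRT is a
  pure binomial model); beta-binomial regression and covariates are out
  of scope.
* The q-value procedure is Benjamini–Hochberg, a deliberate, documented
  substitution for less reproducible default procedures in comparable
  toolchains.
* Annotation facets are assignment rules, not enrichment statistics.
* The CLI stages re-read the previous stage's TSVs; extremely large
  genomes would want a binary interchange format.
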