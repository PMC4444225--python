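# Methods

## The problem

`wgsinterp` models the use of whole-genome sequencing (WGS) in a cancer
genetics clinic: given per-sample variant call tables for two patient
cohorts — carriers of a known pathogenic mutation in *BRCA1/2* (the
"control" population for background carrier rates) and patients without
one (the "test" population) — decide which genes can be interpreted
clinically from WGS alone, report per-patient burdens of potentially
pathogenic variants, and confirm previously diagnosed mutations.

## Variant quality calibration

Platforms that report two per-allele variant quality scores are
calibrated by sequencing the same individual twice (e.g. lymphoblast and
fibroblast DNA) and measuring genotype concordance across a sweep of
quality thresholds. A site of the swept class enters the passing
universe at threshold *t* when every replicate that calls it does so
with all relevant allele qualities ≥ *t*; concordance is the fraction of
the universe with identical genotypes, and the excluded fraction is
measured against all called sites of the class. An empty universe
reports concordance as absent, never as 0.

Working defaults: SNVs are retained only when **both** allele qualities
are ≥ 100 (hemizygous calls are judged on their single quality); indels
(insertions, deletions, block substitutions) only when qualities are
strictly **above** 150, reflecting their systematically lower calling
quality. The phrase "excluded when below the bound for both alleles" is
ambiguous between a strict and a lenient reading; we implement the
strict one (retain only if all relevant qualities pass) as the default
and expose `QcConfig(strict_both_alleles=False)` for the lenient
alternative. Averaged sweeps are means over replicate pairs, not pooled
sites; with seven pairs the two conventions differ only in weighting
when pairs have unequal site counts.

## PPV and LoF classification

A *potentially pathogenic variant* (PPV) is a quality-passing
nonsynonymous variant with allele frequency **strictly below 1%** in
both reference panels (an ESP6500-like exome panel and a HapMap-like
panel from the same platform), in a panel gene. A frequency absent from
a panel passes that panel's check — this is what makes "novel"
meaningful, so absent frequencies are preserved as absent, never coerced
to zero. Loss-of-function (LoF) classes: nonsense, canonical-splice-
disrupting, misstart and nonstop SNVs, plus frameshift indels; in-frame
indels are never LoF. Three nested analysis modes — all nonsynonymous
PPVs, LoF only, LoF SNVs only — trade sensitivity for specificity.
In-silico deleteriousness scores are carried through and summarized per
consequence class but never used for classification.

Clinical-mutation confirmation uses exact (gene, chrom, pos, ref, alt)
identity — no fuzzy windows, so the check is deterministic and testable.
Copy-number and intronic (IVS) diagnoses are outside WGS small-variant
calling and are excluded from the detection-rate denominator; a matching
call that fails the quality filter counts as a low-quality recovery.

## Gene variance and interpretability

For each panel gene and cohort we compute the **carrier fraction**
(individuals with ≥ 1 PPV in the gene) and the **carrier burden** (mean
PPV count per individual); the former defines interpretability, the
latter is the plotted quantity, and both are reported. Because PPVs sit
below 1% allele frequency, heterozygous carriers of any single variant
should appear in < 2% of individuals; a gene whose control-cohort
carrier fraction is strictly below 2% is *clinically interpretable*
(exactly 2% is not). Genes with no PPVs in either cohort are
interpretable. Panel-percentage summaries exclude, by default, the genes
that define the control cohort (*BRCA1/2*, whose carrier fraction is
100% by construction); recurrent platform artifacts (e.g. a frameshift
artifact in *GEN1*) are excluded via the panel's exclusion list, which
removes them from selection while keeping them in composition counts.
Narrowing the PPV definition can only shrink carrier sets, so
percent-interpretable is provably non-decreasing across the mode chain —
the package's acceptance property standing in for the cohort-scale
percentages.

A variant annotated to two overlapping genes counts once per gene, so
per-gene counts sum to at least the total PPV count; within one gene and
sample, duplicate reports of the same site collapse to one PPV.

## Exact statistics

Proportion CIs are exact Clopper–Pearson intervals (inversion of
binomial tail sums via `scipy.stats.binomtest(...).proportion_ci`),
reproducing the worked example 17/82 → 20.7% [12.6–31.1%]; this
reproduction is what validates the Clopper–Pearson reading of "CI from
the binomial probability". Fisher's exact test uses the two-sided
probability-mass convention (sum of same-margin tables with probability
≤ the observed table's). Both are cross-checked in the test suite
against independent oracles: full hypergeometric enumeration from
binomial coefficients (every table with all margins ≤ 30) and tail-sum
bisection to 1e-10 (every (k, n) with n ≤ 30). Report percentages are
rounded half-up to one decimal.

## The synthetic generator

`synthetic_data` emulates the data structure the analysis assumes, not
sequencing itself (no reads, no phasing):

* **Panel**: log-normal coding lengths (log-mean 7.5 ≈ 1.8 kb median,
  log-sd 0.8 — the spread of clinical panel genes).
* **Background**: per individual and gene, `Poisson(mu * L_g)` rare
  missense SNVs; default `mu = 2.2e-5`/bp gives ≈ 7 panel PPVs per
  individual on a 163-gene panel, matching the clinic-scale burden.
* **Frequencies**: a variant is novel (absent from both panels) with
  probability 0.4633; otherwise both panel frequencies are rare (< 1%)
  with probability 0.9, else common — so most non-novel simulated
  variants pass the rare filter by construction.
* **Planting**: each planted LoF variant is carried heterozygously by
  exactly `floor(pi * n)` randomly chosen samples of its cohort at a
  fixed in-gene site (a warning is raised when `pi * n < 1`).
* **Cohorts**: defaults of 176 control and 82 test samples, the study
  sizes the pipeline targets.
* **Replicates**: each of the pair's calls draws a quality from
  `floor(Beta(8, 2) * 300)` and flips its genotype (het ↔ hom)
  independently with probability `eps(q) = 0.4 / (1 + exp((q-100)/25))`
  — logistic, strictly decreasing; only monotonicity is contractually
  required, and a constant-`eps` override exists for closed-form checks
  (expected concordance `(1-eps)^2 + eps^2`).

What the generator does **not** emulate: linkage and recurrence
structure of real variants, population stratification of allele
frequencies, error modes that drop calls entirely rather than flipping
genotypes, CNVs and intronic variants. Passing tests therefore
demonstrate the correctness of the filtering, counting and statistical
machinery under the stated model, not calling accuracy on real genomes.

## Worked-example fixtures

The packaged fixtures encode the published study tables: the 163-gene
clinical panel (135 dominant, 24 recessive, 4 X-linked; cancer-associated
flags), the published LoF PPV findings in both cohorts (six carrier-cohort
patients in four panel genes; 17 distinct non-BRCA patients, 13 of them in
cancer-associated genes of the 163 panel), and the per-sample
confirmation accounting (75 and 88 expected-detectable diagnoses, 8 and
10 low-quality recoveries, 16 of 18 of them indels). Genomic coordinates
and coding lengths are not published at this granularity; the builders
assign deterministic **synthetic** coordinates (one megabase block per
gene) and synthetic log-normal lengths, and no computed quantity depends
on them.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at desk scale,
chosen to make each property decisive at comfortable margins: 100
simulations of a 25-gene, 90-sample cohort for carrier-fraction
recovery; 200 genes × 100 samples for the size-correlation property
(`r² > 0.5`); 10–20 replicate pairs of 1200–1500 sites for concordance
monotonicity with a Monte-Carlo slack of 0.003; oracle enumeration caps
of 30 on margins. Ties in the Fisher enumeration are accepted at a
relative tolerance of 1e-10; VCF float fields are single-precision, so
frequencies round-trip through the vcf dialect at six significant
digits (the tsv dialect round-trips exactly).

## Known limitations

No transcript-model annotation (consequences are consumed, not
computed), no CNV/IVS handling, no compound-heterozygote logic for
recessive genes (carrier status only, as reported), no per-gene
statistical test, and no penetrance modeling. The comparison of WGS
against published panel-testing rates is expressible through
`fisher_exact`, but the comparator study's raw counts are not published,
so no packaged example reproduces that p-value.
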