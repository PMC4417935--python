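# Methods

`embryoqtl` analyses gene expression in embryos from a two-strain mouse cross
design: reciprocal F1 hybrids of C57BL/6 (B6) and Cast/Ei (Cast), and N2
embryos from backcrossing (B6xCast) F1 mice to B6 in both directions.  Four
genetic mechanisms are read out from 3'-biased RNA-seq of whole embryos:
cis-regulatory variation (allele-specific expression and cis-eQTL),
trans-regulation (trans-eQTL and hotspots), genomic imprinting, and maternal
genetic effects.  A synthetic-data generator reproduces the statistical
structure of this design so that every stage can be verified against known
ground truth at desk scale.

## Read-level preprocessing

**Poly(A) trimming.** 3'-biased reads frequently run into the mRNA poly(A)
tail.  For every candidate trim position `i` (number of bases kept, `0..len`)
a score `s_i` is computed: the sum of base qualities of A's after position
`i` minus three times the sum of qualities of non-A's after position `i`
(`s_len = 0`; N counts as non-A).  All bases after the argmax are removed iff
at least 3 bases would be trimmed.  Ties in the argmax are broken toward
keeping more bases — the conservative choice where the score cannot
distinguish trim points.  The trimmer is idempotent and is tested against an
independent per-position enumeration oracle.

**Repeat filter.** Reads are aligned by an external aligner against both
parental genomes plus spliced transcriptomes (alignment itself is outside
this package); the filter operates on the resulting candidate records.  A
read is discarded when the edit-distance gap between its best and second-best
alignment at *distinct* genomic positions is within 3 (1 per mismatch, 2 per
indel), or when equally-best alignments map to more than one genomic
position.  Candidates whose transcriptome hits project to the same genomic
locus (same reference, position, strand, splice structure) are consolidated
into one record first, so a genomic hit and its own splice-junction
projection never count as ambiguity.

## Allele votes and expression

Allele-specific expression is quantified only at high-quality
strain-distinguishing SNPs at least 50 bp from any annotated Cast indel.  A
read covering n usable SNPs contributes 1/n vote per SNP to its gene's B6 /
Cast / "other" totals, so each read carries total vote mass 1; this damps
the effect of sequencing errors at single SNP positions.  The B6 allele
fraction (BAF) of a gene is B6 votes / (B6 + Cast votes); "other" votes are
excluded from the denominator.

Total expression is exon-overlapping read counts normalised to reads per
million mapped (RPM).  Genes enter the analyses when mean RPM >= 5, at most
5% of their reads were removed by the repeat filter, they are not on a
retrogene exclusion list, and they are autosomal.  Embryo sex is called by
1-D 2-means on Xist RPM (females express Xist robustly; males not at all);
when the split explains less than half the variance the distribution is
considered unimodal and sex is left unknown.

## Genotyping

N2 embryos are B6/B6 or B6/Cast at every autosomal locus, in blocks
delimited by the crossovers of the F1 gamete.  Genes with >= 20 SNP-covering
reads get a preliminary call from their B6 vote fraction: homozygous at
>= 0.9, heterozygous below (the backcross has no Cast/Cast class, so a single
boundary suffices; at 100 votes it separates Binomial(100, 0.5) from
Binomial(100, 0.998) with error below 1e-6).  Genes below 20 reads are
"unknown".

Per embryo and chromosome, preliminary calls are smoothed with a two-state
Viterbi HMM: known calls emit the observed state with probability 1 - eps
(default eps = 0.02, matching the homozygous vote error rate), unknowns emit
uniformly, and the chain switches state with probability t = 1e-4 per gene
step.  Genetic distance between adjacent genes is not modelled.  These two
parameters are exposed in configuration; t was chosen so that expected false
breakpoints per chromosome stay well below 0.01 at realistic coverage.  The
Viterbi implementation is verified against exhaustive path enumeration on
thousands of seeded toy chromosomes.  After smoothing, low-coverage genes
lying between the two confident calls that flank an inferred breakpoint are
reset to unknown: the HMM cannot place them on either side reliably.

Adjacent genes whose genotype vectors agree across all embryos (unknowns are
wildcards) are merged left-to-right into marker regions, the unit of eQTL
testing; a relaxed mode tolerates up to a configurable number of
disagreements with the running consensus.  The consensus call per (region,
embryo) is the majority of known calls, set to unknown when homozygous and
heterozygous counts are within 1 of each other — except for a unanimous
single call, which is kept.

## ASE, imprinting, developmental trends

**ASE.** For each gene, per heterozygous embryo (F1 and N2 pooled),
d = (Cast votes - B6 votes) / library size x 1e6; a one-sample t-test of d
against 0, Bonferroni-corrected over tested genes (>= 3 informative embryos).
Library normalisation is what makes deep F1 libraries and shallow N2
libraries commensurable.  A significant gene additionally needs mean BAF
outside [0.45, 0.55]; tiny but consistent imbalances are not called.  On
null simulations the t-test p-values are uniform and agree with a sign-flip
permutation reference without being anticonservative.

**Imprinting.** Votes are pooled within each reciprocal-cross direction.
Each direction's pooled B6 count is tested against the gene's cross-pooled
B6 fraction with a two-sided binomial test (exact below 1000 informative
votes, normal approximation with continuity correction above).  Using the
cross-pooled fraction as the null absorbs cis effects: a biallelic gene with
BAF 0.3 in both crosses shows no deviation.  The reported p is the larger of
the two per-direction p-values and significance additionally requires the
two crosses to deviate in opposite allele directions — the defining
signature of parent-of-origin expression.  This construction is a
reconstruction choice: pooled-count binomial tests per direction, combined
conservatively via the maximum.

**Developmental trends.** Spearman correlation of per-embryo BAF (or total
RPM) with somite count, Benjamini-Hochberg q-values; allelic trends are
called at q < 0.10 (>= 10 heterozygous embryos spanning >= 5 distinct somite
counts), total-expression trends at q < 0.05.

## Maternal effects

Two-sided Mann-Whitney U on RPM between N2 embryos with B6/B6 mothers and
those with B6/Cast F1 mothers, Bonferroni-corrected over tested genes
(>= 5 embryos per class).  Sidedness is a package choice; the Bonferroni
denominator is the number of genes actually tested.  The design excludes the
mitochondrial confound structurally — all F1 dams descend from B6 females,
so every N2 embryo carries B6 mitochondria — and this is enforced as a
metadata validation rule, not a statistical test.

Significant genes pass a confound battery: (a) the test repeated on female
embryos only; (b) litters as the unit of analysis (litter-mean expression);
(c) effect direction consistent across somite tertiles; (d) maternal class
must predict the gene better (smaller Mann-Whitney p) than embryonic
genotype at every imprinted locus, otherwise the signal is better explained
as a trans effect downstream of an imprinted gene.  "Better predictor" is
operationalised as the p-value comparison in (d); tertiles in (c) are a
package choice for "consistent across developmental stage".

## eQTL mapping

Expression is log(RPM+1) residualised against sex, sequencing batch and
somite count (missing somite counts mean-imputed), then against the top k=5
principal factors of the residual matrix.  This linear factor normalisation
absorbs unknown batch structure; genotype signal, which is not a dominant
global expression factor in a backcross, survives it.  Each gene is tested
against every marker region with a two-sided Wilcoxon rank-sum comparing
heterozygous vs homozygous embryos (>= 5 per class; unknown-genotype embryos
excluded per marker).  The scan is computed vectorised with the normal
approximation, tie correction and continuity correction, and is tested
against scipy's Mann-Whitney on random instances.

Downstream analyses keep the most significant marker per chromosome per
gene.  False discovery rates come from global embryo-label permutations of
the genotype matrix (default 20), which preserve inter-gene expression
correlation; q(p) = mean permuted count of results at or below p divided by
the observed count, monotonised to be non-decreasing in p.  An eQTL is cis
iff its marker region is on the target gene's chromosome — the conservative
chromosome-identity definition; no distance window is offered by default.

**Hotspots.** Per marker region, the number of target genes with scan
p < 0.005 is compared between the observed scan and pooled permuted scans
with a two-sample KS test.  Two p-values are reported: the asymptotic KS p
(comparable to published analyses) and a calibrated p that ranks the
observed KS statistic among leave-one-out statistics of the permuted scans.
The calibrated p exists because per-marker counts are strongly correlated
along chromosomes, which violates the KS independence assumption and makes
the asymptotic p anticonservative even under the null; the calibrated
version is exchangeable by construction (its resolution is limited to
1/(permutations+1)).

**ASE concordance.** With mu_g the mean expression of embryos with genotype
g, BAF_exp = mu_hom / (mu_hom + mu_het) and BAF_pred =
BAF_exp / (2 (1 - BAF_exp)) — the plug-in inversion of the two-genotype
mean model.  BAF_exp = 1/2 predicts balanced expression; BAF_exp = 2/3 is
the Cast-silent limit (BAF_pred = 1); noise in the means can push BAF_pred
above 1, in which case it is reported as-is (or NA at the BAF_exp = 1
pole).  Predicted BAF is rank-correlated with vote-measured BAF overall and
for the 1000 genes with the highest allele-informative coverage.

**Conservation.** Externally supplied per-gene constraint scores (e.g. GERP
coding-sequence averages) are Spearman-correlated with effect size
(-log10 eQTL p or |BAF - 0.5|) after removing lowly expressed genes, whose
scores are systematically low.

## Synthetic data generator

The generator emulates the study design: 8 + 8 reciprocal F1 embryos and
65 + 89 reciprocal N2 embryos by default, 19 autosomes.

- **Crossovers**: per F1 gamete and chromosome, Poisson(0.5 Morgans)
  crossovers placed uniformly, no interference.  0.5 M per chromosome is the
  *observable* map length implied by roughly a thousand detectable marker
  regions among ~150 embryos, below the full mouse genetic map because
  breakpoints between detectable markers are what the analysis sees.
- **Counts**: negative binomial (gamma-Poisson) around library_size x
  baseline RPM x effect multipliers; dispersion 0.05 (count CV ~22%), the
  low end of bulk RNA-seq dispersion appropriate for isogenic littermate
  embryos where biological variability is modest and counting noise
  dominates at 3'-tag depth.  Dispersion 0 degenerates to Poisson.
- **Effects**: cis allelic fold changes scale the Cast allele of
  heterozygotes; maternal folds multiply expression under B6 mothers;
  imprinting silences the allele of the configured parental origin down to a
  residual fraction (homozygotes silence one of their two B6 copies);
  somite trends are log-linear in somite count; an optional hotspot locus
  multiplies trans targets in heterozygous carriers.
- **Allele votes**: SNP-covering reads are Binomial(counts, 0.3) by default
  (3'-tag reads concentrated in SNP-dense 3' UTRs); votes are multinomial
  with a 0.002 "other" error rate, B6 probability equal to the gene's true
  allelic ratio in heterozygotes and 0.998 in homozygotes — so the
  genotyper faces realistically mislabeled votes.
- **Structure**: litters of ~6 embryos per cross direction; multiplexed
  sequencing lanes of 12 with *randomised* membership (pooled barcoded
  libraries are not confounded with cross direction); lane effects are
  multiplicative log-normal per (lane, gene), sd 0.1; F1 libraries are 13x
  deeper than N2 (matching the reported mean depths); somite counts uniform
  on 42–57.

What the generator does **not** emulate: reference-mapping bias (reads are
never aligned), SNP-density variation across genes, transcript-level
structure (single-exon genes), sex chromosomes and mitochondria (the
analyses are autosome-restricted), and litter-correlated biological noise
beyond what the maternal/litter structure induces.  Passing recovery tests
therefore demonstrates correctness of the statistics under the stated noise
model, not robustness to alignment artefacts.

## Numerical choices and degenerate inputs

- Viterbi ties (equal path scores) resolve toward no transition; breakpoint
  placement between two genes is recorded by flanking gene ids.
- A chromosome with no confident call for an embryo is all-unknown rather
  than an arbitrary path.
- BAF is undefined (NA) below 1 informative vote; per-analysis minimum
  embryo counts: 3 (ASE), 10 (developmental ASE), 5 per class (Mann-Whitney
  and rank-sum tests).
- The rank-sum scan returns NaN for markers whose genotype classes are too
  small after unknown exclusion; such markers never enter best-marker
  selection.
- Percentages in reports round half-up at the printed precision.

## Problem sizes used by the test suite

The acceptance-style checks run at the full embryo design (154 N2 + 16 F1)
with ~2000 genes over 19 autosomes for calibration/recovery suites, 1000
genes over 10 autosomes for hotspot and concordance studies, and 20
replicates for null-calibration and null-uniformity checks; these sizes give
each check enough resolution while keeping a full run of the suite within a
coffee break.

## Known limitations

- The imprinting test construction (pooled per-cross binomial against the
  cross-pooled fraction) is one reasonable reconstruction; per-embryo exact
  tests would weight deep embryos differently.
- The HMM ignores genetic distances; very uneven gene spacing would make a
  distance-aware transition model preferable.
- PEER-style inference of hidden factors is replaced by principal factors of
  covariate residuals; with strong non-linear batch structure the linear
  stand-in removes less variance.
- The hotspot KS p inherits the correlated-counts caveat described above;
  use the calibrated p for inference and the asymptotic p only for
  comparability.
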