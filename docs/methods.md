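# Methods

This note states the statistical conventions the package implements, the
design of the synthetic ground-truth generators, and the calibration
analysis behind the acceptance-test tolerances. Problem sizes (cohort
sizes, site counts, replicate counts) are the package's own choices,
selected so that every stochastic check is decisive at desk scale.

## Differential editing

**Editing levels and OEL.** An editing level is the fraction of
transcripts edited at a site, in [0, 1]; missing entries mark sites
without sufficient coverage in a sample. The overall editing level (OEL)
of a sample is the mean over its non-missing sites; samples with no
observations are omitted rather than given an OEL of 0. Per-region OELs
average within each annotation class (3'-UTR, 5'-UTR, exonic, intronic,
intergenic, ncRNA — a closed vocabulary enforced at ingest).

**Groups and conditions.** Tumor samples labeled "Progressive Disease"
are resistant, "Complete Response" sensitive; other labels are dropped. A
condition is one (cancer, drug) pair and is analyzed only when both groups
have ≥ 3 samples. Cell lines are labeled by z-scoring ln(IC50) within a
compound using the sample (n−1) standard deviation; strictly z > 0.8 is
resistant, strictly z < −0.8 sensitive, everything else intermediate.

**Informative sites and the DES rule.** A site is informative for a
condition when it has ≥ 3 non-missing values in each group. A DES is an
informative site with two-sided Wilcoxon rank-sum p < 0.05 and
|Diff| ≥ 0.05, where Diff = mean(resistant) − mean(sensitive); Diff > 0 is
over-editing. The p < 0.05 call is deliberately uncorrected (a BH q-value
column is emitted for transparency). The rank-sum test is exact when both
groups have ≤ 25 values and no ties occur, otherwise the normal
approximation with continuity and tie correction is used; both-constant
pooled vectors get p = 1. The exact convention is two-sided
p = min(1, 2·min(lower tail, upper tail)), each tail including the
observed statistic. Consequences the tests pin down:

- at 3 vs 3 the smallest achievable exact two-sided p is 2/C(6,3) = 0.1,
  so no DES can be called from minimum group sizes;
- at 20 vs 20 the attained level of the exact test at nominal 0.05 is
  0.04909 (the null distribution is discrete).

**Patterns.** Per condition the package reports over/under DES counts and
the over-editing proportion, and regresses that proportion on the ADAR
log2 fold change across conditions (conditions with zero DESs are
excluded). Cross-condition DES overlap uses the Meet/Min (Simpson) index
|A∩B| / min(|A|, |B|).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) = `hypergeom.sf(k−1, N, K, n)`, always including the observed
count. For regions: N = informative sites of the condition (pooled unique
sites for the integrative variant), K = informative sites in the region,
n = DESs, k = DESs in the region. For genes the background *changes per
gene*: K is the gene's own informative-site count, so genes with many
editing sites are not called enriched merely for being long; N still
counts every informative site, including intergenic ones.

## Prognosis

Each site's editing levels are dichotomized at the median over all samples
with survival data; values strictly above the median form the over-editing
group (ties go under, deterministically). The groups are compared by a
univariate Cox proportional-hazards model (Efron tie handling, via
lifelines) and a log-rank test. A site is prognosis-related when the
log-rank p < 0.05. A DES is *consistent* when its risk direction matches
its resistance direction: over-edited with HR > 1 or under-edited with
HR < 1; HR = 1 is indeterminate and excluded. Complete separation is
retried with a small ridge penalty and flagged `converged = False`.

## miRNA target rewiring

Sequences are handled as uppercase RNA; DNA input is normalized
losslessly. Canonical sites for a miRNA with seed 2–8 are, on the UTR:
8mer = revcomp(2–8) + A, 7mer-m8 = revcomp(2–8), 7mer-A1 = revcomp(2–7)
+ A. Matching is exact Watson-Crick (no G:U wobble), and overlapping
matches anchored at the same 6-nt core report only the strongest type
(8mer > 7mer-m8 > 7mer-A1). In-silico editing replaces A with G at 1-based
transcript positions and errors on any non-A position, catching strand or
coordinate bugs upstream.

Rewiring compares, per edited position and miRNA, the seed sites
overlapping that position before and after the edit, matched by core
locus: a *gain* is a core locus hosting a canonical site only after
editing, a *loss* only before. A type change at a surviving locus (an
8mer weakening to a 7mer-m8 when the A1 adenosine is edited) is not
called, because a canonical site still exists there; and distal sites
elsewhere on the UTR never produce events.

**Triplet screen.** For an over-edited DES the edited (rewired) form
dominates in resistant samples; for an under-edited DES the roles swap
(the symmetric extended rule, switchable off). The group where the
rewired interaction is active must show Pearson r < 0 with p < α that the
other group lacks; the gene's log2 fold change (resistant/sensitive mean
ratio, direction only, no magnitude threshold) must point away from the
repressed group; and the miRNA must not be differentially expressed
(rank-sum p ≥ α). All three criteria must hold.

## Synthetic generators

- **Editing profile.** Site levels are Beta(mean·c, (1−mean)·c) draws
  (defaults mean 0.25, concentration 20); a `des_fraction` of sites gets
  the resistant-group beta mean shifted by ±`effect_size` (default 0.15,
  validated against the (0, 1) support — never clipped, so the expected
  group difference equals the planted diff exactly). Missingness is
  missing-completely-at-random.
- **ADAR expression.** expression = a + b·OEL + noise with
  σ² = b²·Var(OEL)·(1−R²)/R², so the population R² of the linear fit
  equals the target (default 0.11); target 0 draws expression independent
  of OEL.
- **Survival.** Exponential event times with hazard 0.1·HR for the
  exposed group and 0.1 otherwise; independent censoring at a uniform
  fraction of the event time. In the pipeline generator, resistant
  samples carry the elevated hazard, so over-edited DESs are genuinely
  risk factors and the consistency statistic has a known truth.
- **UTR rewiring.** Gains plant an 8mer whose core G is replaced by A
  (so the unedited UTR holds *no* canonical site anywhere, and one edit
  creates exactly one); losses plant an intact 8mer with an A in its
  core. Backgrounds are resampled until the planted miRNA has zero
  accidental sites on the UTR, making recovery collision-free by
  construction. Core-region edits are used rather than m8/A1 edits
  precisely because editing the flanking positions can leave or create a
  weaker canonical site and would break the zero/one-site invariant.
- **Triplet expression.** The active group's gene values are built from
  the miRNA values with correlation −ρ (default 0.9) around a lower mean
  (70 vs 100); planted miRNAs are non-DE *by construction* — with equal
  group sizes the sensitive group is a permutation of the resistant
  values, so the rank-sum test sees identical distributions.

## Acceptance calibration

Two acceptance checks compare empirical rejection fractions with a 99%
binomial band around the nominal 0.05; because the underlying null
distributions are discrete, the attained level is slightly below 0.05 and
the fixtures are sized so the attained level sits inside the band with a
multi-sigma margin *before* any test is run:

- **Type-I error (Wilcoxon).** 20 seeds × 2000 sites at 20 vs 20 with no
  missingness gives 40 000 exact tests; the attained level is 0.04909 and
  the band is 0.05 ± 2.576·√(0.05·0.95/40 000) = [0.0472, 0.0528].
- **Permutation null (gene enrichment).** 5 genes × 40 000 informative
  sites with 100 000 DESs assigned at random: per-gene DES counts under a
  random assignment are multivariate hypergeometric — the exact
  permutation distribution — and the large counts make the tail nearly
  continuous (attained level 0.0496). 1000 permutations give 5000 tests
  and a band of [0.0421, 0.0579], leaving ≥ 2.4σ margins on both sides.

All other acceptance tests check exact oracle equality (full enumeration
of rank assignments; direct hypergeometric pmf summation; brute-force
seed-site scanning), planted-truth recovery with known direction, or
byte-level determinism of the full pipeline.
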