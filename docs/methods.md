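# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `haplofine`, in the
spirit of the model documentation shipped with simulation and statistics
packages.

## The inferential core

The analysis targets a locus in near-complete linkage disequilibrium: two
founder haplotypes (one carrying the nonrisk allele at every candidate
variant, one carrying every risk allele) plus rare recombinants between
them.  Single-variant association cannot rank variants that sit on the same
haplotype; recombinant haplotypes can, because they decouple subsets of the
locus.  The exclusion rule formalizes this:

> variant v is excluded if some non-reference haplotype h either (a)
> carries v's *nonrisk* allele while being classified *risk*, or (b)
> carries v's *risk* allele while being classified *protective* or *null*.

Classes come from one joint ("multivariable") logistic regression of
case-control status on the per-individual copy counts of every retained
haplotype except the all-nonrisk reference H0, so each class is an odds
ratio against H0 chromosomes.  "Null" means p > α (α = 0.05 by default)
regardless of direction.  The retained variants — those no haplotype
contradicts — form the minimal risk-associated set, reported in genomic
order with the spanned base-pair interval.

Three caveats are deliberate features of the implementation:

* **Reference neutrality.** H0 never contributes exclusion evidence; the
  classes are defined relative to it.
* **Power auditing.** A haplotype can be "null" purely from low count.  The
  exclusion report therefore attaches each evidence haplotype's chromosome
  count, but the rule itself is applied as stated — interpreting
  underpowered nulls is the analyst's job, not the algorithm's.
* **Monotonicity.** Adding haplotypes can only grow the excluded set.  This
  is tested, along with equivalence to a brute-force restatement of the
  rule over bounded exhaustive grids of haplotype/class configurations.

## Association models

All fits are maximum-likelihood logistic regressions computed by
Newton–Raphson with step halving (convergence: max |score| < 1e−8 or
relative log-likelihood change < 1e−10, cap 100 iterations), standard
errors from the observed information.  The fitter is written in-package
because the mediation bootstrap and the calibration tests perform a few
hundred thousand small fits, which rules out heavyweight model objects; it
is cross-checked against `statsmodels.Logit` to 1e−8 in the test suite.
Rank-deficient designs raise an error naming the collinear columns
(QR with column pivoting); quasi-separated fits (|log-OR| > 12) are
returned flagged and excluded downstream rather than raised.

Single-variant scans use additive risk-allele dosage in [0, 2] plus the
standard adjustment set (WGA batch flag, PC1, PC2).  Inference is Wald
throughout — OR = e^β with exp(β ± 1.96·se) intervals — matching how such
loci are conventionally reported.  Because the locus-scale signals reach
−log10 P of several hundred, all tail probabilities are computed in log
space from the normal log-survival function and reported as −log10 P; the
test suite checks agreement with an arbitrary-precision oracle up to
|Z| = 60.

**Credible sets.** Per-variant approximate Bayes factors follow the
Wakefield form ABF = √(V/(V+W)) · exp(Z²W/(2V(V+W))), V = se², evaluated
in log space and normalized over the locus to posterior probabilities of
association (equal priors across variants).  The prior variance of the
log-OR defaults to W = 0.04 (sd 0.2), a conventional choice for
case-control fine-mapping; it is a surfaced, logged parameter because the
PPA column of any published table depends on it.  The 99% credible set is
greedy by descending PPA, ties broken by genomic position for determinism,
and is minimal by construction (dropping its last member breaks the level).

**Conditional scan.** Stepwise: each round refits every remaining variant
with the lead (plus previously detected variants) as covariates and admits
the best variant with conditional p below the threshold (default 5×10⁻⁸, a
conventional genome-wide level; the threshold is configurable because no
single value is canonical for a locus-restricted scan).  Variants collinear
with the conditioning set are skipped with a log entry.

**Mediation screen.** For every pair of non-lead variants with |D′| to the
lead above 0.8, the statistic is δ = β_lead(without pair) − β_lead(with
pair as covariates).  δ is bootstrapped (default 1000 replicates) by
resampling individuals with replacement within case and control strata —
stratified because the data are quota-sampled — with the +1-corrected
two-sided percentile P, p = (1 + #{|δ*−δ| ≥ |δ|})/(B+1), and
Benjamini–Hochberg FDR across pairs.  Strata are canonicalized by row
content before resampling so the P-value is invariant to the order
individuals arrive in.  "Significant mediation" is declared at q < 0.05
together with a relative drop δ/β_unadj > 0.5; the drop threshold is an
explicit operationalization of "the effect drops strongly", and both knobs
are configurable.  Pairs that jointly determine the lead dosage make the
adjusted model collinear; they are flagged `full-collinearity` and excluded
from FDR rather than ridge-stabilized, since a shrunken δ would not answer
the question being asked.

A statistical note: when the tested pair is nearly independent of the
lead, δ is a second-order (O(1/n)) statistic and the nonparametric
bootstrap over-disperses it, making the test conservative.  Under the
screen's operative null — pairs in strong LD with the lead, which is
exactly what the D′ prefilter admits — δ has a first-order component and
the calibration test (500 null data sets at n = 800, B = 199) shows
rejection rates consistent with the nominal 0.05.

## LD statistics

D, D′ and r² are computed by direct counting on phased chromosomes:
D = p_AB − p_A·p_B; D′ = D/D_max with the usual positive/negative
normalizers; r² = D²/(p_A(1−p_A)p_B(1−p_B)).  D keeps its sign internally;
D′ is reported as |D′| as published tables do.  Threshold comparisons are
strict (> 0.8).  A genotype-based EM fallback for unphased input is
deliberately out of scope — phased input is the pipeline contract, and LD
from counting is exact.  Monomorphic variants have undefined LD and are
excluded from threshold lists with a warning.

## EM phasing and dosages

Haplotype frequencies are estimated by the classic gene-counting EM over
diplotypes: E-step weights each individual's compatible ordered pair
(a, b) by f_a·f_b (×2 when a ≠ b), M-step re-estimates f; convergence at
max |Δf| < 1e−8 or 500 sweeps; the log-likelihood trace is retained and
tested for monotonicity, and 2-variant problems are checked against a
brute-force simplex grid search to 1e−4.  Initialization is uniform, so
runs are deterministic.

The haplotype space is restricted rather than the full 2^M cube: seeded
from individuals with ≤ 1 heterozygous site (whose resolutions are certain
or both real), closed under complementation against every observed
genotype (if a is in the space and g − a is a valid haplotype, it joins),
with full per-individual enumeration as a fallback (cap 18 heterozygous
sites; beyond that the individual is reported by index).  For step-like
locus haplotypes this closure is small — on simulated 25-variant data it
recovers the empirical haplotype frequencies of the true phased sample to
machine precision — while uniform-seeding experiments with wider seeding
produced thousands of spurious candidates and visibly degraded estimates.

Phase uncertainty is propagated by drawing R = 100 full phasings from the
per-individual diplotype posteriors (posterior draws from one converged
EM, not independent EM restarts: the posterior is what encodes phase
uncertainty, whereas restart scatter would conflate frequency-estimation
instability).  Replicate chromosomes are mapped onto the best-guess
haplotype set by exact match; non-matching draws accumulate in an explicit
`unmapped_mass` column instead of being forced to the nearest haplotype,
preserving the invariant Σ_h d[i,h] + unmapped[i] = 2.  The dosage
regression is the count regression with fractional copies; with
unambiguous phase it reproduces the count-based fit exactly (tested).

## The synthetic locus

The generator emulates the study conditions the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| founders | all-0, all-1 | all-nonrisk and all-risk haplotypes |
| founder freqs | 0.7 / 0.3 | risk-haplotype frequency 0.3 |
| recomb_rate | 0.02 | per-chromosome single-crossover probability |
| causal variant | rs10490924 | the locus's canonical functional candidate |
| β_causal | ln 2.787 | published lead per-allele odds ratio |
| β₀ | logit(0.05) | baseline prevalence ≈ 5% |
| WGA fraction / effect | 0.2 / 0.2 | batch covariate |
| PC1, PC2 effects | 0.1 / 0.1 | mild stratification analogues |

The published record fixes the effect size and the case/control totals but
not the haplotype frequencies; the 0.3 / 0.02 values are explicit defaults
chosen as realistic for a common risk haplotype with rare recombination,
and everything is overridable.  Recombinants are single-crossover products
of two independent founder draws with a uniform breakpoint, so every
generated haplotype is a step vector — matching the observed haplotype
shapes at such loci and keeping the pool analytically enumerable (pool
frequencies are computed exactly, not sampled).  Double crossovers are
deliberately absent.

Case-control sampling is prospective with rejection against the quotas
(disease status from the logistic model, individuals kept until both
quotas fill, abort with a diagnostic after a configurable attempt cap).
Under a logistic model, outcome-dependent sampling changes only the
intercept, so per-allele and per-haplotype odds ratios remain estimable at
their population values — this is what makes the generate-and-refit
recovery of OR 2.787 a valid check.

What the generator does *not* emulate: genotyping error, imputation
uncertainty (INFO scores), coalescent ancestry structure, double
crossovers, or linkage to variants outside the candidate map.  Passing
tests therefore demonstrate correctness of the analysis logic under the
idealized locus model, not robustness to data-quality pathologies.

## Problem sizes in the shipped tests

Simulation-backed tests run at 5,000 cases + 5,000 controls (20,000
chromosomes) with 6–12 replicate seeds, bootstrap checks at B = 199 over
500 null data sets, and the acceptance script averages 25 replicates —
sizes at which the Monte-Carlo error of each checked quantity is well
below its assertion tolerance.  Recombinant classes in the end-to-end
recovery tests are given a few hundred chromosomes each: haplotype classes
below roughly fifty chromosomes are underpowered at α = 0.05 and classify
null, which the exclusion rule then (correctly, per its stated logic)
turns into exclusions — the behavior is exercised separately, and the
power audit columns exist precisely for it.

## Known limitations

* The exclusion rule is deterministic given the classes; no posterior over
  causal configurations is computed, and borderline classifications
  (p ≈ α) flip the result — the report's evidence lists are the audit
  trail.
* Individuals carrying a below-floor haplotype are excluded from the
  count-based regression (a pooled `Hpool` mode exists behind a flag).
  Exclusion avoids a phantom rare-haplotype class at the cost of a
  slightly smaller sample.
* The mediation bootstrap is conservative for pairs nearly independent of
  the lead (second-order statistic); its calibration holds in the
  strong-LD regime the prefilter admits.
* Reference-panel imputation and external phasing tools are out of scope;
  the pipeline phases internally by EM and analyzes only variants present
  in the input.
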