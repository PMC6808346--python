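# Methods

## The analysis

The pipeline implements the classic two-cohort polygenic-profile design for
a candidate-gene SNP panel:

1. **QC.** Individuals with genotype missingness > 3% are removed first;
   then SNPs with minor-allele frequency < 1%, call rate < 95%, or an exact
   Hardy–Weinberg test p < 5e-7. The individual-level filter runs before
   SNP statistics are computed, so call rates and frequencies refer to the
   retained sample. The HWE test is the exact conditional test (sum of
   probabilities of same-parity heterozygote counts no more probable than
   the observed one), classic formulation without mid-p correction.
2. **Split.** A uniformly random half-split (⌈n/2⌉ discovery, ⌊n/2⌋
   replication) driven by the master seed.
3. **Association.** Per SNP, OLS of the quantitative trait on 0/1/2 dosage
   with intercept, complete cases per SNP, two-sided p from t with n−2 df.
   No covariates by default (an ordinary allelic trend test); ordinal
   instruments are treated as quantitative. Monomorphic or zero-variance
   cases are flagged degenerate (β undefined, p = 1).
4. **Clumping.** Greedy, p-ascending (ties by position then identifier):
   each index SNP absorbs unassigned same-chromosome SNPs within the window
   whose dosage r² exceeds the threshold. LD is composite genotype r²
   (squared Pearson correlation of dosages over complete pairs) — no phase
   is modelled, and haplotype-EM r² is deliberately not used. LD is
   computed in the discovery cohort, the cohort supplying the p-values.
   Defaults follow common PRS-tool conventions: r² 0.1, 250 kb, p ceiling 1.
5. **Scoring.** S_i(T) averages β̂_j·g_ij over post-clump SNPs with p ≤ T;
   missing dosages are imputed as 2× the effect-allele frequency of the
   scored cohort; alleles are reconciled to the scored dataset by flipping
   (g → 2−g) when the weight's effect allele matches the dataset's other
   allele. Averaging rather than summing keeps scores comparable across
   thresholds; R² and p are invariant to this affine choice. The grid is
   {.01, .02, …, .50}: zero is excluded (an empty score is undefined) and
   .50 included.
6. **Best fit.** Two first-class modes, because the reporting conventions
   in this literature use both: `scan_in_target` scans the grid in the
   replication cohort and reports the maximal-R² threshold (ties go to the
   smaller threshold — fewer SNPs); `fixed_from_discovery` locates the best
   threshold in the discovery cohort and evaluates only that threshold in
   the target. The default pipeline uses `scan_in_target`.
7. **Families and FDR.** Eight consistency fits (base = target) and six
   cross-trait fits (expressive-language weights → disorder caseness plus
   five SDQ subscales) are adjusted by Benjamini–Hochberg *within each
   family separately* (m = 8 and m = 6); this split is what makes the
   published adjusted columns exactly recoverable from the published
   nominal columns. Caseness as a target is fitted by a linear probability
   model for uniformity with the quantitative machinery; a logistic
   alternative (McFadden pseudo-R², likelihood-ratio p) is available via
   `dld_link="logistic"`.
8. **Overlap.** The SNP sets of two best-fit models are compared by exact
   intersection; the shared fraction is reported as 100·|A∩B|/|A|, rounded
   to the nearest percent for display. Because cross-trait scores reuse the
   base trait's weights, the two sets are nested whenever one threshold is
   below the other.

## The synthetic cohort

**Genotypes.** Within each gene block, two haplotype-level latent Gaussian
AR(1) processes (one parameter ρ per block) are thresholded at the
allele-frequency quantile; dosage = sum of the two haplotypes. This gives
exact marginal frequencies, a block-diagonal LD pattern that decays with
distance, and independence between blocks. Allele frequencies are uniform
on (0.05, 0.5]; genotypes are missing completely at random at 1% by
default. The default panel is 1,229 SNPs over the six candidate loci,
allocated proportionally to the hg38 gene spans (ATP2C2 36, CMIP 101,
CNTNAP2 880, DCDC2 70, FOXP2 102, KIAA0319 40).

**LD strength.** The AR parameter defaults to ρ = 0.93, calibrated so that
the number of clumped SNPs entering a threshold-.50 model (~120 of 1,229)
matches the published best-fit model sizes at that threshold (111 and 123
SNPs). Weaker defaults (ρ = 0.8) leave roughly twice as many index SNPs as
the real panel exhibits.

**Phenotypes.** y = √h²·G + √(1−h²)·ε on the liability scale, where G is
the standardized weighted sum of standardized dosages at the causal SNPs
and ε is unit Gaussian noise, optionally mixed with a cohort-wide shared
environmental factor (loading λ per trait, noise variance kept at 1 so h²
is unaffected). The liability is mapped onto each instrument affinely
(midpoint + liability × span/6, so ±3 SD covers the printed range), clipped
and rounded. The default architectures are deliberately weak: the
expressive-language trait carries 65 causal SNPs explaining 1% of variance;
the peer-problems trait shares 27 of them with sign-flipped effects
(language-lowering alleles raise problem scores) plus 13 of its own at
h² = 0.8%; the remaining traits carry small independent architectures
(h² 0.2–0.5%). Shared environmental loadings (positive for language
measures, negative for problem subscales) give the phenotype correlation
matrix the usual sign structure.

**Caseness.** Disorder status is derived, not simulated directly: affected
iff at least two of (a) pragmatic, (b) nonword-repetition, (c) receptive
scores more than 1 SD below the sample-standardized mean, or (d) a positive
speech/language-therapy flag. The therapy flag is a noisy logistic
indicator of low latent language, P = expit(−3.0 − 1.3·z̄), where z̄ is the
standardized mean language liability — the intercept puts the base rate
near 5% so that derived prevalence lands in the mid-single digits.
ASD-like and hearing-like flags (1.5% each, independent) exclude a child
from both groups; missing criterion data yields an explicit
excluded-for-missingness status.

**What the simulator does not model.** Recruitment and attrition, multiple
births, ancestry structure and relatedness, genotyping batch effects,
imputation uncertainty, real haplotype-block irregularity, and
instrument-specific item behaviour (floor/ceiling shapes beyond clipping).
Passing tests therefore demonstrate the *machinery* — calibration under the
null, recovery of planted weak architectures, exact arithmetic — not
cohort-specific effect sizes, which are irreproducible without the
restricted data.

## Numerical and design choices

- **Seeds.** One master seed; every stochastic operation derives a child
  generator from (seed, operation tag) via hashed SeedSequences, so stages
  are reproducible and independent.
- **PLINK I/O** is implemented directly (v1.00 SNP-major BED, two-bit codes
  packed from the low bits; BIM's first allele is the counted allele).
  Round-trips are lossless, including the missing code.
- **Ties and degeneracies.** Clumping breaks p ties by position then
  identifier; best-fit ties go to the smaller threshold; monomorphic LD
  columns count as r² = 0 (never clumped); empty S(T) rows are flagged and
  excluded from best-fit selection; p-values are floored at the smallest
  positive double to keep the FDR step valid.
- **Report rounding** is 3 decimals, round-half-even, applied only for
  display; full precision is kept internally.
- **Filter idempotence** holds at the default thresholds; with thresholds
  placed exactly on the discreteness boundary of small panels a second
  pass can remove further individuals (the individual filter's denominator
  changes once SNPs are dropped).

## Validation experiments and their sizes

Replicate studies in the test suite run the core machinery directly
(without file round-trips). Problem sizes are the package's own choices:

- **Null calibration**: 500 replicates of the full discovery→replication
  path at h² = 0, n = 5,435 split 2,718/2,717, on a 120-SNP two-block
  panel (the fixed-threshold replication p-value's calibration does not
  depend on panel width); the α = .05 rejection rate is required to lie
  within ±.02 of .05, and lands at .050.
- **Parameter recovery**: 25 signal replicates (65 causal of 1,229 SNPs,
  causal component 1% of variance) against 25 matched null replicates at
  the full panel and sample size. The test statistic is the replicate
  median of the best-fit replication R²; it must exceed the 95th percentile
  of the sampling distribution of the null median (seeded bootstrap). The
  medians differ about two-fold (≈0.0015 vs ≈0.0007). Note that the
  *per-replicate* null 95th percentile (≈0.0023) is higher than the signal
  median — a single study in this regime is only marginally powered, which
  is exactly the picture the motivating analysis reports (best consistency
  fit R² = .182%, nominal p = .042). A median-vs-extreme-order-statistic
  comparison was therefore rejected as a recovery test in favour of the
  standard detection test on the median's sampling distribution.
- **Shared-fraction monotonicity**: 12 paired replicates with common random
  numbers (same genotypes and base weights; only the target trait's shared
  causal fraction f varies), fixed threshold .50; mean cross-trait R² rises
  ≈0.0006 → 0.0015 → 0.0026 over f = 0, .5, 1.

## Known limitations

- Composite genotype r² slightly underestimates haplotype r² at low MAF;
  clump boundaries can differ from phase-aware tools on real data.
- The linear probability model for caseness ignores the bounded mean
  structure; with ~6% prevalence its p-values are nevertheless close to
  the logistic ones at these effect sizes.
- Best-fit threshold scanning maximizes over ~50 correlated tests; the
  reported nominal p at the best threshold is optimistic by construction
  (the family-wise FDR column, not the scan, carries the inference).
- The AR(1) latent model produces smoothly decaying LD; real candidate
  loci have irregular block boundaries and occasional long-range LD.
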