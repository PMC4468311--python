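# Methods

`methylaging` implements a four-stage analysis of why one tissue (the
cerebellum in the motivating application) appears epigenetically younger
than the rest of the body, together with a synthetic-data generator that
makes every stage testable against known ground truth.

## 1. Epigenetic clock

**Beta values.** Methylation fractions come from fluorescence intensities
as `β = max(M,0) / (max(M,0) + max(U,0) + 100)`. The +100 offset is the
Illumina convention that stabilizes low-intensity probes; it is not
configurable because the formula is exact. β is bounded in [0, 1), monotone
increasing in M and decreasing in U.

**Calibration transform.** Chronological age `x` is mapped to the clock's
internal scale by

    F(x) = log(x+1) − log(a+1)   for x ≤ a
    F(x) = (x−a) / (a+1)         for x > a

with `adult_age` a (default 20 years): logarithmic during development,
linear in adulthood, continuous and strictly increasing with F(a)=0. The
clock file, not the code, carries `a`, so clocks with other calibrations
plug in. `inverse_transform_age` is the exact inverse; round trips hold to
machine precision.

**Prediction.** DNAm age = `F⁻¹(intercept + Σ wᵢ βᵢ)` over the clock CpGs.
Missing clock CpGs are never silently dropped: they are an error unless
imputation from a gold-standard mean is explicitly requested, and the
per-sample imputation count is reported.

**Normalization.** Full beta-mixture (BMIQ-style) normalization is out of
scope. The implemented contract is the same — reference every sample to a
gold standard — via per-sample monotone quantile anchoring over the
gold-covered CpGs: each sample's values are replaced by the gold-standard
values at the same within-sample quantile (mid-ranks for ties). The map
preserves rank order, is idempotent, and is the identity for a sample
already distributed like the standard. It is pluggable and off by default.

## 2. Age acceleration

Acceleration is the residual of DNAm age from an OLS regression of DNAm
age on chronological age fitted **only on reference samples** (default:
every tissue except the contrast tissue). Negative values mean
epigenetically younger than expected. Descriptive statistics follow the
usual multi-region comparison layout:

* per-tissue mean ± SE within age bands `[0,60) [60,80) [80,100) [100,∞)`
  (closed on the left, configurable), with technical replicates averaged to
  one value per subject and tissue *before* any group statistic to avoid
  pseudo-replication;
* Kruskal–Wallis across tissues within a band (mid-ranks, tie correction,
  χ² reference with k−1 df; all-identical data is reported as H=0, p=1 with
  a degeneracy flag rather than an error);
* Pearson correlation of DNAm age with age;
* replicate concordance: Pearson r over replicate DNAm-age pairs, paired by
  sorted replicate index within subject and tissue (all unordered pairs
  when there are more than two).

## 3. Differential-expression meta-analysis

For each region contrast a paired t-statistic is computed on
within-subject differences; the matched design cancels subject-level
confounders exactly (an invariance tested literally). Probes with zero
difference variance are flagged and excluded from the ranking universe.

The k contrast statistics are combined with the **scaled Stouffer** rank
recipe: within each contrast, ascending mid-ranks r of the t-statistics
(of −t for the low scale) are scaled to r/(m+1), mapped through the
standard normal quantile, summed over contrasts and divided by √k. The
exact variant of the published rank-combination implementation is
under-specified, so this recipe is fixed here and verified against an
independently coded brute force rather than against the external
implementation — a documented deviation risk. Upper-tail normal p-values
per scale are converted to Storey q-values (λ grid 0.05…0.90 step 0.05,
cubic-polynomial smoother evaluated at λ=0.90, clipped to (0,1], fallback
π₀=1 for m<100; q_(i) = min_{j≥i} π₀·m·p_(j)/j, which reduces exactly to
Benjamini–Hochberg at π₀=1). Selection at a one-sided FDR threshold
(default 0.05) gives disjoint over-/under-expressed sets.

*Terminology note:* the procedure is described upstream both as "local
false discovery rates" and as "q-values"; these are different quantities.
Tail-area q-values are implemented, matching the thresholding language.

**Known limitation.** The rank combination treats the k contrasts as
independent, but contrasts of one region against several others share that
region's samples, so the per-probe t-statistics correlate (≈0.5) and the
combined Z has heavier-than-normal tails. With strong planted signal this
surfaces as a small number of opposite-scale false calls at genome scale.
This is inherent to the method as specified, not corrected here.

## 4. GWAS gene-set enrichment

Per-study SNP effects are combined by fixed-effects inverse-variance
meta-analysis (weights SE⁻², combined SE = (Σw)^−½, two-sided normal p).
SNPs are assigned to every gene whose interval, extended by ±50 kb
(configurable) and kept 0-based half-open, contains them; GWAS positions
are 1-based on input and converted at parse time. Each gene is scored by
its **best (minimum) assigned SNP p-value**; genes without SNPs are
excluded and counted. The MAGENTA-style confounder regression (gene size,
SNP density) is deliberately not implemented — it is exposed as a
`score_hook` for callers who need an adjusted score.

Enrichment of a gene set counts members at or below the empirical
5th-percentile score cutoff (95th-percentile significance cutoff) and
compares against random gene sets of equal size resampled without
replacement from the scored universe — resampling *sets*, not SNPs,
preserves the gene-score distribution. p = (1 + #{perm ≥ observed}) /
(1 + n_perms), never 0 and never above 1; runs start at 10,000
permutations and escalate to 100,000 when the initial p < 10⁻⁴. The
cutoff is taken over all scored genes (autosome-only filtering, if wanted,
is the caller's input choice). A DAVID-style hypergeometric
over-representation test (n, fold enrichment, upper-tail p, Bonferroni
across the sets tested in one run) covers expression gene lists.

## 5. Synthetic data: the stated world

The generator emulates the *statistical structure* of the source study,
not its biology:

* **Clock construction.** Each CpG gets baseline βᵢ ∈ [0.3, 0.7], a random
  direction, and a slope on the transformed-age scale scaled so betas stay
  inside [0.05, 0.95] for ages 0–120; weights satisfy Σwᵢsᵢ = 1 with the
  intercept cancelling baselines, so a noiseless profile at transformed
  age t scores exactly t and both transform branches are exercised.
* **Methylation.** Tissue-specific aging-rate multipliers enter as
  `F(rate·age)`; a cerebellum-like tissue uses rate 0.6, references 1.0,
  so noiseless DNAm age is exactly `rate·age` and the closed-form
  acceleration is `rate·age` minus the fitted reference line. Noise is
  i.i.d. Gaussian on the beta scale, clipped to [0, 1].
  `noise_sd_beta = 0.2` is calibrated so that, in a replicate design like
  the study's 30-tissue single-donor panel, replicate DNAm-age concordance
  lands near the reported r ≈ 0.7 (the implied DNAm-age noise is ≈3 years
  for a 353-CpG clock). At this noise level beta clipping is *not*
  negligible near the envelope: it attenuates the reference-fit slope to
  ≈0.88. Clipping (not resampling) is kept for simplicity; analyses that
  compare against the *fitted* line absorb the shared attenuation.
* **Cohort design.** The default bundle uses 40 subjects across 6 brain
  regions with band occupancy 3/8/15/14 from young to 100+, mirroring the
  centenarian-enriched sampling of the source datasets. Because the
  generative model separates the slow tissue from birth (unlike the real
  data, where regions diverge only late in life), the young band's
  non-significance arises from its sparse occupancy — a deliberate,
  pre-registered design choice, not a fitted one.
* **Expression.** Probe baseline + subject random intercept + per-region
  scalar shift + planted effects in the contrast region + i.i.d. noise.
  Region shifts are scalars shared across probes (library-size-like) so
  that unplanted probes are genuinely null for the rank-based
  meta-analysis; per-probe region effects would make every probe truly
  differential.
* **GWAS.** One SNP panel (default 5 SNPs per gene placed inside ±40 kb);
  genes of designated enriched sets carry one causal SNP whose effect sign
  is drawn once and shared across studies; study SEs follow
  1/√(2·MAF·(1−MAF)·n). No linkage disequilibrium, probe chemistry, or
  cellular heterogeneity is simulated — green tests establish that the
  *pipeline arithmetic* recovers planted structure, not that it would
  survive those real-data complications.
* **Determinism.** One global seed fans out to per-stage child streams via
  `SeedSequence` spawn keys; identical seeds give byte-identical files.

## Numerical choices

* Permutation subsets are drawn by random-key `argpartition` (vectorized,
  chunked to bound memory); the permutation p carries the +1/(n+1)
  correction.
* The enrichment cutoff is the linear-interpolation empirical quantile;
  tail membership is `score ≤ cutoff`, used identically for the observed
  and permuted counts.
* Kruskal–Wallis on all-identical data → (0, 1, flagged); Pearson on
  zero-variance input → error.
* Degenerate (sd = 0) paired-t probes carry a signed-infinity sentinel and
  are excluded from the ranking universe, reported separately.
* q-value π₀ uses a cubic polynomial fit as the smoother; for m < 100 the
  estimate is unstable and π₀ = 1 is used.

## Calibration-test design

The uniformity check of the permutation p-values (KS test against the
continuous uniform) uses a universe of 1500 genes, sets of 300 and a 75th
percentile cutoff: the null tail count then has SD ≈ 7, so the discrete
permutation null has enough support points for the continuous KS reference
to apply. With small sets (e.g. 3 genes) the null is a 4-atom
hypergeometric and a KS test would reject on discreteness alone; the small
setting is instead checked exactly against enumeration of all C(10,3)
subsets.
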