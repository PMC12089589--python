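# Methods

`polymr` implements a two-sample Mendelian randomization (MR) workflow
specialized for drug-target questions with multiple target genes
(polypharmacology), together with the polygenic-risk-score (PRS) drug
association analysis that complements it. This note records the models,
the numerical conventions, and the choices made where the design was
genuinely open.

## Two-sample MR model

For variant $j$, let $\hat\beta_{Xj} \pm \sigma_{Xj}$ be its association
with the exposure and $\hat\beta_{Yj} \pm \sigma_{Yj}$ with the outcome,
estimated in non-overlapping samples and expressed per copy of a shared
effect allele. Under the instrumental-variable assumptions the estimand
$\theta$ satisfies $\beta_{Yj} = \theta\,\beta_{Xj}$; directional
pleiotropy adds a variant-level intercept term $\alpha_j$.

Estimators (all authored here in closed form):

- **Wald ratio** (1 instrument): $\hat\theta = \hat\beta_Y/\hat\beta_X$,
  with the first-order delta-method standard error
  $\sigma_Y/|\hat\beta_X|$.
- **IVW** (≥ 2): weighted least squares of $\hat\beta_Y$ on
  $\hat\beta_X$ through the origin with weights $w_j = 1/\sigma_{Yj}^2$.
  Fixed-effect SE is $(\sum_j w_j\hat\beta_{Xj}^2)^{-1/2}$; the
  multiplicative random-effects variant scales the variance by
  $\max(1, Q/(k-1))$ with Cochran's $Q$.
- **MR-Egger** (≥ 3): the same weighted regression with a free
  intercept, fitted after orienting every instrument so
  $\hat\beta_{Xj} \ge 0$ (the allele coding is free, and a sign-definite
  exposure axis is what makes the intercept interpretable as average
  directional pleiotropy). Rücker's $Q'$ is the weighted residual sum of
  squares; $Q' \le Q$ always, because the intercept-free model is
  nested.

Model choice for ≥ 3 instruments follows the Rücker ladder with a single
level $\alpha$ (default 0.05) for all comparisons: $Q$ against
$\chi^2_{k-1}$ (fixed IVW if not significant), then $Q - Q'$ against
$\chi^2_1$ (random IVW), then $Q'$ against $\chi^2_{k-2}$ (fixed Egger),
else random-effects Egger. With 1 or 2 instruments the ladder cannot
run; the dispatcher uses the Wald ratio or fixed-effect IVW
respectively. Every comparison (statistic, df, critical value, branch)
is recorded in a decision trace.

P-value conventions are fixed to avoid silent drift between
implementations: standard normal for Wald and fixed-effect IVW, Student
t with $k-1$ df for random-effects IVW and $k-2$ df for Egger. The
pleiotropy flag is the random-effects Egger intercept test at the
nominal $\alpha$, computed for every ladder outcome so the flag does not
depend on which model was selected.

**Known property of the weighting.** The weights $1/\sigma_{Yj}^2$
ignore exposure-side sampling error (the convention of mainstream MR
software). Two visible consequences, both reproduced by the calibration
checks: a small attenuation of the mean estimate (order
$\sigma_X^2/\beta_X^2$, about 0.5% of $\theta$ under the default
conditions), and 95% CIs whose true coverage is close to
$2\Phi(1.96/\sqrt{1+\theta^2}) - 1 \approx 93.9\%$ rather than 95% when
$\theta = 0.3$ and the two samples are of equal size, because the
neglected term $\theta^2\sigma_X^2$ understates the estimator variance.
At $\theta = 0$ the term vanishes and the type-I error is nominal.

## Instrument selection

Candidates are harmonized exposure–outcome variants. The selection
pipeline applies, in order: a strict p-value threshold on the exposure
association (defaults $5\times10^{-8}$ genome-wide,
$1\times10^{-4}$ drug-target), an optional restriction to flanked gene
regions (drug-target mode; flank default 5 kbp, intervals 1-based
inclusive; BED input is converted from 0-based half-open on read), and
greedy LD clumping (defaults $r^2 < 0.001$ genome-wide, $r^2 < 0.1$
drug-target; window 10 Mbp).

Clumping repeatedly promotes the remaining candidate with the smallest
exposure p-value and discards candidates within ±window having
$r^2 \ge$ threshold with it — i.e. the window is a half-window around
the index variant, matching the clumping tools in common use ("10 Mbp
window" is ambiguous; this interpretation is the deliberate one). Ties
on p-value break by (chromosome, position, variant id) so results are
independent of input order. $r^2$ from a dosage panel is the squared
Pearson correlation of effect-allele dosages; monomorphic variants get
$r^2 = 0$ against everything (undefined correlation), cross-chromosome
pairs are 0 by construction.

Harmonization accepts allele swaps (outcome beta negated) and strand
flips (complement). Palindromic variants (A/T, C/G) cannot be resolved
from labels; they are kept only if both effect-allele frequencies are
available, both fall outside [0.42, 0.58] (configurable) and both lie on
the same side of 0.5 — otherwise dropped. Duplicated variant ids are
removed entirely (no arbitrary survivor), and positions observed with
more than two alleles are dropped as multi-allelic. A missing standard
error with beta and p present is reconstructed as
$|\beta|/|\Phi^{-1}(p/2)|$ and counted in the cleaning report.

## The polypharmacology screen

The screen evaluates every exposure × gene-selection cell. For
amlodipine the packaged catalogue defines eight experiment groups: one
"all_targets" selection holding the seven DrugBank target genes
(CACNA1C, CACNB1, CACNA1I, CACNA1B, CACNA2D3, CA1, SMPD1) and seven
single-gene selections. The shipped coordinates are approximate GRCh38
gene spans and are deliberately an editable text table with a build tag:
coordinates must be verified against the builds of the datasets actually
analysed.

Significance uses a layered Bonferroni threshold
$\alpha / n_\text{traits} / n_\text{selections}$ (with
$n_\text{selections} = 1$ in genome-wide mode); with $\alpha = 0.05$,
140 traits and 8 selections this is $0.05/140 \approx 3.57\times10^{-4}$
and $0.05/1120 \approx 4.46\times10^{-5}$. A cell is "significant
without pleiotropy" when it passes the corrected threshold and the Egger
intercept test does not reject at the nominal $\alpha$ — the pleiotropy
gate is intentionally nominal, not corrected, so it stays a conservative
screen on effect interpretability. Cells with no surviving instruments
produce rows with reason codes rather than gaps, keeping the result
table's cardinality fixed at exposures × selections.

## PRS and drug association

Per-chromosome scores are the mean over scored variants of
dosage × weight, with $K_{ji}$ the number of non-missing dosages of
individual $j$ on chromosome $i$; a missing dosage leaves both the mean
and $K_{ji}$ for that individual only. Genome-wide scores are the
$K$-weighted mean

$$\mathrm{PRS}_j = \frac{\sum_i \mathrm{PRS}_{ji} K_{ji}}{\sum_i K_{ji}},$$

which is algebraically the plain mean of dosage × weight over all scored
variants — the decomposition is exact, and a chromosome-split invariance
test holds it to 1e-12. "Mean effect per chromosome" is read as the mean
of dosage × weight (the convention of standard scoring tools); the
literal alternative (mean of weights alone) would make scores
genotype-independent and is rejected. Scores are standardized with the
sample (n−1) SD on the analysis cohort after dropping unscorable
individuals.

Associations are maximum-likelihood logistic fits (statsmodels) of a
binary outcome on the standardized PRS and drug status, plus covariates
only if supplied — none are added by default. Constant predictors,
one-class outcomes, separation and non-convergence raise diagnostic
errors rather than returning silent coefficients.

## Synthetic data

The generators produce the fixtures every other module is tested
against, as pure functions of a seed (one seed, split deterministically
per sub-generator).

- **Panel**: haplotypes from a latent Gaussian AR(1) process
  (correlation `ld_decay` between neighbours) thresholded at each
  variant's allele frequency; dosage is the sum of two haplotypes.
  Allele frequencies vary smoothly along the chromosome (sorted draws
  from `maf_range`) because thresholding attenuates correlation badly
  when adjacent thresholds differ. The realized empirical $r^2$ matrix
  is returned alongside the panel so clumping is tested against the LD
  the panel actually carries.
- **Two-sample GWAS**: summary statistics are drawn directly from the
  effect/noise model rather than by regressing simulated genotypes —
  estimator tests need exactly known betas, and the panel is only needed
  for LD. True exposure effects are positive
  (`instrument_beta_range` = (0.08, 0.20) by default, chosen so every
  instrument has F > 30 at n = 50,000 even at the rarest allowed MAF)
  for `instrument_fraction` of variants; the outcome's true effect is
  $\theta\beta_X$ plus per-instrument pleiotropy
  $\sim N(\mu_\alpha, \sigma_\alpha^2)$ drawn independently of
  instrument strength, so the InSIDE condition holds and the Egger
  intercept consistently estimates $\mu_\alpha$. Observed statistics add
  noise with $\mathrm{se} = (2\,\mathrm{maf}(1-\mathrm{maf})\,N)^{-1/2}$
  and p-values satisfy $p = 2(1-\Phi(|\beta/\mathrm{se}|))$ exactly.
  Positive true effects are a free allele-coding choice, not a loss of
  generality; harmonization is still exercised because the outcome's
  allele labels are randomly swapped per variant.
- **Gene annotation**: disjoint contiguous gene blocks over the variant
  map with recorded membership, so drug-target selection has planted
  ground truth.
- **PRS cohort**: Binomial(2, maf) dosages with optional missingness;
  outcome $\sim$ Bernoulli(logistic($-1 + 0.4 z - 0.3 D$)) by default,
  where $z$ is the standardized true score and $D$ drug status at 10%
  prevalence, optionally tilted by the score for confounding-by-
  indication experiments (negative-control designs).

What the generators do **not** emulate: realistic human LD maps,
population structure and relatedness, case–control ascertainment,
winner's-curse in instrument discovery, sample overlap between exposure
and outcome studies, and genotype-derived (rather than model-derived)
summary statistics. Passing tests therefore certify the estimators and
plumbing under the stated model, not robustness to those real-data
features.

## Problem sizes and numerics

Calibration checks use 500 replicates of 20-instrument studies at
n = 50,000 per sample (IVW recovery at $\theta = 0.3$, type-I error at
$\theta = 0$, Egger intercept recovery at planted pleiotropy 0.05);
association recovery uses one 20,000-person cohort and 100 replicates of
4,000-person cohorts for the null-drug rejection rate; the clumping
oracle enumerates all $2^{12}$ subsets of a 12-variant toy and checks
greedy output across 100 input permutations. Recovery tolerances are
absolute (0.01 on $\theta$, 0.005 on the intercept): tighter,
pure-Monte-Carlo tolerances would be violated by the documented
first-order attenuation, which is a property of the estimator, not of
the implementation.

Floating output in CLI tables is printed at 6 significant digits.
Degenerate inputs are errors, not warnings: zero exposure beta (Wald),
all-zero exposure betas (IVW), no exposure-beta variance after
orientation (Egger), zero-variance scores (standardization), constant
predictors and separation (logistic fits).

## Known limitations

- Exposure-side uncertainty is ignored by design in all weights; no
  second-order or Steiger-style corrections are provided.
- The Rücker ladder uses one $\alpha$ for all three comparisons; no
  multiplicity adjustment across the ladder.
- The packaged gene coordinates are a convenience stand-in; real
  analyses must supply verified, build-matched annotations.
- No liftover, no reference-genome allele validation, and no LD panel
  retrieval: LD is always a user- or simulator-supplied input.
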