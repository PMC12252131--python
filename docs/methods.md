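# Methods

This note records the models, conventions and numerical choices behind
`gxetools`, and what the synthetic-data tests do and do not demonstrate.

## Phenotype model and variance decomposition

Phenotypes follow the additive plasticity model

    y_ijk = mu + g_i + (1 + b_i) * E_j + rep_jk + eps_ijk

for genotype i, environment j, replicate k. `E_j` is the environment
effect, `g_i` the genotype main effect, `b_i` the plasticity deviation
(`1 + b_i` is the Finlay–Wilkinson slope), `rep_jk` a replicate block
effect drawn once per environment × replicate, and `eps` i.i.d. Gaussian
plot noise.

**ANOVA.** Strata are Genotype, ENVs, Rep, Genotype:ENVs, Residuals. Rep
is modeled as a crossed main effect (one blocking level shared across
environments — consistent with a replicate stratum of 2 degrees of
freedom in a 3-replicate trial), not nested within environment. *Variance
%* is each stratum's share of the total sum of squares about the grand
mean — the convention under which published trial tables sum to 100 —
not a REML variance component. Balanced designs use the classical
group-mean closed forms (exact, fast at any scale); unbalanced data fall
back to sequential (type I) least-squares sums of squares in the fixed
order Genotype, ENVs, Rep, Genotype:ENVs, with a warning. F statistics
test each stratum's mean square against the residual mean square.

**Finlay–Wilkinson.** `E_j` is the environment mean minus the grand mean
of environment means (so `sum_j E_j = 0`), and each genotype's
environment means are regressed on `E_j` by ordinary least squares.
Slopes are identified only relative to the mean response: if the sampled
`b_i` do not average exactly zero, fitted slopes equal
`(1 + b_i)/(1 + mean(b))`. The exact-recovery tests therefore center the
planted slopes; the generator draws `b_i` with mean zero so slopes
average 1 in expectation, the standard convention.

**GGE.** The genotype × environment mean table is column-centered
(removing `mu + beta_j`) and decomposed by SVD; axis k explains
`lambda_k^2 / sum lambda^2`. Scores carry the symmetric scaling
`sqrt(lambda_k)` on each side (the published model does not state a
scaling; the symmetric split treats genotypes and environments evenly).
Sign convention for PCA and GGE alike: each axis is flipped so its
largest-magnitude environment loading (marker loading for genotype PCA)
is positive, making outputs reproducible across BLAS implementations.
Missing cells raise — imputation is out of scope.

## Derived daily indices

With Tbase = 10 °C: `gdd = max(0, (tmax+tmin)/2 − 10)` (negative thermal
time is non-physical, so the daily value is clamped at zero);
`dtr = tmax − tmin`; `prdtr = pcp/dtr` and `ptq = radn/gdd` fall back to
0 when their denominator is ≤ 0 so every value is finite;
`ptt = gdd × dh` with `dh` the daily sunshine duration. Window
aggregation uses the **arithmetic mean** over the closed day interval for
all 13 factors: means keep windows of different lengths comparable, and
cumulative readings (total GDD and the like) are recoverable as
mean × length.

## Sliding-window scan

Default grid: start days 1–145, durations 5–150, ends bounded only by the
last recorded day — 10,730 windows per factor for a 150-day season. For
each window the per-environment window means are correlated with the
per-environment population phenotype means (n = number of environments).
p-values use the exact t transform `t = r sqrt((n−2)/(1−r^2))` on n−2
degrees of freedom, two-sided, with `−log p` in base 10; `|r| = 1`
returns the float-tiny floor rather than zero. A permutation option
(`pearson_perm_p`) estimates the randomization p by re-pairing; note that
at n = 14 the t-based (bivariate-normal sampling) probability and the
randomization probability conditioned on the observed sample differ by
O(1/n) for atypical samples — more than the Monte-Carlo error of 10^5
permutations — so the two should not be expected to agree to MC accuracy
on every draw. No multiple-testing correction is applied across the
~139k windows; the scan is exploratory and ranked by |r| (ties: larger
−log p, then earlier start, then shorter duration).

## Random forest and SHAP key windows

The attribution model is a regression forest with 500 trees and the
squared-error criterion, `max_features = 0.3` and `min_samples_leaf = 5`.
The two non-pinned settings are package choices: exhaustive split search
(`max_features = 1`) makes importance winner-take-all among correlated
windows and hides secondary drivers, while `sqrt` dilutes it over chance
correlates; 0.3 balanced identification quality and cost in the recovery
experiments, and leaf size 5 is the common regression-forest default that
also bounds tree depth. Genotype principal components (column-centered,
unscaled PCA of the {0,1} marker matrix, retained to >90% cumulative
variance) enter as covariates but are never eligible as key windows.

SHAP values are computed by an exact **path-dependent TreeSHAP** written
for this package (no installed library provides tree SHAP values): for
each sample, attributions are the Shapley values of the game whose
coalition value is the tree's expected output when coalition features
follow the sample and the remaining splits are averaged with training
cover weights. The recursion maintains Lundberg's path-weight polynomial
(O(leaves × depth²) per sample per tree) and is numba-compiled; tests
verify exact agreement with a brute-force enumeration over all feature
coalitions on small trees and the local-accuracy identity
`E[f] + Σ φ = f(x)` on forests (float tolerance 1e−8).

Selection: per 5-day stride-1 window, impurity importance and mean |SHAP|
are profiled over start days per factor, smoothed with a centered 5-window
moving average whose edges shrink to the available neighbors, and
thresholded at τ = 0.10 of each profile's **global** maximum across all
environmental windows. A window must pass **both** criteria (an AND rule;
`or`/single-criterion modes exist behind a flag) — the combination logic
and the global (not per-factor) cut are package choices. Overlapping or
adjacent significant windows of one factor merge into a single period
(minimum start, maximum end), ranked by peak smoothed mean |SHAP|.

## Cross-environment evaluation

Environments are randomly partitioned into equal folds (7 × 2 for a
14-environment trial); each fold is held out in turn and predictions from
all folds are pooled before computing PCC, R² (about the pooled observed
mean) and MSE — metrics of the combined prediction vector, not fold
averages. Samples are genotype × environment observations,
replicate-averaged by default (replicates carry no distinct features);
rep-level rows are available behind a flag. Environment features depend
only on weather and genotype PCs only on markers, so held-out phenotypes
cannot leak into training — the suite asserts that permuting held-out
phenotypes leaves their predictions unchanged. Learners beyond the
pinned forest settings use library defaults with fixed seeds; SVR,
BayesianRidge and ElasticNet are wrapped with feature standardization.

## Synthetic-trial generator

Weather is a sinusoidal seasonal baseline plus AR(1) daily noise
(persistence 0.6) per variable, truncated at physical bounds
(tmin ≤ tmean ≤ tmax by construction; humidity clipped to [0, 100];
nonnegative precipitation, sunshine, radiation, wind). Three archetypes
bracket the contrast between an arid high-radiation region (mean daily
precipitation 0.4–1.2 mm, radiation peaking near 28 MJ m⁻² day⁻¹,
humidity ~50%), a semi-arid region (2.0–5.1 mm) and a humid one
(4.8–7.2 mm, radiation < 20, humidity ~75%); each environment draws its
mean precipitation uniformly from the archetype range (gamma-distributed
daily amounts, shape 2) plus small site/year offsets in temperature,
humidity and wind. The default trial has 14 environments (6 arid, 5
semi-arid, 3 humid), 250 lines, 3 replicates and a 150-day season.
Markers are biallelic homozygous {0,1} in contiguous founder blocks with
a small flip rate, so a low-dimensional PC representation exists.

Default planted windows give each trait 1–2 mid-to-late-season drivers
with effect sizes chosen once so the ANOVA shares are realistic for this
kind of trial (environment-dominant yield traits, genotype-dominant
fiber-quality traits); genotype effects and plasticity slopes are normal
with trait-typical spreads. Everything is driven by
`numpy.random.SeedSequence`, and identical seeds give bit-identical
tables.

**What the generator does not emulate:** spatial/temporal correlation
between environments, missing data, non-Gaussian trait noise,
marker-linked genotype effects (genotype effects are independent of the
marker blocks), and cross-variable weather dependence (each variable's
AR noise is independent; the derived indices reintroduce deterministic
dependence). Passing recovery tests therefore show the machinery is
correct and identifiable under the stated signal structure — not that
real trials satisfy those conditions.

## Recovery experiments: design and identifiability limits

Two structural facts shape the test conditions, found while designing the
recovery experiments and worth knowing before applying the scan to data:

- **Regional level offsets destroy temporal localization.** When
  environments span contrasting climate regions, every window of a factor
  with a large regional level difference (radiation, humidity) carries
  nearly the same cross-environment signal (cross-window correlation
  ≈ 0.8 in the mixed-archetype generator), and factors whose regional
  levels co-vary (temperature with humidity) act as proxies for one
  another. A window scan can then identify *that* a factor matters but
  not reliably *when*, unless the signal is strong enough for the exact
  window to outrank its own proxies (the scan-recovery test plants a
  window explaining ~60% of phenotypic variance — the environment share a
  yield trait shows — and localizes it exactly in 20/20 seeded trials).
- **Per-factor attribution needs many environments.** Window features
  vary only between environments; with 14 environments and ~1800 windows
  the maximum chance |r| (~0.85) exceeds the correlation of each of two
  additive drivers with the combined environment effect (~0.71), so no
  attribution method can separate them reliably. The forest/SHAP recovery
  test therefore uses a homogeneous-region trial with 70 environments and
  plants the two factors that have no derived-index aliases (humidity and
  wind); under those conditions both 15-day windows are recovered at
  day-range Jaccard ≥ 0.5 in 18/20 seeds while selecting < 3% of the 1898
  windows. The feature-selection benefit (median cross-environment R²
  delta over 10 seeds, ≈ +0.6) is tested at the standard 14 environments,
  where selection denoises prediction even when per-factor attribution is
  ambiguous.

Forests also cannot extrapolate environment-level window means beyond the
training range (piecewise-constant predictions), capping their pooled
cross-environment PCC near 0.85–0.90 even on noise-free causal features
where a linear model reaches 0.95+; the harness's model registry makes
such comparisons one-liners.

## Problem sizes

The test suite and the acceptance script run on scaled-down trials chosen
to keep each experiment's statistics stable while staying lightweight:
3–60 lines, 6–70 environments, 300–500 markers, 500-tree forests. The
published-table arithmetic uses the printed sums of squares directly and
involves no simulation.
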