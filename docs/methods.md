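# Methods

## The latent threshold model

Self-reported walking pace is observed as three ordered categories
(slow / steady / brisk). The package treats the category `D` as a coarsening
of an unobserved continuous pace `L ~ N(mu_L, sigma_L^2)` in miles per hour,
with fixed thresholds at 3 and 4 mph. Two identities carry the whole
analysis:

1. **Latent SD.** `sigma_L = (t2 - t1) / (PhiInv(pi0 + pi1) - PhiInv(pi0))`,
   with `pi_k` the marginal category proportions. A covariate-adjusted
   variant reads the residual latent SD off the cutpoint gap of an ordered
   probit of `D` on covariates (`sigma_L_from_cutpoints`); on the published
   category split the marginal formula gives 0.588 mph. Both are exposed
   because the two routes differ slightly in real data and the choice is an
   analysis decision, not a model fact.
2. **Latent rescaling.** A standardised genetic effect `beta_G` becomes a
   per-mph effect via `beta_L = beta_G / (theta * sigma_L)`, where `theta^2`
   is the proportion of latent variance explained by the instruments.
   `theta^2` is treated as a sensitivity parameter on the grid
   {0.0050, 0.0072, 0.0100}; `observed_to_latent_r2` maps a variance
   explained on the observed 0/1/2 coding to the latent scale through
   `theta2 = r2_obs * Var(D) / (phi(t1*) + phi(t2*))^2` with standardised
   thresholds `t*`, validated by Monte-Carlo rather than by citation.

## Estimation

**Ordered probit.** Hand-implemented Newton–Raphson with analytic gradient
and observed Hessian, cutpoints parameterised as `(c1, log(c2 - c1))` to
keep the ordering unconstrained, step-halving line search, and standard
errors from the observed information. The line-search acceptance slack
tracks float rounding of the log-likelihood sum (`1e-10 * |loglik|`) so
terminal Newton steps are not rejected on large cohorts; convergence is
declared at a score max-norm below 1e-6. A per-SNP scan warm-starts every
variant's fit from the covariate-only fit, which keeps a 65-variant scan on
a 50k cohort under two seconds. statsmodels' `OrderedModel` serves as an
independent cross-check in the tests, never as the implementation.

**One-sample MR.** Linear predictor of the joint 65-variant probit
(genetic part only), standardised to unit SD; Cox proportional hazards
(lifelines, Efron ties) or logistic regression of the event on the score
with covariate adjustment; latent rescaling as above. The bootstrap
resamples individuals and refits the probit stage inside every resample
(full-procedure bootstrap — the conservative reading when the score's
estimation error matters). The proportional-hazards diagnostic is the
Pearson correlation between scaled Schoenfeld residuals of the score and
rank-normalised log follow-up time, with Blom offsets `(r - 3/8)/(n + 1/4)`
for the rank normalisation.

**Two-sample MR.** Wald-ratio based estimators on harmonised summary
statistics:

- *IVW* with first-order weights `(alpha_hat/se_b)^2` and a multiplicative
  random-effects SE inflation `sqrt(Q/(J-1))` whenever Cochran's Q exceeds
  its degrees of freedom (never narrows the CI).
- *Weighted median* by linear interpolation on the midpoint
  cumulative-weight grid; SE from 1000 seed-controlled parametric bootstrap
  draws of `(alpha_hat, b)`.
- *MR-Egger* as weighted regression with free intercept after orienting all
  variants to positive exposure effects; residual variance floored at 1
  (multiplicative random effects); a warning attaches when the spread of
  instrument strengths is too small for the slope to be well identified.
- *RAPS* in its simple (non-Huberised) form: the nuisance-profiled
  objective `-(1/2) sum (b - beta*alpha_hat)^2 / (se_b^2 + beta^2 se_a^2 +
  tau^2)`, which deliberately has **no** log-determinant term in the slope
  direction — including one would reintroduce the weak-instrument shrinkage
  the method exists to remove — while the overdispersion `tau^2 >= 0` is
  updated from the full marginal normal likelihood; slope and tau^2 are
  iterated to convergence and the SE comes from the profile curvature.

Standardisation uses `beta_G = sqrt(sum alpha_hat_j^2 * 2 f_j(1-f_j)) *
beta` exactly as defined, i.e. with the *estimated* exposure effects; at low
instrument strength the estimation noise in `alpha_hat^2` inflates this
factor by roughly `sqrt(1 + 1/F_mean)`, which partially offsets the
regression-dilution of the IVW slope. This interplay is a property of the
published procedure, not of this implementation.

**Steiger filtering.** Classical correlated-correlations Z (the pooled
Z-bar-1* variant, common-index case) on *signed* correlations; a variant is
flagged when the two-sided P is below the suggestive threshold (0.05) AND
its trait correlation exceeds its exposure correlation in magnitude. An
earlier design compared folded magnitudes directly, but folding makes the
null distribution conservative whenever correlations sit within about two
sampling SDs of zero — the typical GWAS regime — so the signed statistic,
which is exactly calibrated under the exchangeable null, is used with the
magnitude condition kept in the flag rule. Consequence: under the null the
two-sided rejection rate equals the threshold while the *directional* flag
rate is half of it. Binary traits enter through point-biserial (numeric
Pearson) correlation. Multiple traits are tested without multiplicity
adjustment, matching the suggestive-threshold usage.

**Mediation.** LD-free mtCOJO conditioning of the outcome effects
(`b_zy|m = b_zy - b_zm * beta_my`, delta-method SE), a mediator-conditional
ordered-probit exposure scan, and the difference method on the log-odds
scale: `indirect = log OR_total - log OR_direct`, proportion mediated
`indirect/total`. The mediator→outcome effect `beta_my` is itself an IVW
estimate on a separate mediator instrument panel. Bootstrap CIs draw total
and direct as independent Gaussians (their joint resampling scheme being
unspecified, independence is the conservative assumption and is flagged as
such). The full conditional-LD mtCOJO machinery is out of scope because the
instruments are clumped to independence by construction.

**Clumping.** Greedy: sort by ascending P (ties by chromosome, position,
id — determinism matters for testing), accept iff P below threshold, r^2 at
most 0.001 against every accepted variant, and distance above 10,000 kb on
the same chromosome, applied pairwise to accepted variants.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes —
not any individual-level data:

- Hardy–Weinberg `Binomial(2, f)` genotypes, LD-free (instruments are
  clumped to r^2 <= 0.001 in the application, so LD would be inert); an
  optional Gaussian-copula block-LD mode exists solely to exercise clumping.
- Latent pace with defaults `sigma_L = 0.588`, `mu_L = 3.863` chosen to
  reproduce the 7.1/52.1/40.8% category split exactly; per-variant effects
  drawn with magnitudes uniform in a ~2.4-fold range (random signs) and
  rescaled so the instruments explain exactly `theta2_true` of the latent
  variance — the generated `theta^2` is constructed, not estimated.
- A single standard-normal confounder loading on both the exposure
  (0.15 mph) and the outcome linear predictor (0.30 log-hazard): enough to
  bias the naive association visibly while leaving the instruments valid.
- A BMI-like mediator (mean 27.3, SD 4.7) downstream of the latent exposure
  with slope −3 kg/m^2 per mph, its own 40-variant panel explaining 2% of
  its variance, and a configurable mediated share `s`: the outcome linear
  predictor carries `(1-s) * beta_L` directly and `s * beta_L` through the
  mediator, so direct and mediated parts sum exactly on the log scale.
  With `s = 0` the mediator is generated independent of the exposure, so
  "no mediation" also means "no exposure–mediator association".
- Exponential proportional-hazards events with uniform entry over two years
  (administrative censoring in [10, 12] years) and baseline hazard 0.00158
  per year, calibrated once so the default cohort has a ~2.9% event rate;
  age (0.07 log-hazard/year) and sex effects provide realistic covariate
  structure. The exponential choice is a stand-in — the real event-time
  distribution is characterised only by its median follow-up — and the
  event indicator doubles as the cumulative-incidence outcome for the
  logistic analyses (log-OR ≈ log-HR at this event rate).
- Optional "reverse" variants that carry no exposure effect but act
  directly on the mediator (0.05% of its variance each): the planted
  outcome-first instruments that Steiger filtering should catch.
- All randomness flows from one integer seed through `SeedSequence`
  spawning; two-cohort generation shares the population-level quantities
  (frequencies, variant effects, mediator and pleiotropy effects) and draws
  individuals independently.

What passing tests on this generator do **not** show: robustness to LD
between instruments, to population stratification beyond noise covariates,
to assortative mating or dynastic effects, to individual-specific reporting
thresholds (misclassification), or to real event-time distributions with
non-constant baseline hazards.

## Validation design and problem sizes

The quantitative contracts are checked at three levels:

1. **Exact identities** — theta^2-grid rescaling of published ratios,
   difference-method worked examples, the latent-SD formula on the
   published category split — asserted to printed precision.
2. **Oracle equivalences** — probit MLE vs an independent dense grid
   search, IVW vs explicit weighted least squares (1e-12), weighted median
   vs brute-force cumulative-weight interpolation, clumping vs an
   independent exhaustive greedy loop.
3. **Statistical properties on synthetic cohorts** — chosen sizes:
   estimator recovery runs 40 replicate pairs of 50,000-individual cohorts
   with 65 instruments and the per-variant effects scaled so mean
   instrument F ≈ 38, inside the application's 10.8–70.7 range; keeping
   that F regime at a reduced cohort size requires a larger generated
   `theta^2` (0.05), because instrument strength scales with `n *
   theta^2 / J` and ratio-based estimators acquire textbook
   weak-instrument dilution (~15% here) once mean F drops to ~5 — a
   finite-size artefact the full-size study does not have. Mediation
   recovery uses 24 replicate pairs of 20,000 (same F logic) and compares
   the ratio of mean effects to the generated share with a jackknife SE,
   because per-replicate ratios of noisy log-odds are heavy-tailed.
   Calibration checks use 400 summary-level replicates (Egger intercept),
   1,500 vectorised draws (Steiger null), and 60 cohort replicates
   (Schoenfeld P uniformity). Tolerances are 3 Monte-Carlo SEs of the
   replicate mean throughout — they tighten or widen with the replicate
   count rather than being tuned constants.

## Known limitations

- The probit scan refits each variant separately (no score-test shortcut);
  fine to ~1e5 x 200, not genome-scale.
- RAPS is the simple profile variant: no Huber/Tukey robustification, so
  single gross outliers are better handled by the weighted median here.
- The weighted-median SE is parametric-bootstrap only.
- `sigma_L` estimation assumes all three categories are populated; cohorts
  missing an outer category have no identified latent scale.
- No support for more than 3 exposure categories in this version.
- Mediation CIs assume independent total and direct estimates; with both
  derived from overlapping instrument sets the truth is positively
  correlated differences, making the reported intervals conservative.
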