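# latentmr

Mendelian randomisation for **coarsened ordinal exposures**, built around a
latent-variable threshold model. The motivating application is self-reported
walking pace — recorded only as *slow*, *steady/average* or *brisk* — as an
exposure for coronary artery disease, where per-category causal effect
estimates are ill-defined and a latent continuous exposure in physical units
(miles per hour) is the interpretable estimand.

## The model

An unobserved continuous exposure `L ~ N(mu_L, sigma_L^2)` (mph) is reported
as an ordered category `D` via fixed thresholds:

```
D = 0  if L <= 3 mph,   D = 1  if 3 < L <= 4 mph,   D = 2  if L > 4 mph
```

The category frequencies `pi_k` identify the latent SD through the spacing of
the thresholds in quantile units:

```
sigma_L = (4 - 3) / (PhiInv(pi0 + pi1) - PhiInv(pi0))
```

Genetic instruments enter through ordered **probit** regression of `D`; a
causal estimate `beta` on the probit/outcome scale is standardised by the
genetic share of the latent exposure and moved to per-mph units:

```
beta_G = sqrt( sum_j alpha_hat_j^2 * 2 f_j (1 - f_j) ) * beta
beta_L = beta_G / (theta * sigma_L)
```

where `theta^2` — the proportion of latent variance explained by the
instruments — is a sensitivity parameter varied over a grid (default 0.0050,
0.0072, 0.0100). `exp(beta_L)` is then a hazard or odds ratio per 1 mph.

The package implements, as scikit-learn-style estimators with thin
functional wrappers:

- `OrderedProbit` — Newton–Raphson ordered probit MLE plus a fast per-SNP
  ordinal association scan (`per_snp_scan`);
- `OneSampleMR` — genetic score → standardise → Cox proportional hazards
  (or logistic) → latent rescaling, with a full-procedure bootstrap and a
  Schoenfeld-residual proportional-hazards diagnostic;
- `IVW`, `WeightedMedian`, `Egger`, `RAPS` — two-sample summary-statistic
  estimators with allele harmonisation (`harmonise`) and latent-scale
  standardisation;
- `steiger_test` / `filter_instruments` — directionality filtering via the
  correlated-correlations Z test;
- `mtcojo_adjust`, `condition_exposure`, `difference_method` — mediation
  through a BMI-like mediator on the log-odds scale;
- `clump` — greedy P-value / LD / distance instrument selection;
- a synthetic-cohort generator (`simulate_cohort`, `simulate_two_cohorts`)
  that emulates the statistical structure of the application: ~7.1/52.1/40.8%
  category split, 65 independent instruments, ~2.9% event rate over ~12
  years, shared confounding, and a configurable mediated share.

## Worked example

`examples/demo.yaml` simulates two disjoint cohorts of 20,000 individuals
(instrument effects scaled to explain 5% of latent variance so a single run
at this size is informative; true latent OR 0.38 per mph; 45% of the effect
routed through the mediator) and runs the full pipeline:

```
latentmr -v all --config examples/demo.yaml
latentmr report demo_results/results.json
```

which prints (output of the run with `seed: 7`):

```
config f14aaff8ec61 seed 7  sigma_L=0.587

One-sample (hazard ratios per 1 mph):
  all      theta2=0.0500  HR 0.36 (0.19-0.68)  P=0.0014
  steiger  theta2=0.0500  HR 0.37 (0.20-0.69)  P=0.0019

Two-sample (odds ratios per 1 mph):
  all      ivw              theta2=0.0500  OR 0.52 (0.27-1.01)
  all      weighted_median  theta2=0.0500  OR 0.55 (0.22-1.40)
  all      raps             theta2=0.0500  OR 0.49 (0.25-0.96)
  all      egger            theta2=0.0500  OR 0.57 (0.06-5.15)
  ...

Mediation (difference method):
  theta2=0.0500  total OR 0.52 direct OR 0.64  indirect OR 0.81
  proportion mediated 32% (-317-174%)
```

Reading the output: `sigma_L=0.587` is the latent SD recovered from the
simulated category split; the one-sample HR 0.36 (0.19–0.68) brackets the
generating value of 0.38 per mph; the two-sample estimators agree with each
other within their (wider) uncertainties; and the mediation stage attributes
roughly a third of the total effect to the mediator at this cohort size (the
generating share is 45%, and the wide bootstrap interval shows how little
information a 20k-cohort carries about that ratio).

Every stage is also callable as a library function — see the docstrings in
`latentmr.onesample`, `latentmr.twosample` and `latentmr.mediation` — and as
individual CLI subcommands (`simulate`, `clump`, `onesample`, `twosample`,
`steiger`, `mediate`, `report`).

## Documentation

`docs/methods.md` describes the model, the generator's design and its
limitations, and the numerical choices in detail.
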