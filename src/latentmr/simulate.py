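"""Synthetic individual-level cohorts with the structure the analysis assumes.

The generator emulates a biobank-style cohort in which:

* ``n_snps`` independent Hardy-Weinberg variants carry small additive effects
  on a latent continuous walking pace ``L`` (mph), together explaining a
  fixed share ``theta2_true`` of its variance;
* ``L ~ N(mu_L, sigma_L^2)`` is reported only as a 3-category pace
  (slow / steady / brisk) via thresholds at 3 and 4 mph, with default
  parameters chosen so the category frequencies are about 7.1 / 52.1 / 40.8%;
* a BMI-like mediator sits downstream of ``L`` and carries a configurable
  share of its effect on the outcome;
* the outcome is an exponential proportional-hazards event (coronary artery
  disease analogue) with uniform-entry administrative censoring, with the
  baseline hazard calibrated so roughly 2.9% of individuals have an event
  over ~12 years of follow-up;
* a shared standard-normal confounder loads on both ``L`` and the outcome,
  so the naive exposure-outcome association is biased while the genetic
  instruments are not.

A second, disjoint cohort plus :func:`export_summary_stats` provides the
two-sample design: probit per-SNP exposure effects from one half, logistic
log-odds outcome effects from the other.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import linear_scan, logistic_scan
from .ordinal import per_snp_scan

__all__ = [
    "SimulationConfig",
    "Cohort",
    "simulate_genotypes",
    "simulate_latent_and_categories",
    "simulate_mediator_and_outcome",
    "simulate_cohort",
    "simulate_two_cohorts",
    "export_summary_stats",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
]

# Defaults reproducing the target category split (7.1 / 52.1 / 40.8%)
_TARGET_PI = (0.071, 0.521, 0.408)
_Z0 = stats.norm.ppf(_TARGET_PI[0])
_Z1 = stats.norm.ppf(_TARGET_PI[0] + _TARGET_PI[1])
DEFAULT_SIGMA_L = float(1.0 / (_Z1 - _Z0))  # ~0.588 mph
DEFAULT_MU_L = float(3.0 - DEFAULT_SIGMA_L * _Z0)  # ~3.863 mph

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Effects are on the scales used throughout the analysis: per-SNP latent
    effects ``alpha`` in mph per allele, the causal effect ``beta_L_true`` in
    log-hazard (equivalently, at this event rate, log-odds) per mph, the
    mediator slope in mediator units (kg/m^2) per mph.
    """

    n_individuals: int = 50_000
    n_snps: int = 65
    allele_freq_range: tuple[float, float] = (0.10, 0.90)
    alpha: np.ndarray | None = None  # per-SNP mph/allele; auto-scaled if None
    theta2_true: float = 0.0072
    mu_L: float = DEFAULT_MU_L
    sigma_L_true: float = DEFAULT_SIGMA_L
    thresholds: tuple[float, float] = (3.0, 4.0)
    beta_L_true: float = float(np.log(0.38))
    mediator_share: float = 0.45
    confounder_effect: tuple[float, float] = (0.15, 0.30)  # loadings on L, outcome
    pleiotropy_sd: float = 0.0  # SD of direct SNP->outcome log-hazard effects
    baseline_hazard: float = 0.00158  # events/year; calibrated to ~2.9% over 12y
    followup_years: float = 12.0
    seed: int = 0
    # mediator (BMI analogue)
    n_mediator_snps: int = 40
    mediator_r2: float = 0.02  # variance of mediator explained by its own SNPs
    mediator_mean: float = 27.3
    mediator_sd: float = 4.7
    mediator_slope: float = -3.0  # kg/m^2 per mph of latent pace
    # instruments that act on the mediator instead of the exposure
    n_reverse_snps: int = 0
    reverse_snp_r2: float = 0.0005  # mediator variance share per reverse SNP
    # population-level per-SNP effects, fixed across cohorts when supplied
    mediator_effects: np.ndarray | None = None  # length n_snps + n_mediator_snps
    pleiotropy_effects: np.ndarray | None = None
    # covariate effects
    age_effect_L: float = -0.012  # mph per year of age
    age_effect_outcome: float = 0.07  # log-hazard per year
    sex_effect_outcome: float = -0.4  # log-hazard for female vs male
    # optional block LD for clumping tests: list of (start, stop, r)
    ld_blocks: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"allele_freq_range must be within [0, 1], got {self.allele_freq_range}"
            )
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ConfigurationError("n_individuals and n_snps must be >= 1")
        if self.sigma_L_true <= 0:
            raise ConfigurationError("sigma_L_true must be positive")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ConfigurationError("thresholds must be strictly increasing")
        if not 0.0 <= self.theta2_true < 1.0:
            raise ConfigurationError("theta2_true must lie in [0, 1)")
        if not 0.0 <= self.mediator_share <= 1.0:
            raise ConfigurationError("mediator_share must lie in [0, 1]")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline_hazard must be non-negative")
        if self.n_reverse_snps > self.n_snps:
            raise ConfigurationError("n_reverse_snps cannot exceed n_snps")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Cohort:
    """Individual-level synthetic cohort plus per-variant truth metadata."""

    genotypes: np.ndarray  # (n, n_snps + n_mediator_snps) allele counts
    snps: pd.DataFrame  # id, chrom, pos, effect/other allele, freq, role, truths
    data: pd.DataFrame  # phenotypes and covariates, one row per individual
    config: SimulationConfig

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def instrument_index(self) -> np.ndarray:
        return np.flatnonzero(self.snps["role"].isin(["instrument", "reverse"]))

    @property
    def mediator_index(self) -> np.ndarray:
        return np.flatnonzero(self.snps["role"] == "mediator")

    @property
    def instrument_genotypes(self) -> np.ndarray:
        return self.genotypes[:, self.instrument_index]

    @property
    def covariate_matrix(self) -> np.ndarray:
        return self.data[["age", "sex", "pc1", "pc2"]].to_numpy(float)

    @property
    def theta2_generated(self) -> float:
        """Exact share of latent variance explained by the instruments.

        Computed from the constructed per-SNP effects and drawn frequencies,
        so it matches ``theta2_true`` identically when ``alpha`` was
        auto-scaled.
        """
        ins = self.snps[self.snps["role"].isin(["instrument", "reverse"])]
        var_g = float(
            (ins["true_alpha"] ** 2 * 2.0 * ins["freq"] * (1.0 - ins["freq"])).sum()
        )
        return var_g / self.config.sigma_L_true**2

    def to_table(self, path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)

    @property
    def event_rate(self) -> float:
        return float(self.data["event_indicator"].mean())


def _spawn(seed: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator, n_snps: int | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Hardy-Weinberg genotypes: allele counts ``Binomial(2, f_j)`` per variant.

    Returns the ``(n, m)`` allele-count matrix and the drawn frequencies.
    When ``config.ld_blocks`` is set, variants inside each block are generated
    from a Gaussian copula with the requested haplotype correlation (used only
    to exercise LD clumping).
    """
    m = config.n_snps if n_snps is None else n_snps
    lo, hi = config.allele_freq_range
    if freqs is not None:
        f = np.asarray(freqs, dtype=float)
        if f.shape != (m,):
            raise ConfigurationError("freqs must have one entry per variant")
    elif hi > lo:
        f = rng.uniform(lo, hi, size=m)
    else:
        f = np.full(m, float(lo))
    n = config.n_individuals
    G = rng.binomial(2, f, size=(n, m)).astype(np.int8)
    for start, stop, r in config.ld_blocks:
        if stop > m:
            raise ConfigurationError(f"ld block {(start, stop)} outside 0..{m}")
        k = stop - start
        cov = np.full((k, k), r) + (1.0 - r) * np.eye(k)
        chol = np.linalg.cholesky(cov)
        block = np.zeros((n, k), dtype=np.int8)
        for _hap in range(2):
            z = rng.standard_normal((n, k)) @ chol.T
            block += (z < stats.norm.ppf(f[start:stop])).astype(np.int8)
        G[:, start:stop] = block
    return G, f


def _resolve_alpha(config: SimulationConfig, f: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-SNP latent effects (mph/allele) scaled so the instruments explain
    exactly ``theta2_true`` of the latent variance; reverse variants get 0."""
    m = config.n_snps
    if config.alpha is not None:
        alpha = np.asarray(config.alpha, dtype=float)
        if alpha.shape != (m,):
            raise ConfigurationError("alpha must have length n_snps")
        return alpha
    mag = rng.uniform(0.5, 1.2, size=m)
    sign = rng.choice([-1.0, 1.0], size=m)
    alpha = mag * sign
    if config.n_reverse_snps:
        alpha[m - config.n_reverse_snps:] = 0.0
    var_unit = np.sum(alpha**2 * 2.0 * f[:m] * (1.0 - f[:m]))
    target = config.theta2_true * config.sigma_L_true**2
    if var_unit > 0 and target > 0:
        alpha *= np.sqrt(target / var_unit)
    elif target == 0:
        alpha[:] = 0.0
    return alpha


def simulate_latent_and_categories(
    genotypes: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    alpha: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    age: np.ndarray | None = None,
    confounder: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent exposure ``L`` and its 3-category coarsening.

    ``L`` is the sum of the centred genetic score, an age trend, the shared
    confounder and a normal residual sized so ``Var(L) = sigma_L_true^2``.
    """
    if config.sigma_L_true <= 0:
        raise ConfigurationError("sigma_L_true must be positive")
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if alpha is None:
        alpha = _resolve_alpha(config, G.mean(axis=0) / 2.0, rng)
    if freqs is None:
        freqs = G.mean(axis=0) / 2.0
    gvalue = (G - 2.0 * freqs) @ alpha
    c_L = config.confounder_effect[0]
    var_age = (config.age_effect_L * 8.0) ** 2
    var_g = float(np.sum(alpha**2 * 2.0 * freqs * (1.0 - freqs)))
    var_resid = config.sigma_L_true**2 - var_g - c_L**2 - var_age
    if var_resid <= 0:
        raise ConfigurationError(
            "sigma_L_true^2 smaller than the structural variance components"
        )
    age_term = (
        config.age_effect_L * (age - 57.1) if age is not None else np.zeros(n)
    )
    conf = confounder if confounder is not None else rng.standard_normal(n)
    L = (
        config.mu_L
        + gvalue
        + age_term
        + c_L * conf
        + np.sqrt(var_resid) * rng.standard_normal(n)
    )
    t1, t2 = config.thresholds
    D = np.digitize(L, [t1, t2]).astype(np.int8)
    return L, D


def simulate_mediator_and_outcome(
    cohort: Cohort, config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Attach mediator, event time and indicator to a cohort in place.

    Total log-hazard per mph of latent exposure is ``beta_L_true``; the share
    ``mediator_share`` flows through the mediator (direct plus mediated parts
    sum exactly on the log scale).  Events are exponential given the linear
    predictor with uniform-entry administrative censoring.
    """
    config = config or cohort.config
    rng = rng or _spawn(config.seed, 3)
    if config.baseline_hazard < 0:
        raise ConfigurationError("baseline_hazard must be non-negative")
    df = cohort.data
    n = cohort.n
    L = df["latent_exposure"].to_numpy()
    conf = df["confounder"].to_numpy()

    # mediator: downstream of L plus its own genetic component
    snps = cohort.snps
    med_idx = cohort.mediator_index
    rev_mask = (snps["role"] == "reverse").to_numpy()
    # with no mediated share the mediator is generated independent of the
    # exposure (pure genetics + noise), so direct and total effects coincide
    gamma = config.mediator_slope if config.mediator_share > 0 else 0.0
    var_m = config.mediator_sd**2
    if config.mediator_effects is not None:
        delta_med = np.asarray(config.mediator_effects, dtype=float)
        if delta_med.shape != (len(snps),):
            raise ConfigurationError(
                "mediator_effects must have one entry per variant"
            )
    else:
        delta_med = np.zeros(len(snps))
        if med_idx.size:
            f_med = snps["freq"].to_numpy()[med_idx]
            per_snp_var = config.mediator_r2 * var_m / med_idx.size
            delta = np.sqrt(per_snp_var / (2.0 * f_med * (1.0 - f_med)))
            delta *= rng.choice([-1.0, 1.0], size=med_idx.size)
            delta_med[med_idx] = delta
        if rev_mask.any():
            f_rev = snps["freq"].to_numpy()[rev_mask]
            delta_med[rev_mask] = np.sqrt(
                config.reverse_snp_r2 * var_m / (2.0 * f_rev * (1.0 - f_rev))
            ) * rng.choice([-1.0, 1.0], size=int(rev_mask.sum()))
    med_gen = np.zeros(n)
    nz = np.flatnonzero(delta_med)
    if nz.size:
        f_nz = snps["freq"].to_numpy()[nz]
        med_gen = (cohort.genotypes[:, nz].astype(float) - 2.0 * f_nz) @ delta_med[nz]
    var_gen_m = float(np.sum(
        delta_med**2 * 2.0 * snps["freq"].to_numpy()
        * (1.0 - snps["freq"].to_numpy())
    ))
    var_resid_m = var_m - gamma**2 * config.sigma_L_true**2 - var_gen_m
    if var_resid_m <= 0:
        raise ConfigurationError("mediator_sd^2 smaller than structural components")
    M = (
        config.mediator_mean
        + gamma * (L - config.mu_L)
        + med_gen
        + np.sqrt(var_resid_m) * rng.standard_normal(n)
    )

    # outcome: exponential PH
    s = config.mediator_share
    beta_direct = (1.0 - s) * config.beta_L_true
    beta_m = s * config.beta_L_true / gamma if gamma != 0 else 0.0
    pleio = np.zeros(n)
    if config.pleiotropy_effects is not None:
        pleio_effects = np.asarray(config.pleiotropy_effects, dtype=float)
        if pleio_effects.shape != (len(snps),):
            raise ConfigurationError(
                "pleiotropy_effects must have one entry per variant"
            )
    else:
        pleio_effects = np.zeros(len(snps))
        if config.pleiotropy_sd > 0:
            idx = cohort.instrument_index
            pleio_effects[idx] = rng.normal(0.0, config.pleiotropy_sd,
                                            size=idx.size)
    nzp = np.flatnonzero(pleio_effects)
    if nzp.size:
        f_i = snps["freq"].to_numpy()[nzp]
        pleio = (cohort.genotypes[:, nzp].astype(float) - 2.0 * f_i) @ pleio_effects[nzp]
    lp = (
        beta_direct * (L - config.mu_L)
        + beta_m * (M - config.mediator_mean)
        + config.confounder_effect[1] * conf
        + pleio
        + config.age_effect_outcome * (df["age"].to_numpy() - 57.1)
        + config.sex_effect_outcome * (df["sex"].to_numpy() - 0.546)
    )
    hazard = config.baseline_hazard * np.exp(lp)
    with np.errstate(divide="ignore"):
        t_event = rng.exponential(1.0, size=n) / np.where(hazard > 0, hazard, np.nan)
    t_event = np.where(np.isnan(t_event), np.inf, t_event)
    # uniform entry over 2 years -> administrative censoring in [fu-2, fu]
    censor = config.followup_years - rng.uniform(0.0, 2.0, size=n)
    event = (t_event <= censor).astype(np.int8)
    time = np.minimum(t_event, censor)

    df["mediator"] = M
    df["event_time"] = time
    df["event_indicator"] = event
    cohort.snps["true_mediator_effect"] = delta_med
    cohort.snps["true_pleiotropy"] = pleio_effects
    return cohort


def _draw_alleles(m: int, rng: np.random.Generator):
    """Non-palindromic allele pairs (palindromes are built by tests directly)."""
    ea, oa = [], []
    for _ in range(m):
        a = _BASES[rng.integers(4)]
        choices = [b for b in _BASES if b not in (a, _COMPLEMENT[a])]
        ea.append(a)
        oa.append(choices[rng.integers(2)])
    return ea, oa


def simulate_cohort(config: SimulationConfig, seed: int | None = None,
                    id_offset: int = 0, freqs: np.ndarray | None = None) -> Cohort:
    """Generate a full cohort: genotypes, covariates, exposure, mediator, outcome."""
    seed = config.seed if seed is None else seed
    rng_g = _spawn(seed, 1)
    rng_p = _spawn(seed, 2)
    rng_o = _spawn(seed, 3)
    n = config.n_individuals
    m_total = config.n_snps + config.n_mediator_snps
    G, f = simulate_genotypes(config, rng_g, n_snps=m_total, freqs=freqs)
    alpha_ins = _resolve_alpha(config, f, rng_g)
    alpha = np.concatenate([alpha_ins, np.zeros(config.n_mediator_snps)])

    roles = ["instrument"] * (config.n_snps - config.n_reverse_snps)
    roles += ["reverse"] * config.n_reverse_snps
    roles += ["mediator"] * config.n_mediator_snps
    ea, oa = _draw_alleles(m_total, rng_g)
    snps = pd.DataFrame(
        {
            "snp": [f"rs{j + 1:05d}" for j in range(m_total)],
            "chrom": (np.arange(m_total) % 22) + 1,
            "pos": rng_g.integers(1, 2_000_000_00, size=m_total),
            "effect_allele": ea,
            "other_allele": oa,
            "freq": f,
            "role": roles,
            "true_alpha": alpha,
        }
    )

    age = rng_p.normal(57.1, 8.0, size=n)
    sex = (rng_p.random(n) < 0.546).astype(np.int8)  # 1 = female
    pc1, pc2 = rng_p.standard_normal(n), rng_p.standard_normal(n)
    confounder = rng_p.standard_normal(n)
    L, D = simulate_latent_and_categories(
        G[:, : config.n_snps], config, rng_p, alpha=alpha_ins,
        freqs=f[: config.n_snps], age=age, confounder=confounder,
    )
    data = pd.DataFrame(
        {
            "id": np.arange(id_offset, id_offset + n),
            "age": age,
            "sex": sex,
            "pc1": pc1,
            "pc2": pc2,
            "confounder": confounder,
            "latent_exposure": L,
            "exposure_category": D,
        }
    )
    cohort = Cohort(genotypes=G, snps=snps, data=data, config=config)
    return simulate_mediator_and_outcome(cohort, config, rng_o)


def simulate_two_cohorts(config: SimulationConfig, seed: int | None = None
                         ) -> tuple[Cohort, Cohort]:
    """Disjoint exposure and outcome cohorts sharing the same variant panel.

    Both cohorts are drawn with the same variant frequencies and true effects
    (same variant metadata) but independent individuals, mimicking two
    non-overlapping samples from one population.
    """
    seed = config.seed if seed is None else seed
    exp = simulate_cohort(config, seed=seed, id_offset=0)
    out_cfg = config.replace(
        alpha=np.asarray(exp.snps["true_alpha"][: config.n_snps]),
        mediator_effects=exp.snps["true_mediator_effect"].to_numpy(),
        pleiotropy_effects=exp.snps["true_pleiotropy"].to_numpy(),
    )
    out = simulate_cohort(
        out_cfg, seed=seed + 1, id_offset=config.n_individuals,
        freqs=exp.snps["freq"].to_numpy(),
    )
    # same panel: identical variant identities in both samples
    for col in ("snp", "effect_allele", "other_allele", "chrom", "pos"):
        out.snps[col] = exp.snps[col].to_numpy()
    return exp, out


def export_summary_stats(
    cohort_exposure: Cohort,
    cohort_outcome: Cohort,
    adjust_covariates: bool = True,
    which: str = "instrument",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample summary statistics from two disjoint cohorts.

    The exposure half is an ordered-probit per-SNP scan of the 3-category
    exposure; the outcome half is a per-SNP logistic scan of the event
    indicator (cumulative incidence over follow-up).  ``which`` selects the
    ``"instrument"`` panel (exposure instruments, including any reverse
    variants) or the ``"mediator"`` panel.
    """
    shared = np.intersect1d(
        cohort_exposure.data["id"].to_numpy(), cohort_outcome.data["id"].to_numpy()
    )
    if shared.size:
        raise ValueError(
            f"cohorts share {shared.size} individuals; the two-sample design "
            "requires non-overlapping samples"
        )
    if which == "instrument":
        idx_e = cohort_exposure.instrument_index
        idx_o = cohort_outcome.instrument_index
    elif which == "mediator":
        idx_e = cohort_exposure.mediator_index
        idx_o = cohort_outcome.mediator_index
    else:
        raise ValueError("which must be 'instrument' or 'mediator'")
    meta_e = cohort_exposure.snps.iloc[idx_e]
    meta_o = cohort_outcome.snps.iloc[idx_o]
    cov_e = cohort_exposure.covariate_matrix if adjust_covariates else None
    cov_o = cohort_outcome.covariate_matrix if adjust_covariates else None

    if which == "instrument":
        exposure = per_snp_scan(
            cohort_exposure.genotypes[:, idx_e].astype(float),
            cohort_exposure.data["exposure_category"].to_numpy(),
            cov_e,
            snp_ids=meta_e["snp"], effect_alleles=meta_e["effect_allele"],
            other_alleles=meta_e["other_allele"],
        )
    else:
        exposure = linear_scan(
            cohort_exposure.genotypes[:, idx_e].astype(float),
            cohort_exposure.data["mediator"].to_numpy(),
            cov_e,
            snp_ids=meta_e["snp"], effect_alleles=meta_e["effect_allele"],
            other_alleles=meta_e["other_allele"],
        )
    outcome = logistic_scan(
        cohort_outcome.genotypes[:, idx_o].astype(float),
        cohort_outcome.data["event_indicator"].to_numpy(),
        cov_o,
        snp_ids=meta_o["snp"], effect_alleles=meta_o["effect_allele"],
        other_alleles=meta_o["other_allele"],
    )
    return exposure, outcome


def write_genotypes_vcf(cohort: Cohort, path) -> None:
    """Minimal VCF-like text export (CHROM, POS, ID, REF, ALT, GT columns)."""
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tID\tREF\tALT\t" +
                 "\t".join(str(i) for i in cohort.data["id"]) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in cohort.snps.iterrows():
            gts = "\t".join(gt_codes[int(g)] for g in cohort.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp}\t{row.other_allele}\t"
                f"{row.effect_allele}\t{gts}\n"
            )


def read_genotypes_vcf(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read the minimal VCF-like text form back into allele counts + metadata."""
    meta_rows, geno_rows = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[5:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            meta_rows.append(parts[:5])
            geno_rows.append([gt.count("1") for gt in parts[5:]])
    meta = pd.DataFrame(
        meta_rows, columns=["chrom", "pos", "snp", "other_allele", "effect_allele"]
    )
    meta["chrom"] = meta["chrom"].astype(int)
    meta["pos"] = meta["pos"].astype(int)
    G = np.array(geno_rows, dtype=np.int8).T
    return G, meta
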