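"""Summary-statistic mediation through a continuous mediator (BMI analogue).

The difference method on the log-odds scale: with a *total* effect of the
latent exposure on the outcome and a *direct* effect estimated after
conditioning both sides of the MR on the mediator —

* SNP-exposure effects refitted with the mediator as an extra ordered-probit
  covariate (:func:`condition_exposure`);
* SNP-outcome effects adjusted by the LD-free mtCOJO identity
  ``b_zy|m = b_zy - b_zm * beta_my`` (:func:`mtcojo_adjust`), where
  ``beta_my`` is the mediator's causal effect on the outcome estimated by
  IVW on a separate mediator instrument set —

the indirect effect is ``log OR_total - log OR_direct`` and the proportion
mediated is their ratio, with CIs from a Gaussian parametric bootstrap that
treats total and direct as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import linear_scan
from .ordinal import per_snp_scan
from .simulate import Cohort, export_summary_stats
from .twosample import MREstimate, harmonise, ivw

__all__ = [
    "MediationResult",
    "condition_exposure",
    "mtcojo_adjust",
    "difference_method",
    "estimate_mediation",
]


@dataclass(frozen=True)
class MediationResult:
    """Total/direct/indirect log-odds effects on the latent per-mph scale."""

    total: float
    direct: float
    indirect: float
    se_indirect: float
    ci95_indirect: tuple[float, float]
    proportion_mediated: float
    ci95_proportion: tuple[float, float]
    theta2: float
    n_boot: int

    @property
    def or_indirect(self) -> float:
        return float(np.exp(self.indirect))

    def to_dict(self) -> dict:
        return {
            "total_beta_L": self.total,
            "direct_beta_L": self.direct,
            "indirect_beta_L": self.indirect,
            "indirect_or": self.or_indirect,
            "se_indirect": self.se_indirect,
            "ci95_indirect_low": self.ci95_indirect[0],
            "ci95_indirect_high": self.ci95_indirect[1],
            "proportion_mediated": self.proportion_mediated,
            "ci95_proportion_low": self.ci95_proportion[0],
            "ci95_proportion_high": self.ci95_proportion[1],
            "theta2": self.theta2,
        }


def condition_exposure(genotypes, y, mediator, covariates=None, **scan_kwargs
                       ) -> pd.DataFrame:
    """Per-SNP ordered-probit exposure effects conditional on the mediator.

    The mediator joins the covariate matrix of the ordinal scan.  Raises if
    the mediator is collinear with an existing covariate (it then adds no
    information and the probit is rank-deficient).
    """
    med = np.asarray(mediator, dtype=float)[:, None]
    if covariates is None:
        C = med
    else:
        C = np.column_stack([np.asarray(covariates, float), med])
        rank_without = np.linalg.matrix_rank(C[:, :-1])
        if np.linalg.matrix_rank(C) == rank_without:
            raise ValueError("mediator is collinear with the covariates")
    return per_snp_scan(genotypes, y, C, **scan_kwargs)


def mtcojo_adjust(
    outcome: pd.DataFrame,
    snp_mediator_effects: pd.DataFrame,
    beta_my: float,
    se_beta_my: float = 0.0,
) -> pd.DataFrame:
    """Condition SNP-outcome effects on the mediator (LD-free mtCOJO).

    For independent (clumped) instruments the conditional effect is
    ``b_zy|m = b_zy - b_zm * beta_my`` with the delta-method SE
    ``sqrt(se_zy^2 + beta_my^2 se_zm^2 + b_zm^2 se_my^2)``.  Variants with no
    mediator effect available are dropped (recorded in ``attrs['dropped']``).
    """
    med = snp_mediator_effects[["snp", "beta", "se"]].rename(
        columns={"beta": "b_zm", "se": "se_zm"}
    )
    merged = outcome.merge(med, on="snp", how="left")
    missing = merged["b_zm"].isna()
    dropped = merged.loc[missing, "snp"].tolist()
    merged = merged[~missing].copy()
    merged["beta"] = merged["beta"] - merged["b_zm"] * beta_my
    merged["se"] = np.sqrt(
        merged["se"] ** 2
        + beta_my**2 * merged["se_zm"] ** 2
        + merged["b_zm"] ** 2 * se_beta_my**2
    )
    out = merged.drop(columns=["b_zm", "se_zm"])
    out.attrs["dropped"] = dropped
    return out


def difference_method(
    total: MREstimate, direct: MREstimate, n_boot: int = 1000, seed: int = 0
) -> MediationResult:
    """Indirect effect and proportion mediated by the difference method.

    Both inputs must be on the same theta2/sigma_L scale.  CIs come from
    ``n_boot`` independent Gaussian draws of (total, direct) using their
    standard errors.
    """
    if not np.isclose(total.theta2, direct.theta2) or not np.isclose(
        total.sigma_L, direct.sigma_L
    ):
        raise ValueError("total and direct estimates are on different scales")
    t, d = total.beta_L, direct.beta_L
    if abs(t) < 1e-12:
        raise ValueError(
            "total effect is (numerically) zero: the proportion mediated is "
            "undefined; report the indirect effect only"
        )
    indirect = t - d
    proportion = indirect / t
    rng = np.random.default_rng(seed)
    t_star = t + total.se_L * rng.standard_normal(n_boot)
    d_star = d + direct.se_L * rng.standard_normal(n_boot)
    ind_star = t_star - d_star
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_star = ind_star / t_star
    ci_ind = np.percentile(ind_star, [2.5, 97.5])
    ci_prop = np.percentile(prop_star[np.isfinite(prop_star)], [2.5, 97.5])
    return MediationResult(
        total=float(t),
        direct=float(d),
        indirect=float(indirect),
        se_indirect=float(ind_star.std(ddof=1)),
        ci95_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        proportion_mediated=float(proportion),
        ci95_proportion=(float(ci_prop[0]), float(ci_prop[1])),
        theta2=float(total.theta2),
        n_boot=n_boot,
    )


def estimate_mediation(
    cohort_exposure: Cohort,
    cohort_outcome: Cohort,
    theta2: float,
    sigma_L: float,
    estimator_factory=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[MediationResult, MREstimate, MREstimate]:
    """End-to-end mediation analysis on a pair of disjoint cohorts.

    1. total effect: marginal two-sample MR on the instrument panel;
    2. mediator -> outcome effect ``beta_my``: IVW on the mediator panel
       (linear mediator scan in the exposure cohort, logistic outcome scan
       in the outcome cohort);
    3. direct effect: mediator-conditional exposure scan + mtCOJO-adjusted
       outcome effects, same estimator;
    4. difference method.

    ``estimator_factory(theta2, sigma_L)`` returns a fitted-MR factory;
    defaults to IVW.
    """
    if estimator_factory is None:
        def estimator_factory(t2, sl):  # noqa: ANN001
            return lambda tab: ivw(tab, theta2=t2, sigma_L=sl)
    run = estimator_factory(theta2, sigma_L)

    # 1. total effect
    exp_tab, out_tab = export_summary_stats(cohort_exposure, cohort_outcome)
    total = run(harmonise(exp_tab, out_tab))

    # 2. mediator -> outcome, raw slope (log-odds per mediator unit)
    med_exp, med_out = export_summary_stats(
        cohort_exposure, cohort_outcome, which="mediator"
    )
    med_tab = harmonise(med_exp, med_out)
    beta_my_fit = ivw(med_tab, theta2=theta2, sigma_L=sigma_L)
    beta_my, se_my = beta_my_fit.beta, beta_my_fit.se

    # 3. direct effect
    idx = cohort_exposure.instrument_index
    meta = cohort_exposure.snps.iloc[idx]
    cond_exp = condition_exposure(
        cohort_exposure.genotypes[:, idx].astype(float),
        cohort_exposure.data["exposure_category"].to_numpy(),
        cohort_exposure.data["mediator"].to_numpy(),
        cohort_exposure.covariate_matrix,
        snp_ids=meta["snp"], effect_alleles=meta["effect_allele"],
        other_alleles=meta["other_allele"],
    )
    idx_o = cohort_outcome.instrument_index
    meta_o = cohort_outcome.snps.iloc[idx_o]
    b_zm = linear_scan(
        cohort_outcome.genotypes[:, idx_o].astype(float),
        cohort_outcome.data["mediator"].to_numpy(),
        cohort_outcome.covariate_matrix,
        snp_ids=meta_o["snp"], effect_alleles=meta_o["effect_allele"],
        other_alleles=meta_o["other_allele"],
    )
    out_cond = mtcojo_adjust(out_tab, b_zm, beta_my, se_my)
    direct = run(harmonise(cond_exp, out_cond))

    med = difference_method(total, direct, n_boot=n_boot, seed=seed)
    return med, total, direct
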