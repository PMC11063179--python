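"""One-sample Mendelian randomisation via a standardised genetic score.

The four-step procedure:

1. fit an ordered probit of the 3-category exposure on all instruments
   (plus covariates) and form its linear predictor — the predicted genetic
   value of the latent exposure;
2. standardise the linear predictor to unit SD;
3. fit the outcome model — Cox proportional hazards of the event on the
   standardised score with covariate adjustment (Efron ties), or logistic
   regression in odds mode — giving the standardised effect ``beta_G``;
4. rescale to the latent per-mph effect ``beta_L = beta_G / (theta sigma_L)``.

Uncertainty for the full procedure comes from a nonparametric bootstrap over
individuals in which the probit stage is refitted inside every resample.
A proportional-hazards diagnostic correlates scaled Schoenfeld residuals
with rank-normalised log follow-up time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.base import BaseEstimator

from ._glm import _logistic_newton
from .latent_scale import rescale_to_latent
from .ordinal import OrderedProbit, linear_predictor
from .simulate import Cohort
from .twosample import MREstimate

__all__ = ["OneSampleMR", "onesample_fit", "bootstrap_ci", "ph_diagnostic"]

_COVARIATES = ("age", "sex", "pc1", "pc2")


def _design(cohort: Cohort, covariates) -> tuple[np.ndarray, np.ndarray]:
    G = cohort.instrument_genotypes.astype(float)
    C = cohort.data[list(covariates)].to_numpy(float)
    return G, C


class OneSampleMR(BaseEstimator):
    """Score-based one-sample MR estimator.

    Parameters
    ----------
    theta2, sigma_L : float
        Latent-scale sensitivity parameter and latent SD used in step 4.
    outcome_model : {"hazard", "odds"}
        Cox proportional hazards (default) or logistic regression.
    covariates : sequence of str
        Columns of the cohort table adjusted for in both stages.

    Attributes
    ----------
    estimate_ : MREstimate
    probit_ : OrderedProbit
        The stage-1 exposure fit.
    cox_ : lifelines.CoxPHFitter, hazard mode only.
    """

    def __init__(self, theta2: float = 0.0072, sigma_L: float = 0.57,
                 outcome_model: str = "hazard",
                 covariates: tuple[str, ...] = _COVARIATES):
        self.theta2 = theta2
        self.sigma_L = sigma_L
        self.outcome_model = outcome_model
        self.covariates = covariates

    def fit(self, cohort: Cohort):
        if self.outcome_model not in ("hazard", "odds"):
            raise ValueError("outcome_model must be 'hazard' or 'odds'")
        G, C = _design(cohort, self.covariates)
        y = cohort.data["exposure_category"].to_numpy()
        events = cohort.data["event_indicator"].to_numpy()
        if events.sum() == 0:
            raise ValueError("no events in cohort; outcome model undefined")
        self.probit_ = OrderedProbit().fit(np.column_stack([G, C]), y)
        # predicted genetic value: the genetic part of the linear predictor,
        # standardised to unit SD (covariates are adjusted for separately in
        # the outcome model)
        genetic_fit = OrderedProbit()
        genetic_fit.coef_ = self.probit_.coef_[: G.shape[1]]
        genetic_fit.cutpoints_ = self.probit_.cutpoints_
        genetic_fit.vcov_ = None
        score = linear_predictor(genetic_fit, G)
        self.score_ = score

        if self.outcome_model == "hazard":
            df = pd.DataFrame({"time": cohort.data["event_time"],
                               "event": events, "score": score})
            for c in self.covariates:
                df[c] = cohort.data[c].to_numpy()
            cox = CoxPHFitter()
            cox.fit(df, duration_col="time", event_col="event")
            beta_G = float(cox.params_["score"])
            se_G = float(cox.standard_errors_["score"])
            self.cox_ = cox
            self._cox_df = df
            scale = "hazard"
        else:
            X = np.column_stack([np.ones(cohort.n), score, C])
            beta, vcov = _logistic_newton(X, events.astype(float),
                                          np.zeros(X.shape[1]))
            beta_G = float(beta[1])
            se_G = float(np.sqrt(vcov[1, 1]))
            scale = "odds"

        res = rescale_to_latent(beta_G, se_G, self.theta2, self.sigma_L)
        self.estimate_ = MREstimate(
            method=f"onesample_{scale}", beta=beta_G, se=se_G, beta_G=beta_G,
            se_G=se_G, beta_L=res.beta_L, se_L=res.se_L, ci95=res.ci95,
            pval=res.pval, theta2=self.theta2, sigma_L=self.sigma_L,
            n_snps=G.shape[1], scale=scale,
        )
        return self


def onesample_fit(cohort: Cohort, theta2: float, sigma_L: float,
                  outcome_model: str = "hazard",
                  covariates=_COVARIATES) -> MREstimate:
    """Functional wrapper around :class:`OneSampleMR`."""
    est = OneSampleMR(theta2=theta2, sigma_L=sigma_L,
                      outcome_model=outcome_model, covariates=covariates)
    return est.fit(cohort).estimate_


def _resample(cohort: Cohort, idx: np.ndarray) -> Cohort:
    return Cohort(
        genotypes=cohort.genotypes[idx],
        snps=cohort.snps,
        data=cohort.data.iloc[idx].reset_index(drop=True),
        config=cohort.config,
    )


def bootstrap_ci(cohort: Cohort, estimator: OneSampleMR, n_boot: int = 1000,
                 seed: int = 0, max_failures: float = 0.1):
    """Full-procedure nonparametric bootstrap of the one-sample estimate.

    Individuals are resampled with replacement and the complete pipeline —
    ordered probit, score standardisation, outcome model — is refitted in
    each resample.  Returns ``(se_L, (lo, hi))``: the bootstrap SE and the
    2.5/97.5 percentile interval of ``beta_L``.  Aborts if more than
    ``max_failures`` of the resamples fail to fit.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n = cohort.n
    estimates, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            est = estimator.__class__(**estimator.get_params())
            est.fit(_resample(cohort, idx))
            estimates.append(est.estimate_.beta_L)
        except Exception:  # noqa: BLE001 - any stage failure counts
            failures += 1
            if failures > max_failures * n_boot:
                raise RuntimeError(
                    f"bootstrap aborted: {failures} failures in "
                    f"{failures + len(estimates)} resamples"
                ) from None
    estimates = np.asarray(estimates)
    se = float(estimates.std(ddof=1))
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return se, (float(lo), float(hi))


def _blom_rank_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offsets (r-3/8)/(n+1/4)."""
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 0.375) / (x.size + 0.25))


def ph_diagnostic(fitted: OneSampleMR) -> tuple[float, float]:
    """Proportional-hazards check for the score coefficient.

    Pearson correlation between the scaled Schoenfeld residuals of the
    standardised genetic score and the rank-normalised natural log of
    follow-up time, with its two-sided test P.  Only defined for hazard-mode
    fits with at least two events.
    """
    if getattr(fitted, "estimate_", None) is None:
        raise ValueError("estimator is not fitted")
    if fitted.estimate_.scale != "hazard":
        raise ValueError("PH diagnostic applies to hazard-mode fits only")
    resid = fitted.cox_.compute_residuals(fitted._cox_df, kind="scaled_schoenfeld")
    times = fitted._cox_df.loc[resid.index, "time"].to_numpy(float)
    return _ph_from_residuals(resid, times)


def _ph_from_residuals(resid: pd.DataFrame, times: np.ndarray) -> tuple[float, float]:
    if resid.shape[0] < 2:
        raise ValueError("PH diagnostic needs at least two events")
    z = _blom_rank_normal(np.log(times))
    r, p = stats.pearsonr(resid["score"].to_numpy(), z)
    return float(r), float(p)
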