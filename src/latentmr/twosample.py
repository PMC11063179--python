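"""Summary-statistic Mendelian randomisation with latent-scale rescaling.

Inputs are harmonised per-variant pairs ``(alpha_hat_j, b_j)``: the ordinal
(probit-scale) exposure effect and the log-odds outcome effect, with SEs and
effect-allele frequencies ``f_j``.  Estimators:

* :class:`IVW` - inverse-variance weighted average of Wald ratios
  ``b_j / alpha_hat_j`` (equivalently weighted regression of ``b`` on
  ``alpha_hat`` through the origin), with a multiplicative random-effects SE
  when Cochran's Q exceeds its degrees of freedom;
* :class:`WeightedMedian` - the 50% weighted percentile of Wald ratios,
  SE by parametric bootstrap;
* :class:`Egger` - weighted regression with a free intercept (directional
  pleiotropy), variants oriented so every exposure effect is positive;
* :class:`RAPS` - maximum profile likelihood accounting for measurement error
  in both coordinates plus additive overdispersion ``tau^2 >= 0``.

Every causal slope ``beta`` is standardised to the genetic share of the
latent exposure, ``beta_G = sqrt(sum_j alpha_hat_j^2 sigma_Zj^2) * beta``
with ``sigma_Zj^2 = 2 f_j (1 - f_j)``, and then moved to the per-mph latent
scale, ``beta_L = beta_G / (theta * sigma_L)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .latent_scale import rescale_to_latent

__all__ = [
    "MREstimate",
    "harmonise",
    "IVW",
    "WeightedMedian",
    "Egger",
    "RAPS",
    "ivw",
    "weighted_median",
    "egger",
    "raps",
    "standardise_and_rescale",
    "cochran_q",
    "weighted_median_point",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on raw, standardised and latent scales."""

    method: str
    beta: float  # raw slope: log-odds per probit-scale unit of exposure
    se: float
    beta_G: float  # standardised by the genetic share of the latent exposure
    se_G: float
    beta_L: float  # per mph of latent exposure
    se_L: float
    ci95: tuple[float, float]  # on beta_L
    pval: float
    theta2: float
    sigma_L: float
    n_snps: int
    scale: str = "odds"
    intercept: float | None = None  # Egger only
    intercept_se: float | None = None
    intercept_pval: float | None = None
    tau2: float | None = None  # RAPS overdispersion
    q: float | None = None  # Cochran's Q (IVW)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta_L))

    @property
    def ci95_or(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "theta2": self.theta2,
            "sigma_L": self.sigma_L,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "beta_G": self.beta_G,
            "se_G": self.se_G,
            "beta_L": self.beta_L,
            "se_L": self.se_L,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "ratio": self.or_,
            "ratio_ci95_low": self.ci95_or[0],
            "ratio_ci95_high": self.ci95_or[1],
            "pval": self.pval,
            "scale": self.scale,
        }
        for key in ("intercept", "intercept_se", "intercept_pval", "tau2", "q"):
            val = getattr(self, key)
            if val is not None:
                d[key] = val
        return d


# --------------------------------------------------------------------------
# harmonisation
# --------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_freq_window: tuple[float, float] = (0.42, 0.58),
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect allele.

    Variants whose outcome alleles are swapped get their log-odds sign
    flipped and frequency mirrored; strand flips are resolved through base
    complements; strand-ambiguous palindromic variants with intermediate
    frequency are dropped with a warning, as are unresolvable mismatches.

    Returns the harmonised instrument table with columns ``snp,
    effect_allele, other_allele, eaf, alpha_hat, se_alpha, pval_exposure,
    b, se_b, pval_outcome, sigma2_Z, n_exposure, n_outcome``.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    rows, dropped = [], []
    lo, hi = palindrome_freq_window
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        b, eaf_o = rec.beta_out, rec.eaf_out
        if _is_palindromic(ea_e, oa_e):
            f = rec.eaf_exp
            if lo < f < hi:
                dropped.append((rec.snp, "palindromic, ambiguous frequency"))
                continue
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            b, eaf_o = -b, 1.0 - eaf_o
        elif (
            _COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)
        ) == (ea_e, oa_e):
            pass  # strand flip, same orientation
        elif (
            _COMPLEMENT.get(ea_o), _COMPLEMENT.get(oa_o)
        ) == (oa_e, ea_e):
            b, eaf_o = -b, 1.0 - eaf_o
        else:
            dropped.append((rec.snp, "allele mismatch"))
            continue
        f = float(rec.eaf_exp)
        rows.append(
            (rec.snp, ea_e, oa_e, f, rec.beta_exp, rec.se_exp, rec.pval_exp,
             float(b), rec.se_out, rec.pval_out, 2.0 * f * (1.0 - f),
             rec.n_exp, rec.n_out)
        )
    if dropped:
        warnings.warn(
            f"harmonise dropped {len(dropped)} variant(s): "
            + "; ".join(f"{s} ({why})" for s, why in dropped),
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows,
        columns=["snp", "effect_allele", "other_allele", "eaf", "alpha_hat",
                 "se_alpha", "pval_exposure", "b", "se_b", "pval_outcome",
                 "sigma2_Z", "n_exposure", "n_outcome"],
    )
    table.attrs["n_dropped"] = len(dropped)
    table.attrs["dropped"] = dropped
    return table


def _validate(instruments: pd.DataFrame, min_snps: int, method: str
              ) -> pd.DataFrame:
    required = {"alpha_hat", "se_alpha", "b", "se_b"}
    missing = required - set(instruments.columns)
    if missing:
        raise ValueError(f"instrument table lacks columns {sorted(missing)}")
    tab = instruments.dropna(subset=list(required))
    zero = tab["alpha_hat"] == 0
    if zero.any():
        warnings.warn(
            f"{method}: excluded {int(zero.sum())} variant(s) with zero "
            "exposure effect", stacklevel=3,
        )
        tab = tab[~zero]
    if len(tab) < min_snps:
        raise ValueError(f"{method} requires >= {min_snps} usable variants")
    return tab


def standardise_and_rescale(
    beta: float, se: float, instruments: pd.DataFrame, theta2: float,
    sigma_L: float, method: str = "custom", scale: str = "odds", **extra,
) -> MREstimate:
    """Standardise a raw slope by the genetic share and move it to mph units."""
    if len(instruments) == 0:
        raise ValueError("empty instrument set")
    if "sigma2_Z" in instruments.columns:
        s2 = instruments["sigma2_Z"].to_numpy(float)
    else:
        f = instruments["eaf"].to_numpy(float)
        s2 = 2.0 * f * (1.0 - f)
    g_share = float(np.sqrt(np.sum(instruments["alpha_hat"].to_numpy(float) ** 2
                                   * s2)))
    beta_G, se_G = g_share * beta, g_share * se
    res = rescale_to_latent(beta_G, se_G, theta2, sigma_L)
    return MREstimate(
        method=method, beta=float(beta), se=float(se), beta_G=float(beta_G),
        se_G=float(se_G), beta_L=res.beta_L, se_L=res.se_L, ci95=res.ci95,
        pval=res.pval, theta2=theta2, sigma_L=sigma_L,
        n_snps=int(len(instruments)), scale=scale, **extra,
    )


def cochran_q(instruments: pd.DataFrame) -> tuple[float, int]:
    """Cochran's Q heterogeneity statistic of the Wald ratios and its df."""
    tab = _validate(instruments, 2, "cochran_q")
    a = tab["alpha_hat"].to_numpy(float)
    b = tab["b"].to_numpy(float)
    w = (a / tab["se_b"].to_numpy(float)) ** 2
    ratios = b / a
    beta = float(np.sum(w * ratios) / np.sum(w))
    return float(np.sum(w * (ratios - beta) ** 2)), len(tab) - 1


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class _SummaryMREstimator(BaseEstimator):
    """Shared machinery: fit on an instrument table, rescale, expose results."""

    _method = "abstract"
    _min_snps = 2

    def __init__(self, theta2: float = 0.0072, sigma_L: float = 0.57):
        self.theta2 = theta2
        self.sigma_L = sigma_L

    def _point(self, tab: pd.DataFrame) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, instruments: pd.DataFrame):
        tab = _validate(instruments, self._min_snps, self._method)
        out = self._point(tab)
        extra = {k: v for k, v in out.items() if k not in ("beta", "se")}
        self.estimate_ = standardise_and_rescale(
            out["beta"], out["se"], tab, self.theta2, self.sigma_L,
            method=self._method, **extra,
        )
        self.beta_ = self.estimate_.beta
        self.se_ = self.estimate_.se
        self.n_snps_ = self.estimate_.n_snps
        return self


class IVW(_SummaryMREstimator):
    """Inverse-variance weighted estimator.

    Weights are first-order Wald-ratio weights ``w_j = (alpha_hat_j /
    se_b_j)^2``.  ``random_effects="auto"`` applies a multiplicative
    random-effects inflation ``sqrt(Q / (J - 1))`` when Cochran's Q exceeds
    its degrees of freedom (never narrows the CI).
    """

    _method = "ivw"
    _min_snps = 2

    def __init__(self, theta2: float = 0.0072, sigma_L: float = 0.57,
                 random_effects: str = "auto"):
        super().__init__(theta2=theta2, sigma_L=sigma_L)
        self.random_effects = random_effects

    def _point(self, tab):
        a = tab["alpha_hat"].to_numpy(float)
        b = tab["b"].to_numpy(float)
        w = (a / tab["se_b"].to_numpy(float)) ** 2
        ratios = b / a
        sw = np.sum(w)
        beta = float(np.sum(w * ratios) / sw)
        se = float(1.0 / np.sqrt(sw))
        q = float(np.sum(w * (ratios - beta) ** 2))
        df = len(tab) - 1
        if self.random_effects == "auto" and df > 0 and q > df:
            se *= np.sqrt(q / df)
        return {"beta": beta, "se": se, "q": q}


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with linear interpolation across the
    cumulative-weight grid (midpoint convention)."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


class WeightedMedian(_SummaryMREstimator):
    """Weighted median of Wald ratios; consistent when valid instruments carry
    a majority of the weight.  SE from a parametric bootstrap of
    ``(alpha_hat, b)``."""

    _method = "weighted_median"
    _min_snps = 3

    def __init__(self, theta2: float = 0.0072, sigma_L: float = 0.57,
                 n_boot: int = 1000, seed: int = 0):
        super().__init__(theta2=theta2, sigma_L=sigma_L)
        self.n_boot = n_boot
        self.seed = seed

    def _point(self, tab):
        a = tab["alpha_hat"].to_numpy(float)
        b = tab["b"].to_numpy(float)
        se_a = tab["se_alpha"].to_numpy(float)
        se_b = tab["se_b"].to_numpy(float)
        w = (a / se_b) ** 2
        beta = weighted_median_point(b / a, w)
        rng = np.random.default_rng(self.seed)
        a_star = a + se_a * rng.standard_normal((self.n_boot, a.size))
        b_star = b + se_b * rng.standard_normal((self.n_boot, b.size))
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            ai = a_star[i]
            ok = ai != 0
            boots[i] = weighted_median_point(
                b_star[i][ok] / ai[ok], (ai[ok] / se_b[ok]) ** 2
            )
        return {"beta": beta, "se": float(boots.std(ddof=1))}


class Egger(_SummaryMREstimator):
    """MR-Egger: weighted regression of ``b`` on ``alpha_hat`` with a free
    intercept, variants oriented to positive exposure effects first.

    The slope is the causal estimate; the intercept estimates directional
    pleiotropy, with a Wald test attached.
    """

    _method = "egger"
    _min_snps = 3

    def _point(self, tab):
        a = tab["alpha_hat"].to_numpy(float).copy()
        b = tab["b"].to_numpy(float).copy()
        flip = a < 0
        a[flip], b[flip] = -a[flip], -b[flip]
        w = 1.0 / tab["se_b"].to_numpy(float) ** 2
        X = np.column_stack([np.ones_like(a), a])
        WX = w[:, None] * X
        xtwx = X.T @ WX
        coef = np.linalg.solve(xtwx, WX.T @ b)
        resid = b - X @ coef
        df = len(a) - 2
        sigma2 = float(np.sum(w * resid**2) / df)
        vcov = np.linalg.inv(xtwx) * max(sigma2, 1.0)  # multiplicative RE
        se_slope = float(np.sqrt(vcov[1, 1]))
        se_int = float(np.sqrt(vcov[0, 0]))
        spread = a.std() / a.mean() if a.mean() != 0 else 0.0
        if abs(spread) < 0.1:
            warnings.warn(
                "egger: little spread in instrument strengths; the slope is "
                "weakly identified", stacklevel=3,
            )
        int_p = float(2.0 * stats.t.sf(abs(coef[0] / se_int), df))
        return {
            "beta": float(coef[1]), "se": se_slope,
            "intercept": float(coef[0]), "intercept_se": se_int,
            "intercept_pval": int_p,
        }


class RAPS(_SummaryMREstimator):
    """Robust adjusted profile score (simple, non-Huberised variant).

    With measurement error in both coordinates the per-variant nuisance
    means profile out to the objective

        l(beta; tau2) = -0.5 sum_j (b_j - beta alpha_hat_j)^2 / v_j,
        v_j = se_bj^2 + beta^2 se_alphaj^2 + tau2,

    which has no log-determinant term in ``beta`` (that term belongs only to
    the overdispersion parameter) — this is what removes IVW's
    weak-instrument dilution.  ``tau2 >= 0`` solves the marginal normal score
    equation at the current slope; slope and overdispersion are iterated to
    convergence.
    """

    _method = "raps"
    _min_snps = 3

    def __init__(self, theta2: float = 0.0072, sigma_L: float = 0.57,
                 overdispersion: bool = True):
        super().__init__(theta2=theta2, sigma_L=sigma_L)
        self.overdispersion = overdispersion

    @staticmethod
    def _neg_profile(beta, tau2, a, b, se_a2, se_b2):
        v = se_b2 + beta**2 * se_a2 + tau2
        return 0.5 * float(np.sum((b - beta * a) ** 2 / v))

    @staticmethod
    def _update_tau2(beta, a, b, se_a2, se_b2):
        """Maximise the marginal normal log-likelihood over tau2 >= 0."""
        base = se_b2 + beta**2 * se_a2
        resid2 = (b - beta * a) ** 2

        def neg_ll(log_t):
            v = base + np.exp(log_t)
            return 0.5 * float(np.sum(np.log(v) + resid2 / v))

        ll0 = 0.5 * float(np.sum(np.log(base) + resid2 / base))
        res = optimize.minimize_scalar(
            neg_ll, bounds=(-25.0, 5.0), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(np.exp(res.x)) if res.fun < ll0 else 0.0

    def fit(self, instruments: pd.DataFrame):
        tab = _validate(instruments, self._min_snps, self._method)
        a = tab["alpha_hat"].to_numpy(float)
        b = tab["b"].to_numpy(float)
        se_a2 = tab["se_alpha"].to_numpy(float) ** 2
        se_b2 = tab["se_b"].to_numpy(float) ** 2

        w = a**2 / se_b2
        beta = float(np.sum(w * (b / a)) / np.sum(w))  # IVW start
        width = 10.0 * (abs(beta) + 1.0)
        tau2 = 0.0
        trace = []
        for _ in range(50):
            res = optimize.minimize_scalar(
                self._neg_profile, args=(tau2, a, b, se_a2, se_b2),
                bounds=(beta - width, beta + width), method="bounded",
                options={"xatol": 1e-10},
            )
            new_beta = float(res.x)
            new_tau2 = (
                self._update_tau2(new_beta, a, b, se_a2, se_b2)
                if self.overdispersion else 0.0
            )
            trace.append((new_beta, new_tau2))
            if (abs(new_beta - beta) < 1e-7 * (1.0 + abs(beta))
                    and abs(new_tau2 - tau2) < 1e-10 * (1.0 + tau2)):
                beta, tau2 = new_beta, new_tau2
                break
            beta, tau2 = new_beta, new_tau2
        else:
            raise RuntimeError(
                f"RAPS profile iteration did not converge; trace={trace[-5:]}"
            )
        # curvature-based SE on beta at fixed tau2
        h = 1e-5 * (abs(beta) + 1.0)
        f0 = self._neg_profile(beta, tau2, a, b, se_a2, se_b2)
        d2 = (
            self._neg_profile(beta + h, tau2, a, b, se_a2, se_b2)
            - 2.0 * f0
            + self._neg_profile(beta - h, tau2, a, b, se_a2, se_b2)
        ) / h**2
        se = float(1.0 / np.sqrt(max(d2, 1e-12)))
        self.estimate_ = standardise_and_rescale(
            beta, se, tab, self.theta2, self.sigma_L, method=self._method,
            tau2=float(tau2),
        )
        self.beta_, self.se_, self.n_snps_ = beta, se, len(tab)
        return self


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------

def ivw(instruments, theta2=0.0072, sigma_L=0.57, **kw) -> MREstimate:
    return IVW(theta2=theta2, sigma_L=sigma_L, **kw).fit(instruments).estimate_


def weighted_median(instruments, theta2=0.0072, sigma_L=0.57, n_boot=1000,
                    seed=0) -> MREstimate:
    est = WeightedMedian(theta2=theta2, sigma_L=sigma_L, n_boot=n_boot, seed=seed)
    return est.fit(instruments).estimate_


def egger(instruments, theta2=0.0072, sigma_L=0.57) -> MREstimate:
    return Egger(theta2=theta2, sigma_L=sigma_L).fit(instruments).estimate_


def raps(instruments, theta2=0.0072, sigma_L=0.57, **kw) -> MREstimate:
    return RAPS(theta2=theta2, sigma_L=sigma_L, **kw).fit(instruments).estimate_
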