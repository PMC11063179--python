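"""Latent-threshold arithmetic for a 3-category coarsened exposure.

A continuous exposure ``L ~ N(mu_L, sigma_L^2)`` (walking pace in mph) is
observed only as an ordered category ``D in {0, 1, 2}`` via fixed thresholds
(by default 3 and 4 mph).  The category frequencies ``pi_k`` identify
``sigma_L`` through the spacing of the thresholds in quantile units:

    sigma_L = (t2 - t1) / (PhiInv(pi0 + pi1) - PhiInv(pi0))

Genetic effect estimates made on the standardised (probit) or observed
(0/1/2-coded) scale are rescaled to the per-mph latent scale with
``beta_L = beta_G / (theta * sigma_L)``, where ``theta^2`` is the proportion
of latent variance explained by the instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CategoryFrequencies",
    "LatentScaleParams",
    "estimate_sigma_L",
    "sigma_L_from_cutpoints",
    "observed_to_latent_r2",
    "rescale_to_latent",
    "DEFAULT_THETA2_GRID",
]

#: Sensitivity grid for the share of latent variance explained by instruments.
DEFAULT_THETA2_GRID = (0.0050, 0.0072, 0.0100)


@dataclass(frozen=True)
class CategoryFrequencies:
    """Proportions of the three ordered exposure categories (slow/steady/brisk)."""

    pi0: float
    pi1: float
    pi2: float
    counts: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        pis = (self.pi0, self.pi1, self.pi2)
        if not all(0.0 < p < 1.0 for p in pis):
            raise ValueError(f"category proportions must lie in (0, 1), got {pis}")
        if abs(sum(pis) - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {sum(pis)!r}")

    @classmethod
    def from_counts(cls, n0: int, n1: int, n2: int) -> "CategoryFrequencies":
        total = n0 + n1 + n2
        if total <= 0 or min(n0, n1, n2) <= 0:
            raise ValueError("all three category counts must be positive")
        return cls(n0 / total, n1 / total, n2 / total, counts=(n0, n1, n2))

    @classmethod
    def from_categories(cls, d: np.ndarray) -> "CategoryFrequencies":
        d = np.asarray(d)
        counts = [int(np.sum(d == k)) for k in (0, 1, 2)]
        return cls.from_counts(*counts)

    def as_array(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.pi2])


@dataclass(frozen=True)
class LatentScaleParams:
    """Parameters of the latent exposure scale used for rescaling."""

    sigma_L: float
    theta2: float
    mu_L: float = float("nan")
    thresholds: tuple[float, float] = (3.0, 4.0)

    def __post_init__(self) -> None:
        if self.sigma_L <= 0:
            raise ValueError("sigma_L must be positive")
        if not 0.0 < self.theta2 < 1.0:
            raise ValueError("theta2 must lie in (0, 1)")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly increasing")


def estimate_sigma_L(
    freqs: CategoryFrequencies, thresholds: tuple[float, float] = (3.0, 4.0)
) -> float:
    """Latent-scale SD from marginal category frequencies.

    ``sigma_L = (t2 - t1) / (PhiInv(pi0 + pi1) - PhiInv(pi0))`` with the
    thresholds in physical units (mph).  Raises if either outer category is
    empty, since the corresponding quantile is then unbounded.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be strictly increasing")
    p_lo = freqs.pi0
    p_hi = freqs.pi0 + freqs.pi1
    if not 0.0 < p_lo < p_hi < 1.0:
        raise ValueError(
            "cumulative category proportions must satisfy 0 < pi0 < pi0+pi1 < 1"
        )
    gap = stats.norm.ppf(p_hi) - stats.norm.ppf(p_lo)
    return (t2 - t1) / gap


def sigma_L_from_cutpoints(
    cutpoints: tuple[float, float] | np.ndarray,
    thresholds: tuple[float, float] = (3.0, 4.0),
) -> float:
    """Covariate-adjusted latent SD from ordered-probit cutpoints.

    An ordered probit of the category on covariates estimates cutpoints on
    the residual (unit-variance) latent scale; the physical thresholds are
    ``(t2 - t1)`` mph apart, so the residual SD in mph is
    ``(t2 - t1) / (c2 - c1)``.  This is the covariate-adjusted alternative to
    :func:`estimate_sigma_L`.
    """
    c1, c2 = float(cutpoints[0]), float(cutpoints[1])
    if not c1 < c2:
        raise ValueError("cutpoints must be strictly increasing")
    t1, t2 = thresholds
    return (t2 - t1) / (c2 - c1)


def _standardised_thresholds(freqs: CategoryFrequencies) -> tuple[float, float]:
    """Thresholds of the coarsening on the standardised latent scale."""
    return (
        float(stats.norm.ppf(freqs.pi0)),
        float(stats.norm.ppf(freqs.pi0 + freqs.pi1)),
    )


def observed_to_latent_r2(r2_observed: float, freqs: CategoryFrequencies) -> float:
    """Transform variance explained on the observed 0/1/2 scale to the latent scale.

    Writing ``t1, t2`` for the standardised thresholds implied by the category
    frequencies, a small shift ``delta`` of the latent mean moves the expected
    observed code by ``(phi(t1) + phi(t2)) * delta``, while ``Var(D)`` follows
    from the frequencies.  Hence

        theta2 = r2_observed * Var(D) / (phi(t1) + phi(t2))^2.
    """
    if not 0.0 <= r2_observed < 1.0:
        raise ValueError("r2_observed must lie in [0, 1)")
    t1, t2 = _standardised_thresholds(freqs)
    pis = freqs.as_array()
    codes = np.array([0.0, 1.0, 2.0])
    mean_d = float(pis @ codes)
    var_d = float(pis @ (codes - mean_d) ** 2)
    slope = stats.norm.pdf(t1) + stats.norm.pdf(t2)
    return r2_observed * var_d / slope**2


@dataclass(frozen=True)
class RescaledEstimate:
    """Effect estimate moved to the per-mph latent scale."""

    beta_L: float
    se_L: float
    ci95: tuple[float, float]
    pval: float
    theta2: float
    sigma_L: float
    ratio: float = field(default=float("nan"))  # exp(beta_L), an HR or OR

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", float(np.exp(self.beta_L)))

    @property
    def ci95_ratio(self) -> tuple[float, float]:
        return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))


def rescale_to_latent(
    beta_G: float, se_G: float, theta2: float, sigma_L: float
) -> RescaledEstimate:
    """Rescale a standardised log-HR/log-OR to the per-mph latent scale.

    ``beta_L = beta_G / (sqrt(theta2) * sigma_L)``; the SE scales by the same
    factor, and the 95% CI is formed on the log scale before exponentiation.
    """
    if theta2 <= 0:
        raise ValueError("theta2 must be positive (theta2 = 0 gives no genetic share)")
    if sigma_L <= 0:
        raise ValueError("sigma_L must be positive")
    if se_G < 0:
        raise ValueError("se_G must be non-negative")
    scale = np.sqrt(theta2) * sigma_L
    beta_L = beta_G / scale
    se_L = se_G / scale
    z = stats.norm.ppf(0.975)
    ci = (beta_L - z * se_L, beta_L + z * se_L)
    if se_L > 0:
        pval = float(2.0 * stats.norm.sf(abs(beta_L) / se_L))
    else:
        pval = float("nan")
    return RescaledEstimate(
        beta_L=float(beta_L),
        se_L=float(se_L),
        ci95=(float(ci[0]), float(ci[1])),
        pval=pval,
        theta2=float(theta2),
        sigma_L=float(sigma_L),
    )
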