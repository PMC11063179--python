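"""Directionality filtering of instruments via Steiger's test for correlated
correlations.

An instrument selected for the exposure should correlate more strongly with
the exposure than with the outcome or any downstream risk factor.  For each
variant ``g`` and trait ``y`` the test compares ``r_gx`` (variant-exposure)
with ``r_gy`` (variant-trait) using Steiger's Z-bar-1* statistic for two
correlations sharing the common index ``g`` (the pooled-estimate variant of
the correlated-correlations Z test).  Variants with a stronger trait
correlation at a suggestive P threshold are flagged and removed before the
Mendelian randomisation is repeated.

The Z statistic uses the signed correlations (the classical correlated-
correlations test, which is exactly calibrated under the null of equal
correlations); the *flag* additionally requires the trait correlation to
exceed the exposure correlation in magnitude, so only outcome-first variants
are removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["steiger_test", "filter_instruments"]


def steiger_test(r_gx: float, r_gy: float, r_xy: float, n: int
                 ) -> tuple[float, float]:
    """Z statistic and two-sided P for r_gy vs r_gx with common index g.

    Fisher z-transforms of the two signed correlations are compared with the
    correlated-correlations variance term evaluated at the pooled
    correlation (Steiger's Z-bar-1*).  The statistic is oriented so that
    ``z > 0`` means the trait correlation exceeds the exposure correlation
    (outcome-first evidence).
    """
    if n <= 3:
        raise ValueError("Steiger test requires n > 3")
    for r in (r_gx, r_gy, r_xy):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r_gx) == 1.0 or abs(r_gy) == 1.0:
        raise ValueError("|r| = 1 gives an infinite Fisher z-transform")
    z1, z2 = np.arctanh(r_gy), np.arctanh(r_gx)
    rbar2 = ((r_gx + r_gy) / 2.0) ** 2
    psi = (r_xy * (1.0 - 2.0 * rbar2)
           - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r_xy**2))
    cbar = psi / (1.0 - rbar2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * cbar))
    pval = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), pval


def _standardise(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    return (x - x.mean(axis=0)) / np.where(sd > 0, sd, np.nan)


def filter_instruments(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    traits: pd.DataFrame,
    threshold: float = 0.05,
    snp_ids=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag and drop instruments with outcome-first Steiger evidence.

    Correlations use the observed scales: the 0/1/2 exposure code, plain
    Pearson for continuous traits and point-biserial (numeric Pearson) for
    binary ones.  A variant is removed when, for ANY supplied trait, the
    Steiger P is below ``threshold`` AND its trait correlation magnitude
    exceeds its exposure correlation magnitude.

    Returns ``(kept_indices, results)`` where results holds one row per
    variant x trait with the correlations, Z, P and flag.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    if traits.shape[0] != n or np.asarray(exposure).shape[0] != n:
        raise ValueError("genotypes, exposure and traits must share n rows")
    snp_ids = [f"snp{j}" for j in range(m)] if snp_ids is None else list(snp_ids)

    Gz = _standardise(G)
    xz = _standardise(np.asarray(exposure, float)[:, None])[:, 0]
    r_gx = Gz.T @ xz / n
    rows = []
    flagged_any = np.zeros(m, dtype=bool)
    for trait in traits.columns:
        tz = _standardise(traits[trait].to_numpy(float)[:, None])[:, 0]
        r_gy = Gz.T @ tz / n
        r_xy = float(xz @ tz / n)
        for j in range(m):
            z, p = steiger_test(r_gx[j], r_gy[j], r_xy, n)
            flag = bool(p < threshold and abs(r_gy[j]) > abs(r_gx[j]))
            flagged_any[j] |= flag
            rows.append((snp_ids[j], trait, float(r_gx[j]), float(r_gy[j]),
                         r_xy, z, p, flag))
    results = pd.DataFrame(
        rows, columns=["snp", "trait", "r_gx", "r_gy", "r_xy", "z", "pval",
                       "flagged"],
    )
    kept = np.flatnonzero(~flagged_any)
    if kept.size == 0:
        raise ValueError("Steiger filtering removed every instrument")
    return kept, results
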