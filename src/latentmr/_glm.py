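"""Fast per-variant logistic and linear association scans.

These produce the outcome and mediator halves of the summary statistics:
a log-odds ratio per variant for the binary disease indicator (Newton/IRLS
logistic, warm-started from the covariate-only fit) and an OLS slope per
variant for continuous traits (computed in closed form after residualising
on covariates).  Both return the summary-stat table dialect
``snp, effect_allele, other_allele, eaf, beta, se, pval, n``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = ["logistic_scan", "linear_scan"]

_SUMMARY_COLUMNS = ["snp", "effect_allele", "other_allele", "eaf", "beta", "se",
                    "pval", "n"]


def _logistic_newton(X, y, start, tol=1e-8, max_iter=30):
    beta = start.copy()
    for _ in range(max_iter):
        mu = special.expit(X @ beta)
        grad = X.T @ (y - mu)
        w = mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            vcov = np.linalg.inv(H)
            return beta, vcov
    raise RuntimeError("logistic regression did not converge")


def logistic_scan(genotypes, y, covariates=None, snp_ids=None,
                  effect_alleles=None, other_alleles=None) -> pd.DataFrame:
    """Per-variant logistic regression of a binary outcome, covariate-adjusted."""
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot fit a logistic model")
    C = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    snp_ids = [f"snp{j}" for j in range(m)] if snp_ids is None else list(snp_ids)
    effect_alleles = ["A"] * m if effect_alleles is None else list(effect_alleles)
    other_alleles = ["G"] * m if other_alleles is None else list(other_alleles)

    ones = np.ones((n, 1))
    base_X = np.hstack([ones, C])
    base_beta, _ = _logistic_newton(base_X, y, np.zeros(base_X.shape[1]))

    rows = []
    for j in range(m):
        g = G[:, j]
        eaf = g.mean() / 2.0
        if g.std() == 0:
            rows.append((snp_ids[j], effect_alleles[j], other_alleles[j],
                         float(eaf), np.nan, np.nan, np.nan, n))
            continue
        X = np.hstack([ones, g[:, None], C])
        start = np.insert(base_beta, 1, 0.0)
        beta, vcov = _logistic_newton(X, y, start)
        b, se = float(beta[1]), float(np.sqrt(vcov[1, 1]))
        pval = float(2.0 * stats.norm.sf(abs(b) / se))
        rows.append((snp_ids[j], effect_alleles[j], other_alleles[j],
                     float(eaf), b, se, pval, n))
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def linear_scan(genotypes, y, covariates=None, snp_ids=None,
                effect_alleles=None, other_alleles=None) -> pd.DataFrame:
    """Per-variant OLS of a continuous trait, covariate-adjusted.

    Uses Frisch-Waugh residualisation: trait and genotypes are projected off
    the covariates (plus intercept) once, then every slope is a ratio of
    cross-products, so the scan is a single matrix product.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    n, m = G.shape
    y = np.asarray(y, dtype=float)
    C = np.empty((n, 0)) if covariates is None else np.atleast_2d(
        np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    snp_ids = [f"snp{j}" for j in range(m)] if snp_ids is None else list(snp_ids)
    effect_alleles = ["A"] * m if effect_alleles is None else list(effect_alleles)
    other_alleles = ["G"] * m if other_alleles is None else list(other_alleles)

    Q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)), C]))
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)
    gss = (G_res**2).sum(axis=0)
    eaf = G.mean(axis=0) / 2.0
    dof = n - Q.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (G_res.T @ y_res) / gss
        rss = (y_res**2).sum() - beta**2 * gss
        se = np.sqrt(np.maximum(rss, 0.0) / dof / gss)
    beta = np.where(gss > 0, beta, np.nan)
    se = np.where(gss > 0, se, np.nan)
    with np.errstate(invalid="ignore"):
        pval = 2.0 * stats.t.sf(np.abs(beta / se), dof)
    return pd.DataFrame(
        {"snp": snp_ids, "effect_allele": effect_alleles,
         "other_allele": other_alleles, "eaf": eaf, "beta": beta, "se": se,
         "pval": pval, "n": n},
        columns=_SUMMARY_COLUMNS,
    )
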