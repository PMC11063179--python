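"""Instrument selection: greedy P-value / LD / distance clumping.

Candidates are sorted by ascending association P (ties broken by genomic
position, then id).  A variant is accepted iff its P is below the
significance threshold AND it is in low LD (r^2 at or below the threshold)
with every previously accepted variant AND it lies further than the distance
window from every accepted variant on the same chromosome.  The result is
deterministic and inclusion-maximal under the greedy order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClumpConfig", "clump", "ld_matrix", "read_ld_matrix"]


@dataclass(frozen=True)
class ClumpConfig:
    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    distance_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.distance_kb <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0, 1]")


def ld_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between variant columns (monomorphic columns give 0)."""
    G = np.asarray(genotypes, dtype=float)
    sd = G.std(axis=0)
    Z = (G - G.mean(axis=0)) / np.where(sd > 0, sd, np.nan)
    r = np.nan_to_num(Z.T @ Z / G.shape[0])
    np.fill_diagonal(r, 1.0)
    return r**2


def read_ld_matrix(path) -> np.ndarray:
    """Read a square r^2 matrix from whitespace-delimited text (or .mtx)."""
    path = str(path)
    if path.endswith(".mtx"):
        from scipy.io import mmread

        mat = mmread(path)
        return np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
    return np.loadtxt(path)


def clump(
    summary: pd.DataFrame,
    ld: np.ndarray,
    config: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Greedy clumping of a summary-stat table.

    ``summary`` needs columns ``snp, chrom, pos, pval``; ``ld`` is the square
    r^2 matrix aligned with the row order of ``summary``.  Returns the kept
    variant ids in acceptance order.
    """
    required = {"snp", "chrom", "pos", "pval"}
    if not required <= set(summary.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    m = len(summary)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (m, m):
        raise ValueError(
            f"LD matrix shape {ld.shape} does not cover the {m} candidates"
        )
    if np.isnan(ld).any():
        raise ValueError("LD matrix contains missing entries")

    order = summary.reset_index(drop=True).sort_values(
        ["pval", "chrom", "pos", "snp"], kind="mergesort"
    )
    kept: list[int] = []
    dist = config.distance_kb * 1000.0
    for i, rec in zip(order.index, order.itertuples(index=False)):
        if rec.pval >= config.p_threshold:
            break  # sorted by P: nothing further can pass
        ok = True
        for k in kept:
            if ld[i, k] > config.r2_threshold:
                ok = False
                break
            same_chrom = summary["chrom"].iloc[k] == rec.chrom
            if same_chrom and abs(summary["pos"].iloc[k] - rec.pos) <= dist:
                ok = False
                break
        if ok:
            kept.append(i)
    return summary["snp"].iloc[kept].tolist()
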