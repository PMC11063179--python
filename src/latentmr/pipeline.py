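"""End-to-end pipeline: simulate -> instruments -> one-sample -> two-sample ->
Steiger filter -> mediation, driven by a YAML config.

Output is a results bundle in the configured directory: ``results.json`` with
every estimate (stamped with the config hash and seed), TSV tables of the
summary statistics and Steiger results, a run log, and an optional scatter
plot of per-variant exposure vs outcome effects with fitted estimator lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import latent_scale as ls
from .mediation import estimate_mediation
from .onesample import OneSampleMR, ph_diagnostic
from .ordinal import OrderedProbit
from .simulate import Cohort, SimulationConfig, export_summary_stats, simulate_two_cohorts
from .steiger import filter_instruments
from .twosample import Egger, IVW, RAPS, WeightedMedian, harmonise

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "run_pipeline"]

log = logging.getLogger("latentmr")

_ESTIMATORS = {
    "ivw": IVW,
    "weighted_median": WeightedMedian,
    "raps": RAPS,
    "egger": Egger,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed numerically (exit code 3 in the CLI)."""


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "latentmr_results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    theta2_grid: tuple[float, ...] = ls.DEFAULT_THETA2_GRID
    sigma_L_mode: str = "marginal"  # or "probit" (covariate-adjusted)
    estimators: tuple[str, ...] = ("ivw", "weighted_median", "raps", "egger")
    steiger_threshold: float = 0.05
    n_boot_median: int = 1000
    n_boot_mediation: int = 1000
    run_onesample: bool = True
    run_twosample: bool = True
    run_steiger: bool = True
    run_mediation: bool = True
    make_plot: bool = False

    def __post_init__(self) -> None:
        if self.sigma_L_mode not in ("marginal", "probit"):
            raise ConfigError("sigma_L_mode must be 'marginal' or 'probit'")
        unknown = set(self.estimators) - set(_ESTIMATORS)
        if unknown:
            raise ConfigError(f"unknown estimators: {sorted(unknown)}")
        if not self.theta2_grid:
            raise ConfigError("theta2_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        if overrides:
            raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("simulation", {})
        if not isinstance(sim_raw, dict):
            raise ConfigError("simulation section must be a mapping")
        sim_allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_allowed
        if sim_unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(sim_unknown)}")
        for key in ("allele_freq_range", "thresholds", "confounder_effect"):
            if key in sim_raw and isinstance(sim_raw[key], list):
                sim_raw[key] = tuple(sim_raw[key])
        try:
            sim = SimulationConfig(**sim_raw)
            for key in ("theta2_grid", "estimators"):
                if key in raw and isinstance(raw[key], list):
                    raw[key] = tuple(raw[key])
            return cls(simulation=sim, **raw)
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _sigma_L_for(cohort: Cohort, mode: str) -> float:
    freqs = ls.CategoryFrequencies.from_categories(
        cohort.data["exposure_category"].to_numpy()
    )
    if mode == "marginal":
        return ls.estimate_sigma_L(freqs, cohort.config.thresholds)
    fit = OrderedProbit().fit(
        cohort.covariate_matrix, cohort.data["exposure_category"].to_numpy()
    )
    return ls.sigma_L_from_cutpoints(fit.cutpoints_, cohort.config.thresholds)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except (ConfigError, PipelineError):
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("simulate")
def _simulate(cfg: PipelineConfig):
    sim = cfg.simulation.replace(seed=cfg.seed)
    exp, out = simulate_two_cohorts(sim)
    log.info(
        "simulated 2 x %d individuals, %d instruments (+%d mediator SNPs), "
        "event rates %.3f / %.3f",
        sim.n_individuals, sim.n_snps, sim.n_mediator_snps,
        exp.event_rate, out.event_rate,
    )
    return exp, out


@_stage("onesample")
def _onesample(cfg, exp, sigma_L, instrument_subset=None, tag="all"):
    rows = []
    cohort = exp
    if instrument_subset is not None:
        keep_cols = np.concatenate([
            exp.instrument_index[instrument_subset], exp.mediator_index
        ])
        cohort = Cohort(
            genotypes=exp.genotypes[:, keep_cols],
            snps=exp.snps.iloc[keep_cols].reset_index(drop=True),
            data=exp.data, config=exp.config,
        )
    for theta2 in cfg.theta2_grid:
        est = OneSampleMR(theta2=theta2, sigma_L=sigma_L).fit(cohort)
        rec = est.estimate_.to_dict()
        rec["instrument_set"] = tag
        r, p = ph_diagnostic(est)
        rec["ph_corr"], rec["ph_pval"] = r, p
        rows.append(rec)
    return rows


@_stage("twosample")
def _twosample(cfg, table, sigma_L, tag="all"):
    rows = []
    for name in cfg.estimators:
        for theta2 in cfg.theta2_grid:
            kwargs = {"theta2": theta2, "sigma_L": sigma_L}
            if name == "weighted_median":
                kwargs.update(n_boot=cfg.n_boot_median, seed=cfg.seed)
            est = _ESTIMATORS[name](**kwargs).fit(table)
            rec = est.estimate_.to_dict()
            rec["instrument_set"] = tag
            rows.append(rec)
    return rows


@_stage("steiger")
def _steiger(cfg, exp):
    idx = exp.instrument_index
    traits = pd.DataFrame(
        {
            "outcome": exp.data["event_indicator"].to_numpy(float),
            "mediator": exp.data["mediator"].to_numpy(float),
        }
    )
    kept, results = filter_instruments(
        exp.genotypes[:, idx].astype(float),
        exp.data["exposure_category"].to_numpy(float),
        traits,
        threshold=cfg.steiger_threshold,
        snp_ids=exp.snps["snp"].iloc[idx],
    )
    n_flagged = idx.size - kept.size
    log.info("Steiger filtering: %d of %d instruments flagged, %d kept",
             n_flagged, idx.size, kept.size)
    return kept, results


@_stage("mediate")
def _mediate(cfg, exp, out, sigma_L):
    rows = []
    for theta2 in cfg.theta2_grid:
        med, total, direct = estimate_mediation(
            exp, out, theta2, sigma_L,
            n_boot=cfg.n_boot_mediation, seed=cfg.seed,
        )
        rec = med.to_dict()
        rec["total_or"] = float(np.exp(total.beta_L))
        rec["direct_or"] = float(np.exp(direct.beta_L))
        rows.append(rec)
    return rows


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every enabled stage; write the bundle; return the results dict."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }

    exp, out = _simulate(cfg)
    sigma_L = _sigma_L_for(exp, cfg.sigma_L_mode)
    freqs = ls.CategoryFrequencies.from_categories(
        exp.data["exposure_category"].to_numpy())
    results["sigma_L"] = sigma_L
    results["category_frequencies"] = list(freqs.as_array())
    results["theta2_generated"] = exp.theta2_generated
    results["event_rate"] = exp.event_rate

    exp_tab, out_tab = export_summary_stats(exp, out)
    table = harmonise(exp_tab, out_tab)
    exp_tab.to_csv(outdir / "exposure_summary.tsv", sep="\t", index=False)
    out_tab.to_csv(outdir / "outcome_summary.tsv", sep="\t", index=False)

    if cfg.run_onesample:
        results["onesample"] = _onesample(cfg, exp, sigma_L)
    if cfg.run_twosample:
        results["twosample"] = _twosample(cfg, table, sigma_L)
    if cfg.run_steiger:
        kept, stg = _steiger(cfg, exp)
        stg.to_csv(outdir / "steiger.tsv", sep="\t", index=False)
        kept_ids = exp.snps["snp"].iloc[exp.instrument_index[kept]]
        filtered = table[table["snp"].isin(set(kept_ids))]
        results["steiger"] = {
            "n_flagged": int(exp.instrument_index.size - kept.size),
            "kept": list(kept_ids),
        }
        if cfg.run_onesample:
            results["onesample_steiger"] = _onesample(
                cfg, exp, sigma_L, instrument_subset=kept, tag="steiger")
        if cfg.run_twosample:
            results["twosample_steiger"] = _twosample(
                cfg, filtered, sigma_L, tag="steiger")
    if cfg.run_mediation:
        results["mediation"] = _mediate(cfg, exp, out, sigma_L)

    if cfg.make_plot:
        _scatter_plot(table, cfg, sigma_L, outdir / "instruments.png")

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    log.info("results bundle written to %s", outdir)
    return results


def _scatter_plot(table, cfg, sigma_L, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.errorbar(table["alpha_hat"], table["b"], xerr=table["se_alpha"],
                yerr=table["se_b"], fmt="o", ms=3, alpha=0.6, lw=0.5)
    grid = np.linspace(table["alpha_hat"].min(), table["alpha_hat"].max(), 2)
    for name in cfg.estimators:
        est = _ESTIMATORS[name](theta2=cfg.theta2_grid[0], sigma_L=sigma_L)
        est.fit(table)
        icept = getattr(est.estimate_, "intercept", None) or 0.0
        ax.plot(grid, icept + est.beta_ * grid, label=name)
    ax.set_xlabel("variant-exposure effect (probit scale)")
    ax.set_ylabel("variant-outcome effect (log odds)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
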