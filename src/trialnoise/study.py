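"""Simulation-study engine: generate, estimate three ways, score.

Each study simulates trial-level data sets from known truth and compares
three estimators of the latent between-task correlations:

* sample correlations of person-by-task effects (attenuated),
* Spearman-corrected correlations using variance-components
  reliabilities (disattenuated in expectation but unstable), and
* posterior means and 95% equal-tailed intervals from the hierarchical
  multi-task model.

Quality is summarized by RMSE against truth (capturing both bias and
imprecision) and, for the model, by credible-interval coverage.

Replicates are seeded counter-style: child seed sequences are spawned
from the master seed per replicate, so any study is exactly reproducible
from (config, seed) and replicates are independent streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from trialnoise.descriptives import (
    clip_correlation,
    full_reliability,
    person_task_effects,
    sample_correlation,
    spearman_correction,
    split_half_reliability,
)
from trialnoise.models import McmcSettings, MultiTaskModel
from trialnoise.simulate import (
    SIX_TASK_ETA,
    SIX_TASK_LOADINGS,
    simulate_six_task,
    simulate_two_task,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_two_task_study",
    "run_six_task_study",
    "run_spearman_instability_study",
    "rmse",
    "coverage",
    "summarize_study",
]


@dataclass
class StudyConfig:
    """Settings for a simulation study.

    ``replicates`` may be an int (same count everywhere) or, for the
    two-task design, a mapping from rho level to count.  ``reliability``
    selects the Spearman-correction denominator: ``"full"``
    (variance-components, default) or ``"split_half"``.
    """

    design: str = "two_task"  # two_task | six_task | spearman_instability
    replicates: int | dict = 100
    rho_grid: tuple = (0.2, 0.5, 0.8)
    rho: float = 0.8  # instability design
    I: int = 200
    L: int = 100
    sigma: float = 200.0
    sigma_theta: float = 25.0
    w: tuple = SIX_TASK_LOADINGS
    eta: float = SIX_TASK_ETA
    include_model: bool = True
    clip_spearman: bool = True
    reliability: str = "full"
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("two_task", "six_task", "spearman_instability"):
            raise ValueError(f"unknown design {self.design!r}")
        reps = (
            self.replicates.values()
            if isinstance(self.replicates, dict)
            else [self.replicates]
        )
        if any(r < 1 for r in reps):
            raise ValueError("replicates must be >= 1")
        if self.design == "two_task" and not self.rho_grid:
            raise ValueError("rho_grid must be non-empty")

    def reps_for(self, level: float) -> int:
        if isinstance(self.replicates, dict):
            return int(self.replicates[level])
        return int(self.replicates)


@dataclass
class StudyResult:
    """Per-replicate estimates plus the config that produced them.

    ``records`` has one row per replicate (and, for six tasks, per task
    pair): truth, the three estimates, and model interval bounds where
    applicable.  Summaries are always recomputed from these records via
    :func:`summarize_study`.
    """

    design: str
    records: pd.DataFrame
    config: StudyConfig

    def summary(self) -> dict:
        return summarize_study(self)


def rmse(estimates, truths) -> float:
    """Root-mean-square error, missing pairs excluded with a count report.

    Captures both bias and imprecision; undefined (NaN, with a warning)
    when no complete pairs remain.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")
    if est.size == 0:
        raise ValueError("need at least one pair")
    ok = np.isfinite(est) & np.isfinite(tru)
    n_missing = int((~ok).sum())
    if n_missing:
        warnings.warn(f"excluding {n_missing} missing pairs from RMSE", stacklevel=2)
    if not ok.any():
        warnings.warn("all pairs missing; RMSE undefined", stacklevel=2)
        return float("nan")
    return float(np.sqrt(np.mean((est[ok] - tru[ok]) ** 2)))


def coverage(intervals, truths) -> float:
    """Fraction of (lo, hi) intervals containing the true value."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    tru = np.asarray(truths, dtype=float)
    if arr.shape[0] != tru.shape[0]:
        raise ValueError("intervals and truths must have equal length")
    if np.any(arr[:, 0] > arr[:, 1]):
        raise ValueError("intervals must have lo <= hi")
    return float(np.mean((arr[:, 0] <= tru) & (tru <= arr[:, 1])))


def _reliability_fn(config: StudyConfig):
    if config.reliability == "full":
        return full_reliability
    if config.reliability == "split_half":
        return split_half_reliability
    raise ValueError(f"unknown reliability method {config.reliability!r}")


def _replicate_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def _mcmc_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def _fit_model(table, config: StudyConfig, seed: int) -> pd.DataFrame:
    model = MultiTaskModel(
        iterations=config.mcmc.iterations,
        burn_in=config.mcmc.burn_in,
        thin=config.mcmc.thin,
        chains=config.mcmc.chains,
        seed=seed,
        keep_person_draws=False,
        check_convergence=False,
    ).fit(table)
    return model.correlation_summary_


def _spearman_for_pair(eff, rel: dict, task_a, task_b) -> tuple[float, float]:
    r = sample_correlation(eff, task_a, task_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corrected = spearman_correction(r, rel[task_a], rel[task_b])
    return r, corrected


def run_two_task_study(config: StudyConfig) -> StudyResult:
    """Two-task design: each rho level replicated, three estimators each.

    At the default conditions each replicate is an 80,000-trial data set
    (I=200 persons x 2 tasks x 2 conditions x L=100 trials).
    """
    rel_fn = _reliability_fn(config)
    rows = []
    total = sum(config.reps_for(rho) for rho in config.rho_grid)
    seeds = iter(_replicate_seeds(config.seed, total))
    for rho in config.rho_grid:
        for rep in range(config.reps_for(rho)):
            ss = next(seeds)
            sim_ss, fit_ss = ss.spawn(2)
            table, truth = simulate_two_task(
                rho,
                I=config.I,
                L=config.L,
                sigma=config.sigma,
                sigma_theta=config.sigma_theta,
                rng=np.random.default_rng(sim_ss),
            )
            eff = person_task_effects(table)
            rel = {t: rel_fn(table, t).value for t in ("task1", "task2")}
            r, corrected = _spearman_for_pair(eff, rel, "task1", "task2")
            row = {
                "rho_level": rho,
                "replicate": rep,
                "true_rho": rho,
                "sample_r": r,
                "spearman_raw": corrected,
                "spearman_clipped": clip_correlation(corrected),
            }
            if config.include_model:
                summ = _fit_model(table, config, _mcmc_seed(fit_ss))
                row["model_mean"] = float(summ["mean"].iloc[0])
                row["model_lo"] = float(summ["lo"].iloc[0])
                row["model_hi"] = float(summ["hi"].iloc[0])
            rows.append(row)
    return StudyResult("two_task", pd.DataFrame(rows), config)


def run_six_task_study(config: StudyConfig) -> StudyResult:
    """Six-task one-factor design: all 15 pairwise correlations per run.

    True correlations come from Sigma = w w' + eta^2 I and span near zero
    to about 0.80; each replicate is a 240,000-trial data set at the
    defaults.
    """
    rel_fn = _reliability_fn(config)
    n_reps = config.reps_for(None) if isinstance(config.replicates, int) else None
    if n_reps is None:
        raise ValueError("six_task design takes an integer replicate count")
    rows = []
    seeds = _replicate_seeds(config.seed, n_reps)
    for rep, ss in enumerate(seeds):
        sim_ss, fit_ss = ss.spawn(2)
        table, truth = simulate_six_task(
            I=config.I,
            L=config.L,
            sigma=config.sigma,
            rng=np.random.default_rng(sim_ss),
        )
        eff = person_task_effects(table)
        tasks = [f"task{j + 1}" for j in range(6)]
        rel = {t: rel_fn(table, t).value for t in tasks}
        model_summ = (
            _fit_model(table, config, _mcmc_seed(fit_ss))
            if config.include_model
            else None
        )
        for j, k in combinations(range(6), 2):
            ta, tb = tasks[j], tasks[k]
            r, corrected = _spearman_for_pair(eff, rel, ta, tb)
            row = {
                "replicate": rep,
                "task_a": ta,
                "task_b": tb,
                "true_rho": float(truth.true_correlations[j, k]),
                "sample_r": r,
                "spearman_raw": corrected,
                "spearman_clipped": clip_correlation(corrected),
            }
            if model_summ is not None:
                sel = model_summ[
                    (model_summ["task_a"] == ta) & (model_summ["task_b"] == tb)
                ].iloc[0]
                row["model_mean"] = float(sel["mean"])
                row["model_lo"] = float(sel["lo"])
                row["model_hi"] = float(sel["hi"])
            rows.append(row)
    return StudyResult("six_task", pd.DataFrame(rows), config)


def run_spearman_instability_study(config: StudyConfig | None = None) -> StudyResult:
    """Distribution of Spearman-corrected correlations at fixed truth.

    Defaults to the typical conditions (rho=.8, I=200, L=100,
    sigma=200 ms, sigma_theta=25 ms) with 1000 replicates and no MCMC;
    the headline summary is the fraction of corrected values above 1.0.
    """
    if config is None:
        config = StudyConfig(
            design="spearman_instability", replicates=1000, include_model=False
        )
    rel_fn = _reliability_fn(config)
    rows = []
    n_reps = config.reps_for(config.rho) if isinstance(config.replicates, dict) else int(config.replicates)
    for rep, ss in enumerate(_replicate_seeds(config.seed, n_reps)):
        table, truth = simulate_two_task(
            config.rho,
            I=config.I,
            L=config.L,
            sigma=config.sigma,
            sigma_theta=config.sigma_theta,
            rng=np.random.default_rng(ss),
        )
        eff = person_task_effects(table)
        rel = {t: rel_fn(table, t).value for t in ("task1", "task2")}
        r, corrected = _spearman_for_pair(eff, rel, "task1", "task2")
        rows.append(
            {
                "replicate": rep,
                "true_rho": config.rho,
                "sample_r": r,
                "spearman_raw": corrected,
                "spearman_clipped": clip_correlation(corrected),
            }
        )
    return StudyResult("spearman_instability", pd.DataFrame(rows), config)


def _method_columns(records: pd.DataFrame, clip: bool) -> dict[str, str]:
    methods = {
        "sample": "sample_r",
        "spearman": "spearman_clipped" if clip else "spearman_raw",
    }
    if "model_mean" in records.columns:
        methods["model"] = "model_mean"
    return methods


def summarize_study(result: StudyResult) -> dict:
    """Tidy summary tables recomputed from the per-replicate records.

    Returns a dict of DataFrames/values keyed by summary name; the exact
    keys depend on the design (per-method RMSE, per-level coverage, a
    long boxplot-ready table, and for the instability design the
    min/max/fraction-above-1 digest).
    """
    records = result.records
    if records.empty:
        raise ValueError("empty study result")
    cfg = result.config
    out: dict = {}
    methods = _method_columns(records, clip=cfg.clip_spearman)
    long = records.melt(
        id_vars=[c for c in ("rho_level", "replicate", "task_a", "task_b", "true_rho")
                 if c in records.columns],
        value_vars=list(methods.values()),
        var_name="method",
        value_name="estimate",
    )
    inverse = {v: k for k, v in methods.items()}
    long["method"] = long["method"].map(inverse)
    out["long"] = long

    if result.design == "spearman_instability":
        raw = records["spearman_raw"].to_numpy()
        finite = raw[np.isfinite(raw)]
        out["instability"] = {
            "n": int(len(records)),
            "n_defined": int(len(finite)),
            "min": float(finite.min()),
            "max": float(finite.max()),
            "mean": float(finite.mean()),
            "fraction_gt_1": float(np.mean(finite > 1.0)),
            "percent_gt_1": float(100.0 * np.mean(finite > 1.0)),
        }
        return out

    # per-method RMSE (pooled over pairs and replicates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rmse_rows = [
            {"method": m, "rmse": rmse(records[col], records["true_rho"]),
             "n_missing": int((~np.isfinite(records[col])).sum())}
            for m, col in methods.items()
        ]
    out["rmse"] = pd.DataFrame(rmse_rows)

    if result.design == "two_task":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            by_level = [
                {"method": m, "rho_level": lvl,
                 "rmse": rmse(g[col], g["true_rho"])}
                for m, col in methods.items()
                for lvl, g in records.groupby("rho_level")
            ]
        out["rmse_by_level"] = pd.DataFrame(by_level)

    if "model_lo" in records.columns:
        cov_rows = []
        if "rho_level" in records.columns:
            for lvl, g in records.groupby("rho_level"):
                cov_rows.append(
                    {"rho_level": lvl,
                     "coverage": coverage(g[["model_lo", "model_hi"]].to_numpy(),
                                          g["true_rho"])}
                )
        cov_rows.append(
            {"rho_level": "pooled",
             "coverage": coverage(records[["model_lo", "model_hi"]].to_numpy(),
                                  records["true_rho"])}
        )
        out["coverage"] = pd.DataFrame(cov_rows)
    return out
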