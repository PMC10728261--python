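"""Classical estimators for contrast-based tasks.

Sample effects (person-by-task difference scores), split-half and
variance-components ("full") reliabilities, Pearson correlations of
effects, and Spearman's correction for attenuation.

The sample effect for person i on task j is

    d_ij = mean RT(incongruent) - mean RT(congruent),

in milliseconds.  Because each d_ij carries trial noise of variance
``sigma^2 (1/L_cong + 1/L_incong)``, correlations between columns of d are
attenuated relative to the latent correlations of true effects; the
estimators here quantify and (via Spearman's correction) undo that
attenuation, at the price of instability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialnoise.trial_data import CONGRUENT, INCONGRUENT, TrialTable

__all__ = [
    "EffectTable",
    "ReliabilityEstimate",
    "UndefinedResult",
    "person_task_effects",
    "sample_correlation",
    "split_half_reliability",
    "spearman_brown",
    "full_reliability",
    "spearman_correction",
    "clip_correlation",
]


class UndefinedResult(Warning):
    """Signalled when an estimator's result is mathematically undefined."""


@dataclass
class EffectTable:
    """Person-by-task sample effects with per-task summaries.

    ``effects`` has one row per person-by-task:
    ``person, task, effect, n_congruent, n_incongruent``;
    ``summary`` has one row per task: ``task, mean_effect, sd_effect,
    n_persons`` where ``sd_effect`` is s_d, the SD of persons' sample
    effects (signal plus trial noise).
    """

    effects: pd.DataFrame
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            self.summary = _summarize_effects(self.effects)

    def pivot(self) -> pd.DataFrame:
        """Person-by-task wide matrix of effects (NaN where missing)."""
        return self.effects.pivot(index="person", columns="task", values="effect")


def _summarize_effects(effects: pd.DataFrame) -> pd.DataFrame:
    g = effects.groupby("task", observed=True)["effect"]
    return (
        pd.DataFrame(
            {
                "mean_effect": g.mean(),
                "sd_effect": g.std(ddof=1),
                "n_persons": g.size(),
            }
        )
        .reset_index()
    )


@dataclass
class ReliabilityEstimate:
    """A per-task reliability with the ingredients that produced it.

    ``method`` is ``"full"`` (variance components) or ``"split_half"``.
    ``value`` may be negative for the full method when the moment estimate
    of true variance is negative; it is reported as-is, never truncated.
    """

    task: object
    method: str
    value: float
    detail: dict = field(default_factory=dict)


def _cell_stats(table: TrialTable) -> pd.DataFrame:
    """Per person x task x condition: trial count, mean, within-cell SS."""
    df = table.data
    work = pd.DataFrame(
        {
            "person": df["person"].to_numpy(),
            "task": df["task"].to_numpy(),
            "condition": df["condition"].to_numpy(),
            "rt": df["rt"].to_numpy(),
            "rt2": df["rt"].to_numpy() ** 2,
        }
    )
    out = work.groupby(["person", "task", "condition"], observed=True).agg(
        n=("rt", "size"), s=("rt", "sum"), s2=("rt2", "sum")
    )
    out["mean"] = out["s"] / out["n"]
    out["ss"] = np.maximum(out["s2"] - out["s"] ** 2 / out["n"], 0.0)
    return out.drop(columns=["s", "s2"]).reset_index()


def person_task_effects(table: TrialTable) -> EffectTable:
    """Tabulate sample effects d_ij = mean(incongruent) - mean(congruent).

    Person-by-task cells missing either condition are dropped with a
    warning; everything else is one row per person-by-task.
    """
    df = table.data
    means = (
        df.groupby(["person", "task", "condition"], observed=True)["rt"]
        .agg(["mean", "size"])
        .unstack("condition")
    )
    have_both = means["mean"].get(CONGRUENT)
    if (
        CONGRUENT not in means["mean"].columns
        or INCONGRUENT not in means["mean"].columns
    ):
        raise ValueError("table must contain both conditions")
    ok = means["mean"][CONGRUENT].notna() & means["mean"][INCONGRUENT].notna()
    if (~ok).any():
        dropped = means.index[~ok].tolist()
        warnings.warn(
            f"dropping {len(dropped)} person x task cells missing a condition: "
            f"{dropped[:10]}",
            stacklevel=2,
        )
    means = means.loc[ok]
    effects = pd.DataFrame(
        {
            "person": means.index.get_level_values("person"),
            "task": means.index.get_level_values("task"),
            "effect": (
                means["mean"][INCONGRUENT] - means["mean"][CONGRUENT]
            ).to_numpy(),
            "n_congruent": means["size"][CONGRUENT].to_numpy().astype(int),
            "n_incongruent": means["size"][INCONGRUENT].to_numpy().astype(int),
        }
    ).reset_index(drop=True)
    return EffectTable(effects)


def sample_correlation(effects: EffectTable, task_a, task_b) -> float:
    """Pearson correlation of paired sample effects for two tasks.

    Persons missing either task are excluded pairwise.  Returns NaN (with
    an :class:`UndefinedResult` warning) when fewer than 3 complete pairs
    remain or either task has zero variance.
    """
    wide = effects.pivot()
    for t in (task_a, task_b):
        if t not in wide.columns:
            raise KeyError(f"task {t!r} not present")
    pair = wide[[task_a, task_b]].dropna()
    if len(pair) < 3:
        warnings.warn("fewer than 3 complete pairs", UndefinedResult, stacklevel=2)
        return float("nan")
    x = pair[task_a].to_numpy()
    y = pair[task_b].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in a task", UndefinedResult, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_brown(r_half: float) -> float:
    """Spearman-Brown step-up of a half-test correlation: 2r/(1+r)."""
    if not -1 <= r_half <= 1:
        raise ValueError("r_half must lie in [-1, 1]")
    if r_half == -1:
        warnings.warn("r_half = -1 has no Spearman-Brown value", UndefinedResult,
                      stacklevel=2)
        return float("nan")
    return 2.0 * r_half / (1.0 + r_half)


def split_half_reliability(table: TrialTable, task_id) -> ReliabilityEstimate:
    """Even/odd split-half reliability of a task's sample effects.

    Trials are split by their 0-based index within each person-by-condition
    cell in file order (a deterministic split); effects are computed on each
    half, correlated across persons, and stepped up with Spearman-Brown.
    Persons lacking a trial in every half-by-condition cell are dropped with
    a warning.
    """
    df = table.data[table.data["task"] == task_id]
    if df.empty:
        raise KeyError(f"task {task_id!r} not present")
    df = df.copy()
    df["half"] = df.groupby(["person", "condition"], observed=True).cumcount() % 2
    means = (
        df.groupby(["person", "condition", "half"], observed=True)["rt"]
        .mean()
        .unstack(["condition", "half"])
    )
    needed = [(c, h) for c in (CONGRUENT, INCONGRUENT) for h in (0, 1)]
    for col in needed:
        if col not in means.columns:
            means[col] = np.nan
    ok = means[needed].notna().all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"dropping {int((~ok).sum())} persons with empty half-cells",
            stacklevel=2,
        )
    means = means.loc[ok]
    d_even = means[(INCONGRUENT, 0)] - means[(CONGRUENT, 0)]
    d_odd = means[(INCONGRUENT, 1)] - means[(CONGRUENT, 1)]
    r_half = float(np.corrcoef(d_even, d_odd)[0, 1])
    value = spearman_brown(np.clip(r_half, -1.0, 1.0))
    return ReliabilityEstimate(
        task=task_id,
        method="split_half",
        value=value,
        detail={"r_half": r_half, "n_persons": int(len(means))},
    )


def full_reliability(table: TrialTable, task_id) -> ReliabilityEstimate:
    """Variance-components ("full") reliability of a task's sample effects.

    Pools the within person-by-condition trial variance into sigma^2-hat,
    subtracts each person's implied effect-error variance
    ``sigma^2-hat (1/L_cong + 1/L_incong)`` from the observed variance of
    sample effects, and reports the ratio of the moment estimate of true
    variance to the observed variance.  Uses cross-trial variability like an
    ANOVA decomposition, so it is more efficient than the split-half
    estimate; the value can be negative when sampling error dominates.
    """
    sub = TrialTable(table.data[table.data["task"] == task_id])
    if len(sub) == 0:
        raise KeyError(f"task {task_id!r} not present")
    cells = _cell_stats(sub)
    dof = (cells["n"] - 1).sum()
    if dof <= 0:
        raise ValueError("need >= 2 trials in at least one cell")
    sigma2_hat = float(cells["ss"].sum() / dof)
    eff = person_task_effects(sub).effects
    var_d = float(np.var(eff["effect"], ddof=1))
    err_var = sigma2_hat * (1.0 / eff["n_congruent"] + 1.0 / eff["n_incongruent"])
    mean_err = float(err_var.mean())
    sigma2_theta_moment = var_d - mean_err
    if var_d == 0:
        warnings.warn("zero variance of sample effects", UndefinedResult,
                      stacklevel=2)
        value = float("nan")
    else:
        value = sigma2_theta_moment / var_d
    return ReliabilityEstimate(
        task=task_id,
        method="full",
        value=value,
        detail={
            "sigma2_hat": sigma2_hat,
            "var_d": var_d,
            "mean_effect_error_var": mean_err,
            "sigma2_theta_moment": sigma2_theta_moment,
            "n_persons": int(len(eff)),
        },
    )


def spearman_correction(r_xy: float, r_xx: float, r_yy: float) -> float:
    """Disattenuate a correlation: r' = r_xy / sqrt(r_xx * r_yy).

    The result is deliberately NOT truncated to [-1, 1]; out-of-range
    values are legal output and diagnostic of the correction's
    instability.  A non-positive reliability product makes the correction
    undefined (NaN with an :class:`UndefinedResult` warning).
    """
    if not np.isfinite(r_xx) or not np.isfinite(r_yy) or r_xx * r_yy <= 0:
        warnings.warn(
            "non-positive reliability product; correction undefined",
            UndefinedResult,
            stacklevel=2,
        )
        return float("nan")
    return float(r_xy / np.sqrt(r_xx * r_yy))


def clip_correlation(r: float) -> float:
    """Clip a correlation estimate to the valid range [-1, 1]."""
    if not np.isfinite(r):
        return float("nan")
    return float(min(1.0, max(-1.0, r)))
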