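"""Hierarchical Bayesian models for trial-level contrast data.

Two conjugate Gibbs samplers, exposed as sklearn-style estimators:

:class:`OneTaskModel`
    Variance-components model for a single task,

        Y_ikl ~ Normal(alpha_i + x_k theta_i, sigma^2),
        theta_i ~ Normal(mu_theta, sigma_theta^2),

    separating trial noise sigma from true individual variation
    sigma_theta.  The posterior means of sigma and sigma_theta are the
    quantities whose ratio gamma = sigma_theta/sigma governs correlation
    attenuation.

:class:`MultiTaskModel`
    The J-task extension with a latent covariance,

        Y_ijkl ~ Normal(alpha_ij + x_k theta_ij, sigma^2),
        theta_i ~ N_J(mu, Sigma_theta),  Sigma_theta ~ Inverse-Wishart,

    whose per-draw correlation matrices rho_jk = Sigma_jk /
    sqrt(Sigma_jj Sigma_kk) estimate the latent (disattenuated)
    correlations among tasks, with honest posterior uncertainty.

All full conditionals are conjugate (normal for alpha, theta and mu;
inverse-gamma for the variances; inverse-Wishart for Sigma_theta), and the
likelihood enters only through per-cell trial counts, means, and the
pooled within-cell sum of squares, so one Gibbs iteration costs O(I*J)
whatever the number of trials.

Priors default to weakly informative settings on the RT scale: baselines
Normal(800, 1000^2) ms, trial variance Inverse-Gamma(0.1, 1e5) ms^2
(i.e. IG(0.1, 0.1) on seconds^2), mean effects Normal(50, 100^2) ms, and
effect variance Inverse-Gamma(2, 900) ms^2 — the last is the informative
choice, encoding that true inhibition effects vary on the order of tens
of ms, and sets the amount of hierarchical regularization.  The
inverse-Wishart uses df = J+3 and scale 1800 I so each diagonal's
marginal is exactly that Inverse-Gamma(2, 900).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from trialnoise.trial_data import CONGRUENT, INCONGRUENT, TrialTable

__all__ = [
    "OneTaskPriors",
    "MultiTaskPriors",
    "McmcSettings",
    "PosteriorDraws",
    "OneTaskModel",
    "MultiTaskModel",
    "fit_one_task",
    "fit_multi_task",
    "posterior_correlation_summary",
    "convergence_diagnostics",
]

RHAT_WARN = 1.05


# --------------------------------------------------------------------------
# priors and settings
# --------------------------------------------------------------------------
@dataclass
class OneTaskPriors:
    """Priors for the one-task variance-components model (ms scale)."""

    alpha_mean: float = 800.0
    alpha_var: float = 1000.0**2
    sigma2_shape: float = 0.1
    sigma2_scale: float = 0.1e6  # IG(0.1, 0.1) on s^2, rescaled to ms^2
    mu_theta_mean: float = 50.0
    mu_theta_var: float = 100.0**2
    sigma2_theta_shape: float = 2.0
    sigma2_theta_scale: float = 30.0**2

    def __post_init__(self) -> None:
        for name in ("alpha_var", "sigma2_shape", "sigma2_scale",
                     "mu_theta_var", "sigma2_theta_shape", "sigma2_theta_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class MultiTaskPriors:
    """Priors for the J-task latent-correlation model (ms scale).

    The inverse-Wishart on Sigma_theta defaults to df = J+3 and scale
    1800 I, so each diagonal's implied marginal is
    Inverse-Gamma((df-J+1)/2, S_jj/2) = Inverse-Gamma(2, 900) — the same
    prior placed on sigma_theta^2 in the one-task model.
    """

    J: int
    alpha_mean: float = 800.0
    alpha_var: float = 1000.0**2
    sigma2_shape: float = 0.1
    sigma2_scale: float = 0.1e6
    mu_mean: float = 50.0
    mu_var: float = 100.0**2
    iw_df: float | None = None
    iw_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.J < 2:
            raise ValueError("MultiTaskPriors needs J >= 2 tasks")
        if self.iw_df is None:
            self.iw_df = self.J + 3
        if self.iw_scale is None:
            self.iw_scale = 1800.0 * np.eye(self.J)
        self.iw_scale = np.asarray(self.iw_scale, dtype=float)
        if self.iw_df <= self.J - 1:
            raise ValueError("iw_df must exceed J - 1")
        if self.iw_scale.shape != (self.J, self.J):
            raise ValueError("iw_scale must be J x J")
        if not np.allclose(self.iw_scale, self.iw_scale.T):
            raise ValueError("iw_scale must be symmetric")
        if np.linalg.eigvalsh(self.iw_scale).min() <= 0:
            raise ValueError("iw_scale must be positive definite")


@dataclass
class McmcSettings:
    """Chain lengths and seeding for the Gibbs samplers."""

    iterations: int = 5000
    burn_in: int = 1000
    thin: int = 1
    chains: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


# --------------------------------------------------------------------------
# draws container
# --------------------------------------------------------------------------
@dataclass
class PosteriorDraws:
    """Retained post-burn-in Gibbs draws, shaped (chains, draws, ...).

    ``Sigma_theta`` is (C, D, J, J); for the one-task model J = 1 and its
    single entry is sigma_theta^2.  ``theta``/``alpha`` are (C, D, I, J)
    and may be omitted to save memory in large simulation studies.
    """

    mu: np.ndarray
    sigma2: np.ndarray
    Sigma_theta: np.ndarray
    tasks: list
    persons: list
    theta: np.ndarray | None = None
    alpha: np.ndarray | None = None

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.mu.shape[1]

    @property
    def J(self) -> int:
        return self.mu.shape[2]

    def sigma_draws(self) -> np.ndarray:
        """Trial-noise SD draws, (C, D)."""
        return np.sqrt(self.sigma2)

    def sigma_theta_draws(self) -> np.ndarray:
        """Per-task true-effect SD draws, (C, D, J)."""
        diag = np.diagonal(self.Sigma_theta, axis1=-2, axis2=-1)
        return np.sqrt(diag)

    def correlation_draws(self) -> np.ndarray:
        """Per-draw latent correlation matrices, (C, D, J, J)."""
        d = np.sqrt(np.diagonal(self.Sigma_theta, axis1=-2, axis2=-1))
        corr = self.Sigma_theta / (d[..., :, None] * d[..., None, :])
        # exact unit diagonal despite float round-off
        idx = np.arange(self.J)
        corr[..., idx, idx] = 1.0
        return corr

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Merge the chain and draw axes of a (C, D, ...) array."""
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])


# --------------------------------------------------------------------------
# sufficient statistics
# --------------------------------------------------------------------------
@dataclass
class _SuffStats:
    persons: list
    tasks: list
    n0: np.ndarray  # (I, J) congruent trial counts
    m0: np.ndarray  # (I, J) congruent cell means
    n1: np.ndarray  # (I, J) incongruent counts
    m1: np.ndarray  # (I, J) incongruent means
    ss_within: float  # pooled within-cell sum of squares
    n_total: int

    @property
    def I(self) -> int:
        return len(self.persons)

    @property
    def J(self) -> int:
        return len(self.tasks)

    def sample_effects(self) -> np.ndarray:
        return self.m1 - self.m0


def _sufficient_stats(table: TrialTable) -> _SuffStats:
    """Per-cell counts, means, and pooled within-cell SS.

    Persons missing any task-by-condition cell are excluded with a
    warning (no missing-data augmentation).
    """
    df = table.data
    if len(df) == 0:
        return _SuffStats([], [], *(np.zeros((0, 0)),) * 4, 0.0, 0)
    work = pd.DataFrame(
        {
            "person": df["person"].to_numpy(),
            "task": df["task"].to_numpy(),
            "condition": df["condition"].to_numpy(),
            "rt": df["rt"].to_numpy(),
            "rt2": df["rt"].to_numpy() ** 2,
        }
    )
    cells = (
        work.groupby(["person", "task", "condition"], observed=True)
        .agg(n=("rt", "size"), s=("rt", "sum"), s2=("rt2", "sum"))
    )
    cells["mean"] = cells["s"] / cells["n"]
    cells["ss"] = np.maximum(cells["s2"] - cells["s"] ** 2 / cells["n"], 0.0)
    n_wide = cells["n"].unstack(["task", "condition"])
    m_wide = cells["mean"].unstack(["task", "condition"])
    tasks = sorted(set(n_wide.columns.get_level_values("task")))
    needed = [(t, c) for t in tasks for c in (CONGRUENT, INCONGRUENT)]
    for col in needed:
        if col not in n_wide.columns:
            n_wide[col] = np.nan
            m_wide[col] = np.nan
    complete = n_wide[needed].notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"excluding {int((~complete).sum())} persons missing some "
            "task x condition cell",
            stacklevel=2,
        )
    n_wide = n_wide.loc[complete]
    m_wide = m_wide.loc[complete]
    persons = n_wide.index.tolist()
    kept = cells.loc[cells.index.get_level_values("person").isin(set(persons))]
    n0 = n_wide.loc[:, [(t, CONGRUENT) for t in tasks]].to_numpy(dtype=float)
    m0 = m_wide.loc[:, [(t, CONGRUENT) for t in tasks]].to_numpy(dtype=float)
    n1 = n_wide.loc[:, [(t, INCONGRUENT) for t in tasks]].to_numpy(dtype=float)
    m1 = m_wide.loc[:, [(t, INCONGRUENT) for t in tasks]].to_numpy(dtype=float)
    return _SuffStats(
        persons=persons,
        tasks=tasks,
        n0=n0,
        m0=m0,
        n1=n1,
        m1=m1,
        ss_within=float(kept["ss"].sum()),
        n_total=int(kept["n"].sum()),
    )


def _draw_invgamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    """Inverse-gamma draw, shape/scale parameterization."""
    return scale / rng.gamma(shape)


def _draw_invwishart(
    rng: np.random.Generator, df: float, scale: np.ndarray
) -> np.ndarray:
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng)


# --------------------------------------------------------------------------
# Gibbs kernels
# --------------------------------------------------------------------------
def _run_one_task_chain(
    st: _SuffStats,
    priors: OneTaskPriors,
    mcmc: McmcSettings,
    rng: np.random.Generator,
    fix_alpha: np.ndarray | None = None,
    fix_sigma2: float | None = None,
) -> dict:
    I = st.I
    n0 = st.n0[:, 0] if I else np.zeros(0)
    m0 = st.m0[:, 0] if I else np.zeros(0)
    n1 = st.n1[:, 0] if I else np.zeros(0)
    m1 = st.m1[:, 0] if I else np.zeros(0)

    # moment-based initialization
    d = m1 - m0
    alpha = m0.copy() if fix_alpha is None else np.broadcast_to(
        np.asarray(fix_alpha, float), (max(I, 1),)
    )[:I].copy()
    theta = d.copy()
    mu = float(np.mean(d)) if I else priors.mu_theta_mean
    dof = st.n_total - 2 * I
    if fix_sigma2 is not None:
        sigma2 = float(fix_sigma2)
    elif dof > 0 and st.ss_within > 0:
        sigma2 = st.ss_within / dof
    else:
        sigma2 = priors.sigma2_scale / (priors.sigma2_shape + 1)
    st2 = float(np.var(d, ddof=1)) if I >= 2 else priors.sigma2_theta_scale / 3
    st2 = max(st2, 1e-6)

    n_kept = mcmc.n_kept
    out = {
        "mu": np.empty((n_kept, 1)),
        "sigma2": np.empty(n_kept),
        "Sigma_theta": np.empty((n_kept, 1, 1)),
        "theta": np.empty((n_kept, I, 1)),
        "alpha": np.empty((n_kept, I, 1)),
    }
    kept = 0
    for it in range(mcmc.iterations):
        if I:
            # alpha_i | rest
            if fix_alpha is None:
                prec = (n0 + n1) / sigma2 + 1.0 / priors.alpha_var
                mean = (
                    (n0 * m0 + n1 * (m1 - theta)) / sigma2
                    + priors.alpha_mean / priors.alpha_var
                ) / prec
                alpha = mean + rng.standard_normal(I) / np.sqrt(prec)
            # theta_i | rest — likelihood from incongruent cells only
            prec = n1 / sigma2 + 1.0 / st2
            mean = (n1 * (m1 - alpha) / sigma2 + mu / st2) / prec
            theta = mean + rng.standard_normal(I) / np.sqrt(prec)
        # mu_theta | theta
        prec = I / st2 + 1.0 / priors.mu_theta_var
        mean = (theta.sum() / st2 + priors.mu_theta_mean / priors.mu_theta_var) / prec
        mu = mean + rng.standard_normal() / np.sqrt(prec)
        # sigma_theta^2 | theta, mu
        st2 = _draw_invgamma(
            rng,
            priors.sigma2_theta_shape + I / 2.0,
            priors.sigma2_theta_scale + 0.5 * np.sum((theta - mu) ** 2),
        )
        # sigma^2 | rest
        if fix_sigma2 is None:
            ssr = st.ss_within + np.sum(
                n0 * (m0 - alpha) ** 2 + n1 * (m1 - alpha - theta) ** 2
            )
            sigma2 = _draw_invgamma(
                rng,
                priors.sigma2_shape + st.n_total / 2.0,
                priors.sigma2_scale + 0.5 * ssr,
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out["mu"][kept, 0] = mu
            out["sigma2"][kept] = sigma2
            out["Sigma_theta"][kept, 0, 0] = st2
            out["theta"][kept, :, 0] = theta
            out["alpha"][kept, :, 0] = alpha
            kept += 1
    return out


def _run_multi_task_chain(
    st: _SuffStats,
    priors: MultiTaskPriors,
    mcmc: McmcSettings,
    rng: np.random.Generator,
    keep_person_draws: bool,
) -> dict:
    I, J = st.I, st.J
    n0, m0, n1, m1 = st.n0, st.m0, st.n1, st.m1
    balanced = I > 0 and np.all(n1 == n1.flat[0])

    # moment-based initialization
    d = m1 - m0 if I else np.zeros((0, J))
    alpha = m0.copy()
    theta = d.copy()
    mu = d.mean(axis=0) if I else np.full(J, priors.mu_mean)
    dof = st.n_total - 2 * I * J
    if dof > 0 and st.ss_within > 0:
        sigma2 = st.ss_within / dof
    else:
        sigma2 = priors.sigma2_scale / (priors.sigma2_shape + 1)
    if I >= 2:
        Sigma = np.cov(d.T) + 1e-3 * np.eye(J)
    else:
        Sigma = priors.iw_scale / (priors.iw_df + J + 1)
    Sigma_inv = np.linalg.inv(Sigma)

    n_kept = mcmc.n_kept
    out = {
        "mu": np.empty((n_kept, J)),
        "sigma2": np.empty(n_kept),
        "Sigma_theta": np.empty((n_kept, J, J)),
    }
    if keep_person_draws:
        out["theta"] = np.empty((n_kept, I, J))
        out["alpha"] = np.empty((n_kept, I, J))
    kept = 0
    eyeJ = np.eye(J)
    for it in range(mcmc.iterations):
        if I:
            # alpha_ij | rest, elementwise normal
            prec = (n0 + n1) / sigma2 + 1.0 / priors.alpha_var
            mean = (
                (n0 * m0 + n1 * (m1 - theta)) / sigma2
                + priors.alpha_mean / priors.alpha_var
            ) / prec
            alpha = mean + rng.standard_normal((I, J)) / np.sqrt(prec)
            # theta_i | rest, multivariate normal per person
            b = n1 * (m1 - alpha) / sigma2 + (Sigma_inv @ mu)  # (I, J)
            z = rng.standard_normal((I, J))
            if balanced:
                P = Sigma_inv + np.diag(n1[0]) / sigma2
                C = np.linalg.inv(P)
                theta = b @ C.T + z @ np.linalg.cholesky(C).T
            else:
                P = Sigma_inv[None, :, :] + (
                    n1[:, :, None] * eyeJ[None, :, :]
                ) / sigma2
                C = np.linalg.inv(P)
                theta = np.einsum("ijk,ik->ij", C, b) + np.einsum(
                    "ijk,ik->ij", np.linalg.cholesky(C), z
                )
        # mu | theta, Sigma
        M = I * Sigma_inv + eyeJ / priors.mu_var
        Cmu = np.linalg.inv(M)
        bmu = Sigma_inv @ theta.sum(axis=0) + priors.mu_mean / priors.mu_var
        mu = Cmu @ bmu + np.linalg.cholesky(Cmu) @ rng.standard_normal(J)
        # Sigma_theta | theta, mu
        dev = theta - mu
        Sigma = _draw_invwishart(rng, priors.iw_df + I, priors.iw_scale + dev.T @ dev)
        Sigma_inv = np.linalg.inv(Sigma)
        # sigma^2 | rest
        if I:
            ssr = st.ss_within + np.sum(
                n0 * (m0 - alpha) ** 2 + n1 * (m1 - alpha - theta) ** 2
            )
        else:
            ssr = 0.0
        sigma2 = _draw_invgamma(
            rng,
            priors.sigma2_shape + st.n_total / 2.0,
            priors.sigma2_scale + 0.5 * ssr,
        )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            out["mu"][kept] = mu
            out["sigma2"][kept] = sigma2
            out["Sigma_theta"][kept] = Sigma
            if keep_person_draws:
                out["theta"][kept] = theta
                out["alpha"][kept] = alpha
            kept += 1
    return out


def _stack_chains(chain_outs: list[dict], st: _SuffStats) -> PosteriorDraws:
    keep_persons = "theta" in chain_outs[0]
    return PosteriorDraws(
        mu=np.stack([c["mu"] for c in chain_outs]),
        sigma2=np.stack([c["sigma2"] for c in chain_outs]),
        Sigma_theta=np.stack([c["Sigma_theta"] for c in chain_outs]),
        theta=np.stack([c["theta"] for c in chain_outs]) if keep_persons else None,
        alpha=np.stack([c["alpha"] for c in chain_outs]) if keep_persons else None,
        tasks=st.tasks,
        persons=st.persons,
    )


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------
def _diag_dict(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Group-level parameters as named (C, D) arrays for diagnostics."""
    out: dict[str, np.ndarray] = {"sigma2": draws.sigma2}
    tasks = draws.tasks or [f"task{j + 1}" for j in range(draws.J)]
    for j, t in enumerate(tasks):
        out[f"mu[{t}]"] = draws.mu[:, :, j]
        out[f"sigma2_theta[{t}]"] = draws.Sigma_theta[:, :, j, j]
    if draws.J > 1:
        corr = draws.correlation_draws()
        for j in range(draws.J):
            for k in range(j + 1, draws.J):
                out[f"rho[{tasks[j]},{tasks[k]}]"] = corr[:, :, j, k]
    return out


def convergence_diagnostics(draws) -> pd.DataFrame:
    """Split-chain R-hat and effective sample size per group-level parameter.

    Accepts a :class:`PosteriorDraws` or a mapping of name -> (chains,
    draws) array.  Single chains are split in half so the diagnostic is
    always defined.
    """
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        named = _diag_dict(draws)
    else:
        named = {k: np.atleast_2d(np.asarray(v)) for k, v in draws.items()}
    rows = []
    for name, arr in named.items():
        if arr.shape[0] == 1:
            half = arr.shape[1] // 2
            arr = np.stack([arr[0, :half], arr[0, half : 2 * half]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data = az.convert_to_dataset(arr)
            rhat = float(az.rhat(data)["x"].values)
            ess = float(az.ess(data)["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)


def posterior_correlation_summary(
    draws: PosteriorDraws, level: float = 0.95
) -> pd.DataFrame:
    """Posterior mean and equal-tailed interval per task pair.

    Returns one row per unordered pair (j < k) with columns
    ``task_a, task_b, mean, lo, hi``.
    """
    if draws.n_draws == 0:
        raise ValueError("no draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    corr = draws.flat(draws.correlation_draws())
    tail = (1.0 - level) / 2.0
    tasks = draws.tasks or [f"task{j + 1}" for j in range(draws.J)]
    rows = []
    for j in range(draws.J):
        for k in range(j + 1, draws.J):
            r = corr[:, j, k]
            rows.append(
                {
                    "task_a": tasks[j],
                    "task_b": tasks[k],
                    "mean": float(np.mean(r)),
                    "lo": float(np.quantile(r, tail)),
                    "hi": float(np.quantile(r, 1.0 - tail)),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------
class _GibbsBase(BaseEstimator):
    def _settings(self) -> McmcSettings:
        return McmcSettings(
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            chains=self.chains,
            seed=self.seed,
        )

    def _chain_rngs(self) -> list[np.random.Generator]:
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in ss.spawn(self.chains)]

    def _check_convergence(self) -> None:
        diag = convergence_diagnostics(self.draws_)
        self.diagnostics_ = diag
        bad = diag[diag["rhat"] > RHAT_WARN]
        if len(bad):
            warnings.warn(
                "possible non-convergence (split R-hat > "
                f"{RHAT_WARN}): {bad['parameter'].tolist()}",
                stacklevel=3,
            )

    @staticmethod
    def _as_table(X) -> TrialTable:
        if isinstance(X, TrialTable):
            return X
        return TrialTable(pd.DataFrame(X))


class OneTaskModel(_GibbsBase):
    """Gibbs sampler for the one-task variance-components model.

    Parameters
    ----------
    priors
        :class:`OneTaskPriors`; defaults encode the RT scale.
    iterations, burn_in, thin, chains, seed
        Chain settings; two chains of 5000 with 1000 burn-in by default.
    check_convergence
        Compute split R-hat/ESS after fitting and warn above 1.05.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    sigma_, sigma_theta_, mu_theta_ : float posterior means
    theta_ : posterior mean true effect per person (shrunken estimates)
    diagnostics_ : DataFrame of R-hat / ESS (if requested)
    """

    def __init__(
        self,
        priors: OneTaskPriors | None = None,
        iterations: int = 5000,
        burn_in: int = 1000,
        thin: int = 1,
        chains: int = 2,
        seed: int | None = None,
        check_convergence: bool = True,
    ):
        self.priors = priors
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.chains = chains
        self.seed = seed
        self.check_convergence = check_convergence

    def fit(self, X, y=None, fix_alpha=None, fix_sigma2=None):
        """Fit to a single-task :class:`TrialTable` (or long DataFrame).

        ``fix_alpha`` / ``fix_sigma2`` pin those parameters at known
        values instead of sampling them (used for validating the
        remaining conditionals against numerical posteriors).
        """
        table = self._as_table(X)
        st = _sufficient_stats(table)
        if st.J > 1:
            raise ValueError(
                f"OneTaskModel expects a single task, got {st.J}; "
                "use MultiTaskModel"
            )
        priors = self.priors or OneTaskPriors()
        mcmc = self._settings()
        outs = [
            _run_one_task_chain(
                st, priors, mcmc, rng, fix_alpha=fix_alpha, fix_sigma2=fix_sigma2
            )
            for rng in self._chain_rngs()
        ]
        self.draws_ = _stack_chains(outs, st)
        self.sigma_ = float(np.mean(self.draws_.sigma_draws()))
        self.sigma_theta_ = float(np.mean(self.draws_.sigma_theta_draws()))
        self.mu_theta_ = float(np.mean(self.draws_.mu))
        self.theta_ = self.draws_.flat(self.draws_.theta)[:, :, 0].mean(axis=0)
        self.gamma_ = self.sigma_theta_ / self.sigma_
        if self.check_convergence and st.I:
            self._check_convergence()
        return self

    def predict(self, X=None) -> np.ndarray:
        """Shrunken per-person effect estimates (posterior means)."""
        return self.theta_


class MultiTaskModel(_GibbsBase):
    """Gibbs sampler for the J-task latent-correlation model.

    Attributes (after ``fit``)
    --------------------------
    draws_ : PosteriorDraws
    correlation_ : (J, J) posterior mean latent correlation matrix
    correlation_summary_ : per-pair mean and 95% equal-tailed interval
    sigma_ : posterior mean trial-noise SD
    sigma_theta_ : (J,) posterior mean per-task true-effect SDs
    mu_ : (J,) posterior mean task effects
    """

    def __init__(
        self,
        priors: MultiTaskPriors | None = None,
        iterations: int = 5000,
        burn_in: int = 1000,
        thin: int = 1,
        chains: int = 2,
        seed: int | None = None,
        keep_person_draws: bool = True,
        check_convergence: bool = True,
        interval_level: float = 0.95,
    ):
        self.priors = priors
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.chains = chains
        self.seed = seed
        self.keep_person_draws = keep_person_draws
        self.check_convergence = check_convergence
        self.interval_level = interval_level

    def fit(self, X, y=None):
        table = self._as_table(X)
        st = _sufficient_stats(table)
        if st.J < 2 and self.priors is None:
            raise ValueError("MultiTaskModel needs >= 2 tasks")
        priors = self.priors or MultiTaskPriors(J=st.J)
        if st.J and priors.J != st.J:
            raise ValueError(f"priors are for J={priors.J} but data have J={st.J}")
        if not st.J:
            # no data: draws come straight from the priors
            st = _SuffStats(
                [], [f"task{j + 1}" for j in range(priors.J)],
                np.zeros((0, priors.J)), np.zeros((0, priors.J)),
                np.zeros((0, priors.J)), np.zeros((0, priors.J)), 0.0, 0,
            )
        mcmc = self._settings()
        outs = [
            _run_multi_task_chain(st, priors, mcmc, rng, self.keep_person_draws)
            for rng in self._chain_rngs()
        ]
        self.draws_ = _stack_chains(outs, st)
        corr = self.draws_.flat(self.draws_.correlation_draws())
        self.correlation_ = corr.mean(axis=0)
        self.correlation_summary_ = posterior_correlation_summary(
            self.draws_, self.interval_level
        )
        self.sigma_ = float(np.mean(self.draws_.sigma_draws()))
        self.sigma_theta_ = self.draws_.flat(
            self.draws_.sigma_theta_draws()
        ).mean(axis=0)
        self.mu_ = self.draws_.flat(self.draws_.mu).mean(axis=0)
        if self.draws_.theta is not None and self.draws_.theta.shape[2]:
            self.theta_ = self.draws_.flat(self.draws_.theta).mean(axis=0)
        if self.check_convergence and st.I:
            self._check_convergence()
        return self

    def predict(self, X=None) -> np.ndarray:
        """Posterior mean latent correlation matrix."""
        return self.correlation_


# --------------------------------------------------------------------------
# functional wrappers
# --------------------------------------------------------------------------
def fit_one_task(
    table: TrialTable,
    priors: OneTaskPriors | None = None,
    mcmc: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the one-task model; thin wrapper over :class:`OneTaskModel`."""
    mcmc = mcmc or McmcSettings()
    model = OneTaskModel(
        priors=priors,
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        chains=mcmc.chains,
        seed=mcmc.seed,
    ).fit(table)
    return model.draws_


def fit_multi_task(
    table: TrialTable,
    priors: MultiTaskPriors | None = None,
    mcmc: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the multi-task model; thin wrapper over :class:`MultiTaskModel`."""
    mcmc = mcmc or McmcSettings()
    model = MultiTaskModel(
        priors=priors,
        iterations=mcmc.iterations,
        burn_in=mcmc.burn_in,
        thin=mcmc.thin,
        chains=mcmc.chains,
        seed=mcmc.seed,
    ).fit(table)
    return model.draws_
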