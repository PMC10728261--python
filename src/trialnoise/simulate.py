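"""Trial-level synthetic data generators with recorded ground truth.

The generative model mirrors the hierarchical measurement model: person i
has a baseline alpha_ij and a true effect theta_ij on task j; trial RTs
are

    Y_ijkl ~ Normal(alpha_ij + x_k * theta_ij, sigma^2),

with x_k = 0/1 the congruent/incongruent contrast code.  True effects are
drawn from a multivariate normal N_J(mu, Sigma_theta); Sigma_theta may be
specified directly or through a one-factor structure
Sigma = w w' + eta^2 I, where a standard-normal ability z_i is loaded onto
task j with loading w_j and eta is residual (task-specific) variability.

Default study conditions are a large inhibition battery: I = 200 persons,
L = 100 trials per condition, sigma = 200 ms trial noise, and
sigma_theta = 25 ms of true individual variation (signal-to-noise 1-to-8);
the six-task generator uses loadings 1.5..22.5 ms with eta = 10 ms,
producing true correlations from near zero to about 0.80.

Baselines do not affect effects or correlations; they default to
Normal(800 ms, 100 ms) for realistic-looking RTs.  Simulated RTs are
real-valued and may in principle be negative under extreme noise; they
are kept as-is for model fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trialnoise.trial_data import CONDITIONS, TrialTable

__all__ = [
    "PopulationSpec",
    "TruthRecord",
    "covariance_from_factor",
    "correlation_from_covariance",
    "draw_true_effects",
    "simulate_trials",
    "simulate_two_task",
    "simulate_six_task",
]

#: six-task one-factor loadings (ms) spanning near-zero to strong coupling
SIX_TASK_LOADINGS = (1.5, 5.7, 9.9, 14.1, 18.3, 22.5)
SIX_TASK_ETA = 10.0

DEFAULT_SIGMA = 200.0
DEFAULT_SIGMA_THETA = 25.0
DEFAULT_MU = 50.0
DEFAULT_I = 200
DEFAULT_L = 100
DEFAULT_BASELINE_MEAN = 800.0
DEFAULT_BASELINE_SD = 100.0


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def covariance_from_factor(w, eta: float) -> np.ndarray:
    """One-factor covariance Sigma = w w' + eta^2 I (PSD by construction)."""
    w = np.asarray(w, dtype=float)
    if eta < 0:
        raise ValueError("eta must be >= 0")
    return np.outer(w, w) + eta**2 * np.eye(len(w))


def correlation_from_covariance(Sigma: np.ndarray) -> np.ndarray:
    """Convert a covariance to a correlation matrix.

    Zero-variance tasks get zero off-diagonal correlation (undefined in
    principle, but 0 keeps the matrix usable downstream).
    """
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.sqrt(np.diag(Sigma))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = Sigma / np.outer(d, d)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class PopulationSpec:
    """Generative truth for a battery of J tasks.

    ``mu`` is the vector of task mean effects (ms); ``Sigma_theta`` the
    J x J covariance of true effects (ms^2), optionally built from a
    one-factor structure; ``sigma`` the within-cell trial-noise SD (ms).
    """

    mu: np.ndarray
    Sigma_theta: np.ndarray
    sigma: float = DEFAULT_SIGMA
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    baseline_sd: float = DEFAULT_BASELINE_SD
    w: np.ndarray | None = None
    eta: float | None = None

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.Sigma_theta = np.asarray(self.Sigma_theta, dtype=float)
        J = len(self.mu)
        if self.Sigma_theta.shape != (J, J):
            raise ValueError("Sigma_theta must be J x J with J = len(mu)")
        if not np.allclose(self.Sigma_theta, self.Sigma_theta.T):
            raise ValueError("Sigma_theta must be symmetric")
        eig = np.linalg.eigvalsh(self.Sigma_theta)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("Sigma_theta must be positive semi-definite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def J(self) -> int:
        return len(self.mu)

    @classmethod
    def from_factor(
        cls,
        mu,
        w,
        eta: float,
        sigma: float = DEFAULT_SIGMA,
        baseline_mean: float = DEFAULT_BASELINE_MEAN,
        baseline_sd: float = DEFAULT_BASELINE_SD,
    ) -> "PopulationSpec":
        """Build the covariance from a one-factor structure w w' + eta^2 I."""
        w = np.asarray(w, dtype=float)
        return cls(
            mu=np.asarray(mu, dtype=float),
            Sigma_theta=covariance_from_factor(w, eta),
            sigma=sigma,
            baseline_mean=baseline_mean,
            baseline_sd=baseline_sd,
            w=w,
            eta=eta,
        )

    def true_correlations(self) -> np.ndarray:
        return correlation_from_covariance(self.Sigma_theta)


@dataclass
class TruthRecord:
    """Realized latent quantities behind a simulated data set."""

    theta: np.ndarray  # I x J true effects, ms
    alpha: np.ndarray  # I x J true baselines, ms
    true_correlations: np.ndarray  # J x J
    spec: PopulationSpec = field(repr=False, default=None)
    seed: object = None

    @property
    def I(self) -> int:
        return self.theta.shape[0]

    @property
    def J(self) -> int:
        return self.theta.shape[1]


def draw_true_effects(spec: PopulationSpec, I: int, rng) -> TruthRecord:
    """Draw I persons' true effects and baselines from the population.

    theta rows are i.i.d. N_J(mu, Sigma_theta); baselines are
    N(baseline_mean, baseline_sd^2) independently per person and task.
    """
    if I < 2:
        raise ValueError("need I >= 2 persons")
    rng = _as_rng(rng)
    theta = rng.multivariate_normal(spec.mu, spec.Sigma_theta, size=I, method="eigh")
    alpha = rng.normal(spec.baseline_mean, spec.baseline_sd, size=(I, spec.J))
    return TruthRecord(
        theta=theta,
        alpha=alpha,
        true_correlations=spec.true_correlations(),
        spec=spec,
    )


def simulate_trials(truth: TruthRecord, sigma: float, L: int, rng) -> TrialTable:
    """Simulate exactly L trials per person x task x condition.

    Rows are ordered by person, task, condition (congruent first), then
    trial index; total row count is I * J * 2 * L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = _as_rng(rng)
    I, J = truth.theta.shape
    n = I * J * 2 * L
    # per-row cell indices (person slowest, trial fastest)
    person = np.repeat(np.arange(I), J * 2 * L)
    task = np.tile(np.repeat(np.arange(J), 2 * L), I)
    x = np.tile(np.repeat(np.array([0, 1]), L), I * J)
    mean = truth.alpha[person, task] + x * truth.theta[person, task]
    rt = mean + sigma * rng.standard_normal(n)
    condition = pd.Categorical.from_codes(x, categories=list(CONDITIONS))
    task_labels = [f"task{j + 1}" for j in range(J)]
    df = pd.DataFrame(
        {
            "person": person,
            "task": pd.Categorical.from_codes(task, categories=task_labels),
            "condition": condition,
            "rt": rt,
        }
    )
    return TrialTable(df)


def simulate_two_task(
    rho: float,
    I: int = DEFAULT_I,
    L: int = DEFAULT_L,
    sigma: float = DEFAULT_SIGMA,
    sigma_theta: float = DEFAULT_SIGMA_THETA,
    mu: float | tuple = DEFAULT_MU,
    rng=None,
) -> tuple[TrialTable, TruthRecord]:
    """Two tasks with latent effect correlation rho.

    Defaults are the typical large-study conditions (I=200, L=100,
    sigma=200 ms, sigma_theta=25 ms), i.e. 80,000 trials per data set.
    """
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    rng = _as_rng(rng)
    mu_vec = np.full(2, mu, dtype=float) if np.isscalar(mu) else np.asarray(mu, float)
    Sigma = sigma_theta**2 * np.array([[1.0, rho], [rho, 1.0]])
    spec = PopulationSpec(mu=mu_vec, Sigma_theta=Sigma, sigma=sigma)
    truth = draw_true_effects(spec, I, rng)
    table = simulate_trials(truth, sigma, L, rng)
    return table, truth


def simulate_six_task(
    I: int = DEFAULT_I,
    L: int = DEFAULT_L,
    sigma: float = DEFAULT_SIGMA,
    mu: float = DEFAULT_MU,
    rng=None,
) -> tuple[TrialTable, TruthRecord]:
    """Six tasks from the one-factor truth (loadings 1.5..22.5 ms, eta=10).

    Per-task true-effect SDs run from about 10 ms to about 25 ms and true
    correlations from near zero to about 0.80; a data set has 240,000
    trials at the defaults.
    """
    rng = _as_rng(rng)
    spec = PopulationSpec.from_factor(
        mu=np.full(6, mu, dtype=float),
        w=SIX_TASK_LOADINGS,
        eta=SIX_TASK_ETA,
        sigma=sigma,
    )
    truth = draw_true_effects(spec, I, rng)
    table = simulate_trials(truth, sigma, L, rng)
    return table, truth
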