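"""Closed-form attenuation and design-planning math.

With L trials per person per condition, trial-noise SD sigma, and
true-effect SD sigma_theta, the expected correlation of sample effects is
the latent correlation rho shrunk by the attenuation factor

    rho*/rho = L sigma_theta^2 / (L sigma_theta^2 + 2 sigma^2)
             = L / (L + 2/gamma^2),

where gamma = sigma_theta / sigma is the signal-to-noise ratio.  The same
quantity is the model-implied reliability of sample effects, and
sqrt(sigma_theta^2 + 2 sigma^2 / L) is the expected SD of sample effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "DesignSpec",
    "attenuation_factor",
    "expected_observed_correlation",
    "expected_reliability",
    "expected_effect_sd",
    "required_trials",
    "design_report",
]


@dataclass
class DesignSpec:
    """A planned two-condition design.

    Parameters
    ----------
    L
        Trials per person per condition.
    I
        Number of persons.
    sigma
        Trial-noise SD within a person-by-condition cell, ms.
    sigma_theta
        SD of true effects across persons, ms.
    rho
        Optional latent correlation with a second task.
    """

    L: int
    I: int
    sigma: float
    sigma_theta: float
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.sigma_theta < 0:
            raise ValueError("sigma_theta must be >= 0")
        if self.rho is not None and abs(self.rho) > 1:
            raise ValueError("rho must lie in [-1, 1]")

    @property
    def gamma(self) -> float:
        """Signal-to-noise ratio sigma_theta / sigma."""
        return self.sigma_theta / self.sigma


def attenuation_factor(L: int, gamma: float) -> float:
    """Attenuation factor L / (L + 2/gamma^2) of the effect correlation.

    Strictly increasing in both L and gamma; in (0, 1] for gamma > 0.
    gamma = 0 (no true individual variation) returns 0.0 with a warning:
    any observed correlation is then pure noise.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if gamma == 0:
        warnings.warn("gamma = 0: degenerate signal, attenuation factor is 0",
                      stacklevel=2)
        return 0.0
    return L / (L + 2.0 / gamma**2)


def expected_observed_correlation(
    rho: float, L: int, sigma: float, sigma_theta: float
) -> float:
    """Expected correlation of sample effects for latent correlation rho."""
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    if sigma_theta == 0:
        return 0.0
    return rho * attenuation_factor(L, sigma_theta / sigma)


def expected_reliability(L: int, sigma: float, sigma_theta: float) -> float:
    """Model-implied reliability of sample effects.

    Algebraically identical to :func:`attenuation_factor` at
    gamma = sigma_theta / sigma: the proportion of effect-score variance
    that is true individual variance.
    """
    num = L * sigma_theta**2
    return num / (num + 2.0 * sigma**2)


def expected_effect_sd(L: int, sigma: float, sigma_theta: float) -> float:
    """Expected SD of sample effects, sqrt(sigma_theta^2 + 2 sigma^2 / L).

    The second term is the trial-noise contribution to difference scores.
    """
    return math.sqrt(sigma_theta**2 + 2.0 * sigma**2 / L)


def required_trials(sigma: float, target_se: float) -> int:
    """Smallest L with difference-score standard error <= target.

    The standard error of a person's sample effect is sigma*sqrt(2/L), so
    L = ceil(2 sigma^2 / target_se^2).  E.g. holding each effect to a
    10 ms standard error under 200 ms trial noise needs L = 800 trials per
    condition (1600 per task).
    """
    if sigma <= 0 or target_se <= 0:
        raise ValueError("sigma and target_se must be > 0")
    return math.ceil(2.0 * sigma**2 / target_se**2)


def design_report(spec: DesignSpec, target_se: float | None = None) -> dict:
    """All planning quantities for a design, as a flat dict."""
    out = {
        "L": spec.L,
        "I": spec.I,
        "sigma": spec.sigma,
        "sigma_theta": spec.sigma_theta,
        "gamma": spec.gamma,
        "attenuation_factor": attenuation_factor(spec.L, spec.gamma)
        if spec.gamma > 0
        else 0.0,
        "expected_reliability": expected_reliability(
            spec.L, spec.sigma, spec.sigma_theta
        ),
        "expected_effect_sd": expected_effect_sd(spec.L, spec.sigma, spec.sigma_theta),
    }
    if spec.rho is not None:
        out["expected_observed_correlation"] = expected_observed_correlation(
            spec.rho, spec.L, spec.sigma, spec.sigma_theta
        )
    if target_se is not None:
        out["required_trials"] = required_trials(spec.sigma, target_se)
    return out
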