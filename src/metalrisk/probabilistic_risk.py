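"""Probabilistic cancer risk: moment-matched log-normal Monte Carlo.

Given the arithmetic mean m and standard deviation s of a total cancer risk
estimate, the unique log-normal with those moments has

    σ² = ln(1 + (s/m)²),    μ = ln(m) − σ²/2,

so the fit is closed-form (no data, no optimisation).  Draws are summarised
by the 5th/50th/95th percentiles (linear interpolation between order
statistics, numpy's default) and by the fraction of draws above a risk
threshold.  Analytic quantiles exp(μ + σ·Φ⁻¹(p)) serve as the exact oracle
for the simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "LognormalFit",
    "SimulationResult",
    "fit_lognormal_moments",
    "analytic_quantile",
    "simulate",
    "exceedance",
]


@dataclass(frozen=True)
class LognormalFit:
    source_mean: float
    source_sd: float
    mu: float
    sigma: float


@dataclass
class SimulationResult:
    draws: np.ndarray
    n_iter: int
    seed: int
    percentiles: dict[int, float]
    threshold: float
    exceedance: float
    fit: LognormalFit | None = field(default=None)


def fit_lognormal_moments(mean: float, sd: float) -> LognormalFit:
    """Log-normal parameters whose arithmetic mean/SD equal the given values."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0 for a log-normal fit")
    sigma2 = log(1.0 + (sd / mean) ** 2)
    mu = log(mean) - sigma2 / 2.0
    return LognormalFit(source_mean=mean, source_sd=sd, mu=mu, sigma=sqrt(sigma2))


def analytic_quantile(fit: LognormalFit, p: float) -> float:
    """Exact quantile exp(μ + σ·Φ⁻¹(p)) of the fitted distribution."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return exp(fit.mu + fit.sigma * stats.norm.ppf(p))


def simulate(
    fit: LognormalFit,
    n: int = 10_000,
    seed: int = 0,
    threshold: float = 1e-6,
    percentiles: tuple[int, ...] = (5, 50, 95),
) -> SimulationResult:
    """Draw ``n`` log-normal samples and summarise them; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=fit.mu, sigma=fit.sigma, size=n)
    pct = {int(p): float(np.percentile(draws, p)) for p in percentiles}
    result = SimulationResult(
        draws=draws,
        n_iter=n,
        seed=seed,
        percentiles=pct,
        threshold=threshold,
        exceedance=float(np.mean(draws > threshold)),
        fit=fit,
    )
    return result


def exceedance(result: SimulationResult, threshold: float) -> float:
    """Fraction of draws above ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return float(np.mean(result.draws > threshold))
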