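"""Marginal-likelihood estimation by path sampling and stepping-stone
sampling over a ladder of power posteriors, and Bayes-factor comparison.

The power posterior at inverse temperature ``beta`` is proportional to
``prior × likelihood^beta``; the ladder runs from the posterior (beta = 1)
down to the prior (beta = 0) along quantiles of a Beta(shape, 1)
distribution, which concentrates steps near the prior end where the
integrand changes fastest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alignment import Alignment
from .errors import InvalidInputError
from .mcmc import ChainConfig, ModelConfig, run_mcmc
from .trees import TimeTree

__all__ = [
    "power_schedule",
    "PowerPosteriorRun",
    "run_power_posteriors",
    "path_sampling_logml",
    "stepping_stone_logml",
    "ModelComparison",
    "log_bayes_factor",
    "ConjugateNormalModel",
]


def power_schedule(n_steps: int, beta_shape: float = 0.3) -> np.ndarray:
    """Descending beta ladder: quantiles of Beta(beta_shape, 1) at
    ``k/(n_steps-1)``, i.e. ``beta_k = (k/(n_steps-1))^(1/beta_shape)``."""
    if n_steps < 2:
        raise InvalidInputError("schedule needs at least 2 steps")
    if beta_shape <= 0:
        raise InvalidInputError("beta_shape must be > 0")
    q = np.arange(n_steps - 1, -1, -1) / (n_steps - 1)
    return q ** (1.0 / beta_shape)


@dataclass
class PowerPosteriorRun:
    """Per-beta post-burnin log-likelihood samples."""

    betas: np.ndarray
    logl_samples: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.betas) < 2:
            raise InvalidInputError("need at least 2 betas")
        if np.any(np.diff(self.betas) >= 0):
            raise InvalidInputError("betas must be strictly descending")
        if np.any((self.betas < 0) | (self.betas > 1)):
            raise InvalidInputError("betas must lie in [0, 1]")
        if len(self.logl_samples) != len(self.betas):
            raise InvalidInputError("one sample array per beta required")

    def means(self) -> np.ndarray:
        return np.array([np.mean(s) for s in self.logl_samples])


def run_power_posteriors(
    config: ModelConfig,
    aln: Alignment,
    schedule: np.ndarray,
    chain: ChainConfig,
    seed: int,
    init_tree: TimeTree | None = None,
    initial_burnin: int | None = None,
) -> PowerPosteriorRun:
    """Sample every rung of the beta ladder, descending from the posterior.

    Each rung's chain starts from the previous rung's final state; the first
    rung gets an extra burn-in (``initial_burnin`` generations, default
    3x the per-rung length).  Per-rung burn-in follows ``chain.burnin_fraction``.
    """
    schedule = np.asarray(schedule, dtype=float)
    if np.any(np.diff(schedule) >= 0):
        raise InvalidInputError("schedule must be strictly descending")
    rng = np.random.default_rng(seed)
    state = None
    logl = []
    if initial_burnin is None:
        initial_burnin = 3 * chain.n_generations
    for i, beta in enumerate(schedule):
        gens = chain.n_generations + (initial_burnin if i == 0 else 0)
        sub_seed = int(rng.integers(2**31 - 1))
        cc = ChainConfig(
            n_generations=gens, thin=chain.thin,
            burnin_fraction=max(chain.burnin_fraction,
                                initial_burnin / gens if i == 0 else 0.0),
            tune=chain.tune, sample_trees=False,
            target_acceptance=chain.target_acceptance,
        )
        tr = run_mcmc(config, aln, cc, seed=sub_seed, init_tree=init_tree,
                      beta=float(beta), init_state=state)
        state = tr.final_state
        logl.append(tr.burned().df["logL"].to_numpy())
    return PowerPosteriorRun(
        betas=schedule, logl_samples=logl,
        metadata={"seed": seed, "per_step_generations": chain.n_generations,
                  "thin": chain.thin},
    )


def _check_endpoints(run: PowerPosteriorRun) -> None:
    if not (np.isclose(run.betas[0], 1.0) and np.isclose(run.betas[-1], 0.0)):
        warnings.warn(
            "beta ladder does not span [0, 1]; marginal-likelihood estimate "
            "is biased by the missing endpoint(s)",
            stacklevel=3,
        )


def path_sampling_logml(run: PowerPosteriorRun) -> float:
    """Trapezoidal integration of the mean log-likelihood over beta."""
    _check_endpoints(run)
    means = run.means()
    b = run.betas
    return float(np.sum((b[:-1] - b[1:]) * (means[:-1] + means[1:]) / 2.0))


def stepping_stone_logml(run: PowerPosteriorRun) -> float:
    """Stepping-stone estimator: importance ratios between adjacent rungs,
    each estimated from the samples at the lower (smaller-beta) rung, with
    log-sum-exp guarding."""
    _check_endpoints(run)
    total = 0.0
    for k in range(len(run.betas) - 1):
        db = run.betas[k] - run.betas[k + 1]
        x = run.logl_samples[k + 1]
        total += float(logsumexp(db * x) - np.log(len(x)))
    return total


# --------------------------------------------------------------- comparison
_KASS_RAFTERY = (
    (1.0, "barely worth mentioning"),
    (3.0, "positive"),
    (5.0, "strong"),
    (np.inf, "very strong"),
)


@dataclass
class ModelComparison:
    log_ml_a: float
    log_ml_b: float
    log_bayes_factor: float
    interpretation: str
    favoured: str | None

    def __post_init__(self):
        if not np.isclose(self.log_bayes_factor,
                          self.log_ml_a - self.log_ml_b):
            raise InvalidInputError("inconsistent Bayes factor")


def log_bayes_factor(log_ml_a: float, log_ml_b: float) -> ModelComparison:
    """Natural-log Bayes factor with the conventional evidence labels
    ((0,1] barely worth mentioning, (1,3] positive, (3,5] strong, >5 very
    strong; ties at a boundary take the weaker label).  A negative value
    favours model b with the mirrored label; zero favours neither."""
    if not (np.isfinite(log_ml_a) and np.isfinite(log_ml_b)):
        raise InvalidInputError("marginal likelihoods must be finite")
    bf = float(log_ml_a) - float(log_ml_b)
    mag = abs(bf)
    if bf == 0.0:
        return ModelComparison(log_ml_a, log_ml_b, 0.0,
                               "no preference", None)
    for bound, label in _KASS_RAFTERY:
        if mag <= bound:
            break
    return ModelComparison(log_ml_a, log_ml_b, bf, label,
                           "a" if bf > 0 else "b")


# ----------------------------------------------------------------- toy model
@dataclass
class ConjugateNormalModel:
    """Known-variance normal likelihood with a conjugate normal prior on the
    mean — the standard validation target for marginal-likelihood
    estimators, because the log marginal is available in closed form and
    every power posterior is itself normal (so rungs can be sampled
    exactly)."""

    data: np.ndarray
    sigma: float = 1.0
    prior_mean: float = 0.0
    prior_sd: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.sigma <= 0 or self.prior_sd <= 0:
            raise InvalidInputError("scales must be positive")

    def log_likelihood(self, mu: np.ndarray | float):
        mu = np.asarray(mu, dtype=float)
        n = len(self.data)
        ss = np.sum((self.data[None, ...] - np.atleast_1d(mu)[..., None]) ** 2,
                    axis=-1)
        out = -0.5 * ss / self.sigma**2 - n * np.log(
            self.sigma * np.sqrt(2 * np.pi))
        return float(out) if np.ndim(mu) == 0 else out

    def analytic_log_marginal(self) -> float:
        """Log of the exact marginal: y ~ MVN(mu0 1, sigma^2 I + tau^2 J)."""
        n = len(self.data)
        y = self.data - self.prior_mean
        s2, t2 = self.sigma**2, self.prior_sd**2
        # Sherman–Morrison for (s2 I + t2 11')
        quad = (np.dot(y, y) / s2
                - t2 * np.sum(y) ** 2 / (s2 * (s2 + n * t2)))
        logdet = n * np.log(s2) + np.log1p(n * t2 / s2)
        return float(-0.5 * (n * np.log(2 * np.pi) + logdet + quad))

    def power_posterior_run(self, schedule: np.ndarray, n_samples: int,
                            seed: int) -> PowerPosteriorRun:
        """Exact sampling of each rung (the power posterior is conjugate:
        precision ``1/tau^2 + beta n/sigma^2``)."""
        rng = np.random.default_rng(seed)
        schedule = np.asarray(schedule, dtype=float)
        n = len(self.data)
        logl = []
        for beta in schedule:
            prec = 1.0 / self.prior_sd**2 + beta * n / self.sigma**2
            mean = (self.prior_mean / self.prior_sd**2
                    + beta * np.sum(self.data) / self.sigma**2) / prec
            mus = rng.normal(mean, 1.0 / np.sqrt(prec), size=n_samples)
            logl.append(self.log_likelihood(mus))
        return PowerPosteriorRun(betas=schedule, logl_samples=logl,
                                 metadata={"seed": seed, "model": "conjugate-normal"})
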