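"""HKY substitution model, discrete-gamma rate heterogeneity, clock models.

The rate matrix follows the HKY85 parameterization: off-diagonal entry
``q_ij`` is proportional to ``kappa * pi_j`` for transitions (A<->G, C<->T)
and ``pi_j`` for transversions, normalized so the expected number of
substitutions per unit branch length is 1 (``-sum_i pi_i q_ii = 1``).
Branch lengths handed to :func:`transition_probabilities` are therefore in
expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .errors import InvalidInputError

__all__ = [
    "SubstitutionModel",
    "ClockModel",
    "hky_rate_matrix",
    "hky_eigen",
    "transition_probabilities",
    "discrete_gamma_categories",
]

_TRANSITION_PAIRS = ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T in ACGT order


def _check_freqs(base_freqs) -> np.ndarray:
    f = np.asarray(base_freqs, dtype=float)
    if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
        raise InvalidInputError("base_freqs must be 4 positive values summing to 1")
    return f


def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """Normalized 4x4 HKY instantaneous rate matrix (state order A, C, G, T)."""
    if not np.isfinite(kappa) or kappa <= 0:
        raise InvalidInputError("kappa must be finite and > 0")
    f = _check_freqs(base_freqs)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = kappa * f[j] if (i, j) in _TRANSITION_PAIRS else f[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -np.dot(f, np.diag(q))  # expected rate under stationarity
    return q / mu


def hky_eigen(kappa: float, base_freqs):
    """Eigendecomposition of the normalized HKY generator.

    Returns ``(rates, U, Uinv)`` with ``Q = U @ diag(rates) @ Uinv``.  Uses a
    symmetric similarity transform (time reversibility), so the decomposition
    is numerically stable.
    """
    f = _check_freqs(base_freqs)
    q = hky_rate_matrix(kappa, f)
    sqrt_f = np.sqrt(f)
    sym = q * (sqrt_f[:, None] / sqrt_f[None, :])  # D^1/2 Q D^-1/2, symmetric
    lam, vec = np.linalg.eigh(sym)
    u = vec / sqrt_f[:, None]
    uinv = vec.T * sqrt_f[None, :]
    return lam, u, uinv


def transition_probabilities(q: np.ndarray, d: float) -> np.ndarray:
    """P = exp(Q d) for a branch length ``d`` in substitutions per site."""
    if d < 0:
        raise InvalidInputError("branch length must be non-negative")
    lam, vec = np.linalg.eig(q)
    p = (vec * np.exp(lam * d)[None, :]) @ np.linalg.inv(vec)
    p = np.real(p)
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


from functools import lru_cache


@lru_cache(maxsize=512)
def _gamma_categories_cached(alpha: float, k: int) -> np.ndarray:
    edges = _gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    cdf_hi = gammainc(alpha + 1.0, np.concatenate([edges, [np.inf]]) * alpha)
    cdf_lo = gammainc(alpha + 1.0, np.concatenate([[0.0], edges]) * alpha)
    rates = (cdf_hi - cdf_lo) * k
    rates /= rates.mean()
    rates.setflags(write=False)
    return rates


def discrete_gamma_categories(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, mean 1).

    The category means are computed from the incomplete-gamma identity
    ``E[X; a < X < b] = F_{alpha+1}(b) - F_{alpha+1}(a)`` for
    ``X ~ Gamma(alpha, scale 1/alpha)`` and renormalized so they average to
    exactly 1.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise InvalidInputError("alpha must be finite and > 0")
    k = int(k)
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    return _gamma_categories_cached(float(alpha), k)


@dataclass
class SubstitutionModel:
    """Partitioned HKY+Gamma model: partition 0 = codon positions 1+2
    (linked), partition 1 = codon position 3, sharing the tree and clock."""

    kappa: np.ndarray = field(default_factory=lambda: np.array([8.0, 8.0]))
    base_freqs: np.ndarray = field(
        default_factory=lambda: np.full((2, 4), 0.25)
    )
    gamma_alpha: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.5]))
    n_categories: int = 4
    # relative rate of partition 1 (codon3) over partition 0; the absolute
    # per-partition multipliers are renormalized to site-weighted mean 1
    rate_ratio: float = 1.0

    def __post_init__(self):
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.gamma_alpha = np.atleast_1d(np.asarray(self.gamma_alpha, dtype=float))
        self.base_freqs = np.atleast_2d(np.asarray(self.base_freqs, dtype=float))
        if np.any(self.kappa <= 0) or np.any(self.gamma_alpha <= 0):
            raise InvalidInputError("kappa and gamma_alpha must be > 0")
        for f in self.base_freqs:
            _check_freqs(f)
        if self.rate_ratio <= 0:
            raise InvalidInputError("rate_ratio must be > 0")
        if self.n_categories < 1:
            raise InvalidInputError("n_categories must be >= 1")

    @property
    def n_partitions(self) -> int:
        return len(self.kappa)

    def partition_rates(self, site_counts) -> np.ndarray:
        """Per-partition rate multipliers with site-weighted mean exactly 1.

        ``site_counts`` gives the number of sites in each partition.
        """
        w = np.asarray(site_counts, dtype=float)
        if self.n_partitions == 1:
            return np.ones(1)
        raw = np.array([1.0, self.rate_ratio])
        return raw * w.sum() / np.dot(w, raw)

    @classmethod
    def single_partition(cls, kappa=8.0, base_freqs=None, gamma_alpha=0.5,
                         n_categories=4) -> "SubstitutionModel":
        if base_freqs is None:
            base_freqs = np.full(4, 0.25)
        return cls(
            kappa=np.array([kappa]),
            base_freqs=np.asarray(base_freqs, dtype=float)[None, :],
            gamma_alpha=np.array([gamma_alpha]),
            n_categories=n_categories,
        )


@dataclass
class ClockModel:
    """Strict or uncorrelated-lognormal (UCLN) relaxed clock.

    ``mean_rate`` is in substitutions/site/year.  Under UCLN each branch has
    an independent lognormal multiplier with real-space mean 1
    (log-mean ``-sigma^2/2``); under the strict clock all multipliers are 1.
    """

    kind: str = "strict"
    mean_rate: float = 4.5e-7
    ucln_sigma: float = 0.0
    branch_multipliers: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("strict", "ucln"):
            raise InvalidInputError(f"unknown clock kind {self.kind!r}")
        if not np.isfinite(self.mean_rate) or self.mean_rate <= 0:
            raise InvalidInputError("mean_rate must be finite and > 0")
        if self.ucln_sigma < 0:
            raise InvalidInputError("ucln_sigma must be >= 0")
        if self.branch_multipliers is not None:
            self.branch_multipliers = np.asarray(self.branch_multipliers, dtype=float)
            if np.any(self.branch_multipliers <= 0):
                raise InvalidInputError("branch multipliers must be positive")

    def multipliers_for(self, n_branches: int, rng: np.random.Generator | None = None):
        if self.kind == "strict" or self.ucln_sigma == 0.0:
            return np.ones(n_branches)
        if self.branch_multipliers is not None:
            if len(self.branch_multipliers) != n_branches:
                raise InvalidInputError(
                    f"expected {n_branches} branch multipliers, "
                    f"got {len(self.branch_multipliers)}"
                )
            return self.branch_multipliers
        if rng is None:
            raise InvalidInputError("UCLN clock without multipliers needs an RNG")
        mu = -0.5 * self.ucln_sigma**2
        return rng.lognormal(mean=mu, sigma=self.ucln_sigma, size=n_branches)
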