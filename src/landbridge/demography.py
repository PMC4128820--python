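"""Single-deme demographic models for the coalescent.

Population size is parameterized throughout as the composite quantity
``N_ef * T`` — female effective population size times mean generation time —
measured in **years**, so that the instantaneous pairwise coalescence rate at
time ``t`` (years BP) is ``1 / N(t)`` per year.  This is exactly the quantity
a single-locus mitochondrial coalescent identifies, and the quantity skyline
plots display.

Three model kinds are supported:

``constant``
    ``N(t) = theta0``.
``expansion``
    ``N(t) = theta0 * (f + (1 - f) * exp(-g * t))`` looking backwards in
    time, with growth rate ``g >= 0`` per year and ancestral fraction
    ``f in [0, 1]``.  ``f = 0`` is pure exponential growth; ``f > 0`` adds an
    ancestral asymptote ``f * theta0`` (the "expansion growth" model of the
    BEAST tradition).
``skyline``
    piecewise-constant ``N`` across groups of coalescent intervals, the
    classic Bayesian skyline parameterization: ``group_sizes[j]`` coalescent
    intervals share size ``group_thetas[j]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["DemographicModel", "coalescent_log_density"]


@dataclass
class DemographicModel:
    kind: str = "constant"
    theta0: float = 10_000.0
    growth_rate: float = 0.0
    ancestral_fraction: float = 0.0
    group_sizes: np.ndarray | None = None
    group_thetas: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "expansion", "skyline"):
            raise InvalidInputError(f"unknown demographic model kind {self.kind!r}")
        if not np.isfinite(self.theta0) or self.theta0 <= 0:
            raise InvalidInputError("theta0 must be finite and > 0")
        if self.kind == "expansion":
            if self.growth_rate < 0 or not np.isfinite(self.growth_rate):
                raise InvalidInputError("growth_rate must be finite and >= 0")
            if not 0.0 <= self.ancestral_fraction <= 1.0:
                raise InvalidInputError("ancestral_fraction must lie in [0, 1]")
        if self.kind == "skyline":
            if self.group_sizes is None or self.group_thetas is None:
                raise InvalidInputError("skyline model needs group_sizes and group_thetas")
            self.group_sizes = np.asarray(self.group_sizes, dtype=np.int64)
            self.group_thetas = np.asarray(self.group_thetas, dtype=float)
            if len(self.group_sizes) != len(self.group_thetas):
                raise InvalidInputError("group_sizes and group_thetas must have equal length")
            if np.any(self.group_sizes < 1):
                raise InvalidInputError("every skyline group must own >= 1 interval")
            if np.any(~np.isfinite(self.group_thetas)) or np.any(self.group_thetas <= 0):
                raise InvalidInputError("group_thetas must be finite and > 0")

    # -- population size and cumulative coalescent intensity -----------------
    def size_at(self, t: np.ndarray | float, coal_times: np.ndarray | None = None):
        """N(t) in years.  For skyline models the piecewise function is tied
        to the coalescent event times of a particular genealogy, which the
        caller must supply (ascending)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            return np.broadcast_to(self.theta0, t.shape).copy()
        if self.kind == "expansion":
            f = self.ancestral_fraction
            return self.theta0 * (f + (1.0 - f) * np.exp(-self.growth_rate * t))
        boundaries = self._skyline_boundaries(coal_times)
        idx = np.searchsorted(boundaries, t, side="right")
        return self.group_thetas[idx]

    def intensity(self, t: float) -> float:
        """Lambda(t) = integral_0^t dt' / N(t') for constant/expansion models."""
        if self.kind == "constant":
            return t / self.theta0
        if self.kind == "expansion":
            g, f = self.growth_rate, self.ancestral_fraction
            if g == 0.0:
                return t / self.theta0
            if f == 0.0:
                return np.expm1(g * t) / (g * self.theta0)
            return np.log1p(f * np.expm1(g * t)) / (self.theta0 * f * g)
        raise InvalidInputError("skyline intensity is genealogy-bound; use coalescent_log_density")

    def inverse_intensity(self, lam: float) -> float:
        """Solve Lambda(t) = lam for t (constant/expansion only)."""
        if self.kind == "constant":
            return lam * self.theta0
        g, f = self.growth_rate, self.ancestral_fraction
        if g == 0.0:
            return lam * self.theta0
        if f == 0.0:
            return np.log1p(g * self.theta0 * lam) / g
        z = np.expm1(self.theta0 * f * g * lam) / f
        return np.log1p(z) / g

    def _skyline_boundaries(self, coal_times):
        """Ages at which theta changes: the coalescent events closing groups."""
        if coal_times is None:
            raise InvalidInputError("skyline model requires genealogy coalescent times")
        coal_times = np.sort(np.asarray(coal_times, dtype=float))
        if int(self.group_sizes.sum()) != len(coal_times):
            raise InvalidInputError(
                f"skyline group_sizes sum to {int(self.group_sizes.sum())}, "
                f"but the genealogy has {len(coal_times)} coalescent intervals"
            )
        ends = np.cumsum(self.group_sizes)[:-1]
        return coal_times[ends - 1] if len(ends) else np.empty(0)


def coalescent_log_density(tree, demography: DemographicModel) -> float:
    """Log density of a genealogy under the (possibly time-varying) coalescent.

    Standard inhomogeneous form: for each coalescence at time ``t_i`` a factor
    ``1/N(t_i)``, and for each inter-event interval with ``k`` active lineages
    a survival factor ``exp(-C(k,2) * int dt/N(t))``.  Closed-form integrals
    are used for all three model kinds.
    """
    times = tree.coalescent_times()
    n = tree.n_tips
    if demography.kind == "skyline":
        per_interval = np.repeat(
            demography.group_thetas, demography.group_sizes
        )
        if len(per_interval) != n - 1:
            raise InvalidInputError(
                "skyline group sizes must sum to n_tips - 1 for this genealogy"
            )
    logp = 0.0
    t_prev = 0.0
    for j, t in enumerate(times):
        k = n - j  # lineages active during (t_prev, t)
        pairs = k * (k - 1) / 2.0
        if demography.kind == "skyline":
            theta = per_interval[j]
            logp += -np.log(theta) - pairs * (t - t_prev) / theta
        else:
            n_event = float(demography.size_at(t))
            if n_event <= 0 or not np.isfinite(n_event):
                raise InvalidInputError("population size must be positive over the tree")
            logp += -np.log(n_event)
            logp += -pairs * (demography.intensity(t) - demography.intensity(t_prev))
        t_prev = t
    return float(logp)
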