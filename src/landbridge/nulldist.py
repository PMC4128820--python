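"""Coalescent null distributions for neutrality statistics.

The significance procedure conditions on the observed number of segregating
sites: ``S`` mutations are dropped onto constant-size coalescent genealogies
with probability proportional to branch length (infinite-sites), and the
statistic is recomputed on each replicate.  The Tajima's D path is fully
vectorized across replicates; the Fu's F_S path tracks haplotype identity
per replicate and is looped.

This module also hosts the count-based statistic kernels (shared between the
alignment-facing functions in :mod:`landbridge.popgen` and the simulators),
plus the exact log-space unsigned Stirling numbers used by the Ewens
sampling formula.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .errors import UndefinedStatisticError

__all__ = [
    "tajima_constants",
    "tajima_d_from_counts",
    "fu_fs_from_counts",
    "log_unsigned_stirling_row",
    "null_tajima_d",
    "null_fu_fs",
]


@lru_cache(maxsize=None)
def tajima_constants(n: int) -> dict[str, float]:
    """The canonical a1, a2, b1, b2, c1, c2, e1, e2 coefficient chain."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_from_counts(n: int, s, pi_hat):
    """Tajima's D from sample size, segregating sites, and mean pairwise
    difference count (per alignment, uncorrected)."""
    if n < 4:
        raise UndefinedStatisticError("Tajima's D needs >= 4 sequences")
    c = tajima_constants(n)
    s = np.asarray(s, dtype=float)
    var = c["e1"] * s + c["e2"] * s * (s - 1.0)
    if np.any(s < 1):
        raise UndefinedStatisticError("Tajima's D undefined with no segregating sites")
    return (np.asarray(pi_hat, dtype=float) - s / c["a1"]) / np.sqrt(var)


@lru_cache(maxsize=None)
def log_unsigned_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n, by the exact log-space recurrence
    |s(m+1, k)| = m |s(m, k)| + |s(m, k-1)|."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        prev = row.copy()
        row[0] = -np.inf
        shifted = np.concatenate([[-np.inf], prev[:-1]])
        with np.errstate(divide="ignore"):
            row[1:] = np.logaddexp(np.log(m - 1.0) + prev[1:] if m > 1
                                   else np.full(n, -np.inf), shifted[1:])
    return row


def _log_ewens_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 0..n under the Ewens sampling formula."""
    ls = log_unsigned_stirling_row(n)
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return ls + k * np.log(theta) - log_rising


def fu_fs_from_counts(n: int, k_obs, theta_pi):
    """Fu's F_S from haplotype count and the pairwise estimate of theta.

    ``F_S = ln(S' / (1 - S'))`` with ``S' = P(K >= k_obs | theta_pi)`` under
    the Ewens sampling formula; both tails are accumulated in log space.
    """
    scalar = np.isscalar(k_obs) or np.ndim(k_obs) == 0
    k_obs = np.atleast_1d(np.asarray(k_obs, dtype=int))
    theta_pi = np.atleast_1d(np.asarray(theta_pi, dtype=float))
    if np.any(theta_pi <= 0):
        raise UndefinedStatisticError(
            "Fu's F_S undefined when the pairwise theta estimate is 0"
        )
    out = np.empty(len(k_obs))
    for i, (ko, th) in enumerate(zip(k_obs, theta_pi)):
        logp = _log_ewens_pmf(n, th)
        upper = logsumexp(logp[ko:])
        lower = logsumexp(logp[:ko])
        if not np.isfinite(upper) or not np.isfinite(lower):
            raise UndefinedStatisticError(
                "Ewens tail probability degenerate (S' numerically 0 or 1)"
            )
        out[i] = upper - lower
    return float(out[0]) if scalar else out


# ------------------------------------------------------------ null simulators
def _coalescent_intervals(n: int, n_sims: int, rng: np.random.Generator):
    """Exponential inter-coalescent waits (constant size, arbitrary units)."""
    ks = np.arange(n, 1, -1, dtype=float)
    return rng.exponential(1.0, size=(n_sims, n - 1)) / (ks * (ks - 1) / 2.0)


def null_tajima_d(n: int, s_obs: int, n_sims: int, rng: np.random.Generator,
                  batch: int = 4000) -> np.ndarray:
    """Tajima's D recomputed on ``n_sims`` constant-size genealogies with
    exactly ``s_obs`` mutations dropped proportionally to branch length."""
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        t = _coalescent_intervals(n, b, rng)
        w = t * np.arange(n, 1, -1)[None, :]  # total length in interval
        sizes = np.ones((b, n))
        hist = np.empty((b, n - 1, n))
        rows = np.arange(b)
        for j in range(n - 1):
            k = n - j
            hist[:, j, :] = sizes
            a = rng.integers(0, k, b)
            c = rng.integers(0, k - 1, b)
            c = np.where(c >= a, c + 1, c)
            sizes[rows, a] += sizes[rows, c]
            sizes[rows, c] = sizes[rows, k - 1]
        cw = np.cumsum(w, axis=1)
        u = rng.random((b, s_obs)) * cw[:, -1][:, None]
        interval = (u[:, :, None] > cw[:, None, :]).sum(axis=2)
        interval = np.minimum(interval, n - 2)
        k_at = n - interval
        lineage = (rng.random((b, s_obs)) * k_at).astype(np.int64)
        i_desc = hist[rows[:, None], interval, lineage]
        pi_hat = (i_desc * (n - i_desc)).sum(axis=1) * 2.0 / (n * (n - 1))
        out[done:done + b] = tajima_d_from_counts(n, s_obs, pi_hat)
        done += b
    return out


def null_fu_fs(n: int, s_obs: int, n_sims: int, rng: np.random.Generator):
    """Fu's F_S on simulated genealogies; returns (values, n_undefined).

    Haplotype identity is tracked exactly: a mutation on a branch marks every
    descendant tip, and tips sharing the same mutation set share a haplotype.
    """
    values = np.full(n_sims, np.nan)
    n_undef = 0
    ks = np.arange(n, 1, -1, dtype=float)
    for b in range(n_sims):
        t = rng.exponential(1.0, n - 1) / (ks * (ks - 1) / 2.0)
        w = t * ks
        # merge history with descendant-tip bookkeeping
        members: list[list[int]] = [[i] for i in range(n)]
        hist_members: list[list[list[int]]] = []
        for j in range(n - 1):
            hist_members.append(list(members))
            k = n - j
            a, c = rng.choice(k, size=2, replace=False)
            a, c = (a, c) if a < c else (c, a)
            merged = members[a] + members[c]
            members[a] = merged
            members[c] = members[k - 1]
            members = members[: k - 1]
        cw = np.cumsum(w)
        u = rng.random(s_obs) * cw[-1]
        intervals = np.minimum(np.searchsorted(cw, u, side="right"), n - 2)
        muts_per_tip: list[list[int]] = [[] for _ in range(n)]
        pi_sum = 0.0
        for m, j in enumerate(intervals):
            k = n - j
            lin = int(rng.integers(0, k))
            tips = hist_members[j][lin]
            for tip in tips:
                muts_per_tip[tip].append(m)
            i_desc = len(tips)
            pi_sum += i_desc * (n - i_desc)
        pi_hat = pi_sum * 2.0 / (n * (n - 1))
        k_obs = len({tuple(m) for m in muts_per_tip})
        try:
            values[b] = fu_fs_from_counts(n, k_obs, pi_hat)
        except UndefinedStatisticError:
            n_undef += 1
    return values, n_undef
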