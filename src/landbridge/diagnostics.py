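"""Trace diagnostics: effective sample size, HPD intervals, chain pooling."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .mcmc import PosteriorTrace

__all__ = ["ess", "hpd_interval", "combine_chains"]


def ess(series, return_flag: bool = False):
    """Effective sample size ``N / (1 + 2 * sum_k rho_k)``.

    Autocorrelations are summed up to (and excluding) the first non-positive
    estimate (initial positive sequence truncation).  A constant series is
    reported as ESS = N with a degeneracy flag.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise InvalidInputError("ESS needs at least 10 samples")
    v = x.var()
    if v == 0.0:
        return (float(n), True) if return_flag else float(n)
    xc = x - x.mean()
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        s += rho[k]
    out = n / (1.0 + 2.0 * s)
    return (float(out), False) if return_flag else float(out)


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(prob * N)`` sorted
    samples; ties broken toward the lower start."""
    if not 0.0 < prob < 1.0:
        raise InvalidInputError("prob must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise InvalidInputError("HPD interval needs at least 20 samples")
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lowest) start on ties
    return float(x[i]), float(x[i + m - 1])


def combine_chains(traces: list[PosteriorTrace],
                   burnin_fraction: float | None = None) -> PosteriorTrace:
    """Pool chains after per-chain burnin removal.

    All chains must share a parameter schema; metadata records the per-chain
    provenance (seeds and generation counts).
    """
    if not traces:
        raise InvalidInputError("no chains to combine")
    cols = list(traces[0].df.columns)
    for t in traces[1:]:
        if list(t.df.columns) != cols:
            raise InvalidInputError("chains have different parameter schemas")
        if t.labels != traces[0].labels:
            raise InvalidInputError("chains have different tip label sets")
    burned = [t.burned(burnin_fraction) for t in traces]
    df = pd.concat([t.df for t in burned], ignore_index=True)
    tree_samples = [s for t in burned for s in t.tree_samples]
    meta = {
        "combined_from": [t.metadata.get("seed") for t in traces],
        "per_chain_generations": [t.metadata.get("n_generations") for t in traces],
        "n_generations": traces[0].metadata.get("n_generations"),
        "burnin_fraction": 0.0,  # already applied per chain
        "thin": traces[0].metadata.get("thin"),
        "per_chain_metadata": [t.metadata for t in traces],
    }
    return PosteriorTrace(df, tree_samples, traces[0].labels, meta)
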