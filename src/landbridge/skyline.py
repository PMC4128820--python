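"""Bayesian skyline reconstruction: N_ef * T through time.

For every posterior sample the skyline demographic model induces a
piecewise-constant population-size function whose pieces are groups of that
sample's coalescent intervals.  The curve reports, at each grid time, the
pointwise median and 95% HPD of this function over the posterior sample,
truncated at the posterior median root age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import hpd_interval
from .errors import InvalidInputError
from .mcmc import PosteriorTrace

__all__ = ["SkylineCurve", "skyline_curve", "export_skyline", "read_skyline"]


@dataclass
class SkylineCurve:
    times: np.ndarray        # years BP, ascending from 0
    median: np.ndarray       # N_ef * T, years
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    truncation_age: float    # posterior median root age

    def __post_init__(self):
        if np.any(self.hpd_lower > self.median) or np.any(self.median > self.hpd_upper):
            raise InvalidInputError("HPD band must bracket the median")

    def at(self, t: float) -> float:
        """Median population size at the grid time nearest to ``t``
        (clipped to the curve's support)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.median[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_bp": self.times, "median": self.median,
            "hpd_lower": self.hpd_lower, "hpd_upper": self.hpd_upper,
        })


def skyline_curve(trace: PosteriorTrace, grid_size: int = 100) -> SkylineCurve:
    """Pointwise median and 95% HPD of the skyline trajectory.

    The trace must come from a skyline-model run (per-sample group sizes and
    group thetas logged alongside the sampled genealogy).
    """
    theta_cols = sorted(c for c in trace.df.columns if c.startswith("skyline_theta"))
    size_cols = sorted(c for c in trace.df.columns if c.startswith("skyline_size"))
    if not theta_cols or not size_cols:
        raise InvalidInputError("trace was not sampled under a skyline model")
    if len(trace.tree_samples) != len(trace.df):
        raise InvalidInputError(
            "skyline reconstruction needs a tree sample per logged state"
        )
    if grid_size < 2:
        raise InvalidInputError("grid_size must be >= 2")
    thetas = trace.df[theta_cols].to_numpy()
    sizes = trace.df[size_cols].to_numpy().astype(np.int64)
    n_samp = len(trace.df)
    n_tips = (len(trace.tree_samples[0][1]) + 1) // 2

    root_ages = np.array([ages.max() for _, _, ages in trace.tree_samples])
    trunc = float(np.median(root_ages))
    times = np.linspace(0.0, trunc, grid_size)

    values = np.empty((n_samp, grid_size))
    for i in range(n_samp):
        _, _, ages = trace.tree_samples[i]
        coal = np.sort(ages[n_tips:])
        ends = np.cumsum(sizes[i])[:-1]
        boundaries = coal[ends - 1] if len(ends) else np.empty(0)
        idx = np.searchsorted(boundaries, times, side="right")
        values[i] = thetas[i][idx]
    med = np.median(values, axis=0)
    lo = np.empty(grid_size)
    hi = np.empty(grid_size)
    for j in range(grid_size):
        if n_samp >= 20:
            lo[j], hi[j] = hpd_interval(values[:, j], 0.95)
        else:
            lo[j], hi[j] = values[:, j].min(), values[:, j].max()
    return SkylineCurve(times, med, lo, hi, trunc)


def export_skyline(curve: SkylineCurve, path, plot_path=None) -> None:
    """Write the curve as TSV (time_bp, median, hpd_lower, hpd_upper);
    optionally render a log-scaled plot alongside."""
    curve.to_frame().to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(curve.times / 1000.0, curve.median, lw=2, color="k",
                label="median")
        ax.plot(curve.times / 1000.0, curve.hpd_lower, lw=0.8, color="gray")
        ax.plot(curve.times / 1000.0, curve.hpd_upper, lw=0.8, color="gray",
                label="95% HPD")
        ax.set_yscale("log")
        ax.set_xlabel("time (ka BP)")
        ax.set_ylabel(r"$N_{ef} \times T$ (years)")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)


def read_skyline(path) -> SkylineCurve:
    df = pd.read_csv(path, sep="\t")
    expected = ["time_bp", "median", "hpd_lower", "hpd_upper"]
    if list(df.columns) != expected:
        raise InvalidInputError(f"skyline TSV must have columns {expected}")
    return SkylineCurve(
        df["time_bp"].to_numpy(), df["median"].to_numpy(),
        df["hpd_lower"].to_numpy(), df["hpd_upper"].to_numpy(),
        truncation_age=float(df["time_bp"].iloc[-1]),
    )
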