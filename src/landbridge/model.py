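"""Statsmodels-style modelling surface.

:class:`CalibratedClockModel` binds an alignment to a full model
specification (substitution + clock + demographic prior + calibrations);
``fit()`` runs one or more MCMC chains and returns a
:class:`PosteriorResults` object carrying the pooled trace, parameter
summaries with HPD intervals and ESS, node-time tables, MCC trees and
skyline reconstructions.  ``marginal_likelihood()`` runs the power-posterior
ladder and returns both path-sampling and stepping-stone estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .alignment import Alignment
from .diagnostics import combine_chains, ess, hpd_interval
from .errors import InvalidInputError
from .mcmc import ChainConfig, ModelConfig, PosteriorTrace, run_mcmc
from .model_selection import (
    PowerPosteriorRun,
    path_sampling_logml,
    power_schedule,
    run_power_posteriors,
    stepping_stone_logml,
)
from .skyline import SkylineCurve, skyline_curve
from .treesummary import MccTree, induced_prior_report, mcc_tree, node_time_summary
from .trees import TimeTree

__all__ = ["CalibratedClockModel", "PosteriorResults", "MarginalLikelihoodResult"]


@dataclass
class MarginalLikelihoodResult:
    log_ml_path: float
    log_ml_stepping_stone: float
    run: PowerPosteriorRun

    @property
    def discrepancy(self) -> float:
        """|path sampling - stepping stone|: the convergence diagnostic."""
        return abs(self.log_ml_path - self.log_ml_stepping_stone)


class CalibratedClockModel:
    """A Bayesian coalescent dating model bound to one alignment.

    Parameters
    ----------
    alignment
        The sequence data; ``None`` builds a prior-only model (sampling the
        joint prior over genealogies and parameters).
    config
        Full model specification.  Clade definitions used for tMRCA logging
        can be supplied either on the config or via ``clades``.
    """

    def __init__(self, alignment: Alignment | None, config: ModelConfig,
                 clades: dict[str, list[str]] | None = None):
        if clades:
            merged = dict(config.clades)
            merged.update(clades)
            config = replace(config, clades=merged)
        if alignment is not None:
            known = set(alignment.ids)
            for name, taxa in config.clades.items():
                missing = set(taxa) - known
                if missing:
                    raise InvalidInputError(
                        f"clade {name!r} names unknown taxa: {sorted(missing)}"
                    )
        self.alignment = alignment
        self.config = config

    @classmethod
    def from_fasta(cls, path, config: ModelConfig,
                   clades: dict[str, list[str]] | None = None) -> "CalibratedClockModel":
        return cls(Alignment.from_fasta(path), config, clades)

    # ------------------------------------------------------------------ fit
    def fit(
        self,
        n_generations: int = 200_000,
        seed: int = 0,
        n_chains: int = 1,
        thin: int = 100,
        burnin_fraction: float = 0.10,
        prior_only: bool = False,
        init_tree: TimeTree | None = None,
        sample_trees: bool = True,
    ) -> "PosteriorResults":
        """Run ``n_chains`` independent MCMC chains and pool them after
        per-chain burnin.  Chain ``i`` uses seed ``seed + i``."""
        chain_cfg = ChainConfig(
            n_generations=n_generations, thin=thin,
            burnin_fraction=burnin_fraction, sample_trees=sample_trees,
        )
        aln = None if prior_only else self.alignment
        traces = [
            run_mcmc(self.config, aln, chain_cfg, seed=seed + i,
                     init_tree=init_tree)
            for i in range(n_chains)
        ]
        return PosteriorResults(self, traces, burnin_fraction)

    # --------------------------------------------------- marginal likelihood
    def marginal_likelihood(
        self,
        n_steps: int = 32,
        generations_per_step: int = 4_000,
        seed: int = 0,
        thin: int = 10,
        beta_shape: float = 0.3,
        init_tree: TimeTree | None = None,
    ) -> MarginalLikelihoodResult:
        if self.alignment is None:
            raise InvalidInputError("marginal likelihood requires sequence data")
        schedule = power_schedule(n_steps, beta_shape)
        chain_cfg = ChainConfig(n_generations=generations_per_step, thin=thin,
                                burnin_fraction=0.25)
        run = run_power_posteriors(self.config, self.alignment, schedule,
                                   chain_cfg, seed=seed, init_tree=init_tree)
        return MarginalLikelihoodResult(
            log_ml_path=path_sampling_logml(run),
            log_ml_stepping_stone=stepping_stone_logml(run),
            run=run,
        )


class PosteriorResults:
    """Posterior sample with summary machinery (statsmodels-results style)."""

    def __init__(self, model: CalibratedClockModel,
                 chains: list[PosteriorTrace], burnin_fraction: float):
        self.model = model
        self.chains = chains
        self.burnin_fraction = burnin_fraction
        self.trace = combine_chains(chains, burnin_fraction) \
            if len(chains) > 1 else chains[0].burned(burnin_fraction)

    # ------------------------------------------------------------- summaries
    _SKIP_COLS = ("state",)

    def parameter_names(self) -> list[str]:
        return [c for c in self.trace.df.columns if c not in self._SKIP_COLS]

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, median, 95% HPD and ESS per logged parameter.

        ESS is reported for the pooled post-burnin sample; per-chain ESS
        (the convergence criterion) is available via :meth:`ess_by_chain`.
        """
        rows = []
        for name in self.parameter_names():
            x = self.trace.df[name].to_numpy(dtype=float)
            lo, hi = hpd_interval(x) if len(x) >= 20 else (x.min(), x.max())
            e, flag = ess(x, return_flag=True) if len(x) >= 10 else (np.nan, True)
            rows.append({
                "parameter": name, "mean": x.mean(), "sd": x.std(ddof=1),
                "median": float(np.median(x)), "hpd_lower": lo, "hpd_upper": hi,
                "ess": e, "degenerate": flag,
            })
        return pd.DataFrame(rows).set_index("parameter")

    def ess_by_chain(self, min_ess: float = 200.0) -> pd.DataFrame:
        """Per-chain ESS table with a flag where ESS < ``min_ess``."""
        rows = []
        for i, ch in enumerate(self.chains):
            b = ch.burned(self.burnin_fraction)
            for name in self.parameter_names():
                x = b.df[name].to_numpy(dtype=float)
                e = ess(x) if len(x) >= 10 else np.nan
                rows.append({"chain": i, "parameter": name, "ess": e,
                             "below_target": bool(e < min_ess)})
        return pd.DataFrame(rows)

    def node_times(self, clades: dict[str, list[str]] | None = None):
        cl = clades if clades is not None else self.model.config.clades
        return node_time_summary(self.trace, cl)

    def node_times_frame(self, clades=None, ka: bool = True) -> pd.DataFrame:
        """Node-time table; ages in ka BP (3 decimals) by default."""
        scale = 1e-3 if ka else 1.0
        rows = [
            {
                "clade": s.clade,
                "hpd_lower": round(s.hpd_lower * scale, 3),
                "median": round(s.median * scale, 3),
                "hpd_upper": round(s.hpd_upper * scale, 3),
            }
            for s in self.node_times(clades)
        ]
        return pd.DataFrame(rows)

    def mcc_tree(self) -> MccTree:
        return mcc_tree(self.trace)

    def skyline(self, grid_size: int = 100) -> SkylineCurve:
        return skyline_curve(self.trace, grid_size)

    def induced_prior_report(self) -> pd.DataFrame:
        return induced_prior_report(self.trace,
                                    list(self.model.config.calibrations))

    def __str__(self) -> str:  # pragma: no cover - formatting only
        s = self.summary()
        head = (f"CalibratedClockModel results: {len(self.chains)} chain(s), "
                f"{self.trace.n_samples} pooled samples\n")
        return head + s.to_string(float_format=lambda v: f"{v:.6g}")
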