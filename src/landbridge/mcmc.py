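"""Metropolis–Hastings sampler over calibrated coalescent genealogies.

The target density is

    posterior(tree, params)  ∝  L(alignment | tree, params)^beta
                                × coalescent(tree | demography)
                                × calibrations(tree)
                                × parameter priors × UCLN branch-rate prior

with ``beta = 1`` for ordinary posterior sampling, ``beta = 0`` (or a missing
alignment) for prior-only sampling, and intermediate ``beta`` for the power
posteriors used in marginal-likelihood estimation.

Operators: node-age moves (uniform in the parent/children bracket), root and
whole-tree scaling, a rate/age "updown" move along the clock ridge, a
symmetric subtree-exchange topology move, multiplicative scale moves for
scalar parameters, a two-state frequency shuffle, UCLN multiplier scale and
swap moves, and skyline group-theta scale plus group-boundary moves.  Scale
factors are auto-tuned toward 23% acceptance during burnin only, so the
post-burnin chain satisfies detailed balance; tuned values are recorded in
the trace metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .demography import DemographicModel
from .errors import InvalidInputError
from .likelihood import TreeLikelihood
from .priors import (
    CalibrationPrior,
    ExponentialPrior,
    LogNormalPrior,
)
from .substitution import ClockModel, SubstitutionModel
from .trees import TimeTree

__all__ = ["ModelConfig", "ChainConfig", "PosteriorTrace", "run_mcmc", "initial_tree"]


# ------------------------------------------------------------- configuration
@dataclass
class ModelConfig:
    """Everything defining one MCMC target: substitution + clock models,
    demographic (tree) prior, calibrations, and which parameters to sample."""

    subst: SubstitutionModel = field(default_factory=SubstitutionModel)
    clock: ClockModel = field(default_factory=ClockModel)
    demography: DemographicModel = field(default_factory=DemographicModel)
    calibrations: tuple[CalibrationPrior, ...] = ()
    clades: dict[str, list[str]] = field(default_factory=dict)
    fixed_topology: bool = False

    estimate_rate: bool = True
    estimate_kappa: bool = True
    estimate_alpha: bool = True
    estimate_freqs: bool = False
    estimate_rate_ratio: bool = True
    estimate_demography: bool = True
    estimate_ucln_sigma: bool = True

    rate_prior: LogNormalPrior = field(
        default_factory=lambda: LogNormalPrior(np.log(5e-7), 1.5)
    )
    kappa_prior: LogNormalPrior = field(
        default_factory=lambda: LogNormalPrior(1.0, 1.25)
    )
    alpha_prior: ExponentialPrior = field(default_factory=lambda: ExponentialPrior(1.0))
    rate_ratio_prior: LogNormalPrior = field(
        default_factory=lambda: LogNormalPrior(0.0, 1.5)
    )
    theta_prior: LogNormalPrior = field(
        default_factory=lambda: LogNormalPrior(np.log(20_000.0), 2.0)
    )
    growth_prior: ExponentialPrior = field(
        default_factory=lambda: ExponentialPrior(2e-4)
    )
    ucln_sigma_prior: ExponentialPrior = field(
        default_factory=lambda: ExponentialPrior(1.0 / 3.0)
    )


@dataclass
class ChainConfig:
    n_generations: int = 100_000
    thin: int = 100
    burnin_fraction: float = 0.10
    tune: bool = True
    sample_trees: bool = True
    target_acceptance: float = 0.23


# ------------------------------------------------------------------- state
class _State:
    __slots__ = (
        "parent", "ages", "rate", "kappa", "alpha", "rate_ratio", "freqs",
        "theta0", "growth", "group_thetas", "group_sizes",
        "ucln_sigma", "multipliers",
        "loglik", "log_coal", "log_cal", "log_prior",
    )

    def clone(self) -> "_State":
        st = _State()
        st.parent = self.parent
        st.ages = self.ages.copy()
        st.rate = self.rate
        st.kappa = self.kappa.copy()
        st.alpha = self.alpha.copy()
        st.rate_ratio = self.rate_ratio
        st.freqs = self.freqs
        st.theta0 = self.theta0
        st.growth = self.growth
        st.group_thetas = None if self.group_thetas is None else self.group_thetas.copy()
        st.group_sizes = None if self.group_sizes is None else self.group_sizes.copy()
        st.ucln_sigma = self.ucln_sigma
        st.multipliers = None if self.multipliers is None else self.multipliers.copy()
        st.loglik = self.loglik
        st.log_coal = self.log_coal
        st.log_cal = self.log_cal
        st.log_prior = self.log_prior
        return st


def _coal_logp(state: _State, config: ModelConfig, n_tips: int) -> float:
    """Vectorized variable-size coalescent log density on state arrays."""
    times = np.sort(state.ages[n_tips:])
    k = np.arange(n_tips, 1, -1, dtype=float)
    pairs = k * (k - 1) / 2.0
    dt = np.diff(np.concatenate([[0.0], times]))
    kind = config.demography.kind
    if kind == "constant":
        th = state.theta0
        return float(-(n_tips - 1) * np.log(th) - np.dot(pairs, dt) / th)
    if kind == "expansion":
        th, g = state.theta0, state.growth
        f = config.demography.ancestral_fraction
        if g == 0.0:
            return float(-(n_tips - 1) * np.log(th) - np.dot(pairs, dt) / th)
        if f == 0.0:
            lam = np.expm1(g * times) / (g * th)
            log_n = np.log(th) - g * times
        else:
            lam = np.log1p(f * np.expm1(g * times)) / (th * f * g)
            log_n = np.log(th) + np.log(f + (1 - f) * np.exp(-g * times))
        dlam = np.diff(np.concatenate([[0.0], lam]))
        return float(-np.sum(log_n) - np.dot(pairs, dlam))
    # skyline: theta per coalescent interval via group sizes
    per_int = np.repeat(state.group_thetas, state.group_sizes)
    return float(-np.sum(np.log(per_int)) - np.sum(pairs * dt / per_int))


class _CalEngine:
    """Calibration evaluation with topology-keyed MRCA caching."""

    def __init__(self, config: ModelConfig, labels: Sequence[str]):
        self.cals = list(config.calibrations)
        self.labels = list(labels)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.tipsets = []
        for cal in self.cals:
            if cal.target == "root" and cal.taxa is None:
                self.tipsets.append(None)
            else:
                self.tipsets.append(
                    np.asarray(sorted(self.index[t] for t in cal.taxa), dtype=np.int64)
                )
        self._cache_key = None
        self._cache = None

    def resolve(self, parent: np.ndarray):
        key = parent.tobytes()
        if key == self._cache_key:
            return self._cache
        n_nodes = len(parent)
        n_tips = (n_nodes + 1) // 2
        masks = np.zeros((n_nodes, n_tips), dtype=bool)
        masks[np.arange(n_tips), np.arange(n_tips)] = True
        children = [[] for _ in range(n_nodes)]
        root = 0
        for i, p in enumerate(parent):
            if p >= 0:
                children[p].append(i)
            else:
                root = i
        order = []
        stack = [root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(children[i])
        for i in reversed(order):
            p = parent[i]
            if p >= 0:
                masks[p] |= masks[i]
        resolved = []
        for cal, tips in zip(self.cals, self.tipsets):
            if tips is None:
                resolved.append((root, True))
                continue
            node = int(tips[0])
            want = np.zeros(n_tips, dtype=bool)
            want[tips] = True
            while not np.all(want <= masks[node]):
                node = int(parent[node])
            mono = int(masks[node].sum()) == len(tips)
            resolved.append((node, mono))
        self._cache_key = key
        self._cache = resolved
        return resolved

    def logp(self, state: _State) -> float:
        if not self.cals:
            return 0.0
        total = 0.0
        for cal, (node, mono) in zip(self.cals, self.resolve(state.parent)):
            if cal.taxa is not None and cal.monophyly_enforced and not mono:
                return -np.inf
            lp = cal.log_density_at(float(state.ages[node]))
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def mrca_age(self, state: _State, taxa: Sequence[str]) -> float:
        tips = np.asarray(sorted(self.index[t] for t in taxa), dtype=np.int64)
        if len(tips) == 1:
            return 0.0
        parent = state.parent
        n_nodes = len(parent)
        n_tips = (n_nodes + 1) // 2
        # ascend from one tip, checking descendant masks only along the path
        anc = []
        node = int(tips[0])
        while node >= 0:
            anc.append(node)
            node = int(parent[node])
        depth_of = {nd: i for i, nd in enumerate(anc)}
        deepest = 0
        for t in tips[1:]:
            node = int(t)
            while node not in depth_of:
                node = int(parent[node])
            deepest = max(deepest, depth_of[node])
        return float(state.ages[anc[deepest]])


def _param_log_prior(state: _State, config: ModelConfig) -> float:
    lp = 0.0
    if config.estimate_rate:
        lp += config.rate_prior.logpdf(state.rate)
    if config.estimate_kappa:
        lp += sum(config.kappa_prior.logpdf(k) for k in state.kappa)
    if config.estimate_alpha:
        lp += sum(config.alpha_prior.logpdf(a) for a in state.alpha)
    if config.estimate_rate_ratio and config.subst.n_partitions == 2:
        lp += config.rate_ratio_prior.logpdf(state.rate_ratio)
    if config.estimate_demography:
        if config.demography.kind == "skyline":
            lp += sum(config.theta_prior.logpdf(t) for t in state.group_thetas)
        else:
            lp += config.theta_prior.logpdf(state.theta0)
            if config.demography.kind == "expansion":
                lp += config.growth_prior.logpdf(state.growth)
    if config.clock.kind == "ucln":
        if config.estimate_ucln_sigma:
            lp += config.ucln_sigma_prior.logpdf(state.ucln_sigma)
        s = state.ucln_sigma
        m = state.multipliers[state.parent >= 0]
        if s == 0.0:
            lp += 0.0 if np.allclose(m, 1.0) else -np.inf
        else:
            mu = -0.5 * s * s
            z = (np.log(m) - mu) / s
            lp += float(np.sum(-0.5 * z * z - np.log(m * s * np.sqrt(2 * np.pi))))
    return float(lp)


# ----------------------------------------------------------------- operators
class _Op:
    dirty_lik = True
    dirty_coal = True
    dirty_cal = True
    dirty_prior = False
    tunable = True

    def __init__(self, name: str, weight: float, scale: float = 0.5):
        self.name = name
        self.weight = weight
        self.scale = scale
        self.n_proposed = 0
        self.n_accepted = 0

    def propose(self, st: _State, rng, n_tips: int):  # -> log-Hastings or None
        raise NotImplementedError


class _NodeAge(_Op):
    tunable = False

    def propose(self, st, rng, n_tips):
        n_nodes = len(st.parent)
        internal = [i for i in range(n_tips, n_nodes) if st.parent[i] >= 0]
        if not internal:
            return None
        i = internal[rng.integers(len(internal))]
        kids = np.flatnonzero(st.parent == i)
        lo = float(st.ages[kids].max())
        hi = float(st.ages[st.parent[i]])
        st.ages[i] = rng.uniform(lo, hi)
        return 0.0


class _RootScale(_Op):
    def propose(self, st, rng, n_tips):
        root = int(np.flatnonzero(st.parent < 0)[0])
        kids = np.flatnonzero(st.parent == root)
        lo = float(st.ages[kids].max())
        m = np.exp(self.scale * (rng.random() - 0.5))
        st.ages[root] = lo + (st.ages[root] - lo) * m
        return float(np.log(m))


class _TreeScale(_Op):
    def propose(self, st, rng, n_tips):
        m = np.exp(self.scale * (rng.random() - 0.5))
        st.ages[n_tips:] = st.ages[n_tips:] * m
        return (len(st.ages) - n_tips) * float(np.log(m))


class _RateAgeUpDown(_Op):
    dirty_prior = True

    def propose(self, st, rng, n_tips):
        m = np.exp(self.scale * (rng.random() - 0.5))
        st.ages[n_tips:] = st.ages[n_tips:] * m
        st.rate = st.rate / m
        return (len(st.ages) - n_tips - 1) * float(np.log(m))


class _RidgeUpDown(_Op):
    """Joint move along the clock ridge: all node ages and theta scale up
    while the rate scales down (the classic upDown operator)."""

    dirty_prior = True

    def propose(self, st, rng, n_tips):
        m = np.exp(self.scale * (rng.random() - 0.5))
        st.ages[n_tips:] = st.ages[n_tips:] * m
        st.rate = st.rate / m
        n_extra = 0
        if st.group_thetas is not None:
            st.group_thetas = st.group_thetas * m
            n_extra = len(st.group_thetas)
        else:
            st.theta0 = st.theta0 * m
            n_extra = 1
        return (len(st.ages) - n_tips + n_extra - 1) * float(np.log(m))


class _Exchange(_Op):
    """Symmetric subtree swap: pick two non-root nodes, neither ancestral to
    the other, and exchange their parents; valid only if ages allow."""

    tunable = False

    def propose(self, st, rng, n_tips):
        n_nodes = len(st.parent)
        root = int(np.flatnonzero(st.parent < 0)[0])
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j or i == root or j == root:
            return None
        pi, pj = int(st.parent[i]), int(st.parent[j])
        if pi == pj:
            return None
        if st.ages[pj] <= st.ages[i] or st.ages[pi] <= st.ages[j]:
            return None
        # ancestry check along the two root paths
        node = pi
        while node >= 0:
            if node == j:
                return None
            node = int(st.parent[node])
        node = pj
        while node >= 0:
            if node == i:
                return None
            node = int(st.parent[node])
        parent = st.parent.copy()
        parent[i], parent[j] = pj, pi
        st.parent = parent
        return 0.0


class _Scale(_Op):
    dirty_lik = False
    dirty_coal = False
    dirty_cal = False
    dirty_prior = True

    def __init__(self, name, weight, attr, scale=0.5, index=None,
                 dirty_lik=False, dirty_coal=False):
        super().__init__(name, weight, scale)
        self.attr = attr
        self.index = index
        self.dirty_lik = dirty_lik
        self.dirty_coal = dirty_coal

    def propose(self, st, rng, n_tips):
        m = np.exp(self.scale * (rng.random() - 0.5))
        val = getattr(st, self.attr)
        if self.index is None and np.isscalar(val):
            setattr(st, self.attr, val * m)
        else:
            arr = val
            idx = self.index if self.index is not None else rng.integers(len(arr))
            arr[idx] = arr[idx] * m
        return float(np.log(m))


class _FreqStep(_Op):
    dirty_coal = False
    dirty_cal = False
    dirty_prior = True

    def propose(self, st, rng, n_tips):
        freqs = st.freqs.copy()
        p = rng.integers(freqs.shape[0])
        a, b = rng.choice(4, size=2, replace=False)
        delta = (rng.random() - 0.5) * self.scale * 0.2
        freqs[p, a] += delta
        freqs[p, b] -= delta
        if freqs[p, a] <= 1e-3 or freqs[p, b] <= 1e-3:
            return None
        st.freqs = freqs
        return 0.0


class _MultiplierScale(_Op):
    dirty_coal = False
    dirty_cal = False
    dirty_prior = True

    def propose(self, st, rng, n_tips):
        branches = np.flatnonzero(st.parent >= 0)
        b = branches[rng.integers(len(branches))]
        m = np.exp(self.scale * (rng.random() - 0.5))
        st.multipliers[b] = st.multipliers[b] * m
        return float(np.log(m))


class _MultiplierSwap(_Op):
    tunable = False
    dirty_coal = False
    dirty_cal = False
    dirty_prior = False

    def propose(self, st, rng, n_tips):
        branches = np.flatnonzero(st.parent >= 0)
        b1, b2 = rng.choice(branches, size=2, replace=False)
        st.multipliers[b1], st.multipliers[b2] = st.multipliers[b2], st.multipliers[b1]
        return 0.0


class _GroupBoundary(_Op):
    tunable = False
    dirty_lik = False
    dirty_cal = False
    dirty_prior = False

    def propose(self, st, rng, n_tips):
        m = len(st.group_sizes)
        if m < 2:
            return None
        j = rng.integers(m - 1)
        direction = 1 if rng.random() < 0.5 else -1
        new = st.group_sizes.copy()
        new[j] += direction
        new[j + 1] -= direction
        if new[j] < 1 or new[j + 1] < 1:
            return None
        st.group_sizes = new
        return 0.0


# ------------------------------------------------------------------- trace
@dataclass
class PosteriorTrace:
    """Sampled parameters and trees from one chain (or pooled chains)."""

    df: pd.DataFrame
    tree_samples: list[tuple[int, np.ndarray, np.ndarray]]
    labels: list[str]
    metadata: dict
    final_state: object = None  # chain handoff for power-posterior ladders

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def burned(self, burnin_fraction: float | None = None) -> "PosteriorTrace":
        frac = self.metadata.get("burnin_fraction", 0.1) \
            if burnin_fraction is None else burnin_fraction
        if not 0.0 <= frac < 1.0:
            raise InvalidInputError("burnin fraction must be in [0, 1)")
        gen_cut = frac * self.metadata["n_generations"]
        df = self.df[self.df["state"] >= gen_cut].reset_index(drop=True)
        trees = [t for t in self.tree_samples if t[0] >= gen_cut]
        meta = dict(self.metadata, burnin_applied=frac)
        return PosteriorTrace(df, trees, self.labels, meta)

    def trees(self) -> list[TimeTree]:
        return [TimeTree(p, a, self.labels) for _, p, a in self.tree_samples]

    def to_tsv(self, path) -> None:
        """Tracer-style tab-separated log (header row, 'state' first)."""
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PosteriorTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(df, [], [], {"n_generations": int(df["state"].max()),
                                "burnin_fraction": 0.0})


# -------------------------------------------------------------- initial tree
def initial_tree(config: ModelConfig, labels: Sequence[str], seed) -> TimeTree:
    """A heuristic starting genealogy respecting hard calibration bounds:
    each calibrated taxon set is made monophyletic with its MRCA at the
    center of the calibration's support, remaining lineages join above."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = list(labels)
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ages = np.zeros(n_nodes)
    next_internal = n

    clade_cals = [c for c in config.calibrations if c.taxa is not None]
    root_cals = [c for c in config.calibrations if c.taxa is None]
    used: set[int] = set()
    roots: list[int] = []
    targets: list[float] = []
    for cal in clade_cals:
        tips = [index[t] for t in cal.taxa]
        if used & set(tips):
            raise InvalidInputError("overlapping calibrated taxon sets")
        used.update(tips)
        lo, hi = cal.density.support
        target = 0.5 * (lo + hi) if np.isfinite(hi) else lo * 1.5
        active = list(tips)
        if len(active) == 1:
            roots.append(active[0])
            targets.append(0.0)
            continue
        heights = np.sort(rng.uniform(0.3 * target, target, size=len(active) - 1))
        heights[-1] = target
        for h in heights:
            node = next_internal
            next_internal += 1
            ages[node] = h
            i1, i2 = rng.choice(len(active), size=2, replace=False)
            parent[active[i1]] = node
            parent[active[i2]] = node
            for idx in sorted((i1, i2), reverse=True):
                active.pop(idx)
            active.append(node)
        roots.append(active[0])
        targets.append(target)
    free = [i for i in range(n) if i not in used]
    active = free + roots
    base = max(targets, default=0.0)
    if root_cals:
        lo, hi = root_cals[0].density.support
        peak = getattr(root_cals[0].density, "peak", None)
        root_target = float(peak) if peak is not None else (
            0.5 * (lo + hi) if np.isfinite(hi) else lo * 1.5)
        root_target = max(root_target, base * 1.3 + 1.0)
    else:
        root_target = max(2.0 * config.demography.theta0, base * 1.5 + 1.0)
    k = len(active)
    if k == 1:
        return TimeTree(parent, ages, labels)
    heights = np.sort(rng.uniform(base + 0.05 * (root_target - base),
                                  root_target, size=k - 1))
    heights[-1] = root_target
    for h in heights:
        node = next_internal
        next_internal += 1
        ages[node] = h
        i1, i2 = rng.choice(len(active), size=2, replace=False)
        parent[active[i1]] = node
        parent[active[i2]] = node
        for idx in sorted((i1, i2), reverse=True):
            active.pop(idx)
        active.append(node)
    return TimeTree(parent, ages, labels)


# --------------------------------------------------------------------- chain
def _build_operators(config: ModelConfig, n_tips: int, prior_only: bool):
    ops: list[_Op] = []
    n_int = n_tips - 1
    ops.append(_NodeAge("node_age", weight=max(n_int - 1, 1) * 2.0))
    ops.append(_RootScale("root_scale", weight=3.0, scale=0.3))
    ops.append(_TreeScale("tree_scale", weight=3.0, scale=0.15))
    if config.estimate_rate and not prior_only:
        ops.append(_RateAgeUpDown("rate_age_updown", weight=4.0, scale=0.15))
        ops.append(_Scale("rate_scale", 4.0, "rate", scale=0.3, dirty_lik=True))
        if config.estimate_demography:
            ops.append(_RidgeUpDown("ridge_updown", weight=4.0, scale=0.15))
    if not config.fixed_topology:
        ops.append(_Exchange("exchange", weight=max(n_int, 4) * 1.0))
    if not prior_only:
        if config.estimate_kappa:
            for p in range(config.subst.n_partitions):
                ops.append(_Scale(f"kappa{p}", 1.0, "kappa", 0.4, index=p,
                                  dirty_lik=True))
        if config.estimate_alpha:
            for p in range(config.subst.n_partitions):
                ops.append(_Scale(f"alpha{p}", 1.0, "alpha", 0.6, index=p,
                                  dirty_lik=True))
        if config.estimate_rate_ratio and config.subst.n_partitions == 2:
            ops.append(_Scale("rate_ratio", 1.0, "rate_ratio", 0.3,
                              dirty_lik=True))
        if config.estimate_freqs:
            ops.append(_FreqStep("freqs", 1.0, scale=0.5))
    if config.estimate_demography:
        if config.demography.kind == "skyline":
            m = len(config.demography.group_thetas)
            ops.append(_Scale("group_theta", weight=max(m, 2) * 1.5,
                              attr="group_thetas", scale=0.7, dirty_coal=True))
            ops.append(_GroupBoundary("group_boundary", weight=max(m - 1, 1) * 1.0))
        else:
            ops.append(_Scale("theta0", 2.0, "theta0", 0.5, dirty_coal=True))
            if config.demography.kind == "expansion":
                ops.append(_Scale("growth", 2.0, "growth", 0.7, dirty_coal=True))
    if config.clock.kind == "ucln" and not prior_only:
        ops.append(_MultiplierScale("ucln_mult", weight=max(n_int, 4) * 1.0,
                                    scale=0.5))
        ops.append(_MultiplierSwap("ucln_swap", weight=3.0))
        if config.estimate_ucln_sigma:
            ops.append(_Scale("ucln_sigma", 2.0, "ucln_sigma", 0.5))
    return ops


def _init_state(config: ModelConfig, tree: TimeTree, rng) -> _State:
    st = _State()
    st.parent = tree.parent.copy()
    st.ages = tree.ages.copy()
    st.rate = config.clock.mean_rate
    st.kappa = config.subst.kappa.copy()
    st.alpha = config.subst.gamma_alpha.copy()
    st.rate_ratio = config.subst.rate_ratio
    st.freqs = config.subst.base_freqs.copy()
    st.theta0 = config.demography.theta0
    st.growth = config.demography.growth_rate if config.demography.kind == "expansion" else 0.0
    if config.demography.kind == "skyline":
        st.group_sizes = config.demography.group_sizes.copy()
        st.group_thetas = config.demography.group_thetas.copy()
    else:
        st.group_sizes = None
        st.group_thetas = None
    st.ucln_sigma = config.clock.ucln_sigma
    if config.clock.kind == "ucln":
        st.multipliers = np.ones(tree.n_nodes)
    else:
        st.multipliers = None
    st.loglik = np.nan
    st.log_coal = np.nan
    st.log_cal = np.nan
    st.log_prior = np.nan
    return st


def _subst_from_state(st: _State, config: ModelConfig) -> SubstitutionModel:
    return SubstitutionModel(
        kappa=st.kappa, base_freqs=st.freqs, gamma_alpha=st.alpha,
        n_categories=config.subst.n_categories, rate_ratio=st.rate_ratio,
    )


def run_mcmc(
    config: ModelConfig,
    aln: Alignment | None,
    chain: ChainConfig,
    seed: int,
    init_tree: TimeTree | None = None,
    beta: float = 1.0,
    init_state: _State | None = None,
) -> PosteriorTrace:
    """Sample the (power-)posterior; ``aln=None`` samples the joint prior.

    Identical seed, config and inputs yield a bit-identical trace.
    """
    rng = np.random.default_rng(seed)
    prior_only = aln is None or beta == 0.0
    if aln is not None:
        labels = list(aln.ids)
    elif init_tree is not None:
        labels = list(init_tree.labels)
    else:
        taxa = sorted({t for c in config.calibrations if c.taxa for t in c.taxa})
        for cl in config.clades.values():
            for t in cl:
                if t not in taxa:
                    taxa.append(t)
        if not taxa:
            raise InvalidInputError(
                "prior-only sampling needs an init tree, clades, or calibrated taxa"
            )
        labels = list(taxa)
    if init_state is not None:
        st = init_state.clone()
    else:
        if init_tree is None:
            init_tree = initial_tree(config, labels, rng)
        elif list(init_tree.labels) != labels:
            init_tree = TimeTree(
                init_tree.parent.copy(), init_tree.ages.copy(), init_tree.labels
            )
            if set(init_tree.labels) != set(labels):
                raise InvalidInputError("init tree labels do not match alignment")
            # reorder alignment-to-tree tip index mapping by relabeling tips
            perm = [init_tree.labels.index(lab) for lab in labels]
            remap = np.arange(init_tree.n_nodes)
            remap[np.asarray(perm)] = np.arange(len(labels))
            parent = init_tree.parent.copy()
            new_parent = np.empty_like(parent)
            for old in range(init_tree.n_nodes):
                new = remap[old] if old < len(labels) else old
                p = parent[old]
                new_parent[new] = remap[p] if 0 <= p < len(labels) else p
            ages = init_tree.ages.copy()
            ages[: len(labels)] = 0.0
            init_tree = TimeTree(new_parent, ages, labels)
        st = _init_state(config, init_tree, rng)
    n_tips = len(labels)

    evaluator = TreeLikelihood(aln, config.subst.n_partitions) if aln is not None else None
    cal_engine = _CalEngine(config, labels)

    def eval_lik(s: _State) -> float:
        if evaluator is None or beta == 0.0:
            return 0.0
        mult = s.multipliers if config.clock.kind == "ucln" else None
        return evaluator.loglik(s.parent, s.ages, s.rate,
                                _subst_from_state(s, config), mult)

    if config.demography.kind == "skyline" and \
            int(st.group_sizes.sum()) != n_tips - 1:
        raise InvalidInputError("skyline group sizes must sum to n_tips - 1")
    st.loglik = eval_lik(st)
    st.log_coal = _coal_logp(st, config, n_tips)
    st.log_cal = cal_engine.logp(st)
    st.log_prior = _param_log_prior(st, config)
    if not np.isfinite(st.log_coal + st.log_cal + st.log_prior):
        raise InvalidInputError(
            "initial state has zero prior density; provide a valid init tree"
        )

    ops = _build_operators(config, n_tips, prior_only)
    weights = np.array([op.weight for op in ops])
    weights = weights / weights.sum()
    burnin_gen = chain.burnin_fraction * chain.n_generations
    tune_decay = {op.name: 0 for op in ops}

    records = []
    tree_samples = []
    clade_items = list(config.clades.items())

    def record(gen: int):
        root = int(np.flatnonzero(st.parent < 0)[0])
        # at beta=0 the likelihood does not enter the chain, but its sampled
        # values are still needed by stepping-stone estimators
        logl = st.loglik
        if beta == 0.0 and evaluator is not None:
            mult = st.multipliers if config.clock.kind == "ucln" else None
            logl = evaluator.loglik(st.parent, st.ages, st.rate,
                                    _subst_from_state(st, config), mult)
        row = {
            "state": gen,
            "logL": logl,
            "logPrior": st.log_coal + st.log_cal + st.log_prior,
            "rate": st.rate,
            "root_age": float(st.ages[root]),
            "rate_ratio": st.rate_ratio,
        }
        for p in range(config.subst.n_partitions):
            row[f"kappa{p + 1}"] = st.kappa[p]
            row[f"alpha{p + 1}"] = st.alpha[p]
        if config.demography.kind == "skyline":
            for j, th in enumerate(st.group_thetas):
                row[f"skyline_theta{j + 1}"] = th
            for j, sz in enumerate(st.group_sizes):
                row[f"skyline_size{j + 1}"] = int(sz)
        else:
            row["theta0"] = st.theta0
            if config.demography.kind == "expansion":
                row["growth"] = st.growth
        if config.clock.kind == "ucln":
            row["ucln_sigma"] = st.ucln_sigma
        for name, taxa in clade_items:
            row[f"tmrca_{name}"] = cal_engine.mrca_age(st, taxa)
        records.append(row)
        if chain.sample_trees:
            tree_samples.append((gen, st.parent.copy(), st.ages.copy()))

    record(0)
    for gen in range(1, chain.n_generations + 1):
        op = ops[rng.choice(len(ops), p=weights)]
        op.n_proposed += 1
        cand = st.clone()
        lh = op.propose(cand, rng, n_tips)
        accepted = False
        if lh is not None:
            cand.log_cal = cal_engine.logp(cand) if op.dirty_cal else st.log_cal
            if np.isfinite(cand.log_cal):
                cand.log_prior = _param_log_prior(cand, config) if op.dirty_prior \
                    else st.log_prior
                if np.isfinite(cand.log_prior):
                    cand.log_coal = _coal_logp(cand, config, n_tips) \
                        if op.dirty_coal else st.log_coal
                    cand.loglik = eval_lik(cand) if op.dirty_lik else st.loglik
                    log_ratio = (
                        beta * (cand.loglik - st.loglik)
                        + (cand.log_coal - st.log_coal)
                        + (cand.log_cal - st.log_cal)
                        + (cand.log_prior - st.log_prior)
                        + lh
                    )
                    if np.isfinite(log_ratio) and np.log(rng.random()) < log_ratio:
                        st = cand
                        accepted = True
        if accepted:
            op.n_accepted += 1
        if chain.tune and op.tunable and gen <= burnin_gen:
            # Robbins–Monro step toward the target acceptance rate
            tune_decay[op.name] += 1
            step = 1.0 / np.sqrt(tune_decay[op.name] + 10.0)
            op.scale *= np.exp(step * ((1.0 if accepted else 0.0)
                                       - chain.target_acceptance))
            op.scale = float(np.clip(op.scale, 1e-4, 10.0))
        if gen % chain.thin == 0:
            record(gen)

    op_stats = {
        op.name: {
            "proposed": op.n_proposed,
            "accepted": op.n_accepted,
            "scale": op.scale,
        }
        for op in ops
    }
    warnings = [
        f"operator {op.name!r} accepted nothing in {op.n_proposed} proposals"
        for op in ops if op.n_proposed >= 50 and op.n_accepted == 0
    ]
    meta = {
        "seed": seed,
        "n_generations": chain.n_generations,
        "thin": chain.thin,
        "burnin_fraction": chain.burnin_fraction,
        "beta": beta,
        "prior_only": prior_only,
        "operators": op_stats,
        "warnings": warnings,
    }
    df = pd.DataFrame.from_records(records)
    return PosteriorTrace(df, tree_samples, labels, meta, final_state=st)
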