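"""Diversity and neutrality statistics with coalescent-simulation p-values.

Two deliberately distinct notions of "pairwise difference" coexist here,
matching their standard definitions:

* nucleotide diversity ``pi`` is a per-site, multiple-hit-corrected distance
  (Kimura two-parameter with Jin–Nei gamma correction);
* Tajima's D and Fu's F_S use raw per-alignment difference *counts*, because
  their variance theory assumes the infinite-sites model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import NUC_CODES, Alignment
from .errors import (
    DegenerateComparisonError,
    InvalidInputError,
    SaturationError,
    UndefinedStatisticError,
)
from .nulldist import (
    fu_fs_from_counts,
    null_fu_fs,
    null_tajima_d,
    tajima_d_from_counts,
)

__all__ = [
    "DiversityEstimate",
    "NeutralityTestResult",
    "count_site_differences",
    "k2p_gamma_distance",
    "nucleotide_diversity",
    "segregating_sites",
    "mean_pairwise_differences",
    "tajimas_d",
    "fus_fs",
    "count_haplotypes",
    "coalescent_null_test",
]

_VALID = (1, 2, 4, 8)  # unambiguous A, C, G, T bitmasks


@dataclass
class DiversityEstimate:
    pi: float
    se_pi: float
    n_sequences: int
    alpha: float


@dataclass
class NeutralityTestResult:
    statistic_name: str
    observed: float
    p_coal: float
    n_simulations: int
    seed: int
    n_undefined: int = 0
    warning: str | None = None

    @property
    def p_label(self) -> str:
        if self.p_coal == 0.0:
            return f"<{1.0 / self.n_simulations:g}"
        return f"{self.p_coal:g}"


# --------------------------------------------------------------- pair counts
def count_site_differences(seq_a: str, seq_b: str):
    """Transition proportion P, transversion proportion Q, and the number of
    retained sites L, under pairwise deletion of ambiguous/gapped sites."""
    if len(seq_a) != len(seq_b):
        raise InvalidInputError("sequences must have equal length")
    code = np.full(256, 255, dtype=np.uint8)
    for ch, c in NUC_CODES.items():
        code[ord(ch)] = c
    a = code[np.frombuffer(seq_a.upper().encode("ascii"), dtype=np.uint8)]
    b = code[np.frombuffer(seq_b.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(a == 255) or np.any(b == 255):
        raise InvalidInputError("unknown nucleotide symbol")
    valid = np.isin(a, _VALID) & np.isin(b, _VALID)
    length = int(valid.sum())
    if length == 0:
        raise DegenerateComparisonError("no comparable sites after pairwise deletion")
    diff = valid & (a != b)
    # A|G = 5 and C|T = 10 identify the two transition pairs
    ts = diff & np.isin(a | b, (5, 10))
    p = ts.sum() / length
    q = (diff.sum() - ts.sum()) / length
    return float(p), float(q), length


def k2p_gamma_distance(p: float, q: float, alpha: float | None = 0.1705) -> float:
    """Kimura two-parameter distance with Jin–Nei gamma rate correction.

    ``d = (alpha/2) * [(1-2P-Q)^(-1/alpha) + (1/2)(1-2Q)^(-1/alpha) - 3/2]``;
    with ``alpha=None`` (or infinite) the uncorrected K2P log formula is used.
    """
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P correction saturated (P={p:.4f}, Q={q:.4f})"
        )
    if alpha is None or np.isinf(alpha):
        return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))
    if alpha <= 0:
        raise InvalidInputError("gamma shape alpha must be > 0")
    return float(alpha / 2.0 * (w1 ** (-1.0 / alpha)
                                + 0.5 * w2 ** (-1.0 / alpha) - 1.5))


def _pair_tables(aln: Alignment):
    """Per-pair per-site transition/transversion/valid indicators."""
    codes = aln.codes
    n = aln.n_sequences
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid_cell = aln.is_valid_base()
    ts = np.empty((len(pairs), aln.n_sites), dtype=np.float64)
    tv = np.empty_like(ts)
    va = np.empty_like(ts)
    for idx, (i, j) in enumerate(pairs):
        v = valid_cell[i] & valid_cell[j]
        diff = v & (codes[i] != codes[j])
        t = diff & np.isin(codes[i] | codes[j], (5, 10))
        ts[idx] = t
        tv[idx] = diff & ~t
        va[idx] = v
    return pairs, ts, tv, va


def nucleotide_diversity(aln: Alignment, alpha: float = 0.1705,
                         n_boot: int = 1000, seed: int = 0) -> DiversityEstimate:
    """Mean gamma-corrected K2P distance over all sequence pairs, with a
    site-resampling bootstrap standard error (columns resampled with
    replacement, ``pi`` recomputed per replicate)."""
    if aln.n_sequences < 2:
        raise InvalidInputError("nucleotide diversity needs >= 2 sequences")
    pairs, ts, tv, va = _pair_tables(aln)
    ts_tot, tv_tot, va_tot = ts.sum(1), tv.sum(1), va.sum(1)
    if np.any(va_tot == 0):
        bad = pairs[int(np.argmax(va_tot == 0))]
        raise DegenerateComparisonError(
            f"pair {aln.ids[bad[0]]!r}/{aln.ids[bad[1]]!r} shares no comparable sites"
        )
    dists = np.array([
        k2p_gamma_distance(ts_tot[i] / va_tot[i], tv_tot[i] / va_tot[i], alpha)
        if _unsaturated(ts_tot[i] / va_tot[i], tv_tot[i] / va_tot[i])
        else _raise_saturated(aln, pairs[i])
        for i in range(len(pairs))
    ])
    pi = float(dists.mean())
    se = 0.0
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        w = rng.multinomial(aln.n_sites,
                            np.full(aln.n_sites, 1.0 / aln.n_sites),
                            size=n_boot).T.astype(float)
        ts_b, tv_b, va_b = ts @ w, tv @ w, va @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b = ts_b / va_b
            q_b = tv_b / va_b
            w1 = 1.0 - 2.0 * p_b - q_b
            w2 = 1.0 - 2.0 * q_b
            d_b = alpha / 2.0 * (w1 ** (-1.0 / alpha)
                                 + 0.5 * w2 ** (-1.0 / alpha) - 1.5)
        ok = np.all(np.isfinite(d_b) & (w1 > 0) & (w2 > 0), axis=0)
        reps = d_b[:, ok].mean(axis=0)
        se = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return DiversityEstimate(pi=pi, se_pi=se, n_sequences=aln.n_sequences,
                             alpha=alpha)


def _unsaturated(p, q):
    return (1.0 - 2.0 * p - q) > 0 and (1.0 - 2.0 * q) > 0


def _raise_saturated(aln, pair):
    raise SaturationError(
        f"pair {aln.ids[pair[0]]!r}/{aln.ids[pair[1]]!r} is saturated"
    )


# -------------------------------------------------- infinite-sites summaries
def segregating_sites(aln: Alignment) -> int:
    """Columns with at least two distinct unambiguous bases."""
    valid = aln.is_valid_base()
    seg = 0
    for j in range(aln.n_sites):
        col = aln.codes[valid[:, j], j]
        if len(np.unique(col)) >= 2:
            seg += 1
    return seg


def mean_pairwise_differences(aln: Alignment) -> float:
    """Mean raw difference count over all unordered pairs (pairwise deletion,
    uncorrected) — the infinite-sites estimator of theta used by D and F_S."""
    codes = aln.codes
    valid = aln.is_valid_base()
    n = aln.n_sequences
    total = 0.0
    for i in range(n):
        v = valid[i] & valid[i + 1:]
        total += ((codes[i] != codes[i + 1:]) & v).sum()
    return float(total / (n * (n - 1) / 2.0))


def tajimas_d(aln: Alignment) -> float:
    """Tajima (1989) D from segregating sites and mean pairwise differences."""
    if aln.n_sequences < 4:
        raise UndefinedStatisticError("Tajima's D needs >= 4 sequences")
    s = segregating_sites(aln)
    if s == 0:
        raise UndefinedStatisticError("no segregating sites")
    return float(tajima_d_from_counts(aln.n_sequences, s,
                                      mean_pairwise_differences(aln)))


def count_haplotypes(aln: Alignment) -> int:
    """Distinct full-length sequence strings (literal comparison after
    uppercasing; sequences differing only in ambiguity codes are distinct)."""
    return len({aln.sequence(i) for i in range(aln.n_sequences)})


def fus_fs(aln: Alignment) -> float:
    """Fu (1997) F_S via the Ewens sampling formula with exact Stirling
    numbers, using the pairwise theta estimate and the haplotype count."""
    if aln.n_sequences < 2:
        raise UndefinedStatisticError("Fu's F_S needs >= 2 sequences")
    theta = mean_pairwise_differences(aln)
    if theta <= 0:
        raise UndefinedStatisticError("all sequences identical: theta_pi = 0")
    return float(fu_fs_from_counts(aln.n_sequences, count_haplotypes(aln), theta))


# ------------------------------------------------------------------ p-values
def coalescent_null_test(aln: Alignment, statistic_name: str, n_sims: int,
                         seed: int, two_tailed: bool = False) -> NeutralityTestResult:
    """Empirical p-value of a neutrality statistic against the constant-size
    coalescent null, conditioning on the observed number of segregating
    sites (mutations dropped proportional to branch length).

    The default tail is lower (negative statistics signal expansion); a
    two-tailed p doubles the smaller tail.
    """
    if statistic_name not in ("tajima_d", "fu_fs"):
        raise InvalidInputError(f"unknown statistic {statistic_name!r}")
    if n_sims < 1:
        raise InvalidInputError("n_sims must be >= 1")
    observed = tajimas_d(aln) if statistic_name == "tajima_d" else fus_fs(aln)
    s_obs = segregating_sites(aln)
    if s_obs == 0:
        raise UndefinedStatisticError("no segregating sites")
    rng = np.random.default_rng(seed)
    n = aln.n_sequences
    if statistic_name == "tajima_d":
        sims = null_tajima_d(n, s_obs, n_sims, rng)
        n_undef = 0
    else:
        sims, n_undef = null_fu_fs(n, s_obs, n_sims, rng)
        sims = sims[np.isfinite(sims)]
    lower = float(np.mean(sims <= observed))
    if two_tailed:
        p = min(1.0, 2.0 * min(lower, float(np.mean(sims >= observed))))
    else:
        p = lower
    warning = None
    if n_undef > 0.01 * n_sims:
        warning = f"statistic undefined on {n_undef}/{n_sims} null replicates"
    return NeutralityTestResult(
        statistic_name=statistic_name, observed=float(observed), p_coal=p,
        n_simulations=n_sims, seed=seed, n_undefined=n_undef, warning=warning,
    )
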