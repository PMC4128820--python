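"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: likelihoods
are computed by exhaustive enumeration of ancestral states, Tajima's D and
Fu's F_S by literal formula transcription in exact rational arithmetic
(sympy Stirling numbers, fractions), and distances by direct evaluation of
the published formulas.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np
from sympy.functions.combinatorial.numbers import stirling

from landbridge.alignment import AMBIGUITY_MASKS
from landbridge.substitution import (
    discrete_gamma_categories,
    hky_rate_matrix,
    transition_probabilities,
)


def enumeration_loglik(tree, aln, subst, rate):
    """Tree likelihood by brute-force summation over all internal-state
    assignments, per site, per gamma category."""
    k = subst.n_categories
    if subst.n_partitions == 2:
        part = aln.partition_of_site()
    else:
        part = np.zeros(aln.n_sites, dtype=int)
    counts = [(part == p).sum() for p in range(subst.n_partitions)]
    prates = subst.partition_rates(counts)
    n = tree.n_tips
    nn = tree.n_nodes
    total = 0.0
    for site in range(aln.n_sites):
        p = part[site]
        q = hky_rate_matrix(subst.kappa[p], subst.base_freqs[p])
        cats = discrete_gamma_categories(subst.gamma_alpha[p], k)
        lik = 0.0
        for c in range(k):
            pm = {
                i: transition_probabilities(
                    q,
                    (tree.ages[tree.parent[i]] - tree.ages[i])
                    * rate * prates[p] * cats[c],
                )
                for i in range(nn) if tree.parent[i] >= 0
            }
            internals = list(range(n, nn))
            root = tree.root
            s = 0.0
            for assign in itertools.product(range(4), repeat=len(internals)):
                st = dict(zip(internals, assign))
                pr = subst.base_freqs[p][st[root]]
                for i in range(nn):
                    pa = tree.parent[i]
                    if pa < 0:
                        continue
                    if i < n:
                        pr *= float(np.dot(pm[i][st[pa]],
                                           AMBIGUITY_MASKS[aln.codes[i, site]]))
                    else:
                        pr *= pm[i][st[pa], st[i]]
                s += pr
            lik += s / k
        total += np.log(lik)
    return total


# --------------------------------------------------------- exact statistics
def exact_tajima_d(aln) -> float:
    """Tajima's D with the coefficient chain carried in exact rationals."""
    n = aln.n_sequences
    codes = aln.codes
    valid = np.isin(codes, (1, 2, 4, 8))
    s = 0
    for j in range(aln.n_sites):
        col = codes[valid[:, j], j]
        if len(set(col.tolist())) >= 2:
            s += 1
    diffs = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            v = valid[i] & valid[j]
            diffs += int(((codes[i] != codes[j]) & v).sum())
    pi = diffs / Fraction(n * (n - 1), 2)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi - Fraction(s) / a1) / np.sqrt(float(var)))


def exact_fu_fs(aln) -> float:
    """Fu's F_S via exact Ewens probabilities (sympy unsigned Stirling
    numbers of the first kind, rational theta from pairwise differences)."""
    n = aln.n_sequences
    codes = aln.codes
    valid = np.isin(codes, (1, 2, 4, 8))
    diffs = Fraction(0)
    for i in range(n):
        for j in range(i + 1, n):
            v = valid[i] & valid[j]
            diffs += int(((codes[i] != codes[j]) & v).sum())
    theta = diffs / Fraction(n * (n - 1), 2)
    k_obs = len({aln.sequence(i) for i in range(n)})
    # P(K = k) = |s(n,k)| theta^k / theta^(n)  (rising factorial)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    probs = []
    for k in range(n + 1):
        snk = int(stirling(n, k, kind=1, signed=False))
        probs.append(snk * theta**k / rising)
    s_prime = sum(probs[k_obs:])
    other = sum(probs[:k_obs])
    return float(np.log(float(s_prime)) - np.log(float(other)))


def gamma_category_means_quadrature(alpha: float, k: int) -> np.ndarray:
    """Category means of the mean-1 gamma by direct numerical quadrature."""
    from scipy import stats

    dist = stats.gamma(alpha, scale=1.0 / alpha)
    edges = dist.ppf(np.linspace(0, 1, k + 1))
    means = [
        dist.expect(lambda x: x, lb=lo, ub=hi) * k
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    means = np.asarray(means)
    return means / means.mean()


def hpd_exhaustive(samples, prob=0.95):
    """HPD by scanning every window of the sorted sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        w = x[i + m - 1] - x[i]
        if w < best[0]:
            best = (w, (float(x[i]), float(x[i + m - 1])))
    return best[1]
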