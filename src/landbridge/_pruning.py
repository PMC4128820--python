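"""Compiled inner loop for the pruning likelihood.

The numba kernel evaluates the full partitioned-mixture likelihood for one
tree in a single pass: transition matrices from the cached HKY
eigendecomposition, post-order partials with per-pattern rescaling, and the
weighted log-sum at the root.  Falls back transparently to the vectorized
numpy path in :mod:`landbridge.likelihood` if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def prune_loglik(
    postorder,      # (n_internal,) internal node ids, children-first
    child1,         # (n_nodes,) child ids (-1 for tips)
    child2,
    d_subs,         # (n_nodes,) substitution lengths of the branch above
    lam, u, uinv,   # (4,), (4,4), (4,4) eigendecomposition of Q
    cat_rates,      # (k,)
    partials,       # (n_nodes, k, npat, 4) workspace, tip rows pre-filled
    scale_log,      # (n_nodes, npat) workspace
    weights,        # (npat,)
    freqs,          # (4,)
    n_tips,
):
    n_nodes = child1.shape[0]
    npat = partials.shape[2]
    k = cat_rates.shape[0]

    # transition matrices per (node, category)
    pmat = np.empty((n_nodes, k, 4, 4))
    ex = np.empty(4)
    for b in range(n_nodes):
        for c in range(k):
            d = d_subs[b] * cat_rates[c]
            for m in range(4):
                ex[m] = np.exp(lam[m] * d)
            for i in range(4):
                for j in range(4):
                    acc = (u[i, 0] * ex[0] * uinv[0, j]
                           + u[i, 1] * ex[1] * uinv[1, j]
                           + u[i, 2] * ex[2] * uinv[2, j]
                           + u[i, 3] * ex[3] * uinv[3, j])
                    pmat[b, c, i, j] = acc if acc > 0.0 else 0.0

    root = postorder[postorder.shape[0] - 1]
    for idx in range(postorder.shape[0]):
        node = postorder[idx]
        a = child1[node]
        b = child2[node]
        for pat in range(npat):
            scale_log[node, pat] = scale_log[a, pat] + scale_log[b, pat]
        for c in range(k):
            pa = pmat[a, c]
            pb = pmat[b, c]
            la = partials[a, c]
            lb = partials[b, c]
            out = partials[node, c]
            for pat in range(npat):
                for i in range(4):
                    s1 = (pa[i, 0] * la[pat, 0] + pa[i, 1] * la[pat, 1]
                          + pa[i, 2] * la[pat, 2] + pa[i, 3] * la[pat, 3])
                    s2 = (pb[i, 0] * lb[pat, 0] + pb[i, 1] * lb[pat, 1]
                          + pb[i, 2] * lb[pat, 2] + pb[i, 3] * lb[pat, 3])
                    out[pat, i] = s1 * s2
        # per-pattern rescale across categories and states
        for pat in range(npat):
            mx = 0.0
            for c in range(k):
                for i in range(4):
                    v = partials[node, c, pat, i]
                    if v > mx:
                        mx = v
            if mx <= 0.0:
                return -np.inf
            if mx < 1e-30 or mx > 1e30:
                inv = 1.0 / mx
                for c in range(k):
                    for i in range(4):
                        partials[node, c, pat, i] *= inv
                scale_log[node, pat] += np.log(mx)

    total = 0.0
    for pat in range(npat):
        site = 0.0
        for c in range(k):
            for i in range(4):
                site += freqs[i] * partials[root, c, pat, i]
        site /= k
        if site <= 0.0:
            return -np.inf
        total += weights[pat] * (np.log(site) + scale_log[root, pat])
    return total
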