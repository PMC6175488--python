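"""Pruning (independent-contrasts) core for the multivariate Brownian model.

The profile log-likelihood of tip data X (n x p) under
``vec(X) ~ N(1 (x) alpha, Sigma (x) C)`` is computed in one post-order pass
without forming C.  At each internal node the two child partials are merged:
the contrast ``m1 - m2`` has variance ``(v1 + v2) * Sigma`` and the merged
partial mean gets extra variance ``v1*v2/(v1+v2)``.  The pass returns

* ``logdet_c`` — log|C|,
* ``S``        — sum over contrasts of ``u u' / var`` (the root residual is
  zero at the GLS mean, so it contributes nothing),
* ``alpha``    — the GLS/ML phylogenetic mean (the root partial mean),
* ``v_root``   — accumulated root variance factor (1' C^-1 1 = 1/v_root).

Profiling Sigma at its conditional ML value ``S/n`` gives

``loglik = -0.5 * (n p log 2π + p log|C| + n log|S/n| + n p)``.

Trees must be strictly bifurcating; merge variances are edge length times the
edge's effective rate scalar.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _pruning_pass(postorder, left, right, is_tip, vlen, X):
    """One post-order contrasts pass.

    postorder : int64[n_nodes], children before parents
    left/right: int64[n_nodes], child ids for internal nodes (-1 at tips)
    is_tip    : bool[n_nodes]
    vlen      : float64[n_nodes], effective rate x branch length per edge
                (0 at the root)
    X         : float64[n_nodes, p], tip rows hold data
    """
    n_nodes = postorder.shape[0]
    p = X.shape[1]
    mean = np.zeros((n_nodes, p))
    extra = np.zeros(n_nodes)
    S = np.zeros((p, p))
    logdet_c = 0.0
    root = postorder[n_nodes - 1]
    for idx in range(n_nodes):
        node = postorder[idx]
        if is_tip[node]:
            for j in range(p):
                mean[node, j] = X[node, j]
            extra[node] = 0.0
        else:
            c1 = left[node]
            c2 = right[node]
            v1 = vlen[c1] + extra[c1]
            v2 = vlen[c2] + extra[c2]
            var = v1 + v2
            logdet_c += np.log(var)
            for j in range(p):
                u_j = mean[c1, j] - mean[c2, j]
                for k in range(p):
                    u_k = mean[c1, k] - mean[c2, k]
                    S[j, k] += u_j * u_k / var
                mean[node, j] = (v2 * mean[c1, j] + v1 * mean[c2, j]) / var
            extra[node] = v1 * v2 / var
    v_root = extra[root] + vlen[root]
    logdet_c += np.log(v_root)
    alpha = mean[root].copy()
    return logdet_c, S, alpha, v_root


@njit(cache=True)
def _effective_rates(n_nodes, entry_edge, entry_is_clade, entry_scalar, subtree_flat, subtree_start, subtree_len):
    """Per-edge effective rate = product of covering scalars (default 1).

    Clade scalars multiply the target edge and every descendant edge
    (stem-inclusive); branch scalars multiply their edge only.  Subtree node
    lists are passed flattened (CSR-style) per edge.
    """
    rates = np.ones(n_nodes)
    for e in range(entry_edge.shape[0]):
        edge = entry_edge[e]
        r = entry_scalar[e]
        if entry_is_clade[e]:
            s = subtree_start[edge]
            for k in range(subtree_len[edge]):
                rates[subtree_flat[s + k]] *= r
        else:
            rates[edge] *= r
    return rates
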