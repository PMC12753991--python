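"""Collapsed-Gibbs sweep kernel for the LDA sampler.

One full sweep resamples every token's topic from its collapsed full
conditional  P(z_i = k) ∝ (n_dk + α) (n_kw + β) / (n_k + Vβ),  consuming one
pre-drawn uniform per token.  The uniforms are drawn outside the kernel so
that the jitted and pure-Python paths execute identical arithmetic on an
identical stream and therefore produce bit-identical chains.
"""

from __future__ import annotations

import numpy as np


def _sweep_py(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, uniforms):
    K = n_dk.shape[1]
    V = n_kw.shape[1]
    vbeta = V * beta
    cum = np.empty(K)
    for i in range(tokens.shape[0]):
        w = tokens[i]
        d = doc_of[i]
        k = z[i]
        n_dk[d, k] -= 1
        n_kw[k, w] -= 1
        n_k[k] -= 1
        total = 0.0
        for kk in range(K):
            total += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (
                n_k[kk] + vbeta)
            cum[kk] = total
        u = uniforms[i] * total
        knew = 0
        while cum[knew] < u and knew < K - 1:
            knew += 1
        z[i] = knew
        n_dk[d, knew] += 1
        n_kw[knew, w] += 1
        n_k[knew] += 1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sweep = njit(cache=True)(_sweep_py)
except Exception:  # pragma: no cover
    _sweep = _sweep_py


def run_sweeps(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta,
               n_sweeps, rng) -> None:
    """Run ``n_sweeps`` in-place Gibbs sweeps, drawing one uniform per token
    per sweep from ``rng``."""
    n = tokens.shape[0]
    for _ in range(n_sweeps):
        uniforms = rng.random(n)
        _sweep(tokens, doc_of, z, n_dk, n_kw, n_k, alpha, beta, uniforms)
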