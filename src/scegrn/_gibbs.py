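"""Collapsed Gibbs sampling kernel for latent Dirichlet allocation.

Operates on the token list of a binarized cell x region matrix (one token per
accessible (cell, region) entry).  Compiled with numba; the kernel is seeded
and single-threaded, so runs are reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _run_gibbs(cells, regions, n_cells, n_regions, T, alpha, beta,
               n_iterations, seed):
    np.random.seed(seed)
    n_tokens = cells.shape[0]
    z = np.empty(n_tokens, dtype=np.int64)
    n_ct = np.zeros((n_cells, T), dtype=np.int64)
    n_tr = np.zeros((T, n_regions), dtype=np.int64)
    n_t = np.zeros(T, dtype=np.int64)
    len_c = np.zeros(n_cells, dtype=np.int64)
    for i in range(n_tokens):
        t = np.random.randint(0, T)
        z[i] = t
        n_ct[cells[i], t] += 1
        n_tr[t, regions[i]] += 1
        n_t[t] += 1
        len_c[cells[i]] += 1

    probs = np.empty(T, dtype=np.float64)
    ll_trace = np.empty(n_iterations, dtype=np.float64)
    rbeta = n_regions * beta
    for it in range(n_iterations):
        for i in range(n_tokens):
            c = cells[i]
            r = regions[i]
            told = z[i]
            n_ct[c, told] -= 1
            n_tr[told, r] -= 1
            n_t[told] -= 1
            tot = 0.0
            for t in range(T):
                p = (n_ct[c, t] + alpha) * (n_tr[t, r] + beta) / (n_t[t] + rbeta)
                probs[t] = p
                tot += p
            u = np.random.random() * tot
            acc = 0.0
            tnew = T - 1
            for t in range(T):
                acc += probs[t]
                if u < acc:
                    tnew = t
                    break
            z[i] = tnew
            n_ct[c, tnew] += 1
            n_tr[tnew, r] += 1
            n_t[tnew] += 1
        # per-token predictive log-likelihood under current count estimates
        ll = 0.0
        for i in range(n_tokens):
            c = cells[i]
            r = regions[i]
            s = 0.0
            for t in range(T):
                s += ((n_ct[c, t] + alpha) / (len_c[c] + T * alpha)
                      * (n_tr[t, r] + beta) / (n_t[t] + rbeta))
            ll += np.log(s)
        ll_trace[it] = ll
    return z, n_ct, n_tr, n_t, len_c, ll_trace
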