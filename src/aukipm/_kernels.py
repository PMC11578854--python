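"""Compiled inner loops for the fitting engine.

The numpy implementation in :mod:`aukipm.cmr` is the reference route (tested
against the enumeration oracle); this module repeats the same forward
recursion as fused scalar loops for the sampler's inner iteration, where the
likelihood is evaluated tens of thousands of times.  Equivalence between the
two routes is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def cmr_forward_kernel(counts, mark, chick, a1, a2, g1, g2, eps, group,
                       nodes, logW, shift, lgc):  # pragma: no cover - compiled
    """Per-history log-likelihoods, batched over parameter sets.

    counts (n, T) int64; mark (n,) int64; chick (n,) bool;
    a1/a2 (P, T-1); g1/g2 (P, 4); eps (P, 2, T); group (n, T) int64;
    nodes/logW (P, n, Q); shift (P, n) = max_q logW; lgc (n, T) = log c!.
    Returns (P, n) log probabilities *before* the marking-event truncation
    term (applied by the caller, which also knows the eps==0 limit).
    """
    P, n, Q = nodes.shape
    T = counts.shape[1]
    out = np.empty((P, n))
    for p in range(P):
        for i in range(n):
            m = mark[i]
            is_chick = chick[i]
            lik = 0.0
            for q in range(Q):
                h = nodes[p, i, q]
                w = np.exp(logW[p, i, q] - shift[p, i])
                # activation at marking occasion
                e_m = eps[p, group[i, m], m]
                c_m = counts[i, m]
                if e_m > 0.0:
                    lam = e_m * h
                    p2 = np.exp(c_m * np.log(lam) - lam - lgc[i, m])
                else:
                    p2 = 1.0 if c_m == 1 else 0.0
                p0 = 0.0
                p1 = 0.0
                for t in range(m, T - 1):
                    if is_chick and t == m:
                        phi = a1[p, t]
                        gam1 = 0.0
                        gam2 = 0.0
                    else:
                        phi = a2[p, t]
                        age = t - m if is_chick else 4
                        if age > 4:
                            age = 4
                        gam1 = g1[p, age - 1]
                        gam2 = g2[p, age - 1]
                    pa = (p1 * gam1 + p2 * gam2) * phi
                    pu = (p1 * (1.0 - gam1) + p2 * (1.0 - gam2)) * phi
                    pd = p0 + (p1 + p2) * (1.0 - phi)
                    c = counts[i, t + 1]
                    e = eps[p, group[i, t + 1], t + 1]
                    lam = e * h
                    if c == 0:
                        p2 = pa * np.exp(-lam)
                        p1 = pu
                        p0 = pd
                    else:
                        if lam > 0.0:
                            p2 = pa * np.exp(c * np.log(lam) - lam - lgc[i, t + 1])
                        else:
                            p2 = 0.0
                        p1 = 0.0
                        p0 = 0.0
                lik += w * (p0 + p1 + p2)
            out[p, i] = np.log(lik) + shift[p, i] if lik > 0.0 else -np.inf
    return out
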