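"""Compiled inner loop for the conditional Pradel likelihood gradient.

Scalar translation of :func:`paleocmr.likelihood.loglik_natural_grad`,
used on the optimizer's hot path.  Assumes every probability is strictly
inside (0, 1) — guaranteed by the logit clamp on fitted parameters.  The
numpy implementation stays the reference (and handles boundary values);
the test suite checks this kernel against numerical differentiation of
the numpy objective.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def natural_grad_kernel(phi, gamma, p, W, f, l, conditional):  # pragma: no cover
    n, T = W.shape
    dphi = np.zeros((n, T - 1))
    dgamma = np.zeros((n, T - 1))
    dp = np.zeros((n, T))
    total = 0.0
    xi = np.empty(T)
    chi = np.empty(T)
    v = np.empty(T)
    logN = np.empty(T)
    logB = np.empty(T)
    u = np.empty(T)
    for i in range(n):
        fi = f[i]
        li = l[i]
        xi[0] = 1.0
        for t in range(1, T):
            g = gamma[i, t - 1]
            xi[t] = (1.0 - g) + g * (1.0 - p[i, t - 1]) * xi[t - 1]
        chi[T - 1] = 1.0
        for t in range(T - 2, -1, -1):
            chi[t] = (1.0 - phi[i, t]) + phi[i, t] * (1.0 - p[i, t + 1]) * chi[t + 1]

        ll = math.log(xi[fi]) + math.log(p[i, fi]) + math.log(chi[li])
        for t in range(fi, li):
            ll += math.log(phi[i, t])
            dphi[i, t] += 1.0 / phi[i, t]
        dp[i, fi] += 1.0 / p[i, fi]
        for t in range(fi + 1, li + 1):
            if W[i, t] > 0:
                ll += math.log(p[i, t])
                dp[i, t] += 1.0 / p[i, t]
            else:
                ll += math.log(1.0 - p[i, t])
                dp[i, t] -= 1.0 / (1.0 - p[i, t])

        # chi tail backprop from the last detection
        gad = 1.0 / chi[li]
        for t in range(li, T - 1):
            dphi[i, t] += gad * ((1.0 - p[i, t + 1]) * chi[t + 1] - 1.0)
            dp[i, t + 1] -= gad * phi[i, t] * chi[t + 1]
            gad *= phi[i, t] * (1.0 - p[i, t + 1])
        # xi tail backprop from the first detection
        had = 1.0 / xi[fi]
        for t in range(fi, 0, -1):
            dgamma[i, t - 1] += had * ((1.0 - p[i, t - 1]) * xi[t - 1] - 1.0)
            dp[i, t - 1] -= had * gamma[i, t - 1] * xi[t - 1]
            had *= gamma[i, t - 1] * (1.0 - p[i, t - 1])

        if conditional:
            logN[0] = 0.0
            for t in range(1, T):
                logN[t] = (
                    logN[t - 1]
                    + math.log(phi[i, t - 1])
                    - math.log(gamma[i, t - 1])
                )
            v[T - 1] = 1.0 - p[i, T - 1]
            for a in range(T - 2, -1, -1):
                v[a] = (1.0 - p[i, a]) * (
                    (1.0 - phi[i, a]) + phi[i, a] * v[a + 1]
                )
            logB[0] = 0.0
            mmax = 0.0
            for a in range(1, T):
                logB[a] = logN[a] + math.log(1.0 - gamma[i, a - 1])
                if logB[a] > mmax:
                    mmax = logB[a]
            D = 0.0
            for a in range(T):
                u[a] = math.exp(logB[a] - mmax) * (1.0 - v[a])
                D += u[a]
            ll += logN[fi] - (math.log(D) + mmax)
            for a in range(T):
                u[a] /= D

            for s in range(fi):
                dphi[i, s] += 1.0 / phi[i, s]
                dgamma[i, s] -= 1.0 / gamma[i, s]
            Usuf = 0.0
            for s in range(T - 2, -1, -1):
                Usuf += u[s + 1]
                dphi[i, s] -= Usuf / phi[i, s]
                dgamma[i, s] += Usuf / gamma[i, s] + u[s + 1] / (
                    1.0 - gamma[i, s]
                )
            z = 0.0
            for a in range(T):
                r = u[a] / (1.0 - v[a])
                if a == 0:
                    z = r
                else:
                    z = r + z * (1.0 - p[i, a - 1]) * phi[i, a - 1]
                if a < T - 1:
                    dphi[i, a] += z * (1.0 - p[i, a]) * (v[a + 1] - 1.0)
                    dp[i, a] -= z * ((1.0 - phi[i, a]) + phi[i, a] * v[a + 1])
                else:
                    dp[i, a] -= z
        total += ll
    return total, dphi, dgamma, dp
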