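"""Pradel seniority capture-mark-recapture likelihood.

For a genus with detection history omega over occasions 1..T, first
detection f and last detection l, the core history probability is

    Q(h) = xi_f * p_f * prod_{t=f}^{l-1} [ phi_t * p_{t+1}^{w_{t+1}}
             * (1 - p_{t+1})^{1 - w_{t+1}} ] * chi_l

with the two "tail" recursions

    xi_1 = 1,    xi_t = (1 - gamma_t) + gamma_t (1 - p_{t-1}) xi_{t-1}
    chi_T = 1,   chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1}.

xi_f is the probability of never being detected before f given presence
at f (entry weighted by the seniority parameters gamma); chi_l is the
probability of never being detected after l (exit weighted by survival
phi).  :func:`pradel_loglik` returns log Q.

Q alone is a probability *conditional on presence at f*, which differs
per history; maximizing sum(log Q) degenerates (it is monotone
decreasing in every gamma).  The proper Pradel likelihood re-expresses
the unconditional history probability through the relative expected
abundance N_t implied by the seniority parameterization
(N_t = N_{t-1} phi_{t-1} / gamma_t, N_1 = 1) and conditions on the genus
being detected at least once:

    L(h) = N_f * Q(h) / D,
    D    = sum_a B_a (1 - v_a),

where B_a is the expected number of entries at occasion a (B_1 = N_1,
B_a = N_a (1 - gamma_a)) and v_a the probability an entrant at a is
never detected (v_T = 1 - p_T, v_a = (1-p_a)[(1-phi_a) + phi_a v_{a+1}]).
Then sum over all nonzero histories of L(h) = 1, seniority is estimable,
and the >=1-detection ascertainment of real datasets is accounted for.
:func:`pradel_conditional_loglik` returns log L; fitting maximizes it.

All parameters are per genus x occasion, obtained by inverse-logit of
linear predictors (clamped to +/-15 to keep probabilities off the exact
0/1 boundary).  The gradient is computed analytically by reverse-mode
accumulation through all recursions, vectorized over genera.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .formulas import DesignMatrices

__all__ = [
    "LOGIT_CLAMP",
    "first_last",
    "pradel_loglik",
    "pradel_conditional_loglik",
    "natural_params",
    "total_loglik",
    "total_conditional_loglik",
    "total_loglik_grad",
]

LOGIT_CLAMP = 15.0


def first_last(detections: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """0-based first and last detection occasion per history row."""
    W = np.atleast_2d(np.asarray(detections))
    if np.any(W.sum(axis=1) < 1):
        raise ValueError("every capture history needs at least one detection")
    f = W.argmax(axis=1)
    l = W.shape[1] - 1 - W[:, ::-1].argmax(axis=1)
    return f, l


def _as_2d(phi, gamma, p, detections):
    W = np.atleast_2d(np.asarray(detections, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    n, T = W.shape
    if phi.shape != (n, T - 1) or gamma.shape != (n, T - 1) or p.shape != (n, T):
        raise ValueError("parameter arrays do not match history shape")
    return phi, gamma, p, W


def _tails(
    phi: np.ndarray, gamma: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """xi (n, T) and chi (n, T) recursions for all occasions.

    ``phi`` is (n, T-1) with column t the interval t -> t+1; ``gamma`` is
    (n, T-1) with column t-1 the seniority at occasion t; ``p`` is (n, T).
    """
    n, T = p.shape
    xi = np.empty((n, T))
    xi[:, 0] = 1.0
    for t in range(1, T):
        g = gamma[:, t - 1]
        xi[:, t] = (1.0 - g) + g * (1.0 - p[:, t - 1]) * xi[:, t - 1]
    chi = np.empty((n, T))
    chi[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - p[:, t + 1]) * chi[
            :, t + 1
        ]
    return xi, chi


def _core_loglik(phi, gamma, p, W, f, l):
    """log Q per history (masked so boundary 0/1 probabilities stay finite)."""
    n, T = W.shape
    xi, chi = _tails(phi, gamma, p)
    rows = np.arange(n)
    tgrid = np.arange(T)
    ll = np.log(xi[rows, f]) + np.log(p[rows, f]) + np.log(chi[rows, l])
    span_phi = (tgrid[None, : T - 1] >= f[:, None]) & (
        tgrid[None, : T - 1] <= l[:, None] - 1
    )
    span_det = (tgrid[None, :] >= f[:, None] + 1) & (tgrid[None, :] <= l[:, None])
    with np.errstate(divide="ignore"):
        ll += np.where(span_phi, np.log(phi), 0.0).sum(axis=1)
        det_term = np.where(W > 0, np.log(p), np.log1p(-p))
    ll += np.where(span_det, det_term, 0.0).sum(axis=1)
    return ll, xi, chi, span_phi, span_det


def _never_detected(phi, gamma, p):
    """v (n, T): P(never detected | entry at occasion a), per genus."""
    n, T = p.shape
    v = np.empty((n, T))
    v[:, T - 1] = 1.0 - p[:, T - 1]
    for a in range(T - 2, -1, -1):
        v[:, a] = (1.0 - p[:, a]) * (
            (1.0 - phi[:, a]) + phi[:, a] * v[:, a + 1]
        )
    return v


def _entry_terms(phi, gamma, p, f):
    """log N_f and log D per genus, plus intermediates for the gradient.

    logN[:, t] is the cumulative log relative abundance; logB the log
    expected entries per occasion; everything is computed in logs and
    normalized per genus for stability.
    """
    n, T = p.shape
    with np.errstate(divide="ignore"):
        step = np.log(phi) - np.log(gamma)  # (n, T-1)
    logN = np.zeros((n, T))
    logN[:, 1:] = np.cumsum(step, axis=1)
    logB = logN.copy()
    logB[:, 1:] += np.log1p(-gamma)
    v = _never_detected(phi, gamma, p)
    # D = sum_a exp(logB_a) (1 - v_a), log-sum-exp per genus
    m = logB.max(axis=1, keepdims=True)
    Dt = np.exp(logB - m) * (1.0 - v)
    D = Dt.sum(axis=1)
    logD = np.log(D) + m[:, 0]
    rows = np.arange(n)
    return logN[rows, f], logD, v, Dt / D[:, None], logB


def pradel_loglik(
    phi: np.ndarray,
    gamma: np.ndarray,
    p: np.ndarray,
    detections: np.ndarray,
) -> np.ndarray:
    """Per-history log of the core probability Q (conditional on presence
    at the first detection).

    Shapes: ``phi`` (n, T-1), ``gamma`` (n, T-1), ``p`` (n, T),
    ``detections`` (n, T); 1-D arrays are accepted for a single history.
    """
    phi, gamma, p, W = _as_2d(phi, gamma, p, detections)
    f, l = first_last(W)
    ll, *_ = _core_loglik(phi, gamma, p, W, f, l)
    return ll


def pradel_conditional_loglik(
    phi: np.ndarray,
    gamma: np.ndarray,
    p: np.ndarray,
    detections: np.ndarray,
) -> np.ndarray:
    """Per-history log-likelihood conditional on >= 1 detection:
    log N_f + log Q - log D.  These terms sum to a proper probability
    distribution over observable histories and make seniority estimable;
    this is the objective the model fits maximize."""
    phi, gamma, p, W = _as_2d(phi, gamma, p, detections)
    f, l = first_last(W)
    ll, *_ = _core_loglik(phi, gamma, p, W, f, l)
    logNf, logD, *_ = _entry_terms(phi, gamma, p, f)
    return ll + logNf - logD


def natural_params(
    design: DesignMatrices, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map coefficients to (phi, gamma, p) probability arrays via the logit."""
    b_phi, b_gamma, b_p = design.split(np.asarray(beta, dtype=float))
    n = design.n_genera
    phi = expit(np.clip(design.phi.eta(b_phi, n), -LOGIT_CLAMP, LOGIT_CLAMP))
    gamma = expit(np.clip(design.gamma.eta(b_gamma, n), -LOGIT_CLAMP, LOGIT_CLAMP))
    p = expit(np.clip(design.p.eta(b_p, n), -LOGIT_CLAMP, LOGIT_CLAMP))
    return phi, gamma, p


def total_loglik(
    design: DesignMatrices, beta: np.ndarray, detections: np.ndarray
) -> float:
    """Sum of the core per-history terms log Q at coefficient vector beta
    (diagnostic; the fitting objective is the conditional version)."""
    phi, gamma, p = natural_params(design, beta)
    return float(pradel_loglik(phi, gamma, p, detections).sum())


def total_conditional_loglik(
    design: DesignMatrices, beta: np.ndarray, detections: np.ndarray
) -> float:
    """Total conditional log-likelihood (the fitting objective)."""
    phi, gamma, p = natural_params(design, beta)
    return float(pradel_conditional_loglik(phi, gamma, p, detections).sum())


def loglik_natural_grad(
    phi: np.ndarray,
    gamma: np.ndarray,
    p: np.ndarray,
    detections: np.ndarray,
    conditional: bool = True,
):
    """Total log-likelihood and its gradient in the natural parameters.

    Reverse-mode accumulation through the xi/chi tails and, when
    ``conditional``, through the abundance and ascertainment terms.
    Returns ``(total, dphi, dgamma, dp)`` with the d-arrays shaped like
    the parameter arrays.
    """
    phi, gamma, p, W = _as_2d(phi, gamma, p, detections)
    n, T = W.shape
    f, l = first_last(W)
    ll, xi, chi, span_phi, span_det = _core_loglik(phi, gamma, p, W, f, l)
    rows = np.arange(n)

    dphi = np.zeros_like(phi)
    dgamma = np.zeros_like(gamma)
    dp = np.zeros_like(p)

    # in-span terms of log Q (double-where keeps 0/1 boundaries finite)
    dphi += span_phi / phi
    dp[rows, f] += 1.0 / p[rows, f]
    with np.errstate(divide="ignore"):
        dp += np.where(span_det & (W > 0), 1.0 / p, 0.0)
        dp += np.where(span_det & (W == 0), -1.0 / (1.0 - p), 0.0)

    # chi tail: forward sweep from each genus's last detection
    g = np.zeros(n)
    for t in range(T - 1):
        g = np.where(l == t, 1.0 / chi[:, t], g)
        ga = g * (l <= t)
        dphi[:, t] += ga * ((1.0 - p[:, t + 1]) * chi[:, t + 1] - 1.0)
        dp[:, t + 1] += ga * (-phi[:, t] * chi[:, t + 1])
        g = g * phi[:, t] * (1.0 - p[:, t + 1])

    # xi tail: backward sweep from each genus's first detection
    h = np.zeros(n)
    for t in range(T - 1, 0, -1):
        h = np.where(f == t, 1.0 / xi[:, t], h)
        ha = h * (f >= t)
        dgamma[:, t - 1] += ha * ((1.0 - p[:, t - 1]) * xi[:, t - 1] - 1.0)
        dp[:, t - 1] += ha * (-gamma[:, t - 1] * xi[:, t - 1])
        h = h * gamma[:, t - 1] * (1.0 - p[:, t - 1])

    if conditional:
        logNf, logD, v, u, _ = _entry_terms(phi, gamma, p, f)
        ll = ll + logNf - logD
        tgrid = np.arange(T - 1)
        # log N_f = sum_{s<f} (log phi_s - log gamma_s)
        pre_f = tgrid[None, :] < f[:, None]
        dphi += pre_f / phi
        dgamma -= pre_f / gamma
        # -log D, B-part: u_a are the normalized weights B_a(1-v_a)/D.
        # suffix sums U_s = sum_{a>s} u_a
        U = np.flip(np.cumsum(np.flip(u, axis=1), axis=1), axis=1)
        Us = U[:, 1:]  # U_s over s = 0..T-2
        dphi -= Us / phi
        dgamma += Us / gamma
        dgamma += u[:, 1:] / (1.0 - gamma)
        # -log D, v-part via the adjoint z_a = d(-logD)/dv_a
        r = u / (1.0 - v)  # B_a / D (safe: v < 1 whenever p > 0)
        z = np.zeros(n)
        for a in range(T):
            if a == 0:
                z = r[:, 0]
            else:
                z = r[:, a] + z * (1.0 - p[:, a - 1]) * phi[:, a - 1]
            if a < T - 1:
                dphi[:, a] += z * (1.0 - p[:, a]) * (v[:, a + 1] - 1.0)
                # dv_a/dp_a = -[(1-phi_a) + phi_a v_{a+1}]  (= -v_a/(1-p_a))
                dp[:, a] += z * -(
                    (1.0 - phi[:, a]) + phi[:, a] * v[:, a + 1]
                )
            else:
                dp[:, a] += z * (-1.0)

    return float(ll.sum()), dphi, dgamma, dp


def total_loglik_grad(
    design: DesignMatrices,
    beta: np.ndarray,
    detections: np.ndarray,
    conditional: bool = True,
) -> tuple[float, np.ndarray]:
    """Fitting objective and its analytic gradient in beta.

    Chains the natural-parameter gradient (compiled kernel; clamped
    parameters are strictly inside (0,1)) through the inverse logit and
    projects onto the design columns.
    """
    from ._kernels import natural_grad_kernel

    W = np.ascontiguousarray(np.asarray(detections, dtype=np.float64))
    phi, gamma, p = natural_params(design, beta)
    f, l = first_last(W)
    total, dphi, dgamma, dp = natural_grad_kernel(
        np.ascontiguousarray(phi),
        np.ascontiguousarray(gamma),
        np.ascontiguousarray(p),
        W,
        f.astype(np.int64),
        l.astype(np.int64),
        conditional,
    )
    grad = np.concatenate(
        [
            design.phi.project(dphi * phi * (1.0 - phi)),
            design.gamma.project(dgamma * gamma * (1.0 - gamma)),
            design.p.project(dp * p * (1.0 - p)),
        ]
    )
    return total, grad
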