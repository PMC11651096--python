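"""Vectorized univariate Cox proportional-hazards fits.

Screening thousands of latent features means thousands of single-covariate
Cox fits; this module runs them all simultaneously.  For each feature a
scalar coefficient is estimated by Newton iteration on the partial
log-likelihood with Efron's tie correction, and a Wald p-value is derived
from the observed information.  Features with (numerically) zero variance
and fits that fail to converge are flagged instead of raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ITER = 50
TOL = 1e-9
# Cap on |beta| on the standardized-covariate scale.  A covariate that
# perfectly orders the deaths has no finite MLE (monotone partial
# likelihood); iterating further only collapses the observed information
# (and with it the Wald statistic) toward zero.  Stopping at a moderate
# boundary reports a large, finite Wald z there — the same behavior
# lifelines exhibits when it halts with a convergence warning.
MAX_ABS_BETA = 12.0
ETA_CLIP = 60.0


@dataclass
class UnivariateCoxResult:
    coef: np.ndarray          # beta per feature (on the original scale)
    se: np.ndarray            # Wald standard error
    p_value: np.ndarray       # two-sided Wald p
    converged: np.ndarray     # bool per feature
    at_boundary: np.ndarray   # hit the |beta| cap (monotone likelihood)
    zero_variance: np.ndarray  # bool per feature


def _event_groups(time: np.ndarray, event: np.ndarray):
    """Precompute risk-set boundaries and tie groups on time-sorted data.

    Returns (order, groups) where each group is (risk_start, event_indices)
    for one distinct event time, positions referring to the sorted arrays.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(bool)
    groups = []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.arange(i, j)[e[i:j]]
        if ev.size:
            groups.append((i, ev))
        i = j
    return order, groups


def _loglik_grad_hess(X: np.ndarray, beta: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial log-likelihood, gradient and information per feature (Efron).

    ``X`` is time-sorted (n, p); ``beta`` is (p,).  All outputs are (p,).
    """
    eta = X * beta  # (n, p) elementwise column scaling
    eta = np.clip(eta, -ETA_CLIP, ETA_CLIP)
    w = np.exp(eta)
    xw = X * w
    x2w = X * xw
    # reverse cumulative sums: S*[i] = sum over samples with position >= i
    S0 = np.cumsum(w[::-1], axis=0)[::-1]
    S1 = np.cumsum(xw[::-1], axis=0)[::-1]
    S2 = np.cumsum(x2w[::-1], axis=0)[::-1]

    ll = np.zeros(beta.shape)
    grad = np.zeros(beta.shape)
    info = np.zeros(beta.shape)
    for start, ev in groups:
        d = ev.size
        tw0 = w[ev].sum(axis=0)
        tw1 = xw[ev].sum(axis=0)
        tw2 = x2w[ev].sum(axis=0)
        ll += eta[ev].sum(axis=0)
        grad += X[ev].sum(axis=0)
        for l in range(d):
            f = l / d
            d0 = S0[start] - f * tw0
            d1 = S1[start] - f * tw1
            d2 = S2[start] - f * tw2
            ll -= np.log(d0)
            r1 = d1 / d0
            grad -= r1
            info += d2 / d0 - r1**2
    return ll, grad, info


def univariate_cox(
    features: np.ndarray, time: np.ndarray, event: np.ndarray
) -> UnivariateCoxResult:
    """Fit one Cox model per feature column, all vectorized.

    Features are internally standardized for numerical stability; reported
    coefficients are rescaled back to the input scale.  Monotone-likelihood
    columns (a covariate that perfectly orders the deaths has no finite MLE)
    hit the iteration/step caps and are flagged as non-converged.
    """
    X = np.asarray(features, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    if event.sum() == 0:
        raise ValueError("no events observed; Cox screening impossible")

    sd = X.std(axis=0)
    zero_var = sd < 1e-12
    safe_sd = np.where(zero_var, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / safe_sd

    order, groups = _event_groups(time, event)
    Xo = Xs[order]

    beta = np.zeros(p)
    ll, grad, info = _loglik_grad_hess(Xo, beta, groups)
    active = ~zero_var
    converged = np.zeros(p, dtype=bool)
    for _ in range(MAX_ITER):
        step = np.zeros(p)
        ok = active & (info > 1e-12)
        step[ok] = grad[ok] / info[ok]
        step = np.clip(step, -2.0, 2.0)
        if not ok.any():
            break
        new_beta = beta + np.where(active, step, 0.0)
        new_beta = np.clip(new_beta, -MAX_ABS_BETA, MAX_ABS_BETA)
        new_ll, new_grad, new_info = _loglik_grad_hess(Xo, new_beta, groups)
        # step-halving where the likelihood worsened
        worse = active & (new_ll < ll - 1e-12)
        halvings = 0
        while worse.any() and halvings < 10:
            new_beta[worse] = (beta[worse] + new_beta[worse]) / 2.0
            new_ll, new_grad, new_info = _loglik_grad_hess(Xo, new_beta, groups)
            worse = active & (new_ll < ll - 1e-12)
            halvings += 1
        moved = np.abs(new_beta - beta)
        newly = active & (moved < TOL) & np.isfinite(new_ll)
        converged |= newly
        active &= ~newly
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if not active.any():
            break

    finite = np.isfinite(beta) & np.isfinite(info) & (info > 1e-12)
    se_std = np.full(p, np.nan)
    se_std[finite] = 1.0 / np.sqrt(info[finite])
    z = np.full(p, np.nan)
    z[finite] = beta[finite] / se_std[finite]
    pval = np.full(p, np.nan)
    pval[finite] = 2.0 * stats.norm.sf(np.abs(z[finite]))

    converged &= finite
    converged[zero_var] = False
    at_boundary = (~zero_var) & (np.abs(beta) >= MAX_ABS_BETA - 1e-9)
    converged[at_boundary] = False
    # report on original scale
    coef = np.where(zero_var, np.nan, beta / safe_sd)
    se = np.where(zero_var, np.nan, se_std / safe_sd)
    pval[zero_var] = np.nan
    return UnivariateCoxResult(
        coef=coef,
        se=se,
        p_value=pval,
        converged=converged,
        at_boundary=at_boundary,
        zero_variance=zero_var,
    )
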