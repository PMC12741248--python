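"""Breslow partial-likelihood machinery shared across modules.

Supports case weights and delayed entry (counting-process intervals
``(entry, time]``), which covers unpenalized evaluation fits, landmark
analyses and the IPCW-expanded data of the Fine-Gray model. All risk-set
sums are suffix sums over sorted arrays, so a likelihood/gradient/
Hessian evaluation is O(n log n + n p^2).
"""

from __future__ import annotations

import numpy as np

__all__ = ["breslow_loglik", "breslow_derivatives", "newton_cox"]


def _risk_sums(values, time, entry, death_times):
    """sum of ``values`` over the risk set {i : entry_i < t <= time_i}.

    ``values`` may be (n,) or (n, k); returns per death time.
    """
    values = np.atleast_2d(values.T).T  # (n, k)
    order_t = np.argsort(time, kind="stable")
    suffix_t = np.cumsum(values[order_t][::-1], axis=0)[::-1]
    # index of first subject with time >= t
    pos_t = np.searchsorted(time[order_t], death_times, side="left")
    total_t = np.vstack([suffix_t, np.zeros((1, values.shape[1]))])
    in_time = total_t[pos_t]
    if entry is None:
        return in_time
    order_e = np.argsort(entry, kind="stable")
    suffix_e = np.cumsum(values[order_e][::-1], axis=0)[::-1]
    pos_e = np.searchsorted(entry[order_e], death_times, side="left")
    total_e = np.vstack([suffix_e, np.zeros((1, values.shape[1]))])
    out_entry = total_e[pos_e]  # subjects with entry >= t are not yet at risk
    return in_time - out_entry


def _prepare(time, event, weights, entry):
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    n = time.size
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    e = None if entry is None else np.asarray(entry, float)
    if e is not None and np.any(e >= time):
        raise ValueError("entry times must precede exit times")
    death_times, death_index = np.unique(time[event], return_inverse=True)
    return time, event, w, e, death_times, death_index


def breslow_loglik(eta, time, event, weights=None, entry=None):
    """Breslow log partial likelihood at linear predictor ``eta``."""
    time, event, w, e, death_times, death_index = _prepare(time, event, weights, entry)
    if death_times.size == 0:
        return 0.0
    shift = float(np.max(eta))
    r = w * np.exp(np.asarray(eta, float) - shift)
    S0 = _risk_sums(r, time, e, death_times)[:, 0]
    # weighted number of deaths at each death time
    dw = np.bincount(death_index, weights=w[event], minlength=death_times.size)
    d_eta = np.bincount(death_index, weights=(w * eta)[event],
                        minlength=death_times.size)
    return float(np.sum(d_eta - dw * (np.log(S0) + shift)))


def breslow_derivatives(beta, X, time, event, weights=None, entry=None):
    """(loglik, gradient, negative Hessian) of the Breslow partial likelihood."""
    X = np.asarray(X, float)
    time, event, w, e, death_times, death_index = _prepare(time, event, weights, entry)
    eta = X @ beta
    shift = float(np.max(eta))
    r = w * np.exp(eta - shift)
    n, p = X.shape
    S0 = _risk_sums(r, time, e, death_times)[:, 0]
    S1 = _risk_sums(r[:, None] * X, time, e, death_times)  # (D, p)
    outer = X[:, :, None] * X[:, None, :]  # (n, p, p)
    S2 = _risk_sums(r[:, None] * outer.reshape(n, p * p), time, e,
                    death_times).reshape(-1, p, p)
    dw = np.bincount(death_index, weights=w[event], minlength=death_times.size)
    d_eta = np.bincount(death_index, weights=(w * eta)[event],
                        minlength=death_times.size)
    ll = float(np.sum(d_eta - dw * (np.log(S0) + shift)))
    xbar = S1 / S0[:, None]
    grad = (w[event][:, None] * X[event]).sum(axis=0) - (dw[:, None] * xbar).sum(axis=0)
    info = np.einsum("d,dij->ij", dw, S2 / S0[:, None, None]) - np.einsum(
        "d,di,dj->ij", dw, xbar, xbar
    )
    return ll, grad, info


def newton_cox(X, time, event, weights=None, entry=None, tol=1e-10,
               max_iter=100):
    """Unpenalized Cox fit (Breslow ties) by Newton-Raphson with step halving.

    Returns ``(beta, cov)`` where ``cov`` is the inverse observed
    information (model-based covariance of ``beta``).
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if not np.asarray(event).astype(bool).any():
        raise ValueError("no events observed")
    beta = np.zeros(p)
    ll, grad, info = breslow_derivatives(beta, X, time, event, weights, entry)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            new_ll = breslow_loglik(X @ candidate, time, event, weights, entry)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = candidate
        new_ll, grad, info = breslow_derivatives(beta, X, time, event, weights,
                                                 entry)
        if abs(new_ll - ll) < tol * (abs(ll) + 1.0):
            ll = new_ll
            break
        ll = new_ll
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise RuntimeError(
            "singular information matrix: separation or collinear covariates"
        )
    return beta, cov
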