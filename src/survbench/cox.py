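"""Fast single-covariate Cox proportional-hazards scoring.

Marginal-association screening and subsampled selection repeatedly fit a
one-covariate Cox model to thousands of features, so the partial-likelihood
Newton iteration is implemented here vectorized across features (Breslow tie
handling).  Each feature is standardized internally; coefficients are
reported on the original scale.  ``lifelines`` is used as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CoxScore", "univariate_cox_score", "batch_univariate_cox"]

_MAX_BETA = 20.0  # cap on the standardized coefficient (monotone likelihood guard)


@dataclass(frozen=True)
class CoxScore:
    coefficient: float
    hazard_ratio: float
    p_value: float
    converged: bool


def _prepare(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")  # descending time
    time_s, event_s = time[order], event[order]
    # index of the last member of each tied-time group (risk set boundary)
    n = len(time_s)
    group_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time_s[j + 1] == time_s[i]:
            j += 1
        group_end[i : j + 1] = j
        i = j + 1
    return order, event_s, group_end


def _newton(x_std: np.ndarray, event_s: np.ndarray, group_end: np.ndarray,
            max_iter: int = 40, tol: float = 1e-9):
    """Vectorized Newton on the Breslow partial log-likelihood.

    x_std: (n, p) standardized covariates already in descending-time order.
    Returns (beta_std, info, converged), each of shape (p,).
    """
    n, p = x_std.shape
    ev = event_s.astype(bool)
    beta = np.zeros(p)
    converged = np.zeros(p, dtype=bool)
    info = np.full(p, np.nan)
    for _ in range(max_iter):
        eta = np.clip(x_std * beta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w, axis=0)[group_end]
        s1 = np.cumsum(w * x_std, axis=0)[group_end]
        s2 = np.cumsum(w * x_std * x_std, axis=0)[group_end]
        mu = s1 / s0
        score = np.sum(x_std[ev] - mu[ev], axis=0)
        info = np.sum(s2[ev] / s0[ev] - mu[ev] ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        beta = np.clip(beta + step, -_MAX_BETA, _MAX_BETA)
        converged = np.abs(step) < tol
        if converged.all():
            break
    at_bound = np.abs(beta) >= _MAX_BETA
    return beta, info, converged & ~at_bound


def batch_univariate_cox(X, time, event):
    """Fit a single-covariate Cox model per column of ``X``.

    Parameters
    ----------
    X : array (n_samples, n_features)
    time, event : censored outcome arrays

    Returns
    -------
    dict of arrays ``coefficient``, ``hazard_ratio``, ``p_value``, ``converged``.
    Constant (zero-variance) columns and failed fits get ``p_value = 1`` and
    NaN coefficients so screening callers can treat them as uninformative.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if int(np.sum(event)) < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    order, event_s, group_end = _prepare(time, event)
    sd = X.std(axis=0, ddof=0)
    ok = np.isfinite(sd) & (sd > 0) & np.all(np.isfinite(X), axis=0)
    p = X.shape[1]
    coef = np.full(p, np.nan)
    pval = np.ones(p)
    conv = np.zeros(p, dtype=bool)
    if ok.any():
        mean = X[:, ok].mean(axis=0)
        x_std = (X[order][:, ok] - mean) / sd[ok]
        beta_std, info, converged = _newton(x_std, event_s, group_end)
        with np.errstate(invalid="ignore"):
            z = beta_std * np.sqrt(np.maximum(info, 0.0))
        pv = 2 * stats.norm.sf(np.abs(z))
        pv = np.where(np.isfinite(pv), pv, 1.0)
        coef[ok] = beta_std / sd[ok]
        pval[ok] = np.clip(pv, np.finfo(float).tiny, 1.0)
        conv[ok] = converged
    return {
        "coefficient": coef,
        "hazard_ratio": np.exp(coef),
        "p_value": pval,
        "converged": conv,
    }


def univariate_cox_score(feature, outcome) -> CoxScore:
    """Single-covariate Cox fit: (coefficient, hazard ratio, Wald p-value).

    Raises on a constant feature; a non-converged fit is returned with
    ``converged=False`` and NaN coefficient rather than failing silently.
    """
    x = np.asarray(feature, dtype=float)
    if hasattr(outcome, "time"):
        time, event = np.asarray(outcome.time, float), np.asarray(outcome.event, int)
    else:
        time, event = (np.asarray(a) for a in outcome)
    if x.std(ddof=0) == 0 or not np.all(np.isfinite(x)):
        raise ValueError("feature is constant or non-finite; univariate Cox undefined")
    res = batch_univariate_cox(x[:, None], time, event)
    conv = bool(res["converged"][0])
    if not conv:
        return CoxScore(np.nan, np.nan, np.nan, False)
    return CoxScore(
        coefficient=float(res["coefficient"][0]),
        hazard_ratio=float(res["hazard_ratio"][0]),
        p_value=float(res["p_value"][0]),
        converged=True,
    )
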