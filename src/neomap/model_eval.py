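"""Posterior-predictive model comparison: DIC, WAIC and LPML.

All three criteria are computed from an S x n matrix of pointwise
log-likelihood values over retained posterior draws:

* DIC = Dbar + pD with Dbar the posterior mean deviance and
  pD = Dbar - D(plug-in); the plug-in deviance is evaluated at the
  posterior mean of the latent linear predictor.
* WAIC = -2 (lppd - pWAIC); lppd sums log posterior-mean likelihoods
  (log-sum-exp over draws), pWAIC sums the per-point variances of the
  log-likelihood.
* LPML = sum_i log CPO_i with the conditional predictive ordinate
  estimated by the harmonic mean of the likelihood over draws; larger
  LPML is better and is the primary ranking criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["EvalMetrics", "dic", "waic", "lpml", "compare", "evaluate_fit"]


@dataclass
class EvalMetrics:
    DIC: float
    pD: float
    WAIC: float
    pWAIC: float
    LPML: float
    n_points: int


def _check_matrix(ll: np.ndarray) -> np.ndarray:
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need an (S, n) matrix with S >= 2 draws")
    bad = ~np.isfinite(ll).all(axis=1)
    if bad.any():
        raise ValueError(f"non-finite log-likelihood in draw(s) {np.flatnonzero(bad).tolist()}")
    return ll


def dic(pointwise_loglik: np.ndarray, loglik_at_posterior_mean: float) -> tuple[float, float]:
    """Deviance information criterion and its effective parameter count pD."""
    ll = _check_matrix(pointwise_loglik)
    dbar = float((-2.0 * ll.sum(axis=1)).mean())
    d_hat = -2.0 * float(loglik_at_posterior_mean)
    pd_ = dbar - d_hat
    return dbar + pd_, pd_


def waic(pointwise_loglik: np.ndarray) -> tuple[float, float]:
    """Widely-applicable information criterion and its penalty pWAIC."""
    ll = _check_matrix(pointwise_loglik)
    S = ll.shape[0]
    lppd = float((logsumexp(ll, axis=0) - np.log(S)).sum())
    p_waic = float(ll.var(axis=0, ddof=1).sum())
    return -2.0 * (lppd - p_waic), p_waic


def lpml(pointwise_loglik: np.ndarray) -> tuple[float, np.ndarray]:
    """Log pseudo marginal likelihood and per-point CPO values.

    CPO_i is the harmonic mean of the likelihood over draws, computed via
    log-sum-exp of the negated log-likelihood.  Points whose CPO estimate
    is numerically zero, or whose harmonic-mean weights are dominated by a
    single draw (max weight share > 0.5), are excluded with a warning.
    """
    ll = _check_matrix(pointwise_loglik)
    S = ll.shape[0]
    neg = -ll
    log_cpo = -(logsumexp(neg, axis=0) - np.log(S))
    max_share = np.exp(neg.max(axis=0) - logsumexp(neg, axis=0))
    unstable = max_share > 0.5
    degenerate = ~np.isfinite(log_cpo)
    drop = degenerate
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} CPO value(s) numerically zero; excluded from LPML"
        )
    if unstable.any():
        warnings.warn(
            f"harmonic-mean CPO unstable at {int(unstable.sum())} point(s) "
            "(one draw carries > 50% of the weight)"
        )
    cpo = np.where(drop, np.nan, np.exp(log_cpo))
    return float(log_cpo[~drop].sum()), cpo


def evaluate_fit(fit) -> EvalMetrics:
    """All three criteria from a fitted model's stored pointwise log-likelihood."""
    ll = fit.samples.loglik
    dic_val, pd_ = dic(ll, fit.loglik_at_mean)
    waic_val, p_waic = waic(ll)
    lpml_val, _ = lpml(ll)
    return EvalMetrics(
        DIC=dic_val,
        pD=pd_,
        WAIC=waic_val,
        pWAIC=p_waic,
        LPML=lpml_val,
        n_points=ll.shape[1],
    )


def compare(models: list[tuple[str, EvalMetrics]]) -> pd.DataFrame:
    """Rank candidate models: largest LPML first, ties broken by smaller DIC.

    DIC and WAIC are reported alongside (smaller is better).  Models must
    have been evaluated on the same number of data points.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    n_points = {m.n_points for _, m in models}
    if len(n_points) != 1:
        raise ValueError(f"models evaluated on different data sizes: {sorted(n_points)}")
    table = pd.DataFrame(
        [
            {
                "model": name,
                "DIC": m.DIC,
                "pD": m.pD,
                "WAIC": m.WAIC,
                "pWAIC": m.pWAIC,
                "LPML": m.LPML,
            }
            for name, m in models
        ]
    )
    table = table.sort_values(["LPML", "DIC"], ascending=[False, True], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)
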