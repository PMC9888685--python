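"""Kaplan-Meier (Stute) weights, weighted least-squares node models, and
censored-residual imputation.

Under random right censoring, least squares on the observed log times is
inconsistent because censored observations are biased low. Stute's estimator
repairs this by weighting each ordered observation with the jump of the
Kaplan-Meier estimator of the event-time distribution at that point: censored
observations get weight zero and the mass they would have carried is pushed
onto later event times. Every tree node fits its local model

    y = theta0 + theta1 * x [+ theta2 * x * w] + e

by minimising the Stute-weighted residual sum of squares over its own
members, with weights recomputed from the node's own (y, delta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StuteWeights",
    "NodeModel",
    "ResidualSet",
    "FitError",
    "stute_weights",
    "fit_node_model",
    "impute_residuals",
]


class FitError(RuntimeError):
    """Node model cannot be fitted (degenerate design)."""


@dataclass
class StuteWeights:
    """Kaplan-Meier jump weights for one node sample.

    ``order`` sorts y ascending (events before censorings at ties);
    ``d`` is aligned to the *original* record order and sums to at most 1,
    with equality exactly when the largest ordered observation is an event.
    """

    order: np.ndarray
    d: np.ndarray

    @property
    def d_sorted(self):
        return self.d[self.order]


def _sort_order(y, delta):
    # ascending y; events first at equal y (standard KM convention)
    return np.lexsort((-np.asarray(delta), np.asarray(y)))


def _stute_d_sorted(delta_sorted: np.ndarray) -> np.ndarray:
    """Jump weights in sorted order: d_1 = delta_(1)/n and
    d_i = delta_(i)/(n-i+1) * prod_{j<i} ((n-j)/(n-j+1))^delta_(j)."""
    delta_sorted = np.asarray(delta_sorted, float)
    n = delta_sorted.size
    i = np.arange(1, n + 1, dtype=float)
    base = (n - i) / (n - i + 1.0)
    factors = np.where(delta_sorted > 0, base, 1.0)
    prod = np.empty(n)
    prod[0] = 1.0
    if n > 1:
        np.cumprod(factors[:-1], out=prod[1:])
    return delta_sorted / (n - i + 1.0) * prod


def stute_weights(y, delta) -> StuteWeights:
    """Kaplan-Meier weights for a node sample, aligned to the input order."""
    y = np.asarray(y, float)
    delta = np.asarray(delta)
    if y.size == 0:
        raise ValueError("stute_weights: empty sample")
    if y.shape != delta.shape:
        raise ValueError("stute_weights: y and delta lengths differ")
    order = _sort_order(y, delta)
    d_sorted = _stute_d_sorted(delta[order])
    d = np.empty_like(d_sorted)
    d[order] = d_sorted
    return StuteWeights(order=order, d=d)


@dataclass
class NodeModel:
    """Stute-weighted least-squares fit within one node.

    ``theta2`` is None for a PRISM fit; ``theta2_dropped`` records the case
    where the x*w column was degenerate (w constant among weighted focus
    records) and the interaction was removed — downstream disparity
    calculations then treat theta2 as 0.
    """

    theta0: float
    theta1: float
    theta2: float | None
    rss: float
    n: int
    n_events: int
    mean_log_surv: float
    theta2_dropped: bool = False

    def predict(self, x, w=None):
        x = np.asarray(x, float)
        yhat = self.theta0 + self.theta1 * x
        if self.theta2 is not None and w is not None:
            yhat = yhat + self.theta2 * x * np.asarray(w, float)
        return yhat


def _wls_core(y, d, x, w):
    """Stute-weighted normal equations for the (1, x[, x*w]) design, via
    explicit weighted sums (x is 0/1 so x*x = x and x*(x*w) = x*w).

    Returns (theta0, theta1, theta2 | None, dropped, residuals, weighted rss).
    Raises FitError for an all-zero weight vector or a constant focus column
    among the positively weighted rows; a degenerate x*w column (w constant
    among weighted focus rows) falls back to the two-parameter design.
    """
    s0 = d.sum()
    if s0 <= 0:
        raise FitError("all weights zero (no events in node)")
    dx = d * x
    su = dx.sum()
    if su <= 0 or s0 - su <= 0:
        raise FitError("degenerate focus column: single focus group among events")
    b0 = d @ y
    bu = dx @ y
    theta2 = None
    dropped = False
    if w is not None:
        dv = dx * w
        sv = dv.sum()
        svv = dv @ w
        bv = dv @ y
        # weighted variance of w among focus rows: zero => x*w collinear with x
        varw = svv - sv * sv / su
        if varw <= 1e-12 * max(1.0, abs(svv)):
            dropped = True
        else:
            A = np.array([[s0, su, sv], [su, su, sv], [sv, sv, svv]])
            t0, t1, t2 = np.linalg.solve(A, np.array([b0, bu, bv]))
            theta2 = float(t2)
            resid = y - (t0 + t1 * x + t2 * x * w)
    if theta2 is None:
        t0 = (b0 - bu) / (s0 - su)
        t1 = bu / su - t0
        resid = y - (t0 + t1 * x)
    return (float(t0), float(t1), theta2, dropped, resid,
            float(d @ (resid * resid)))


def fit_node_model(y, delta, x, weights: StuteWeights, w=None) -> NodeModel:
    """Fit the node regression by Stute-weighted least squares.

    HPRISM mode is selected by passing the contextual values ``w``; the design
    is then (1, x, x*w). Raises :class:`FitError` when the focus column is
    constant on positively-weighted rows. A degenerate x*w column silently
    falls back to the PRISM design with ``theta2_dropped`` set.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    d = weights.d
    w = None if w is None else np.asarray(w, float)
    t0, t1, t2, dropped, _, rss = _wls_core(y, d, x, w)
    return NodeModel(
        theta0=t0,
        theta1=t1,
        theta2=t2,
        rss=rss,
        n=int(y.size),
        n_events=int(np.asarray(delta).sum()),
        mean_log_surv=float(d @ y / d.sum()),
        theta2_dropped=dropped,
    )


@dataclass
class ResidualSet:
    r: np.ndarray
    r_hat: np.ndarray
    delta: np.ndarray


def _impute(r, delta):
    """r_hat_i = r_i for events; for censored i the mean of uncensored
    residuals strictly greater than r_i, falling back to r_i when none are."""
    r = np.asarray(r, float)
    ev = np.asarray(delta) > 0
    r_hat = r.copy()
    r_ev = np.sort(r[ev])
    if r_ev.size:
        # suffix means of the sorted uncensored residuals
        suffix = np.cumsum(r_ev[::-1])[::-1] / np.arange(r_ev.size, 0, -1)
        cens = ~ev
        pos = np.searchsorted(r_ev, r[cens], side="right")
        vals = r[cens].copy()
        inside = pos < r_ev.size
        vals[inside] = suffix[pos[inside]]
        r_hat[cens] = vals
    return r_hat


def impute_residuals(model: NodeModel, y, delta, x, w=None) -> ResidualSet:
    """Censored-residual imputation: replace a censored residual by the mean
    of the uncensored residuals exceeding it (an estimate of E(e | e > r))."""
    r = np.asarray(y, float) - model.predict(x, w)
    return ResidualSet(r=r, r_hat=_impute(r, np.asarray(delta)), delta=np.asarray(delta))
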