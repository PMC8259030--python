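"""Locally weighted polynomial regression (loess) with pointwise bands.

Degree-2 local fits with tricube weights over the `span` fraction of
nearest neighbours.  Pointwise standard errors come from the linear-
smoother form of the fit: yhat(x0) = l(x0)' y, so Var yhat = sigma^2 ||l||^2
with sigma^2 estimated from the residuals at the observed points.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["LoessSmoother"]


def _local_weights(x, x0, span):
    n = len(x)
    q = max(int(np.ceil(span * n)), 3)
    d = np.abs(x - x0)
    dq = np.sort(d)[min(q, n) - 1]
    if dq == 0:
        dq = np.finfo(float).eps
    u = np.clip(d / dq, 0.0, 1.0)
    return (1.0 - u ** 3) ** 3


class LoessSmoother(BaseEstimator, RegressorMixin):
    """Loess fit of y on a single covariate.

    Parameters
    ----------
    span : fraction of points entering each local fit, in (0, 1].
    degree : local polynomial degree (2 = local quadratic).
    """

    def __init__(self, span: float = 0.75, degree: int = 2):
        self.span = span
        self.degree = degree

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if not (0 < self.span <= 1):
            raise ValueError("span must lie in (0, 1]")
        if len(x) != len(y) or len(x) < self.degree + 1:
            raise ValueError("need at least degree+1 points")
        self.x_, self.y_ = x, y
        # residual variance from the fit at the observed points
        yhat, l2, trL = self._predict_raw(x, need_trace=True)
        dof = max(len(x) - trL, 1.0)
        self.sigma2_ = float(np.sum((y - yhat) ** 2) / dof)
        return self

    def _predict_raw(self, x_new, need_trace=False):
        x, y = self.x_, self.y_
        deg = self.degree
        yhat = np.empty(len(x_new))
        l2 = np.empty(len(x_new))
        trL = 0.0
        obs_pos = {v: i for i, v in enumerate(x)} if need_trace else {}
        for i, x0 in enumerate(np.asarray(x_new, dtype=float)):
            w = _local_weights(x, x0, self.span)
            mask = w > 0
            A = np.vander(x[mask] - x0, deg + 1, increasing=True)
            W = w[mask]
            AtW = A.T * W
            beta_mat = np.linalg.pinv(AtW @ A) @ AtW  # (deg+1) x m
            lvec = np.zeros(len(x))
            lvec[mask] = beta_mat[0]
            yhat[i] = lvec @ y
            l2[i] = float(lvec @ lvec)
            if need_trace and x0 in obs_pos:
                trL += lvec[obs_pos[x0]]
        return (yhat, l2, trL) if need_trace else (yhat, l2)

    def predict(self, X, return_se: bool = False):
        check_is_fitted(self, "x_")
        x_new = np.asarray(X, dtype=float).reshape(-1)
        yhat, l2 = self._predict_raw(x_new)
        if return_se:
            return yhat, np.sqrt(self.sigma2_ * l2)
        return yhat
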