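"""L1-penalized sparse inverse covariance (graphical lasso) solver.

Minimizes, over symmetric positive-definite Theta,

    -log det Theta + tr(S Theta) + lambda * sum_{i != j} |Theta_ij|

(the diagonal is not penalized).  The solver is proximal gradient (ISTA)
with backtracking line search; each step soft-thresholds the off-diagonal
after a gradient step on the smooth part (gradient S - Theta^{-1}), and
backtracking rejects any step that leaves the positive-definite cone.
Warm starts make penalty-path sweeps cheap.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glasso_fit", "glasso_objective", "glasso_path", "EDGE_EPS"]

EDGE_EPS = 1e-8  # |Theta_ij| above this counts as an edge


def glasso_objective(Theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized negative log-likelihood (to be minimized)."""
    if not np.all(np.isfinite(Theta)):
        return np.inf
    if not _is_pd((Theta + Theta.T) / 2):  # -logdet is defined on the PD cone only
        return np.inf
    _, logdet = np.linalg.slogdet(Theta)
    off = np.abs(Theta).sum() - np.abs(np.diag(Theta)).sum()
    val = -logdet + np.sum(S * Theta) + lam * off
    return float(val) if np.isfinite(val) else np.inf


def _soft_threshold_offdiag(M: np.ndarray, t: float) -> np.ndarray:
    out = np.sign(M) * np.maximum(np.abs(M) - t, 0.0)
    np.fill_diagonal(out, np.diag(M))
    return out


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def glasso_fit(S: np.ndarray, lam: float, tol: float = 1e-6,
               max_iter: int = 5000, Theta0: np.ndarray | None = None):
    """Fit the graphical lasso at one penalty.

    Parameters
    ----------
    S : symmetric positive semi-definite sample covariance.
    lam : penalty >= 0 on the off-diagonal of the precision matrix.
    Theta0 : optional warm-start precision (must be PD).

    Returns
    -------
    (Theta, adjacency): the precision matrix estimate and the boolean
    off-diagonal support (|Theta_ij| > 1e-8).

    Raises
    ------
    RuntimeError if the maximum parameter change has not fallen below
    `tol` within `max_iter` iterations.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or np.max(np.abs(S - S.T)) > 1e-8:
        raise ValueError("S must be a symmetric square matrix")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = S.shape[0]

    if Theta0 is not None and _is_pd(Theta0):
        Theta = Theta0.copy()
    else:
        Theta = np.diag(1.0 / (np.diag(S) + lam + 1e-12))

    def _pen(M):
        return lam * (np.abs(M).sum() - np.abs(np.diag(M)).sum())

    def _smooth(M):
        sign, logdet = np.linalg.slogdet(M)
        return np.inf if sign <= 0 else float(-logdet + np.sum(S * M))

    step = 1.0 / max(np.linalg.norm(S, 2), 1.0)
    f = glasso_objective(Theta, S, lam)
    Y = Theta.copy()  # FISTA extrapolation point
    t_mom = 1.0
    delta = np.inf
    for it in range(1, max_iter + 1):
        if not _is_pd(Y):
            Y, t_mom = Theta.copy(), 1.0
        grad = S - np.linalg.inv(Y)
        smooth_y = _smooth(Y)
        # backtracking proximal step from Y
        for _ in range(60):
            cand = _soft_threshold_offdiag(Y - step * grad, lam * step)
            cand = (cand + cand.T) / 2
            if not _is_pd(cand):
                step *= 0.5
                continue
            diff = cand - Y
            quad = smooth_y + np.sum(grad * diff) + np.sum(diff * diff) / (2 * step)
            smooth_cand = _smooth(cand)
            if smooth_cand <= quad + 1e-12 * max(1.0, abs(quad)):
                break
            step *= 0.5
        else:
            raise RuntimeError(f"glasso line search failed at iteration {it}")
        f_cand = smooth_cand + _pen(cand)
        extrapolated = t_mom > 1.0
        if extrapolated and f_cand > f + 1e-10 * max(1.0, abs(f)):
            # momentum overshot: restart and take a plain step next
            Y, t_mom = Theta.copy(), 1.0
            continue
        delta = np.max(np.abs(cand - Theta))
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        Y = cand + ((t_mom - 1.0) / t_next) * (cand - Theta)
        t_mom = t_next
        Theta, f = cand, f_cand
        # relative convergence: parameter change measured against the
        # largest precision entry (absolute 'tol' for well-scaled problems)
        if delta < tol * max(1.0, np.max(np.abs(Theta))):
            adjacency = (np.abs(Theta) > EDGE_EPS)
            np.fill_diagonal(adjacency, False)
            return Theta, adjacency
        step *= 1.3  # optimistic step growth; backtracking will shrink again
    raise RuntimeError(
        f"glasso did not converge within {max_iter} iterations (last change {delta:.2e})")


def lambda_max(S: np.ndarray) -> float:
    """Smallest penalty at which the estimated graph is empty."""
    off = np.abs(S - np.diag(np.diag(S)))
    return float(off.max())


def glasso_path(S: np.ndarray, lambdas: np.ndarray, tol: float = 1e-6,
                max_iter: int = 5000):
    """Fit a decreasing penalty path with warm starts.

    Returns a list of (Theta, adjacency) in the order of `lambdas`
    (expected sorted descending).
    """
    out = []
    Theta = None
    prev_lam = None
    for lam in lambdas:
        try:
            Theta, adj = glasso_fit(S, lam, tol=tol, max_iter=max_iter, Theta0=Theta)
        except RuntimeError:
            if prev_lam is None or prev_lam <= lam:
                raise
            # bridge a large penalty jump with intermediate warm-start fits
            for frac in (0.5, 0.75):
                mid = prev_lam ** (1 - frac) * lam ** frac
                Theta, _ = glasso_fit(S, mid, tol=tol * 10, max_iter=max_iter,
                                      Theta0=Theta)
            Theta, adj = glasso_fit(S, lam, tol=tol, max_iter=max_iter, Theta0=Theta)
        out.append((Theta, adj))
        prev_lam = lam
    return out
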