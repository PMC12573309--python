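"""Exact random-intercept linear mixed model via profiled (RE)ML.

The model is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sb2),  e_ij ~ N(0, se2),

i.e. an arbitrary fixed-effects design with a single random intercept per
group.  For this structure the marginal covariance of group i is
``se2 * (I + lam * 11')`` with ``lam = sb2/se2``, so beta and se2 have closed
forms given lam (Woodbury identity on the group sufficient statistics) and the
(restricted) likelihood reduces to a smooth 1-D function of log(lam).  We
optimise that scalar profile exactly, which makes a fit cost microseconds —
this solver sits inside the NIPALS loop and inside permutation resampling, so
it is the package's hot path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptFit", "fit_random_intercept"]


@dataclass
class RandomInterceptFit:
    """Result of a random-intercept LME fit."""

    beta: np.ndarray            # fixed-effect coefficients
    sigma_b2: float             # random-intercept variance
    sigma_e2: float             # residual variance
    group_labels: list          # distinct group ids, order of first appearance
    blups: np.ndarray           # predicted random intercept per group (same order)
    reml: bool
    converged: bool
    loglik: float


class _GroupStats:
    """Per-group sufficient statistics for the profile likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        labels, inverse = np.unique(groups, return_inverse=True)
        order = np.argsort(inverse, kind="stable")
        self.labels = list(labels)
        self.n_groups = len(labels)
        self.N, self.p = X.shape
        Xs, ys, inv_s = X[order], y[order], inverse[order]
        # contiguous group slices
        starts = np.flatnonzero(np.r_[True, np.diff(inv_s) != 0])
        ends = np.r_[starts[1:], len(inv_s)]
        self.sizes = (ends - starts).astype(float)
        self.XtX = Xs.T @ Xs
        self.Xty = Xs.T @ ys
        self.yty = float(ys @ ys)
        # group sums of X rows and of y
        self.Sx = np.add.reduceat(Xs, starts, axis=0)          # (G, p)
        self.Sy = np.add.reduceat(ys, starts)                   # (G,)

    def gls(self, lam: float):
        """GLS normal equations for V_i = I + lam*11' (up to se2)."""
        w = lam / (1.0 + lam * self.sizes)                      # Woodbury weights
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        beta = np.linalg.solve(A, b)
        # r'V^{-1}r = r'r - sum_i w_i (sum_j r_ij)^2 with r = y - X beta
        ry = self.Sy - self.Sx @ beta
        rss = (
            self.yty
            - 2.0 * float(self.Xty @ beta)
            + float(beta @ (self.XtX @ beta))
            - float(w @ (ry * ry))
        )
        return beta, A, ry, w, max(rss, 1e-300)

    def neg2_profile(self, log_lam: float, reml: bool) -> float:
        lam = np.exp(log_lam)
        _, A, _, _, rss = self.gls(lam)
        logdet_v = float(np.sum(np.log1p(lam * self.sizes)))
        dof = self.N - self.p if reml else self.N
        val = dof * np.log(rss / dof) + logdet_v
        if reml:
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            val += logdet_a
        return val


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    *,
    reml: bool = True,
) -> RandomInterceptFit:
    """Fit ``y = X beta + b_group + e`` by profiled (restricted) maximum
    likelihood.

    Exact for the random-intercept structure: the variance ratio is found by
    scalar optimisation of the analytically profiled likelihood, everything
    else is closed form.  BLUPs are ``lam/(1+lam*m_i) * (group residual sum)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "fixed-effects design is rank deficient (too few distinct time points "
            "for the requested basis)"
        )
    stats = _GroupStats(X, y, np.asarray(groups))

    res = minimize_scalar(
        stats.neg2_profile,
        bounds=(-20.0, 20.0),
        args=(reml,),
        method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    # boundary: effectively zero random-intercept variance
    if log_lam <= -19.5 or stats.neg2_profile(-30.0, reml) <= res.fun + 1e-10:
        lam = 0.0
        beta, A, ry, w, rss = stats.gls(0.0)
    else:
        lam = float(np.exp(log_lam))
        beta, A, ry, w, rss = stats.gls(lam)
    dof = stats.N - stats.p if reml else stats.N
    sigma_e2 = rss / dof
    sigma_b2 = lam * sigma_e2
    if lam > 0:
        blups = (lam / (1.0 + lam * stats.sizes)) * ry
    else:
        blups = np.zeros(stats.n_groups)
    return RandomInterceptFit(
        beta=beta,
        sigma_b2=float(sigma_b2),
        sigma_e2=float(sigma_e2),
        group_labels=stats.labels,
        blups=blups,
        reml=reml,
        converged=bool(res.success),
        loglik=-0.5 * float(res.fun),
    )
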