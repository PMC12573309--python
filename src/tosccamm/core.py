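"""Sparse CCA for repeated measurements with latent trajectories.

The estimator alternates NIPALS-style weight updates between two longitudinal
views while modelling time dynamics on the *latent* scores rather than the
features.  One component is extracted per run of :func:`nipals_component`:

1. project X onto the current weights, ``η = X wx`` (unit norm);
2. fit a trajectory model to η over X's (id, time) grid;
3. predict η̃ on Y's (id, time) grid — this bridges non-matching visit
   schedules and pools information across an individual's repeated visits;
4. update ``w̃y = Yᵀ η̃``, soft-threshold to exactly ``qy`` nonzeros,
   renormalise; ``γ = Y wy`` (unit norm);
5. the mirror-image pass updates ``wx`` with exactly ``px`` nonzeros;
6. iterate until the canonical correlation stabilises.

Because η and γ live on different row sets, the canonical correlation is
computed between trajectory-aligned quantities: ``ρ = cor(η, γ̃)`` on X's rows
(and symmetrically on Y's rows; both are reported).

Sparsity is an exact-cardinality (ℓ0-style) constraint: the threshold is the
(k+1)-th largest absolute entry, so generically exactly k weights survive.
Subsequent components are extracted after rank-1 deflation of both matrices by
the unit-norm latent scores, which enforces orthogonality of the latent
variables across components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .longdata import LongitudinalView, PairedLongitudinalData, standardize_columns
from .trajectories import TrajectoryFit, TrajectorySpec, fit_trajectory, predict_trajectory

__all__ = [
    "CanonicalComponent",
    "TosccammResult",
    "soft_threshold_topk",
    "deflate",
    "nipals_component",
    "fit_tosccamm",
]


def soft_threshold_topk(w: np.ndarray, k: int) -> np.ndarray:
    """Soft-threshold ``w`` so that (generically) exactly ``k`` entries survive.

    The threshold is λ = the (k+1)-th largest absolute entry (λ = 0 when
    ``k == len(w)``); each entry becomes ``sign(w_j)·max(|w_j| − λ, 0)`` and
    the result is rescaled to unit Euclidean norm.  Exactly ``k`` nonzeros
    when the k-th and (k+1)-th largest magnitudes differ and the k-th is
    nonzero; boundary ties (stable order, lower indices first) shrink to zero,
    giving fewer.  An all-zero input is returned as-is with a warning.
    """
    w = np.asarray(w, float)
    if not 1 <= k <= len(w):
        raise ValueError(f"k must be in [1, {len(w)}], got {k}")
    a = np.abs(w)
    if not a.any():
        warnings.warn("soft_threshold_topk: all-zero input (degenerate)", stacklevel=2)
        return np.zeros_like(w)
    if k == len(w):
        lam = 0.0
    else:
        order = np.argsort(-a, kind="stable")
        lam = a[order[k]]
    out = np.sign(w) * np.maximum(a - lam, 0.0)
    nrm = np.linalg.norm(out)
    if nrm > 0:
        out /= nrm
    else:
        warnings.warn("soft_threshold_topk: thresholding removed all entries", stacklevel=2)
    return out


def deflate(matrix: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Remove a unit-norm latent score's rank-1 contribution from a matrix.

    Returns ``M − u (uᵀ M)``; every column of the result is orthogonal to
    ``u``.  Idempotent (a projection).
    """
    matrix = np.asarray(matrix, float)
    latent = np.asarray(latent, float)
    if latent.ndim != 1 or matrix.shape[0] != latent.shape[0]:
        raise ValueError(
            f"latent length {latent.shape} does not match matrix rows {matrix.shape[0]}"
        )
    return matrix - np.outer(latent, latent @ matrix)


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


@dataclass
class CanonicalComponent:
    """One extracted canonical pair.

    ``eta``/``gamma`` are the unit-norm latent scores over X's/Y's rows
    (of the *deflated* matrices used for this component); ``rho`` is the
    trajectory-aligned canonical correlation on X's rows and ``rho_y`` its
    Y-side counterpart.
    """

    wx: np.ndarray
    wy: np.ndarray
    eta: np.ndarray
    gamma: np.ndarray
    eta_fit: TrajectoryFit | None
    gamma_fit: TrajectoryFit | None
    rho: float
    rho_y: float
    n_iter: int
    converged: bool
    gamma_pred_x: np.ndarray | None = None   # γ̃ aligned to X's rows
    eta_pred_y: np.ndarray | None = None     # η̃ aligned to Y's rows

    @property
    def support_x(self) -> np.ndarray:
        return np.flatnonzero(self.wx)

    @property
    def support_y(self) -> np.ndarray:
        return np.flatnonzero(self.wy)


@dataclass
class TosccammResult:
    """Ordered sequence of canonical components with reproducibility info."""

    components: list[CanonicalComponent]
    sparsity: list[tuple[int, int]]
    deflation_record: list[dict] = field(default_factory=list)
    preprocessing: dict | None = None
    seed: int | None = None
    spec_x: TrajectorySpec | None = None
    spec_y: TrajectorySpec | None = None

    @property
    def K(self) -> int:
        return len(self.components)

    def weights_frame(self, feature_names_x=None, feature_names_y=None) -> pd.DataFrame:
        rows = []
        for k, comp in enumerate(self.components, start=1):
            for view, w, names in (("x", comp.wx, feature_names_x), ("y", comp.wy, feature_names_y)):
                for j in np.flatnonzero(w):
                    rows.append(
                        {
                            "view": view,
                            "feature": names[j] if names is not None else f"{view}{j}",
                            "component": k,
                            "weight": w[j],
                        }
                    )
        return pd.DataFrame(rows, columns=["view", "feature", "component", "weight"])

    def scores_frame(self, data: PairedLongitudinalData) -> pd.DataFrame:
        rows = []
        for k, comp in enumerate(self.components, start=1):
            for view, v, ids, times, pred in (
                ("eta", comp.eta, data.x_view.ids, data.x_view.times, comp.gamma_pred_x),
                ("gamma", comp.gamma, data.y_view.ids, data.y_view.times, comp.eta_pred_y),
            ):
                for r in range(len(v)):
                    rows.append(
                        {
                            "id": ids[r],
                            "time": times[r],
                            "component": k,
                            "variable": view,
                            "score": v[r],
                            "predicted_other": pred[r] if pred is not None else np.nan,
                        }
                    )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "K": self.K,
            "seed": self.seed,
            "sparsity": [list(s) for s in self.sparsity],
            "spec_x": self.spec_x.to_dict() if self.spec_x else None,
            "spec_y": self.spec_y.to_dict() if self.spec_y else None,
            "components": [
                {
                    "component": k + 1,
                    "rho": c.rho,
                    "rho_y": c.rho_y,
                    "n_iter": c.n_iter,
                    "converged": c.converged,
                    "nnz_wx": int(np.count_nonzero(c.wx)),
                    "nnz_wy": int(np.count_nonzero(c.wy)),
                    "eta_fixed_effects": None
                    if c.eta_fit is None
                    else list(map(float, c.eta_fit.fixed_effects)),
                    "eta_variance_components": None
                    if c.eta_fit is None
                    else list(map(float, c.eta_fit.variance_components)),
                    "gamma_fixed_effects": None
                    if c.gamma_fit is None
                    else list(map(float, c.gamma_fit.fixed_effects)),
                    "gamma_variance_components": None
                    if c.gamma_fit is None
                    else list(map(float, c.gamma_fit.variance_components)),
                }
                for k, c in enumerate(self.components)
            ],
        }

    def write(self, outdir, data: PairedLongitudinalData | None = None) -> None:
        """Write weights CSV, latent-scores CSV and fit-summary JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names_x = data.x_view.feature_names if data is not None else None
        names_y = data.y_view.feature_names if data is not None else None
        self.weights_frame(names_x, names_y).to_csv(outdir / "weights.csv", index=False)
        if data is not None:
            self.scores_frame(data).to_csv(outdir / "scores.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


def _init_weight(init, p: int, rng: np.random.Generator) -> np.ndarray:
    if init is None:
        w = rng.standard_normal(p)
    else:
        w = np.asarray(init, float)
        if w.shape != (p,):
            raise ValueError(f"init weight must have shape ({p},), got {w.shape}")
    return _unit(w)


def _degenerate(p, q, nx, ny, n_iter) -> CanonicalComponent:
    return CanonicalComponent(
        wx=np.zeros(p),
        wy=np.zeros(q),
        eta=np.zeros(nx),
        gamma=np.zeros(ny),
        eta_fit=None,
        gamma_fit=None,
        rho=0.0,
        rho_y=0.0,
        n_iter=n_iter,
        converged=False,
    )


def nipals_component(
    data: PairedLongitudinalData,
    px: int,
    qy: int,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    init=None,
    *,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    ls_weights: bool = False,
    n_starts: int = 1,
) -> CanonicalComponent:
    """Extract one canonical component by the trajectory-augmented NIPALS loop.

    ``data`` is assumed column-standardized.  ``init`` may be an explicit
    p-vector; otherwise ``n_starts`` unit vectors are drawn from ``rng``
    (required then), the loop is run from each and the start with the largest
    ``|rho|`` wins — the thresholded update is greedy and a single random
    start can converge to a weaker component, so restarts stabilise the
    extraction order.  Deterministic given the generator state.
    ``ls_weights`` switches the weight update from the covariance form
    ``w̃ = Mᵀ s`` to full least squares ``(MᵀM)⁻¹ Mᵀ s``.
    Convergence is declared when ``|ρ(l) − ρ(l−1)| ≤ tol``.

    A thresholding step that zeroes an entire weight vector yields a
    degenerate component with ``rho = 0`` and ``converged = False``.
    """
    if init is not None or n_starts <= 1:
        return _nipals_single(
            data, px, qy, spec_x, spec_y, init,
            rng=rng, tol=tol, max_iter=max_iter, ls_weights=ls_weights,
        )
    if rng is None:
        raise ValueError("provide either an init vector or an rng for initialization")
    p = data.x_view.features.shape[1]
    inits = [_unit(rng.standard_normal(p)) for _ in range(n_starts)]
    best = None
    for w0 in inits:
        comp = _nipals_single(
            data, px, qy, spec_x, spec_y, w0,
            rng=None, tol=tol, max_iter=max_iter, ls_weights=ls_weights,
        )
        if best is None or abs(comp.rho) > abs(best.rho):
            best = comp
    return best


def _nipals_single(
    data: PairedLongitudinalData,
    px: int,
    qy: int,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    init=None,
    *,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    ls_weights: bool = False,
) -> CanonicalComponent:
    X, Y = data.x_view.features, data.y_view.features
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both views must contain at least one row")
    nx, p = X.shape
    ny, q = Y.shape
    if not (1 <= px <= p and 1 <= qy <= q):
        raise ValueError(f"sparsity levels must satisfy 1<=px<={p}, 1<=qy<={q}")
    x_ids, x_t = data.x_view.ids, data.x_view.times
    y_ids, y_t = data.y_view.ids, data.y_view.times

    if init is None and rng is None:
        raise ValueError("provide either an init vector or an rng for initialization")
    wx = _init_weight(init, p, rng if rng is not None else np.random.default_rng(0))

    if ls_weights:
        # cached pseudo-inverses for the least-squares variant
        pinv_x = np.linalg.pinv(X)
        pinv_y = np.linalg.pinv(Y)

    rho_prev = 0.0
    rho = rho_y = 0.0
    eta_fit = gamma_fit = None
    gamma_pred_x = eta_pred_y = None
    wy = np.zeros(q)
    converged = False
    n_iter = 0
    for l in range(1, max_iter + 1):
        n_iter = l
        eta = _unit(X @ wx)
        if not eta.any():
            return _degenerate(p, q, nx, ny, l)
        eta_fit = fit_trajectory(spec_x, x_ids, x_t, eta)
        eta_pred_y = predict_trajectory(eta_fit, y_ids, y_t)
        wy_raw = (pinv_y @ eta_pred_y) if ls_weights else Y.T @ eta_pred_y
        wy = soft_threshold_topk(wy_raw, qy)
        if not wy.any():
            return _degenerate(p, q, nx, ny, l)
        gamma = _unit(Y @ wy)
        gamma_fit = fit_trajectory(spec_y, y_ids, y_t, gamma)
        gamma_pred_x = predict_trajectory(gamma_fit, x_ids, x_t)
        wx_raw = (pinv_x @ gamma_pred_x) if ls_weights else X.T @ gamma_pred_x
        wx = soft_threshold_topk(wx_raw, px)
        if not wx.any():
            return _degenerate(p, q, nx, ny, l)
        eta = _unit(X @ wx)
        rho = _pearson(eta, gamma_pred_x)
        rho_y = _pearson(gamma, eta_pred_y)
        if abs(rho - rho_prev) <= tol:
            converged = True
            break
        rho_prev = rho

    # final latent scores and trajectory fits for the converged weights
    eta = _unit(X @ wx)
    gamma = _unit(Y @ wy)
    eta_fit = fit_trajectory(spec_x, x_ids, x_t, eta)
    eta_pred_y = predict_trajectory(eta_fit, y_ids, y_t)
    gamma_fit = fit_trajectory(spec_y, y_ids, y_t, gamma)
    gamma_pred_x = predict_trajectory(gamma_fit, x_ids, x_t)
    rho = _pearson(eta, gamma_pred_x)
    rho_y = _pearson(gamma, eta_pred_y)
    return CanonicalComponent(
        wx=wx,
        wy=wy,
        eta=eta,
        gamma=gamma,
        eta_fit=eta_fit,
        gamma_fit=gamma_fit,
        rho=rho,
        rho_y=rho_y,
        n_iter=n_iter,
        converged=converged,
        gamma_pred_x=gamma_pred_x,
        eta_pred_y=eta_pred_y,
    )


def fit_tosccamm(
    data: PairedLongitudinalData,
    K: int,
    sparsity,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    seed: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    ls_weights: bool = False,
    standardize: bool = True,
    n_starts: int = 5,
) -> TosccammResult:
    """Extract ``K`` canonical components sequentially with deflation.

    ``sparsity`` is either a single ``(px, qy)`` pair used for every component
    or a list of ``K`` pairs.  After each component both matrices are deflated
    by the component's unit-norm latent scores, so latent variables of
    distinct components are orthogonal.  The seed fully determines the random
    initializations; a fixed seed reproduces the result bit-for-bit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    sparsity = list(sparsity)
    if len(sparsity) == 2 and isinstance(sparsity[0], (int, np.integer)):
        sparsity = [tuple(sparsity)] * K
    if len(sparsity) != K:
        raise ValueError(f"sparsity must give one (px, qy) pair per component (K={K})")
    sparsity = [tuple(map(int, s)) for s in sparsity]

    preprocessing = None
    if standardize:
        xs, cx, sx = standardize_columns(data.x_view)
        ys, cy, sy = standardize_columns(data.y_view)
        preprocessing = {
            "x_centers": cx, "x_scales": sx,
            "y_centers": cy, "y_scales": sy,
        }
    else:
        xs, ys = data.x_view, data.y_view

    rng = np.random.default_rng(seed)
    Xd, Yd = xs.features.copy(), ys.features.copy()
    components: list[CanonicalComponent] = []
    deflation_record: list[dict] = []
    for k in range(K):
        px, qy = sparsity[k]
        view_x = LongitudinalView(xs.ids, xs.times, Xd, list(xs.feature_names))
        view_y = LongitudinalView(ys.ids, ys.times, Yd, list(ys.feature_names))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # paired-view id warnings already issued
            sub = PairedLongitudinalData(view_x, view_y)
        comp = nipals_component(
            sub, px, qy, spec_x, spec_y,
            rng=rng, tol=tol, max_iter=max_iter, ls_weights=ls_weights,
            n_starts=n_starts,
        )
        components.append(comp)
        if comp.eta.any():
            Xd = deflate(Xd, comp.eta)
        if comp.gamma.any():
            Yd = deflate(Yd, comp.gamma)
        deflation_record.append({"eta": comp.eta.copy(), "gamma": comp.gamma.copy()})
    return TosccammResult(
        components=components,
        sparsity=sparsity,
        deflation_record=deflation_record,
        preprocessing=preprocessing,
        seed=seed,
        spec_x=spec_x,
        spec_y=spec_y,
    )
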