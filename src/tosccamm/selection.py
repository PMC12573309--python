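"""Model selection: sparsity CV, adjusted CPEV and permutation testing.

All three procedures respect the clustered structure of longitudinal data:
cross-validation folds partition *individuals* (never rows), and the
permutation null reassigns whole individuals' Y series against X, keeping each
series — and hence the within-individual correlation — intact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .core import deflate, fit_tosccamm, nipals_component, _pearson, _unit
from .longdata import LongitudinalView, PairedLongitudinalData, standardize_columns
from .trajectories import TrajectorySpec, fit_trajectory, predict_trajectory

__all__ = [
    "CvResult",
    "PermutationResult",
    "cv_select",
    "adj_cpev",
    "permutation_test",
]


@dataclass
class CvResult:
    """Cross-validation scores and chosen sparsity per component."""

    grid: list[tuple[int, int]]
    scores: pd.DataFrame           # component, px, qy, mean_score, se, n_folds_used
    chosen: list[tuple[int, int]]  # per component
    n_folds: int
    seed: int

    def scores_frame(self) -> pd.DataFrame:
        return self.scores

    def to_json(self, path) -> None:
        payload = {
            "grid": [list(g) for g in self.grid],
            "chosen": [list(c) for c in self.chosen],
            "n_folds": self.n_folds,
            "seed": self.seed,
            "scores": self.scores.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class PermutationResult:
    """Permutation null distributions and p-values per component."""

    observed_rho: list[float]
    null_rhos: np.ndarray          # (K, B)
    p_values: list[float]
    B: int
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "observed_rho": self.observed_rho,
            "p_values": self.p_values,
            "B": self.B,
            "seed": self.seed,
            "null_rhos": self.null_rhos.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _paired_quiet(x_view, y_view) -> PairedLongitudinalData:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PairedLongitudinalData(x_view, y_view)


def _oof_score(
    train: PairedLongitudinalData,
    test: PairedLongitudinalData,
    px: int,
    qy: int,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    n_starts: int,
) -> float:
    """Out-of-fold aligned correlation for one (px, qy) pair and one fold.

    Weights are learned on the training individuals; on the held-out
    individuals the Y-side latent scores are bridged to X's grid with the
    trajectory model and correlated with the X-side scores.  The absolute
    value is used because the sign of a canonical pair is arbitrary.
    """
    comp = nipals_component(
        train, px, qy, spec_x, spec_y, rng=rng, tol=tol, max_iter=max_iter,
        n_starts=n_starts,
    )
    if not (comp.wx.any() and comp.wy.any()):
        return 0.0
    eta_t = test.x_view.features @ comp.wx
    gamma_t = test.y_view.features @ comp.wy
    if eta_t.std() == 0 or gamma_t.std() == 0:
        return 0.0
    gfit = fit_trajectory(spec_y, test.y_view.ids, test.y_view.times, _unit(gamma_t))
    gamma_on_x = predict_trajectory(gfit, test.x_view.ids, test.x_view.times)
    return abs(_pearson(eta_t, gamma_on_x))


def cv_select(
    data: PairedLongitudinalData,
    grid,
    n_folds: int,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    seed: int,
    *,
    n_components: int = 1,
    tol: float = 1e-6,
    max_iter: int = 100,
    standardize: bool = True,
    n_starts: int = 5,
) -> CvResult:
    """Choose ``(px, qy)`` per component by individual-level cross-validation.

    Folds partition the individuals (all visits of an individual stay
    together) and depend only on the seed and the id set.  For each grid pair
    the mean out-of-fold aligned correlation is computed; the winner is the
    pair with the highest mean, ties resolved toward sparser models (smaller
    px+qy, then smaller px).  Components beyond the first are selected on
    matrices deflated by the previous components' full-data refits.
    """
    grid = [tuple(map(int, g)) for g in grid]
    if not grid:
        raise ValueError("grid must be non-empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")

    if standardize:
        xs, *_ = standardize_columns(data.x_view)
        ys, *_ = standardize_columns(data.y_view)
    else:
        xs, ys = data.x_view, data.y_view

    individuals = np.array(sorted(set(xs.unique_ids) | set(ys.unique_ids)), dtype=object)
    folds = list(
        KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32)).split(individuals)
    )

    Xd, Yd = xs.features.copy(), ys.features.copy()
    rows = []
    chosen: list[tuple[int, int]] = []
    ss = np.random.SeedSequence(seed)
    for k in range(n_components):
        view_x = LongitudinalView(xs.ids, xs.times, Xd, list(xs.feature_names))
        view_y = LongitudinalView(ys.ids, ys.times, Yd, list(ys.feature_names))
        per_pair: dict[tuple[int, int], list[float]] = {g: [] for g in grid}
        for fi, (tr_idx, te_idx) in enumerate(folds):
            train_ids, test_ids = individuals[tr_idx], individuals[te_idx]
            te_x = view_x.subset(test_ids)
            te_y = view_y.subset(test_ids)
            if len(set(te_x.unique_ids)) < 2 or len(set(te_y.unique_ids)) < 2:
                warnings.warn(f"fold {fi}: fewer than 2 test individuals, skipped")
                continue
            train = _paired_quiet(view_x.subset(train_ids), view_y.subset(train_ids))
            test = _paired_quiet(te_x, te_y)
            for gi, (px, qy) in enumerate(grid):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(k, fi, gi))
                )
                per_pair[(px, qy)].append(
                    _oof_score(train, test, px, qy, spec_x, spec_y, rng, tol,
                               max_iter, n_starts)
                )
        if all(len(v) == 0 for v in per_pair.values()):
            raise ValueError("all cross-validation folds were skipped")
        stats = []
        for (px, qy), vals in per_pair.items():
            vals = np.asarray(vals)
            mean = float(vals.mean()) if len(vals) else -np.inf
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            stats.append((px, qy, mean, se, len(vals)))
            rows.append(
                {"component": k + 1, "px": px, "qy": qy,
                 "mean_score": mean, "se": se, "n_folds_used": len(vals)}
            )
        stats.sort(key=lambda s: (-s[2], s[0] + s[1], s[0]))
        best = (stats[0][0], stats[0][1])
        chosen.append(best)

        # deflate with a full-data refit at the chosen sparsity
        refit_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k, 9999)))
        comp = nipals_component(
            _paired_quiet(view_x, view_y), best[0], best[1], spec_x, spec_y,
            rng=refit_rng, tol=tol, max_iter=max_iter, n_starts=n_starts,
        )
        if comp.eta.any():
            Xd = deflate(Xd, comp.eta)
        if comp.gamma.any():
            Yd = deflate(Yd, comp.gamma)

    return CvResult(
        grid=grid,
        scores=pd.DataFrame(rows),
        chosen=chosen,
        n_folds=n_folds,
        seed=seed,
    )


def adj_cpev(view_matrix: np.ndarray, scores) -> float:
    """Adjusted cumulative percentage of explained variance.

    Fraction of the (original, standardized) matrix's total variance captured
    by the span of the latent score vectors of components 1..k:
    ``trace(MᵀP M)/trace(MᵀM)`` with ``P`` the orthogonal projector onto the
    span.  Depends on the span only (invariant to recombination of the
    scores); nondecreasing in k.  ``k = 0`` (no scores) returns 0.
    """
    M = np.asarray(view_matrix, float)
    if scores is None:
        return 0.0
    if isinstance(scores, np.ndarray) and scores.ndim == 2:
        S = np.asarray(scores, float)          # columns are score vectors
    else:
        scores = list(scores)
        if not scores:
            return 0.0
        S = np.column_stack([np.asarray(s, float) for s in scores])
    if S.size == 0:
        return 0.0
    if S.shape[0] != M.shape[0]:
        raise ValueError("score vectors must have one entry per matrix row")
    total = float(np.sum(M * M))
    if total == 0:
        return 0.0
    # orthonormal basis of the span (rank-tolerant)
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * max(S.shape) * np.finfo(float).eps)) if sv.size else 0
    if rank == 0:
        return 0.0
    Q = U[:, :rank]
    return float(np.sum((Q.T @ M) ** 2) / total)


def permutation_test(
    data: PairedLongitudinalData,
    K: int,
    sparsity,
    spec_x: TrajectorySpec,
    spec_y: TrajectorySpec,
    B: int,
    seed: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
    standardize: bool = True,
    n_starts: int = 5,
) -> PermutationResult:
    """Clustered permutation test for the number of canonical components.

    The null distribution for component k is built by reassigning whole
    individuals' Y series against X (a seeded permutation of the Y id labels;
    each series stays intact, preserving within-individual correlation) and
    refitting component k on the observed fit's deflated matrices.  P-values
    are ``(1 + #{|ρ*_b| ≥ |ρ_k|}) / (B + 1)``; absolute values because the
    sign of a canonical pair is arbitrary.
    """
    if B < 19:
        raise ValueError("B must be >= 19")
    n_x = len(set(data.x_view.unique_ids))
    n_y = len(set(data.y_view.unique_ids))
    if n_x < 5 or n_y < 5:
        raise ValueError("permutation testing needs at least 5 individuals per view")

    if standardize:
        xs, *_ = standardize_columns(data.x_view)
        ys, *_ = standardize_columns(data.y_view)
    else:
        xs, ys = data.x_view, data.y_view
    std_data = _paired_quiet(xs, ys)

    observed = fit_tosccamm(
        std_data, K, sparsity, spec_x, spec_y, seed,
        tol=tol, max_iter=max_iter, standardize=False, n_starts=n_starts,
    )

    rng = np.random.default_rng(seed)
    y_ids_unique = np.array(ys.unique_ids, dtype=object)
    null = np.zeros((K, B))
    p_values = []
    Xd, Yd = xs.features.copy(), ys.features.copy()
    for k in range(K):
        obs_rho = abs(observed.components[k].rho)
        view_x = LongitudinalView(xs.ids, xs.times, Xd, list(xs.feature_names))
        px, qy = observed.sparsity[k]
        for b in range(B):
            perm = rng.permutation(len(y_ids_unique))
            mapping = dict(zip(y_ids_unique, y_ids_unique[perm]))
            y_ids_perm = np.array([mapping[i] for i in ys.ids], dtype=object)
            view_y = LongitudinalView(y_ids_perm, ys.times, Yd, list(ys.feature_names))
            comp = nipals_component(
                _paired_quiet(view_x, view_y), px, qy, spec_x, spec_y,
                rng=rng, tol=tol, max_iter=max_iter, n_starts=n_starts,
            )
            null[k, b] = abs(comp.rho)
        p = (1.0 + np.sum(null[k] >= obs_rho)) / (B + 1.0)
        p_values.append(float(p))
        eta_k = observed.deflation_record[k]["eta"]
        gamma_k = observed.deflation_record[k]["gamma"]
        if eta_k.any():
            Xd = deflate(Xd, eta_k)
        if gamma_k.any():
            Yd = deflate(Yd, gamma_k)

    return PermutationResult(
        observed_rho=[abs(c.rho) for c in observed.components],
        null_rhos=null,
        p_values=p_values,
        B=B,
        seed=seed,
    )
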