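"""Synthetic longitudinal two-view data with a shared dynamic latent variable.

The generative process follows probabilistic CCA with time dynamics: for each
component k a *single* latent series ``z_k,i(t)`` — a smooth nonlinear
population curve plus an individual random offset and iid noise — drives both
views.  Observations are ``x_i(t) = Σ_k z_k,i(t) w_x,k + ε`` with sparse true
weight vectors and noise that is AR(1)-correlated over time within each
feature (unit marginal variance, nonzero off-diagonals — time-dependent
noise), independent across features.  Finally a fixed fraction of whole visits
is removed uniformly at random from each view separately, so the two views end
up with different, irregular per-individual visit patterns; an individual may
lose none, several or all of its visits.

Defaults are the simulation-study conditions: n=100 individuals, p=10,000 and
q=200 features, 10 visits at t=1..10, two latent components with 10 (X) and
5 (Y) truly nonzero weights each, and 20% / 30% of X / Y visits removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .longdata import LongitudinalView, PairedLongitudinalData, write_long_csv
from .trajectories import design_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "latent_curve",
    "generate",
    "evaluate_recovery",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-data generator (defaults = study conditions)."""

    n: int = 100                    # individuals
    p: int = 10_000                 # X features
    q: int = 200                    # Y features
    n_times: int = 10               # visits per individual, at t = 1..n_times
    n_components: int = 2
    true_support_x: int = 10        # nonzero X weights per component
    true_support_y: int = 5         # nonzero Y weights per component
    theta0: float = 0.5             # component-1 linear trend
    theta1: float = 0.4             # component-1 oscillation frequency
    theta2: float = -1.2            # component-2 linear trend
    sigma_b: float = 0.5            # SD of individual random offsets on z
    sigma_e: float = 0.5            # SD of iid noise on z
    rho_t: float = 0.3              # AR(1) parameter of the observation noise
    noise_sd: float = 1.0           # marginal SD of the observation noise
                                    # (1 = unit diagonal; 0 = noiseless limit)
    miss_x: float = 0.20            # fraction of X visits removed
    miss_y: float = 0.30            # fraction of Y visits removed
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.miss_x < 1 and 0 <= self.miss_y < 1):
            raise ValueError("missingness fractions must be in [0, 1)")
        if self.n_components * self.true_support_x > self.p:
            raise ValueError("disjoint X supports exceed the number of X features")
        if self.n_components * self.true_support_y > self.q:
            raise ValueError("disjoint Y supports exceed the number of Y features")
        if not -1 < self.rho_t < 1:
            raise ValueError("rho_t must be in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n < 1 or self.n_times < 1 or self.n_components < 1:
            raise ValueError("n, n_times and n_components must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(1, self.n_times + 1, dtype=float)


@dataclass
class SimulatedDataset:
    """Generated data plus the ground truth needed to score recovery."""

    data: PairedLongitudinalData
    truth: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def latent_curve(k: int, t, config: SimulationConfig) -> np.ndarray:
    """Population latent curve of component ``k`` (1-based) at times ``t``.

    Component 1 is a trend with a growing oscillation, θ0·t + sin(θ1·t)·t;
    component 2 is a trend plus a cubic saturation term,
    θ2·t + (1 + t/max(t))³, with max(t) the design-grid maximum.
    """
    t = np.asarray(t, float)
    if k == 1:
        return config.theta0 * t + np.sin(config.theta1 * t) * t
    if k == 2:
        t_max = float(config.grid[-1])
        return config.theta2 * t + (1.0 + t / t_max) ** 3
    raise ValueError("latent curves are defined for components 1 and 2")


def _true_weights(n_feat: int, support: int, n_comp: int) -> np.ndarray:
    """Sparse true weights: disjoint fixed supports, equal magnitudes
    ``1/sqrt(support)`` with alternating signs."""
    W = np.zeros((n_feat, n_comp))
    mag = 1.0 / np.sqrt(support)
    for k in range(n_comp):
        idx = np.arange(k * support, (k + 1) * support)
        W[idx, k] = mag * np.where(np.arange(support) % 2 == 0, 1.0, -1.0)
    return W


def _ar1_noise_into(out: np.ndarray, rng: np.random.Generator, rho: float) -> None:
    """Fill ``out`` of shape (n, T, f) with AR(1)-in-time noise of unit
    marginal variance, independent across individuals and features."""
    n, T, f = out.shape
    out[:, 0, :] = rng.standard_normal((n, f))
    innov_sd = np.sqrt(1.0 - rho * rho)
    for t in range(1, T):
        out[:, t, :] = rho * out[:, t - 1, :] + innov_sd * rng.standard_normal((n, f))


def generate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one synthetic paired longitudinal dataset.

    The same latent realization drives both views; the views differ only in
    their observation noise and in which visits survive removal.  Exactly
    ``round(miss·n·n_times)`` visits are removed per view (deterministic row
    counts).  A fixed seed reproduces the dataset bit-for-bit.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, T, K = cfg.n, cfg.n_times, cfg.n_components
    grid = cfg.grid

    z_pop = np.stack([latent_curve(k + 1, grid, cfg) for k in range(K)])      # (K, T)
    b = rng.normal(0.0, cfg.sigma_b, size=(K, n))                             # offsets
    eps = rng.normal(0.0, cfg.sigma_e, size=(K, n, T))
    z = z_pop[:, None, :] + b[:, :, None] + eps                               # (K, n, T)

    Wx = _true_weights(cfg.p, cfg.true_support_x, K)
    Wy = _true_weights(cfg.q, cfg.true_support_y, K)

    # signal (n, T, f) = sum_k z_k (n,T) ⊗ w_k (f)
    z_nt = np.moveaxis(z, 0, -1)                                              # (n, T, K)
    X = np.empty((n, T, cfg.p))
    _ar1_noise_into(X, rng, cfg.rho_t)
    if cfg.noise_sd != 1.0:
        X *= cfg.noise_sd
    X += z_nt @ Wx.T
    Y = np.empty((n, T, cfg.q))
    _ar1_noise_into(Y, rng, cfg.rho_t)
    if cfg.noise_sd != 1.0:
        Y *= cfg.noise_sd
    Y += z_nt @ Wy.T

    ids_full = np.repeat([f"s{i:03d}" for i in range(n)], T)
    times_full = np.tile(grid, n)

    def _drop(frac: float, total: int) -> np.ndarray:
        n_remove = int(round(frac * total))
        removed = rng.choice(total, size=n_remove, replace=False)
        mask = np.ones(total, dtype=bool)
        mask[removed] = False
        return mask

    keep_x = _drop(cfg.miss_x, n * T)
    keep_y = _drop(cfg.miss_y, n * T)

    x_view = LongitudinalView(
        ids_full[keep_x], times_full[keep_x], X.reshape(n * T, cfg.p)[keep_x],
        [f"x{j}" for j in range(cfg.p)],
    )
    y_view = LongitudinalView(
        ids_full[keep_y], times_full[keep_y], Y.reshape(n * T, cfg.q)[keep_y],
        [f"y{j}" for j in range(cfg.q)],
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # missingness can leave ids in one view only
        data = PairedLongitudinalData(x_view, y_view)
    truth = {
        "Wx": Wx,
        "Wy": Wy,
        "z": z,                      # (K, n, T) individual latent series, full grid
        "z_pop": z_pop,              # (K, T) population curves
        "grid": grid,
        "ids": np.array([f"s{i:03d}" for i in range(n)], dtype=object),
        "keep_x": keep_x,
        "keep_y": keep_y,
    }
    return SimulatedDataset(data=data, truth=truth, config=cfg)


def evaluate_recovery(dataset: SimulatedDataset, result) -> dict:
    """Score a fitted model against the generator's ground truth.

    Estimated components are matched to true components by maximal absolute
    correlation between the estimated latent scores and the true latent series
    on X's surviving rows (optimal one-to-one assignment), with signs aligned.
    Returns per-component support true/false positives for both views and the
    correlation between the estimated mean latent path (the trajectory fit's
    fixed-effects curve on the full grid) and the true population curve.
    """
    truth = dataset.truth
    cfg = dataset.config
    n, T = cfg.n, cfg.n_times
    keep_x = truth["keep_x"]
    # row -> (individual index, time index) on the full grid
    ii, tt = np.divmod(np.flatnonzero(keep_x), T)
    K_true = truth["z"].shape[0]
    comps = result.components
    K_est = len(comps)

    C = np.zeros((K_est, K_true))
    for a, comp in enumerate(comps):
        for j in range(K_true):
            zr = truth["z"][j, ii, tt]
            e = comp.eta
            if e.std() > 0 and zr.std() > 0:
                C[a, j] = np.corrcoef(e, zr)[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(C))

    out = []
    for a, j in zip(rows, cols):
        comp = comps[a]
        sign = 1.0 if C[a, j] >= 0 else -1.0
        sx_true = set(np.flatnonzero(truth["Wx"][:, j]))
        sy_true = set(np.flatnonzero(truth["Wy"][:, j]))
        sx_est = set(comp.support_x)
        sy_est = set(comp.support_y)
        traj_corr = np.nan
        if comp.eta_fit is not None and comp.eta_fit.spec.family != "passthrough":
            curve = design_matrix(comp.eta_fit.spec, truth["grid"]) @ comp.eta_fit.fixed_effects
            if curve.std() > 0:
                traj_corr = sign * np.corrcoef(curve, truth["z_pop"][j])[0, 1]
        out.append(
            {
                "component": a + 1,
                "matched_truth": j + 1,
                "latent_corr": abs(C[a, j]),
                "sign": sign,
                "tp_x": len(sx_est & sx_true),
                "fp_x": len(sx_est - sx_true),
                "tp_y": len(sy_est & sy_true),
                "fp_y": len(sy_est - sy_true),
                "trajectory_corr": float(traj_corr),
            }
        )
    return {"components": out}


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write x.csv / y.csv (long format), the true weights and latent series,
    the generating config and a manifest with the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_long_csv(dataset.data.x_view, outdir / "x.csv")
    write_long_csv(dataset.data.y_view, outdir / "y.csv")
    truth, cfg = dataset.truth, dataset.config

    wrows = []
    for view, W, prefix in (("x", truth["Wx"], "x"), ("y", truth["Wy"], "y")):
        for j, k in zip(*np.nonzero(W)):
            wrows.append(
                {"view": view, "feature": f"{prefix}{j}", "component": k + 1,
                 "weight": W[j, k]}
            )
    pd.DataFrame(wrows).to_csv(outdir / "truth_weights.csv", index=False)

    zrows = []
    K, n, T = truth["z"].shape
    for k in range(K):
        for i in range(n):
            for t in range(T):
                zrows.append(
                    {"component": k + 1, "id": truth["ids"][i],
                     "time": truth["grid"][t], "z": truth["z"][k, i, t],
                     "z_pop": truth["z_pop"][k, t]}
                )
    pd.DataFrame(zrows).to_csv(outdir / "truth_latent.csv", index=False)

    with open(outdir / "config.yaml", "w") as fh:
        for key, val in asdict(cfg).items():
            fh.write(f"{key}: {val}\n")
    manifest = {
        "seed": cfg.seed,
        "n_rows_x": int(dataset.data.x_view.n_rows),
        "n_rows_y": int(dataset.data.y_view.n_rows),
        "p": cfg.p,
        "q": cfg.q,
        "n": cfg.n,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
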