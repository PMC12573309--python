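"""Pluggable latent-trajectory models f(t; θ).

Within the multiple-measurements NIPALS loop, each view's latent scores are a
scalar time series per individual on that view's own visit grid.  A trajectory
model is fitted to those scores and then used to *predict* them on the other
view's (id, time) grid, bridging non-matching visit schedules.  All supported
families are linear mixed models with a single random intercept per
individual and a fixed-effects time basis:

``random_intercept_linear``
    f(t) = α_i + β t.
``random_intercept_polynomial`` (degree d)
    f(t) = α_i + β_1 t + … + β_d t^d (raw powers).
``change_point``
    f(t) = a_i + a_1 t + a_2 t² + a_3 t³ + β t·1{t>s} — a cubic trend with an
    extra slope switched on after a known change point ``s`` (event-centred
    time; ``s`` is supplied, never estimated).
``passthrough``
    Degenerate identity model: returns the training scores unchanged when the
    prediction grid coincides with the training grid.  With one visit per
    individual this reduces the longitudinal algorithm to plain sparse CCA.

Prediction for an individual never seen at fit time uses the fixed-effects
curve only (the BLUP of an unobserved random intercept is its prior mean 0),
which is what allows an id present in one view but absent in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._lme import fit_random_intercept

__all__ = [
    "TrajectorySpec",
    "TrajectoryFit",
    "design_row",
    "design_matrix",
    "fit_trajectory",
    "predict_trajectory",
]

_FAMILIES = {
    "random_intercept_linear",
    "random_intercept_polynomial",
    "change_point",
    "passthrough",
}


@dataclass(frozen=True)
class TrajectorySpec:
    """Declarative description of a trajectory family and its options.

    Parameters
    ----------
    family
        One of ``random_intercept_linear``, ``random_intercept_polynomial``,
        ``change_point``, ``passthrough``.
    degree
        Polynomial degree ``d >= 1`` (polynomial family; the change-point
        family always uses a cubic trend).
    change_point
        The known change time ``s`` (change-point family). Defaults to 0,
        i.e. event-centred time.
    shift_after_change
        If True the post-change term uses ``(t - s)·1{t>s}`` instead of
        ``t·1{t>s}``.
    reml
        Restricted maximum likelihood for the variance components (default);
        plain ML when False.
    """

    family: str = "random_intercept_linear"
    degree: int = 1
    change_point: float = 0.0
    shift_after_change: bool = False
    reml: bool = True

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown trajectory family {self.family!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "degree": self.degree,
            "change_point": self.change_point,
            "shift_after_change": self.shift_after_change,
            "reml": self.reml,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrajectorySpec":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class TrajectoryFit:
    """A fitted trajectory model.

    ``fixed_effects`` holds the coefficient vector on the family's basis
    (see :func:`design_row`); ``random_intercepts`` maps each individual seen
    at fit time to its predicted (BLUP) offset; ``variance_components`` is
    ``(random-intercept variance, residual variance)``.
    """

    spec: TrajectorySpec
    fixed_effects: np.ndarray
    random_intercepts: dict
    variance_components: tuple[float, float]
    fallback: bool = False
    _passthrough: dict = field(default_factory=dict, repr=False)

    def fitted(self, ids, times) -> np.ndarray:
        return predict_trajectory(self, ids, times)


def design_row(spec: TrajectorySpec, t: float) -> np.ndarray:
    """Fixed-effects regression basis at a single time point."""
    return design_matrix(spec, np.array([float(t)]))[0]


def design_matrix(spec: TrajectorySpec, times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, float)
    if spec.family == "random_intercept_linear":
        return np.column_stack([np.ones_like(t), t])
    if spec.family == "random_intercept_polynomial":
        return np.vander(t, spec.degree + 1, increasing=True)
    if spec.family == "change_point":
        s = spec.change_point
        post = (t - s) if spec.shift_after_change else t
        return np.column_stack(
            [np.ones_like(t), t, t**2, t**3, post * (t > s)]
        )
    raise ValueError(f"family {spec.family!r} has no regression basis")


def fit_trajectory(spec: TrajectorySpec, ids, times, values) -> TrajectoryFit:
    """Fit the trajectory model to latent scores observed at (id, time) pairs.

    Mixed-model families are estimated exactly by profiled (RE)ML; if the
    optimiser fails, the fit falls back to fixed-effects-only least squares
    with zero random-intercept variance and is flagged via ``fallback``.
    Requires at least two distinct individuals (except for ``passthrough``).
    """
    ids = np.asarray(ids, dtype=object)
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if not (len(ids) == len(times) == len(values)):
        raise ValueError("ids, times and values must have equal length")

    if spec.family == "passthrough":
        table: dict = {}
        counts: dict = {}
        for i, t, v in zip(ids, times, values):
            key = (i, float(t))
            table[key] = table.get(key, 0.0) + v
            counts[key] = counts.get(key, 0) + 1
        table = {k: table[k] / counts[k] for k in table}
        return TrajectoryFit(
            spec=spec,
            fixed_effects=np.zeros(0),
            random_intercepts={},
            variance_components=(0.0, 0.0),
            _passthrough=table,
        )

    if len(set(ids)) < 2:
        raise ValueError("trajectory fitting needs at least 2 distinct individuals")
    X = design_matrix(spec, times)
    try:
        res = fit_random_intercept(X, values, ids, reml=spec.reml)
        if not res.converged:
            raise RuntimeError("variance-ratio optimisation did not converge")
    except np.linalg.LinAlgError:
        raise
    except Exception:
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        resid = values - X @ beta
        dof = max(len(values) - X.shape[1], 1)
        return TrajectoryFit(
            spec=spec,
            fixed_effects=beta,
            random_intercepts={i: 0.0 for i in set(ids)},
            variance_components=(0.0, float(resid @ resid / dof)),
            fallback=True,
        )
    return TrajectoryFit(
        spec=spec,
        fixed_effects=res.beta,
        random_intercepts=dict(zip(res.group_labels, res.blups)),
        variance_components=(res.sigma_b2, res.sigma_e2),
    )


def predict_trajectory(fit: TrajectoryFit, ids, times) -> np.ndarray:
    """Predict latent scores at arbitrary (id, time) pairs.

    Individuals seen at fit time get fixed-effects curve + their BLUP
    intercept; unseen individuals get the fixed-effects curve only.
    Extrapolation beyond the fitted time range is permitted.  Output order
    matches input order.
    """
    ids = np.asarray(ids, dtype=object)
    times = np.asarray(times, float)
    if fit.spec.family == "passthrough":
        out = np.empty(len(ids))
        for r, (i, t) in enumerate(zip(ids, times)):
            key = (i, float(t))
            if key not in fit._passthrough:
                raise KeyError(
                    f"passthrough trajectory cannot predict unseen pair {key}; "
                    "grids must coincide"
                )
            out[r] = fit._passthrough[key]
        return out
    X = design_matrix(fit.spec, times)
    offsets = np.fromiter(
        (fit.random_intercepts.get(i, 0.0) for i in ids), float, count=len(ids)
    )
    return X @ fit.fixed_effects + offsets
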