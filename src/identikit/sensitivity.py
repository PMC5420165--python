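"""Output sensitivities, weighting and the influence filter.

The sensitivities s_i = dy/dtheta_i are obtained by integrating the forward
sensitivity equations — the state equations augmented with

    dX_i/dt = (df/dx) X_i + df/dtheta_i,   X_i(t0) = dx0/dtheta_i,

so the augmented system has dimension N_x * (1 + N_theta).  The initial
condition is zero for rate parameters and a unit entry on the matching state
when theta_i is an initial-condition parameter.  A central finite-difference
fallback is available for models without usable symbolic partials.

Each sensitivity is scaled by the square root of the record weight, stacked
over all data records, and summarised per parameter by the root-mean-square
score; parameters whose score falls four orders of magnitude (by default)
below the largest score are classified non-influential and removed from the
collinearity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (ExperimentDesign, KineticModel, MeasurementSet,
                    MeasurementMatchError, SimulationFailure,
                    _integrate_piecewise, simulate)

DEFAULT_CUTOFF_RATIO = 1e-4


class AllZeroSensitivityError(ValueError):
    """No observable depends on any parameter: nothing can be estimated."""


@dataclass
class SensitivityTrajectory:
    """Raw observable sensitivities on a design's time grid.

    ``values[t, j, i]`` is dy_j/dtheta_i at sample time ``times[t]``.
    """

    times: np.ndarray
    values: np.ndarray
    obs_names: list[str]
    param_names: list[str]


@dataclass
class SensitivityBundle:
    """Scaled, stacked sensitivities with per-parameter influence scores."""

    stacked_matrix: pd.DataFrame   # N_D rows x parameter columns
    msqr: pd.Series                # root-mean-square score per parameter
    influential_mask: pd.Series    # bool per parameter
    cutoff_used: float

    @property
    def influential_params(self) -> list[str]:
        return list(self.msqr.index[self.influential_mask])

    @property
    def non_influential_params(self) -> list[str]:
        return list(self.msqr.index[~self.influential_mask])


def forward_sensitivities(model: KineticModel, design: ExperimentDesign,
                          theta, rtol: float = 1e-8, atol: float = 1e-10,
                          check_bounds: bool = True) -> SensitivityTrajectory:
    """Integrate the forward sensitivity equations for one experiment."""
    theta = np.asarray(theta, dtype=float)
    if check_bounds:
        model.check_bounds(theta)
    nx, npar = model.n_states, model.n_params
    f = model.rhs()
    jac = model.jacobians()
    zx = [0.0] * nx
    zu = [0.0] * len(model.input_names)
    x0 = np.asarray(model.init()(zx, list(theta), zu), dtype=float).ravel()
    X0 = np.asarray(jac["dx0dp"](zx, list(theta), zu), dtype=float).reshape(nx, npar)
    z0 = np.concatenate([x0, X0.ravel()])

    def rhs_fn(t, z, u):
        x = z[:nx]
        X = z[nx:].reshape(nx, npar)
        dx = np.asarray(f(list(x), list(theta), list(u)), dtype=float).ravel()
        Jx = np.asarray(jac["dfdx"](list(x), list(theta), list(u)),
                        dtype=float).reshape(nx, nx)
        Jp = np.asarray(jac["dfdp"](list(x), list(theta), list(u)),
                        dtype=float).reshape(nx, npar)
        return np.concatenate([dx, (Jx @ X + Jp).ravel()])

    times = design.sample_times
    traj = _integrate_piecewise(model, design, rhs_fn, z0, times, rtol, atol)
    ny = model.n_obs
    out = np.empty((len(times), ny, npar))
    for t in range(len(times)):
        x = traj[t, :nx]
        X = traj[t, nx:].reshape(nx, npar)
        Gx = np.asarray(jac["dgdx"](list(x), list(theta), zu),
                        dtype=float).reshape(ny, nx)
        Gp = np.asarray(jac["dgdp"](list(x), list(theta), zu),
                        dtype=float).reshape(ny, npar)
        out[t] = Gx @ X + Gp
    return SensitivityTrajectory(times, out, list(model.obs_names),
                                 list(model.param_names))


def finite_difference_sensitivities(model: KineticModel, design: ExperimentDesign,
                                    theta, rel_step: float = 1e-6,
                                    rtol: float = 1e-8, atol: float = 1e-10
                                    ) -> SensitivityTrajectory:
    """Central-difference sensitivities; fallback for black-box models."""
    theta = np.asarray(theta, dtype=float)
    times = design.sample_times
    out = np.empty((len(times), model.n_obs, model.n_params))
    for i in range(model.n_params):
        h = rel_step * max(abs(theta[i]), 1e-12)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        yp = simulate(model, design, tp, rtol, atol, check_bounds=False).observables
        ym = simulate(model, design, tm, rtol, atol, check_bounds=False).observables
        out[:, :, i] = (yp - ym) / (2 * h)
    return SensitivityTrajectory(times, out, list(model.obs_names),
                                 list(model.param_names))


def record_sensitivities(model: KineticModel,
                         designs: Sequence[ExperimentDesign],
                         data: MeasurementSet, theta,
                         method: str = "forward",
                         rtol: float = 1e-8, atol: float = 1e-10,
                         check_bounds: bool = True) -> pd.DataFrame:
    """Raw sensitivity of each measured record w.r.t. each parameter.

    Rows follow the canonical record order of ``data``; columns are the model
    parameters.
    """
    if isinstance(designs, ExperimentDesign):
        designs = [designs]
    fn = {"forward": forward_sensitivities,
          "fd": finite_difference_sensitivities}[method]
    kw = {} if method == "fd" else {"check_bounds": check_bounds}
    trajs = {d.experiment_id: fn(model, d, theta, rtol=rtol, atol=atol, **kw)
             for d in designs}
    raw = np.empty((data.n_records, model.n_params))
    for idx, row in enumerate(data.records.itertuples(index=False)):
        traj = trajs.get(row.experiment)
        if traj is None:
            raise MeasurementMatchError(
                f"record {idx}: no design for experiment {row.experiment!r}")
        ti = np.where(np.isclose(traj.times, row.time, rtol=0, atol=1e-9))[0]
        if len(ti) == 0:
            raise MeasurementMatchError(
                f"record {idx}: time {row.time} not in sensitivity grid")
        raw[idx] = traj.values[ti[0], traj.obs_names.index(row.observable)]
    return pd.DataFrame(raw, columns=model.param_names)


def scale_sensitivities(raw: pd.DataFrame, data: MeasurementSet) -> pd.DataFrame:
    """Weight each row by sqrt(w), matching the residual scaling."""
    if len(raw) != data.n_records:
        raise ValueError("raw sensitivity rows do not match measurement records")
    w = np.sqrt(data.records["weight"].to_numpy())
    return raw.mul(w, axis=0)


def msqr_scores(stacked: pd.DataFrame) -> pd.Series:
    """Root-mean-square of each parameter's scaled sensitivities over all
    N_D records: sqrt((1/N_D) * sum_j s~_ij^2)."""
    return np.sqrt((stacked ** 2).mean(axis=0))


def filter_influential(msqr: pd.Series, ratio: float = DEFAULT_CUTOFF_RATIO
                       ) -> tuple[pd.Series, float]:
    """Classify parameters as influential: score >= ratio * max(score).

    Parameters below the cutoff are practically non-identifiable
    (non-influential) and are dropped from the collinearity analysis.
    Borderline equality counts as influential.
    """
    if float(msqr.max()) <= 0.0:
        raise AllZeroSensitivityError(
            "all sensitivity scores are zero: no observable depends on any parameter")
    cutoff = ratio * float(msqr.max())
    return msqr >= cutoff, cutoff


def analyse_sensitivities(model, designs, data, theta, ratio=DEFAULT_CUTOFF_RATIO,
                          method: str = "forward", rtol: float = 1e-8,
                          atol: float = 1e-10, check_bounds: bool = True
                          ) -> SensitivityBundle:
    """Full sensitivity stage: raw -> scaled/stacked -> msqr -> influence mask."""
    raw = record_sensitivities(model, designs, data, theta, method=method,
                               rtol=rtol, atol=atol, check_bounds=check_bounds)
    stacked = scale_sensitivities(raw, data)
    scores = msqr_scores(stacked)
    mask, cutoff = filter_influential(scores, ratio)
    return SensitivityBundle(stacked, scores, mask, cutoff)
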