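"""Regularized weighted least-squares calibration with a hybrid
global/local optimizer.

The estimation problem is

    minimize   Q_LS(theta) + alpha * Gamma(theta)
    subject to theta_min <= theta <= theta_max

with Q_LS the weighted sum of squared residuals and Gamma the Tikhonov
penalty (theta - theta_ref)' W'W (theta - theta_ref).  A small alpha
(default 0.1) reflects weak prior knowledge: the penalty combats
ill-posedness and overfitting without being allowed to improve the fit —
a regularized solution should never reach a lower Q_LS than the
unregularized one.

The optimizer is a scatter-search-style hybrid: a Latin-hypercube initial
population, a reference set maintained by quality and diversity, pairwise
combination of its members, and periodic local refinement of the best point
with a bounded trust-region least-squares solve on the stacked residual
vector augmented with the regularization rows sqrt(alpha) * W (theta -
theta_ref) (keeping the Tikhonov term inside the least-squares structure).
Stopping is budget-based (objective evaluations), and everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import (ExperimentDesign, KineticModel, MeasurementSet,
                    SimulationFailure)

DEFAULT_ALPHA = 0.1
_FAIL_RESIDUAL = 1e6    # per-record residual substituted on integration failure


@dataclass
class CalibrationResult:
    """Estimates plus the convergence trace of the search."""

    theta_hat: np.ndarray
    q_ls: float
    penalty: float
    trace: list[tuple[int, float]]      # (evaluations, best objective so far)
    seed: int
    evaluations: int
    param_names: list[str]

    @property
    def total(self) -> float:
        return self.q_ls + self.penalty

    def summary(self) -> str:
        lines = ["Calibration result",
                 "==================",
                 f"objective (Q_LS + alpha*Gamma): {self.total:.6g}",
                 f"Q_LS:                           {self.q_ls:.6g}",
                 f"regularization penalty:         {self.penalty:.6g}",
                 f"objective evaluations:          {self.evaluations}",
                 f"seed:                           {self.seed}",
                 "",
                 f"{'parameter':<16}{'estimate':>14}"]
        for n, v in zip(self.param_names, self.theta_hat):
            lines.append(f"{n:<16}{v:>14.6g}")
        return "\n".join(lines)


@dataclass
class CalibrationProblem:
    """Bundles model, designs, data and the regularization setup.

    ``transform='log10'`` runs the search in log10 parameter space (useful
    for rate constants spanning decades); the penalty is always evaluated on
    the natural scale of theta.
    """

    model: KineticModel
    designs: Sequence[ExperimentDesign]
    data: MeasurementSet
    alpha: float = DEFAULT_ALPHA
    theta_ref: np.ndarray | None = None
    W: np.ndarray | None = None
    transform: str = "none"
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if isinstance(self.designs, ExperimentDesign):
            self.designs = [self.designs]
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.transform not in ("none", "log10"):
            raise ValueError("transform must be 'none' or 'log10'")
        bounds = self.model.bounds
        if self.theta_ref is None:
            ref = self.model.nominal
            if ref is None:
                ref = np.sqrt(bounds[:, 0] * bounds[:, 1]) if np.all(bounds[:, 0] > 0) \
                    else bounds.mean(axis=1)
            self.theta_ref = np.asarray(ref, dtype=float)
        else:
            self.theta_ref = np.asarray(self.theta_ref, dtype=float)
        if np.any(self.theta_ref < bounds[:, 0]) or np.any(self.theta_ref > bounds[:, 1]):
            raise ValueError("theta_ref must lie within the parameter bounds")
        if self.W is None:
            # relative penalty: deviations measured against |theta_ref|
            self.W = 1.0 / np.maximum(np.abs(self.theta_ref), 1e-8)
        self.W = np.atleast_1d(np.asarray(self.W, dtype=float))
        if self.W.ndim == 2:
            self.W = np.diag(self.W)
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        self._build_record_index()

    def _build_record_index(self) -> None:
        """Precompute record -> (design, time index, observable index) so the
        residual vector is a vectorized lookup after simulation."""
        by_id = {d.experiment_id: i for i, d in enumerate(self.designs)}
        rec = self.data.records
        nd = len(rec)
        self._rec_design = np.empty(nd, dtype=int)
        self._rec_t = np.empty(nd, dtype=int)
        self._rec_o = np.empty(nd, dtype=int)
        obs_index = {o: i for i, o in enumerate(self.model.obs_names)}
        for idx, row in enumerate(rec.itertuples(index=False)):
            di = by_id[row.experiment]
            times = self.designs[di].sample_times
            ti = np.where(np.isclose(times, row.time, rtol=0, atol=1e-9))[0]
            if len(ti) == 0:
                raise ValueError(f"record {idx}: time {row.time} is not a "
                                 f"sample time of {row.experiment!r}")
            self._rec_design[idx] = di
            self._rec_t[idx] = ti[0]
            self._rec_o[idx] = obs_index[row.observable]
        self._rec_sqrtw = np.sqrt(rec["weight"].to_numpy())
        self._rec_value = rec["value"].to_numpy()

    def _data_residuals(self, theta) -> np.ndarray:
        from .model import simulate
        ys = np.empty(len(self._rec_value))
        for di, d in enumerate(self.designs):
            mask = self._rec_design == di
            if not np.any(mask):
                continue
            obs = simulate(self.model, d, theta, self.rtol, self.atol,
                           check_bounds=False).observables
            ys[mask] = obs[self._rec_t[mask], self._rec_o[mask]]
        return self._rec_sqrtw * (ys - self._rec_value)

    # -- objective pieces --------------------------------------------------
    def regularization(self, theta) -> float:
        d = self.W * (np.asarray(theta, dtype=float) - self.theta_ref)
        return float(d @ d)

    def objective(self, theta) -> tuple[float, float, float]:
        """(total, Q_LS, Gamma) at theta; integration failures raise."""
        r = self._data_residuals(theta)
        qls = float(r @ r)
        gamma = self.regularization(theta)
        return qls + self.alpha * gamma, qls, gamma

    def stacked_residuals(self, theta) -> np.ndarray:
        """Data residuals plus sqrt(alpha)*W*(theta - theta_ref) rows."""
        r = self._data_residuals(theta)
        if self.alpha > 0:
            reg = np.sqrt(self.alpha) * self.W * (np.asarray(theta) - self.theta_ref)
            r = np.concatenate([r, reg])
        return r

    # -- search-space transform --------------------------------------------
    def _to_search(self, theta):
        return np.log10(theta) if self.transform == "log10" else np.asarray(theta, float)

    def _from_search(self, z):
        return 10.0 ** z if self.transform == "log10" else np.asarray(z, float)

    def _search_bounds(self):
        b = self.model.bounds
        if self.transform == "log10":
            if np.any(b[:, 0] <= 0):
                raise ValueError("log10 transform needs strictly positive bounds")
            return np.log10(b)
        return b

    # -- the hybrid estimator ------------------------------------------------
    def fit(self, seed: int = 0, budget: int = 5000, refset_size: int = 10,
            local_every: int = 3, pop_size: int | None = None
            ) -> CalibrationResult:
        """Scatter-search-style global loop with trust-region local refinement.

        ``budget`` counts objective evaluations (one per residual-vector
        computation, including those spent inside the local solver).
        """
        rng = np.random.default_rng(seed)
        n = self.model.n_params
        lb, ub = self._search_bounds().T
        if pop_size is None:
            pop_size = max(5 * n, 30)

        state = {"evals": 0, "best": np.inf, "trace": []}

        def evaluate(z):
            if state["evals"] >= budget:
                return np.inf
            theta = self._from_search(np.clip(z, lb, ub))
            state["evals"] += 1
            try:
                total, _, _ = self.objective(theta)
            except SimulationFailure:
                total = np.inf
            if total < state["best"]:
                state["best"] = total
                state["trace"].append((state["evals"], total))
            return total

        # diverse bounded initial population
        sampler = qmc.LatinHypercube(d=n, seed=rng)
        pop = qmc.scale(sampler.random(pop_size), lb, ub)
        if self.theta_ref is not None:
            pop[0] = np.clip(self._to_search(self.theta_ref), lb, ub)
        vals = np.array([evaluate(z) for z in pop])
        if not np.any(np.isfinite(vals)):
            raise SimulationFailure(
                "no initial population member could be simulated", float("nan"))

        # reference set: half by quality, half by diversity
        order = np.argsort(vals)
        n_quality = max(1, refset_size // 2)
        ref_idx = list(order[:n_quality])
        remaining = [i for i in order[n_quality:] if np.isfinite(vals[i])]
        while len(ref_idx) < min(refset_size, np.isfinite(vals).sum()) and remaining:
            chosen = pop[ref_idx]
            dists = [min(np.linalg.norm(pop[i] - c) for c in chosen) for i in remaining]
            pick = remaining.pop(int(np.argmax(dists)))
            ref_idx.append(pick)
        ref = [pop[i].copy() for i in ref_idx]
        ref_vals = [vals[i] for i in ref_idx]

        def local_refine(z0):
            """Bounded trust-region least squares on the stacked residuals."""
            remaining = budget - state["evals"]
            if remaining <= 2 * n:
                return z0, None

            def fun(z):
                theta = self._from_search(np.clip(z, lb, ub))
                state["evals"] += 1
                try:
                    r = self.stacked_residuals(theta)
                except SimulationFailure:
                    r = np.full(self.data.n_records + (n if self.alpha > 0 else 0),
                                _FAIL_RESIDUAL)
                total = float(r @ r)
                if total < state["best"]:
                    state["best"] = total
                    state["trace"].append((state["evals"], total))
                return r

            max_nfev = max(2, min(50 * n, remaining // (n + 1)))
            try:
                sol = least_squares(fun, z0, bounds=(lb, ub), method="trf",
                                    max_nfev=max_nfev, diff_step=1e-6)
                return sol.x, float(sol.cost * 2)
            except Exception:
                return z0, None

        iteration = 0
        while state["evals"] < budget:
            iteration += 1
            improved = False
            # pairwise combination of reference-set members
            m = len(ref)
            for i in range(m):
                if state["evals"] >= budget:
                    break
                j = int(rng.integers(m))
                if j == i:
                    j = (i + 1) % m
                lam = rng.uniform(-0.3, 1.3)
                child = ref[i] + lam * (ref[j] - ref[i])
                child += rng.normal(0, 0.01, n) * (ub - lb)
                child = np.clip(child, lb, ub)
                v = evaluate(child)
                worst = int(np.argmax(ref_vals))
                if v < ref_vals[worst]:
                    ref[worst] = child
                    ref_vals[worst] = v
                    improved = True
            # periodic local refinement of the best member
            if iteration % local_every == 0 or not improved:
                b = int(np.argmin(ref_vals))
                z_new, v_new = local_refine(ref[b])
                if v_new is not None and v_new < ref_vals[b]:
                    ref[b], ref_vals[b] = np.clip(z_new, lb, ub), v_new
            if not np.isfinite(min(ref_vals)):
                # restart diversification if everything failed
                pop = qmc.scale(sampler.random(pop_size), lb, ub)
                ref = [pop[i].copy() for i in range(min(refset_size, pop_size))]
                ref_vals = [evaluate(z) for z in ref]

        b = int(np.argmin(ref_vals))
        theta_hat = self._from_search(np.clip(ref[b], lb, ub))
        try:
            total, qls, gamma = self.objective(theta_hat)
        except SimulationFailure:
            qls, gamma = float("inf"), float("inf")
        trace = state["trace"]
        return CalibrationResult(theta_hat, qls, self.alpha * gamma, trace,
                                 seed, state["evals"], list(self.model.param_names))


def hybrid_estimate(problem: CalibrationProblem, seed: int = 0,
                    budget: int = 5000, **kw) -> CalibrationResult:
    """Functional alias for :meth:`CalibrationProblem.fit`."""
    return problem.fit(seed=seed, budget=budget, **kw)
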