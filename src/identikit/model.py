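"""ODE kinetic models, experimental designs and measurement tables.

A :class:`KineticModel` is the standard state-space description used for
biochemical reaction networks,

    dx/dt = f(x, u, theta),    y = g(x, theta),    x(t0) = x0(theta),

with states ``x`` (typically concentrations), piecewise-constant inputs
``u(t)`` (stimuli), positive kinetic parameters ``theta`` and observation
functions ``g`` mapping states to the measurable outputs.  Right-hand
sides, observables and initial conditions are held symbolically (sympy)
so that exact partial derivatives are available to the sensitivity and
graph modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import sympy as sp
import yaml
from scipy.integrate import solve_ivp


class ModelSpecError(ValueError):
    """The model description is inconsistent (unknown symbols, bad bounds...)."""


class SimulationFailure(RuntimeError):
    """The integrator failed; carries the time at which integration stopped."""

    def __init__(self, message: str, failing_time: float):
        super().__init__(f"{message} (integration failed near t={failing_time:g})")
        self.failing_time = failing_time


class MeasurementMatchError(KeyError):
    """A measurement record has no matching simulated point."""


_ALLOWED_FUNCS = {"exp": sp.exp, "log": sp.log, "pow": sp.Pow, "sqrt": sp.sqrt,
                  "sin": sp.sin, "cos": sp.cos, "tanh": sp.tanh}


def parse_expression(text: str, symbols: Mapping[str, sp.Symbol]) -> sp.Expr:
    """Parse an expression string over declared names.

    Grammar: ``+ - * / ^ ** exp log pow sqrt`` and parentheses; ``^`` is
    accepted as power.  Any free symbol that is not a declared state,
    parameter or input raises :class:`ModelSpecError`.
    """
    src = str(text).replace("^", "**")
    local = dict(symbols)
    local.update(_ALLOWED_FUNCS)
    try:
        expr = sp.sympify(src, locals=local, rational=False)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelSpecError(f"cannot parse expression {text!r}: {exc}") from exc
    unknown = {str(s) for s in expr.free_symbols} - set(symbols)
    if unknown:
        raise ModelSpecError(
            f"expression {text!r} references undeclared symbols {sorted(unknown)}")
    return expr


@dataclass
class KineticModel:
    """Symbolic ODE model: states, parameters, inputs, dynamics, observations.

    Parameters
    ----------
    state_names, param_names, input_names
        Identifiers; must be unique across all three categories.
    rhs_exprs
        One sympy expression per state (the vector field ``f``).
    obs_names, obs_exprs
        Observable identifiers and their expressions in states/parameters.
    init_exprs
        One expression per state for ``x0(theta)``, in parameters only.
    bounds
        ``(N_theta, 2)`` array of ``(theta_min, theta_max)`` rows.
    nominal
        Optional nominal parameter vector (used by fixtures and as a
        default reference point).
    """

    state_names: list[str]
    param_names: list[str]
    input_names: list[str]
    rhs_exprs: list[sp.Expr]
    obs_names: list[str]
    obs_exprs: list[sp.Expr]
    init_exprs: list[sp.Expr]
    bounds: np.ndarray
    nominal: np.ndarray | None = None
    _compiled: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float).reshape(len(self.param_names), 2)
        if self.nominal is not None:
            self.nominal = np.asarray(self.nominal, dtype=float)
        self._canonicalize_symbols()
        self._validate()

    def _canonicalize_symbols(self) -> None:
        """Rebind expression symbols by name to the model's canonical symbols.

        Callers may build expressions with differently-flavoured sympy symbols
        (assumptions change symbol identity even at equal names); derivatives
        against the canonical symbols would then silently vanish.
        """
        syms = self.symbols()

        def canon(expr):
            expr = sp.sympify(expr)
            sub = {s: syms[str(s)] for s in expr.free_symbols if str(s) in syms}
            return expr.xreplace(sub)

        self.rhs_exprs = [canon(e) for e in self.rhs_exprs]
        self.obs_exprs = [canon(e) for e in self.obs_exprs]
        self.init_exprs = [canon(e) for e in self.init_exprs]

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        names = self.state_names + self.param_names + self.input_names
        if len(set(names)) != len(names):
            raise ModelSpecError("state/parameter/input names must be unique")
        if len(set(self.obs_names)) != len(self.obs_names):
            raise ModelSpecError("observable names must be unique")
        if len(self.rhs_exprs) != self.n_states:
            raise ModelSpecError("need one ODE right-hand side per state")
        if len(self.init_exprs) != self.n_states:
            raise ModelSpecError("need one initial-condition expression per state")
        if len(self.obs_exprs) != len(self.obs_names):
            raise ModelSpecError("observable names/expressions length mismatch")
        declared = set(names)
        for expr in list(self.rhs_exprs) + list(self.obs_exprs):
            bad = {str(s) for s in expr.free_symbols} - declared
            if bad:
                raise ModelSpecError(f"undeclared symbols {sorted(bad)} in {expr}")
        for expr in self.init_exprs:
            bad = {str(s) for s in expr.free_symbols} - set(self.param_names)
            if bad:
                raise ModelSpecError(
                    f"initial conditions may only use parameters; got {sorted(bad)} in {expr}")
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
            raise ModelSpecError("parameter bounds must satisfy min <= max")

    # -- basic properties -----------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_obs(self) -> int:
        return len(self.obs_names)

    def symbols(self) -> dict[str, sp.Symbol]:
        return {n: sp.Symbol(n, real=True)
                for n in self.state_names + self.param_names + self.input_names}

    # -- compiled callables ----------------------------------------------
    def _lambdify(self, key: str, exprs) -> Callable:
        """Compile (and cache) a callable of (x, theta, u) from expressions."""
        if key not in self._compiled:
            syms = self.symbols()
            x = [syms[n] for n in self.state_names]
            th = [syms[n] for n in self.param_names]
            u = [syms[n] for n in self.input_names]
            fn = sp.lambdify((x, th, u), exprs, modules="numpy")
            self._compiled[key] = fn
        return self._compiled[key]

    def rhs(self) -> Callable:
        return self._lambdify("f", sp.Matrix(self.rhs_exprs))

    def obs(self) -> Callable:
        return self._lambdify("g", sp.Matrix(self.obs_exprs))

    def init(self) -> Callable:
        fn = self._lambdify("x0", sp.Matrix(self.init_exprs))
        return fn

    def jacobians(self) -> dict[str, Callable]:
        """Compiled Jacobians df/dx, df/dtheta, dg/dx, dg/dtheta, dx0/dtheta."""
        if "jac" not in self._compiled:
            syms = self.symbols()
            x = sp.Matrix([syms[n] for n in self.state_names])
            th = sp.Matrix([syms[n] for n in self.param_names])
            f = sp.Matrix(self.rhs_exprs)
            g = sp.Matrix(self.obs_exprs)
            x0 = sp.Matrix(self.init_exprs)
            mats = {
                "dfdx": f.jacobian(x), "dfdp": f.jacobian(th),
                "dgdx": g.jacobian(x), "dgdp": g.jacobian(th),
                "dx0dp": x0.jacobian(th),
            }
            if self.input_names:
                us = sp.Matrix([syms[n] for n in self.input_names])
                mats["dfdu"] = f.jacobian(us)
            args = ([syms[n] for n in self.state_names],
                    [syms[n] for n in self.param_names],
                    [syms[n] for n in self.input_names])
            self._compiled["jac"] = {k: sp.lambdify(args, m, modules="numpy")
                                     for k, m in mats.items()}
        return self._compiled["jac"]

    def check_bounds(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ModelSpecError(
                f"theta has shape {theta.shape}, expected ({self.n_params},)")
        if np.any(theta < self.bounds[:, 0]) or np.any(theta > self.bounds[:, 1]):
            raise ModelSpecError("theta outside declared parameter bounds")

    # -- YAML I/O ---------------------------------------------------------
    @classmethod
    def from_yaml(cls, path_or_text) -> "KineticModel":
        """Load a model from a YAML document.

        Blocks: ``states``, ``parameters`` (name/min/max/nominal), ``inputs``,
        ``odes`` (state -> expression), ``observables`` (name -> expression),
        ``initial_conditions`` (state -> expression in parameters).
        """
        text = path_or_text
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        doc = yaml.safe_load(text)
        states = list(doc["states"])
        params = [p["name"] for p in doc["parameters"]]
        inputs = list(doc.get("inputs", []) or [])
        bounds = np.array([[p["min"], p["max"]] for p in doc["parameters"]], float)
        nominal = None
        if all("nominal" in p for p in doc["parameters"]):
            nominal = np.array([p["nominal"] for p in doc["parameters"]], float)
        syms = {n: sp.Symbol(n, real=True) for n in states + params + inputs}
        psyms = {n: syms[n] for n in params}
        rhs = [parse_expression(doc["odes"][s], syms) for s in states]
        obs_names = list(doc["observables"])
        obs = [parse_expression(doc["observables"][o], syms) for o in obs_names]
        init = [parse_expression(doc["initial_conditions"][s], psyms) for s in states]
        return cls(states, params, inputs, rhs, obs_names, obs, init, bounds, nominal)

    def to_yaml(self, path=None) -> str:
        doc = {
            "states": list(self.state_names),
            "parameters": [
                {"name": n, "min": float(lo), "max": float(hi)}
                for n, (lo, hi) in zip(self.param_names, self.bounds)
            ],
            "inputs": list(self.input_names),
            "odes": {s: str(e) for s, e in zip(self.state_names, self.rhs_exprs)},
            "observables": {o: str(e) for o, e in zip(self.obs_names, self.obs_exprs)},
            "initial_conditions": {s: str(e)
                                   for s, e in zip(self.state_names, self.init_exprs)},
        }
        if self.nominal is not None:
            for p, v in zip(doc["parameters"], self.nominal):
                p["nominal"] = float(v)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class ExperimentDesign:
    """One experiment: stimulus schedule, horizon, observed outputs, sampling.

    ``stimulus`` maps each input name to a sorted list of ``(t_start, value)``
    breakpoints defining a piecewise-constant signal (value holds from
    ``t_start`` until the next breakpoint).
    """

    experiment_id: str
    t0: float
    tf: float
    sample_times: np.ndarray
    observed_outputs: list[str]
    stimulus: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if not self.observed_outputs:
            raise ModelSpecError("observed_outputs must be non-empty")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ModelSpecError("sample_times must be strictly increasing")
        if self.sample_times[0] < self.t0 or self.sample_times[-1] > self.tf:
            raise ModelSpecError("sample_times must lie inside [t0, tf]")
        for name, sched in self.stimulus.items():
            ts = [t for t, _ in sched]
            if sorted(ts) != ts:
                raise ModelSpecError(f"stimulus breakpoints for {name} must be sorted")

    def breakpoints(self) -> np.ndarray:
        """All interior stimulus switch times, sorted and unique."""
        ts = {t for sched in self.stimulus.values() for t, _ in sched
              if self.t0 < t < self.tf}
        return np.array(sorted(ts))

    def input_values(self, t: float, input_names: Sequence[str]) -> np.ndarray:
        """Piecewise-constant input vector at time t (left-continuous holds)."""
        out = np.zeros(len(input_names))
        for i, name in enumerate(input_names):
            val = 0.0
            for tb, v in self.stimulus.get(name, []):
                if tb <= t:
                    val = v
                else:
                    break
            out[i] = val
        return out


class MeasurementSet:
    """Measurement records: (experiment, observable, time, value, weight).

    The canonical record order is the stored row order; the residual vector,
    the stacked sensitivity matrix and ``N_D`` all follow it.
    """

    COLUMNS = ["experiment", "observable", "time", "value", "weight"]

    def __init__(self, records: pd.DataFrame):
        df = pd.DataFrame(records).reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ModelSpecError(f"measurement table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        df["time"] = df["time"].astype(float)
        df["value"] = df["value"].astype(float)
        df["weight"] = df["weight"].astype(float)
        if not np.all(np.isfinite(df["weight"])) or np.any(df["weight"] < 0):
            raise ModelSpecError("weights must be finite and non-negative")
        self.records = df

    @property
    def n_records(self) -> int:
        """Total number of data points across all experiments (N_D)."""
        return len(self.records)

    @classmethod
    def from_csv(cls, path, sep=None) -> "MeasurementSet":
        """Read delimited text with header experiment,observable,time,value
        and either a ``weight`` or a ``sigma`` column (w = 1/sigma^2)."""
        df = pd.read_csv(path, sep=sep, engine="python")
        if "sigma" in df.columns and "weight" not in df.columns:
            df["weight"] = 1.0 / df["sigma"].astype(float) ** 2
        return cls(df)

    def to_csv(self, path, sep=",") -> None:
        self.records.to_csv(path, sep=sep, index=False)

    def validate_against(self, designs: Sequence[ExperimentDesign]) -> None:
        """Every record must match a declared (experiment, time) design point."""
        by_id = {d.experiment_id: d for d in designs}
        for idx, row in self.records.iterrows():
            d = by_id.get(row["experiment"])
            if d is None:
                raise MeasurementMatchError(
                    f"record {idx}: unknown experiment {row['experiment']!r}")
            if row["observable"] not in d.observed_outputs:
                raise MeasurementMatchError(
                    f"record {idx}: observable {row['observable']!r} not observed "
                    f"in experiment {d.experiment_id!r}")
            if not np.any(np.isclose(d.sample_times, row["time"], rtol=0, atol=1e-9)):
                raise MeasurementMatchError(
                    f"record {idx}: time {row['time']} is not a sample time of "
                    f"experiment {d.experiment_id!r}")


@dataclass
class SimulationResult:
    """Trajectories at the design's sample times."""

    times: np.ndarray
    states: np.ndarray        # (n_times, N_x)
    observables: np.ndarray   # (n_times, N_y)
    state_names: list[str]
    obs_names: list[str]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[:, self.obs_names.index(name)]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.state_names.index(name)]


def _integrate_piecewise(model: KineticModel, design: ExperimentDesign,
                         rhs_fn, y0: np.ndarray, eval_times: np.ndarray,
                         rtol: float, atol: float) -> np.ndarray:
    """Integrate a (possibly augmented) system, restarting at every stimulus
    breakpoint so that discontinuous inputs are handled exactly."""
    edges = np.concatenate([[design.t0], design.breakpoints(), [design.tf]])

    def guarded(t, z, u):
        # fail fast on divergence: LSODA can stall indefinitely on NaN/Inf.
        # A single fused sum is cheap; mixed +/-inf sums to NaN, so any
        # non-finite entry makes the total non-finite.
        dz = rhs_fn(t, z, u)
        if not math.isfinite(float(abs(dz).sum() + abs(z).sum())):
            raise SimulationFailure("non-finite state or derivative", float(t))
        return dz

    out = np.empty((len(eval_times), len(y0)))
    filled = np.zeros(len(eval_times), dtype=bool)
    y = np.asarray(y0, dtype=float)
    at_t0 = np.isclose(eval_times, design.t0, rtol=0, atol=1e-12)
    out[at_t0] = y
    filled |= at_t0
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        # constant input over (a, b]; evaluated just inside the segment
        u = design.input_values(a + 1e-12 * max(1.0, abs(a)), model.input_names)
        mask = (~filled) & (eval_times > a) & (eval_times <= b + 1e-12)
        seg_times = eval_times[mask]
        t_eval = np.unique(np.concatenate([seg_times, [b]]))
        sol = solve_ivp(lambda t, z: guarded(t, z, u), (a, b), y, method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationFailure(sol.message, float(sol.t[-1]) if len(sol.t) else a)
        if not np.all(np.isfinite(sol.y)):
            bad = np.where(~np.isfinite(sol.y).all(axis=0))[0]
            raise SimulationFailure("non-finite state", float(sol.t[bad[0]]))
        for i, t in enumerate(sol.t):
            hit = mask & np.isclose(eval_times, t, rtol=0, atol=1e-12)
            out[hit] = sol.y[:, i]
            filled |= hit
        y = sol.y[:, -1]
    if not np.all(filled):
        missing = eval_times[~filled]
        raise SimulationFailure("sample time not reached", float(missing[0]))
    return out


def simulate(model: KineticModel, design: ExperimentDesign, theta,
             rtol: float = 1e-8, atol: float = 1e-10,
             check_bounds: bool = True) -> SimulationResult:
    """Solve the ODEs over [t0, tf] and return x and y at the sample times.

    Integration restarts at every stimulus breakpoint.  A solver failure
    raises :class:`SimulationFailure` carrying the failing time; NaNs never
    propagate silently.
    """
    theta = np.asarray(theta, dtype=float)
    if check_bounds:
        model.check_bounds(theta)
    f = model.rhs()
    zx = [0.0] * model.n_states
    zu = [0.0] * len(model.input_names)
    x0 = np.asarray(model.init()(zx, list(theta), zu), dtype=float).ravel()
    g = model.obs()

    th = list(theta)

    def rhs_fn(t, x, u):
        return np.asarray(f(x, th, u), dtype=float).ravel()

    times = design.sample_times
    states = _integrate_piecewise(model, design, rhs_fn, x0, times, rtol, atol)
    obs = np.empty((len(times), model.n_obs))
    for i, t in enumerate(times):
        obs[i] = np.asarray(g(list(states[i]), list(theta), zu), dtype=float).ravel()
    return SimulationResult(times, states, obs, model.state_names, model.obs_names)


def residuals(model: KineticModel, designs: Sequence[ExperimentDesign],
              data: MeasurementSet, theta, rtol: float = 1e-8,
              atol: float = 1e-10, check_bounds: bool = True) -> np.ndarray:
    """Weighted residual vector r_i = sqrt(w_i) * (y_i(theta) - y~_i).

    ``sum(r**2)`` is the weighted least-squares cost Q_LS(theta).  Record
    order follows the canonical order of ``data``.
    """
    if isinstance(designs, ExperimentDesign):
        designs = [designs]
    sims = {d.experiment_id: simulate(model, d, theta, rtol, atol, check_bounds)
            for d in designs}
    res = np.empty(data.n_records)
    for idx, row in enumerate(data.records.itertuples(index=False)):
        sim = sims.get(row.experiment)
        if sim is None:
            raise MeasurementMatchError(
                f"record {idx}: no design for experiment {row.experiment!r}")
        ti = np.where(np.isclose(sim.times, row.time, rtol=0, atol=1e-9))[0]
        if len(ti) == 0:
            raise MeasurementMatchError(
                f"record {idx}: time {row.time} not simulated for "
                f"experiment {row.experiment!r}")
        if row.observable not in model.obs_names:
            raise MeasurementMatchError(
                f"record {idx}: unknown observable {row.observable!r}")
        y = sim.observables[ti[0], model.obs_names.index(row.observable)]
        res[idx] = math.sqrt(row.weight) * (y - row.value)
    return res


def q_ls(model, designs, data, theta, **kw) -> float:
    """Weighted sum-of-squares cost at theta."""
    r = residuals(model, designs, data, theta, **kw)
    return float(r @ r)
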