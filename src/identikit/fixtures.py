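"""Synthetic test inputs with known identifiability structure.

Two kinds of fixtures are provided.  *Planted matrices* are normalized
sensitivity matrices built directly in column space: a block of mutually
orthogonal columns (a random rotation of the canonical basis) plus planted
linear-dependence groups with an exactly controlled collinearity index, so
collinearity, subset-selection and enumeration code can be exercised without
any ODEs.  *Fixture models* are small kinetic models with a known
ground-truth classification; their datasets follow the standard protocol for
testing calibration methods — simulate with nominal parameters, sample the
trajectories at equidistant time points, and add normally distributed noise
with weights w = 1/sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp

from .collinearity import NormalizedSensitivityMatrix
from .model import ExperimentDesign, KineticModel, MeasurementSet, simulate


@dataclass
class PlantedMatrixSpec:
    """Recipe for a normalized sensitivity matrix with planted structure.

    ``planted_groups`` is a list of ``(size, target_ci)`` pairs.  A group of
    size g consumes g-1 of the orthogonal columns and appends one extra
    column that is a unit combination of them plus a controlled orthogonal
    residual, so that the g-set has exactly the requested CI
    (``target_ci = inf`` plants an exact linear dependence).  Total columns:
    ``orthogonal_count + len(planted_groups)``.
    """

    n_rows: int
    orthogonal_count: int
    planted_groups: list[tuple[int, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for size, ci in self.planted_groups:
            if size < 2:
                raise ValueError("planted groups need size >= 2")
            if ci < 1:
                raise ValueError("target CI must be >= 1")
        needed = self.orthogonal_count + len(self.planted_groups)
        base_needed = self.orthogonal_count + len(self.planted_groups)
        if self.n_rows < base_needed:
            raise ValueError(
                f"n_rows={self.n_rows} too small; need >= {needed} "
                "orthonormal directions (orthogonal columns + one residual per group)")
        used = sum(s - 1 for s, _ in self.planted_groups)
        if used > self.orthogonal_count:
            raise ValueError("planted groups reference more columns than available")


@dataclass
class PlantedMatrix:
    """The generated matrix plus its ground-truth answers."""

    nsm: NormalizedSensitivityMatrix
    group_members: list[tuple[str, ...]]    # members of each planted group
    group_ci: list[float]                   # their exact collinearity indices
    spec: PlantedMatrixSpec


def planted_matrix(spec: PlantedMatrixSpec) -> PlantedMatrix:
    """Build the matrix described by ``spec`` (reproducible by seed).

    For a pair with target CI c the new column v satisfies <u, v> = rho with
    rho = 1 - 1/c^2, giving Gram eigenvalues 1 +/- rho and hence
    CI = 1/sqrt(1-rho) = c exactly.  For a group of size g the extra column
    is sqrt(1-d^2) * w + d * r with w the unit mean of the g-1 base columns
    and r a fresh orthonormal residual; the group's smallest Gram eigenvalue
    is 1 - sqrt(1-d^2), so d^2 = 1 - (1 - 1/c^2)^2 hits the target exactly.
    """
    rng = np.random.default_rng(spec.seed)
    total_dirs = spec.orthogonal_count + len(spec.planted_groups)
    A = rng.normal(size=(spec.n_rows, total_dirs))
    Q, _ = np.linalg.qr(A)
    # random rotation of canonical basis: columns of Q are orthonormal
    base = Q[:, :spec.orthogonal_count]
    residuals = Q[:, spec.orthogonal_count:]

    cols = [base[:, i] for i in range(spec.orthogonal_count)]
    names = [f"p{i + 1}" for i in range(spec.orthogonal_count)]
    group_members, group_ci = [], []
    next_base = 0
    for gi, (size, target) in enumerate(spec.planted_groups):
        g = size - 1
        members = list(range(next_base, next_base + g))
        next_base += g
        r = residuals[:, gi]
        if g == 1:
            rho = 1.0 if np.isinf(target) else 1.0 - 1.0 / target ** 2
            v = rho * cols[members[0]] + np.sqrt(max(0.0, 1.0 - rho ** 2)) * r
            ci_exact = target if np.isfinite(target) else float("inf")
        else:
            w = cols[members[0]].copy()
            for m in members[1:]:
                w = w + cols[m]
            w /= np.linalg.norm(w)
            if np.isinf(target):
                d = 0.0
            else:
                d = np.sqrt(max(0.0, 1.0 - (1.0 - 1.0 / target ** 2) ** 2))
            v = np.sqrt(1.0 - d ** 2) * w + d * r
            ci_exact = target if np.isfinite(target) else float("inf")
        v = v / np.linalg.norm(v)
        cols.append(v)
        vname = f"p{len(cols)}"
        names.append(vname)
        group_members.append(tuple(names[m] for m in members) + (vname,))
        group_ci.append(ci_exact)
    mat = np.column_stack(cols)
    return PlantedMatrix(NormalizedSensitivityMatrix(mat, names),
                         group_members, group_ci, spec)


# -- kinetic model fixtures --------------------------------------------------

def _expr(text, names):
    syms = {n: sp.Symbol(n, real=True) for n in names}
    return sp.sympify(text.replace("^", "**"), locals=syms)


@dataclass
class Fixture:
    """A catalogue entry: model, design, nominal theta and default noise."""

    name: str
    model: KineticModel
    design: ExperimentDesign
    theta: np.ndarray
    noise_sd: float
    ground_truth: dict


def linear_decay() -> Fixture:
    """One-state exponential decay dx/dt = -k*x, x(0)=1, y=x; k identifiable."""
    names = ["x1", "k"]
    model = KineticModel(
        state_names=["x1"], param_names=["k"], input_names=[],
        rhs_exprs=[_expr("-k*x1", names)],
        obs_names=["y1"], obs_exprs=[_expr("x1", names)],
        init_exprs=[sp.Integer(1)],
        bounds=np.array([[1e-3, 10.0]]), nominal=np.array([1.0]))
    design = ExperimentDesign("e1", 0.0, 5.0, np.linspace(0.25, 5.0, 20), ["y1"])
    return Fixture("linear_decay", model, design, np.array([1.0]), 0.05,
                   {"identifiable": ["k"]})


def product2() -> Fixture:
    """dx/dt = -p1*p2*x: only the product p1*p2 is identifiable (a structural
    ridge along p1*p2 = const)."""
    names = ["x1", "p1", "p2"]
    model = KineticModel(
        state_names=["x1"], param_names=["p1", "p2"], input_names=[],
        rhs_exprs=[_expr("-p1*p2*x1", names)],
        obs_names=["y1"], obs_exprs=[_expr("x1", names)],
        init_exprs=[sp.Integer(1)],
        bounds=np.array([[0.1, 10.0], [0.1, 10.0]]),
        nominal=np.array([1.0, 1.0]))
    design = ExperimentDesign("e1", 0.0, 5.0, np.linspace(0.25, 5.0, 20), ["y1"])
    return Fixture("product2", model, design, np.array([1.0, 1.0]), 0.05,
                   {"identifiable_combination": "p1*p2"})


def cascade6() -> Fixture:
    """Three-state cascade with six parameters and planted structure.

        dx1/dt = -(k1 + k2) * x1          # k1, k2 enter only through the sum
        dx2/dt = k3 * x1 - k4 * x2
        dx3/dt = k5 * (x2 - x3)           # x3 unobserved dead end
        y1 = x1,  y2 = x2 + k6            # k6: measurement background

    Ground truth: k5 is non-influential (it only moves the unobserved x3);
    k1 and k2 form an exactly collinear pair (identical sensitivity columns);
    the largest identifiable subset has size 4 — {k3, k4, k6} plus exactly
    one member of the pair.
    """
    names = ["x1", "x2", "x3", "k1", "k2", "k3", "k4", "k5", "k6"]
    model = KineticModel(
        state_names=["x1", "x2", "x3"],
        param_names=["k1", "k2", "k3", "k4", "k5", "k6"],
        input_names=[],
        rhs_exprs=[_expr("-(k1 + k2)*x1", names),
                   _expr("k3*x1 - k4*x2", names),
                   _expr("k5*(x2 - x3)", names)],
        obs_names=["y1", "y2"],
        obs_exprs=[_expr("x1", names), _expr("x2 + k6", names)],
        init_exprs=[sp.Integer(1), sp.Integer(0), sp.Integer(0)],
        bounds=np.array([[0.05, 5.0]] * 6),
        nominal=np.array([0.4, 0.6, 0.8, 0.5, 0.7, 1.2]))
    design = ExperimentDesign("e1", 0.0, 10.0, np.linspace(0.5, 10.0, 20),
                              ["y1", "y2"])
    return Fixture("cascade6", model, design,
                   np.array([0.4, 0.6, 0.8, 0.5, 0.7, 1.2]), 0.05,
                   {"non_influential": ["k5"],
                    "collinear_pair": ("k1", "k2"),
                    "largest_size": 4,
                    "always_identifiable": ["k3", "k4", "k6"]})


CATALOGUE = {"linear_decay": linear_decay, "product2": product2,
             "cascade6": cascade6}


def get_fixture(name: str) -> Fixture:
    try:
        return CATALOGUE[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(CATALOGUE)}") from None


def design_with_sampling(design: ExperimentDesign, n_times: int) -> ExperimentDesign:
    """Same experiment with n_times equidistant sample points in (t0, tf]."""
    times = np.linspace(design.t0, design.tf, n_times + 1)[1:]
    return ExperimentDesign(design.experiment_id, design.t0, design.tf,
                            times, design.observed_outputs, design.stimulus)


def make_dataset(fixture: Fixture, noise_sd: float | None = None,
                 n_times: int | None = None, seed: int = 0) -> MeasurementSet:
    """Noisy dataset from a fixture: equidistant sampling, additive
    N(0, sd^2) noise, weights 1/sd^2 (unit weights for noiseless data).

    The design actually sampled is attached as ``.design_used`` on the
    returned measurement set (it differs from the fixture's default design
    when ``n_times`` is given).
    """
    model, design = fixture.model, fixture.design
    if noise_sd is None:
        noise_sd = fixture.noise_sd
    if n_times is not None:
        design = design_with_sampling(design, n_times)
    rng = np.random.default_rng(seed)
    sim = simulate(model, design, fixture.theta)
    w = 1.0 / noise_sd ** 2 if noise_sd > 0 else 1.0
    rows = []
    for obs in design.observed_outputs:
        y = sim.observable(obs)
        noise = rng.normal(0.0, noise_sd, len(y)) if noise_sd > 0 else 0.0
        for t, v in zip(sim.times, y + noise):
            rows.append((design.experiment_id, obs, t, v, w))
    ms = MeasurementSet(pd.DataFrame(rows, columns=MeasurementSet.COLUMNS))
    ms.design_used = design
    return ms
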