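"""Model representation, simulation and residuals."""

import numpy as np
import pandas as pd
import pytest
import sympy as sp

import identikit as ik
from identikit.model import (ExperimentDesign, KineticModel, MeasurementSet,
                             MeasurementMatchError, ModelSpecError)


def tiny_model(rhs="-k*x1", obs="x1", init="1", bounds=(1e-3, 10.0)):
    names = {"x1": sp.Symbol("x1"), "k": sp.Symbol("k")}
    return KineticModel(
        state_names=["x1"], param_names=["k"], input_names=[],
        rhs_exprs=[sp.sympify(rhs, locals=names)],
        obs_names=["y1"], obs_exprs=[sp.sympify(obs, locals=names)],
        init_exprs=[sp.sympify(init, locals={"k": names["k"]})],
        bounds=np.array([bounds]))


def design(times, t0=0.0, tf=None):
    times = np.asarray(times, float)
    return ExperimentDesign("e1", t0, tf if tf is not None else times[-1],
                            times, ["y1"])


class TestSimulate:
    def test_linear_decay_closed_form(self):
        sim = ik.simulate(tiny_model(), design([0.5, 1.0, 2.0]), [1.0])
        assert sim.observable("y1")[1] == pytest.approx(np.exp(-1.0), abs=1e-6)
        np.testing.assert_allclose(sim.observable("y1"),
                                   np.exp(-np.array([0.5, 1.0, 2.0])), atol=1e-6)

    def test_constant_dynamics(self):
        m = tiny_model(rhs="0", init="k")   # x0 = c, dx/dt = 0
        sim = ik.simulate(m, design([1.0, 3.0, 5.0]), [2.5])
        np.testing.assert_allclose(sim.observable("y1"), 2.5, rtol=1e-12)

    def test_observable_algebraic_map(self):
        m = tiny_model(obs="2*x1")
        sim = ik.simulate(m, design([1.0]), [1.0])
        assert sim.observable("y1")[0] == pytest.approx(2 * np.exp(-1.0), abs=1e-6)

    def test_deterministic_bitwise(self, cascade):
        a = ik.simulate(cascade.model, cascade.design, cascade.theta)
        b = ik.simulate(cascade.model, cascade.design, cascade.theta)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.observables, b.observables)

    def test_tolerance_self_consistency(self, cascade):
        coarse = ik.simulate(cascade.model, cascade.design, cascade.theta,
                             rtol=1e-6, atol=1e-8)
        fine = ik.simulate(cascade.model, cascade.design, cascade.theta,
                           rtol=1e-7, atol=1e-9)
        assert np.abs(coarse.states - fine.states).max() < 1e-6

    def test_theta_out_of_bounds_rejected(self):
        with pytest.raises(ModelSpecError):
            ik.simulate(tiny_model(), design([1.0]), [100.0])

    def test_blowup_reports_failing_time(self):
        m = tiny_model(rhs="k*x1^3", bounds=(0.1, 1e6))
        with pytest.raises(ik.SimulationFailure) as exc:
            ik.simulate(m, design([5.0, 50.0], tf=50.0), [1e5])
        assert np.isfinite(exc.value.failing_time)

    def test_piecewise_input_restarts(self):
        """Zero-order-hold input: x integrates the step stimulus exactly."""
        names = {"x1": sp.Symbol("x1"), "k": sp.Symbol("k"), "u1": sp.Symbol("u1")}
        m = KineticModel(["x1"], ["k"], ["u1"],
                         [sp.sympify("k*u1", locals=names)],
                         ["y1"], [names["x1"]], [sp.Integer(0)],
                         np.array([[0.1, 10.0]]))
        d = ExperimentDesign("e1", 0.0, 2.0, np.array([0.5, 1.0, 1.5, 2.0]),
                             ["y1"], {"u1": [(0.0, 1.0), (1.0, -1.0)]})
        sim = ik.simulate(m, d, [2.0])
        # dx/dt = 2*u: rises to 2 at t=1 then falls symmetrically
        np.testing.assert_allclose(sim.observable("y1"), [1.0, 2.0, 1.0, 0.0],
                                   atol=1e-7)


class TestResiduals:
    @pytest.mark.parametrize("w, y_meas, expected_r, expected_q", [
        (1.0, np.exp(-1.0), 0.0, 0.0),      # perfect fit
        (1.0, np.exp(-1.0) - 1.0, 1.0, 1.0),
        (4.0, np.exp(-1.0) - 1.0, 2.0, 4.0),
    ])
    def test_single_record_arithmetic(self, w, y_meas, expected_r, expected_q):
        m = tiny_model()
        d = design([1.0])
        data = MeasurementSet(pd.DataFrame(
            [("e1", "y1", 1.0, y_meas, w)], columns=MeasurementSet.COLUMNS))
        r = ik.residuals(m, d, data, [1.0])
        assert r[0] == pytest.approx(expected_r, abs=1e-6)
        assert r @ r == pytest.approx(expected_q, abs=1e-5)

    def test_qls_equals_triple_sum(self, cascade, cascade_data):
        """The residual-vector sum of squares equals the explicit
        sum over experiments/observables/times."""
        r = ik.residuals(cascade.model, cascade.design, cascade_data, cascade.theta)
        direct = 0.0
        sim = ik.simulate(cascade.model, cascade.design, cascade.theta)
        for row in cascade_data.records.itertuples():
            i = np.argmin(np.abs(sim.times - row.time))
            y = sim.observable(row.observable)[i]
            direct += row.weight * (y - row.value) ** 2
        assert float(r @ r) == pytest.approx(direct, rel=1e-12)

    def test_unmatched_record_names_offender(self, cascade, cascade_data):
        bad = cascade_data.records.copy()
        bad.loc[0, "time"] = 123.0
        with pytest.raises(MeasurementMatchError, match="record 0"):
            ik.residuals(cascade.model, cascade.design, MeasurementSet(bad),
                         cascade.theta)


class TestValidation:
    def test_duplicate_names_rejected(self):
        with pytest.raises(ModelSpecError):
            KineticModel(["a"], ["a"], [], [sp.Integer(0)], ["y"],
                         [sp.Symbol("a")], [sp.Integer(1)], np.array([[0, 1]]))

    def test_undeclared_symbol_rejected(self):
        with pytest.raises(ModelSpecError, match="undeclared"):
            tiny_model(rhs="-k*zz")

    def test_bad_bounds_rejected(self):
        with pytest.raises(ModelSpecError):
            tiny_model(bounds=(2.0, 1.0))

    def test_negative_weight_rejected(self):
        with pytest.raises(ModelSpecError):
            MeasurementSet(pd.DataFrame([("e1", "y1", 1.0, 0.0, -1.0)],
                                        columns=MeasurementSet.COLUMNS))

    def test_nonmonotone_sample_times_rejected(self):
        with pytest.raises(ModelSpecError):
            ExperimentDesign("e1", 0.0, 2.0, np.array([1.0, 0.5]), ["y1"])


class TestIO:
    def test_yaml_round_trip(self, cascade, tmp_path):
        path = tmp_path / "m.yaml"
        cascade.model.to_yaml(path)
        loaded = ik.KineticModel.from_yaml(path)
        assert loaded.param_names == cascade.model.param_names
        np.testing.assert_array_equal(loaded.bounds, cascade.model.bounds)
        a = ik.simulate(loaded, cascade.design, cascade.theta)
        b = ik.simulate(cascade.model, cascade.design, cascade.theta)
        np.testing.assert_allclose(a.observables, b.observables, rtol=1e-12)

    def test_caret_power_parsed(self):
        m = tiny_model(rhs="-k*x1^2")
        x1 = m.symbols()["x1"]
        assert sp.degree(m.rhs_exprs[0], x1) == 2

    def test_sigma_column_converted(self, tmp_path, cascade, cascade_data):
        df = cascade_data.records.copy()
        df["sigma"] = 0.5
        df = df.drop(columns="weight")
        p = tmp_path / "d.csv"
        df.to_csv(p, index=False)
        ms = MeasurementSet.from_csv(p)
        np.testing.assert_allclose(ms.records["weight"], 4.0)
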