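"""Forward sensitivities, scaling, msqr scores and the influence filter."""

import numpy as np
import pandas as pd
import pytest
import sympy as sp

import identikit as ik
from identikit.model import ExperimentDesign, KineticModel, MeasurementSet
from identikit.sensitivity import AllZeroSensitivityError


def test_decay_sensitivity_closed_form(decay):
    """dx/dt = -k x, x0 = 1: dy/dk = -t exp(-k t)."""
    st = ik.forward_sensitivities(decay.model, decay.design, [1.0])
    t = decay.design.sample_times
    np.testing.assert_allclose(st.values[:, 0, 0], -t * np.exp(-t), atol=1e-7)


def test_absent_parameter_zero_sensitivity():
    names = {n: sp.Symbol(n) for n in ["x1", "k", "dead"]}
    m = KineticModel(["x1"], ["k", "dead"], [],
                     [sp.sympify("-k*x1", locals=names)],
                     ["y1"], [names["x1"]], [sp.Integer(1)],
                     np.array([[0.1, 10.0], [0.1, 10.0]]))
    d = ExperimentDesign("e1", 0.0, 2.0, np.array([0.5, 1.0, 2.0]), ["y1"])
    st = ik.forward_sensitivities(m, d, [1.0, 1.0])
    np.testing.assert_array_equal(st.values[:, 0, 1], 0.0)


def test_initial_condition_parameter_unit_start():
    """When theta_i is the initial condition of state j, s_i(t0) = 1."""
    names = {n: sp.Symbol(n) for n in ["x1", "k", "c"]}
    m = KineticModel(["x1"], ["k", "c"], [],
                     [sp.sympify("-k*x1", locals=names)],
                     ["y1"], [names["x1"]], [names["c"]],
                     np.array([[0.1, 10.0], [0.1, 10.0]]))
    d = ExperimentDesign("e1", 0.0, 2.0, np.array([0.0, 1.0, 2.0]), ["y1"])
    st = ik.forward_sensitivities(m, d, [1.0, 1.0])
    assert st.values[0, 0, 1] == pytest.approx(1.0, abs=1e-10)   # dc at t0
    assert st.values[0, 0, 0] == pytest.approx(0.0, abs=1e-10)   # rate param at t0
    # with x0 = c: x(t) = c exp(-kt), so dx/dc = exp(-kt)
    np.testing.assert_allclose(st.values[:, 0, 1], np.exp(-d.sample_times),
                               atol=1e-8)


def test_finite_difference_agrees_with_forward(decay):
    fwd = ik.forward_sensitivities(decay.model, decay.design, [1.0])
    fd = ik.sensitivity.finite_difference_sensitivities(
        decay.model, decay.design, [1.0])
    scale = np.abs(fwd.values).max()
    assert np.abs(fwd.values - fd.values).max() / scale < 1e-3


class TestScaling:
    @pytest.mark.parametrize("w, raw, expected", [
        (4.0, 3.0, 6.0),
        (0.0, 123.0, 0.0),
        (1.0, -2.5, -2.5),
    ])
    def test_entry_arithmetic(self, w, raw, expected):
        data = MeasurementSet(pd.DataFrame([("e1", "y1", 1.0, 0.0, w)],
                                           columns=MeasurementSet.COLUMNS))
        out = ik.scale_sensitivities(pd.DataFrame({"p": [raw]}), data)
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_unit_weights_identity(self, cascade, cascade_data):
        raw = ik.record_sensitivities(cascade.model, cascade.design,
                                      cascade_data, cascade.theta)
        ones = cascade_data.records.copy()
        ones["weight"] = 1.0
        scaled = ik.scale_sensitivities(raw, MeasurementSet(ones))
        pd.testing.assert_frame_equal(scaled, raw)


class TestMsqr:
    def test_examples(self):
        col = pd.DataFrame({"a": [5.0, 5.0], "b": [3.0, 4.0], "c": [0.0, 0.0]})
        s = ik.msqr_scores(col)
        assert s["a"] == pytest.approx(5.0)
        assert s["b"] == pytest.approx(np.sqrt(12.5))
        assert s["c"] == 0.0

    def test_permutation_invariance(self, cascade_bundle):
        stacked = cascade_bundle.stacked_matrix
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(stacked))
        shuffled = stacked.iloc[perm].reset_index(drop=True)
        pd.testing.assert_series_equal(ik.msqr_scores(stacked),
                                       ik.msqr_scores(shuffled))


class TestFilter:
    def test_cutoff_example(self):
        msqr = pd.Series([1.0, 1e-3, 1e-5], index=list("abc"))
        mask, cutoff = ik.filter_influential(msqr, ratio=1e-4)
        assert cutoff == pytest.approx(1e-4)
        assert list(mask) == [True, True, False]

    def test_all_equal_all_influential(self):
        mask, _ = ik.filter_influential(pd.Series([2.0, 2.0, 2.0]))
        assert mask.all()

    def test_borderline_inclusive(self):
        mask, _ = ik.filter_influential(pd.Series([1.0, 1e-4]), ratio=1e-4)
        assert list(mask) == [True, True]

    def test_all_zero_errors(self):
        with pytest.raises(AllZeroSensitivityError):
            ik.filter_influential(pd.Series([0.0, 0.0]))

    def test_cascade_noninfluential_parameter_cut(self, cascade_bundle):
        """k5 only moves the unobserved dead-end state: filtered out."""
        assert cascade_bundle.non_influential_params == ["k5"]
        assert set(cascade_bundle.influential_params) == {"k1", "k2", "k3",
                                                          "k4", "k6"}


def test_experiment_concatenation_commutes(cascade):
    """Joint analysis of two experiments equals row-wise concatenation of
    their individual stacked matrices."""
    d1 = cascade.design
    d2 = ExperimentDesign("e2", d1.t0, d1.tf, d1.sample_times[::2],
                          d1.observed_outputs)
    fx2 = ik.Fixture("tmp", cascade.model, d2, cascade.theta, 0.05, {})
    ms1 = ik.make_dataset(cascade, seed=1)
    ms2 = ik.make_dataset(fx2, seed=2)
    joint = MeasurementSet(pd.concat([ms1.records, ms2.records],
                                     ignore_index=True))
    raw_joint = ik.record_sensitivities(cascade.model, [d1, d2], joint,
                                        cascade.theta)
    raw1 = ik.record_sensitivities(cascade.model, d1, ms1, cascade.theta)
    raw2 = ik.record_sensitivities(cascade.model, d2, ms2, cascade.theta)
    stacked_joint = ik.scale_sensitivities(raw_joint, joint)
    parts = pd.concat([ik.scale_sensitivities(raw1, ms1),
                       ik.scale_sensitivities(raw2, ms2)], ignore_index=True)
    pd.testing.assert_frame_equal(stacked_joint, parts)
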