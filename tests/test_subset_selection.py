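"""QR ordering, penalized objective and the binary VNS subset search."""

import numpy as np
import pytest

import identikit as ik
from identikit.collinearity import NormalizedSensitivityMatrix
from identikit.fixtures import PlantedMatrixSpec, planted_matrix
from conftest import random_nsm


def orthonormal_nsm(n, names=None):
    names = names or [f"p{i+1}" for i in range(n)]
    return NormalizedSensitivityMatrix(np.eye(max(n, len(names)))[:, :len(names)],
                                       names)


class TestQROrdering:
    def test_orthonormal_keeps_input_order(self):
        nsm = orthonormal_nsm(4)
        assert ik.qr_ordering(nsm) == ["p1", "p2", "p3", "p4"]

    def test_duplicate_ranked_last(self):
        m = np.column_stack([np.eye(5)[:, 0], np.eye(5)[:, 1], np.eye(5)[:, 0]])
        nsm = NormalizedSensitivityMatrix(m, ["e1", "e2", "dup"])
        assert ik.qr_ordering(nsm)[-1] == "dup"

    def test_near_copy_ranked_last(self):
        rho = 0.999
        base = np.eye(6)[:, :4]
        v = rho * base[:, 0] + np.sqrt(1 - rho ** 2) * np.eye(6)[:, 4]
        nsm = NormalizedSensitivityMatrix(np.column_stack([base, v]),
                                          ["a", "b", "c", "d", "near"])
        assert ik.qr_ordering(nsm)[-1] == "near"


class TestGreedyPrefix:
    def test_all_orthogonal_full_set(self):
        nsm = orthonormal_nsm(5)
        ps = ik.greedy_prefix(ik.qr_ordering(nsm), nsm, 20.0)
        assert set(ps.members) == set(nsm.param_names)

    def test_duplicate_stops_prefix(self):
        m = np.column_stack([np.eye(5)[:, 0], np.eye(5)[:, 1], np.eye(5)[:, 0]])
        nsm = NormalizedSensitivityMatrix(m, ["e1", "e2", "dup"])
        ps = ik.greedy_prefix(ik.qr_ordering(nsm), nsm, 20.0)
        assert ps.size == 2

    def test_empty_ranking(self):
        nsm = orthonormal_nsm(2)
        assert ik.greedy_prefix([], nsm, 20.0) is None


class TestPenalizedObjective:
    def test_p1_half_at_threshold(self):
        """P1 = CI/(2 CI*) reaches exactly 0.5 when CI hits the threshold."""
        pm = planted_matrix(PlantedMatrixSpec(10, 3, [(2, 20.0)], seed=0))
        bits = [1 if p in pm.group_members[0] else 0 for p in pm.nsm.param_names]
        obj = ik.penalized_objective(bits, pm.nsm, 20.0)
        # CI = CI*: P1 = 0.5, P2 = (CI - CI*)^2 = 0
        assert obj == pytest.approx(2 - 0.5, abs=1e-9)

    def test_p2_quadratic_above_threshold(self):
        pm = planted_matrix(PlantedMatrixSpec(10, 3, [(2, 23.0)], seed=0))
        bits = [1 if p in pm.group_members[0] else 0 for p in pm.nsm.param_names]
        obj = ik.penalized_objective(bits, pm.nsm, 20.0)
        assert obj == pytest.approx(2 - 0.5 * 23 / 20 - 9.0, abs=1e-8)

    def test_five_orthogonal_columns(self):
        nsm = orthonormal_nsm(5)
        obj = ik.penalized_objective([1] * 5, nsm, 20.0)
        assert obj == pytest.approx(5 - 0.5 / 20, abs=1e-12)

    def test_empty_selection_zero(self):
        nsm = orthonormal_nsm(3)
        assert ik.penalized_objective([0, 0, 0], nsm, 20.0) == 0.0


class TestVNS:
    def test_identity_selects_everything(self):
        nsm = orthonormal_nsm(6)
        res = ik.vns_maximize(nsm, 20.0, seed=0, budget=2000)
        assert set(res.best_subset.members) == set(nsm.param_names)
        assert res.best_subset.ci == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_column_excluded(self):
        m = np.column_stack([np.eye(8)[:, :5], np.eye(8)[:, 0]])
        nsm = NormalizedSensitivityMatrix(m, [f"p{i}" for i in range(6)])
        res = ik.vns_maximize(nsm, 20.0, seed=1, budget=3000)
        assert res.best_subset.size == 5
        oracle = ik.brute_force_largest(nsm, 20.0)
        assert res.best_subset.size == oracle.max_size

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_8_columns(self, seed):
        rng = np.random.default_rng(seed)
        nsm = random_nsm(rng, 12, 8)
        res = ik.vns_maximize(nsm, 1.8, seed=seed, budget=4000)
        oracle = ik.brute_force_largest(nsm, 1.8)
        assert res.best_subset.size == oracle.max_size

    def test_never_below_initial(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            nsm = random_nsm(rng, 10, 7)
            res = ik.vns_maximize(nsm, 2.0, seed=seed, budget=1500)
            if res.initial_subset is not None:
                assert res.best_subset.size >= res.initial_subset.size

    def test_ties_favour_lower_ci(self):
        """Among equal-size optima the smaller collinearity index wins (P1)."""
        v1 = np.eye(6)[:, 0]
        v2 = 0.9 * v1 + np.sqrt(1 - 0.81) * np.eye(6)[:, 1]   # CI ~ 3.16 pair
        v3 = np.eye(6)[:, 2]                                   # orthogonal to v1
        nsm = NormalizedSensitivityMatrix(np.column_stack([v1, v2, v3]),
                                          ["a", "b", "c"])
        # threshold 2: {a,b} inadmissible; best pairs {a,c} and {b,c};
        # {a,c} has CI exactly 1, {b,c} also 1 -> both optimal; with
        # threshold 3.5 the triple is inadmissible? CI(abc) >= CI(ab) ~ 3.16
        res = ik.vns_maximize(nsm, 3.0, seed=0, budget=2000)
        assert res.best_subset.size == 2
        assert res.best_subset.ci == pytest.approx(1.0, abs=1e-9)


class TestThresholdSweep:
    def test_orthogonal_constant_full_size(self):
        nsm = orthonormal_nsm(4)
        table = ik.threshold_sweep(nsm, [2, 10, 20, 40], seed=0, budget=500)
        assert (table["max_size"] == 4).all()

    def test_planted_pair_step(self):
        """A pair planted at CI = 15 caps the size at N-1 for CI* <= 15."""
        pm = planted_matrix(PlantedMatrixSpec(12, 5, [(2, 15.0)], seed=3))
        n = pm.nsm.n_params
        table = ik.threshold_sweep(pm.nsm, [5.0, 10.0, 20.0, 30.0], seed=0,
                                   budget=2000)
        sizes = dict(zip(table["ci_threshold"], table["max_size"]))
        assert sizes[5.0] == n - 1 and sizes[10.0] == n - 1
        assert sizes[20.0] == n and sizes[30.0] == n

    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(7)
        nsm = random_nsm(rng, 14, 9)
        table = ik.threshold_sweep(nsm, np.linspace(1.2, 30, 8), seed=2,
                                   budget=1500)
        assert (np.diff(table["max_size"]) >= 0).all()
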