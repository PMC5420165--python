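"""Largest identifiable subset by pivoted-QR initialization + binary VNS.

Finding the maximum-cardinality parameter set whose collinearity index stays
below CI* is a nonlinear integer program.  It is solved here as a penalized
maximization over inclusion bitstrings,

    maximize  sum_k i_k - P1(i) - P2(i)
    P1 = CI(S_i) / (2 CI*)                      (0.5 at the threshold)
    P2 = 0 if CI(S_i) < CI*, else (CI - CI*)^2  (soft constraint, a=1, b=2)

P1 is small enough never to change the optimal size but breaks ties between
equal-size subsets in favour of the lower collinearity index; P2 softly
enforces the threshold.  The search is a binary Variable Neighbourhood
Search seeded with a greedy prefix of the column-pivoted (rank-revealing)
QR ordering of the normalized sensitivity matrix, whose permutation places
the most mutually orthogonal columns first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .collinearity import (DEFAULT_CI_THRESHOLD, NormalizedSensitivityMatrix,
                           ParameterSubset, collinearity_index)

DEFAULT_KMAX = 4
DEFAULT_STALL = 20
BUDGET_PER_PARAM = 5000


@dataclass
class SubsetSelectionResult:
    best_subset: ParameterSubset
    objective_value: float
    initial_subset: ParameterSubset | None
    evaluations: int
    seed: int
    threshold: float


def qr_ordering(nsm: NormalizedSensitivityMatrix) -> list[str]:
    """Parameter ranking from column-pivoted Householder QR.

    The permutation orders columns from most to least mutually orthogonal;
    exact ties keep ascending column index (LAPACK pivots on the first
    maximal remaining norm).
    """
    if nsm.n_params == 0:
        raise ValueError("empty sensitivity matrix")
    _, _, piv = scipy.linalg.qr(nsm.matrix, pivoting=True, mode="economic")
    return [nsm.param_names[i] for i in piv]


def greedy_prefix(ranked: list[str], nsm: NormalizedSensitivityMatrix,
                  threshold: float = DEFAULT_CI_THRESHOLD) -> ParameterSubset | None:
    """Longest prefix of the QR ranking with CI < CI* (VNS incumbent).

    Because CI never decreases when a parameter is added, the first prefix
    that violates the threshold ends the scan.  Returns ``None`` for an
    empty ranking.
    """
    if not ranked:
        return None
    best = None
    for n in range(1, len(ranked) + 1):
        ps = collinearity_index(nsm, ranked[:n])
        if ps.ci < threshold:
            best = ps
        else:
            break
    return best


class _Objective:
    """Penalized set-size objective with an evaluation counter and cache."""

    def __init__(self, nsm: NormalizedSensitivityMatrix, threshold: float):
        self.nsm = nsm
        self.threshold = threshold
        self.evaluations = 0
        self._cache: dict[tuple[int, ...], float] = {}
        # the penalty on threshold violations is soft, so the search may pass
        # through (or even prefer) slightly inadmissible selections; the best
        # CI < CI* selection seen is tracked separately and is what gets
        # reported.
        self.best_admissible: ParameterSubset | None = None
        self.best_admissible_value = -np.inf

    def __call__(self, bits: np.ndarray) -> float:
        key = tuple(int(b) for b in bits)
        if key in self._cache:
            return self._cache[key]
        size = int(sum(key))
        if size == 0:
            val = 0.0                      # no columns selected
        else:
            members = [self.nsm.param_names[i] for i, b in enumerate(key) if b]
            ps = collinearity_index(self.nsm, members)
            self.evaluations += 1
            if not np.isfinite(ps.ci):
                val = -np.inf              # rank-deficient selection
            else:
                p1 = 0.5 * ps.ci / self.threshold
                p2 = 0.0 if ps.ci < self.threshold else (ps.ci - self.threshold) ** 2
                val = size - p1 - p2
                if ps.ci < self.threshold and val > self.best_admissible_value:
                    self.best_admissible = ps
                    self.best_admissible_value = val
        self._cache[key] = val
        return val


def penalized_objective(bits, nsm: NormalizedSensitivityMatrix,
                        threshold: float = DEFAULT_CI_THRESHOLD) -> float:
    """Objective value of one inclusion bitstring (empty selection -> 0)."""
    return _Objective(nsm, threshold)(np.asarray(bits, dtype=int))


def _local_search(bits: np.ndarray, obj: _Objective, budget: int) -> np.ndarray:
    """Best-improvement single-bit-flip descent to local optimality."""
    bits = bits.copy()
    current = obj(bits)
    improved = True
    while improved and obj.evaluations < budget:
        improved = False
        best_val, best_i = current, -1
        for i in range(len(bits)):
            if obj.evaluations >= budget:
                break
            trial = bits.copy()
            trial[i] ^= 1
            v = obj(trial)
            if v > best_val:
                best_val, best_i = v, i
        if best_i >= 0:
            bits[best_i] ^= 1
            current = best_val
            improved = True
    return bits


def vns_maximize(nsm: NormalizedSensitivityMatrix,
                 threshold: float = DEFAULT_CI_THRESHOLD,
                 seed: int = 0, budget: int | None = None,
                 k_max: int = DEFAULT_KMAX, stall: int = DEFAULT_STALL,
                 initial: ParameterSubset | None = None) -> SubsetSelectionResult:
    """Binary VNS over inclusion bitstrings, deterministic given ``seed``.

    Shaking samples a random k-bit flip (k = 1..k_max); local search is
    best-improvement single-bit flips; an improving move resets k, otherwise
    k grows, and the search stops after ``stall`` full neighbourhood sweeps
    without improvement or when the evaluation budget is spent.  The result
    is never worse than the greedy QR-prefix incumbent.
    """
    n = nsm.n_params
    if budget is None:
        budget = BUDGET_PER_PARAM * n
    rng = np.random.default_rng(seed)
    obj = _Objective(nsm, threshold)

    init_ps = initial if initial is not None else greedy_prefix(
        qr_ordering(nsm), nsm, threshold)
    bits = np.zeros(n, dtype=int)
    if init_ps is not None:
        for p in init_ps.members:
            bits[nsm.param_names.index(p)] = 1
    bits = _local_search(bits, obj, budget)
    best, best_val = bits.copy(), obj(bits)

    k, stalled = 1, 0
    while obj.evaluations < budget and stalled < stall:
        trial = best.copy()
        flip = rng.choice(n, size=min(k, n), replace=False)
        trial[flip] ^= 1
        trial = _local_search(trial, obj, budget)
        v = obj(trial)
        if v > best_val:
            best, best_val = trial.copy(), v
            k, stalled = 1, 0
        else:
            k += 1
            if k > k_max:
                k = 1
                stalled += 1

    if obj.best_admissible is not None:
        best_ps, best_val = obj.best_admissible, obj.best_admissible_value
    else:
        best_ps = ParameterSubset((), float("inf"), 0.0)
        best_val = 0.0
    return SubsetSelectionResult(best_ps, best_val, init_ps,
                                 obj.evaluations, seed, threshold)


def threshold_sweep(nsm: NormalizedSensitivityMatrix, thresholds,
                    seed: int = 0, budget: int | None = None) -> pd.DataFrame:
    """Largest-subset size over a grid of CI thresholds.

    Each grid point runs one VNS search; runs at larger thresholds are
    warm-started with the previous best subset (any subset identifiable at a
    lower threshold stays identifiable), which makes the reported sizes
    monotone non-decreasing by construction.
    """
    rows = []
    prev: ParameterSubset | None = None
    for i, ci_star in enumerate(sorted(float(t) for t in thresholds)):
        warm = None
        if prev is not None and prev.size > 0 and prev.ci < ci_star:
            warm = prev
        res = vns_maximize(nsm, ci_star, seed=seed + i, budget=budget,
                           initial=warm)
        if prev is not None and res.best_subset.size < prev.size:
            res.best_subset = prev     # monotonicity guarantee
        rows.append((ci_star, res.best_subset.size, res.best_subset.ci,
                     ",".join(res.best_subset.members)))
        prev = res.best_subset
    return pd.DataFrame(rows, columns=["ci_threshold", "max_size", "ci", "members"])
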