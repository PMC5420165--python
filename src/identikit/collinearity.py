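"""Collinearity index of parameter subsets.

Each influential parameter's stacked sensitivity vector is normalized to unit
Euclidean length, removing bias from differing absolute sensitivities.  For a
subset K with normalized matrix S_K the collinearity index is

    CI_K = 1 / min_{||a||=1} ||S_K a|| = 1 / sqrt(lambda_min(S_K' S_K)),

computed here from the smallest singular value of S_K (identical by
definition, numerically safer than an eigendecomposition of the Gram
matrix).  CI_K = 1 means the subset's sensitivity directions are mutually
orthogonal; a large CI_K means a change in one parameter can be almost
fully compensated by the others.  A subset is classified identifiable when
CI_K is strictly below a threshold CI* (conventionally 20: roughly 95% of
the output variation caused by one parameter can be compensated within the
subset at that level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_CI_THRESHOLD = 20.0
LAMBDA_FLOOR = 1e-12   # below this eigenvalue the subset is rank deficient


@dataclass
class NormalizedSensitivityMatrix:
    """Unit-norm sensitivity columns for the influential parameters."""

    matrix: np.ndarray            # N_D x m, each column unit Euclidean norm
    param_names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        norms = np.linalg.norm(self.matrix, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("columns must have unit Euclidean norm")

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def columns(self, subset: Sequence[str]) -> np.ndarray:
        idx = [self.param_names.index(p) for p in subset]
        return self.matrix[:, idx]


@dataclass(frozen=True)
class ParameterSubset:
    """A parameter set with its collinearity index."""

    members: tuple[str, ...]
    ci: float
    lambda_min: float

    @property
    def size(self) -> int:
        return len(self.members)

    def __str__(self):
        return f"{{{', '.join(self.members)}}}: CI={self.ci:.4g}"


def normalize(stacked: pd.DataFrame, influential_mask: pd.Series | None = None
              ) -> NormalizedSensitivityMatrix:
    """Unit-normalize the stacked sensitivity columns of the influential set."""
    if influential_mask is not None:
        stacked = stacked.loc[:, np.asarray(influential_mask, dtype=bool)]
    mat = stacked.to_numpy(dtype=float)
    norms = np.linalg.norm(mat, axis=0)
    if np.any(norms <= 0):
        bad = [c for c, n in zip(stacked.columns, norms) if n <= 0]
        raise RuntimeError(
            f"zero-norm sensitivity column(s) {bad} reached normalization; "
            "the influence filter should have removed them")
    return NormalizedSensitivityMatrix(mat / norms, list(stacked.columns))


def collinearity_index(nsm: NormalizedSensitivityMatrix,
                       subset: Iterable[str]) -> ParameterSubset:
    """Collinearity index of a parameter subset via the smallest singular
    value; rank-deficient subsets (lambda_min below the numeric floor) are
    flagged with an infinite CI."""
    members = tuple(subset)
    if not members:
        raise ValueError("subset must be non-empty")
    unknown = set(members) - set(nsm.param_names)
    if unknown:
        raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
    S = nsm.columns(members)
    smin = np.linalg.svd(S, compute_uv=False)[-1]
    lam = float(smin ** 2)
    ci = float("inf") if lam < LAMBDA_FLOOR else 1.0 / np.sqrt(lam)
    return ParameterSubset(members, ci, lam)


def is_identifiable(subset: ParameterSubset,
                    threshold: float = DEFAULT_CI_THRESHOLD) -> bool:
    """A subset is identifiable iff CI < CI* (strict; infinite CI never is)."""
    return subset.ci < threshold


def pairwise_ci_table(nsm: NormalizedSensitivityMatrix) -> pd.DataFrame:
    """CI of every parameter pair (long format: p1, p2, ci, lambda_min)."""
    rows = []
    names = nsm.param_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ps = collinearity_index(nsm, (names[i], names[j]))
            rows.append((names[i], names[j], ps.ci, ps.lambda_min))
    return pd.DataFrame(rows, columns=["param1", "param2", "ci", "lambda_min"])
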