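import numpy as np
import pytest

import identikit as ik
from identikit.collinearity import NormalizedSensitivityMatrix


@pytest.fixture(scope="session")
def decay():
    """One-parameter exponential-decay fixture."""
    return ik.get_fixture("linear_decay")


@pytest.fixture(scope="session")
def cascade():
    """Six-parameter cascade fixture with planted identifiability structure."""
    return ik.get_fixture("cascade6")


@pytest.fixture(scope="session")
def cascade_data(cascade):
    """One noisy cascade dataset (5% noise, fixed seed)."""
    return ik.make_dataset(cascade, seed=11)


@pytest.fixture(scope="session")
def cascade_bundle(cascade, cascade_data):
    """Sensitivity bundle at the true parameters."""
    return ik.analyse_sensitivities(cascade.model, cascade.design,
                                    cascade_data, cascade.theta)


@pytest.fixture(scope="session")
def cascade_nsm(cascade_bundle):
    return ik.normalize(cascade_bundle.stacked_matrix,
                        cascade_bundle.influential_mask)


def random_nsm(rng, n_rows, n_cols):
    """Random column-normalized matrix for property tests."""
    m = rng.normal(size=(n_rows, n_cols))
    m /= np.linalg.norm(m, axis=0)
    return NormalizedSensitivityMatrix(m, [f"p{i+1}" for i in range(n_cols)])


def sphere_min_norm(S, rng, n_directions=100_000, polish_steps=200):
    """Independent oracle for min_{||a||=1} ||S a||.

    Samples random unit directions, keeps the best, and polishes it with a
    shifted power iteration on the Gram matrix (matrix-vector products only;
    no LAPACK spectral routines are involved, so this path is independent of
    the SVD used by the implementation).
    """
    k = S.shape[1]
    alphas = rng.normal(size=(n_directions, k))
    alphas /= np.linalg.norm(alphas, axis=1, keepdims=True)
    norms = np.linalg.norm(S @ alphas.T, axis=0)
    a = alphas[int(np.argmin(norms))]
    G = S.T @ S
    shift = float(k)          # unit columns: largest eigenvalue <= k
    for _ in range(polish_steps):
        a = shift * a - G @ a
        a /= np.linalg.norm(a)
    return min(float(norms.min()), float(np.linalg.norm(S @ a)))
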