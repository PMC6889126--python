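"""Shared fixtures and independent numerical oracles for the test suite."""

import numpy as np
import pytest

from beliefwalk.belief_space import BeliefLattice, make_initial_distribution


def expm_series(M: np.ndarray, terms: int = 60) -> np.ndarray:
    """Truncated-Taylor matrix exponential with scaling and squaring.

    Independent brute-force oracle for the propagator constructions: the
    argument is halved until its norm is small, the Taylor series is summed
    directly, and the result is squared back up.  Accuracy ~1e-12 for the
    small matrices used in tests.
    """
    M = np.asarray(M)
    norm = np.linalg.norm(M, np.inf)
    n_sq = max(0, int(np.ceil(np.log2(max(norm, 1e-300)))) + 1) if norm > 0.5 else 0
    A = M / (2**n_sq)
    out = np.eye(M.shape[0], dtype=A.dtype)
    term = out.copy()
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    for _ in range(n_sq):
        out = out @ out
    return out


@pytest.fixture(scope="session")
def lattice99() -> BeliefLattice:
    return BeliefLattice(99)


@pytest.fixture(scope="session")
def init99(lattice99) -> np.ndarray:
    return make_initial_distribution(lattice99)


@pytest.fixture(scope="session")
def lattice6() -> BeliefLattice:
    return BeliefLattice(6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
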