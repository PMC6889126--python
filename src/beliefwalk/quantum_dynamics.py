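"""Quantum walk dynamics of belief change with projective measurement collapse.

The belief state is a complex amplitude vector over the evidence lattice,
evolving under the Schrödinger law ``psi(t) = U(t) psi(0)`` with
``U(t) = expm(-i t H)``.  The Hamiltonian is tridiagonal: a constant real
coupling ``sigma`` between neighbouring evidence states (the "diffusion"
parameter) and a linear potential ramp ``H[j, j] = mu * j / n`` across the
lattice (the "drift" parameter; ``j`` is the 1-based state index).  Because
the nearest-neighbour band has negative effective mass around zero
momentum, a *positive* ``mu`` drifts the packet toward high states, i.e.
toward certainty in the correct direction.

Rating probabilities are squared norms of projected amplitudes.  For a
sequence of two ratings, the first rating projects the amplitude vector
onto the reported category's block (collapse); the unnormalized projected
vector is evolved and projected again, and its squared norm carries the
joint probability.  Unlike the Markov chain, summing these joint
probabilities over the first rating does *not* reproduce the
no-measurement marginal: the intermediate collapse destroys the coherence
between category blocks, producing an interference effect.
:func:`interference_effect` measures exactly this difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh_tridiagonal

from .belief_space import (
    CATEGORIES,
    BeliefLattice,
    category_index,
    category_masses,
    validate_amplitudes,
)

__all__ = [
    "QuantumParams",
    "hamiltonian",
    "unitary_matrix",
    "unitary_matrices",
    "joint_table_q",
    "marginal_rating_probability_q",
    "joint_rating_probability_q",
    "interference_effect",
]


@dataclass(frozen=True)
class QuantumParams:
    """Drift/diffusion parameterization of the quantum walk.

    ``mu`` scales the linear diagonal potential; ``sigma`` is the real
    off-diagonal coupling between neighbouring states.  A complex coupling
    is admissible in principle but the model is restricted to real
    ``sigma`` to keep two free parameters.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma"):
            v = getattr(self, name)
            if isinstance(v, complex) or not np.isfinite(v):
                raise ValueError(f"{name} must be a finite real number, got {v!r}")


def hamiltonian(params: QuantumParams, lattice: BeliefLattice) -> np.ndarray:
    """Tridiagonal Hamiltonian: ``H[j, j] = mu * j / n`` (1-based ``j``),
    ``sigma`` on both off-diagonals.  Real symmetric, hence Hermitian."""
    n = lattice.n_states
    H = np.zeros((n, n))
    np.fill_diagonal(H, params.mu * lattice.states / n)
    idx = np.arange(n - 1)
    H[idx, idx + 1] = params.sigma
    H[idx + 1, idx] = params.sigma
    return H


def unitary_matrices(params: QuantumParams, times, lattice: BeliefLattice) -> dict[float, np.ndarray]:
    """Unitary propagators ``U(t) = expm(-i t H)`` for each requested time.

    ``H`` is real symmetric tridiagonal, so a single spectral decomposition
    ``H = Q diag(w) Q^T`` serves every time point:
    ``U(t) = Q exp(-i t w) Q^T``.  The orthogonal similarity keeps the
    construction numerically stable for any parameter values.
    """
    n = lattice.n_states
    diag = params.mu * lattice.states / n
    off = np.full(n - 1, params.sigma, dtype=float)
    return _unitary_from_tridiagonal(diag, off, times)


def _unitary_from_tridiagonal(diag: np.ndarray, off: np.ndarray, times) -> dict[float, np.ndarray]:
    """Spectral construction of ``expm(-i t H)`` for a real symmetric
    tridiagonal ``H`` given by its diagonal and off-diagonal."""
    times = sorted({float(t) for t in times})
    for t in times:
        if t < 0:
            raise ValueError("evolution time must be nonnegative")
    w, Q = eigh_tridiagonal(np.asarray(diag, dtype=float), np.asarray(off, dtype=float))
    return {t: (Q * np.exp(-1j * t * w)) @ Q.T for t in times}


def unitary_matrix(params: QuantumParams, t: float, lattice: BeliefLattice) -> np.ndarray:
    """Unitary propagator ``U(t)``; requires ``t >= 0``."""
    if t < 0:
        raise ValueError("evolution time must be nonnegative")
    return unitary_matrices(params, [t], lattice)[float(t)]


def joint_table_q(params: QuantumParams, t1: float, t2: float, init_amps: np.ndarray,
                  lattice: BeliefLattice) -> np.ndarray:
    """Joint probability table of the two category ratings at ``t1`` and ``t2``.

    Entry ``[k, l]`` is the squared norm of
    ``M_l U(t2 - t1) M_k U(t1) psi(0)``: the amplitudes are evolved to
    ``t1``, projected onto block ``k`` *without renormalization* (the
    projected vector's norm carries the first-rating probability), evolved
    for the remaining lag, and projected onto block ``l``.  The table sums
    to 1 by unitarity and the resolution of the identity.
    """
    if not 0 < t1 < t2:
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    psi0 = validate_amplitudes(init_amps)
    U = unitary_matrices(params, [t1, t2 - t1], lattice)
    return _joint_from_unitaries(U[float(t1)], U[float(t2 - t1)], psi0, lattice)


def _joint_from_unitaries(U1: np.ndarray, Udt: np.ndarray, psi0: np.ndarray,
                          lattice: BeliefLattice) -> np.ndarray:
    """3x3 joint category table given the two stage propagators."""
    psi1 = U1 @ psi0
    n = lattice.n_states
    collapsed = np.zeros((n, 3), dtype=complex)
    for a, cat in enumerate(CATEGORIES):
        blk = lattice.category_block(cat)
        collapsed[blk, a] = psi1[blk]
    psi2 = Udt @ collapsed
    table = np.empty((3, 3))
    for b, cat in enumerate(CATEGORIES):
        table[:, b] = (np.abs(psi2[lattice.category_block(cat), :]) ** 2).sum(axis=0)
    return table


def marginal_rating_probability_q(params: QuantumParams, t1: float, t2: float,
                                  category: str, init_amps: np.ndarray,
                                  lattice: BeliefLattice) -> float:
    """Probability of rating ``category`` at ``t2`` with no intermediate
    measurement (evolution ``t1`` then ``t2 - t1``, collapse only at the end)."""
    if not 0 < t1 <= t2:
        raise ValueError(f"need 0 < t1 <= t2, got t1={t1}, t2={t2}")
    psi0 = validate_amplitudes(init_amps)
    U = unitary_matrices(params, [t1, t2 - t1], lattice)
    psi2 = U[float(t2 - t1)] @ (U[float(t1)] @ psi0)
    return float(category_masses(np.abs(psi2) ** 2, lattice)[category_index(category)])


def joint_rating_probability_q(params: QuantumParams, t1: float, t2: float,
                               cat1: str, cat2: str, init_amps: np.ndarray,
                               lattice: BeliefLattice) -> float:
    """Probability of rating ``cat1`` at ``t1`` and then ``cat2`` at ``t2``."""
    table = joint_table_q(params, t1, t2, init_amps, lattice)
    return float(table[category_index(cat1), category_index(cat2)])


def interference_effect(params: QuantumParams, t1: float, t2: float, category: str,
                        init_amps: np.ndarray, lattice: BeliefLattice) -> float:
    """Signed interference of the intermediate rating on the ``t2`` marginal.

    Returns ``sum_k p(k at t1, category at t2) - p(category at t2)``: the
    probability of the second rating *with* an intervening first rating
    minus the probability *without* one.  Identically zero for the Markov
    chain (Chapman-Kolmogorov); generally nonzero for the quantum walk,
    and exactly zero when ``sigma = 0`` (diagonal dynamics commute with the
    category projectors).
    """
    table = joint_table_q(params, t1, t2, init_amps, lattice)
    marginal = marginal_rating_probability_q(params, t1, t2, category, init_amps, lattice)
    return float(table[:, category_index(category)].sum() - marginal)
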