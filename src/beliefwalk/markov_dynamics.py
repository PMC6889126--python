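"""Continuous-time Markov chain dynamics of belief change.

The belief state performs a nearest-neighbour random walk on the evidence
lattice, generated by a tridiagonal intensity matrix ``K`` with downward
rate ``alpha`` and upward rate ``beta``.  The chain is parameterized by a
drift rate ``mu = alpha / (alpha + beta)`` and a diffusion rate
``gamma = alpha + beta`` (both rates per second).  Note the direction
convention implied by the intensity matrix (``K[i, j] = alpha`` for
``i = j - 1``): ``mu > 1/2`` drifts toward *low* states, so drift toward
the correct/high end of the rescored rating scale corresponds to
``mu < 1/2``.

The transition operator is the matrix exponential ``T(t) = expm(t K)``.
Response probabilities arise by evolving an initial distribution and
summing the probability mass inside a rating category's block; sequential
(joint) probabilities project the distribution onto the first-rating block
before the second evolution stage.  Because the category projectors resolve
the identity and ``T`` obeys the Chapman-Kolmogorov semigroup law, summing
the joint probabilities over the first rating reproduces the marginal
exactly — the Markov model predicts *no interference* from the intermediate
rating, which is the central qualitative contrast with the quantum walk in
:mod:`beliefwalk.quantum_dynamics`.

A drift-variability variant ("Markov-V") mixes the joint probabilities over
a discretized normal distribution of drift rates with common diffusion rate
``upsilon``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.stats import norm

from .belief_space import (
    CATEGORIES,
    BeliefLattice,
    category_index,
    category_masses,
    validate_distribution,
)

__all__ = [
    "MarkovParams",
    "MarkovVParams",
    "intensity_matrix",
    "transition_matrix",
    "transition_matrices",
    "joint_table",
    "marginal_rating_probability",
    "joint_rating_probability",
    "drift_grid",
    "markov_v_joint_table",
    "markov_v_joint_probability",
]

logger = logging.getLogger(__name__)

# Drift grid points are clipped into this open interval so every mixture
# component remains a valid chain.
_MU_CLIP = (1e-6, 1.0 - 1e-6)
_clip_warned = False  # the clipping warning is emitted once per process


@dataclass(frozen=True)
class MarkovParams:
    """Drift/diffusion parameterization of the belief random walk.

    ``mu`` in (0, 1) is the drift rate ``alpha / (alpha + beta)``;
    ``gamma > 0`` is the diffusion rate ``alpha + beta`` (events per
    second).
    """

    mu: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if self.gamma <= 0.0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    @property
    def alpha(self) -> float:
        """Downward (toward state 1) transition rate, 1/s."""
        return self.mu * self.gamma

    @property
    def beta(self) -> float:
        """Upward (toward state n) transition rate, 1/s."""
        return (1.0 - self.mu) * self.gamma


@dataclass(frozen=True)
class MarkovVParams:
    """Parameters of the drift-variability (Markov-V) mixture.

    The drift rate varies from trial to trial as Normal(``mu_mean``,
    ``mu_sd``²); ``upsilon`` is the common diffusion rate.
    """

    mu_mean: float
    mu_sd: float
    upsilon: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu_mean < 1.0:
            raise ValueError(f"mu_mean must lie in (0, 1), got {self.mu_mean}")
        if self.mu_sd < 0.0:
            raise ValueError(f"mu_sd must be nonnegative, got {self.mu_sd}")
        if self.upsilon <= 0.0:
            raise ValueError(f"upsilon must be positive, got {self.upsilon}")


def intensity_matrix(params: MarkovParams, lattice: BeliefLattice) -> np.ndarray:
    """Conservative tridiagonal generator ``K`` of the belief random walk.

    ``K[j-1, j] = alpha`` (downward move) and ``K[j+1, j] = beta`` (upward
    move) on the interior.  Each diagonal entry equals minus the total
    outgoing rate of its column, so boundary columns lose only their single
    available move and every column sums to zero: probability is conserved
    and ``expm(t K)`` is a proper stochastic matrix.
    """
    n = lattice.n_states
    a, b = params.alpha, params.beta
    K = np.zeros((n, n))
    idx = np.arange(n - 1)
    K[idx, idx + 1] = a       # i = j - 1: move down at rate alpha
    K[idx + 1, idx] = b       # i = j + 1: move up at rate beta
    np.fill_diagonal(K, -K.sum(axis=0))
    return K


def _float_gcd(values, tol: float = 1e-9) -> float:
    """Approximate positive gcd of a set of floats (0.0 if none found)."""
    g = 0.0
    for v in values:
        v = abs(float(v))
        if v < tol:
            continue
        g = v if g == 0.0 else math.gcd(round(g / tol), round(v / tol)) * tol
    return g


def transition_matrices(K: np.ndarray, times) -> dict[float, np.ndarray]:
    """Transition matrices ``T(t) = expm(t K)`` for each requested time.

    When the times share a common base step (as the 0.5/1.0/1.5/2.0 s lags
    of the experimental design do), a single matrix exponential at the base
    step is computed and the remaining operators are built by the semigroup
    property ``T(m b) = T(b)^m``, which is both faster and exactly
    consistent across lags.
    """
    times = sorted({float(t) for t in times})
    for t in times:
        if t < 0:
            raise ValueError("evolution time must be nonnegative")
    out: dict[float, np.ndarray] = {}
    n = K.shape[0]
    pos = [t for t in times if t > 0]
    if 0.0 in times:
        out[0.0] = np.eye(n)
    if not pos:
        return out
    base = _float_gcd(pos)
    mults = [round(t / base) for t in pos] if base > 0 else []
    if base > 0 and max(mults) <= 64 and all(abs(m * base - t) < 1e-9 for m, t in zip(mults, pos)):
        Tb = expm(base * K)
        powers = {1: Tb}
        for t, m in zip(pos, mults):
            if m not in powers:
                # build T(b)^m from the largest available smaller power
                k = max(p for p in powers if p <= m)
                P = powers[k]
                while k < m:
                    P = P @ Tb
                    k += 1
                    powers[k] = P
            out[t] = powers[m]
    else:
        for t in pos:
            out[t] = expm(t * K)
    return out


def transition_matrix(params: MarkovParams, t: float, lattice: BeliefLattice) -> np.ndarray:
    """Stochastic transition matrix ``T(t) = expm(t K)``; requires ``t >= 0``."""
    if t < 0:
        raise ValueError("evolution time must be nonnegative")
    return transition_matrices(intensity_matrix(params, lattice), [t])[float(t)]


def _joint_from_propagators(T1: np.ndarray, Tdt: np.ndarray, init: np.ndarray,
                            lattice: BeliefLattice) -> np.ndarray:
    """3x3 joint category table given the two stage propagators."""
    phi1 = T1 @ init
    n = lattice.n_states
    collapsed = np.zeros((n, 3))
    for a, cat in enumerate(CATEGORIES):
        blk = lattice.category_block(cat)
        collapsed[blk, a] = phi1[blk]
    phi2 = Tdt @ collapsed  # column a: unnormalized distribution after collapse on category a
    table = np.empty((3, 3))
    for b, cat in enumerate(CATEGORIES):
        table[:, b] = phi2[lattice.category_block(cat), :].sum(axis=0)
    return table


def joint_table(params: MarkovParams, t1: float, t2: float, init: np.ndarray,
                lattice: BeliefLattice) -> np.ndarray:
    """Joint probability table of the two category ratings at ``t1`` and ``t2``.

    Entry ``[k, l]`` is the probability of rating category ``k`` at ``t1``
    followed by category ``l`` at ``t2`` (categories in L/M/H order): the
    initial distribution is evolved to ``t1``, projected onto block ``k``
    (without renormalization), evolved for ``t2 - t1``, and summed over
    block ``l``.  The table sums to 1.
    """
    if not 0 < t1 < t2:
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    init = validate_distribution(init)
    K = intensity_matrix(params, lattice)
    T = transition_matrices(K, [t1, t2 - t1])
    return _joint_from_propagators(T[float(t1)], T[float(t2 - t1)], init, lattice)


def marginal_rating_probability(params: MarkovParams, t1: float, t2: float,
                                category: str, init: np.ndarray,
                                lattice: BeliefLattice) -> float:
    """Probability of rating category ``category`` at ``t2`` with no
    intermediate measurement (the evolution runs ``t1`` then ``t2 - t1``)."""
    if not 0 < t1 <= t2:
        raise ValueError(f"need 0 < t1 <= t2, got t1={t1}, t2={t2}")
    init = validate_distribution(init)
    K = intensity_matrix(params, lattice)
    T = transition_matrices(K, [t1, t2 - t1])
    phi2 = T[float(t2 - t1)] @ (T[float(t1)] @ init)
    return float(category_masses(phi2, lattice)[category_index(category)])


def joint_rating_probability(params: MarkovParams, t1: float, t2: float,
                             cat1: str, cat2: str, init: np.ndarray,
                             lattice: BeliefLattice) -> float:
    """Probability of rating ``cat1`` at ``t1`` and then ``cat2`` at ``t2``."""
    table = joint_table(params, t1, t2, init, lattice)
    return float(table[category_index(cat1), category_index(cat2)])


def drift_grid(mu_mean: float, mu_sd: float, n_grid: int = 21) -> tuple[np.ndarray, np.ndarray]:
    """Discretized normal distribution of drift rates.

    Returns ``n_grid`` equally spaced points spanning ``mu_mean ± 3
    mu_sd`` with weights proportional to the normal density, renormalized
    to sum 1.  Points falling outside (0, 1) are clipped just inside and a
    warning is logged.  With ``mu_sd = 0`` the grid degenerates to the
    single point ``mu_mean``.
    """
    if n_grid < 1 or n_grid % 2 == 0:
        raise ValueError("n_grid must be a positive odd integer")
    if mu_sd == 0.0:
        return np.array([mu_mean]), np.array([1.0])
    mus = np.linspace(mu_mean - 3.0 * mu_sd, mu_mean + 3.0 * mu_sd, n_grid)
    w = norm.pdf(mus, loc=mu_mean, scale=mu_sd)
    if mus[0] < _MU_CLIP[0] or mus[-1] > _MU_CLIP[1]:
        global _clip_warned
        if not _clip_warned:
            logger.warning(
                "drift grid for mu_mean=%g, mu_sd=%g extends outside (0, 1); clipping "
                "(further occurrences logged at debug level)", mu_mean, mu_sd)
            _clip_warned = True
        else:
            logger.debug("drift grid for mu_mean=%g, mu_sd=%g clipped", mu_mean, mu_sd)
        mus = np.clip(mus, *_MU_CLIP)
        # clipping can stack several grid points on a boundary; merge them
        mus, inverse = np.unique(mus, return_inverse=True)
        w = np.bincount(inverse, weights=w)
    return mus, w / w.sum()


def markov_v_joint_table(params: MarkovVParams, t1: float, t2: float, init: np.ndarray,
                         lattice: BeliefLattice, n_grid: int = 21) -> np.ndarray:
    """Joint category table of the drift-variability mixture.

    The plain-chain joint table is averaged over the discretized drift
    distribution at common diffusion rate ``upsilon``; with ``mu_sd = 0``
    this reduces exactly to :func:`joint_table`.
    """
    if not 0 < t1 < t2:
        raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
    init = validate_distribution(init)
    mus, weights = drift_grid(params.mu_mean, params.mu_sd, n_grid)
    table = np.zeros((3, 3))
    for m, w in zip(mus, weights):
        table += w * joint_table(MarkovParams(m, params.upsilon), t1, t2, init, lattice)
    return table


def markov_v_joint_probability(params: MarkovVParams, t1: float, t2: float,
                               cat1: str, cat2: str, init: np.ndarray,
                               lattice: BeliefLattice, n_grid: int = 21) -> float:
    """Single entry of :func:`markov_v_joint_table`."""
    table = markov_v_joint_table(params, t1, t2, init, lattice, n_grid)
    return float(table[category_index(cat1), category_index(cat2)])
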