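"""Discrete belief lattice, initial states, projectors, and rating categories.

Beliefs about the direction of a noisy motion stimulus are represented as a
position on a one-dimensional lattice of ``n_states`` evidence levels
(99 by default).  State 1 means certainty that the dots move in the
*incorrect* direction, the midpoint state means complete uncertainty, and
state ``n_states`` means certainty in the *correct* direction.  Confidence
ratings on the 0-100 scale are analysed in three categories:

* ``L`` — low ratings, 0-33
* ``M`` — medium ratings, 34-66
* ``H`` — high ratings, 67-100

With ``n_states`` divisible by 3 the lattice splits into three equal
contiguous blocks that correspond to the rating categories, and each
category has an associated diagonal 0/1 projection operator.

Two state containers are used throughout the package: a *belief
distribution* (a probability vector over the lattice, the Markov state) and
an *amplitude vector* (a complex unit vector whose squared moduli are the
measurement probabilities, the quantum state).  Both are plain numpy
arrays; :func:`validate_distribution` and :func:`validate_amplitudes`
enforce their invariants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CATEGORIES",
    "BeliefLattice",
    "category_index",
    "validate_distribution",
    "validate_amplitudes",
    "make_initial_distribution",
    "make_initial_amplitudes",
    "rescore_rating",
    "categorize_rating",
    "category_masses",
]

#: Rating categories in lattice order (low evidence to high evidence).
CATEGORIES: tuple[str, str, str] = ("L", "M", "H")

# Rating-scale category boundaries: L = [0, 33], M = [34, 66], H = [67, 100].
_RATING_EDGES = (33, 66)


def category_index(category: str) -> int:
    """Return the 0-based index of a category label (``L``→0, ``M``→1, ``H``→2)."""
    try:
        return CATEGORIES.index(category)
    except ValueError:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}") from None


@dataclass(frozen=True)
class BeliefLattice:
    """Evidence lattice of ``n_states`` ordered belief states.

    States are indexed 1..n_states.  ``n_states`` must be divisible by 3 so
    the category projectors partition the lattice into equal thirds.
    """

    n_states: int = 99

    def __post_init__(self) -> None:
        if self.n_states <= 0:
            raise ValueError("n_states must be positive")
        if self.n_states % 3 != 0:
            raise ValueError("n_states must be divisible by 3 so the L/M/H projectors tile the lattice")

    @property
    def states(self) -> np.ndarray:
        """State indices 1..n_states."""
        return np.arange(1, self.n_states + 1)

    @property
    def midpoint(self) -> int:
        """The maximally uncertain state ((n+1)//2; 50 for the 99-state lattice)."""
        return (self.n_states + 1) // 2

    def category_block(self, category: str) -> slice:
        """0-based slice of the lattice belonging to ``category``."""
        third = self.n_states // 3
        i = category_index(category)
        return slice(i * third, (i + 1) * third)

    def category_mask(self, category: str) -> np.ndarray:
        """Boolean membership mask of ``category`` over the lattice."""
        mask = np.zeros(self.n_states, dtype=bool)
        mask[self.category_block(category)] = True
        return mask

    def projector(self, category: str) -> np.ndarray:
        """Diagonal 0/1 projection matrix onto the category's state block."""
        return np.diag(self.category_mask(category).astype(float))

    def state_category(self, state: int) -> str:
        """Category label of a 1-based state index."""
        if not 1 <= state <= self.n_states:
            raise ValueError(f"state {state} outside 1..{self.n_states}")
        return CATEGORIES[(state - 1) // (self.n_states // 3)]


def validate_distribution(probs: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Check that ``probs`` is a probability vector; return it as float array."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("belief distribution must be a 1-d vector")
    if np.any(p < -atol):
        raise ValueError("belief distribution has negative entries")
    if abs(p.sum() - 1.0) > max(atol, 1e-12 * p.size):
        raise ValueError(f"belief distribution sums to {p.sum()!r}, not 1")
    return p


def validate_amplitudes(amps: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Check that ``amps`` has unit squared norm; return it as complex array."""
    a = np.asarray(amps, dtype=complex)
    if a.ndim != 1:
        raise ValueError("amplitude vector must be 1-d")
    nrm = float(np.sum(np.abs(a) ** 2))
    if abs(nrm - 1.0) > max(atol, 1e-12 * a.size):
        raise ValueError(f"squared norm of amplitudes is {nrm!r}, not 1")
    return a


def make_initial_distribution(
    lattice: BeliefLattice,
    center: int | None = None,
    sd_states: float = 5.0,
) -> np.ndarray:
    """Discretized Gaussian initial belief distribution.

    Evaluates the normal density with the given center (default: the
    maximally uncertain midpoint state) and standard deviation in lattice
    steps at each state index, truncates at the lattice boundaries, and
    renormalizes to sum 1.
    """
    if sd_states <= 0:
        raise ValueError("sd_states must be positive")
    if center is None:
        center = lattice.midpoint
    if not 1 <= center <= lattice.n_states:
        raise ValueError(f"center {center} outside 1..{lattice.n_states}")
    z = (lattice.states - center) / float(sd_states)
    w = np.exp(-0.5 * z**2)
    return w / w.sum()


def make_initial_amplitudes(dist: np.ndarray) -> np.ndarray:
    """Amplitude vector with zero phase whose squared moduli equal ``dist``.

    Any global phase is unobservable; relative phases would alter the
    dynamics, and the all-zero phase is the minimal assumption for an
    initial state specified only through its probability distribution.
    """
    p = validate_distribution(dist)
    return np.sqrt(p).astype(complex)


def rescore_rating(raw_rating, true_direction):
    """Rescore raw 0-100 ratings so that 100 always means certainty in the
    correct direction.

    Ratings on right-moving trials are kept; ratings on left-moving trials
    become ``100 - rating``.  Accepts scalars or arrays (``true_direction``
    as ``"left"``/``"right"`` or an array of those strings).
    """
    r = np.asarray(raw_rating, dtype=float)
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("ratings must lie in [0, 100]")
    d = np.asarray(true_direction)
    if not np.all(np.isin(d, ("left", "right"))):
        raise ValueError("true_direction must be 'left' or 'right'")
    out = np.where(d == "left", 100.0 - r, r)
    if np.isscalar(raw_rating) or out.ndim == 0:
        return float(out)
    return out


def categorize_rating(rescored_rating):
    """Map rescored 0-100 ratings to category labels L/M/H.

    L covers [0, 33], M covers [34, 66], H covers [67, 100].  Accepts
    scalars (returns a label) or arrays (returns an array of labels).
    """
    r = np.asarray(rescored_rating, dtype=float)
    if np.any(r < 0) or np.any(r > 100):
        raise ValueError("ratings must lie in [0, 100]")
    idx = np.digitize(r, _RATING_EDGES, right=True)
    labels = np.asarray(CATEGORIES, dtype=object)[idx]
    if np.isscalar(rescored_rating) or labels.ndim == 0:
        return str(labels)
    return labels


def category_masses(vec: np.ndarray, lattice: BeliefLattice) -> np.ndarray:
    """Projector masses of a state vector, as a length-3 array in L/M/H order.

    For a belief distribution this is the summed probability in each block;
    for an amplitude vector pass the squared moduli.
    """
    v = np.asarray(vec)
    if v.shape != (lattice.n_states,):
        raise ValueError(f"vector length {v.shape} does not match lattice {lattice.n_states}")
    return np.array([v[lattice.category_block(c)].sum().real for c in CATEGORIES])
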