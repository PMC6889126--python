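"""Synthetic trial-level cohorts sampled from the generative models.

Emulates the structure of the evidence-monitoring experiment: a cohort of
participants (11 by default) views random-dot-motion stimuli at four
coherence levels (2, 4, 8, 16 %), half of the trials moving left, and
gives two confidence ratings per trial under three timing conditions with
rating times (0.5, 1.5), (1.5, 2.5) and (0.5, 2.5) seconds.  Responses are
sampled from either the Markov chain, the quantum walk, or the
drift-variability mixture with known per-coherence parameters, so every
stage of the analysis pipeline can be exercised against a known ground
truth.

Sampling happens at state resolution: the first rating's state is drawn
from the model's state distribution at t1; the state then collapses at
category resolution (Markov: the probability mass is conditioned on the
reported category; quantum: the amplitudes are projected onto the category
block and renormalized), evolves over the second interval, and the second
state is drawn.  The induced 3x3 category tables equal the models' joint
probability tables exactly.  Ratings are emitted as the state index (1-99
on the 0-100 scale) on the *rescored* (correct-direction) scale and then
un-rescored for left-moving trials, so the raw records match the
experiment's raw format.  Motor noise on the rating scale is not
simulated.

The per-coherence default parameters give drift toward the correct
direction that grows with coherence, with first-rating means rising from
roughly the scale midpoint at 2 % coherence toward certainty at 16 %,
echoing the coherence ordering of mean ratings in the behavioral data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .belief_space import BeliefLattice, make_initial_amplitudes, make_initial_distribution
from .markov_dynamics import (
    MarkovParams,
    MarkovVParams,
    drift_grid,
    intensity_matrix,
    transition_matrices,
)
from .quantum_dynamics import QuantumParams, unitary_matrices

__all__ = [
    "CONDITION_TIMES",
    "COHERENCE_LEVELS",
    "CohortConfig",
    "TrialSampler",
    "default_params",
    "sample_trial",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Rating-time pairs (t1, t2) in seconds of the three timing conditions.
CONDITION_TIMES: dict[int, tuple[float, float]] = {
    1: (0.5, 1.5),
    2: (1.5, 2.5),
    3: (0.5, 2.5),
}

#: Motion-coherence levels in percent.
COHERENCE_LEVELS: tuple[int, ...] = (2, 4, 8, 16)

# Drift grows with coherence.  Markov drift toward the correct (high) end
# means mu < 1/2 under the intensity-matrix direction convention; for the
# quantum walk the linear potential with positive mu pushes the packet
# toward high states.  Diffusion rates are held constant across coherence.
_DEFAULT_PARAMS: dict[str, dict[int, object]] = {
    "markov": {
        2: MarkovParams(0.47, 30.0),
        4: MarkovParams(0.42, 30.0),
        8: MarkovParams(0.33, 30.0),
        16: MarkovParams(0.18, 30.0),
    },
    "quantum": {
        2: QuantumParams(3.0, 45.0),
        4: QuantumParams(6.0, 45.0),
        8: QuantumParams(10.0, 45.0),
        16: QuantumParams(16.0, 45.0),
    },
    "markov_v": {
        2: MarkovVParams(0.47, 0.08, 30.0),
        4: MarkovVParams(0.42, 0.08, 30.0),
        8: MarkovVParams(0.33, 0.08, 30.0),
        16: MarkovVParams(0.18, 0.08, 30.0),
    },
}

_COHORT_HEADER = "# beliefwalk-cohort v1"
_COLUMNS = ["participant", "session", "coherence", "direction", "condition",
            "t1", "t2", "rating1", "rating2"]


def default_params(model: str) -> dict[int, object]:
    """Per-coherence generating parameters used when a config supplies none."""
    try:
        return dict(_DEFAULT_PARAMS[model])
    except KeyError:
        raise ValueError(f"unknown model {model!r}") from None


@dataclass(frozen=True)
class CohortConfig:
    """Design and ground truth of a synthetic cohort.

    ``params`` maps coherence level to the generating parameter object of
    ``model`` (defaults to :func:`default_params`); ``seed`` controls all
    randomness through per-participant derived substreams.
    """

    model: str = "quantum"
    n_participants: int = 11
    trials_per_cell: int = 48
    coherence_levels: tuple[int, ...] = COHERENCE_LEVELS
    conditions: tuple[int, ...] = (1, 2, 3)
    left_fraction: float = 0.5
    params: Mapping[int, object] | None = None
    init_sd: float = 5.0
    drift_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if not 0.0 <= self.left_fraction <= 1.0:
            raise ValueError("left_fraction must lie in [0, 1]")
        if self.drift_jitter_sd < 0.0:
            raise ValueError("drift_jitter_sd must be nonnegative")
        unknown = [c for c in self.conditions if c not in CONDITION_TIMES]
        if unknown:
            raise ValueError(f"unknown condition id(s) {unknown}; valid: {sorted(CONDITION_TIMES)}")

    def params_for(self, coherence: int) -> object:
        table = self.params if self.params is not None else _DEFAULT_PARAMS[self.model]
        try:
            return table[coherence]
        except KeyError:
            raise ValueError(f"no generating parameters for coherence {coherence}") from None


def _jitter_drift(model: str, params: object, delta: float) -> object:
    """Perturb a parameter object's drift component by ``delta``."""
    if model == "markov":
        return MarkovParams(float(np.clip(params.mu + delta, 0.01, 0.99)), params.gamma)
    if model == "markov_v":
        return MarkovVParams(float(np.clip(params.mu_mean + delta, 0.01, 0.99)),
                             params.mu_sd, params.upsilon)
    if model == "quantum":
        return QuantumParams(params.mu + delta, params.sigma)
    raise ValueError(f"unknown model {model!r}")


class TrialSampler:
    """Precomputed sampling distributions for one (model, params, t1, t2) cell.

    Each mixture component holds the state distribution of the first
    rating and, per first-rating category, the state distribution of the
    second rating after the category-level collapse.  The plain models have
    one component; the drift-variability mixture has one per drift-grid
    point.
    """

    def __init__(self, model: str, params: object, t1: float, t2: float,
                 init: np.ndarray, lattice: BeliefLattice, n_grid: int = 21):
        if not 0 < t1 < t2:
            raise ValueError(f"need 0 < t1 < t2, got t1={t1}, t2={t2}")
        self.lattice = lattice
        self.model = model
        n = lattice.n_states
        blocks = [lattice.category_block(c) for c in ("L", "M", "H")]

        def markov_component(p: MarkovParams) -> tuple[np.ndarray, list[np.ndarray]]:
            T = transition_matrices(intensity_matrix(p, lattice), [t1, t2 - t1])
            phi1 = T[float(t1)] @ init
            seconds = []
            for blk in blocks:
                mass = phi1[blk].sum()
                if mass > 1e-14:
                    cond = np.zeros(n)
                    cond[blk] = phi1[blk] / mass
                    seconds.append(np.maximum(T[float(t2 - t1)] @ cond, 0.0))
                else:
                    seconds.append(np.full(n, 1.0 / n))  # never sampled in practice
            return np.maximum(phi1, 0.0), seconds

        if model == "markov":
            comps = [(1.0, *markov_component(params))]
        elif model == "markov_v":
            mus, weights = drift_grid(params.mu_mean, params.mu_sd, n_grid)
            comps = [(w, *markov_component(MarkovParams(m, params.upsilon)))
                     for m, w in zip(mus, weights)]
        elif model == "quantum":
            psi0 = make_initial_amplitudes(init)
            U = unitary_matrices(params, [t1, t2 - t1], lattice)
            psi1 = U[float(t1)] @ psi0
            p1 = np.abs(psi1) ** 2
            seconds = []
            for blk in blocks:
                mass = p1[blk].sum()
                if mass > 1e-14:
                    proj = np.zeros(n, dtype=complex)
                    proj[blk] = psi1[blk] / np.sqrt(mass)
                    seconds.append(np.abs(U[float(t2 - t1)] @ proj) ** 2)
                else:
                    seconds.append(np.full(n, 1.0 / n))
            comps = [(1.0, p1, seconds)]
        else:
            raise ValueError(f"unknown model {model!r}")

        self.weights = np.array([w for w, _, _ in comps])
        self.first = [p1 / p1.sum() for _, p1, _ in comps]
        self.second = [[p2 / p2.sum() for p2 in seconds] for _, _, seconds in comps]

    def sample(self, n_trials: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n_trials`` (state1, state2) pairs (1-based indices)."""
        n = self.lattice.n_states
        third = n // 3
        state1 = np.empty(n_trials, dtype=int)
        state2 = np.empty(n_trials, dtype=int)
        comp = (rng.choice(len(self.weights), size=n_trials, p=self.weights)
                if len(self.weights) > 1 else np.zeros(n_trials, dtype=int))
        for ci in np.unique(comp):
            rows = np.flatnonzero(comp == ci)
            s1 = rng.choice(n, size=rows.size, p=self.first[ci])
            state1[rows] = s1 + 1
            cats = s1 // third
            for k in range(3):
                sub = rows[cats == k]
                if sub.size:
                    state2[sub] = rng.choice(n, size=sub.size, p=self.second[ci][k]) + 1
        return state1, state2


def sample_trial(model: str, params: object, condition_times: tuple[float, float],
                 init: np.ndarray, rng: np.random.Generator,
                 lattice: BeliefLattice | None = None) -> tuple[int, int, int, int]:
    """Sample a single trial; returns (state1, state2, rating1, rating2).

    Ratings equal the state indices on the rescored (correct-direction)
    scale.  For generating whole cohorts prefer :func:`generate_cohort`,
    which reuses the precomputed sampler across trials.
    """
    lattice = lattice or BeliefLattice()
    t1, t2 = condition_times
    sampler = TrialSampler(model, params, t1, t2, init, lattice)
    s1, s2 = sampler.sample(1, rng)
    return int(s1[0]), int(s2[0]), int(s1[0]), int(s2[0])


def generate_cohort(config: CohortConfig, lattice: BeliefLattice | None = None) -> pd.DataFrame:
    """Generate a full factorial synthetic cohort as a trial table.

    One record per trial with columns ``participant``, ``session``,
    ``coherence``, ``direction``, ``condition``, ``t1``, ``t2``,
    ``rating1``, ``rating2``.  Deterministic for a fixed config: every
    participant draws from an independent substream derived from
    ``config.seed``.
    """
    lattice = lattice or BeliefLattice()
    init = make_initial_distribution(lattice, sd_states=config.init_sd)
    shared: dict[tuple, TrialSampler] = {}
    if config.drift_jitter_sd == 0.0:
        for coh in config.coherence_levels:
            for cond in config.conditions:
                t1, t2 = CONDITION_TIMES[cond]
                shared[(coh, cond)] = TrialSampler(
                    config.model, config.params_for(coh), t1, t2, init, lattice)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    frames = []
    for pidx, seed in enumerate(seeds, start=1):
        rng = np.random.default_rng(seed)
        if config.drift_jitter_sd > 0.0:
            # per-participant heterogeneity: perturb the drift parameter on
            # the model's own drift scale, one draw per participant
            delta = rng.normal(0.0, config.drift_jitter_sd)
            samplers = {}
            for coh in config.coherence_levels:
                jittered = _jitter_drift(config.model, config.params_for(coh), delta)
                for cond in config.conditions:
                    t1, t2 = CONDITION_TIMES[cond]
                    samplers[(coh, cond)] = TrialSampler(
                        config.model, jittered, t1, t2, init, lattice)
        else:
            samplers = shared
        records = []
        for coh in config.coherence_levels:
            for cond in config.conditions:
                t1, t2 = CONDITION_TIMES[cond]
                m = config.trials_per_cell
                s1, s2 = samplers[(coh, cond)].sample(m, rng)
                left = rng.random(m) < config.left_fraction
                r1 = np.where(left, 100 - s1, s1)
                r2 = np.where(left, 100 - s2, s2)
                for i in range(m):
                    records.append((pidx, coh, "left" if left[i] else "right",
                                    cond, t1, t2, int(r1[i]), int(r2[i])))
        frame = pd.DataFrame(records, columns=["participant", "coherence", "direction",
                                               "condition", "t1", "t2", "rating1", "rating2"])
        # trials run in three roughly equal sessions per participant
        frame.insert(1, "session", 1 + (np.arange(len(frame)) * 3) // len(frame))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort trial table as versioned tab-separated text."""
    with open(path, "w") as fh:
        fh.write(_COHORT_HEADER + "\n")
        cohort.to_csv(fh, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort trial table written by :func:`write_cohort` (or any
    tab-separated table with the same columns)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table is missing column(s) {missing}")
    return frame
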