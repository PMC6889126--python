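"""Maximum-likelihood fitting of the belief-dynamics models to rating tables.

Each observation cell of the experiment (one participant, one coherence
level, one timing condition) is a 3x3 table of counts of (first rating
category, second rating category).  The models predict the corresponding
3x3 joint probability table, so the data are multinomial and the fit
criterion is the multinomial log likelihood summed over the calibration
conditions.  Model discrepancy is reported as ``G^2 = -2 LL``.

The calibration/generalization workflow mirrors the study design: the two
free parameters (three for the drift-variability variant) are estimated
from the timing conditions (0.5 s, 1.5 s) and (1.5 s, 2.5 s), and the same
estimates then *predict* the joint table of the held-out condition
(0.5 s, 2.5 s).  :func:`compare_models` forms the signed differences
``G^2_diff`` and ``BIC_diff`` used to compare Markov against quantum
dynamics (positive values favor the second model).

Optimization is multi-start bounded local search (L-BFGS-B) with starts on
a seeded Latin hypercube; scale parameters are sampled on a log scale.
The drift-variability model additionally warm-starts from the plain
Markov solution, whose drift and diffusion estimates are consistent
starting values for the mixture's mean and diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .belief_space import BeliefLattice, make_initial_amplitudes, validate_distribution
from . import markov_dynamics as md
from . import quantum_dynamics as qd

__all__ = [
    "MODEL_NAMES",
    "LIKELIHOOD_FLOOR",
    "JointCountTable",
    "FitReport",
    "ComparisonReport",
    "FitError",
    "make_params",
    "n_parameters",
    "predicted_table",
    "predicted_tables",
    "table_loglik",
    "fit_calibration",
    "generalization_predict",
    "generalization_g2",
    "compare_models",
]

logger = logging.getLogger(__name__)

MODEL_NAMES = ("markov", "quantum", "markov_v")

#: Floor applied to predicted cell probabilities inside the log likelihood,
#: so empty predicted cells with observed counts yield a finite penalty.
LIKELIHOOD_FLOOR = 1e-10

# Optimization bounds per model (box constraints of the local search).
_BOUNDS: dict[str, tuple[tuple[float, float], ...]] = {
    "markov": ((0.001, 0.999), (1e-3, 200.0)),
    "quantum": ((-50.0, 50.0), (1e-3, 50.0)),
    "markov_v": ((0.001, 0.999), (0.0, 0.5 - 1e-6), (1e-3, 200.0)),
}

# Sub-box of the bounds used to place multi-start points, with a flag per
# dimension for log-scale placement (rates span orders of magnitude).
_START_BOX: dict[str, tuple[tuple[float, float, bool], ...]] = {
    "markov": ((0.05, 0.95, False), (0.5, 80.0, True)),
    "quantum": ((-45.0, 45.0, False), (0.2, 50.0, True)),
    "markov_v": ((0.05, 0.95, False), (0.01, 0.3, False), (0.5, 80.0, True)),
}

_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "markov": ("mu", "gamma"),
    "quantum": ("mu", "sigma"),
    "markov_v": ("mu_mean", "mu_sd", "upsilon"),
}


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best incumbent."""

    def __init__(self, message: str, best: "FitReport | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class JointCountTable:
    """3x3 counts of (first rating category, second rating category) for one
    participant x coherence x timing-condition cell, with the condition's
    rating times in seconds."""

    counts: np.ndarray
    t1: float
    t2: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValueError(f"counts must be 3x3, got shape {c.shape}")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(int))
        if not 0 < self.t1 < self.t2:
            raise ValueError(f"need 0 < t1 < t2, got t1={self.t1}, t2={self.t2}")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())


@dataclass
class FitReport:
    """Result of a maximum-likelihood calibration fit.

    ``predicted_tables`` maps condition id to the model's 3x3 probability
    table at the fitted parameters; ``g2 = -2 * loglik``.
    """

    model_name: str
    params: object
    loglik: float
    g2: float
    predicted_tables: dict[int, np.ndarray]
    n_obs: int
    condition_ids: tuple[int, ...]
    condition_times: dict[int, tuple[float, float]]
    n_starts: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        """Plain-data form for JSON/text serialization."""
        return {
            "model": self.model_name,
            "params": {k: float(getattr(self.params, k)) for k in _PARAM_NAMES[self.model_name]},
            "loglik": float(self.loglik),
            "g2": float(self.g2),
            "n_obs": int(self.n_obs),
            "condition_ids": list(self.condition_ids),
            "converged": bool(self.converged),
            "predicted_tables": {str(k): np.asarray(v).tolist() for k, v in self.predicted_tables.items()},
        }


@dataclass(frozen=True)
class ComparisonReport:
    """Signed model-comparison statistics.

    ``g2_diff = g2_a - g2_b`` (positive favors model b) and
    ``bic_diff = g2_diff + n_extra_params * ln(n_obs)``, penalizing model a
    for ``n_extra_params`` additional free parameters relative to model b.
    """

    g2_diff: float
    bic_diff: float
    n_extra_params: int
    n_obs: int


def make_params(model: str, vector) -> object:
    """Build the parameter object of ``model`` from a flat vector."""
    v = [float(x) for x in np.atleast_1d(vector)]
    if model == "markov":
        return md.MarkovParams(*v)
    if model == "quantum":
        return qd.QuantumParams(*v)
    if model == "markov_v":
        return md.MarkovVParams(*v)
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def params_vector(model: str, params: object) -> np.ndarray:
    """Flat vector form of a parameter object (inverse of :func:`make_params`)."""
    return np.array([getattr(params, k) for k in _PARAM_NAMES[model]], dtype=float)


def n_parameters(model: str) -> int:
    """Number of free parameters of ``model`` (2, or 3 for markov_v)."""
    return len(_PARAM_NAMES[model])


def predicted_tables(model: str, params: object, times: list[tuple[float, float]],
                     init: np.ndarray, lattice: BeliefLattice,
                     n_grid: int = 21) -> list[np.ndarray]:
    """Joint probability tables at several (t1, t2) pairs, sharing propagators.

    This is the fitting hot path: for the Markov models one matrix
    exponential per drift value covers every requested time pair (the
    design's lags share a 0.5 s base step), and for the quantum model one
    spectral decomposition covers all time points.
    """
    init = validate_distribution(init)
    for t1, t2 in times:
        if not 0 < t1 < t2:
            raise ValueError(f"need 0 < t1 < t2, got ({t1}, {t2})")
    stage_times = sorted({float(t) for pair in times for t in (pair[0], pair[1] - pair[0])})

    if model == "markov":
        K = md.intensity_matrix(params, lattice)
        T = md.transition_matrices(K, stage_times)
        return [md._joint_from_propagators(T[float(t1)], T[float(t2 - t1)], init, lattice)
                for t1, t2 in times]
    if model == "quantum":
        psi0 = make_initial_amplitudes(init)
        U = qd.unitary_matrices(params, stage_times, lattice)
        return [qd._joint_from_unitaries(U[float(t1)], U[float(t2 - t1)], psi0, lattice)
                for t1, t2 in times]
    if model == "markov_v":
        mus, weights = md.drift_grid(params.mu_mean, params.mu_sd, n_grid)
        tables = [np.zeros((3, 3)) for _ in times]
        for m, w in zip(mus, weights):
            K = md.intensity_matrix(md.MarkovParams(m, params.upsilon), lattice)
            T = md.transition_matrices(K, stage_times)
            for out, (t1, t2) in zip(tables, times):
                out += w * md._joint_from_propagators(T[float(t1)], T[float(t2 - t1)], init, lattice)
        return tables
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def predicted_table(model: str, params: object, t1: float, t2: float,
                    init: np.ndarray, lattice: BeliefLattice, n_grid: int = 21) -> np.ndarray:
    """Joint probability table of ``model`` at one (t1, t2) pair."""
    return predicted_tables(model, params, [(t1, t2)], init, lattice, n_grid)[0]


def _counts_loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log likelihood with floored cell probabilities."""
    p = np.maximum(np.asarray(probs, dtype=float), LIKELIHOOD_FLOOR)
    return float(np.sum(np.asarray(counts) * np.log(p)))


def table_loglik(model: str, params: object, table: JointCountTable,
                 init: np.ndarray, lattice: BeliefLattice, n_grid: int = 21) -> float:
    """Multinomial log likelihood of one count table under ``model``."""
    if table.n_trials == 0:
        raise ValueError("count table has zero trials")
    probs = predicted_table(model, params, table.t1, table.t2, init, lattice, n_grid)
    return _counts_loglik(table.counts, probs)


def _make_starts(model: str, n_starts: int, seed: int) -> np.ndarray:
    """Latin-hypercube start points over the model's start box."""
    box = _START_BOX[model]
    sampler = qmc.LatinHypercube(d=len(box), seed=seed)
    u = sampler.random(n_starts)
    starts = np.empty_like(u)
    for j, (lo, hi, log_scale) in enumerate(box):
        if log_scale:
            starts[:, j] = np.exp(np.log(lo) + u[:, j] * (np.log(hi) - np.log(lo)))
        else:
            starts[:, j] = lo + u[:, j] * (hi - lo)
    return starts


def fit_calibration(model: str, tables: Mapping[int, JointCountTable], init: np.ndarray,
                    lattice: BeliefLattice, *, n_starts: int = 5, seed: int = 0,
                    maxiter: int = 200, n_grid: int = 21,
                    warm_start: object | None = None,
                    optimizer_options: dict | None = None) -> FitReport:
    """Maximum-likelihood fit of ``model`` to the calibration count tables.

    ``tables`` maps condition id to its :class:`JointCountTable`; the log
    likelihoods of all supplied tables are summed with equal weight.  The
    optimizer runs bounded local searches from ``n_starts`` seeded
    Latin-hypercube points (plus ``warm_start`` if given; the
    drift-variability model automatically warm-starts from a plain Markov
    fit).  Deterministic for fixed inputs and seed.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    if not tables:
        raise ValueError("no calibration tables supplied")
    cond_ids = tuple(sorted(tables))
    time_pairs = [(tables[c].t1, tables[c].t2) for c in cond_ids]
    counts = [tables[c].counts for c in cond_ids]
    n_obs = int(sum(c.sum() for c in counts))
    if n_obs == 0:
        raise ValueError("calibration tables contain zero trials")
    init = validate_distribution(init)
    bounds = _BOUNDS[model]

    def negloglik(vector: np.ndarray) -> float:
        try:
            params = make_params(model, vector)
            probs = predicted_tables(model, params, time_pairs, init, lattice, n_grid)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        return -sum(_counts_loglik(c, p) for c, p in zip(counts, probs))

    # The drift-variability model warm-starts from the plain Markov solution
    # (consistent starting values for mu_mean and upsilon), so fewer blind
    # Latin-hypercube starts are needed; n_starts counts all starts.
    n_lhs = max(0, n_starts - 2) if model == "markov_v" and warm_start is None else n_starts
    start_list = [np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
                  for s in _make_starts(model, n_lhs, seed)]
    if warm_start is not None:
        start_list.insert(0, params_vector(model, warm_start))
    if model == "markov_v" and warm_start is None:
        base = fit_calibration("markov", tables, init, lattice,
                               n_starts=n_starts, seed=seed, maxiter=maxiter,
                               optimizer_options=optimizer_options)
        for sd0 in (0.02, 0.1):
            start_list.insert(0, np.array([base.params.mu, sd0, base.params.gamma]))

    options = {"maxiter": maxiter, **(optimizer_options or {})}
    best_res = None
    any_success = False
    for x0 in start_list:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds,
                                options=options)
        any_success = any_success or bool(res.success)
        if best_res is None or res.fun < best_res.fun:
            best_res = res
    assert best_res is not None

    params = make_params(model, best_res.x)
    loglik = -float(best_res.fun)
    pred = predicted_tables(model, params, time_pairs, init, lattice, n_grid)
    report = FitReport(
        model_name=model,
        params=params,
        loglik=loglik,
        g2=-2.0 * loglik,
        predicted_tables={c: t for c, t in zip(cond_ids, pred)},
        n_obs=n_obs,
        condition_ids=cond_ids,
        condition_times={c: (tables[c].t1, tables[c].t2) for c in cond_ids},
        n_starts=len(start_list),
        converged=any_success,
    )
    if not any_success:
        raise FitError(f"no optimizer start converged for model {model!r}", best=report)
    return report


def generalization_predict(fit: FitReport, condition_times: tuple[float, float],
                           init: np.ndarray, lattice: BeliefLattice,
                           n_grid: int = 21) -> np.ndarray:
    """Predicted joint table at a new (t1, t2) pair, parameters unchanged.

    This is the generalization-criterion step: the calibration estimates
    are applied as-is to the held-out timing condition.
    """
    t1, t2 = condition_times
    return predicted_table(fit.model_name, fit.params, t1, t2, init, lattice, n_grid)


def generalization_g2(fit: FitReport, table: JointCountTable, init: np.ndarray,
                      lattice: BeliefLattice, n_grid: int = 21) -> float:
    """Prediction discrepancy ``G^2 = -2 LL`` of the held-out count table
    under the calibrated model's a-priori prediction."""
    probs = generalization_predict(fit, (table.t1, table.t2), init, lattice, n_grid)
    return -2.0 * _counts_loglik(table.counts, probs)


def compare_models(fit_a: FitReport, fit_b: FitReport, n_extra_params: int = 0,
                   n_obs: int | None = None) -> ComparisonReport:
    """Signed comparison of two fits on the same data.

    ``g2_diff = g2_a - g2_b`` (positive favors model b);
    ``bic_diff = g2_diff + n_extra_params * ln(n_obs)`` adds the BIC
    penalty for model a's ``n_extra_params`` additional free parameters
    relative to model b (e.g. one extra parameter per participant when
    fits are summed across a cohort), so positive values again favor
    model b.
    """
    if fit_a.n_obs != fit_b.n_obs or fit_a.condition_ids != fit_b.condition_ids:
        raise ValueError("fits were not computed on identical data")
    if n_obs is None:
        n_obs = fit_a.n_obs
    g2_diff = fit_a.g2 - fit_b.g2
    bic_diff = g2_diff + n_extra_params * float(np.log(n_obs))
    return ComparisonReport(g2_diff=float(g2_diff), bic_diff=float(bic_diff),
                            n_extra_params=int(n_extra_params), n_obs=int(n_obs))
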