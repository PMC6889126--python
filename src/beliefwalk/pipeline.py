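"""End-to-end analysis pipeline: tabulate, fit, predict, compare.

Orchestrates the full generalization-criterion analysis on a trial table
(synthetic or real): rescore and categorize the ratings, cross-tabulate
them into per-cell 3x3 count tables, fit each requested model to the two
calibration timing conditions per participant and coherence level, predict
the held-out condition with the calibrated parameters, and aggregate the
prediction discrepancies into per-coherence ``G^2_diff`` comparisons
(positive values favor the quantum model, following the convention that
the Markov-family discrepancy comes first).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belief_space import BeliefLattice, categorize_rating, make_initial_distribution, rescore_rating, CATEGORIES
from .model_fitting import (
    FitReport,
    JointCountTable,
    compare_models,
    fit_calibration,
    generalization_g2,
    generalization_predict,
)
from .synthetic_data import CONDITION_TIMES

__all__ = [
    "RunConfig",
    "CellResult",
    "StudyReport",
    "tabulate",
    "pooled_table",
    "run_generalization_study",
]

logger = logging.getLogger(__name__)

#: Cells with fewer trials than this trigger a warning during tabulation.
MIN_CELL_TRIALS = 10


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a generalization-criterion run.

    ``calibration_conditions`` are fitted; ``generalization_condition`` is
    predicted a priori.  The default rotation (calibrate on conditions 1
    and 2, predict condition 3) is the study design; the other two
    rotations are valid alternatives.
    """

    models: tuple[str, ...] = ("markov", "quantum", "markov_v")
    calibration_conditions: tuple[int, int] = (1, 2)
    generalization_condition: int = 3
    seed: int = 0
    n_starts: int = 5
    maxiter: int = 200
    n_grid: int = 21
    init_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.generalization_condition in self.calibration_conditions:
            raise ValueError("calibration and generalization conditions must be disjoint")
        for c in (*self.calibration_conditions, self.generalization_condition):
            if c not in CONDITION_TIMES:
                raise ValueError(f"unknown condition id {c}; valid: {sorted(CONDITION_TIMES)}")


@dataclass
class CellResult:
    """Fits and generalization discrepancy for one participant x coherence cell."""

    participant: object
    coherence: object
    model: str
    fit: FitReport
    gen_g2: float
    gen_table: np.ndarray


@dataclass
class StudyReport:
    """Full output of :func:`run_generalization_study`."""

    config: RunConfig
    cells: list[CellResult]
    observed_gen_tables: dict  # coherence -> averaged observed 3x3 proportions
    predicted_gen_tables: dict  # (coherence, model) -> averaged predicted 3x3

    def gen_g2_frame(self) -> pd.DataFrame:
        """Tidy frame of generalization G^2 per participant, coherence, model."""
        rows = [
            {"participant": c.participant, "coherence": c.coherence,
             "model": c.model, "gen_g2": c.gen_g2, "calib_g2": c.fit.g2}
            for c in self.cells
        ]
        return pd.DataFrame(rows)

    def summed_gen_g2(self) -> pd.DataFrame:
        """Generalization G^2 summed across participants (coherence x model)."""
        frame = self.gen_g2_frame()
        return frame.pivot_table(index="coherence", columns="model", values="gen_g2",
                                 aggfunc="sum")

    def gen_g2_diff(self, model_a: str = "markov", model_b: str = "quantum") -> pd.Series:
        """Summed generalization ``G^2_diff = G^2_a - G^2_b`` per coherence
        (positive favors model b)."""
        summed = self.summed_gen_g2()
        return summed[model_a] - summed[model_b]

    def to_dict(self) -> dict:
        """Plain-data form of the study report for JSON serialization."""
        out = {
            "config": {
                "models": list(self.config.models),
                "calibration_conditions": list(self.config.calibration_conditions),
                "generalization_condition": self.config.generalization_condition,
                "seed": self.config.seed,
            },
            "cells": [
                {
                    "participant": _plain(c.participant),
                    "coherence": _plain(c.coherence),
                    "model": c.model,
                    "gen_g2": float(c.gen_g2),
                    "gen_table": np.asarray(c.gen_table).tolist(),
                    "fit": c.fit.to_dict(),
                }
                for c in self.cells
            ],
            "observed_gen_tables": {str(k): np.asarray(v).tolist()
                                    for k, v in self.observed_gen_tables.items()},
            "predicted_gen_tables": {f"{k[0]}:{k[1]}": np.asarray(v).tolist()
                                     for k, v in self.predicted_gen_tables.items()},
        }
        return out

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary_text(self) -> str:
        """Human-readable per-coherence tables in the L1/M1/H1 x L2/M2/H2 layout."""
        lines = []
        summed = self.summed_gen_g2()
        lines.append("Generalization G^2 summed across participants:")
        lines.append(summed.round(2).to_string())
        if {"markov", "quantum"} <= set(summed.columns):
            diff = self.gen_g2_diff("markov", "quantum")
            lines.append("\nG^2_diff (markov - quantum; positive favors quantum):")
            lines.append(diff.round(2).to_string())
        row_labels = [f"{c}1" for c in CATEGORIES]
        col_labels = [f"{c}2" for c in CATEGORIES]
        for coh, obs in sorted(self.observed_gen_tables.items(), key=lambda kv: str(kv[0])):
            lines.append(f"\nCoherence {coh} — observed generalization proportions:")
            lines.append(pd.DataFrame(obs, index=row_labels, columns=col_labels)
                         .round(2).to_string())
            for model in self.config.models:
                pred = self.predicted_gen_tables.get((coh, model))
                if pred is not None:
                    lines.append(f"Coherence {coh} — {model} predicted:")
                    lines.append(pd.DataFrame(pred, index=row_labels, columns=col_labels)
                                 .round(2).to_string())
        return "\n".join(lines)


def _plain(value):
    return value.item() if hasattr(value, "item") else value


def tabulate(cohort: pd.DataFrame) -> dict:
    """Cross-tabulate a trial table into per-cell 3x3 joint count tables.

    Ratings are rescored toward the correct direction and categorized;
    returns a dict mapping (participant, coherence, condition) to
    :class:`JointCountTable`.  Unknown condition ids raise; cells with
    fewer than 10 trials log a warning.
    """
    unknown = set(cohort["condition"].unique()) - set(CONDITION_TIMES)
    if unknown:
        raise ValueError(f"unknown condition id(s) {sorted(unknown)}")
    directions = cohort["direction"].to_numpy()
    cat1 = categorize_rating(rescore_rating(cohort["rating1"].to_numpy(), directions))
    cat2 = categorize_rating(rescore_rating(cohort["rating2"].to_numpy(), directions))
    work = cohort[["participant", "coherence", "condition"]].copy()
    work["cat1"] = cat1
    work["cat2"] = cat2
    tables: dict = {}
    for (pid, coh, cond), grp in work.groupby(["participant", "coherence", "condition"]):
        counts = np.zeros((3, 3), dtype=int)
        for i, a in enumerate(CATEGORIES):
            for j, b in enumerate(CATEGORIES):
                counts[i, j] = int(np.sum((grp["cat1"] == a) & (grp["cat2"] == b)))
        t1, t2 = CONDITION_TIMES[int(cond)]
        if counts.sum() < MIN_CELL_TRIALS:
            logger.warning("cell (participant=%s, coherence=%s, condition=%s) has only %d trials",
                           pid, coh, cond, counts.sum())
        tables[(_plain(pid), _plain(coh), int(cond))] = JointCountTable(counts, t1, t2)
    return tables


def pooled_table(tables: dict, coherence, condition: int) -> JointCountTable:
    """Sum count tables across participants for one coherence x condition cell."""
    matching = [t for (pid, coh, cond), t in tables.items()
                if coh == coherence and cond == condition]
    if not matching:
        raise ValueError(f"no tables for coherence {coherence}, condition {condition}")
    counts = sum(t.counts for t in matching)
    return JointCountTable(counts, matching[0].t1, matching[0].t2)


def run_generalization_study(cohort: pd.DataFrame, config: RunConfig | None = None,
                             lattice: BeliefLattice | None = None) -> StudyReport:
    """Run the full generalization-criterion analysis on a trial table.

    Per participant x coherence x model: fit the calibration conditions by
    maximum likelihood, predict the held-out condition with the fitted
    parameters, and score the prediction with ``G^2``.  Fitting failures
    are logged and flagged on the cell rather than silently dropped.
    """
    config = config or RunConfig()
    lattice = lattice or BeliefLattice()
    init = make_initial_distribution(lattice, sd_states=config.init_sd)
    tables = tabulate(cohort)

    participants = sorted({k[0] for k in tables})
    coherences = sorted({k[1] for k in tables})
    gen_cond = config.generalization_condition

    cells: list[CellResult] = []
    for coh in coherences:
        for pid in participants:
            try:
                calib = {c: tables[(pid, coh, c)] for c in config.calibration_conditions}
                heldout = tables[(pid, coh, gen_cond)]
            except KeyError as err:
                raise ValueError(f"missing condition table {err} for participant {pid}, "
                                 f"coherence {coh}") from None
            for model in config.models:
                cell_seed = config.seed  # same optimizer stream per cell keeps runs reproducible
                logger.info("fitting %s for participant=%s coherence=%s", model, pid, coh)
                fit = fit_calibration(model, calib, init, lattice,
                                      n_starts=config.n_starts, seed=cell_seed,
                                      maxiter=config.maxiter, n_grid=config.n_grid)
                gen_tab = generalization_predict(fit, (heldout.t1, heldout.t2),
                                                 init, lattice, config.n_grid)
                g2 = generalization_g2(fit, heldout, init, lattice, config.n_grid)
                cells.append(CellResult(pid, coh, model, fit, g2, gen_tab))

    observed: dict = {}
    predicted: dict = {}
    for coh in coherences:
        props = []
        for pid in participants:
            t = tables[(pid, coh, gen_cond)]
            if t.n_trials > 0:
                props.append(t.counts / t.n_trials)
        observed[coh] = np.mean(props, axis=0)
        for model in config.models:
            preds = [c.gen_table for c in cells
                     if c.coherence == coh and c.model == model]
            predicted[(coh, model)] = np.mean(preds, axis=0)

    return StudyReport(config=config, cells=cells,
                       observed_gen_tables=observed, predicted_gen_tables=predicted)
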