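"""Cohort-level descriptive and inferential statistics.

Implements the statistical tests applied to the rating cohort:

* likelihood-ratio ``G^2`` homogeneity tests between two independent
  multinomial samples (used both on 3-category marginals and on flattened
  3x3 joint tables), computed per participant and summed across the
  cohort with matching degrees-of-freedom bookkeeping;
* the interference test, which compares the marginal category distribution
  of the *second* rating of the (0.5 s, 1.5 s) condition with the *first*
  rating of the (1.5 s, 2.5 s) condition — both taken at the matched
  1.5 s time point, differing only in whether a rating preceded them;
* chi-square tail/quantile utilities for those statistics;
* per-coherence mean rating change from the first to the second rating,
  with a one-sample Hotelling T^2 test of the participant-level
  mean-change vectors against zero.

Cohorts are pandas DataFrames in the trial-table layout produced by
:mod:`beliefwalk.synthetic_data` (columns ``participant``, ``coherence``,
``condition``, ``direction``, ``rating1``, ``rating2``, ...).  Ratings are
rescored toward the correct direction before categorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist

from .belief_space import CATEGORIES, categorize_rating, rescore_rating

__all__ = [
    "HomogeneityTestResult",
    "HotellingResult",
    "MeanChangeSummary",
    "g2_homogeneity",
    "chi2_upper_tail",
    "chi2_quantile",
    "category_counts",
    "interference_test",
    "joint_condition_test",
    "hotelling_one_sample",
    "mean_change_summary",
]


@dataclass(frozen=True)
class HomogeneityTestResult:
    """Summed ``G^2`` homogeneity statistic for one coherence level."""

    g2: float
    df: int
    p_value: float
    per_participant_g2: dict

    @property
    def critical_value_05(self) -> float:
        """Critical value of the chi-square reference at alpha = 0.05."""
        return chi2_quantile(0.95, self.df)


@dataclass(frozen=True)
class HotellingResult:
    """One-sample Hotelling T^2 test of a multivariate mean against zero."""

    t2: float
    f: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class MeanChangeSummary:
    """Per-coherence mean rating change from t1 to t2.

    ``mean_change`` and ``sd_change`` are the per-participant means and
    standard deviations of (rescored rating2 - rescored rating1), averaged
    across participants, one entry per coherence level; ``hotelling`` tests
    the participant-level mean-change vectors against the zero vector.
    """

    coherence_levels: tuple
    mean_change: np.ndarray
    sd_change: np.ndarray
    hotelling: HotellingResult


def g2_homogeneity(counts_a, counts_b) -> tuple[float, int]:
    """Likelihood-ratio ``G^2`` test of homogeneity of two multinomials.

    Expected counts come from the pooled proportions; cells with zero
    observed count contribute 0 (the ``0 * ln 0 := 0`` convention).
    Returns ``(g2, df)`` with ``df = cells - 1``.
    """
    a = np.asarray(counts_a, dtype=float).ravel()
    b = np.asarray(counts_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("count tables must cover the same category space")
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        raise ValueError("count tables must contain at least one observation each")
    pooled = (a + b) / (na + nb)
    g2 = 0.0
    for obs, total in ((a, na), (b, nb)):
        exp = total * pooled
        nz = obs > 0
        g2 += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / exp[nz])))
    return g2, a.size - 1


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if df <= 0:
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("statistic must be nonnegative")
    return float(chi2.sf(x, df))


def chi2_quantile(p: float, df: int) -> float:
    """Chi-square quantile function (inverse of the lower-tail cdf)."""
    if df <= 0:
        raise ValueError("df must be a positive integer")
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    return float(chi2.ppf(p, df))


def category_counts(ratings, directions) -> np.ndarray:
    """3-vector of L/M/H counts of rescored ratings."""
    labels = categorize_rating(rescore_rating(np.asarray(ratings), np.asarray(directions)))
    labels = np.atleast_1d(labels)
    return np.array([int(np.sum(labels == c)) for c in CATEGORIES])


def _require_conditions(cohort: pd.DataFrame, conditions) -> None:
    present = set(cohort["condition"].unique())
    missing = [c for c in conditions if c not in present]
    if missing:
        raise ValueError(f"cohort is missing condition(s) {missing}")


def interference_test(cohort: pd.DataFrame, cond_with: int = 1,
                      cond_without: int = 2) -> dict:
    """Interference test at the matched rating time, per coherence level.

    For every participant and coherence level, the 3-category marginal of
    the *second* rating of ``cond_with`` (taken at its t2) is compared with
    the marginal of the *first* rating of ``cond_without`` (taken at its
    t1) via :func:`g2_homogeneity`; in the experimental design both
    ratings occur 1.5 s into the trial, so under a Markov process the two
    marginals are equal in distribution and the test is a null test.
    Per-participant statistics are summed per coherence level
    (``df = 2 * n_participants``).  Returns a dict mapping coherence level
    to :class:`HomogeneityTestResult`.
    """
    _require_conditions(cohort, [cond_with, cond_without])
    results: dict = {}
    for coh, grp in cohort.groupby("coherence"):
        per_part: dict = {}
        for pid, pgrp in grp.groupby("participant"):
            with_first = pgrp[pgrp["condition"] == cond_with]
            without_first = pgrp[pgrp["condition"] == cond_without]
            if len(with_first) == 0 or len(without_first) == 0:
                raise ValueError(
                    f"participant {pid!r} at coherence {coh!r} lacks a condition")
            ca = category_counts(with_first["rating2"], with_first["direction"])
            cb = category_counts(without_first["rating1"], without_first["direction"])
            g2_i, _ = g2_homogeneity(ca, cb)
            per_part[pid] = g2_i
        g2 = float(sum(per_part.values()))
        df = (len(CATEGORIES) - 1) * len(per_part)
        results[coh] = HomogeneityTestResult(
            g2=g2, df=df, p_value=chi2_upper_tail(g2, df), per_participant_g2=per_part)
    return results


def _joint_counts(frame: pd.DataFrame) -> np.ndarray:
    """Flattened 3x3 joint category counts of (rating1, rating2)."""
    r1 = categorize_rating(rescore_rating(frame["rating1"].to_numpy(),
                                          frame["direction"].to_numpy()))
    r2 = categorize_rating(rescore_rating(frame["rating2"].to_numpy(),
                                          frame["direction"].to_numpy()))
    out = np.zeros((3, 3))
    for i, c1 in enumerate(CATEGORIES):
        for j, c2 in enumerate(CATEGORIES):
            out[i, j] = np.sum((r1 == c1) & (r2 == c2))
    return out.ravel()


def joint_condition_test(cohort: pd.DataFrame, cond_a: int, cond_b: int) -> dict:
    """Homogeneity test between two conditions' 3x3 joint tables.

    A manipulation check that the timing conditions produce different
    joint rating distributions.  Per participant and coherence level the
    flattened 9-cell tables are compared via :func:`g2_homogeneity` and
    summed across participants (``df = 8 * n_participants``).
    """
    _require_conditions(cohort, [cond_a, cond_b])
    results: dict = {}
    for coh, grp in cohort.groupby("coherence"):
        per_part: dict = {}
        for pid, pgrp in grp.groupby("participant"):
            fa = pgrp[pgrp["condition"] == cond_a]
            fb = pgrp[pgrp["condition"] == cond_b]
            if len(fa) == 0 or len(fb) == 0:
                raise ValueError(
                    f"participant {pid!r} at coherence {coh!r} lacks a condition")
            g2_i, _ = g2_homogeneity(_joint_counts(fa), _joint_counts(fb))
            per_part[pid] = g2_i
        g2 = float(sum(per_part.values()))
        df = (len(CATEGORIES) ** 2 - 1) * len(per_part)
        results[coh] = HomogeneityTestResult(
            g2=g2, df=df, p_value=chi2_upper_tail(g2, df), per_participant_g2=per_part)
    return results


def hotelling_one_sample(X: np.ndarray) -> HotellingResult:
    """One-sample Hotelling T^2 test of the rows' mean vector against zero.

    ``X`` is an (n, p) matrix of participant-level vectors.  Uses the
    standard conversion ``F = (n - p) / (p (n - 1)) * T^2`` with
    ``F(p, n - p)`` reference.  With ``p = 1`` this reduces to the square
    of the one-sample t statistic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than dimensions ({p})")
    xbar = X.mean(axis=0)
    if np.allclose(xbar, 0.0, atol=1e-300):
        # degenerate null case (e.g. all changes exactly zero)
        t2 = 0.0
    elif p == 1:
        s2 = float(X.var(ddof=1))
        if s2 == 0.0:
            raise ValueError("zero variance with nonzero mean: T^2 undefined")
        t2 = float(n * xbar[0] ** 2 / s2)
    else:
        S = np.cov(X, rowvar=False, ddof=1)
        try:
            t2 = float(n * xbar @ np.linalg.solve(S, xbar))
        except np.linalg.LinAlgError:
            raise ValueError("singular covariance matrix: T^2 undefined") from None
    f_stat = (n - p) / (p * (n - 1.0)) * t2
    p_value = float(f_dist.sf(f_stat, p, n - p))
    return HotellingResult(t2=t2, f=f_stat, df=(p, n - p), p_value=p_value)


def mean_change_summary(cohort: pd.DataFrame) -> MeanChangeSummary:
    """Mean rating change from t1 to t2 per coherence level, with a
    Hotelling test of zero mean change.

    Per participant and coherence level the mean and standard deviation of
    (rescored rating2 - rescored rating1), pooled over timing conditions,
    are computed; cross-participant averages are reported, and the
    participant-by-coherence matrix of mean changes is tested against the
    zero vector with :func:`hotelling_one_sample`.
    """
    work = cohort.copy()
    directions = work["direction"].to_numpy()
    change = (rescore_rating(work["rating2"].to_numpy(), directions)
              - rescore_rating(work["rating1"].to_numpy(), directions))
    work["change"] = change
    per_cell = work.groupby(["participant", "coherence"])["change"].agg(["mean", "std"])
    mean_mat = per_cell["mean"].unstack("coherence")
    sd_mat = per_cell["std"].unstack("coherence")
    if mean_mat.isna().any().any():
        raise ValueError("every participant needs trials at every coherence level")
    coherences = tuple(mean_mat.columns)
    hot = hotelling_one_sample(mean_mat.to_numpy())
    return MeanChangeSummary(
        coherence_levels=coherences,
        mean_change=mean_mat.mean(axis=0).to_numpy(),
        sd_change=sd_mat.mean(axis=0).to_numpy(),
        hotelling=hot,
    )
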