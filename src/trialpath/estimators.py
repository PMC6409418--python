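"""Probability-of-success (POS) estimators.

Two estimators of phase-transition probabilities are provided, built from
the transition counts of :mod:`trialpath.programs`:

*Path-by-path* — the ratio of development paths in Phase j+1, observed and
non-observed (imputed), to the paths in Phase j that are not still in
progress::

    POS[j, j+1]  =  n(j+1) / (n_obs(j) + n_m(j) - n_ip(j))

with n(4) read as the approval count.  The overall POS (likelihood of
approval) is the fraction of Phase-1 paths, net of paths still in progress
at any phase, that reached approval::

    POS[1, APP]  =  n_approval / (n_obs(1) + n_m(1) - n_ip(1) - n_ip(2) - n_ip(3))

*Phase-by-phase* — the convention of the earlier literature: the ratio of
directly observed phase transitions to directly observed programs::

    POS_p[j, j+1]  =  (n(j+1) - n_m(j)) / (n_obs(j) - n_ip(j))

multiplied across phases for the overall value.  When no phase records are
missing and nothing is censored the two estimators coincide exactly
(telescoping product); when interior phase records are missing the
phase-by-phase product is biased downward while the path-by-path estimate
is not — the central reason this package reconstructs whole paths.

Standard errors are binomial, sqrt(p(1-p)/n) on the estimate's own
denominator; the phase-by-phase product uses a first-order delta method
treating the factors as independent.  Undefined estimates (empty
denominators) raise :class:`~trialpath.errors.UndefinedEstimateError`
carrying the counts; the windowed variant returns None entries instead so
time series stay aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .errors import UndefinedEstimateError
from .programs import (
    ADVANCED,
    APPROVED,
    IN_PROGRESS,
    TERMINATED,
    DevelopmentProgram,
    PhaseState,
    ThresholdConfig,
    TransitionCounts,
    classify_programs,
)

PATH_BY_PATH = "path_by_path"
PHASE_BY_PHASE = "phase_by_phase"
APPROVAL = "approval"


@dataclass(frozen=True)
class PosEstimate:
    """A POS with its numerator, denominator and binomial standard error."""

    value: float
    numerator: int
    denominator: int
    se: float
    method: str
    phase_from: object
    phase_to: object

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "phase_from": self.phase_from,
            "phase_to": self.phase_to,
            "value": self.value,
            "se": self.se,
            "numerator": self.numerator,
            "denominator": self.denominator,
        }


@dataclass(frozen=True)
class Window:
    """A closed calendar interval [t1, t2] for windowed estimation."""

    t1: pd.Timestamp
    t2: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "t1", pd.Timestamp(self.t1))
        object.__setattr__(self, "t2", pd.Timestamp(self.t2))
        if self.t1 > self.t2:
            raise ValueError(f"window start {self.t1} after end {self.t2}")

    def contains(self, date) -> bool:
        return date is not None and not pd.isna(date) and self.t1 <= date <= self.t2


def binomial_se(value: float, denominator: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) of a proportion."""
    if denominator <= 0:
        raise UndefinedEstimateError("standard error needs a positive denominator")
    return math.sqrt(value * (1.0 - value) / denominator)


def _estimate(num, den, method, phase_from, phase_to, counts) -> PosEstimate:
    if den <= 0:
        raise UndefinedEstimateError(
            f"POS {phase_from}->{phase_to} ({method}) undefined: denominator {den}",
            counts=counts,
        )
    value = num / den
    return PosEstimate(value, num, den, binomial_se(value, den), method, phase_from, phase_to)


def pos_path(counts: TransitionCounts, j: int) -> PosEstimate:
    """Path-by-path POS of advancing from Phase j to Phase j+1 (j+1=4 is approval)."""
    num = counts.n(j + 1)
    den = counts.n_observed[j] + counts.n_m[j] - counts.n_ip[j]
    return _estimate(num, den, PATH_BY_PATH, j, j + 1 if j < 3 else APPROVAL, counts)


def pos_path_overall(counts: TransitionCounts) -> PosEstimate:
    """Path-by-path overall POS: the fraction of Phase-1 paths reaching approval."""
    den = (
        counts.n_observed[1]
        + counts.n_m[1]
        - counts.n_ip[1]
        - counts.n_ip[2]
        - counts.n_ip[3]
    )
    return _estimate(counts.n_approval, den, PATH_BY_PATH, 1, APPROVAL, counts)


def pos_to_approval(counts: TransitionCounts, i: int) -> PosEstimate:
    """Path-by-path POS from Phase i through approval (i=1 is the overall POS)."""
    den = counts.n_observed[i] + counts.n_m[i] - sum(counts.n_ip[k] for k in range(i, 4))
    return _estimate(counts.n_approval, den, PATH_BY_PATH, i, APPROVAL, counts)


def pos_phase(counts: TransitionCounts, j: int) -> PosEstimate:
    """Phase-by-phase POS: observed transitions over observed programs at Phase j."""
    num = counts.n(j + 1) - counts.n_m[j]
    den = counts.n_observed[j] - counts.n_ip[j]
    return _estimate(num, den, PHASE_BY_PHASE, j, j + 1 if j < 3 else APPROVAL, counts)


def pos_phase_overall(counts: TransitionCounts) -> PosEstimate:
    """Phase-by-phase overall POS: the product of the three per-phase factors.

    The standard error uses the first-order delta method with independent
    factors; it is zero when any factor is zero.
    """
    factors = []
    for j in (1, 2, 3):
        try:
            factors.append(pos_phase(counts, j))
        except UndefinedEstimateError as exc:
            raise UndefinedEstimateError(
                f"overall phase-by-phase POS undefined: phase {j} factor undefined",
                counts=counts,
            ) from exc
    value = factors[0].value * factors[1].value * factors[2].value
    if all(f.value > 0 for f in factors):
        rel = math.sqrt(sum((f.se / f.value) ** 2 for f in factors))
        se = value * rel
    else:
        se = 0.0
    den = factors[0].denominator
    return PosEstimate(value, counts.n_approval, den, se, PHASE_BY_PHASE, 1, APPROVAL)


# ---------------------------------------------------------------------------
# Windowed (rolling) estimation — phase-by-phase only.


def _windowed_counts(
    classified: List[Tuple[DevelopmentProgram, List[PhaseState]]], window: Window
) -> TransitionCounts:
    """Counts restricted to phase observations whose decisive date is in the window.

    Membership uses each phase's decisive date (latest end among its
    trials); imputed phases carry no date and never enter a window.  The
    transition outcome of an in-window phase is taken from the full-sample
    classification: an advanced phase counts as an observed transition, a
    terminated one as a failure, an in-progress one is excluded from the
    denominator.  The result is meant for the phase-by-phase formulas; the
    conservation law is not asserted (paths cross window boundaries).
    """
    counts = TransitionCounts()
    for prog, states in classified:
        for s in states:
            if s.phase is None:
                continue
            if not window.contains(s.decisive_date):
                continue
            counts.n_observed[s.phase] += 1
            if s.state == IN_PROGRESS:
                counts.n_ip[s.phase] += 1
            elif s.state == TERMINATED:
                counts.n_t[s.phase] += 1
    return counts


def pos_windowed(
    programs: Iterable[DevelopmentProgram],
    window: Window,
    thresholds: ThresholdConfig,
    _classified=None,
) -> Dict[object, Optional[PosEstimate]]:
    """Phase-by-phase POS over phases that ended inside a calendar window.

    Returns a dict with keys 1, 2, 3 and "overall"; entries are None where
    the window holds no eligible observations (kept absent rather than
    raising, for time-series continuity).
    """
    if _classified is None:
        _classified = classify_programs(list(programs), thresholds)
    counts = _windowed_counts(_classified, window)
    out: Dict[object, Optional[PosEstimate]] = {}
    for j in (1, 2, 3):
        den = counts.n_observed[j] - counts.n_ip[j]
        num = counts.n_observed[j] - counts.n_ip[j] - counts.n_t[j]  # advanced in window
        if den > 0:
            v = num / den
            out[j] = PosEstimate(
                v, num, den, binomial_se(v, den), PHASE_BY_PHASE, j,
                j + 1 if j < 3 else APPROVAL,
            )
        else:
            out[j] = None
    if all(out[j] is not None for j in (1, 2, 3)):
        value = out[1].value * out[2].value * out[3].value
        if all(out[j].value > 0 for j in (1, 2, 3)):
            se = value * math.sqrt(sum((out[j].se / out[j].value) ** 2 for j in (1, 2, 3)))
        else:
            se = 0.0
        out["overall"] = PosEstimate(
            value, out[3].numerator, out[1].denominator, se, PHASE_BY_PHASE, 1, APPROVAL
        )
    else:
        out["overall"] = None
    return out


def estimates_table(counts: TransitionCounts, window: Optional[Window] = None) -> pd.DataFrame:
    """Tidy table of every defined estimate from one set of counts."""
    rows = []
    for j in (1, 2, 3):
        for fn in (pos_path, pos_phase):
            try:
                rows.append(fn(counts, j).as_row())
            except UndefinedEstimateError:
                pass
    for i in (2, 3):
        try:
            rows.append(pos_to_approval(counts, i).as_row())
        except UndefinedEstimateError:
            pass
    for fn in (pos_path_overall, pos_phase_overall):
        try:
            rows.append(fn(counts).as_row())
        except UndefinedEstimateError:
            pass
    df = pd.DataFrame(rows)
    if window is not None:
        df["window_start"] = window.t1
        df["window_end"] = window.t2
    return df
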