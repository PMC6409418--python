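"""Subgroup analyses: strata, completion rates, durations, rolling series.

Everything here operates on cleaned records and/or built programs.  Unit
conventions: a month is 30.4375 days and a year 365.25 days; duration
medians use only concluded trials with observed (non-imputed) end dates;
even-count medians average the two middle values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .programs import (
    ADVANCED,
    APPROVED,
    IN_PROGRESS,
    MISSING_IMPUTED,
    TERMINATED,
    DevelopmentProgram,
    PhaseState,
    ThresholdConfig,
    TransitionCounts,
    classify_programs,
)
from .estimators import PosEstimate, Window, pos_path_overall, pos_windowed
from .registry import CONCLUDED_STATUSES, PHASE_TO_CANONICAL

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

#: Default observation floor for biomarker comparisons: almost all biomarker
#: usage is recorded from 2005 on, so earlier records are excluded to keep
#: the with/without comparison fair.
DEFAULT_BIOMARKER_FLOOR = pd.Timestamp("2005-01-01")


@dataclass(frozen=True)
class StratumSpec:
    """A named conjunction of program-level predicates.

    Each non-None field restricts the stratum; predicates compose with AND.
    """

    name: str
    therapeutic_group: Optional[str] = None
    lead_only: bool = False
    orphan: Optional[bool] = None
    sponsor_class: Optional[str] = None
    min_nonindustry_partners: Optional[int] = None

    def matches(self, program: DevelopmentProgram) -> bool:
        if self.therapeutic_group is not None and program.therapeutic_group != self.therapeutic_group:
            return False
        if self.lead_only and program.is_lead_indication is not True:
            return False
        if self.orphan is not None and program.orphan != self.orphan:
            return False
        if self.sponsor_class is not None and self.sponsor_class not in program.sponsor_classes:
            return False
        if (
            self.min_nonindustry_partners is not None
            and program.max_nonindustry_partners < self.min_nonindustry_partners
        ):
            return False
        return True


# ---------------------------------------------------------------------------
# Completion rates, trials per path, durations


def completion_rates(records: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    """Per-phase completion rates: completed / (completed + failed).

    Early positive stops count as completed; ongoing and planned trials are
    excluded from the denominator.  ``by`` adds a grouping column
    (e.g. "therapeutic_group").  Phases with empty denominators are absent
    from the result.
    """
    df = records.copy()
    df["phase"] = df["phase_label"].map(PHASE_TO_CANONICAL)
    df = df[df["status"].isin(CONCLUDED_STATUSES)]
    df["completed_like"] = df["status"].isin(["completed", "terminated_positive"])
    keys = ["phase"] if by is None else [by, "phase"]
    g = df.groupby(keys)["completed_like"].agg(["sum", "count"]).reset_index()
    g = g[g["count"] > 0]
    g["rate"] = g["sum"] / g["count"]
    g = g.rename(columns={"sum": "n_completed", "count": "n_concluded"})
    g["n_completed"] = g["n_completed"].astype(int)
    return g[keys + ["rate", "n_completed", "n_concluded"]]


def trials_per_path(programs: Iterable[DevelopmentProgram]) -> Dict[int, Optional[float]]:
    """Mean number of trials per path, per phase, over paths with >=1 trial there.

    Imputed (zero-trial) phases do not enter the mean.  Phases 1-4.
    """
    tallies: Dict[int, List[int]] = {1: [], 2: [], 3: [], 4: []}
    for prog in programs:
        phases = prog._cols["phase"][prog._index]
        for j in (1, 2, 3, 4):
            k = int((phases == j).sum())
            if k > 0:
                tallies[j].append(k)
    return {j: (float(np.mean(v)) if v else None) for j, v in tallies.items()}


@dataclass
class DurationSummary:
    phase: int
    group: Optional[str]
    median_years: float
    n: int


def duration_stats(records: pd.DataFrame, by: Optional[str] = None):
    """Median trial durations in years, per phase (and group), plus clinic time.

    Only concluded trials with observed (non-imputed) end dates enter the
    medians.  Clinic time per group is the sum of the Phase 1-3 medians —
    the typical years a development effort spends in the clinic.

    Returns ``(summaries, clinic_time)`` where ``summaries`` is a list of
    :class:`DurationSummary` and ``clinic_time`` maps group (or None) to
    years.
    """
    df = records.copy()
    df["phase"] = df["phase_label"].map(PHASE_TO_CANONICAL)
    ok = (
        df["status"].isin(CONCLUDED_STATUSES)
        & df["end_date"].notna()
        & df["start_date"].notna()
        & ~df["end_date_imputed"]
    )
    df = df[ok]
    df["years"] = (df["end_date"] - df["start_date"]).dt.days / DAYS_PER_YEAR
    keys = ["phase"] if by is None else [by, "phase"]
    out: List[DurationSummary] = []
    for key, sub in df.groupby(keys):
        key = (key,) if not isinstance(key, tuple) else key
        group = None if by is None else key[0]
        phase = int(key[-1])
        out.append(DurationSummary(phase, group, float(sub["years"].median()), len(sub)))
    clinic: Dict[Optional[str], float] = {}
    groups = {s.group for s in out}
    for gname in groups:
        phase_meds = {s.phase: s.median_years for s in out if s.group == gname}
        if all(j in phase_meds for j in (1, 2, 3)):
            clinic[gname] = phase_meds[1] + phase_meds[2] + phase_meds[3]
    return out, clinic


def terminated_vs_advanced(
    programs: Iterable[DevelopmentProgram],
    thresholds: ThresholdConfig,
    phase: int,
    window: Optional[Window] = None,
) -> dict:
    """Duration gap (months) between advanced and terminated phases.

    Collects the durations of Phase ``phase`` trials in programs whose
    Phase ``phase`` advanced versus terminated, and reports
    ``delta_months = median(advanced) - median(terminated)`` (positive when
    terminated phases conclude earlier).  ``window`` restricts to phases
    whose decisive date falls inside it (used for 5-year rolling series).
    An empty group yields ``delta_months=None`` with the counts.
    """
    adv: List[float] = []
    term: List[float] = []
    for prog, states in classify_programs(list(programs), thresholds):
        st = next((s for s in states if s.phase == phase), None)
        if st is None or st.state not in (ADVANCED, TERMINATED):
            continue
        if window is not None and not window.contains(st.decisive_date):
            continue
        t = prog.trials_in_phase(phase)
        t = t[
            t["status"].isin(CONCLUDED_STATUSES)
            & t["end_date"].notna()
            & t["start_date"].notna()
            & ~t["end_date_imputed"]
        ]
        months = ((t["end_date"] - t["start_date"]).dt.days / DAYS_PER_MONTH).tolist()
        (adv if st.state == ADVANCED else term).extend(months)
    result = {
        "phase": phase,
        "n_advanced": len(adv),
        "n_terminated": len(term),
        "median_advanced_months": float(np.median(adv)) if adv else None,
        "median_terminated_months": float(np.median(term)) if term else None,
    }
    if adv and term:
        result["delta_months"] = float(np.median(adv) - np.median(term))
    else:
        result["delta_months"] = None
    return result


# ---------------------------------------------------------------------------
# Biomarker phase-wise stratification


def floor_programs(
    programs: Iterable[DevelopmentProgram], date_floor
) -> List[DevelopmentProgram]:
    """Drop records whose status was observed (trial ended) before the floor.

    Records with no end date (ongoing) are kept.  Programs left with no
    records are dropped unless they carry an approval.
    """
    floor = pd.Timestamp(date_floor)
    out = []
    for prog in programs:
        idx = prog._index
        ends = prog._cols["end"][idx]
        keep = np.isnat(ends) | (ends >= floor.to_datetime64())
        new = DevelopmentProgram(
            prog.drug_id, prog.indication_id, prog._frame, idx[keep], prog._cols,
            prog.approval_date,
        )
        new.is_lead_indication = prog.is_lead_indication
        if len(new) or new.approval_date is not None:
            out.append(new)
    return out


def biomarker_counts(
    programs: Iterable[DevelopmentProgram],
    thresholds: ThresholdConfig,
    mode: str = "selection_only",
    date_floor=DEFAULT_BIOMARKER_FLOOR,
) -> Tuple[TransitionCounts, TransitionCounts]:
    """Phase-wise transition counts split by biomarker usage.

    A program's Phase-j observation lands in the biomarker stratum iff at
    least one Phase-j trial carries the biomarker flag; ``selection_only``
    looks at patient-selection biomarkers, ``expanded`` also accepts
    evaluation/identification biomarkers.  Because programs may switch
    stratum between phases, only the phase-by-phase estimators are
    meaningful on the result; approvals follow the Phase-3 stratum.
    Per phase, biomarker + non-biomarker counts add up to the unstratified
    tally under the same date floor.
    """
    if mode not in ("selection_only", "expanded"):
        raise ConfigurationError(f"unknown biomarker mode {mode!r}")
    progs = list(programs)
    if date_floor is not None:
        progs = floor_programs(progs, date_floor)
    bio = TransitionCounts()
    nonbio = TransitionCounts()

    def has_flag(prog, j):
        if prog.phase_has_flag(j, "bio_selection"):
            return True
        return mode == "expanded" and prog.phase_has_flag(j, "bio_evaluation")

    for prog, states in classify_programs(progs, thresholds):
        phase_states = [s for s in states if s.phase is not None]
        if not phase_states:
            continue
        entry_counts = bio if has_flag(prog, phase_states[0].phase) else nonbio
        entry_counts.n_entry[phase_states[0].phase] += 1
        last_stratum = nonbio
        for s in phase_states:
            stratum = bio if has_flag(prog, s.phase) else nonbio
            last_stratum = stratum
            if s.state == MISSING_IMPUTED:
                stratum.n_m[s.phase] += 1
            else:
                stratum.n_observed[s.phase] += 1
                if s.state == IN_PROGRESS:
                    stratum.n_ip[s.phase] += 1
                elif s.state == TERMINATED:
                    stratum.n_t[s.phase] += 1
        if states[-1].phase is None and states[-1].state == APPROVED:
            last_stratum.n_approval += 1
    return bio, nonbio


# ---------------------------------------------------------------------------
# Lead indications


def lead_indications(programs: Iterable[DevelopmentProgram]) -> List[DevelopmentProgram]:
    """Mark exactly one lead indication per drug.

    The lead is the program with the earliest first trial start; ties break
    by earliest end date, then lexicographically smallest indication_id.
    Programs are returned with ``is_lead_indication`` set; the choice is
    invariant under record order.
    """
    progs = list(programs)
    far = pd.Timestamp.max

    def sort_key(p: DevelopmentProgram):
        s = p.earliest_start()
        e = p.earliest_end()
        return (s if s is not None else far, e if e is not None else far, p.indication_id)

    by_drug: Dict[str, List[DevelopmentProgram]] = {}
    for p in progs:
        by_drug.setdefault(p.drug_id, []).append(p)
    for drug, plist in by_drug.items():
        lead = min(plist, key=sort_key)
        for p in plist:
            p.is_lead_indication = p is lead
    return progs


# ---------------------------------------------------------------------------
# Rolling time series


def rolling_series(
    programs: Iterable[DevelopmentProgram],
    years: Sequence[int],
    thresholds: ThresholdConfig,
    window_years: int = 3,
    strata: Optional[Sequence[StratumSpec]] = None,
) -> pd.DataFrame:
    """Phase-by-phase POS over rolling calendar windows.

    For each year t the window runs from January 1 of year
    ``t - window_years + 1`` to December 31 of year t, clipped to the
    snapshot date for the final window.  One row per (year, stratum,
    measure) with measure in {phase1_2, phase2_3, phase3_app, overall};
    windows touching the snapshot carry ``boundary_biased=True`` — too
    little time has passed for terminations to be declared there, so the
    success rates are biased upward.
    """
    progs = list(programs)
    snapshot = thresholds.snapshot_date
    if strata is None:
        strata = [StratumSpec(name="all")]
    measure_names = {1: "phase1_2", 2: "phase2_3", 3: "phase3_app", "overall": "overall"}
    rows = []
    for spec in strata:
        members = [p for p in progs if spec.matches(p)]
        classified = classify_programs(members, thresholds)
        for t in years:
            t1 = pd.Timestamp(year=t - window_years + 1, month=1, day=1)
            nominal_t2 = pd.Timestamp(year=t, month=12, day=31)
            t2 = min(nominal_t2, snapshot)
            window = Window(t1, t2)
            biased = nominal_t2 >= snapshot
            est = pos_windowed(members, window, thresholds, _classified=classified)
            for key in (1, 2, 3, "overall"):
                e = est[key]
                rows.append(
                    {
                        "year": t,
                        "stratum": spec.name,
                        "measure": measure_names[key],
                        "window_start": t1,
                        "window_end": t2,
                        "value": e.value if e else None,
                        "se": e.se if e else None,
                        "numerator": e.numerator if e else None,
                        "denominator": e.denominator if e else None,
                        "boundary_biased": biased,
                    }
                )
    return pd.DataFrame(rows)


def plot_rolling_series(series: pd.DataFrame, path=None, measure: str = "overall"):
    """Plot a rolling POS series (value ± SE per year per stratum).

    Requires matplotlib; returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    sub = series[series["measure"] == measure]
    for name, g in sub.groupby("stratum"):
        g = g.sort_values("year")
        ax.errorbar(g["year"], g["value"], yerr=g["se"], marker="o", capsize=3, label=name)
    ax.set_xlabel("window end year")
    ax.set_ylabel(f"POS ({measure}, phase-by-phase)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# ---------------------------------------------------------------------------
# Non-industry partner conditioning


def partner_conditioning(
    programs: Iterable[DevelopmentProgram], thresholds: ThresholdConfig
) -> dict:
    """Overall path-by-path POS with vs without non-industry partners.

    Programs are stratified by the maximum ``n_nonindustry_partners`` over
    their records (0 vs >=1); returns both estimates plus the
    percentage-point difference.  An empty stratum yields None.
    """
    progs = list(programs)
    from .programs import tabulate_transitions

    def est(pred):
        from .errors import UndefinedEstimateError

        try:
            counts = tabulate_transitions(progs, thresholds, predicate=pred)
            return pos_path_overall(counts)
        except UndefinedEstimateError:
            return None

    without = est(lambda p: p.max_nonindustry_partners == 0)
    with_ = est(lambda p: p.max_nonindustry_partners >= 1)
    diff = (
        (with_.value - without.value) * 100.0
        if with_ is not None and without is not None
        else None
    )
    return {
        "no_partner": without,
        "with_partner": with_,
        "difference_pp": diff,
    }
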