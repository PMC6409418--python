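"""Development-program reconstruction and phase-transition tabulation.

A *development program* (or development path) is the set of all clinical
trials investigating one drug for one indication.  This module groups
registry records into programs, determines each program's maximum observed
phase, imputes interior phases that must have happened but are missing from
the record, classifies every phase of every path into one of the states

    advanced / terminated / in_progress / missing_imputed / approved

and tallies the transition counts that feed the POS estimators.

Termination heuristic
---------------------
A path's highest observed phase i (without an approval) is declared
terminated when the time elapsed from its most recent trial end date to the
data snapshot exceeds a per-phase allowance t_i; the defaults are 360, 540
and 900 days for Phases 1, 2 and 3.  The Phase-3 allowance folds in the
time a sponsor needs to file for approval and the regulator to decide, so
no separate regulatory-event model is used.  If any trial in the phase is
still missing an end date the phase is in progress; if every trial in the
phase failed the phase is terminated regardless of elapsed time.

Conservation law
----------------
Writing n_obs[j] for paths with observed Phase j trials, n_m[j] for paths
whose Phase j was imputed, and n_ip / n_t for in-progress / terminated
states, the flow of paths obeys, for j = 1, 2, 3,

    n[j+1] = n_obs[j] + n_m[j] - n_ip[j] - n_t[j] + n_entry[j+1]

where n[j] = n_obs[j] + n_m[j] is the total path count at phase j (read
n[4] as the approval count) and n_entry[j] counts paths first seen at
phase j.  Leading missing phases are never fabricated — a path enters the
analysis at its first observed phase — so n_entry is the (usually zero)
correction for late entries.  The tabulator asserts this identity on every
tally it produces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .registry import CONCLUDED_STATUSES, PHASE_TO_CANONICAL

# Phase-state labels.
ADVANCED = "advanced"
TERMINATED = "terminated"
IN_PROGRESS = "in_progress"
MISSING_IMPUTED = "missing_imputed"
APPROVED = "approved"

#: Default elapsed-day allowances before a path's last phase is declared
#: terminated.
DEFAULT_THRESHOLDS: Mapping[int, int] = {1: 360, 2: 540, 3: 900}


def canonical_phase(label: str) -> int:
    """Map a phase label to its canonical phase (P1→1, P1_2→2, P2→2, P2_3→3, P3→3, P4→4)."""
    try:
        return PHASE_TO_CANONICAL[label]
    except KeyError:
        raise ConfigurationError(f"unknown phase label {label!r}") from None


@dataclass(frozen=True)
class ThresholdConfig:
    """Snapshot date plus per-phase termination allowances (days)."""

    snapshot_date: pd.Timestamp
    thresholds: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        object.__setattr__(self, "snapshot_date", pd.Timestamp(self.snapshot_date))
        if pd.isna(self.snapshot_date):
            raise ConfigurationError("snapshot_date is required and must be a date")
        for j in (1, 2, 3):
            if j not in self.thresholds or self.thresholds[j] <= 0:
                raise ConfigurationError(f"threshold for phase {j} must be positive")


@dataclass
class PhaseState:
    """Classification of one phase of one development path.

    ``phase`` is 1-3 for clinical phases and None for the terminal approval
    entry; ``decisive_date`` is the latest end date among the phase's trials
    (None for imputed phases, the approval date for the approval entry).
    """

    phase: Optional[int]
    state: str
    decisive_date: Optional[pd.Timestamp] = None


class DevelopmentProgram:
    """All trials for one drug-indication unit (one development path).

    Holds a view into the parent record table (trials are deduplicated by
    trial_id within the program) plus the joined approval date.  Attribute
    accessors derive program-level features from the member records.
    """

    __slots__ = (
        "drug_id", "indication_id", "approval_date", "is_lead_indication",
        "_frame", "_index", "_cols",
    )

    def __init__(self, drug_id, indication_id, frame, index, cols, approval_date=None):
        self.drug_id = drug_id
        self.indication_id = indication_id
        self.approval_date = approval_date
        self.is_lead_indication: Optional[bool] = None
        self._frame = frame
        self._index = index          # integer positions into frame
        self._cols = cols            # dict of shared numpy column arrays

    # -- record access -------------------------------------------------
    @property
    def trials(self) -> pd.DataFrame:
        """Member records as a DataFrame (copy of the parent rows)."""
        return self._frame.iloc[self._index]

    def trials_in_phase(self, phase: int) -> pd.DataFrame:
        """Records of one canonical phase, sorted by end date (absent last)."""
        sub = self._index[self._cols["phase"][self._index] == phase]
        df = self._frame.iloc[sub]
        return df.sort_values("end_date", na_position="last", kind="stable")

    def __len__(self) -> int:
        return len(self._index)

    # -- derived attributes --------------------------------------------
    @property
    def phases_observed(self) -> Tuple[int, ...]:
        """Sorted canonical phases (1-4) with at least one trial."""
        return tuple(sorted(set(self._cols["phase"][self._index].tolist())))

    @property
    def therapeutic_group(self) -> Optional[str]:
        vals = self._cols["therapeutic_group"][self._index]
        return str(pd.Series(vals).mode().iloc[0]) if len(vals) else None

    @property
    def orphan(self) -> bool:
        return bool(self._cols["orphan"][self._index].any())

    @property
    def sponsor_classes(self) -> frozenset:
        return frozenset(self._cols["sponsor_class"][self._index].tolist())

    @property
    def max_nonindustry_partners(self) -> int:
        idx = self._index
        return int(self._cols["n_partners"][idx].max()) if len(idx) else 0

    def earliest_start(self) -> Optional[pd.Timestamp]:
        s = self._cols["start"][self._index]
        s = s[~np.isnat(s)]
        return pd.Timestamp(s.min()) if len(s) else None

    def earliest_end(self) -> Optional[pd.Timestamp]:
        e = self._cols["end"][self._index]
        e = e[~np.isnat(e)]
        return pd.Timestamp(e.min()) if len(e) else None

    def phase_has_flag(self, phase: int, flag_col: str) -> bool:
        """True when at least one trial of the phase carries the boolean flag."""
        idx = self._index[self._cols["phase"][self._index] == phase]
        return bool(self._cols[flag_col][idx].any())

    def __repr__(self):
        return (
            f"DevelopmentProgram({self.drug_id!r}, {self.indication_id!r}, "
            f"n_trials={len(self)}, phases={self.phases_observed}, "
            f"approved={self.approval_date is not None})"
        )


def build_programs(
    records: pd.DataFrame,
    approvals: Optional[pd.DataFrame] = None,
    grouping: Sequence[str] = ("drug_id", "indication_id"),
    phase4_implies_approval: bool = True,
) -> List[DevelopmentProgram]:
    """Group records into development programs.

    Every record is assigned to exactly one program under ``grouping``
    (default drug-indication; drug-indication-sponsor is available for the
    triplet-level robustness variant).  Trials listed under several sponsors
    collapse to a single record per program.  Approvals are joined on
    (drug_id, indication_id); an approval for an unknown pair is kept as a
    trial-less program (excluded from transition counts) and reported via a
    warning diagnostic on the returned list's ``.approval_warnings``
    attribute equivalent — here simply collected and attached to each such
    program.  If ``phase4_implies_approval``, the presence of a Phase 4
    trial implies approval, dated at the earliest Phase 4 start, unless an
    approval record already says otherwise.
    """
    grouping = list(grouping)
    df = records.drop_duplicates(subset=grouping + ["trial_id"]).reset_index(drop=True)

    cols = {
        "phase": df["phase_label"].map(PHASE_TO_CANONICAL).to_numpy(dtype=np.int8),
        "start": df["start_date"].to_numpy(dtype="datetime64[ns]"),
        "end": df["end_date"].to_numpy(dtype="datetime64[ns]"),
        "status": df["status"].to_numpy(dtype=object),
        "therapeutic_group": df["therapeutic_group"].to_numpy(dtype=object),
        "sponsor_class": df["sponsor_class"].to_numpy(dtype=object),
        "orphan": df["orphan"].to_numpy(dtype=bool),
        "bio_selection": df["biomarker_selection"].to_numpy(dtype=bool),
        "bio_evaluation": df["biomarker_evaluation"].to_numpy(dtype=bool),
        "n_partners": df["n_nonindustry_partners"].to_numpy(dtype=np.int64),
    }

    approval_map: Dict[Tuple[str, str], pd.Timestamp] = {}
    if approvals is not None and len(approvals):
        approval_map = {
            (r.drug_id, r.indication_id): r.approval_date
            for r in approvals.itertuples()
        }

    programs: List[DevelopmentProgram] = []
    seen_pairs = set()
    indices = df.groupby(grouping, sort=True).indices
    for key, idx in indices.items():
        key = (key,) if not isinstance(key, tuple) else key
        drug, ind = key[0], key[1]
        approval = approval_map.get((drug, ind))
        prog = DevelopmentProgram(drug, ind, df, np.asarray(idx), cols, approval)
        if approval is None and phase4_implies_approval and 4 in prog.phases_observed:
            p4 = cols["start"][prog._index[cols["phase"][prog._index] == 4]]
            p4 = p4[~np.isnat(p4)]
            if len(p4):
                prog.approval_date = pd.Timestamp(p4.min())
        programs.append(prog)
        seen_pairs.add((drug, ind))

    # approvals with no matching trials: keep as trial-less programs
    for (drug, ind), date in approval_map.items():
        if (drug, ind) not in seen_pairs:
            programs.append(
                DevelopmentProgram(drug, ind, df, np.asarray([], dtype=np.int64), cols, date)
            )
    return programs


def classify_phase_states(
    program: DevelopmentProgram, thresholds: ThresholdConfig
) -> List[PhaseState]:
    """Classify every phase of one development path.

    Returns an ordered list of :class:`PhaseState`: one entry per clinical
    phase from the path's first observed phase up to its highest evidence
    (highest observed phase, or Phase 3 when approved), plus a terminal
    ``approved`` entry when the program reached approval.  Interior phases
    with no records are imputed as successful (``missing_imputed``);
    leading missing phases are never fabricated.
    """
    idx = program._index
    phases = program._cols["phase"][idx]
    ends = program._cols["end"][idx]
    statuses = program._cols["status"][idx]
    snapshot = thresholds.snapshot_date.to_datetime64()

    observed = sorted({int(p) for p in phases if p <= 3})
    approved = program.approval_date is not None

    if not observed:
        if approved:
            return [PhaseState(None, APPROVED, program.approval_date)]
        return []

    entry, top = observed[0], observed[-1]
    obs_set = set(observed)
    states: List[PhaseState] = []
    for j in range(entry, top + 1):
        if j not in obs_set:
            states.append(PhaseState(j, MISSING_IMPUTED, None))
            continue
        mask = phases == j
        jf_ends = ends[mask]
        has_na = bool(np.isnat(jf_ends).any())
        concluded_ends = jf_ends[~np.isnat(jf_ends)]
        decisive = pd.Timestamp(concluded_ends.max()) if len(concluded_ends) else None
        if j < top or approved:
            states.append(PhaseState(j, ADVANCED, decisive))
            continue
        # last observed phase without approval evidence
        jf_status = statuses[mask]
        if has_na:
            states.append(PhaseState(j, IN_PROGRESS, decisive))
        elif (jf_status == "failed").all():
            states.append(PhaseState(j, TERMINATED, decisive))
        else:
            elapsed = (snapshot - concluded_ends.max()) // np.timedelta64(1, "D")
            if elapsed > thresholds.thresholds[j]:
                states.append(PhaseState(j, TERMINATED, decisive))
            else:
                states.append(PhaseState(j, IN_PROGRESS, decisive))

    if approved:
        for j in range(top + 1, 4):
            states.append(PhaseState(j, MISSING_IMPUTED, None))
        states.append(PhaseState(None, APPROVED, program.approval_date))
    return states


def impute_missing_phases(
    program: DevelopmentProgram, states: List[PhaseState]
) -> List[PhaseState]:
    """Fill interior missing phases of a classified path (idempotent).

    Every phase between the path's first evidence and its highest evidence
    (observed phase or approval) that carries no state is marked
    ``missing_imputed``.  Phases below the first observed phase are never
    created: the path enters the analysis where it is first seen.
    """
    phase_states = {s.phase: s for s in states if s.phase is not None}
    if not phase_states:
        return states
    lo = min(phase_states)
    hi = 3 if program.approval_date is not None else max(phase_states)
    terminal = [s for s in states if s.phase is None]
    out = []
    for j in range(lo, hi + 1):
        out.append(phase_states.get(j, PhaseState(j, MISSING_IMPUTED, None)))
    return out + terminal


@dataclass
class TransitionCounts:
    """The n, n_m, n_ip, n_t and approval tallies behind every POS estimate.

    ``n_observed[j]`` counts paths with observed Phase j trials and
    ``n_m[j]`` paths whose Phase j was imputed; ``n(j)`` (their sum) is the
    total number of paths in Phase j, observed and non-observed, with
    ``n(4)`` read as the approval count.  ``n_entry[j]`` counts paths first
    seen at phase j (late entries; zero when every path starts at Phase 1).
    """

    n_observed: Dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_m: Dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_ip: Dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_t: Dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_entry: Dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    n_approval: int = 0

    def n(self, j: int) -> int:
        """Total paths in Phase j (observed + imputed); n(4) is the approval count."""
        if j == 4:
            return self.n_approval
        return self.n_observed[j] + self.n_m[j]

    def conservation_residuals(self) -> Dict[int, int]:
        """Per-phase residuals of the development-path conservation law."""
        res = {}
        for j in (1, 2, 3):
            res[j] = self.n(j + 1) - (
                self.n_observed[j]
                + self.n_m[j]
                - self.n_ip[j]
                - self.n_t[j]
                + (self.n_entry[j + 1] if j + 1 <= 3 else 0)
            )
        return res

    def check(self) -> None:
        res = self.conservation_residuals()
        if any(v != 0 for v in res.values()):
            raise ConsistencyError(f"conservation law violated: residuals {res}")
        for j in (1, 2, 3):
            if min(self.n_observed[j], self.n_m[j], self.n_ip[j], self.n_t[j]) < 0:
                raise ConsistencyError("negative transition count")
            if self.n_ip[j] + self.n_t[j] > self.n(j):
                raise ConsistencyError("stopped paths exceed phase pool")

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(
            {j: self.n_observed[j] + other.n_observed[j] for j in (1, 2, 3)},
            {j: self.n_m[j] + other.n_m[j] for j in (1, 2, 3)},
            {j: self.n_ip[j] + other.n_ip[j] for j in (1, 2, 3)},
            {j: self.n_t[j] + other.n_t[j] for j in (1, 2, 3)},
            {j: self.n_entry[j] + other.n_entry[j] for j in (1, 2, 3)},
            self.n_approval + other.n_approval,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransitionCounts):
            return NotImplemented
        return dataclasses.asdict(self) == dataclasses.asdict(other)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n"] = {j: self.n(j) for j in (1, 2, 3)}
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionCounts":
        def _ints(m):
            return {int(k): int(v) for k, v in m.items()}

        return cls(
            _ints(d["n_observed"]), _ints(d["n_m"]), _ints(d["n_ip"]),
            _ints(d["n_t"]), _ints(d.get("n_entry", {1: 0, 2: 0, 3: 0})),
            int(d["n_approval"]),
        )


def classify_programs(
    programs: Iterable[DevelopmentProgram], thresholds: ThresholdConfig
) -> List[Tuple[DevelopmentProgram, List[PhaseState]]]:
    """Classify many programs once; reused by tabulation and windowed analyses."""
    return [(p, classify_phase_states(p, thresholds)) for p in programs]


def tabulate_transitions(
    programs: Iterable[DevelopmentProgram],
    thresholds: ThresholdConfig,
    predicate: Optional[Callable[[DevelopmentProgram], bool]] = None,
    _classified: Optional[List[Tuple[DevelopmentProgram, List[PhaseState]]]] = None,
) -> TransitionCounts:
    """Tally transition counts over classified development paths.

    For each path and phase j the tally increments ``n_observed``/``n_m``
    according to whether phase j was observed or imputed, plus the
    in-progress / terminated state counters and the approval count.
    The conservation law is asserted on the result.  ``predicate`` filters
    programs (used for strata).  Trial-less programs contribute nothing.
    """
    if _classified is None:
        programs = list(programs)
        _guard_snapshot(programs, thresholds)
        _classified = classify_programs(programs, thresholds)
    counts = TransitionCounts()
    for prog, states in _classified:
        if predicate is not None and not predicate(prog):
            continue
        phase_states = [s for s in states if s.phase is not None]
        if not phase_states:
            continue
        counts.n_entry[phase_states[0].phase] += 1
        for s in phase_states:
            if s.state == MISSING_IMPUTED:
                counts.n_m[s.phase] += 1
            else:
                counts.n_observed[s.phase] += 1
                if s.state == IN_PROGRESS:
                    counts.n_ip[s.phase] += 1
                elif s.state == TERMINATED:
                    counts.n_t[s.phase] += 1
        if states[-1].phase is None and states[-1].state == APPROVED:
            counts.n_approval += 1
    counts.check()
    return counts


def _guard_snapshot(programs, thresholds: ThresholdConfig) -> None:
    """Reject a snapshot date that predates every end date in the data."""
    snapshot = thresholds.snapshot_date.to_datetime64()
    any_end = False
    for p in programs:
        e = p._cols["end"][p._index]
        e = e[~np.isnat(e)]
        if len(e):
            any_end = True
            if e.min() <= snapshot:
                return
    if any_end:
        raise ConfigurationError(
            "snapshot_date is earlier than every trial end date in the data"
        )


def state_table(
    programs: Iterable[DevelopmentProgram], thresholds: ThresholdConfig
) -> pd.DataFrame:
    """Tidy per-program per-phase state table (drug, indication, phase, state, date)."""
    rows = []
    for prog, states in classify_programs(programs, thresholds):
        for s in states:
            rows.append(
                (
                    prog.drug_id,
                    prog.indication_id,
                    s.phase if s.phase is not None else "approval",
                    s.state,
                    s.decisive_date,
                )
            )
    return pd.DataFrame(
        rows, columns=["drug_id", "indication_id", "phase", "state", "decisive_date"]
    )
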