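"""Reading, validating, filtering and repairing trial-registry tables.

A registry is a flat table with one row per (trial, drug, indication,
sponsor) quartet.  The canonical schema is::

    trial_id, drug_id, indication_id, sponsor_id, sponsor_class,
    phase_label, start_date, end_date, end_date_imputed, status,
    therapeutic_group, biomarker_selection, biomarker_evaluation,
    orphan, source_tag, n_nonindustry_partners

Dates are ISO 8601 (``YYYY-MM-DD``); intervals are inclusive of both
endpoints and a trial's duration in days is ``end_date - start_date``.
``phase_label`` is one of ``P1, P1_2, P2, P2_3, P3, P4`` and ``status``
one of ``completed, failed, ongoing, planned, terminated_positive``.
Trials stopped early with positive results (``terminated_positive``)
are treated as completed throughout the package.

The module deliberately keeps records in a :class:`pandas.DataFrame`
(the field's standard container for flat epidemiological tables); the
grouping into development programs happens in :mod:`trialpath.programs`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, ConfigurationError, ImputationError, SchemaError

#: Canonical column order of a registry table.
SCHEMA_COLUMNS = [
    "trial_id",
    "drug_id",
    "indication_id",
    "sponsor_id",
    "sponsor_class",
    "phase_label",
    "start_date",
    "end_date",
    "end_date_imputed",
    "status",
    "therapeutic_group",
    "biomarker_selection",
    "biomarker_evaluation",
    "orphan",
    "source_tag",
    "n_nonindustry_partners",
]

#: Columns that must be present in the header.  ``end_date_imputed`` and
#: ``source_tag`` are optional on input and default to False / "".
REQUIRED_COLUMNS = [c for c in SCHEMA_COLUMNS if c not in ("end_date_imputed", "source_tag")]

PHASE_LABELS = ("P1", "P1_2", "P2", "P2_3", "P3", "P4")
STATUSES = ("completed", "failed", "ongoing", "planned", "terminated_positive")
SPONSOR_CLASSES = ("industry", "non_industry")

#: Statuses of trials that have concluded; after repair these must carry an
#: end date.  Early positive stops count as completed.
CONCLUDED_STATUSES = frozenset({"completed", "failed", "terminated_positive"})

QUARTET = ["trial_id", "drug_id", "indication_id", "sponsor_id"]

#: Combined-phase labels map onto the higher phase: a Phase 1/2 trial is a
#: Phase 2 trial, a Phase 2/3 trial a Phase 3 trial.
PHASE_TO_CANONICAL = {"P1": 1, "P1_2": 2, "P2": 2, "P2_3": 3, "P3": 3, "P4": 4}

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "True": True, "False": False, "t": True, "f": False, "": False,
}


@dataclass
class FilterReport:
    """Tally of what a cleaning step did to a registry table.

    The arithmetic invariant ``n_output == n_input - n_dropped_missing_dates_or_sponsor
    - n_dropped_pre_window`` holds for every report the module produces.
    """

    n_input: int = 0
    n_dropped_missing_dates_or_sponsor: int = 0
    n_dropped_pre_window: int = 0
    n_end_dates_imputed: int = 0
    n_output: int = 0
    diagnostics: list = field(default_factory=list)

    def check(self) -> None:
        if self.n_output != (
            self.n_input
            - self.n_dropped_missing_dates_or_sponsor
            - self.n_dropped_pre_window
        ):
            raise ConfigurationError(f"inconsistent filter report: {self}")
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, int) and v < 0:
                raise ConfigurationError(f"negative count in filter report: {f_.name}")

    def combined(self, other: "FilterReport") -> "FilterReport":
        """Chain two reports: input of the first, output of the second."""
        return FilterReport(
            n_input=self.n_input,
            n_dropped_missing_dates_or_sponsor=(
                self.n_dropped_missing_dates_or_sponsor
                + other.n_dropped_missing_dates_or_sponsor
            ),
            n_dropped_pre_window=self.n_dropped_pre_window + other.n_dropped_pre_window,
            n_end_dates_imputed=self.n_end_dates_imputed + other.n_end_dates_imputed,
            n_output=other.n_output,
            diagnostics=self.diagnostics + other.diagnostics,
        )

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        s = json.dumps(d, indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _parse_dates(series: pd.Series) -> pd.Series:
    """Strict ISO-8601 date parsing; impossible dates coerce to NaT."""
    s = series.fillna("").astype(str).str.strip()
    return pd.to_datetime(s.where(s != "", None), format="%Y-%m-%d", errors="coerce")


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.fillna("").astype(str).str.strip()
    return s.map(_BOOL_MAP)


def read_registry(path, sep: str = ",", drop_invalid: bool = True):
    """Read and validate a registry CSV/TSV.

    Parameters
    ----------
    path : path-like
        File with the canonical schema (see module docstring).
    sep : str
        Field separator ("," for CSV, "\\t" for TSV).
    drop_invalid : bool
        When True (default), rows with unparseable mandatory fields are
        rejected with a row-numbered diagnostic and tallied in the report;
        when False such rows raise :class:`SchemaError`.

    Returns
    -------
    (pandas.DataFrame, FilterReport)
        Validated records in canonical column order, and the drop tally.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    DuplicateKeyError
        If the same (trial, drug, indication, sponsor) quartet appears twice.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")
    if "end_date_imputed" not in raw.columns:
        raw["end_date_imputed"] = "false"
    if "source_tag" not in raw.columns:
        raw["source_tag"] = ""

    dup_mask = raw.duplicated(subset=QUARTET, keep=False)
    if dup_mask.any():
        offenders = (
            raw.loc[raw.duplicated(subset=QUARTET, keep="first"), QUARTET]
            .apply(tuple, axis=1)
            .tolist()
        )
        raise DuplicateKeyError(offenders)

    df = raw.copy()
    df["start_date"] = _parse_dates(raw["start_date"])
    df["end_date"] = _parse_dates(raw["end_date"])
    for col in ("biomarker_selection", "biomarker_evaluation", "orphan", "end_date_imputed"):
        df[col] = _parse_bool(raw[col])
    df["n_nonindustry_partners"] = pd.to_numeric(
        raw["n_nonindustry_partners"].replace("", "0"), errors="coerce"
    )

    diagnostics = []
    bad = pd.Series(False, index=df.index)

    def _flag(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask & ~bad]:
            # +2: 1-based row numbers counting the header line
            diagnostics.append(f"row {i + 2}: {reason}")
        bad.loc[mask] = True

    _flag(
        (raw["start_date"].str.strip() != "") & df["start_date"].isna(),
        "unparseable start_date",
    )
    _flag((raw["end_date"].str.strip() != "") & df["end_date"].isna(), "unparseable end_date")
    _flag(
        df["start_date"].notna() & df["end_date"].notna() & (df["end_date"] < df["start_date"]),
        "end_date before start_date",
    )
    _flag(~df["phase_label"].isin(PHASE_LABELS), "unknown phase_label")
    _flag(~df["status"].isin(STATUSES), "unknown status")
    _flag(~df["sponsor_class"].isin(SPONSOR_CLASSES), "unknown sponsor_class")
    for col in ("biomarker_selection", "biomarker_evaluation", "orphan", "end_date_imputed"):
        _flag(df[col].isna(), f"unparseable boolean {col}")
    _flag(
        df["n_nonindustry_partners"].isna() | (df["n_nonindustry_partners"] < 0),
        "invalid n_nonindustry_partners",
    )
    _flag(df["trial_id"].str.strip() == "", "empty trial_id")

    if bad.any() and not drop_invalid:
        raise SchemaError("; ".join(diagnostics[:10]))

    out = df.loc[~bad, SCHEMA_COLUMNS].reset_index(drop=True)
    out["n_nonindustry_partners"] = out["n_nonindustry_partners"].astype(int)
    for col in ("biomarker_selection", "biomarker_evaluation", "orphan", "end_date_imputed"):
        out[col] = out[col].astype(bool)

    report = FilterReport(
        n_input=len(raw),
        n_dropped_missing_dates_or_sponsor=int(bad.sum()),
        n_output=len(out),
        diagnostics=diagnostics,
    )
    report.check()
    return out, report


def filter_records(
    records: pd.DataFrame,
    window_start,
    drop_unidentified: bool = True,
):
    """Apply the analysis-window and identification filters.

    Removes records whose (observed) end date falls before ``window_start``
    and — when ``drop_unidentified`` is set — records with an absent start
    date or an unidentified (empty) sponsor.  Records with absent end dates
    are kept: concluded ones are repaired later by
    :func:`impute_end_dates`, ongoing/planned ones are censored.

    Returns ``(records, FilterReport)``.
    """
    try:
        window_start = pd.Timestamp(window_start)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"unparseable window_start: {window_start!r}") from exc
    if pd.isna(window_start):
        raise ConfigurationError("window_start is not a date")

    report = FilterReport(n_input=len(records))
    df = records

    if drop_unidentified:
        unid = df["start_date"].isna() | (df["sponsor_id"].fillna("").str.strip() == "")
        report.n_dropped_missing_dates_or_sponsor = int(unid.sum())
        df = df.loc[~unid]

    pre = df["end_date"].notna() & (df["end_date"] < window_start)
    report.n_dropped_pre_window = int(pre.sum())
    df = df.loc[~pre].reset_index(drop=True)

    report.n_output = len(df)
    report.check()
    return df, report


#: Fallback chain for "similar features" in end-date imputation, from most to
#: least specific.  ``_phase`` is the canonical phase (1-4) derived from
#: ``phase_label``; the global median is the last resort.
DEFAULT_FEATURE_KEYS: Sequence[Sequence[str]] = (
    ("_phase", "therapeutic_group", "sponsor_class"),
    ("_phase", "therapeutic_group"),
    ("_phase",),
    (),
)


def _median_days(values: np.ndarray) -> int:
    """Median duration in whole days; even counts average the middle pair,
    halves round up."""
    med = float(np.median(values))
    return int(math.floor(med + 0.5))


def impute_end_dates(records: pd.DataFrame, feature_keys=None):
    """Repair absent end dates on concluded records.

    Each concluded record (status completed/failed/terminated_positive)
    lacking an end date receives ``end_date = start_date + median duration``
    of donor records sharing the most specific available feature key, and is
    flagged ``end_date_imputed``.  Donors are concluded records with observed
    (non-imputed) end dates.  The fallback chain is
    (phase, therapeutic group, sponsor class) → (phase, therapeutic group)
    → (phase) → global.

    Returns ``(records, FilterReport)`` with ``n_end_dates_imputed`` set.

    Raises
    ------
    ImputationError
        If repairs are needed but no donor anywhere has an observed duration.
    """
    if feature_keys is None:
        feature_keys = DEFAULT_FEATURE_KEYS
    df = records.copy()
    needs_phase = any("_phase" in keys for keys in feature_keys)
    if needs_phase:
        df["_phase"] = df["phase_label"].map(PHASE_TO_CANONICAL)

    concluded = df["status"].isin(CONCLUDED_STATUSES)
    targets = concluded & df["end_date"].isna() & df["start_date"].notna()
    report = FilterReport(n_input=len(df), n_output=len(df))
    if not targets.any():
        report.check()
        if needs_phase:
            df = df.drop(columns="_phase")
        return df, report

    donors = concluded & df["end_date"].notna() & ~df["end_date_imputed"] & df["start_date"].notna()
    if not donors.any():
        raise ImputationError("no records with observed durations to impute from")

    ddf = df.loc[donors]
    durations = (ddf["end_date"] - ddf["start_date"]).dt.days.to_numpy()

    # Precompute group medians for each level of the fallback chain.
    level_medians = []
    for keys in feature_keys:
        if len(keys) == 0:
            level_medians.append(_median_days(durations))
        else:
            grouped = (
                pd.Series(durations, index=pd.MultiIndex.from_frame(ddf[list(keys)]))
                .groupby(level=list(range(len(keys))))
                .apply(lambda v: _median_days(v.to_numpy()))
            )
            level_medians.append(grouped)

    imputed_days = []
    for i in df.index[targets]:
        days = None
        for keys, med in zip(feature_keys, level_medians):
            if len(keys) == 0:
                days = med
                break
            k = tuple(df.loc[i, list(keys)])
            k = k[0] if len(k) == 1 else k
            if k in med.index:
                days = int(med.loc[k])
                break
        imputed_days.append(days)

    tidx = df.index[targets]
    df.loc[tidx, "end_date"] = df.loc[tidx, "start_date"] + pd.to_timedelta(
        imputed_days, unit="D"
    )
    df.loc[tidx, "end_date_imputed"] = True
    report.n_end_dates_imputed = len(tidx)
    report.check()
    if needs_phase:
        df = df.drop(columns="_phase")
    return df, report


def clean_registry(path_or_frame, window_start="2000-01-01", sep: str = ","):
    """Convenience pipeline: read → filter → impute, with a combined report."""
    if isinstance(path_or_frame, pd.DataFrame):
        df, rep = path_or_frame, FilterReport(
            n_input=len(path_or_frame), n_output=len(path_or_frame)
        )
    else:
        df, rep = read_registry(path_or_frame, sep=sep)
    df, rep2 = filter_records(df, window_start)
    df, rep3 = impute_end_dates(df)
    return df, rep.combined(rep2).combined(rep3)


def read_approvals(path, sep: str = ",") -> pd.DataFrame:
    """Read a drug-indication approval table (drug_id, indication_id, approval_date)."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("drug_id", "indication_id", "approval_date"):
        if col not in raw.columns:
            raise SchemaError(f"approvals table missing column {col!r}")
    df = raw.copy()
    df["approval_date"] = _parse_dates(raw["approval_date"])
    if df["approval_date"].isna().any():
        bad = raw.loc[df["approval_date"].isna(), "approval_date"].tolist()
        raise SchemaError(f"unparseable approval_date values: {bad[:5]}")
    if df.duplicated(subset=["drug_id", "indication_id"]).any():
        offenders = df.loc[
            df.duplicated(subset=["drug_id", "indication_id"]),
            ["drug_id", "indication_id"],
        ].apply(tuple, axis=1).tolist()
        raise DuplicateKeyError(offenders)
    return df[["drug_id", "indication_id", "approval_date"]]


def write_records(records: pd.DataFrame, path) -> None:
    """Write records in the canonical schema; round-trips losslessly."""
    out = records.copy()
    for col in ("start_date", "end_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d").fillna("")
    out[SCHEMA_COLUMNS].to_csv(path, index=False)


def write_approvals(approvals: pd.DataFrame, path) -> None:
    out = approvals.copy()
    out["approval_date"] = out["approval_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
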