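"""Synthetic trial-registry generator with known ground truth.

Real registry extracts of this kind are proprietary, so the pipeline is
validated against simulated registries whose latent outcomes are known
exactly.  Each drug carries one or more indications; each drug-indication
program walks the idealized Phase 1 → 2 → 3 → approval ladder, advancing
out of phase j with probability theta_j (modified multiplicatively by
biomarker and partner effects).  Phases hold one or more trials with
lognormal durations; trials still running at the snapshot date are emitted
without end dates; a configurable fraction of concluded trials loses its
end date (to exercise end-date imputation); and — the pattern the two POS
estimators disagree on — an advancing program's entire Phase-2 record set
is deleted with probability m, creating the observed-{1,3} paths whose
Phase 2 must be inferred.

Determinism contract: one master seed; each program draws from its own
sub-stream derived from (seed, program counter), so output is byte-stable
regardless of how programs might be batched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .programs import ThresholdConfig, TransitionCounts
from .registry import SCHEMA_COLUMNS

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25

THERAPEUTIC_GROUPS = (
    ("oncology", 0.30),
    ("cns", 0.12),
    ("autoimmune_inflammation", 0.12),
    ("infectious_disease", 0.10),
    ("metabolic_endocrinology", 0.09),
    ("cardiovascular", 0.08),
    ("vaccines", 0.05),
    ("genitourinary", 0.03),
    ("ophthalmology", 0.03),
    ("other", 0.08),
)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic registry.

    Defaults emulate a large industry registry snapshot taken on
    2015-10-31: per-phase advancement probabilities around (0.66, 0.58,
    0.59), median phase durations of 1.6 / 2.9 / 3.8 years, means of
    1.7 / 2.0 / 2.8 / 3.2 trials per path for Phases 1-4, about 35%
    industry sponsorship and ~15% of concluded trials missing end dates.
    """

    n_drugs: int = 1000
    mean_indications_per_drug: float = 1.9      # truncated geometric, >=1
    max_indications_per_drug: int = 6
    theta: Tuple[float, float, float] = (0.664, 0.583, 0.590)
    mean_trials_per_phase: Tuple[float, float, float, float] = (1.7, 2.0, 2.8, 3.2)
    duration_median_days: Tuple[float, float, float, float] = (584.0, 1059.0, 1388.0, 730.0)
    duration_sigma: float = 0.45
    inter_phase_gap_days: Tuple[int, int] = (60, 270)
    approval_gap_days: Tuple[int, int] = (180, 540)
    snapshot_date: str = "2015-10-31"
    program_start_window: Tuple[str, str] = ("2000-01-01", "2012-12-31")
    missingness_m: float = 0.10
    end_date_missing_fraction: float = 0.146
    failed_status_fraction: float = 0.30        # terminal-phase trials tagged failed
    positive_stop_fraction: float = 0.02        # completed trials tagged terminated_positive
    biomarker_fraction: float = 0.08
    biomarker_effect: float = 1.25
    orphan_fraction: float = 0.05
    industry_fraction: float = 0.35
    partner_fraction: float = 0.30
    partner_effect: float = 1.0
    duration_gap_terminated_months: float = 8.0
    emit_phase4: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("missingness_m", "end_date_missing_fraction", "biomarker_fraction",
                     "orphan_fraction", "industry_fraction", "partner_fraction",
                     "failed_status_fraction", "positive_stop_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        worst = max(self.biomarker_effect, 1.0) * max(self.partner_effect, 1.0)
        for j, th in enumerate(self.theta, start=1):
            if not 0.0 <= th <= 1.0:
                raise ConfigurationError(f"theta[{j}] outside [0, 1]: {th}")
            if th * worst > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"theta[{j}]={th} with subgroup effects exceeds 1"
                )
        if any(m < 1.0 for m in self.mean_trials_per_phase):
            raise ConfigurationError("mean_trials_per_phase entries must be >= 1")
        if any(d <= 0 for d in self.duration_median_days) or self.duration_sigma <= 0:
            raise ConfigurationError("duration parameters must be positive")
        if self.mean_indications_per_drug < 1.0:
            raise ConfigurationError("mean_indications_per_drug must be >= 1")
        lo, hi = map(pd.Timestamp, self.program_start_window)
        if lo > hi:
            raise ConfigurationError("empty program_start_window")
        if lo > pd.Timestamp(self.snapshot_date):
            raise ConfigurationError("program_start_window begins after the snapshot")

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class ProgramTruth:
    """Latent outcome of one simulated program."""

    drug_id: str
    indication_id: str
    max_phase: int                  # highest clinical phase entered (1-3)
    approved: bool                  # passed Phase 3 (approval may postdate snapshot)
    approval_date: Optional[pd.Timestamp]
    stopped_phase: Optional[int]    # phase of latent termination, None if approved
    phase2_deleted: bool
    theta_effective: Tuple[float, float, float]
    # per phase 1..4: emission bookkeeping for the censored oracle
    phase_info: Dict[int, dict] = field(default_factory=dict)


@dataclass
class GroundTruth:
    config: GeneratorConfig
    programs: List[ProgramTruth]

    def to_json(self, path=None) -> str:
        d = {
            "config": dataclasses.asdict(self.config),
            "programs": [dataclasses.asdict(p) for p in self.programs],
        }
        s = json.dumps(d, indent=None, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _truncated_geometric(rng, mean: float, upper: int) -> int:
    if mean <= 1.0:
        return 1
    k = int(rng.geometric(1.0 / mean))
    return int(min(max(k, 1), upper))


def generate(config: GeneratorConfig):
    """Simulate a registry.

    Returns ``(records, approvals, truth)``: a record table in the
    canonical schema, an approval table, and the :class:`GroundTruth`
    with every latent decision.  Byte-identical for identical configs.
    """
    config.validate()
    snapshot = pd.Timestamp(config.snapshot_date)
    snap64 = snapshot.to_datetime64()
    start_lo, start_hi = map(pd.Timestamp, config.program_start_window)
    start_hi = min(start_hi, snapshot)
    span_days = max((start_hi - start_lo).days, 0)

    master = np.random.default_rng(config.seed)
    tg_names = [t[0] for t in THERAPEUTIC_GROUPS]
    tg_weights = np.array([t[1] for t in THERAPEUTIC_GROUPS])
    tg_weights = tg_weights / tg_weights.sum()

    rows: List[tuple] = []
    approvals: List[tuple] = []
    truths: List[ProgramTruth] = []

    pidx = 0
    trial_counter = 0
    day = np.timedelta64(1, "D")

    for d in range(config.n_drugs):
        drug_id = f"DRUG{d:06d}"
        rng_d = np.random.default_rng([config.seed, 10_000_019, d])
        n_ind = _truncated_geometric(
            rng_d, config.mean_indications_per_drug, config.max_indications_per_drug
        )
        for i in range(n_ind):
            indication_id = f"IND{i:02d}"
            rng = np.random.default_rng([config.seed, pidx])
            pidx += 1

            tg = tg_names[int(rng.choice(len(tg_names), p=tg_weights))]
            orphan = bool(rng.random() < config.orphan_fraction)
            bio_program = bool(rng.random() < config.biomarker_fraction)
            industry = bool(rng.random() < config.industry_fraction)
            sponsor_class = "industry" if industry else "non_industry"
            sponsor_id = f"SPN{int(rng.integers(0, 2000)):04d}"
            partners = int(rng.integers(1, 4)) if rng.random() < config.partner_fraction else 0

            theta_eff = []
            for th in config.theta:
                t_ = th
                if bio_program:
                    t_ *= config.biomarker_effect
                if partners > 0:
                    t_ *= config.partner_effect
                theta_eff.append(min(t_, 1.0))

            t0 = (start_lo + pd.Timedelta(days=float(rng.random() * span_days))).normalize()
            current = t0.to_datetime64()

            latent_trials: List[dict] = []   # phase, start, end (latent), stopping flag
            phase_info: Dict[int, dict] = {}
            stopped_phase: Optional[int] = None
            approved = False
            approval_date: Optional[pd.Timestamp] = None
            max_phase = 0

            for j in (1, 2, 3):
                max_phase = j
                adv = bool(rng.random() < theta_eff[j - 1])
                k = 1 + int(rng.poisson(config.mean_trials_per_phase[j - 1] - 1.0))
                starts = current + (rng.random(k) * 90.0 * day).astype("timedelta64[D]")
                durs = config.duration_median_days[j - 1] * np.exp(
                    config.duration_sigma * rng.standard_normal(k)
                )
                if not adv:
                    durs = np.maximum(
                        durs - config.duration_gap_terminated_months * DAYS_PER_MONTH, 30.0
                    )
                ends = starts + (durs * day).astype("timedelta64[D]")
                for s_, e_ in zip(starts, ends):
                    latent_trials.append({"phase": j, "start": s_, "end": e_})
                phase_end = ends.max()
                phase_info[j] = {"latent_end": pd.Timestamp(phase_end)}
                if not adv:
                    stopped_phase = j
                    break
                gap = rng.integers(config.inter_phase_gap_days[0], config.inter_phase_gap_days[1] + 1)
                current = phase_end + gap * day

            if stopped_phase is None:
                approved = True
                gap = rng.integers(config.approval_gap_days[0], config.approval_gap_days[1] + 1)
                approval_date = pd.Timestamp(phase_info[3]["latent_end"].to_datetime64() + gap * day)
                if config.emit_phase4 and approval_date <= snapshot:
                    k4 = 1 + int(rng.poisson(config.mean_trials_per_phase[3] - 1.0))
                    starts = approval_date.to_datetime64() + (
                        rng.random(k4) * 540.0 * day
                    ).astype("timedelta64[D]")
                    durs = config.duration_median_days[3] * np.exp(
                        config.duration_sigma * rng.standard_normal(k4)
                    )
                    ends = starts + (durs * day).astype("timedelta64[D]")
                    for s_, e_ in zip(starts, ends):
                        latent_trials.append({"phase": 4, "start": s_, "end": e_})

            # --- emission with right-censoring at the snapshot -----------
            emitted: List[dict] = []
            for t in latent_trials:
                if t["start"] > snap64:
                    continue
                ongoing = t["end"] > snap64
                rec = dict(t)
                rec["ongoing"] = ongoing
                emitted.append(rec)

            # whole-phase-2 deletion for advancing programs (needs an
            # emitted Phase-3 trial so the gap is interior)
            has_p3 = any(t["phase"] == 3 for t in emitted)
            deleted = False
            if (
                max_phase >= 3
                and has_p3
                and config.missingness_m > 0
                and rng.random() < config.missingness_m
            ):
                emitted = [t for t in emitted if t["phase"] != 2]
                deleted = True

            # per-phase bookkeeping for the censored oracle
            for j in (1, 2, 3, 4):
                trials_j = [t for t in emitted if t["phase"] == j]
                concluded = [t for t in trials_j if not t["ongoing"]]
                info = phase_info.setdefault(j, {})
                info.update(
                    {
                        "n_emitted": len(trials_j),
                        "any_ongoing": any(t["ongoing"] for t in trials_j),
                        "max_end_concluded": (
                            pd.Timestamp(max(t["end"] for t in concluded)) if concluded else None
                        ),
                        "n_concluded": len(concluded),
                        "n_failed": 0,  # filled below
                    }
                )

            for t in emitted:
                trial_counter += 1
                trial_id = f"TR{trial_counter:08d}"
                j = t["phase"]
                if j == 1:
                    label = "P1"
                elif j == 2:
                    label = "P1_2" if rng.random() < 0.10 else "P2"
                elif j == 3:
                    label = "P2_3" if rng.random() < 0.08 else "P3"
                else:
                    label = "P4"
                if t["ongoing"]:
                    status = "ongoing"
                    end_str = ""
                else:
                    if j == stopped_phase and rng.random() < config.failed_status_fraction:
                        status = "failed"
                        phase_info[j]["n_failed"] += 1
                    elif rng.random() < config.positive_stop_fraction:
                        status = "terminated_positive"
                    else:
                        status = "completed"
                    if rng.random() < config.end_date_missing_fraction:
                        end_str = ""
                    else:
                        end_str = pd.Timestamp(t["end"]).strftime("%Y-%m-%d")
                bio_sel = bio_program and rng.random() < 0.8
                bio_eval = rng.random() < 0.04
                rows.append(
                    (
                        trial_id,
                        drug_id,
                        indication_id,
                        sponsor_id,
                        sponsor_class,
                        label,
                        pd.Timestamp(t["start"]).strftime("%Y-%m-%d"),
                        end_str,
                        False,
                        status,
                        tg,
                        bio_sel,
                        bio_eval,
                        orphan,
                        "synthetic",
                        partners,
                    )
                )

            if approved and approval_date is not None and approval_date <= snapshot:
                approvals.append((drug_id, indication_id, approval_date.strftime("%Y-%m-%d")))

            truths.append(
                ProgramTruth(
                    drug_id=drug_id,
                    indication_id=indication_id,
                    max_phase=max_phase,
                    approved=approved,
                    approval_date=approval_date,
                    stopped_phase=stopped_phase,
                    phase2_deleted=deleted,
                    theta_effective=tuple(theta_eff),
                    phase_info=phase_info,
                )
            )

    records = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    records["start_date"] = pd.to_datetime(records["start_date"], format="%Y-%m-%d")
    records["end_date"] = pd.to_datetime(
        records["end_date"].where(records["end_date"] != "", None), format="%Y-%m-%d"
    )
    approvals_df = pd.DataFrame(
        approvals, columns=["drug_id", "indication_id", "approval_date"]
    )
    if len(approvals_df):
        approvals_df["approval_date"] = pd.to_datetime(approvals_df["approval_date"])
    else:
        approvals_df["approval_date"] = pd.Series([], dtype="datetime64[ns]")
    return records, approvals_df, GroundTruth(config=config, programs=truths)


def truth_summary(
    truth: GroundTruth, thresholds: Optional[ThresholdConfig] = None
) -> TransitionCounts:
    """Exact latent transition counts, for oracle comparison.

    Without ``thresholds`` the summary ignores censoring and record
    deletion: every program contributes its latent path (phases entered,
    terminal failure or approval).  With ``thresholds`` the summary
    replays the snapshot heuristics over the latent bookkeeping — emitted
    phases, deletions, elapsed-time terminations — and should match the
    pipeline's tabulation exactly (assuming no end-date blanking, which
    perturbs decisive dates).
    """
    counts = TransitionCounts()
    if thresholds is None:
        for p in truth.programs:
            counts.n_entry[1] += 1
            for j in range(1, p.max_phase + 1):
                counts.n_observed[j] += 1
            if p.approved:
                counts.n_approval += 1
            else:
                counts.n_t[p.stopped_phase] += 1
        counts.check()
        return counts

    snapshot = thresholds.snapshot_date
    for p in truth.programs:
        obs = [
            j
            for j in (1, 2, 3)
            if p.phase_info.get(j, {}).get("n_emitted", 0) > 0
            and not (j == 2 and p.phase2_deleted)
        ]
        if not obs:
            continue
        entry, top = obs[0], obs[-1]
        counts.n_entry[entry] += 1
        approval_known = (
            p.approved and p.approval_date is not None and p.approval_date <= snapshot
        )
        for j in range(entry, top + 1):
            if j in obs:
                counts.n_observed[j] += 1
            else:
                counts.n_m[j] += 1
        if approval_known:
            for j in range(top + 1, 4):
                counts.n_m[j] += 1
            counts.n_approval += 1
            continue
        info = p.phase_info[top]
        if info["any_ongoing"]:
            counts.n_ip[top] += 1
        elif info["n_concluded"] > 0 and info["n_failed"] == info["n_concluded"]:
            counts.n_t[top] += 1
        else:
            elapsed = (snapshot - info["max_end_concluded"]).days
            if elapsed > thresholds.thresholds[top]:
                counts.n_t[top] += 1
            else:
                counts.n_ip[top] += 1
    counts.check()
    return counts


def latent_pos(truth: GroundTruth) -> Dict[object, float]:
    """Empirical latent advancement rates (the generator's realized theta)."""
    counts = truth_summary(truth)
    out: Dict[object, float] = {}
    for j in (1, 2, 3):
        out[j] = counts.n(j + 1) / counts.n(j) if counts.n(j) else float("nan")
    out["overall"] = counts.n_approval / counts.n(1) if counts.n(1) else float("nan")
    return out
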