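import pandas as pd
import pytest

from trialpath.registry import SCHEMA_COLUMNS
from trialpath.programs import ThresholdConfig, build_programs

RECORD_DEFAULTS = dict(
    trial_id=None,
    drug_id="D1",
    indication_id="I1",
    sponsor_id="S1",
    sponsor_class="industry",
    phase_label="P1",
    start_date="2005-01-01",
    end_date="2006-01-01",
    end_date_imputed=False,
    status="completed",
    therapeutic_group="oncology",
    biomarker_selection=False,
    biomarker_evaluation=False,
    orphan=False,
    source_tag="fixture",
    n_nonindustry_partners=0,
)


def make_records(rows):
    """Build a canonical record table from sparse row dicts."""
    recs = []
    for i, r in enumerate(rows):
        d = {**RECORD_DEFAULTS, **r}
        if d["trial_id"] is None:
            d["trial_id"] = f"T{i:03d}"
        recs.append(d)
    df = pd.DataFrame(recs, columns=SCHEMA_COLUMNS)
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    df["n_nonindustry_partners"] = df["n_nonindustry_partners"].astype(int)
    return df


def make_approvals(pairs):
    """Approvals table from (drug_id, indication_id, date) triples."""
    df = pd.DataFrame(pairs, columns=["drug_id", "indication_id", "approval_date"])
    df["approval_date"] = pd.to_datetime(df["approval_date"])
    return df


def make_program(trials, approval=None, drug="D1", indication="I1"):
    """One built DevelopmentProgram from (phase_label, start, end, status) tuples."""
    rows = []
    for t in trials:
        phase_label, start, end, status = t
        rows.append(
            dict(
                drug_id=drug,
                indication_id=indication,
                phase_label=phase_label,
                start_date=start,
                end_date=end,
                status=status,
            )
        )
    records = make_records(rows)
    approvals = make_approvals([(drug, indication, approval)]) if approval else None
    progs = build_programs(records, approvals)
    assert len(progs) == 1
    return progs[0]


@pytest.fixture
def snapshot_2015():
    return ThresholdConfig(snapshot_date="2015-10-31")
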