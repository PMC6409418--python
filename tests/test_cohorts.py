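"""Subgroup analytics: completion rates, durations, strata, rolling series."""

import numpy as np
import pandas as pd
import pytest

from trialpath import (
    GeneratorConfig,
    impute_end_dates,
    StratumSpec,
    ThresholdConfig,
    Window,
    biomarker_counts,
    build_programs,
    completion_rates,
    duration_stats,
    floor_programs,
    generate,
    lead_indications,
    partner_conditioning,
    rolling_series,
    tabulate_transitions,
    terminated_vs_advanced,
    trials_per_path,
)
from trialpath.cohorts import DAYS_PER_MONTH

from conftest import make_program, make_records


class TestCompletionRates:
    def test_simple_rate(self):
        rows = [{"phase_label": "P2", "status": "completed"}] * 8
        rows += [{"phase_label": "P2", "status": "failed", "end_date": "2006-01-01"}] * 2
        out = completion_rates(make_records(rows))
        assert out.set_index("phase").loc[2, "rate"] == pytest.approx(0.8)

    def test_all_ongoing_gives_absent_phase(self):
        rows = [{"phase_label": "P2", "status": "ongoing", "end_date": None}] * 3
        out = completion_rates(make_records(rows))
        assert 2 not in out["phase"].tolist()

    def test_positive_early_stop_counts_as_completed(self):
        rows = [{"phase_label": "P1", "status": "completed"}] * 8
        rows += [{"phase_label": "P1", "status": "terminated_positive"}]
        rows += [{"phase_label": "P1", "status": "failed"}]
        out = completion_rates(make_records(rows))
        assert out.set_index("phase").loc[1, "rate"] == pytest.approx(0.9)

    def test_grouped_rates(self):
        rows = [{"therapeutic_group": "oncology", "status": "failed"},
                {"therapeutic_group": "cns", "status": "completed"}]
        out = completion_rates(make_records(rows), by="therapeutic_group")
        byg = out.set_index("therapeutic_group")["rate"]
        assert byg["oncology"] == 0.0 and byg["cns"] == 1.0


class TestTrialsPerPath:
    def test_mean_over_paths(self):
        progs = []
        for k, n in enumerate((1, 2, 3)):
            trials = [("P1", "2005-01-01", "2006-01-01", "completed")] * n
            progs.append(make_program(trials, drug=f"D{k}"))
        assert trials_per_path(progs)[1] == pytest.approx(2.0)

    def test_single_path_single_trial(self):
        prog = make_program([("P2", "2005-01-01", "2006-01-01", "completed")])
        means = trials_per_path([prog])
        assert means[2] == 1.0 and means[1] is None

    def test_imputed_phase_excluded_from_mean(self):
        prog = make_program(
            [("P1", "2004-01-01", "2005-01-01", "completed"),
             ("P3", "2008-01-01", "2010-01-01", "completed")]
        )
        means = trials_per_path([prog])
        assert means[2] is None  # Phase 2 has no trials, imputed or not


class TestDurationStats:
    def test_single_trial_years(self):
        records = make_records(
            [{"start_date": "2010-01-01", "end_date": "2011-07-02"}]  # 547 days
        )
        out, _ = duration_stats(records)
        assert out[0].median_years == pytest.approx(547 / 365.25, abs=1e-9)
        assert out[0].median_years == pytest.approx(1.5, abs=0.01)

    def test_even_count_median(self):
        records = make_records(
            [{"start_date": "2010-01-01", "end_date": "2011-01-01"},    # 1.0 y
             {"start_date": "2010-01-01", "end_date": "2012-01-01"}]    # 2.0 y
        )
        out, _ = duration_stats(records)
        assert out[0].median_years == pytest.approx(1.5, abs=0.01)

    def test_clinic_time_sums_phase_medians(self):
        rows = []
        for label, days in (("P1", 365), ("P2", 731), ("P3", 1096)):
            end = (pd.Timestamp("2010-01-01") + pd.Timedelta(days=days)).strftime("%Y-%m-%d")
            rows.append({"phase_label": label, "start_date": "2010-01-01", "end_date": end})
        out, clinic = duration_stats(make_records(rows))
        expected = (365 + 731 + 1096) / 365.25
        assert clinic[None] == pytest.approx(expected)

    def test_imputed_end_dates_excluded(self):
        records = make_records(
            [{"end_date": "2012-01-01", "end_date_imputed": True}]
        )
        out, _ = duration_stats(records)
        assert out == []


class TestTerminatedVsAdvanced:
    def _fixture(self):
        progs = []
        # advanced Phase 2 (has Phase 3): 731-day Phase-2 trial
        progs.append(
            make_program(
                [("P2", "2006-01-01", "2008-01-01", "completed"),
                 ("P3", "2009-01-01", "2011-01-01", "completed")], drug="ADV",
            )
        )
        # terminated Phase 2 (old end, no Phase 3): 487-day trial
        progs.append(
            make_program(
                [("P2", "2006-01-01", "2007-05-02", "completed")], drug="TERM",
            )
        )
        return progs

    def test_duration_gap_in_months(self, snapshot_2015):
        out = terminated_vs_advanced(self._fixture(), snapshot_2015, phase=2)
        assert out["delta_months"] == pytest.approx((731 - 487) / DAYS_PER_MONTH)

    def test_identical_distributions_give_zero(self, snapshot_2015):
        progs = [
            make_program(
                [("P2", "2006-01-01", "2008-01-01", "completed"),
                 ("P3", "2009-01-01", "2011-01-01", "completed")], drug="A"),
            make_program(
                [("P2", "2006-01-01", "2008-01-01", "completed")], drug="B"),
        ]
        out = terminated_vs_advanced(progs, snapshot_2015, phase=2)
        assert out["delta_months"] == 0.0

    def test_empty_group_reports_absent_delta(self, snapshot_2015):
        progs = self._fixture()[:1]
        out = terminated_vs_advanced(progs, snapshot_2015, phase=2)
        assert out["delta_months"] is None and out["n_terminated"] == 0

    def test_generator_gap_recovered(self, snapshot_2015):
        """The generator's terminated-vs-advanced duration gap is recovered."""
        cfg = GeneratorConfig(n_drugs=400, seed=21, missingness_m=0.0,
                              end_date_missing_fraction=0.0,
                              duration_gap_terminated_months=8.0)
        records, approvals, _ = generate(cfg)
        progs = build_programs(records, approvals)
        out = terminated_vs_advanced(progs, snapshot_2015, phase=2)
        assert out["delta_months"] == pytest.approx(8.0, abs=2.5)


class TestBiomarkerCounts:
    def test_phase_wise_stratum_assignment(self, snapshot_2015):
        prog = make_program(
            [("P1", "2006-01-01", "2007-01-01", "completed"),
             ("P3", "2010-01-01", "2012-01-01", "completed")]
        )
        # add a biomarker Phase-2 trial
        records = make_records(
            [
                {"phase_label": "P1", "start_date": "2006-01-01", "end_date": "2007-01-01"},
                {"phase_label": "P2", "start_date": "2008-01-01", "end_date": "2009-06-01",
                 "biomarker_selection": True},
                {"phase_label": "P3", "start_date": "2010-01-01", "end_date": "2012-01-01"},
            ]
        )
        progs = build_programs(records)
        bio, nonbio = biomarker_counts(progs, snapshot_2015, date_floor=None)
        assert bio.n_observed[2] == 1 and bio.n_observed[1] == 0 and bio.n_observed[3] == 0
        assert nonbio.n_observed[1] == 1 and nonbio.n_observed[3] == 1

    def test_expanded_mode_is_superset(self, snapshot_2015):
        records = make_records(
            [{"phase_label": "P2", "start_date": "2008-01-01", "end_date": "2009-01-01",
              "biomarker_evaluation": True}]
        )
        progs = build_programs(records)
        bio_sel, _ = biomarker_counts(progs, snapshot_2015, mode="selection_only",
                                      date_floor=None)
        bio_exp, _ = biomarker_counts(progs, snapshot_2015, mode="expanded",
                                      date_floor=None)
        for j in (1, 2, 3):
            assert bio_exp.n_observed[j] >= bio_sel.n_observed[j]
        assert bio_exp.n_observed[2] == 1 and bio_sel.n_observed[2] == 0

    def test_no_flags_empty_biomarker_stratum(self, snapshot_2015):
        prog = make_program([("P2", "2008-01-01", "2009-01-01", "completed")])
        bio, nonbio = biomarker_counts([prog], snapshot_2015, date_floor=None)
        assert all(bio.n(j) == 0 for j in (1, 2, 3)) and bio.n_approval == 0

    def test_strata_partition_unstratified_counts(self, snapshot_2015):
        cfg = GeneratorConfig(n_drugs=150, seed=9, biomarker_fraction=0.3)
        records, approvals, _ = generate(cfg)
        records, _ = impute_end_dates(records)
        progs = build_programs(records, approvals)
        floor = "2005-01-01"
        bio, nonbio = biomarker_counts(progs, snapshot_2015, date_floor=floor)
        total = tabulate_transitions(floor_programs(progs, floor), snapshot_2015)
        assert (bio + nonbio) == total


class TestLeadIndications:
    def test_earliest_start_is_lead(self):
        a = make_program([("P1", "2005-03-01", "2006-01-01", "completed")],
                         drug="D", indication="A")
        b = make_program([("P1", "2007-01-01", "2008-01-01", "completed")],
                         drug="D", indication="B")
        progs = lead_indications([b, a])
        leads = {p.indication_id: p.is_lead_indication for p in progs}
        assert leads == {"A": True, "B": False}

    def test_single_indication_is_lead(self):
        p = make_program([("P1", "2005-01-01", "2006-01-01", "completed")])
        assert lead_indications([p])[0].is_lead_indication is True

    def test_exact_tie_breaks_lexicographically(self):
        a = make_program([("P1", "2005-01-01", "2006-01-01", "completed")],
                         drug="D", indication="IA")
        b = make_program([("P1", "2005-01-01", "2006-01-01", "completed")],
                         drug="D", indication="IB")
        progs = lead_indications([b, a])
        leads = {p.indication_id: p.is_lead_indication for p in progs}
        assert leads == {"IA": True, "IB": False}

    def test_exactly_one_lead_per_drug_invariant(self):
        cfg = GeneratorConfig(n_drugs=100, seed=3, mean_indications_per_drug=2.5)
        records, approvals, _ = generate(cfg)
        records, _ = impute_end_dates(records)
        progs = lead_indications(build_programs(records, approvals))
        flags = pd.DataFrame(
            [(p.drug_id, bool(p.is_lead_indication)) for p in progs],
            columns=["drug", "lead"],
        )
        assert (flags.groupby("drug")["lead"].sum() == 1).all()
        # invariant under permutation
        progs2 = lead_indications(list(reversed(build_programs(records, approvals))))
        leads1 = {(p.drug_id, p.indication_id) for p in progs if p.is_lead_indication}
        leads2 = {(p.drug_id, p.indication_id) for p in progs2 if p.is_lead_indication}
        assert leads1 == leads2


class TestRollingSeries:
    def test_window_bounds(self, snapshot_2015):
        series = rolling_series([], [2010], snapshot_2015)
        assert series.iloc[0]["window_start"] == pd.Timestamp("2008-01-01")
        assert series.iloc[0]["window_end"] == pd.Timestamp("2010-12-31")
        assert not series.iloc[0]["boundary_biased"]

    def test_final_window_clipped_to_snapshot_and_flagged(self, snapshot_2015):
        series = rolling_series([], [2015], snapshot_2015)
        assert series.iloc[0]["window_start"] == pd.Timestamp("2013-01-01")
        assert series.iloc[0]["window_end"] == pd.Timestamp("2015-10-31")
        assert bool(series.iloc[0]["boundary_biased"])

    def test_row_count_per_year_and_measure(self, snapshot_2015):
        series = rolling_series([], range(2005, 2016), snapshot_2015)
        assert len(series) == 11 * 4

    def test_observation_tiles_into_three_windows(self, snapshot_2015):
        prog = make_program(
            [("P2", "2007-01-01", "2009-06-01", "completed"),
             ("P3", "2010-01-01", "2012-01-01", "completed")]
        )
        series = rolling_series([prog], range(2005, 2016), snapshot_2015)
        p2 = series[(series.measure == "phase2_3") & series.denominator.notna()]
        assert sorted(p2["year"].tolist()) == [2009, 2010, 2011]


class TestPartnerConditioning:
    def test_identical_strata_near_zero_difference(self, snapshot_2015):
        cfg = GeneratorConfig(n_drugs=400, seed=13, partner_effect=1.0,
                              partner_fraction=0.5, missingness_m=0.0,
                              end_date_missing_fraction=0.0)
        records, approvals, _ = generate(cfg)
        progs = build_programs(records, approvals)
        out = partner_conditioning(progs, snapshot_2015)
        se = 100 * (out["no_partner"].se ** 2 + out["with_partner"].se ** 2) ** 0.5
        assert abs(out["difference_pp"]) <= 3 * se

    def test_configured_partner_effect_recovered(self, snapshot_2015):
        cfg = GeneratorConfig(n_drugs=600, seed=17, partner_effect=1.25,
                              biomarker_effect=1.0,
                              partner_fraction=0.5, missingness_m=0.0,
                              end_date_missing_fraction=0.0,
                              snapshot_date="2050-01-01")
        records, approvals, truth = generate(cfg)
        progs = build_programs(records, approvals)
        out = partner_conditioning(progs, ThresholdConfig("2050-01-01"))
        base = np.prod(cfg.theta)
        expected_pp = 100 * (base * 1.25 ** 3 - base)
        se = 100 * (out["no_partner"].se ** 2 + out["with_partner"].se ** 2) ** 0.5
        assert out["difference_pp"] == pytest.approx(expected_pp, abs=3 * se)

    def test_single_stratum_gives_absent_other(self, snapshot_2015):
        prog = make_program([("P1", "2005-01-01", "2006-01-01", "completed")])
        out = partner_conditioning([prog], snapshot_2015)
        assert out["with_partner"] is None and out["difference_pp"] is None


def test_stratum_spec_conjunction(snapshot_2015):
    prog = make_program([("P2", "2008-01-01", "2009-01-01", "completed")])
    assert StratumSpec("onc", therapeutic_group="oncology").matches(prog)
    assert not StratumSpec("onc-orphan", therapeutic_group="oncology", orphan=True).matches(prog)
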