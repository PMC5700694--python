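"""The record-cleaning rules, their audit trail, and idempotence."""

import datetime as dt

import pandas as pd
import pytest

from heifersim.cleaning import (
    CleaningConfig,
    assign_service_outcomes,
    clean_pipeline,
    compute_gestation,
    flag_problem_seasons,
    remove_carryover,
    remove_same_oestrus,
    renumber_services,
)
from heifersim.errors import DomainError
from heifersim.synthetic import generate_dataset

from helpers import make_calvings, make_services


def season(dates, **kw):
    return make_services([{"service_date": d, **kw} for d in dates])


class TestGestation:
    def test_standard_gestation(self):
        assert compute_gestation("2012-05-01", "2013-02-07") == 282

    def test_long_gestation(self):
        assert compute_gestation("2012-05-01", "2013-03-10") == 313

    def test_calving_must_follow_service(self):
        with pytest.raises(DomainError):
            compute_gestation("2012-05-01", "2012-05-01")


class TestOutcomeAssignment:
    def test_single_service_normal_gestation_is_positive(self):
        services = season(["2012-05-01"])
        calvings = make_calvings([{"calving_date": "2013-02-07"}])  # 282 d
        out, counts = assign_service_outcomes(services, calvings)
        assert list(out["outcome"]) == ["positive"]
        assert counts == {"reassigned": 0, "removed_long": 0, "corrected": 0}

    def test_short_final_gestation_reassigns_to_aligned_earlier_service(self):
        # final service would imply 240 d; the earlier service implies 281 d
        services = season(["2012-05-02", "2012-06-12"])
        calvings = make_calvings([{"calving_date": "2013-02-07"}])
        out, counts = assign_service_outcomes(services, calvings)
        assert len(out) == 1
        assert out["outcome"].iloc[0] == "positive"
        assert out["service_date"].iloc[0] == pd.Timestamp("2012-05-02")
        assert counts["reassigned"] == 1

    def test_overlong_final_gestation_removes_final_service(self):
        services = season(["2012-04-10", "2012-05-01"])
        calvings = make_calvings([{"calving_date": "2013-03-07"}])  # 310 d from final
        out, counts = assign_service_outcomes(services, calvings)
        assert counts["removed_long"] == 1
        assert len(out) == 1
        assert (out["outcome"] == "negative").all()

    def test_negative_final_with_confirming_calving_corrected(self):
        services = season(["2012-05-01"], outcome="negative")
        calvings = make_calvings([{"calving_date": "2013-01-26"}])  # 270 d
        out, counts = assign_service_outcomes(services, calvings)
        assert out["outcome"].iloc[0] == "positive"
        assert counts["corrected"] == 1

    def test_abortion_confers_no_positive_outcome(self):
        services = season(["2012-05-01"])
        calvings = make_calvings([{"calving_date": "2013-02-07", "is_abortion": True}])
        out, _ = assign_service_outcomes(services, calvings)
        assert (out["outcome"] == "negative").all()

    def test_no_calving_leaves_all_negative(self):
        services = season(["2012-05-01", "2012-05-22"])
        out, _ = assign_service_outcomes(services, make_calvings([]))
        assert (out["outcome"] == "negative").all()


class TestSameOestrus:
    def test_gap_below_three_removes_middle_service(self):
        services = season(["2012-05-01", "2012-05-03", "2012-05-24"])  # gaps 2, 21
        out, n = remove_same_oestrus(services)
        assert n == 1
        assert list(out["service_date"].dt.day) == [1, 24]

    def test_gap_of_exactly_three_keeps_both(self):
        services = season(["2012-05-01", "2012-05-04"])
        out, n = remove_same_oestrus(services)
        assert n == 0 and len(out) == 2

    def test_run_of_short_gaps_removes_all_but_first(self):
        services = season(["2012-05-01", "2012-05-02", "2012-05-03"])  # gaps 1, 1
        out, n = remove_same_oestrus(services)
        assert n == 2 and len(out) == 1

    def test_positive_outcome_transfers_to_retained_service(self):
        services = season(["2012-05-01", "2012-05-02"])
        services.loc[1, "outcome"] = "positive"
        out, n = remove_same_oestrus(services)
        assert n == 1
        assert out["outcome"].iloc[0] == "positive"


class TestProblemSeasons:
    def test_repeated_short_intervals_flagged(self):
        services = season(["2012-05-01", "2012-05-09", "2012-05-18", "2012-06-08"])
        assert len(flag_problem_seasons(services)) == 1  # gaps 8, 9, 21

    def test_normal_return_intervals_retained(self):
        services = season(["2012-05-01", "2012-05-22", "2012-06-13"])  # gaps 21, 22
        assert flag_problem_seasons(services) == []

    def test_single_service_below_minimum_count_retained(self):
        assert flag_problem_seasons(season(["2012-05-01"])) == []


class TestCarryover:
    def test_autumn_service_of_open_heifer_removed(self):
        services = season(["2012-05-01", "2012-09-10"], outcome="negative")
        out, n = remove_carryover(services)
        assert n == 1 and len(out) == 1

    def test_window_boundary_kept(self):
        services = season(["2012-07-31"], outcome="negative")
        out, n = remove_carryover(services)
        assert n == 0 and len(out) == 1

    def test_conceiving_season_untouched(self):
        services = season(["2012-05-01", "2012-08-15"])
        services.loc[0, "outcome"] = "positive"
        services.loc[1, "outcome"] = "negative"
        _, n = remove_carryover(services)
        assert n == 0


class TestRenumbering:
    def test_numbers_and_intervals_recomputed(self):
        services = season(["2012-05-01", "2012-05-22", "2012-06-16"])
        services["service_number"] = [1, 3, 4]  # stale numbering
        out = renumber_services(services)
        assert list(out["service_number"]) == [1, 2, 3]
        assert list(out["interservice_days"].dropna()) == [21, 25]
        assert pd.isna(out["interservice_days"].iloc[0])


class TestPipeline:
    def test_audit_counters_equal_planted_defect_ledger(self, defected_dataset):
        services, calvings, ledger = defected_dataset
        _, audit = clean_pipeline(services, calvings)
        planted = ledger.counts()
        assert audit.n_removed_same_oestrus == planted["duplicates"]
        assert audit.n_reassigned_short_gestation == planted["reassignment_extras"]
        assert audit.n_removed_long_gestation == planted["embryonic_long_extras"]
        assert audit.n_corrected_negative_finals == planted["negative_final_flips"]
        assert audit.n_removed_problem_seasons == planted["problem_seasons"]
        assert audit.n_removed_carryover == planted["carryovers"]
        # every defect class exercised
        for key in ("duplicates", "reassignment_extras", "negative_final_flips",
                    "embryonic_long_extras", "carryovers", "problem_seasons"):
            assert planted[key] > 0

    def test_record_conservation(self, defected_dataset):
        services, calvings, _ = defected_dataset
        _, audit = clean_pipeline(services, calvings)
        assert audit.n_output == audit.n_input - audit.total_removed

    def test_cleaning_recovers_undefected_records(self, study_config, defected_dataset):
        services_d, calvings_d, _ = defected_dataset
        cleaned, _ = clean_pipeline(services_d, calvings_d)
        original, _, _ = generate_dataset(study_config, with_defects=False)
        assert set(cleaned["record_id"]) == set(original["record_id"])
        merged = cleaned.set_index("record_id")["outcome"].sort_index()
        expected = original.set_index("record_id")["outcome"].sort_index()
        assert (merged == expected).all()

    def test_clean_data_passes_through_with_zero_audit(self, study_dataset):
        services, calvings = study_dataset
        cleaned, audit = clean_pipeline(services, calvings)
        assert audit.total_removed == 0
        assert audit.n_corrected_negative_finals == 0
        assert len(cleaned) == len(services)

    def test_idempotence(self, defected_dataset):
        services, calvings, _ = defected_dataset
        once, _ = clean_pipeline(services, calvings)
        twice, audit2 = clean_pipeline(once, calvings)
        assert audit2.total_removed == 0
        assert audit2.n_corrected_negative_finals == 0
        assert len(twice) == len(once)
        pd.testing.assert_frame_equal(
            once.sort_values("record_id").reset_index(drop=True)[once.columns],
            twice.sort_values("record_id").reset_index(drop=True)[once.columns],
        )

    def test_positive_seasons_have_one_positive_with_valid_gestation(self, defected_dataset):
        services, calvings, _ = defected_dataset
        cleaned, _ = clean_pipeline(services, calvings)
        cleaned = cleaned.copy()
        cleaned["season_year"] = pd.to_datetime(cleaned["service_date"]).dt.year
        calv = calvings.sort_values(["animal_id", "calving_date"])
        for _, grp in cleaned.groupby(["herd_id", "animal_id", "season_year"]):
            pos = grp[grp["outcome"] == "positive"]
            if pos.empty:
                continue
            assert len(pos) == 1
            service_date = pos["service_date"].iloc[0]
            after = calv[
                (calv["animal_id"] == pos["animal_id"].iloc[0])
                & (pd.to_datetime(calv["calving_date"]) > service_date)
                & (~calv["is_abortion"])
            ]
            gest = (pd.to_datetime(after["calving_date"].iloc[0]) - service_date).days
            assert 267 <= gest <= 300 or abs(gest - 282) <= 15
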