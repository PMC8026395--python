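"""Person-years, annual incidence rates and exact Poisson intervals."""

from dataclasses import replace

import pytest

from lynchrrs import (
    Cohort,
    FollowUpRecord,
    annual_incidence_rates,
    default_params,
    generate_cohort,
    person_years,
    poisson_ci,
)


def _one(record: FollowUpRecord) -> Cohort:
    return Cohort(records=[record])


def _py(bins):
    return {b.bin_start: b.person_years for b in bins}


def _events(bins):
    return {b.bin_start: b.events for b in bins}


class TestPersonYears:
    def test_uneventful_interval_lands_in_one_bin(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=25.0, age_last_obs=30.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert _py(bins)[25] == pytest.approx(5.0)
        assert sum(_py(bins).values()) == pytest.approx(5.0)
        assert sum(_events(bins).values()) == 0

    def test_hysterectomy_censors_endometrial_time(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=25.0, age_last_obs=40.0,
                             age_hysterectomy=27.0, age_bso=27.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert sum(_py(bins).values()) == pytest.approx(2.0)
        assert _py(bins)[25] == pytest.approx(2.0)

    def test_bso_does_not_censor_endometrial_time(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=25.0, age_last_obs=40.0,
                             age_bso=27.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert sum(_py(bins).values()) == pytest.approx(15.0)

    def test_event_truncates_time_and_lands_in_diagnosis_bin(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=38.0, age_last_obs=50.0,
                             age_ec_dx=43.5)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert _py(bins)[35] == pytest.approx(2.0)
        assert _py(bins)[40] == pytest.approx(3.5)
        assert _events(bins)[40] == 1
        assert sum(_events(bins).values()) == 1

    def test_previous_cancer_contributes_no_time(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=38.0, age_last_obs=50.0,
                             age_ec_dx=38.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert sum(_py(bins).values()) == 0.0
        assert sum(_events(bins).values()) == 0
        # but she still contributes ovarian time
        assert sum(_py(person_years(_one(rec), "OC", "MLH1")).values()) == pytest.approx(12.0)

    def test_event_tied_with_surgery_counts_as_event(self):
        rec = FollowUpRecord(id="a", gene="MSH2", age_inclusion=36.5, age_last_obs=55.0,
                             age_hysterectomy=40.0, age_bso=40.0, age_ec_dx=40.0)
        bins = person_years(_one(rec), "EC", "MSH2")
        assert sum(_events(bins).values()) == 1
        assert _events(bins)[40] == 1
        assert sum(_py(bins).values()) == pytest.approx(3.5)

    def test_observation_capped_at_75(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=70.0, age_last_obs=80.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        assert sum(_py(bins).values()) == pytest.approx(5.0)

    def test_combined_endpoint_both_organs_censoring(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=30.0, age_last_obs=50.0,
                             age_hysterectomy=35.0)
        # uterus removed at 35 but ovaries intact: combined risk set continues
        bins = person_years(_one(rec), "EC_or_OC", "MLH1")
        assert sum(_py(bins).values()) == pytest.approx(20.0)
        rec2 = replace(rec, age_bso=40.0)
        bins2 = person_years(_one(rec2), "EC_or_OC", "MLH1")
        assert sum(_py(bins2).values()) == pytest.approx(10.0)

    def test_combined_endpoint_any_surgery_censoring(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=30.0, age_last_obs=50.0,
                             age_hysterectomy=35.0)
        bins = person_years(_one(rec), "EC_or_OC", "MLH1", combined_censoring="any-surgery")
        assert sum(_py(bins).values()) == pytest.approx(5.0)

    def test_unknown_endpoint_or_gene_rejected(self):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=30.0, age_last_obs=40.0)
        with pytest.raises(ValueError):
            person_years(_one(rec), "CRC", "MLH1")
        with pytest.raises(ValueError):
            person_years(_one(rec), "EC", "MSH3")


@pytest.fixture(scope="module")
def msh2_cohort():
    return generate_cohort(default_params("MSH2", n=4000, seed=21))


class TestCohortLevelInvariants:

    @pytest.mark.parametrize("endpoint", ["EC", "OC", "EC_or_OC"])
    def test_person_years_conservation(self, msh2_cohort, endpoint):
        """Binned person-years sum to the at-risk interval lengths."""
        from lynchrrs.incidence import _at_risk_interval

        bins = person_years(msh2_cohort, endpoint, "MSH2")
        total = sum(
            max(0.0, end - start)
            for start, end, _ in (
                _at_risk_interval(r, endpoint, "both-organs") for r in msh2_cohort.records
            )
        )
        assert sum(b.person_years for b in bins) == pytest.approx(total, rel=1e-9)

    def test_removing_a_record_never_increases_any_bin(self, msh2_cohort):
        full = person_years(msh2_cohort, "EC", "MSH2")
        reduced = Cohort(records=msh2_cohort.records[1:])
        sub = person_years(reduced, "EC", "MSH2")
        for b_full, b_sub in zip(full, sub):
            assert b_sub.events <= b_full.events
            assert b_sub.person_years <= b_full.person_years + 1e-9

    def test_each_combined_event_is_a_first_ec_or_oc_event(self, msh2_cohort):
        combined = sum(b.events for b in person_years(msh2_cohort, "EC_or_OC", "MSH2"))
        firsts = 0
        for r in msh2_cohort.records:
            dx = [a for a in (r.age_ec_dx, r.age_oc_dx) if a is not None]
            if dx and min(dx) > r.age_inclusion and min(dx) < 75:
                firsts += 1
        assert combined == firsts


class TestAnnualIncidenceRates:
    def _bins(self, events, py):
        rec = FollowUpRecord(id="a", gene="MLH1", age_inclusion=30.0, age_last_obs=40.0)
        bins = person_years(_one(rec), "EC", "MLH1")
        bins[1].events, bins[1].person_years = events, py
        return bins

    def test_air_is_events_over_person_years(self):
        bins = annual_incidence_rates(self._bins(2, 100.0))
        assert bins[1].air == pytest.approx(0.02)

    def test_zero_events_give_zero_air(self):
        bins = annual_incidence_rates(self._bins(0, 500.0))
        assert bins[1].air == 0.0

    def test_empty_bin_air_undefined_and_flagged(self):
        bins = annual_incidence_rates(self._bins(0, 100.0))
        empty = [b for b in bins if b.person_years == 0]
        assert empty and all(b.air is None and b.unreliable for b in empty)

    def test_low_person_years_flagged_unreliable(self):
        bins = annual_incidence_rates(self._bins(1, 5.0), min_py=10.0)
        assert bins[1].unreliable


class TestPoissonCI:
    def test_zero_events_lower_bound_is_zero(self):
        low, high = poisson_ci(0, 100.0)
        assert low == 0.0 and high > 0.0

    def test_matches_chi_square_worked_example(self):
        # Garwood interval for 10 events in 1000 person-years
        low, high = poisson_ci(10, 1000.0, 0.95)
        assert low == pytest.approx(0.0048, abs=2e-4)
        assert high == pytest.approx(0.0184, abs=2e-4)

    @pytest.mark.parametrize("events,py", [(0, 50.0), (3, 10.0), (17, 812.5), (100, 9000.0)])
    def test_interval_contains_point_estimate(self, events, py):
        low, high = poisson_ci(events, py)
        assert low <= events / py <= high

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            poisson_ci(1, 10.0, level=1.5)

    def test_zero_person_years_rejected(self):
        with pytest.raises(ValueError):
            poisson_ci(1, 0.0)
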