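"""Monte-Carlo engine: event draws, endpoint classification, cohort tallies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammosim import (
    CohortSpec,
    SCREENED,
    UNSCREENED,
    SurvivalSchedule,
    ValidationError,
    aggregate_replicates,
    build_schedule,
    classify_endpoint,
    draw_event_months,
    make_incidence,
    make_life_table,
    simulate_cohort,
    simulate_replicates,
)
from mammosim.simulate import replicate_rng


def _spec(entry_age=60, arm="unscreened", n=25_000.0, **kwargs):
    return CohortSpec(
        entry_age=entry_age,
        arm=arm,
        n_women_by_age=((entry_age, n), (entry_age + 1, n)),
        **kwargs,
    )


# ---------------------------------------------------------------- event draws


def test_zero_hazards_never_produce_an_event():
    rng = np.random.default_rng(0)
    months = draw_event_months(np.zeros(20), rng, size=1000)
    assert np.all(np.isnan(months))
    assert draw_event_months(np.zeros(20), rng) is None


def test_certain_first_year_event_lands_in_first_twelve_months():
    rng = np.random.default_rng(0)
    h = np.zeros(20)
    h[0] = 1.0
    months = draw_event_months(h, rng, size=1000)
    assert np.all((months > 0) & (months <= 12))


def test_event_probability_matches_cumulative_survival():
    """Empirical no-event fraction at n=1e5 matches (1-h)^20 = 0.679."""
    n = 100_000
    rng = np.random.default_rng(3)
    months = draw_event_months(build_schedule(UNSCREENED).annual_hazard, rng, size=n)
    absent = float(np.mean(np.isnan(months)))
    assert abs(absent - 0.679) < 4.0 * math.sqrt(0.679 * 0.321 / n)


def test_event_draw_rejects_invalid_hazards():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        draw_event_months([0.1, 1.5], rng, size=10)


def test_mean_metastasis_free_time_is_about_84_months():
    """Destined tumor deaths under the unscreened constant-hazard schedule
    occur ~112 months after diagnosis on average, i.e. ~84 months after the
    metastasis placed 28 months earlier."""
    rng = np.random.default_rng(4)
    months = draw_event_months(build_schedule(UNSCREENED).annual_hazard, rng, size=200_000)
    destined = months[~np.isnan(months)]
    assert np.mean(destined) - 28.0 == pytest.approx(84.0, abs=3.0)


# ------------------------------------------------------------- classification


@pytest.mark.parametrize(
    "t_bc, t_other, expected",
    [
        (None, None, "E1"),
        (None, 100.0, "E2"),
        (120.0, None, "E4"),  # tumor death unopposed
        (120.0, 130.0, "E4"),  # tumor death first
        (120.0, 100.0, "E6"),  # other death after metastasis (t_met = 92)
        (120.0, 80.0, "E5"),  # other death before metastasis
        (120.0, 120.0, "E6"),  # exact tie resolves to tumor-independent death
        (20.0, 10.0, "E6"),  # metastasis clamped at diagnosis
    ],
)
def test_endpoint_classification_enumerates_all_orderings(t_bc, t_other, expected):
    assert classify_endpoint(t_bc, t_other, met_offset=28.0) == expected


def test_endpoint_classification_rejects_nonpositive_times():
    with pytest.raises(ValidationError):
        classify_endpoint(-1.0, None)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    t_bc=st.one_of(st.none(), st.floats(min_value=0.01, max_value=240.0)),
    t_other=st.one_of(st.none(), st.floats(min_value=0.01, max_value=240.0)),
)
def test_endpoint_classification_is_consistent(t_bc, t_other):
    label = classify_endpoint(t_bc, t_other)
    if t_bc is None:
        assert label == ("E1" if t_other is None else "E2")
    else:
        assert label in {"E4", "E5", "E6"}
        if label == "E4":
            assert t_other is None or t_other > t_bc
        else:
            assert t_other is not None and t_other <= t_bc


# ------------------------------------------------------------ cohort tallies


def test_no_competing_mortality_recovers_tumor_survival(demog):
    """With q = 0 everywhere, only E1/E4 occur and 1 - e3 estimates s20."""
    lt0 = make_life_table(makeham_offset=0.0, gompertz_scale=0.0)
    for calibration in (SCREENED, UNSCREENED):
        spec = _spec(arm=calibration.arm)
        agg = simulate_replicates(
            spec, build_schedule(calibration), lt0, demog.incidence,
            master_seed=11, replicates=20,
        )
        t = agg.mean
        assert t.e2 == 0.0 and t.e5 == 0.0 and t.e6 == 0.0
        assert t.e3 == pytest.approx(t.e4)
        assert t.ll == pytest.approx(t.ll_corr)
        n_draws = t.n_bc * agg.n_replicates
        margin = 4.0 * math.sqrt(calibration.s20 * (1 - calibration.s20) / n_draws)
        assert 1.0 - t.e3 == pytest.approx(calibration.s20, abs=margin)


def test_zero_tumor_hazard_yields_no_tumor_deaths(demog):
    spec = _spec(arm="none")
    rng = np.random.default_rng(5)
    tally = simulate_cohort(
        spec, SurvivalSchedule.no_tumor_mortality(), demog.life_table, demog.incidence, rng
    )
    assert tally.e3 == 0.0
    assert tally.ll == 0.0 and tally.yll == 0.0
    assert tally.e1 + tally.e2 == pytest.approx(1.0)


def test_conservation_holds_in_every_replicate(demog, schedules):
    for arm in ("screened", "unscreened"):
        spec = _spec(arm=arm)
        for rep in range(10):
            rng = replicate_rng(21, spec.entry_age, arm, rep)
            t = simulate_cohort(
                spec, schedules[arm], demog.life_table, demog.incidence, rng
            )
            assert t.e1 + t.e2 + t.e3 == pytest.approx(1.0, abs=1e-12)
            assert t.e4 + t.e5 + t.e6 == pytest.approx(t.e3, abs=1e-12)
            assert t.ll_corr <= t.ll
            assert t.yll_corr <= t.yll


def test_zero_incidence_cohort_has_no_patients(demog, schedules):
    inc0 = make_incidence(base_rate=0.0, plateau_rate=0.0)
    rng = np.random.default_rng(6)
    tally = simulate_cohort(
        _spec(arm="unscreened"), schedules["unscreened"], demog.life_table, inc0, rng
    )
    assert tally.n_bc == 0.0
    assert tally.ll == tally.yll == 0.0
    assert math.isnan(tally.e1)


def test_simulation_is_deterministic_given_the_seed(demog, schedules):
    spec = _spec(arm="screened", n=5000.0)
    args = (spec, schedules["screened"], demog.life_table, demog.incidence)
    a = simulate_replicates(*args, master_seed=9, replicates=3)
    b = simulate_replicates(*args, master_seed=9, replicates=3)
    assert a.mean == b.mean
    c = simulate_replicates(*args, master_seed=10, replicates=3)
    assert c.mean != a.mean


def test_demography_gap_is_a_validation_error(demog, schedules):
    short_lt = make_life_table(max_age=100)
    with pytest.raises(ValidationError, match="life table"):
        simulate_cohort(
            _spec(entry_age=80, arm="unscreened"),
            schedules["unscreened"], short_lt, demog.incidence,
            np.random.default_rng(0),
        )


def test_years_lost_use_residual_life_expectancy_at_death(demog, schedules):
    """Per destined death, YLL averages e(age at tumor death): for entry 60
    occur at mean attained age ~77, so mean YLL per death sits between the
    residual expectancies at 70 and 82."""
    agg = simulate_replicates(
        _spec(entry_age=60, arm="unscreened"), schedules["unscreened"],
        demog.life_table, demog.incidence, master_seed=13, replicates=10,
    )
    per_death = agg.mean.yll / agg.mean.ll
    e = demog.life_table.life_expectancy
    assert float(e([82])[0]) < per_death < float(e([70])[0])


# ---------------------------------------------------------------- aggregation


def test_identical_replicates_average_to_themselves(demog, schedules):
    rng = np.random.default_rng(7)
    t = simulate_cohort(
        _spec(arm="unscreened", n=5000.0), schedules["unscreened"],
        demog.life_table, demog.incidence, rng,
    )
    agg = aggregate_replicates([t, t, t])
    assert agg.mean == t
    assert agg.se["e3"] == 0.0


def test_aggregate_rejects_empty_input():
    with pytest.raises(ValidationError):
        aggregate_replicates([])


def test_replicate_averaging_shrinks_the_standard_error(demog, schedules):
    """The reported standard error of the 50-replicate mean is the
    single-replicate spread divided by sqrt(50)."""
    spec = _spec(arm="unscreened", n=5000.0)
    tallies = [
        simulate_cohort(
            spec, schedules["unscreened"], demog.life_table, demog.incidence,
            replicate_rng(17, spec.entry_age, "unscreened", rep),
        )
        for rep in range(50)
    ]
    agg = aggregate_replicates(tallies)
    spread = np.std([t.e3 for t in tallies], ddof=1)
    assert agg.se["e3"] == pytest.approx(spread / math.sqrt(50))
    assert agg.mean.e1 + agg.mean.e2 + agg.mean.e3 == pytest.approx(1.0, abs=1e-12)


def test_accrual_modes_agree_on_expected_patient_numbers(demog, schedules):
    """At-entry accrual keeps the expected diagnosis count but shifts every
    diagnosis to the entry age."""
    spec_across = _spec(entry_age=50, arm="unscreened")
    spec_at_entry = CohortSpec(
        entry_age=50, arm="unscreened",
        n_women_by_age=spec_across.n_women_by_age, accrual_mode="at-entry",
    )
    a = simulate_replicates(
        spec_across, schedules["unscreened"], demog.life_table, demog.incidence,
        master_seed=19, replicates=10,
    )
    b = simulate_replicates(
        spec_at_entry, schedules["unscreened"], demog.life_table, demog.incidence,
        master_seed=19, replicates=10,
    )
    assert b.mean.n_bc == pytest.approx(a.mean.n_bc, rel=0.05)
    # competing mortality acts at younger attained ages under at-entry accrual
    assert b.mean.e2 < a.mean.e2
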