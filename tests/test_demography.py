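"""Synthetic demography generators, life-table accounting and the CSV dialect."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammosim import (
    DemographyParseError,
    ValidationError,
    default_demography,
    load_demography,
    make_incidence,
    make_life_table,
    make_population,
    residual_life_expectancy,
    save_demography,
)


def test_no_mortality_limit_gives_full_remaining_lifespan():
    lt = make_life_table(makeham_offset=0.0, gompertz_scale=0.0, max_age=105)
    assert np.all(lt.q == 0.0)
    assert np.allclose(lt.e, 105 - lt.age + 0.5)


def test_life_table_q_and_e_are_mutually_consistent(demog):
    lt = demog.life_table
    recomputed = residual_life_expectancy(lt.q)
    assert np.max(np.abs(recomputed - lt.e)) <= 0.01


def test_life_table_shape(demog):
    lt = demog.life_table
    assert np.all((lt.q >= 0) & (lt.q <= 1))
    above40 = lt.q[lt.age >= 40]
    assert np.all(np.diff(above40) >= 0)  # hazard non-decreasing in adulthood
    assert np.all(np.diff(lt.e) < 0)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    offset=st.floats(min_value=0.0, max_value=5e-3),
    scale=st.floats(min_value=1e-7, max_value=1e-4),
    slope=st.floats(min_value=0.05, max_value=0.13),
)
def test_life_table_invariants_hold_for_any_parameters(offset, scale, slope):
    lt = make_life_table(makeham_offset=offset, gompertz_scale=scale, gompertz_slope=slope)
    assert np.all((lt.q >= 0) & (lt.q <= 1))
    unsaturated = lt.q[:-1] < 1.0  # e is pinned at 0.5 once q reaches 1
    assert np.all(np.diff(lt.e)[unsaturated] < 0)
    assert np.all(np.diff(lt.e) <= 0)
    assert np.all(lt.e >= 0)


def test_life_table_rejects_bad_parameters():
    with pytest.raises(ValidationError):
        make_life_table(makeham_offset=-1e-4)
    with pytest.raises(ValidationError):
        make_life_table(gompertz_slope=0.0)
    with pytest.raises(ValidationError):
        make_life_table(max_age=90)


def test_default_twenty_year_survival_brackets(demog):
    """All-cause survival ordering that drives the age gradient of E2."""
    lt = demog.life_table
    assert lt.survival_between(40, 60) > 0.90
    assert lt.survival_between(80, 100) < 0.10


def test_constant_incidence_when_base_equals_plateau():
    inc = make_incidence(base_rate=200.0, plateau_rate=200.0)
    assert np.all(inc.rate_per_100k == 200.0)


def test_incidence_is_anchored_and_monotone(demog):
    inc = demog.incidence
    assert inc.rate([40])[0] == pytest.approx(90.0)
    assert inc.rate([75])[0] == pytest.approx(340.0)
    window = inc.rate_per_100k[(inc.age >= 40) & (inc.age <= 63)]  # up to inflection+10
    assert np.all(np.diff(window) >= 0)
    assert np.all(np.diff(inc.rate_per_100k) >= 0)


def test_incidence_rejects_plateau_below_base():
    with pytest.raises(ValidationError):
        make_incidence(base_rate=300.0, plateau_rate=100.0)


def test_screening_interval_accrues_about_57_bc_per_1000_women(demog):
    """Expected diagnoses over 20 years for the 50-69 entry cohorts."""
    lt, inc, pop = demog.life_table, demog.incidence, demog.population
    bc = women = 0.0
    for entry in range(50, 69):
        w = float(pop.counts([entry])[0])
        women += w
        for r in range(10):
            attained = entry + 2 * r
            wy = w * lt.survival_between(entry, attained) * 2
            bc += wy * float(inc.rate([attained])[0]) / 1e5
    assert 1000.0 * bc / women == pytest.approx(57.0, abs=3.0)


def test_population_declines_at_high_ages(demog):
    pop = demog.population
    assert np.all(pop.count >= 0)
    assert pop.counts([80])[0] < 0.6 * pop.counts([50])[0]
    with pytest.raises(ValidationError):
        make_population(base_count=-1.0)


def test_csv_round_trip_is_exact(demog, tmp_path):
    paths = save_demography(demog, tmp_path)
    loaded = load_demography(paths["lifetable"], paths["incidence"], paths["population"])
    assert np.array_equal(loaded.life_table.age, demog.life_table.age)
    assert np.array_equal(loaded.life_table.q, demog.life_table.q)
    assert np.array_equal(loaded.life_table.e, demog.life_table.e)
    assert np.array_equal(loaded.incidence.rate_per_100k, demog.incidence.rate_per_100k)
    assert np.array_equal(loaded.population.count, demog.population.count)


def test_default_demography_covers_screening_age_range(demog):
    assert demog.start_age <= 40
    assert demog.end_age >= 100


def _write_tables(tmp_path, lt_text=None):
    d = default_demography()
    paths = save_demography(d, tmp_path)
    if lt_text is not None:
        paths["lifetable"].write_text(lt_text)
    return paths


def test_out_of_range_q_names_file_and_row(tmp_path):
    paths = _write_tables(
        tmp_path, "age,q,e\n40,0.001,43.0\n41,1.5,42.0\n42,0.001,41.0\n"
    )
    with pytest.raises(DemographyParseError, match=r"row 3.*outside"):
        load_demography(paths["lifetable"], paths["incidence"], paths["population"])


def test_missing_column_is_reported(tmp_path):
    paths = _write_tables(tmp_path, "age,q\n40,0.001\n41,0.002\n")
    with pytest.raises(DemographyParseError, match="missing column"):
        load_demography(paths["lifetable"], paths["incidence"], paths["population"])


def test_non_contiguous_ages_are_reported(tmp_path):
    paths = _write_tables(
        tmp_path, "age,q,e\n40,0.001,43.0\n42,0.002,41.0\n43,0.002,40.0\n"
    )
    with pytest.raises(DemographyParseError, match="contiguous"):
        load_demography(paths["lifetable"], paths["incidence"], paths["population"])
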