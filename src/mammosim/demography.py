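"""Demography inputs: life table, breast-cancer incidence, female population.

The simulator consumes three tables indexed by single year of age:

* a life table with the annual death probability ``q`` and the residual life
  expectancy ``e`` (used both for competing mortality and for years-of-life-lost
  accounting),
* invasive breast-cancer incidence per 100,000 woman-years,
* female population counts (cohort sizes).

Real tables (national statistics office life tables, cancer-registry incidence)
can be supplied as CSV; the ``make_*`` generators emit synthetic stand-ins with
the statistical structure the analysis assumes — a Gompertz–Makeham adult
mortality curve, incidence rising steeply from age 40 to a plateau in the
60s–70s, and a population pyramid declining at high ages.  The generators are
pure functions of their parameters (no randomness).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DemographyParseError, ValidationError

__all__ = [
    "LifeTable",
    "IncidenceTable",
    "PopulationTable",
    "DemographyTables",
    "residual_life_expectancy",
    "make_life_table",
    "make_incidence",
    "make_population",
    "default_demography",
    "load_demography",
    "save_demography",
]

# Generator defaults, calibrated once (see docs/methods.md) so that synthetic
# 20-year all-cause survival is ~94% from age 40, ~70% from 60 and <10% from 80,
# and so that a 50-69 screening cohort accrues ~57 breast cancers per 1000 women
# over 20 years of follow-up.
DEFAULT_MAKEHAM_OFFSET = 3.0e-4  # age-independent hazard, per year
DEFAULT_GOMPERTZ_SCALE = 1.6e-5  # hazard at age 0, per year
DEFAULT_GOMPERTZ_SLOPE = 0.098  # log-hazard slope, per year of age
DEFAULT_BASE_RATE = 90.0  # incidence per 100k at age 40
DEFAULT_PLATEAU_RATE = 340.0  # incidence per 100k at the plateau
DEFAULT_INFLECTION_AGE = 53.0
DEFAULT_INCIDENCE_WIDTH = 5.0  # logistic width, years
DEFAULT_BASE_COUNT = 27_500.0  # women per single year of age at 40
DEFAULT_ROLLOFF_AGE = 78.0
DEFAULT_ROLLOFF_WIDTH = 6.0
DEFAULT_START_AGE = 40
DEFAULT_MAX_AGE = 120


def _as_age_array(age, name: str) -> np.ndarray:
    age = np.asarray(age, dtype=int)
    if age.ndim != 1 or age.size == 0:
        raise ValidationError(f"{name}: age column must be a non-empty 1-d array")
    if np.any(np.diff(age) != 1):
        raise ValidationError(f"{name}: ages must be contiguous single years")
    return age


@dataclass(frozen=True)
class LifeTable:
    """Annual death probability ``q`` and residual life expectancy ``e`` by age.

    ``q[i]`` is the probability of dying within the year given alive at
    birthday ``age[i]``; ``e[i]`` is the expected number of remaining life
    years at that birthday.  The last tabulated age closes the table: for
    accounting purposes anyone reaching it dies within that year (mid-year),
    so ``e`` at the last age is 0.5.
    """

    age: np.ndarray
    q: np.ndarray
    e: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "age", _as_age_array(self.age, "life table"))
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float))
        if not (self.age.shape == self.q.shape == self.e.shape):
            raise ValidationError("life table: age, q, e must have equal length")
        bad = np.flatnonzero((self.q < 0) | (self.q > 1))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"life table: q={self.q[i]} outside [0, 1] at age {self.age[i]}"
            )
        if np.any(self.e < 0):
            raise ValidationError("life table: e must be non-negative")
        # e strictly decreases with age except where q has saturated to 1,
        # where the accounting pins e at the terminal half-year.
        diffs = np.diff(self.e)
        if np.any(diffs > 0) or np.any((diffs >= 0) & (self.q[:-1] < 1.0)):
            raise ValidationError("life table: e must be strictly decreasing with age")

    @property
    def start_age(self) -> int:
        return int(self.age[0])

    @property
    def end_age(self) -> int:
        return int(self.age[-1])

    def _index(self, ages) -> np.ndarray:
        idx = np.asarray(ages, dtype=int) - self.start_age
        if np.any(idx < 0):
            raise ValidationError(
                f"life table starts at age {self.start_age}; requested younger age"
            )
        # Ages past the table end reuse the terminal row (survival there is
        # negligible by construction).
        return np.minimum(idx, self.age.size - 1)

    def annual_death_prob(self, ages) -> np.ndarray:
        """q at the given integer ages (clamped to the table's last row)."""
        return self.q[self._index(ages)]

    def life_expectancy(self, ages) -> np.ndarray:
        """Residual life expectancy at the given integer ages."""
        return self.e[self._index(ages)]

    def survival_between(self, age_from: int, age_to: int) -> float:
        """Probability of surviving from ``age_from`` to ``age_to`` (birthdays)."""
        if age_to < age_from:
            raise ValidationError("survival_between: age_to must be >= age_from")
        if age_to == age_from:
            return 1.0
        idx = self._index(np.arange(age_from, age_to))
        return float(np.prod(1.0 - self.q[idx]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "q": self.q, "e": self.e})


@dataclass(frozen=True)
class IncidenceTable:
    """Invasive breast-cancer incidence per 100,000 woman-years by age."""

    age: np.ndarray
    rate_per_100k: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "age", _as_age_array(self.age, "incidence table"))
        object.__setattr__(
            self, "rate_per_100k", np.asarray(self.rate_per_100k, dtype=float)
        )
        if self.age.shape != self.rate_per_100k.shape:
            raise ValidationError("incidence table: columns must have equal length")
        if np.any(self.rate_per_100k < 0):
            raise ValidationError("incidence table: rates must be non-negative")

    @property
    def start_age(self) -> int:
        return int(self.age[0])

    @property
    def end_age(self) -> int:
        return int(self.age[-1])

    def rate(self, ages) -> np.ndarray:
        idx = np.asarray(ages, dtype=int) - self.start_age
        if np.any(idx < 0) or np.any(idx >= self.age.size):
            raise ValidationError("incidence table does not cover requested ages")
        return self.rate_per_100k[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "rate_per_100k": self.rate_per_100k})


@dataclass(frozen=True)
class PopulationTable:
    """Number of women alive at each single year of age."""

    age: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "age", _as_age_array(self.age, "population table"))
        object.__setattr__(self, "count", np.asarray(self.count, dtype=float))
        if self.age.shape != self.count.shape:
            raise ValidationError("population table: columns must have equal length")
        if np.any(self.count < 0):
            raise ValidationError("population table: counts must be non-negative")

    @property
    def start_age(self) -> int:
        return int(self.age[0])

    @property
    def end_age(self) -> int:
        return int(self.age[-1])

    def counts(self, ages) -> np.ndarray:
        idx = np.asarray(ages, dtype=int) - self.start_age
        if np.any(idx < 0) or np.any(idx >= self.age.size):
            raise ValidationError("population table does not cover requested ages")
        return self.count[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age, "count": self.count})


@dataclass(frozen=True)
class DemographyTables:
    """The three aligned demography inputs for one simulation run."""

    life_table: LifeTable
    incidence: IncidenceTable
    population: PopulationTable

    @property
    def start_age(self) -> int:
        return max(
            self.life_table.start_age, self.incidence.start_age, self.population.start_age
        )

    @property
    def end_age(self) -> int:
        return min(
            self.life_table.end_age, self.incidence.end_age, self.population.end_age
        )


def residual_life_expectancy(q) -> np.ndarray:
    """Residual life expectancy from annual death probabilities.

    Standard life-table accounting with deaths placed mid-year:
    ``e[i] = 0.5*q[i] + (1-q[i])*(1 + e[i+1])``, closed at the last tabulated
    age with ``e = 0.5`` (death within the terminal year).  With ``q`` equal to
    zero everywhere this gives ``e(a) = max_age - a + 0.5``.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValidationError("q values must lie in [0, 1]")
    e = np.empty_like(q)
    e[-1] = 0.5
    for i in range(q.size - 2, -1, -1):
        e[i] = q[i] * 0.5 + (1.0 - q[i]) * (1.0 + e[i + 1])
    return e


def make_life_table(
    makeham_offset: float = DEFAULT_MAKEHAM_OFFSET,
    gompertz_scale: float = DEFAULT_GOMPERTZ_SCALE,
    gompertz_slope: float = DEFAULT_GOMPERTZ_SLOPE,
    max_age: int = DEFAULT_MAX_AGE,
    start_age: int = DEFAULT_START_AGE,
) -> LifeTable:
    """Synthetic female life table from a Gompertz–Makeham hazard.

    The hazard is ``mu(a) = makeham_offset + gompertz_scale * exp(gompertz_slope*a)``
    and ``q(a) = 1 - exp(-mu(a))``.  ``e`` is computed from ``q`` by
    :func:`residual_life_expectancy`, so the two columns are mutually
    consistent by construction.  Zero offsets/scales are allowed (the
    no-mortality limit); negative parameters and a non-positive slope are not.
    """
    if makeham_offset < 0 or gompertz_scale < 0:
        raise ValidationError("make_life_table: hazard parameters must be >= 0")
    if gompertz_slope <= 0:
        raise ValidationError("make_life_table: gompertz_slope must be > 0")
    if max_age < 100:
        raise ValidationError("make_life_table: max_age must be >= 100")
    if not 0 <= start_age < max_age:
        raise ValidationError("make_life_table: need 0 <= start_age < max_age")
    age = np.arange(start_age, max_age + 1)
    mu = makeham_offset + gompertz_scale * np.exp(gompertz_slope * age)
    q = 1.0 - np.exp(-mu)
    return LifeTable(age=age, q=q, e=residual_life_expectancy(q))


def make_incidence(
    base_rate: float = DEFAULT_BASE_RATE,
    plateau_rate: float = DEFAULT_PLATEAU_RATE,
    inflection_age: float = DEFAULT_INFLECTION_AGE,
    width: float = DEFAULT_INCIDENCE_WIDTH,
    start_age: int = DEFAULT_START_AGE,
    max_age: int = DEFAULT_MAX_AGE,
) -> IncidenceTable:
    """Synthetic age-incidence curve: logistic rise from ``base_rate`` to a plateau.

    The logistic is anchored so that the rate equals ``base_rate`` exactly at
    age 40 and ``plateau_rate`` at age 75 and beyond; in between it rises
    smoothly with inflection at ``inflection_age``.  The curve is monotone
    non-decreasing over the whole table.
    """
    if not 0 <= base_rate <= plateau_rate:
        raise ValidationError("make_incidence: need 0 <= base_rate <= plateau_rate")
    if width <= 0:
        raise ValidationError("make_incidence: width must be > 0")
    age = np.arange(start_age, max_age + 1)
    if plateau_rate == base_rate:
        rate = np.full(age.shape, float(base_rate))
    else:
        def sig(a):
            return 1.0 / (1.0 + np.exp(-(a - inflection_age) / width))

        lo, hi = sig(40.0), sig(75.0)
        frac = np.clip((sig(age.astype(float)) - lo) / (hi - lo), 0.0, 1.0)
        rate = base_rate + (plateau_rate - base_rate) * frac
    return IncidenceTable(age=age, rate_per_100k=rate)


def make_population(
    base_count: float = DEFAULT_BASE_COUNT,
    rolloff_age: float = DEFAULT_ROLLOFF_AGE,
    rolloff_width: float = DEFAULT_ROLLOFF_WIDTH,
    start_age: int = DEFAULT_START_AGE,
    max_age: int = DEFAULT_MAX_AGE,
) -> PopulationTable:
    """Synthetic female population pyramid declining logistically at high ages."""
    if base_count < 0:
        raise ValidationError("make_population: base_count must be >= 0")
    if rolloff_width <= 0:
        raise ValidationError("make_population: rolloff_width must be > 0")
    age = np.arange(start_age, max_age + 1)
    count = base_count / (1.0 + np.exp((age - rolloff_age) / rolloff_width))
    return PopulationTable(age=age, count=count)


def default_demography() -> DemographyTables:
    """The calibrated synthetic demography used throughout tests and examples."""
    return DemographyTables(
        life_table=make_life_table(),
        incidence=make_incidence(),
        population=make_population(),
    )


_EXPECTED_COLUMNS = {
    "life table": ("age", "q", "e"),
    "incidence": ("age", "rate_per_100k"),
    "population": ("age", "count"),
}


def _read_table(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DemographyParseError(f"{path}: file not found")
    df = pd.read_csv(path, float_precision="round_trip")  # bit-exact re-load
    expected = _EXPECTED_COLUMNS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DemographyParseError(f"{path}: missing column(s) {missing}")
    df = df[list(expected)]
    for col in expected:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna()]
        if len(bad):
            raise DemographyParseError(
                f"{path}: row {int(bad[0]) + 2}: non-numeric value in column '{col}'"
            )
        df[col] = values
    ages = df["age"].to_numpy()
    if np.any(ages != ages.astype(int)) or len(ages) == 0:
        raise DemographyParseError(f"{path}: age column must hold integers")
    jumps = np.flatnonzero(np.diff(ages.astype(int)) != 1)
    if jumps.size:
        raise DemographyParseError(
            f"{path}: row {int(jumps[0]) + 3}: ages must be contiguous single years"
        )
    return df


def load_demography(
    path_lifetable, path_incidence, path_population
) -> DemographyTables:
    """Load and validate the three demography CSVs.

    Dialect: comma-separated, header row, dot decimal.  Errors name the
    offending file and row (1-based, counting the header as row 1).  The three
    tables are aligned to their common age range.
    """
    lt_df = _read_table(path_lifetable, "life table")
    q = lt_df["q"].to_numpy()
    bad = np.flatnonzero((q < 0) | (q > 1))
    if bad.size:
        raise DemographyParseError(
            f"{Path(path_lifetable)}: row {int(bad[0]) + 2}: q={q[bad[0]]} outside [0, 1]"
        )
    inc_df = _read_table(path_incidence, "incidence")
    rate = inc_df["rate_per_100k"].to_numpy()
    bad = np.flatnonzero(rate < 0)
    if bad.size:
        raise DemographyParseError(
            f"{Path(path_incidence)}: row {int(bad[0]) + 2}: negative incidence rate"
        )
    pop_df = _read_table(path_population, "population")
    count = pop_df["count"].to_numpy()
    bad = np.flatnonzero(count < 0)
    if bad.size:
        raise DemographyParseError(
            f"{Path(path_population)}: row {int(bad[0]) + 2}: negative population count"
        )

    lo = max(int(df["age"].iloc[0]) for df in (lt_df, inc_df, pop_df))
    hi = min(int(df["age"].iloc[-1]) for df in (lt_df, inc_df, pop_df))
    if hi < lo:
        raise DemographyParseError(
            "demography tables have no common age range "
            f"(life table {lt_df['age'].iloc[0]}-{lt_df['age'].iloc[-1]}, "
            f"incidence {inc_df['age'].iloc[0]}-{inc_df['age'].iloc[-1]}, "
            f"population {pop_df['age'].iloc[0]}-{pop_df['age'].iloc[-1]})"
        )

    def clip(df):
        m = (df["age"] >= lo) & (df["age"] <= hi)
        return df[m].reset_index(drop=True)

    lt_df, inc_df, pop_df = clip(lt_df), clip(inc_df), clip(pop_df)
    return DemographyTables(
        life_table=LifeTable(
            age=lt_df["age"].to_numpy(int),
            q=lt_df["q"].to_numpy(),
            e=lt_df["e"].to_numpy(),
        ),
        incidence=IncidenceTable(
            age=inc_df["age"].to_numpy(int), rate_per_100k=inc_df["rate_per_100k"].to_numpy()
        ),
        population=PopulationTable(
            age=pop_df["age"].to_numpy(int), count=pop_df["count"].to_numpy()
        ),
    )


def save_demography(tables: DemographyTables, directory) -> dict[str, Path]:
    """Write the three tables to ``directory`` in the canonical CSV dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "lifetable": directory / "lifetable.csv",
        "incidence": directory / "incidence.csv",
        "population": directory / "population.csv",
    }
    tables.life_table.to_frame().to_csv(paths["lifetable"], index=False)
    tables.incidence.to_frame().to_csv(paths["incidence"], index=False)
    tables.population.to_frame().to_csv(paths["population"], index=False)
    return paths
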