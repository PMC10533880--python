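"""Per-cohort Monte-Carlo engine: competing events and endpoint accounting.

For one entry-age cohort and one arm, each simulated breast-cancer patient
receives two independent event times over 20 years of follow-up from her
diagnosis:

* a tumor-death time drawn year by year from the arm's annual tumor-death
  hazards (absent = destined cured within the horizon), and
* a tumor-independent death time drawn from the life table's annual death
  probabilities at her attained integer age each follow-up year.

Within the event year the date is uniform.  Metachronous metastasis is placed
a fixed offset (default 28 months) before the would-be tumor death.  The
earliest event decides the endpoint:

=====  =============================================================
E1     no event within 20 years
E2     tumor-independent death only (patient destined cured)
E3     destined tumor death (E3 = E4 + E5 + E6)
E4     tumor death is the first event
E5     tumor-independent death first, before metastasis
E6     tumor-independent death first, after metastasis was diagnosed
=====  =============================================================

Lives lost (LL) counts destined tumor deaths (E3); LL corr counts realized
ones (E4).  Years of life lost (YLL) sums the life table's residual life
expectancy at the age of the (destined) tumor death; YLL corr restricts to E4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import IncidenceTable, LifeTable
from .errors import ValidationError
from .survival import SurvivalSchedule

__all__ = [
    "ARM_CODES",
    "CohortSpec",
    "EndpointTally",
    "AggregatedTally",
    "draw_event_months",
    "classify_endpoint",
    "simulate_cohort",
    "simulate_replicates",
    "aggregate_replicates",
    "replicate_rng",
]

ARM_CODES = {"screened": 0, "unscreened": 1, "none": 2}
_ENDPOINT_FIELDS = ("e1", "e2", "e3", "e4", "e5", "e6")


@dataclass(frozen=True)
class CohortSpec:
    """One entry-age cohort-arm to simulate.

    ``n_women_by_age`` maps the single-year entry ages of the (by default
    2-year) band to their population counts.  ``accrual_mode`` decides when
    the cohort's breast cancers are diagnosed:

    * ``"across-rounds"`` (default): diagnoses spread over the biennial
      screening rounds; age at diagnosis is the attained age at the round.
    * ``"at-entry"``: the same expected number of diagnoses, all placed at
      the entry age (the single-round reading).

    Either way each patient is followed 20 years from her own diagnosis.
    """

    entry_age: int
    arm: str
    n_women_by_age: tuple[tuple[int, float], ...]
    follow_up: int = 20  # years
    met_offset_months: float = 28.0
    screening_interval: int = 2  # years
    accrual_mode: str = "across-rounds"

    def __post_init__(self) -> None:
        if self.arm not in ARM_CODES:
            raise ValidationError(f"CohortSpec: unknown arm {self.arm!r}")
        if self.accrual_mode not in ("across-rounds", "at-entry"):
            raise ValidationError(
                f"CohortSpec: unknown accrual_mode {self.accrual_mode!r}"
            )
        if self.follow_up != 20:
            raise ValidationError("CohortSpec: the model is calibrated to follow_up=20")
        if not 0 < self.met_offset_months < self.follow_up * 12:
            raise ValidationError("CohortSpec: met_offset_months out of range")
        if not self.n_women_by_age:
            raise ValidationError("CohortSpec: n_women_by_age must be non-empty")
        if any(c < 0 for _, c in self.n_women_by_age):
            raise ValidationError("CohortSpec: population counts must be >= 0")

    @property
    def n_women(self) -> float:
        return float(sum(c for _, c in self.n_women_by_age))

    @property
    def n_rounds(self) -> int:
        return self.follow_up // self.screening_interval

    @classmethod
    def from_population(
        cls, population, entry_age: int, arm: str, band_width: int = 2, **kwargs
    ) -> "CohortSpec":
        """Build the spec for a band of ``band_width`` adjacent single-year ages."""
        ages = range(entry_age, entry_age + band_width)
        band = tuple((a, float(population.counts([a])[0])) for a in ages)
        return cls(entry_age=entry_age, arm=arm, n_women_by_age=band, **kwargs)


@dataclass(frozen=True)
class EndpointTally:
    """Endpoint fractions and loss accounting for one simulated cohort-arm.

    ``e1..e6`` are fractions of breast-cancer patients; ``ll``/``ll_corr``
    are counts of destined/realized tumor deaths; ``yll``/``yll_corr`` the
    corresponding years of life lost.  Invariants: e1+e2+e3 = 1 and
    e3 = e4+e5+e6 (exact by construction), ll_corr <= ll, yll_corr <= yll.
    With ``n_bc == 0`` the fractions are NaN and the counts zero.
    """

    n_women: float
    n_bc: float
    e1: float
    e2: float
    e3: float
    e4: float
    e5: float
    e6: float
    ll: float
    ll_corr: float
    yll: float
    yll_corr: float

    def __post_init__(self) -> None:
        if self.n_bc > 0:
            if abs(self.e1 + self.e2 + self.e3 - 1.0) > 1e-9:
                raise ValidationError("EndpointTally: e1+e2+e3 must equal 1")
            if abs(self.e3 - (self.e4 + self.e5 + self.e6)) > 1e-9:
                raise ValidationError("EndpointTally: e3 must equal e4+e5+e6")
        if self.ll_corr > self.ll + 1e-9:
            raise ValidationError("EndpointTally: ll_corr must not exceed ll")
        if self.yll_corr > self.yll + 1e-9:
            raise ValidationError("EndpointTally: yll_corr must not exceed yll")


@dataclass(frozen=True)
class AggregatedTally:
    """Replicate mean tally with Monte-Carlo standard errors."""

    mean: EndpointTally
    se: dict[str, float]
    n_replicates: int


def draw_event_months(annual_hazards, rng, size: int | None = None):
    """Draw event times (months from start) from annual conditional hazards.

    Year ``k`` (1-based) is chosen with probability
    ``prod_{j<k}(1-h_j) * h_k``; the date within the year is uniform on
    (0, 12] months; with probability ``prod(1-h_j)`` no event occurs and the
    result is NaN (scalar call: ``None``).  Two uniforms per draw are always
    consumed (year and within-year date), so the random stream advances
    identically whatever the outcomes.
    """
    h = np.asarray(annual_hazards, dtype=float)
    if h.ndim != 1 or h.size == 0:
        raise ValidationError("draw_event_months: hazards must be a 1-d vector")
    if np.any((h < 0) | (h > 1)):
        raise ValidationError("draw_event_months: hazards must lie in [0, 1]")
    scalar = size is None
    n = 1 if scalar else int(size)
    cum_death = 1.0 - np.cumprod(1.0 - h)
    u_year = rng.random(n)
    u_date = rng.random(n)
    year = np.searchsorted(cum_death, u_year, side="right")  # 0-based event year
    months = np.full(n, np.nan)
    hit = year < h.size
    months[hit] = 12.0 * year[hit] + 12.0 * (1.0 - u_date[hit])  # date in (0, 12]
    if scalar:
        return None if not hit[0] else float(months[0])
    return months


def classify_endpoint(
    t_bc_death: float | None, t_other_death: float | None, met_offset: float = 28.0
) -> str:
    """Endpoint label from the two (possibly absent) event times in months.

    Metastasis is placed ``met_offset`` months before the would-be tumor
    death (clamped at diagnosis).  An exact tie between the two deaths — a
    probability-zero event under continuous dates — resolves to the
    tumor-independent death (E6).
    """
    for t in (t_bc_death, t_other_death):
        if t is not None and (not math.isfinite(t) or t <= 0):
            raise ValidationError("classify_endpoint: defined times must be positive")
    if t_bc_death is None:
        return "E1" if t_other_death is None else "E2"
    if t_other_death is None or t_other_death > t_bc_death:
        return "E4"
    t_met = max(t_bc_death - met_offset, 0.0)
    return "E5" if t_other_death < t_met else "E6"


def _classify_codes(t_bc: np.ndarray, t_other: np.ndarray, met_offset: float) -> np.ndarray:
    """Vectorized endpoint codes 1..6 (NaN marks an absent event)."""
    bc = ~np.isnan(t_bc)
    ot = ~np.isnan(t_other)
    t_met = np.maximum(t_bc - met_offset, 0.0)
    codes = np.empty(t_bc.shape, dtype=np.int8)
    codes[~bc & ~ot] = 1
    codes[~bc & ot] = 2
    e4 = bc & (~ot | (t_other > t_bc))
    codes[e4] = 4
    other_first = bc & ot & (t_other <= t_bc)
    codes[other_first & (t_other < t_met)] = 5
    codes[other_first & (t_other >= t_met)] = 6
    return codes


def _stochastic_round(x: float, rng) -> int:
    """Integer with expectation ``x`` (floor plus a Bernoulli on the fraction)."""
    base = math.floor(x)
    return base + int(rng.random() < (x - base))


def _check_coverage(spec: CohortSpec, life_table: LifeTable, incidence: IncidenceTable) -> None:
    last_entry = max(a for a, _ in spec.n_women_by_age)
    # Oldest attained age that matters is entry + accrual + follow-up; ages past
    # the table end reuse the terminal row, so coverage to entry+2*follow_up
    # (the cohort-label convention) suffices.
    need = spec.entry_age + 2 * spec.follow_up
    if life_table.start_age > spec.entry_age or life_table.end_age < need:
        raise ValidationError(
            f"life table covers {life_table.start_age}-{life_table.end_age}; "
            f"cohort {spec.entry_age} needs {spec.entry_age}-{need}"
        )
    last_dx = last_entry + (
        (spec.n_rounds - 1) * spec.screening_interval
        if spec.accrual_mode == "across-rounds"
        else 0
    )
    if incidence.start_age > spec.entry_age or incidence.end_age < last_dx:
        raise ValidationError(
            f"incidence table covers {incidence.start_age}-{incidence.end_age}; "
            f"cohort {spec.entry_age} needs diagnoses up to age {last_dx}"
        )


def simulate_cohort(
    spec: CohortSpec,
    schedule: SurvivalSchedule,
    life_table: LifeTable,
    incidence: IncidenceTable,
    rng,
) -> EndpointTally:
    """Simulate one cohort-arm once and tally endpoints and losses.

    The expected number of breast cancers per screening round is
    ``incidence(attained age) x woman-years``, with woman-years deflated by
    life-table survival from entry to the round; fractional expectations are
    rounded stochastically (expectation preserved).  Each patient's two event
    draws are independent given her age at diagnosis.
    """
    _check_coverage(spec, life_table, incidence)
    if schedule.horizon != spec.follow_up:
        raise ValidationError("schedule horizon must equal the follow-up period")

    counts = np.zeros(7, dtype=np.int64)  # index 1..6
    yll = 0.0
    yll_corr = 0.0
    n_bc = 0

    for age0, n_women in spec.n_women_by_age:
        for r in range(spec.n_rounds):
            attained = age0 + r * spec.screening_interval
            woman_years = (
                n_women
                * life_table.survival_between(age0, attained)
                * spec.screening_interval
            )
            expected = woman_years * float(incidence.rate([attained])[0]) / 1e5
            n = _stochastic_round(expected, rng)
            if n == 0:
                continue
            dx_age = attained if spec.accrual_mode == "across-rounds" else age0
            t_bc = draw_event_months(schedule.annual_hazard, rng, size=n)
            ages_seq = np.arange(dx_age, dx_age + spec.follow_up)
            t_other = draw_event_months(
                life_table.annual_death_prob(ages_seq), rng, size=n
            )
            codes = _classify_codes(t_bc, t_other, spec.met_offset_months)
            counts += np.bincount(codes, minlength=7)
            destined = ~np.isnan(t_bc)
            if np.any(destined):
                # attained integer age in the follow-up year of the tumor death
                death_year = np.ceil(t_bc[destined] / 12.0).astype(int) - 1
                e_res = life_table.life_expectancy(dx_age + death_year)
                yll += float(e_res.sum())
                yll_corr += float(e_res[codes[destined] == 4].sum())
            n_bc += n

    if n_bc == 0:
        return EndpointTally(
            n_women=spec.n_women, n_bc=0.0,
            e1=np.nan, e2=np.nan, e3=np.nan, e4=np.nan, e5=np.nan, e6=np.nan,
            ll=0.0, ll_corr=0.0, yll=0.0, yll_corr=0.0,
        )
    frac = counts / n_bc
    return EndpointTally(
        n_women=spec.n_women,
        n_bc=float(n_bc),
        e1=frac[1], e2=frac[2], e3=frac[4] + frac[5] + frac[6],
        e4=frac[4], e5=frac[5], e6=frac[6],
        ll=float(counts[4] + counts[5] + counts[6]),
        ll_corr=float(counts[4]),
        yll=yll,
        yll_corr=yll_corr,
    )


def replicate_rng(master_seed: int, entry_age: int, arm: str, replicate: int):
    """Independent, reproducible generator for one (cohort, arm, replicate)."""
    return np.random.default_rng(
        [int(master_seed), int(entry_age), ARM_CODES[arm], int(replicate)]
    )


def aggregate_replicates(tallies: list[EndpointTally]) -> AggregatedTally:
    """Element-wise replicate means plus standard errors of those means."""
    if not tallies:
        raise ValidationError("aggregate_replicates: need at least one replicate")
    fields = ("n_women", "n_bc", *_ENDPOINT_FIELDS, "ll", "ll_corr", "yll", "yll_corr")
    data = {f: np.array([getattr(t, f) for t in tallies]) for f in fields}
    n = len(tallies)

    def _nanmean(v):
        return float(np.mean(v[~np.isnan(v)])) if np.any(~np.isnan(v)) else float("nan")

    def _se(v):
        v = v[~np.isnan(v)]
        return float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0

    mean = EndpointTally(**{f: _nanmean(v) for f, v in data.items()})
    se = {f: _se(v) for f, v in data.items()}
    return AggregatedTally(mean=mean, se=se, n_replicates=n)


def simulate_replicates(
    spec: CohortSpec,
    schedule: SurvivalSchedule,
    life_table: LifeTable,
    incidence: IncidenceTable,
    master_seed: int,
    replicates: int = 50,
) -> AggregatedTally:
    """Repeat :func:`simulate_cohort` and report the replicate mean tally."""
    if replicates < 1:
        raise ValidationError("simulate_replicates: replicates must be >= 1")
    tallies = [
        simulate_cohort(
            spec, schedule, life_table, incidence,
            replicate_rng(master_seed, spec.entry_age, spec.arm, rep),
        )
        for rep in range(replicates)
    ]
    return aggregate_replicates(tallies)
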