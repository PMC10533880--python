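"""Benefit and cost metrics comparing screened and unscreened cohorts.

The arm difference in lives lost gives prevented deaths (PD, from the
destined-death counts LL; PD corr from the realized counts LL corr), the arm
difference in years of life lost gives life-years gained (LY corr).  Relating
these to the number of screening examinations (MSE; by default 10 biennial
screens per woman over 20 years at 88 EUR each) yields the decision metrics:
MSE and EUR per prevented death, MSE and EUR per life-year gained, and their
reciprocals per 10,000 MSE (10,000 MSE = 1000 women screened for 20 years).

Ratios are undefined when no deaths are prevented; they are reported as a
typed "not estimable" value (``None``), never as a division by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .demography import DemographyTables
from .errors import ValidationError
from .simulate import AggregatedTally, CohortSpec, EndpointTally, simulate_replicates
from .survival import SCREENED, UNSCREENED, ArmCalibration, build_schedule

__all__ = [
    "ScreeningPolicy",
    "BenefitSummary",
    "CohortResult",
    "SweepResult",
    "ParticipationResult",
    "IncrementalComparison",
    "compare_arms",
    "sweep_ages",
    "aggregate_interval",
    "participation_scenario",
    "incremental_round_comparison",
]


@dataclass(frozen=True)
class ScreeningPolicy:
    """Screening schedule and unit cost."""

    interval_years: int = 2
    follow_up_years: int = 20
    cost_per_screen: float = 88.0  # EUR

    def __post_init__(self) -> None:
        if self.interval_years <= 0 or self.follow_up_years % self.interval_years:
            raise ValidationError(
                "ScreeningPolicy: follow-up must be a multiple of the interval"
            )
        if self.cost_per_screen < 0:
            raise ValidationError("ScreeningPolicy: cost must be >= 0")

    @property
    def screens_per_woman(self) -> int:
        return self.follow_up_years // self.interval_years


@dataclass(frozen=True)
class BenefitSummary:
    """Arm-difference metrics for one cohort or an age-interval aggregate.

    ``None`` marks a ratio that is not estimable (no deaths prevented).
    ``pd``/``ly`` are uncorrected (destined-death based); the ``_corr``
    variants account for competing-event preemption.
    """

    label: str
    n_women: float
    mse: float
    pd: float
    pd_corr: float
    ly: float
    ly_corr: float
    mse_per_pd: Optional[float]
    mse_per_pd_corr: Optional[float]
    cost_per_pd_corr: Optional[float]
    mse_per_ly_corr: Optional[float]
    cost_per_ly_corr: Optional[float]
    pd_per_10k: Optional[float]
    ly_per_10k: Optional[float]


@dataclass(frozen=True)
class CohortResult:
    """Everything simulated for one entry age: both arms plus their difference."""

    entry_age: int
    screened: AggregatedTally
    unscreened: AggregatedTally
    benefit: BenefitSummary


@dataclass(frozen=True)
class ParticipationResult:
    """Expected deaths at a given participation rate (linear interpolation)."""

    participation: float
    expected_deaths: float
    reduction_percent_at_full: float


@dataclass(frozen=True)
class IncrementalComparison:
    """The four decision quantities for two candidate expansion cohorts."""

    label_lo: str
    label_hi: str
    pd_corr: tuple[Optional[float], Optional[float]]
    mse_per_pd_corr: tuple[Optional[float], Optional[float]]
    cost_per_pd_corr: tuple[Optional[float], Optional[float]]
    ly_corr: tuple[float, float]
    mse_per_ly_corr: tuple[Optional[float], Optional[float]]
    cost_per_ly_corr: tuple[Optional[float], Optional[float]]


def _ratios(
    mse: float, pd: float, pd_corr: float, ly_corr: float, policy: ScreeningPolicy
) -> dict:
    out: dict[str, Optional[float]] = {}
    out["mse_per_pd"] = mse / pd if pd > 0 else None
    if pd_corr > 0:
        out["mse_per_pd_corr"] = mse / pd_corr
        out["cost_per_pd_corr"] = policy.cost_per_screen * (mse / pd_corr)
        out["pd_per_10k"] = 1e4 * pd_corr / mse
    else:
        out["mse_per_pd_corr"] = out["cost_per_pd_corr"] = out["pd_per_10k"] = None
    if ly_corr > 0:
        out["mse_per_ly_corr"] = mse / ly_corr
        out["cost_per_ly_corr"] = policy.cost_per_screen * (mse / ly_corr)
        out["ly_per_10k"] = 1e4 * ly_corr / mse
    else:
        out["mse_per_ly_corr"] = out["cost_per_ly_corr"] = out["ly_per_10k"] = None
    return out


def compare_arms(
    tally_screened: EndpointTally,
    tally_unscreened: EndpointTally,
    n_women: float | None = None,
    policy: ScreeningPolicy = ScreeningPolicy(),
    label: str | None = None,
) -> BenefitSummary:
    """Benefit metrics from a matched pair of cohort-arm tallies."""
    if n_women is None:
        n_women = tally_screened.n_women
    if abs(tally_screened.n_women - tally_unscreened.n_women) > 1e-6:
        raise ValidationError("compare_arms: tallies come from different cohorts")
    mse = policy.screens_per_woman * n_women
    pd = tally_unscreened.ll - tally_screened.ll
    pd_corr = tally_unscreened.ll_corr - tally_screened.ll_corr
    ly = tally_unscreened.yll - tally_screened.yll
    ly_corr = tally_unscreened.yll_corr - tally_screened.yll_corr
    return BenefitSummary(
        label=label if label is not None else "cohort",
        n_women=float(n_women),
        mse=float(mse),
        pd=float(pd),
        pd_corr=float(pd_corr),
        ly=float(ly),
        ly_corr=float(ly_corr),
        **_ratios(mse, pd, pd_corr, ly_corr, policy),
    )


def sweep_ages(
    demography: DemographyTables,
    calibrations: tuple[ArmCalibration, ArmCalibration] = (SCREENED, UNSCREENED),
    policy: ScreeningPolicy = ScreeningPolicy(),
    ages: Sequence[int] = tuple(range(40, 81, 2)),
    master_seed: int = 1,
    replicates: int = 50,
    band_width: int = 2,
    accrual_mode: str = "across-rounds",
    met_offset_months: float = 28.0,
    schedule_mode: str = "constant-hazard",
) -> "SweepResult":
    """Simulate every entry-age cohort in both arms and compare them.

    Returns one :class:`CohortResult` per entry age, in order.  Each
    (cohort, arm, replicate) uses its own seeded generator derived from
    ``master_seed``, so any cell is independently reproducible.
    """
    cal_s, cal_u = calibrations
    if {cal_s.arm, cal_u.arm} != {"screened", "unscreened"}:
        raise ValidationError("sweep_ages: need one screened and one unscreened calibration")
    if cal_s.arm != "screened":
        cal_s, cal_u = cal_u, cal_s
    horizon = policy.follow_up_years
    sched_s = build_schedule(cal_s, mode=schedule_mode, horizon=horizon)
    sched_u = build_schedule(cal_u, mode=schedule_mode, horizon=horizon)
    results = []
    for age in ages:
        tallies = {}
        for arm, sched in (("screened", sched_s), ("unscreened", sched_u)):
            spec = CohortSpec.from_population(
                demography.population,
                entry_age=age,
                arm=arm,
                band_width=band_width,
                follow_up=horizon,
                met_offset_months=met_offset_months,
                screening_interval=policy.interval_years,
                accrual_mode=accrual_mode,
            )
            try:
                tallies[arm] = simulate_replicates(
                    spec, sched, demography.life_table, demography.incidence,
                    master_seed=master_seed, replicates=replicates,
                )
            except ValidationError as err:
                raise ValidationError(f"cohort {age} ({arm}): {err}") from err
        benefit = compare_arms(
            tallies["screened"].mean,
            tallies["unscreened"].mean,
            policy=policy,
            label=f"MC{age}",
        )
        results.append(
            CohortResult(
                entry_age=age,
                screened=tallies["screened"],
                unscreened=tallies["unscreened"],
                benefit=benefit,
            )
        )
    return SweepResult(cohorts=tuple(results), policy=policy)


@dataclass(frozen=True)
class SweepResult:
    """All cohort results of an age sweep plus derived summaries."""

    cohorts: tuple[CohortResult, ...]
    policy: ScreeningPolicy

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(c.entry_age for c in self.cohorts)

    @property
    def summaries(self) -> tuple[BenefitSummary, ...]:
        return tuple(c.benefit for c in self.cohorts)

    def argmin_mse_per_pd_corr(self) -> int:
        """Entry age with the fewest screens per (corrected) prevented death."""
        defined = [
            (c.benefit.mse_per_pd_corr, c.entry_age)
            for c in self.cohorts
            if c.benefit.mse_per_pd_corr is not None
        ]
        if not defined:
            raise ValidationError("argmin: no cohort has an estimable MSE/PD ratio")
        return min(defined)[1]

    def aggregate(self, age_lo: int, age_hi: int, label: str | None = None) -> BenefitSummary:
        """Weighted age-interval aggregate (entry ages in [age_lo, age_hi])."""
        chosen = [c for c in self.cohorts if age_lo <= c.entry_age <= age_hi]
        if not chosen:
            raise ValidationError(f"aggregate: no cohorts in [{age_lo}, {age_hi}]")
        return aggregate_interval(
            chosen, self.policy, label=label or f"SI {age_lo}-{age_hi + 1}"
        )


def aggregate_interval(
    cohorts: Sequence[CohortResult],
    policy: ScreeningPolicy = ScreeningPolicy(),
    label: str = "interval",
) -> BenefitSummary:
    """Sum PD, LY and MSE across cohorts before forming ratios (weighted means)."""
    n_women = sum(c.benefit.n_women for c in cohorts)
    mse = sum(c.benefit.mse for c in cohorts)
    pd = sum(c.benefit.pd for c in cohorts)
    pd_corr = sum(c.benefit.pd_corr for c in cohorts)
    ly = sum(c.benefit.ly for c in cohorts)
    ly_corr = sum(c.benefit.ly_corr for c in cohorts)
    return BenefitSummary(
        label=label,
        n_women=float(n_women),
        mse=float(mse),
        pd=float(pd),
        pd_corr=float(pd_corr),
        ly=float(ly),
        ly_corr=float(ly_corr),
        **_ratios(mse, pd, pd_corr, ly_corr, policy),
    )


def participation_scenario(
    deaths_without_ms: float, deaths_with_full_ms: float, participation: float
) -> ParticipationResult:
    """Expected deaths at partial screening participation.

    Linear interpolation between the no-screening and full-participation
    death counts; the quoted reduction is the full-participation one.
    """
    if not 0.0 <= participation <= 1.0:
        raise ValidationError("participation must lie in [0, 1]")
    if deaths_without_ms < 0 or deaths_with_full_ms < 0:
        raise ValidationError("death counts must be >= 0")
    if deaths_with_full_ms > deaths_without_ms:
        raise ValidationError("full-participation deaths must not exceed baseline deaths")
    if deaths_without_ms == 0:
        raise ValidationError("baseline death count must be > 0")
    expected = deaths_without_ms - participation * (deaths_without_ms - deaths_with_full_ms)
    reduction = 100.0 * (deaths_without_ms - deaths_with_full_ms) / deaths_without_ms
    return ParticipationResult(
        participation=participation,
        expected_deaths=expected,
        reduction_percent_at_full=reduction,
    )


def incremental_round_comparison(
    summary_lo: BenefitSummary, summary_hi: BenefitSummary
) -> IncrementalComparison:
    """Side-by-side decision quantities for two candidate expansion cohorts.

    When an additional screening round could start earlier or end later, four
    aspects decide: prevented deaths, screens (and cost) per prevented death,
    life-years gained, screens (and cost) per life-year gained.
    """
    return IncrementalComparison(
        label_lo=summary_lo.label,
        label_hi=summary_hi.label,
        pd_corr=(summary_lo.pd_corr, summary_hi.pd_corr),
        mse_per_pd_corr=(summary_lo.mse_per_pd_corr, summary_hi.mse_per_pd_corr),
        cost_per_pd_corr=(summary_lo.cost_per_pd_corr, summary_hi.cost_per_pd_corr),
        ly_corr=(summary_lo.ly_corr, summary_hi.ly_corr),
        mse_per_ly_corr=(summary_lo.mse_per_ly_corr, summary_hi.mse_per_ly_corr),
        cost_per_ly_corr=(summary_lo.cost_per_ly_corr, summary_hi.cost_per_ly_corr),
    )
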