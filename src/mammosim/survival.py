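"""Tumor-diameter survival model and per-arm hazard schedules.

The prognostic core of the model is a Gompertz curve mapping tumor diameter
(TD, mm) at diagnosis to 15-year tumor-related survival (percent):

    S15(TD) = 100 - A * exp(-B * exp(-c * TD))

with fitted coefficients A = 58.4, B = 4.46, c = 0.071 (cancer-registry data
in 5-mm diameter increments).  Screening shifts the size distribution at
diagnosis: the screen-era size mix (33.8% / 46.0% / 18.7% in the classes
<=10 mm / >10-20 mm / >20 mm, with class means 7 / 15 / 28 mm) has weighted
mean 14.7 mm and S15 = 87.8%.  Allowing for interval cancers the screened arm
is calibrated to an effective 16 mm (S15 = 86%, extrapolated to 81.9% at 20
years); the unscreened arm to 22.7 mm (S15 = 76%, 67.9% at 20 years).  The
20-year values are treated as printed calibration constants, not re-derived.

Each arm's 20-year survival is expressed as a schedule of annual conditional
tumor-death hazards whose cumulative product of survival equals the arm's
s20; the default schedule is constant over the 20 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "GompertzParams",
    "SizeClassMix",
    "ArmCalibration",
    "SurvivalSchedule",
    "DEFAULT_GOMPERTZ",
    "SCREEN_SIZE_MIX",
    "SCREENED",
    "UNSCREENED",
    "DETECTION_FRACTION",
    "fifteen_year_survival",
    "td_for_survival",
    "weighted_mean_td",
    "build_schedule",
]

# Share of breast cancers in a screened cohort actually found at a screening
# examination (the rest surface as interval cancers or outside the program).
# Its prognostic effect is already folded into the screened arm's effective
# 16-mm calibration, so it enters reporting only, never the survival math.
DETECTION_FRACTION = 0.80


@dataclass(frozen=True)
class GompertzParams:
    """Coefficients of the TD -> 15-year-survival curve (percent scale)."""

    amplitude: float = 58.4  # percent
    shape: float = 4.46  # unitless
    decay: float = 0.071  # per mm

    def __post_init__(self) -> None:
        if min(self.amplitude, self.shape, self.decay) <= 0:
            raise ValidationError("GompertzParams: all coefficients must be > 0")


DEFAULT_GOMPERTZ = GompertzParams()


def fifteen_year_survival(td, params: GompertzParams = DEFAULT_GOMPERTZ):
    """15-year tumor-related survival (percent) at tumor diameter ``td`` mm.

    Strictly decreasing in ``td``; bounded between the asymptote
    ``100 - amplitude`` (large tumors) and 100 (td -> -inf, unreachable).
    Accepts scalars or arrays; negative diameters are rejected.
    """
    td_arr = np.asarray(td, dtype=float)
    if np.any(td_arr < 0):
        raise ValidationError("tumor diameter must be >= 0 mm")
    out = 100.0 - params.amplitude * np.exp(-params.shape * np.exp(-params.decay * td_arr))
    return float(out) if np.isscalar(td) or td_arr.ndim == 0 else out


def td_for_survival(s15: float, params: GompertzParams = DEFAULT_GOMPERTZ) -> float:
    """Tumor diameter (mm) at which 15-year survival equals ``s15`` percent.

    Analytic inverse of :func:`fifteen_year_survival`; ``s15`` must lie
    strictly between the asymptote ``100 - amplitude`` and 100.
    """
    lo = 100.0 - params.amplitude
    if not lo < s15 < 100.0:
        raise ValidationError(
            f"s15={s15} outside the attainable range ({lo:.1f}, 100)"
        )
    inner = math.log(params.amplitude / (100.0 - s15)) / params.shape
    td = -math.log(inner) / params.decay
    if td < 0:
        raise ValidationError(
            f"s15={s15} corresponds to a negative tumor diameter"
        )
    return td


@dataclass(frozen=True)
class SizeClassMix:
    """Tumor-size class shares and class-mean diameters at diagnosis."""

    labels: tuple[str, ...] = ("<=10 mm", ">10-20 mm", ">20 mm")
    shares: tuple[float, ...] = (0.338, 0.460, 0.187)
    mean_td: tuple[float, ...] = (7.0, 15.0, 28.0)

    def __post_init__(self) -> None:
        if not len(self.labels) == len(self.shares) == len(self.mean_td):
            raise ValidationError("SizeClassMix: fields must have equal length")
        if any(s < 0 for s in self.shares):
            raise ValidationError("SizeClassMix: shares must be non-negative")
        if sum(self.shares) <= 0:
            raise ValidationError("SizeClassMix: at least one share must be positive")


# Size distribution of screen-era diagnoses (screening-report data); shares
# are renormalized before use (they sum to 0.985 as printed).
SCREEN_SIZE_MIX = SizeClassMix()


def weighted_mean_td(mix: SizeClassMix = SCREEN_SIZE_MIX) -> float:
    """Share-weighted mean tumor diameter (mm), shares renormalized to 1."""
    total = sum(mix.shares)
    return sum(s * t for s, t in zip(mix.shares, mix.mean_td)) / total


@dataclass(frozen=True)
class ArmCalibration:
    """Effective tumor diameter and tumor-specific survival for one arm.

    ``s15`` and ``s20`` are survival fractions (0-1).  ``s20`` is a printed
    calibration constant for the 20-year horizon, not derived from ``s15``.
    """

    arm: str  # "screened" (+MS) or "unscreened" (-MS)
    effective_td: float  # mm
    s15: float
    s20: float

    def __post_init__(self) -> None:
        if not 0.0 < self.s20 <= self.s15 < 1.0:
            raise ValidationError("ArmCalibration: need 0 < s20 <= s15 < 1")


SCREENED = ArmCalibration(arm="screened", effective_td=16.0, s15=0.86, s20=0.819)
UNSCREENED = ArmCalibration(arm="unscreened", effective_td=22.7, s15=0.76, s20=0.679)


@dataclass(frozen=True)
class SurvivalSchedule:
    """Annual conditional tumor-death hazards over the follow-up horizon.

    The cumulative product of ``1 - annual_hazard`` equals the arm's 20-year
    tumor-specific survival ``s20`` (within 1e-9) unless the schedule was
    built with the no-tumor-mortality flag, in which case all hazards are 0.
    """

    arm: str
    annual_hazard: np.ndarray
    s20: float | None = field(default=None)

    def __post_init__(self) -> None:
        h = np.asarray(self.annual_hazard, dtype=float)
        object.__setattr__(self, "annual_hazard", h)
        if h.ndim != 1 or h.size == 0:
            raise ValidationError("SurvivalSchedule: hazards must be a 1-d vector")
        if np.any((h < 0) | (h >= 1)):
            raise ValidationError("SurvivalSchedule: each hazard must lie in [0, 1)")
        if self.s20 is not None:
            achieved = float(np.prod(1.0 - h))
            if abs(achieved - self.s20) > 1e-9:
                raise ValidationError(
                    f"SurvivalSchedule: cumulative survival {achieved!r} does not "
                    f"match target s20={self.s20!r}"
                )

    @property
    def horizon(self) -> int:
        return int(self.annual_hazard.size)

    @property
    def cumulative_survival(self) -> np.ndarray:
        """Survival to the end of each follow-up year."""
        return np.cumprod(1.0 - self.annual_hazard)

    @classmethod
    def no_tumor_mortality(cls, arm: str = "none", horizon: int = 20) -> "SurvivalSchedule":
        """Dedicated zero-hazard schedule (the no-tumor-mortality limit)."""
        return cls(arm=arm, annual_hazard=np.zeros(horizon), s20=None)


def build_schedule(
    calibration: ArmCalibration,
    mode: str = "constant-hazard",
    custom_hazards=None,
    horizon: int = 20,
) -> SurvivalSchedule:
    """Hazard schedule consistent with the arm's 20-year survival.

    ``constant-hazard`` (default) returns ``horizon`` equal hazards ``h`` with
    ``(1-h)**horizon == s20``.  ``custom`` takes a user hazard vector as a
    shape and rescales it on the cumulative-hazard scale so its product of
    annual survivals equals ``s20`` exactly (for sensitivity analysis).
    Tumor mortality cannot be switched off via ``s20 = 1``; use
    :meth:`SurvivalSchedule.no_tumor_mortality` instead.
    """
    s20 = calibration.s20
    if not 0.0 < s20 < 1.0:
        raise ValidationError("build_schedule: s20 must lie strictly in (0, 1)")
    if mode == "constant-hazard":
        h = 1.0 - s20 ** (1.0 / horizon)
        hazards = np.full(horizon, h)
    elif mode == "custom":
        if custom_hazards is None:
            raise ValidationError("build_schedule: custom mode requires custom_hazards")
        raw = np.asarray(custom_hazards, dtype=float)
        if raw.size != horizon:
            raise ValidationError(
                f"build_schedule: custom_hazards must have length {horizon}"
            )
        if np.any((raw < 0) | (raw >= 1)) or not np.any(raw > 0):
            raise ValidationError(
                "build_schedule: custom hazards must lie in [0, 1) with at least one > 0"
            )
        cum_h = -np.log1p(-raw)
        scale = -math.log(s20) / float(cum_h.sum())
        hazards = 1.0 - np.exp(-scale * cum_h)
    else:
        raise ValidationError(f"build_schedule: unknown mode {mode!r}")
    # Renormalize the last-step rounding so the invariant holds to 1e-9.
    achieved = float(np.prod(1.0 - hazards))
    if abs(achieved - s20) > 1e-12:
        hazards = 1.0 - (1.0 - hazards) * (s20 / achieved) ** (1.0 / horizon)
    return SurvivalSchedule(arm=calibration.arm, annual_hazard=hazards, s20=s20)
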