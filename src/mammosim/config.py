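"""Declarative run configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError
from .survival import DETECTION_FRACTION

__all__ = ["RunConfig"]

_DEFAULT_GOMPERTZ = {"amplitude": 58.4, "shape": 4.46, "decay": 0.071}
_DEFAULT_ARMS = {
    "ms": {"s15": 0.86, "s20": 0.819, "effective_td": 16.0},
    "no_ms": {"s15": 0.76, "s20": 0.679, "effective_td": 22.7},
}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Demography comes either from ``demography_dir`` (the three canonical
    CSVs) or from ``synth`` (keyword overrides for the synthetic generators;
    an empty mapping means calibrated defaults).  Exactly one must be given.
    All remaining defaults are the model's calibration constants: biennial
    screening over 20 years, 28-month metastasis offset, 80% screen-detection
    share, 88 EUR per screen, 50 replicates, entry ages 40-80 in 2-year steps.
    """

    master_seed: int = 1
    replicates: int = 50
    ages: tuple[int, ...] = tuple(range(40, 81, 2))
    band_width: int = 2
    follow_up_years: int = 20
    interval_years: int = 2
    met_offset_months: float = 28.0
    detection_fraction: float = DETECTION_FRACTION
    cost_per_screen: float = 88.0
    accrual_mode: str = "across-rounds"
    si: tuple[int, int] = (50, 68)  # entry-age range of the recommended interval
    gompertz: dict = field(default_factory=lambda: dict(_DEFAULT_GOMPERTZ))
    arms: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_ARMS.items()})
    demography_dir: Optional[str] = None
    synth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.ages = tuple(int(a) for a in self.ages)
        self.si = tuple(int(a) for a in self.si)
        if self.demography_dir is None and self.synth is None:
            raise ConfigError(
                "RunConfig: supply demography_dir or synth generator parameters"
            )
        if self.demography_dir is not None and self.synth is not None:
            raise ConfigError("RunConfig: demography_dir and synth are mutually exclusive")
        if self.replicates < 1:
            raise ConfigError("RunConfig: replicates must be >= 1")
        if not 0.0 <= self.detection_fraction <= 1.0:
            raise ConfigError("RunConfig: detection_fraction must lie in [0, 1]")
        for key in ("ms", "no_ms"):
            if key not in self.arms:
                raise ConfigError(f"RunConfig: arms must define '{key}'")

    @classmethod
    def default_synthetic(cls, **overrides) -> "RunConfig":
        """Calibrated synthetic demography, all printed constants."""
        overrides.setdefault("synth", {})
        return cls(**overrides)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["ages"] = list(self.ages)
        data["si"] = list(self.si)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown configuration keys {sorted(unknown)}")
        return cls(**data)
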