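"""End-to-end orchestration: demography -> simulation -> benefit tables.

``run_pipeline`` executes the full age sweep for one configuration and writes
a run directory of schema-stable CSVs (per-cohort endpoint tables, the
benefit/cost table with its interval aggregate, and the plot-ready by-age
series), a config snapshot and a log.  Output is deterministic given the
master seed.  Plots are optional artifacts; the CSV plot data is always
written so downstream checks never parse images.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .benefits import BenefitSummary, ScreeningPolicy, SweepResult, sweep_ages
from .config import RunConfig
from .demography import (
    DemographyTables,
    default_demography,
    load_demography,
    make_incidence,
    make_life_table,
    make_population,
)
from .errors import ConfigError
from .survival import ArmCalibration

__all__ = ["build_demography", "run_pipeline", "calibrations_from_config"]

log = logging.getLogger("mammosim")

_SYNTH_KEYS = {
    "life_table": ("makeham_offset", "gompertz_scale", "gompertz_slope", "max_age", "start_age"),
    "incidence": ("base_rate", "plateau_rate", "inflection_age", "width"),
    "population": ("base_count", "rolloff_age", "rolloff_width"),
}


def build_demography(config: RunConfig) -> DemographyTables:
    """Demography per the configuration: loaded CSVs or synthetic tables."""
    if config.demography_dir is not None:
        d = Path(config.demography_dir)
        return load_demography(
            d / "lifetable.csv", d / "incidence.csv", d / "population.csv"
        )
    synth = config.synth
    if synth is None:
        raise ConfigError("configuration supplies neither demography_dir nor synth")
    if not synth:
        return default_demography()
    unknown = set(synth) - {k for keys in _SYNTH_KEYS.values() for k in keys}
    if unknown:
        raise ConfigError(f"unknown synth parameters {sorted(unknown)}")
    lt_kwargs = {k: synth[k] for k in _SYNTH_KEYS["life_table"] if k in synth}
    inc_kwargs = {k: synth[k] for k in _SYNTH_KEYS["incidence"] if k in synth}
    pop_kwargs = {k: synth[k] for k in _SYNTH_KEYS["population"] if k in synth}
    return DemographyTables(
        life_table=make_life_table(**lt_kwargs),
        incidence=make_incidence(**inc_kwargs),
        population=make_population(**pop_kwargs),
    )


def calibrations_from_config(config: RunConfig) -> tuple[ArmCalibration, ArmCalibration]:
    ms, no_ms = config.arms["ms"], config.arms["no_ms"]
    return (
        ArmCalibration(arm="screened", effective_td=ms["effective_td"], s15=ms["s15"], s20=ms["s20"]),
        ArmCalibration(arm="unscreened", effective_td=no_ms["effective_td"], s15=no_ms["s15"], s20=no_ms["s20"]),
    )


def _endpoint_rows(sweep: SweepResult, detection_fraction: float) -> pd.DataFrame:
    rows = []
    for cohort in sweep.cohorts:
        for arm_name, agg in (("screened", cohort.screened), ("unscreened", cohort.unscreened)):
            t, se = agg.mean, agg.se
            row = {
                "entry_age": cohort.entry_age,
                "arm": arm_name,
                "n_women": t.n_women,
                "n_bc": t.n_bc,
                "n_bc_screen_detected": (
                    detection_fraction * t.n_bc if arm_name == "screened" else 0.0
                ),
            }
            for f in ("e1", "e2", "e3", "e4", "e5", "e6"):
                row[f"{f}_pct"] = 100.0 * getattr(t, f)
                row[f"se_{f}_pct"] = 100.0 * se[f]
            for f in ("ll", "ll_corr", "yll", "yll_corr"):
                row[f] = getattr(t, f)
                row[f"se_{f}"] = se[f]
            rows.append(row)
    return pd.DataFrame(rows)


def _benefit_row(summary: BenefitSummary, entry_age=None) -> dict:
    row = {"label": summary.label, "entry_age": entry_age}
    for f in (
        "n_women", "mse", "pd", "pd_corr", "ly", "ly_corr",
        "mse_per_pd", "mse_per_pd_corr", "cost_per_pd_corr",
        "mse_per_ly_corr", "cost_per_ly_corr", "pd_per_10k", "ly_per_10k",
    ):
        value = getattr(summary, f)
        row[f] = np.nan if value is None else value
    return row


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the configured age sweep and write the run directory.

    Writes ``tables2_3.csv`` (per-cohort endpoint/loss tables for both arms),
    ``table4.csv`` (benefit metrics per cohort plus the screening-interval
    aggregate), ``endpoints_by_age.csv``, ``mse_per_pd_by_age.csv``,
    ``mse_per_ly_by_age.csv``, ``config.yaml`` and ``run.log``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info(
            "run start: master_seed=%d replicates=%d ages=%s accrual=%s",
            config.master_seed, config.replicates, list(config.ages), config.accrual_mode,
        )
        log.info(
            "replicate seeds derive as [master_seed, entry_age, arm_code, replicate]; "
            "any single replicate can be replayed from those four integers"
        )
        demography = build_demography(config)
        policy = ScreeningPolicy(
            interval_years=config.interval_years,
            follow_up_years=config.follow_up_years,
            cost_per_screen=config.cost_per_screen,
        )
        sweep = sweep_ages(
            demography,
            calibrations=calibrations_from_config(config),
            policy=policy,
            ages=config.ages,
            master_seed=config.master_seed,
            replicates=config.replicates,
            band_width=config.band_width,
            accrual_mode=config.accrual_mode,
            met_offset_months=config.met_offset_months,
        )
        for cohort in sweep.cohorts:
            log.info(
                "cohort %d: n_women=%.0f n_bc=%.1f pd_corr=%.1f",
                cohort.entry_age,
                cohort.benefit.n_women,
                cohort.unscreened.mean.n_bc,
                cohort.benefit.pd_corr,
            )

        endpoints = _endpoint_rows(sweep, config.detection_fraction)
        endpoints.to_csv(out_dir / "tables2_3.csv", index=False)

        benefit_rows = [
            _benefit_row(c.benefit, entry_age=c.entry_age) for c in sweep.cohorts
        ]
        si_lo, si_hi = config.si
        ages_in_si = [a for a in config.ages if si_lo <= a <= si_hi]
        if ages_in_si:
            benefit_rows.append(_benefit_row(sweep.aggregate(si_lo, si_hi)))
        pd.DataFrame(benefit_rows).to_csv(out_dir / "table4.csv", index=False)

        fig_cols = ["entry_age", "arm"] + [f"{f}_pct" for f in ("e1", "e2", "e3", "e4", "e5", "e6")]
        endpoints[fig_cols].to_csv(out_dir / "endpoints_by_age.csv", index=False)
        per_age = pd.DataFrame(
            [_benefit_row(c.benefit, entry_age=c.entry_age) for c in sweep.cohorts]
        )
        per_age[["entry_age", "mse_per_pd", "mse_per_pd_corr"]].to_csv(
            out_dir / "mse_per_pd_by_age.csv", index=False
        )
        per_age[["entry_age", "mse_per_ly_corr"]].to_csv(
            out_dir / "mse_per_ly_by_age.csv", index=False
        )
        config.to_yaml(out_dir / "config.yaml")
        log.info("run complete: %s", out_dir)
    except Exception as err:  # add run context, then re-raise
        log.error("run aborted: %s", err)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out_dir


def plot_sweep(sweep: SweepResult, out_dir) -> list[Path]:
    """Optional PNG plots of the by-age series (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ages = sweep.ages
    written = []

    fig, ax = plt.subplots()
    for key, style in (("mse_per_pd_corr", "-o"), ("mse_per_pd", "--s")):
        ys = [getattr(c.benefit, key) for c in sweep.cohorts]
        ax.plot(ages, [np.nan if y is None else y for y in ys], style, label=key)
    ax.set_xlabel("entry age (years)")
    ax.set_ylabel("screens per prevented death")
    ax.legend()
    path = out_dir / "mse_per_pd_by_age.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots()
    ys = [c.benefit.mse_per_ly_corr for c in sweep.cohorts]
    ax.plot(ages, [np.nan if y is None else y for y in ys], "-o")
    ax.set_xlabel("entry age (years)")
    ax.set_ylabel("screens per life-year gained")
    path = out_dir / "mse_per_ly_by_age.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
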