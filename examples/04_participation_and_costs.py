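"""Participation arithmetic and the incremental-round decision.

Two policy questions built on the sweep: how many deaths does partial
participation leave on the table, and — if an eleventh screening round is
offered — should it start earlier (48) or extend later (70)?  The four
decision quantities are prevented deaths, screens/cost per prevented death,
life-years gained, and screens/cost per life-year.
"""

from mammosim import (
    default_demography,
    incremental_round_comparison,
    participation_scenario,
    sweep_ages,
)

# National death counts: linear interpolation between 0% and 100% screening.
for p in (0.0, 0.5, 0.7, 1.0):
    r = participation_scenario(20657, 16381, p)
    print(f"participation {100 * p:5.1f} % -> expected deaths {r.expected_deaths:8.0f}")
print(f"full-participation mortality reduction: {r.reduction_percent_at_full:.1f} %\n")

sweep = sweep_ages(default_demography(), master_seed=1, replicates=50)
by_age = {c.entry_age: c.benefit for c in sweep.cohorts}
cmp = incremental_round_comparison(by_age[48], by_age[70])

print(f"extra round at {cmp.label_lo} vs {cmp.label_hi}:")
rows = [
    ("prevented deaths (corr)", cmp.pd_corr, "{:.0f}"),
    ("screens per prevented death", cmp.mse_per_pd_corr, "{:.0f}"),
    ("EUR per prevented death", cmp.cost_per_pd_corr, "{:.0f}"),
    ("life-years gained", cmp.ly_corr, "{:.0f}"),
    ("screens per life-year", cmp.mse_per_ly_corr, "{:.0f}"),
    ("EUR per life-year", cmp.cost_per_ly_corr, "{:.0f}"),
]
for name, (lo, hi), fmt in rows:
    print(f"  {name:<28} {fmt.format(lo):>10} {fmt.format(hi):>10}")
print("\nyounger cohorts buy more life-years per death prevented; older ones "
      "need fewer screens per prevented death until competing mortality bites.")
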