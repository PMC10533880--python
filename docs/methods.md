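# Methods

## Model structure

The package models, for each two-year entry cohort between 40 and 80, a
screened (+MS) and an unscreened (−MS) arm that share demography and
incidence and differ only in the tumor-size distribution at diagnosis —
summarized as one effective tumor diameter per arm and hence one
tumor-specific survival function per arm. This deliberately ignores
within-arm prognostic heterogeneity (hormone-receptor subtype, grade,
nodal status): one survival curve per arm is the minimal model in which the
screening effect is exactly the survival gap between the arms.

### Tumor-diameter survival curve

15-year tumor-related survival in percent is
`S15(TD) = 100 − A·exp(−B·exp(−c·TD))` with A = 58.4, B = 4.46,
c = 0.071/mm. The curve is strictly decreasing with asymptote
100 − A = 41.6 % for large tumors; its analytic inverse
`TD(S15) = −ln(ln(A/(100−S15))/B)/c` is exposed for calibration work.

### Arm calibrations

| arm | effective TD | S15 | s20 (20-year) |
|---|---|---|---|
| screened | 16.0 mm | 86 % | 81.9 % |
| unscreened | 22.7 mm | 76 % | 67.9 % |

The 20-year values are carried as printed calibration constants and are
**not** recomputed from S15: no extrapolation rule reproduces both
(constant-cumulative-hazard scaling gives 0.86^(4/3) = 0.818 but
0.76^(4/3) = 0.694 ≠ 0.679), so deriving them would replace data with a
guess. The 80 % screen-detection share is a reporting constant only: its
prognostic content is already folded into the 16-mm effective diameter.

### Hazard schedules

Each arm's s20 becomes a vector of 20 annual conditional tumor-death
hazards whose survival product equals s20 to 1e−9. The default is constant
hazard, h = 1 − s20^(1/20) (0.00993/yr screened, 0.01917/yr unscreened) —
the minimal assumption given that only the cumulative constraint is known.
Under it, destined tumor deaths occur on average 112 months after
diagnosis, hence 84 months after the metastasis placed 28 months earlier,
matching the target mean metastasis-free time. A custom 20-vector shape is
accepted for sensitivity analysis; it is rescaled on the cumulative-hazard
scale so the s20 constraint still holds exactly. Switching tumor mortality
off is a dedicated zero-hazard schedule, never `s20 = 1`.

## The microsimulation

For a cohort entering at age A (single-year ages A and A+1, counts from the
population table), the expected number of breast cancers in biennial round
r is `count × S_alive(A → A+2r) × 2 years × incidence(A+2r)/1e5`, with
`S_alive` from the life table; fractional expectations are rounded
stochastically so the expectation is preserved. Age at diagnosis is the
attained age at the round (`accrual_mode="across-rounds"`, default) or the
entry age (`"at-entry"`, the single-round reading); either way each patient
is followed 20 years from her own diagnosis, so the destined-tumor-death
fraction E3 ≈ 1 − s20 in every cohort.

Each patient draws, independently:

* tumor death from the arm schedule — year k with probability
  `Π_{j<k}(1−h_j)·h_k`, date uniform within the year, absent with
  probability s20;
* tumor-independent death from life-table q at her attained integer age in
  each follow-up year, same within-year rule.

The earlier event decides the endpoint (E1/E2 when no tumor death is
destined; E4/E5/E6 split by the metastasis time `t_bc − 28 months`,
clamped at diagnosis). Exact ties — probability zero under continuous
dates — resolve to the tumor-independent death. Two uniforms are consumed
per draw regardless of outcome, so random streams are reproducible
position-by-position.

Years of life lost per destined tumor death equal the life table's residual
life expectancy at the attained age of the (would-be) tumor death — not at
diagnosis — and `yll_corr` counts only realized (E4) deaths. Each
(cohort, arm, replicate) gets its own generator seeded from
`[master_seed, entry_age, arm_code, replicate]`, so arms and single
replicates replay independently; 50 replicates are averaged by default,
with standard errors reported.

## Benefit metrics

PD = ΔLL and PD corr = ΔLL corr between the arms of one cohort; LY corr =
ΔYLL corr. Screens are counted as 10 per woman (20 years / 2-year interval)
at 88 € each, regardless of deaths during follow-up, matching the
benefit-table construction. Cost identities hold exactly by construction
(€/PD = 88 × MSE/PD; per-10⁴-MSE rates are the exact reciprocals of the
MSE-per-unit ratios). Ratios with no prevented deaths are typed
not-estimable values (`None`), never infinities. Age-interval aggregates
sum PD/LY/MSE across cohorts before forming ratios (weighted-mean
semantics), not averages of per-cohort ratios. The participation scenario
is linear interpolation between the no-screening and full-participation
death counts.

## Synthetic demography

The generators are deterministic functions of their parameters and stand in
for national statistics tables; real tables in the same CSV dialect
(`age,q,e` / `age,rate_per_100k` / `age,count`, comma-separated, dot
decimal) can be substituted via `load_demography`. Calibration constants
were fixed once against population-level anchors:

* **Life table** — Gompertz–Makeham hazard
  `μ(a) = 3e−4 + 1.6e−5·exp(0.098·a)`, q = 1 − exp(−μ), ages 40–120;
  e is recomputed from q by standard accounting (mid-year deaths, table
  closed at the last age), so the columns are consistent by construction.
  This yields 20-year all-cause survival ≈ 94.8 % from 40, 70.8 % from 60,
  8.9 % from 80 — the ordering that drives the age gradient of E2/E5/E6.
* **Incidence** — logistic rise anchored at 90 per 100k at age 40 to a
  340 per 100k plateau at 75 (inflection 53, width 5), chosen so the 50–69
  entry cohorts accrue ≈ 57 breast cancers per 1000 women over 20 years.
* **Population** — logistic rolloff `27,500/(1+exp((a−78)/6))` women per
  single year of age, i.e. cohorts of ≈ 50–55k women — the scale of the
  modeled populations the benefit table is built from. All per-death,
  per-life-year and per-10⁴-screen metrics are invariant to this scale.

What the synthetic demography does **not** emulate: calendar-time trends
(period life tables and incidence are frozen), cohort effects, the exact
national incidence curve (only its anchored shape), and migration. Tests
passing on it therefore establish structural properties — conservation of
endpoint fractions, parameter recovery, age monotonicities, the U-shape of
screens-per-prevented-death with an interior optimum — not the exact
published per-cohort values, which require the original supplementary
demography exported to the CSV dialect. On the synthetic tables the
optimum falls at entry age 54 rather than in the mid-60s, because the
synthetic mid-life mortality is somewhat heavier and the incidence plateau
flatter than the real-data inputs.

## Numerical choices

* Event sampling inverts the cumulative death distribution with one uniform
  (`searchsorted`), vectorized per diagnosis-age group.
* Life-table lookups beyond the last tabulated age reuse the terminal row;
  coverage is validated up to entry age + 40 years.
* The life-expectancy recursion pins e at 0.5 wherever q has saturated to
  1.0 in floating point, so e is strictly decreasing except on that
  saturated tail.
* CSV round-trips are bit-exact (`float_precision="round_trip"` on read).
* Monotonicity of the competing-event attenuation PD corr/PD is asserted on
  an 8-year entry-age grid: adjacent 2-year cohorts at the young end differ
  by only ~0.2–0.4 percentage points, below the Monte-Carlo resolution of
  independent 50-replicate estimates, while the age trend itself is the
  scientific claim.

## Known limitations

Overdiagnosis, false positives, DCIS, recall burden and quality-of-life
effects are out of scope; only mortality effects are modeled. Breast-cancer
deaths beyond 20 years from diagnosis are not counted. Screening
sensitivity and sojourn time are not modeled explicitly — they are absorbed
into the screened arm's effective-diameter calibration. The metastasis
offset is fixed at 28 months (a configuration hook exists, but no
distribution is modeled). Costs are raw multiplications without discounting
or QALY weighting.
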