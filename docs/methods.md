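# Methods

## Model structure and assumptions

The core is a deterministic, discrete-time, stage-structured projection
of a *Vertigo moulinsiana* population. Stages are eggs, juveniles and
three adult age classes distinguished by the number of winters survived;
the age classes differ in survival and fecundity schedules, matching
what is known of first-time versus older reproducers in this snail. Time
is structured as seasons of six active months (May–October); the
November–April period is collapsed into a single overwintering
transition. All state variables are expected counts (real numbers): the
recursion is linear, so it propagates the mean of the underlying
individual-level process exactly, and quantities like growth rates and
extinction ordering are independent of the population's absolute scale.

Assumptions inherited from the model's design: no density dependence, no
environmental stochasticity in the deterministic core, no spatial
structure or dispersal, a single aggregate mortality parameter per stage
(no causes of death are distinguished), rates constant through time, no
egg overwintering, and no fourth adult age class (adults die after their
third season). These keep the model transparent enough that the effect
of changing one parameter — winter survival — can be read directly.

## Parameters

| name | meaning | default | provenance |
|---|---|---|---|
| `d_a1..d_a3` | monthly adult survival per age class | 0.875 | midpoint of the reported 10–15% monthly adult mortality |
| `d_j` | monthly juvenile survival | 0.85 | **placeholder** — not fixed by published text |
| `d_e` | egg hatching ratio (month-to-month) | 0.8 | **placeholder** — not fixed by published text |
| `d_w` | winter survival (juveniles and adults) | 0.7 | scenario baseline; reported field range 0.6–0.73 |
| `a` | same-season recruitment ratio | 0.125 | midpoint of the reported 10–15% |
| `e1`, `e2` | monthly eggs per capita, age 1/2 | (4.75,4.75,4.75,4.75,0,0) | 19 eggs per season, May–August laying window |
| `e3` | monthly eggs per capita, age 3 | 0 | age-3 adults appear in the life-cycle diagram but not in the laying equation |

The uniform spread of the 19-egg seasonal total over the four laying
months is a choice; only the total and the window are constrained.
Alternative schedules load through the YAML config. Because `d_j` and
`d_e` are placeholders, absolute abundances from the defaults are not
comparable to field-parameterised runs (the defaults give a strongly
growing baseline); orderings, structural zeros and linearity properties
are unaffected. Empirically estimated parameter sets are injected
verbatim via `load_config` — nothing in the package re-derives them.

## Maturation bookkeeping (the two modes)

In months 5–6 the cohort hatched three months earlier can mature. The
published recursion subtracts `(1-a)·J(i-3)·d_j` from the juvenile pool
while adding `a·J(i-3)·d_j` to age-1 adults — the non-maturing part of
the lagged term leaves the ledger entirely, which conflicts with the
narrative that most juveniles overwinter and mature next season. Both
interpretations are shipped:

* **literal** (default): exactly the printed equations; required for
  comparability with the published scenario tables.
* **corrected**: only the maturing fraction `a·J(i-3)·d_j` leaves the
  juvenile pool, so the juvenile outflow equals the adult inflow.

Neither mode is unconditionally non-negative: both subtract a fraction
of the lagged *pool* `J(i-3)` rather than a tracked cohort, so the same
individuals can be drained twice (month 5 and month 6) under extreme
parameters (e.g. `a` near 1 with high `d_j`, or very low `d_j` where the
pool shrinks faster than the lag). Any negative intermediate is clamped
to zero and recorded as a diagnostic with its season/month coordinates —
never silently. In corrected mode, conservation of maturing individuals
(juvenile outflow = adult inflow) holds exactly at every step and is
property-tested.

One related boundary choice: the printed month-2 branch is `E(1)·d_e`
alone, which presumes `J(1)=0`. The implementation uses the general form
`J(1)·d_j + E(1)·d_e` — identical in every model-generated season (the
overwintering transition always leaves `J(1)=0`) but consistent for a
user-supplied initial state that starts with juveniles, which the
default initial state (100 individuals per non-egg class) does.

## Cold tolerance and scenarios

Freeze mortality at winter minimum `t_min` is the empirical fraction of
SCP measurements at or above `t_min` (ties freeze). It reduces winter
survival multiplicatively, `d_w' = d_w·(1-m)`: the only rule that
reproduces all four published adjusted values after two-decimal half-up
rounding (0.7·0.97→0.68, 0.7·0.77→0.54, 0.7·0.50=0.35, 0.7·0.05→0.04).
Internal values are never rounded; rounding exists solely for comparison
with printed tables. The five canonical scenarios use the published
mortality fractions directly (`build_paper_scenarios`); the SCP-sample
route is for new analyses.

Scenario summaries: final-season mean/SD/min/max are taken over the six
monthly totals of the last simulated season (SD with `ddof=1`, the only
within-run spread a deterministic model offers). Quasi-extinction is the
first month step from which the total stays below 1.0 individuals for
the rest of the run (a transient dip does not count); steps count active
months only, six per season. `lambda` is the plain percent change
between first- and last-season means — no geometric annualisation, to
stay on the published statistic's scale.

## Synthetic SCP sample

The generator inverts a piecewise-linear freeze-fraction curve anchored
at (0%→−6.3), (3%→−6.3), (23%→−8), (50%→−10), (95%→−14), (100%→−15) °C,
using one stratified uniform draw per 1/n probability stratum
(shuffled). Stratification pins the empirical freeze fractions at the
anchor temperatures to within 1/n of the anchors for *every* seed, so
the calibration (50% at −10 °C, 95% at −14 °C, ±2 points) is not a
matter of Monte-Carlo luck. Two reported summaries of the real winter
data cannot be jointly satisfied and are knowingly compromised: a sample
confined to the observed range [−15, −6.3] cannot also place 3% of its
mass at or above −6 °C (that anchor is instead placed at the −6.3 °C
maximum), and the anchored piecewise-linear curve implies a mean of
about −10.2 °C rather than the reported −9.9 °C. The threshold anchors
were kept authoritative because the scenario machinery consumes
threshold fractions, not means.

What the fixtures do not emulate: stage-specific SCP differences (labels
are carried but no stage-resolved calibration is attempted), measurement
error, between-winter acclimation, and any correlation between cold
tolerance and demography. Tests passing on these fixtures show the
machinery is faithful to its equations and calibration targets — not
that the defaults describe any particular field population.

## Individual-based oracle

The IBM simulates integer individuals under the same per-capita rules:
cohort survival as Binomial draws (distributionally identical to
per-individual Bernoulli trials, vectorised across replicates), egg
counts as Poisson with the scheduled per-capita mean (the published
model specifies only means; Poisson is the documented choice), hatching
and overwintering as Binomials. Maturation draws the lagged cohort's
survivors `Binom(J(i-3), d_j)`, splits them by `a`; maturing ones join
age class 1, and the juvenile pool loses the non-maturing survivors
(literal) or the maturing ones (corrected), mirroring the deterministic
expectations exactly. Negative pools are truncated and counted. Because
every kernel is linear in expectation, replicate means converge to the
deterministic trajectory at rate 1/sqrt(replicates); the acceptance
check runs 10^4 individuals per class, 200 replicates, 2 seasons and
requires agreement within 3 Monte-Carlo standard errors per month.

## Numerical choices and problem sizes

Probabilities are validated into [0,1] at construction; schedules must
be non-negative with exactly six entries. Trajectory CSVs are written
with 17 significant digits and read back with round-trip float parsing,
so write→read is bit-exact. Linearity tests scale by powers of two,
which is exact in binary floating point. Default horizons follow the
scenario experiment (20 seasons = 120 active months); the test suite
uses 1–20 seasons and the oracle comparison above, all of which run in
seconds on one core.

## Known limitations

Absolute abundances under the default parameters are placeholder-driven
(see above). The literal mode's ledger imbalance is reproduced, not
repaired, by default. The published scenario table itself (final sizes
514, 267.5, 7.3, 0, 0 and extinction at 49 and 17 months) requires the
authors' supplementary parameter values and is reproducible only after
injecting them through the config; under any valid parameter set the
package guarantees the monotone severity ordering across scenarios,
which is what the tests assert. `t_min` is exogenous: there is no
snowpack or soil-temperature model.
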