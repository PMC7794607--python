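# Methods

`beecomp` analyses brood dynamics of honeybee (*Apis mellifera*) colonies
under a stressor that raises larval mortality — the motivating case is
chronic exposure to a neonicotinoid fed in sugar syrup — and asks the
colony-level question: how much extra brood must a colony initiate to keep
its brood nest stable, and what does that compensation cost at full colony
scale?

## Demographic model

The larval population is described by a Lefkovitch stage-classified
projection matrix with seven weekly age classes `l_1 .. l_7` plus a queen
class `Q = 1`.  The weekly update is `n_{t+1} = A n_t` with

- fecundity element `A[1, 8] = h`, the number of eggs hatching into larvae
  per week,
- subdiagonal survival `A[x+1, x] = 1 − m_x` for `x = 1..6`, where `m_x` is
  the per-capita weekly mortality of age class `x`,
- queen self-loop `A[8, 8] = 1`.

Larvae surviving week 7 pupate and leave the larval population; the model
therefore carries no eighth class, and the weekly pupation flux
`(1 − m_7) l_7` is available separately (`pupation_flux`).  This keeps the
larval total `L_t = Σ_x l_x` consistent with the seven-class sum.

Because the larval block of `A` is nilpotent and the queen seeds class 1
with `h` larvae every week, any starting state reaches the unique fixed
point after seven applications.  At the fixed point class `x` holds
`h · Π_{j<x}(1 − m_j)` larvae, so the hatch rate that holds the population
at a target `L` is the closed form

    h* = L / Σ_{x=1..7} Π_{j=1..x−1} (1 − m_j).

`stable_hatch_rate` implements this; the test suite checks it against an
independent root-finding oracle (Brent's method on the power-iterated
population total) over 1,000 random schedules at 1e−9 relative tolerance.
`h*` is linear in `L` and non-decreasing in every `m_i`.

Compensation is reported as the fold-increase `h_dosed / h_control`.  The
packaged per-group hatch rates (56, 88, 98, 107 at `L = 300` for control
and three increasing doses) reproduce folds 1.57, 1.75 and 1.91.  The
weekly schedule behind those published rates is not recoverable from the
printed phase aggregates — a geometric decomposition of the control phase
survivals gives `h ≈ 53.4`, not 56 — so the rates are treated as inputs of
the fold computation, not as solver targets.

### Mortality schedules from data

`estimate_weekly_mortality` applies `m_t = 1 − S_{t+1}/S_t` to a cohort
survivor series.  Zero-count denominators yield NaN entries flagged as
undefined weeks; an increasing pair is treated as a data error (a cohort
cannot gain members) and raises unless clamping to `m = 0` is requested.
`expand_phase_survival` bridges phase-aggregate survivals (e.g. 0.78 over
weeks 1–4) to the weekly schedule the matrix needs, assuming equal weekly
survival `s = S^(1/n)` within a phase; the geometric assumption is recorded
in the schedule metadata.  Weeks covered by no phase default to zero
mortality.

## Cohort survival analysis

Fate tables record one row per tracked brood cell per weekly inspection
(`hive_id, treatment, cohort_week, cell_id, week, stage` with stages
`egg/larva/capped/empty/dead/missing`).  A cell marked as a day-4–5 larva
*survives* when it is capped within 2 weeks of marking and the cell is
empty (adult emerged) within 3 weeks — the standard worker schedule caps
around day 9 and emerges around day 21 post-laying; both windows are
configurable.  A cell *dies* when it is emptied or found dead before
capping, is still open past the capping deadline, or never opens in time;
it is *censored* when observations end first.  Censored cells are excluded
from numerator and denominator by default (`censored_policy="died"` treats
them as failures at the week after last observation).

Weekly survivor counts `S_t` count the phase-start cohort still on a
surviving trajectory at week `t`; they are monotone non-increasing per
hive and feed the mortality estimator directly, so on censoring-free data
the product `Π(1 − m_t)` recomposes the phase survival exactly.  Phase
summaries report the mean and sample SD of per-hive survival fractions
(the reporting style of small-n field studies), plus the cell-pooled
fraction, since published aggregates are ambiguous between the two.

## Census analysis

Census tables hold hive × week counts of eggs, larvae and capped brood
("capped" and "pupae" are synonymous here).  The stage-ratio analysis
computes, per hive, `numerator(t) / denominator(t − shift)` with a default
one-week shift (this week's larvae are last week's eggs).  Zero or missing
denominators produce missing ratios, never infinities, and missingness
propagates to medians by omission.  Documented outliers can be excluded
from ratio computation as `(hive, week)` pairs; raw counts are never
altered and exclusions are echoed in the output.  Group summaries take the
median over hives per week, then the median of those weekly medians; means
are emitted alongside because published summaries mix the two statistics.
Seasonal trends are summarised by a descriptive OLS parabola of mean
counts over weeks (statsmodels); mixed-effects inference is out of scope.

## Colony simulator

A deliberately simplified, daily-time-step, cohort-based colony model —
not a re-implementation of any agent-based forager model.  Individual
foraging (scouting, recruitment, landscape, weather) is replaced by an
aggregate honey income with a Bernoulli foraging-day switch, so absolute
colony sizes and modelled survival values are qualitative; within-model
comparisons (dose ordering, calibration recovery) are the supported use.

State: brood cohorts by age since laying (egg 0–2 d, larva 3–8 d, pupa
9–20 d), in-hive workers by adult age (0–20 d), an aggregate forager pool,
and a honey store.  Daily events, in order: stage-specific survival, aging
and promotion (brood age 21 → in-hive, in-hive age 21 → forager), cohort
bookkeeping, egg laying, honey income/consumption.

Key parameters (defaults):

| parameter | default | meaning |
|---|---|---|
| `mortality_egg/larva/pupa` | 0.03 / 0.01 / 0.001 d⁻¹ | baseline brood mortality |
| `mortality_inhive` | 0.004 d⁻¹ | in-hive worker mortality |
| `mortality_forager` | 0.06 d⁻¹ (0.004 off-season) | flight risk; winter bees idle and live for months |
| `peak_laying_rate/day/width` | 1600 eggs·d⁻¹, day 140, 60 d | Gaussian seasonal laying |
| `brood_per_nurse` | 1.0 | brood cells one nurse can tend |
| `forager_nurse_weight` | 0.25 | foragers' reduced contribution to nursing |
| `ProteinFactorNurses` | 1.0 | baseline protein content of brood food |
| `ProteinNursesModifier_Exposed` | 1.0 | multiplier during the exposure window |
| `swarm_threshold/deadline/fraction` | 17,000 adults / day 199 / 0.6 | swarming rule |
| `death_floor` | 4,000 adults at year end | colony death rule |

The pesticide mechanism: larval daily survival is multiplied by
`p^(1/6)` where `p` is the protein factor (baseline × modifier inside the
exposure window), so whole-larval-stage survival scales proportionally to
`p` and a modifier of 0 kills every cohort whose larval window overlaps
the exposure.  The true functional link between brood-food protein and
larval mortality is not published; proportionality is the simplest choice
and the calibration step absorbs mapping differences.

Egg laying is capped by free brood cells (`MAX_BROODCELLS`) and by nurse
capacity `brood_per_nurse × (in-hive + 0.25 × foragers)`.  With
`brood_per_nurse ≈ 1` the nurse workforce mildly limits peak-season
laying; this feedback is what lets a spring larval deficit (fewer nurses
in June) propagate into autumn colony size, producing the graded
dose-response at year end.  The laying peak at day 140 (late May) was set
so the unexposed full-size colony crosses the swarming threshold before
the July 18 deadline and swarms about once per year (measured 1.0 ± 0.2
over 20 replicates); with the peak at midsummer the adult population
peaks too late and no colony ever swarms.

Swarming: when allowed, the first day the adult population exceeds the
threshold before the deadline removes `swarm_fraction` of adults; the
simulation follows the remaining colony through a 25-day laying pause
(queen replacement).  The rule re-arms only after the population falls
back below the threshold (hysteresis), so one crossing yields one swarm.
Adults-only counting is the default: counting brood would trigger
"swarming" in early spring off the overwintered bees alone.  Death rules:
honey depletion (unless the store is topped up daily, `HoneyIdeal`, as for
fed experimental colonies) or fewer than 4,000 adults at year end.

Presets: `fullsize_default` (10,000 foragers on Jan 1, spring exposure
window days 95–130) and `nucleus_2014` (100 pupae + 650 workers on day
209, 250 brood cells, 0.77 kg honey store refilled daily, exposure days
211–253).  The nucleus preset initializes the 150 brood cells not pinned
by the published preset as ongoing laying spread uniformly over egg and
larval ages: an established nest sits at its cap, and starting those
cells empty produces a 21-day laying echo that leaves near-empty cohorts
exactly in the scoring window.

### Brood-survival metric and calibration

Brood survival of a laying-day cohort is its size at 19 days of age
divided by its size at 3 days; the scenario metric averages the last 10
cohorts reaching 19 days inside the scoring window (September 1–10 for
the nucleus).  Calibration grid-searches the exposure modifier over
0.6–1.0 in steps of 0.01 (optionally including 0), running 30 seeded
replicates per grid value and choosing the modifier whose mean metric is
closest to the target (ties toward the larger modifier).

Stochastic stepping draws survivors by inverse-CDF sampling from a
lockstep uniform stream: every simulated day consumes a fixed number of
uniforms, so runs sharing a seed stay on identical streams across grid
values (common random numbers), and the inverse CDF is monotone in the
survival probability, so for a fixed stream a more favorable modifier
never yields fewer survivors.  This makes grid sweeps smooth in the
modifier and calibration self-consistent: a target generated at a known
modifier with the same seed is recovered exactly.  With independent
seeds the binomial noise floor of a 250-cell nucleus at 30 replicates
(SE ≈ 0.007 against a grid step of ≈ 0.009 in metric units) allows
recovery only to within about three grid steps.

## Synthetic data

The fate-table generator draws a per-hive weekly survival on the logit
scale (mean = the group's weekly survival, SD = `hive_effect_sd`, keeping
probabilities in [0, 1]) and then simulates each tracked cell through
independent weekly Bernoulli survival.  Survivors appear as larva,
capped, capped, empty over the phase weeks; failures stop at the failure
week, so generated tables are censoring-free.  The census generator draws
egg counts from a per-group quadratic seasonal trend with additive
Gaussian noise (truncated at zero) and derives larvae and capped brood
from the previous week's counts through fixed conversion ratios with
multiplicative noise; with all noise at zero, the shifted stage ratios
equal the generating ratios exactly.

The `kirchhain2014` preset encodes the published group-level summaries of
a late-summer nucleus-colony exposure study: phase-A (weeks 1–4)
survivals 78/54/46/52 % and phase-B (weeks 4–7) survivals
82.9/34.6/40.3/6.7 % for control and three doses, decomposed to weekly
survivals by cube root (0.9205, 0.9394, 0.4062, …); cohort totals
230/244/248/303 (phase A) and 260/280/218/77 (phase B) over 4–5 hives;
control stage ratios 1.5 larvae/egg and 2.06 capped/larva.  A logit-scale
hive SD of 0.35 approximately matches the printed across-hive SDs; with
only 4–5 hives the realized SD is itself noisy, so exact SD matching is
not asserted anywhere.

What the generators do not emulate: within-hive correlation beyond the
hive random effect, week-specific mortality structure inside a phase
(survival is geometric within phases), censoring and observation gaps,
and any dependence between the fate tables and the census counts.
Passing tests therefore show that the estimators recover the generating
parameters under the model's own assumptions, not that real brood data
meet those assumptions.

## Numerical choices

- Week indexing is 1-based; the compensation table rounds `h` half-up and
  folds to two decimals (both raw and rounded values are kept).
- Schedules admit NaN entries only as flagged undefined weeks; operations
  needing a complete schedule reject them.
- Degenerate inputs: empty fate/census files parse to empty tables with a
  warning; hives with zero initial cells are dropped from summaries with
  a warning; dangling outlier exclusions warn rather than fail; a colony
  with no bees is flagged dead at initialization.
- Simulation problem sizes in the shipped tests and acceptance script
  (200–500 replicate fate tables, 30-replicate grid sweeps, 8–20
  full-size replicates) were chosen to hold Monte-Carlo error comfortably
  below the asserted tolerances.

## Known limitations

- The simulator has no drones, no parasites or disease, no pollen store,
  no landscape or weather input, and its honey economy is aggregate; it
  does not claim numerical equivalence with any published colony model.
- The protein-to-mortality link is an assumption (proportional); only
  calibrated comparisons across modifiers are meaningful.
- The demographic model is density-independent and purely stage-
  structured; no eigenvalue/sensitivity machinery is provided beyond the
  stability condition.
- Phase survivals are decomposed geometrically; if real weekly mortality
  varies within a phase, the reconstructed schedule redistributes it.
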