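"""Simplified cohort-based honeybee colony simulator.

A daily-time-step model of a single colony: the queen lays eggs at a
seasonal rate, brood develops through egg (3 d), larva (6 d) and pupa
(12 d) stages tracked per laying-day cohort, emerging workers spend 21 d
as in-hive bees before graduating to foragers, and every stage carries a
daily mortality.  Honey is an aggregate store fed by foragers on foraging
days and drained by adult and larval consumption.

The pesticide mechanism acts through brood food: nurse bees feed larvae
jelly whose protein content is ``ProteinFactorNurses``, multiplied by
``ProteinNursesModifier_Exposed`` while the colony is inside an exposure
window.  Daily larval survival is scaled by ``p ** (1 / larval_duration)``
so that whole-larval-stage survival is proportional to the protein factor
``p``; a modifier of 0 therefore kills every cohort whose larval window
overlaps the exposure period.

Colony-level rules: a colony whose population exceeds a swarming threshold
before a calendar deadline releases a swarm (a fraction of the adults
leaves; the simulation follows the remaining colony through a laying pause
while the new queen is reared and mated), and a colony dies if it runs out
of honey or ends the year below a minimum population.

This is a deliberately simplified, cohort-based re-implementation of
agent-based colony models: there is no individual foraging (scouting,
recruitment, landscape), so absolute colony sizes and modelled survival
values are qualitative, while within-model comparisons (dose ordering,
calibration recovery) are the intended use.

Two presets are shipped: ``fullsize_default`` (10,000 foragers on
January 1, spring exposure window) and ``nucleus_2014`` (a mating-nucleus
mimic: 100 pupae + 650 workers on day 209, 250 brood cells, a 0.77 kg
honey store refilled daily, late-summer exposure window, brood survival
scored on the last 10 cohorts reaching 19 days of age by September 10).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "StageDurations",
    "SimConfig",
    "ColonyState",
    "SimResult",
    "CalibrationResult",
    "fullsize_default",
    "nucleus_2014",
    "init_colony",
    "step_day",
    "run_scenario",
    "brood_survival_metric",
    "grid_sweep",
    "calibrate_modifier",
    "default_grid",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class StageDurations:
    """Days spent in each developmental stage (standard worker schedule)."""

    egg: int = 3
    larva: int = 6
    pupa: int = 12
    inhive: int = 21

    @property
    def brood(self) -> int:
        return self.egg + self.larva + self.pupa


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulation scenario.

    Field names for the brood-food mechanism and hive limits follow the
    conventional colony-model parameter names (``ProteinFactorNurses``,
    ``ProteinNursesModifier_Exposed``, ``MAX_HONEY_STORE_kg``,
    ``MAX_BROODCELLS``, ``HoneyIdeal``, ``PollenIdeal``).
    """

    # calendar
    start_day: int = 1  # day-of-year the run starts
    years: int = 1
    end_day: int | None = None  # day-of-year to stop in the final year
    # initial population
    initial_foragers: float = 10_000.0
    initial_workers: float = 0.0
    initial_pupae: float = 0.0
    initial_young_brood: float = 0.0  # eggs+larvae, spread uniformly in age
    # development
    stage_durations: StageDurations = field(default_factory=StageDurations)
    # baseline daily mortality per stage
    mortality_egg: float = 0.03
    mortality_larva: float = 0.01
    mortality_pupa: float = 0.001
    mortality_inhive: float = 0.004
    mortality_forager: float = 0.06  # flight risk during the forage season
    mortality_forager_winter: float = 0.004  # idle winter bees live for months
    # seasonal egg laying (Gaussian-peaked daily rate); the peak sits in
    # late May so the adult population peaks before the swarming deadline
    peak_laying_rate: float = 1600.0
    peak_laying_day: int = 140
    laying_width: float = 60.0
    # brood care capacity: brood cells one nurse can tend; foragers help
    # at reduced weight (they feed brood only opportunistically).  Near 1
    # the nurse workforce mildly limits peak-season laying, which is how a
    # spring brood deficit propagates into autumn colony size.
    brood_per_nurse: float = 1.0
    forager_nurse_weight: float = 0.25
    # protein-mediated exposure
    ProteinFactorNurses: float = 1.0
    ProteinNursesModifier_Exposed: float = 1.0
    exposure_window: tuple = (0, 0)  # day-of-year span, inclusive; (0, 0) = never
    # hive limits and honey economy
    MAX_BROODCELLS: float = math.inf
    MAX_HONEY_STORE_kg: float = 50.0
    HoneyIdeal: bool = False
    PollenIdeal: bool = False
    initial_honey_kg: float = 25.0
    honey_income_per_forager_kg: float = 4e-4
    foraging_day_probability: float = 0.7
    forage_season: tuple = (60, 280)
    consumption_adult_kg: float = 8e-6
    consumption_larva_kg: float = 2e-5
    # swarming
    swarming_allowed: bool = True
    swarm_threshold: float = 17_000.0
    swarm_deadline: int = 199  # July 18
    swarm_fraction: float = 0.6
    # adults-only population against the threshold: counting brood would
    # trigger "swarming" in early spring off the overwintered bees alone
    swarm_count_brood: bool = False
    queen_replacement_days: int = 25  # laying pause while the new queen mates
    swarm_rearm_days: int = 14
    # colony death
    death_floor: float = 4_000.0  # adults at year end
    # brood-survival metric (day-of-year span when cohorts must reach 19 d)
    metric_window: tuple | None = None
    # stepping
    stochastic: bool = True
    replicates: int = 30
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.ProteinNursesModifier_Exposed <= 1.0:
            raise ValueError("ProteinNursesModifier_Exposed must lie in [0, 1]")
        if not 0.0 < self.swarm_fraction < 1.0:
            raise ValueError("swarm_fraction must lie in (0, 1)")
        for name in (
            "peak_laying_rate",
            "honey_income_per_forager_kg",
            "consumption_adult_kg",
            "consumption_larva_kg",
            "ProteinFactorNurses",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.exposure_window
        if (lo, hi) != (0, 0) and not (1 <= lo <= hi <= DAYS_PER_YEAR):
            raise ValueError("exposure_window must lie within the year")
        if min(
            self.initial_foragers,
            self.initial_workers,
            self.initial_pupae,
            self.initial_young_brood,
        ) < 0:
            raise ValueError("initial populations must be non-negative")


def fullsize_default(**overrides) -> SimConfig:
    """Standard-sized colony: 10,000 foragers on January 1, spring
    exposure window (rapeseed bloom, days 95-130)."""
    cfg = SimConfig(exposure_window=(95, 130))
    return replace(cfg, **overrides) if overrides else cfg


def nucleus_2014(**overrides) -> SimConfig:
    """Mating-nucleus mimic: 100 pupae and 650 workers on day 209
    (July 28), 250 brood cells, 0.77 kg honey store refilled daily
    (HoneyIdeal), exposure days 211-253, brood survival scored on cohorts
    reaching 19 d between September 1 and 10 (days 244-253)."""
    cfg = SimConfig(
        start_day=209,
        end_day=253,
        years=1,
        initial_foragers=0.0,
        initial_workers=650.0,
        initial_pupae=100.0,
        # an established nest starts at its 250-cell cap: the 150 cells not
        # pinned to pupae hold ongoing laying, spread uniformly in age
        initial_young_brood=150.0,
        MAX_BROODCELLS=250.0,
        MAX_HONEY_STORE_kg=0.77,
        HoneyIdeal=True,
        PollenIdeal=False,
        initial_honey_kg=0.77,
        exposure_window=(211, 253),
        metric_window=(244, 253),
        swarming_allowed=False,
        death_floor=0.0,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ColonyState:
    """Mutable per-day colony state (cohort arrays indexed by age)."""

    day: int  # absolute day index (start_day = first simulated day)
    year: int
    brood: np.ndarray  # age-since-laying 0 .. brood_duration-1
    inhive: np.ndarray  # age-as-adult 0 .. inhive_duration-1
    foragers: float
    honey: float
    alive: bool = True
    death_day: int | None = None
    swarm_days: list = field(default_factory=list)
    lay_pause_until: int = 0
    swarm_armed: bool = True
    ledger: dict = field(default_factory=dict)  # laying day -> cohort record

    @property
    def doy(self) -> int:
        return (self.day - 1) % DAYS_PER_YEAR + 1

    def adults(self) -> float:
        return float(self.inhive.sum() + self.foragers)

    def population(self, include_brood: bool = True) -> float:
        return self.adults() + (float(self.brood.sum()) if include_brood else 0.0)


def init_colony(config: SimConfig) -> ColonyState:
    """Initial colony state for a configuration.

    Initial pupae are spread uniformly across pupal ages and initial
    workers across in-hive ages, so promotions begin smoothly rather than
    as a single synchronized cohort.
    """
    dur = config.stage_durations
    brood = np.zeros(dur.brood, dtype=float)
    if config.initial_pupae:
        pupal_ages = np.arange(dur.egg + dur.larva, dur.brood)
        brood[pupal_ages] = config.initial_pupae / len(pupal_ages)
    if config.initial_young_brood:
        young_ages = np.arange(0, dur.egg + dur.larva)
        brood[young_ages] = config.initial_young_brood / len(young_ages)
    inhive = np.zeros(dur.inhive, dtype=float)
    if config.initial_workers:
        inhive[:] = config.initial_workers / dur.inhive
    if config.stochastic:
        brood = np.floor(brood).astype(float)
        inhive = np.round(inhive).astype(float)
    state = ColonyState(
        day=config.start_day,
        year=1,
        brood=brood,
        inhive=inhive,
        foragers=float(config.initial_foragers),
        honey=min(config.initial_honey_kg, config.MAX_HONEY_STORE_kg),
    )
    if state.population() <= 0:
        state.alive = False
        state.death_day = state.day
    return state


def _in_window(doy: int, window: tuple) -> bool:
    lo, hi = window
    return lo <= doy <= hi and (lo, hi) != (0, 0)


def seasonal_laying_rate(doy: int, config: SimConfig) -> float:
    """Gaussian-peaked seasonal egg-laying rate (eggs/day)."""
    d = doy - config.peak_laying_day
    return config.peak_laying_rate * math.exp(-(d * d) / (2.0 * config.laying_width**2))


def protein_factor(doy: int, config: SimConfig) -> float:
    """Protein content of larval food on a given day of year."""
    p = config.ProteinFactorNurses
    if _in_window(doy, config.exposure_window):
        p *= config.ProteinNursesModifier_Exposed
    return p


def _binom(rng: np.random.Generator, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial survivors via inverse-CDF sampling on a lockstep uniform
    stream.

    Every call consumes exactly ``len(n)`` uniforms regardless of the
    outcome, so two runs sharing a seed stay on identical random streams
    even when their parameters differ (common random numbers); and the
    inverse CDF is monotone in ``p``, so for a fixed stream more favorable
    survival never yields fewer survivors.  Both properties make grid
    sweeps over the exposure modifier smooth in the modifier.
    """
    n = np.asarray(np.round(n), dtype=np.int64)
    u = rng.random(n.shape)
    return np.asarray(_stats.binom.ppf(u, n, np.clip(p, 0.0, 1.0)), dtype=float)


def _poisson(rng: np.random.Generator, lam: float) -> float:
    """Poisson draw via inverse CDF on one uniform (stream lockstep)."""
    if lam <= 0:
        rng.random()  # keep stream consumption fixed
        return 0.0
    return float(_stats.poisson.ppf(rng.random(), lam))


def step_day(state: ColonyState, config: SimConfig, rng: np.random.Generator) -> dict:
    """Advance the colony by one day, in place.

    Order of events: stage-specific survival, aging and promotion, cohort
    bookkeeping (sizes at 3 d and 19 d of age), egg laying, honey income
    and consumption.  Returns an audit dict of the day's fluxes (laid,
    emerged, graduated, died) so conservation can be checked externally.
    """
    if not state.alive:
        return {"laid": 0.0, "emerged": 0.0, "graduated": 0.0, "died": 0.0}
    dur = config.stage_durations
    t = state.day
    doy = state.doy
    before = state.population()

    # --- survival -------------------------------------------------------
    p = protein_factor(doy, config)
    surv = np.empty(dur.brood, dtype=float)
    surv[: dur.egg] = 1.0 - config.mortality_egg
    larva_slice = slice(dur.egg, dur.egg + dur.larva)
    surv[larva_slice] = (1.0 - config.mortality_larva) * p ** (1.0 / dur.larva)
    surv[dur.egg + dur.larva :] = 1.0 - config.mortality_pupa
    in_season = config.forage_season[0] <= doy <= config.forage_season[1]
    m_forager = config.mortality_forager if in_season else config.mortality_forager_winter
    if config.stochastic:
        brood = _binom(rng, state.brood, surv)
        inhive = _binom(
            rng, state.inhive, np.full(dur.inhive, 1.0 - config.mortality_inhive)
        )
        foragers = float(
            _binom(rng, np.array([state.foragers]), np.array([1.0 - m_forager]))[0]
        )
    else:
        brood = state.brood * surv
        inhive = state.inhive * (1.0 - config.mortality_inhive)
        foragers = state.foragers * (1.0 - m_forager)

    # --- aging and promotion -------------------------------------------
    emerged = float(brood[-1])
    brood[1:] = brood[:-1]
    brood[0] = 0.0
    graduated = float(inhive[-1])
    inhive[1:] = inhive[:-1]
    inhive[0] = emerged
    foragers += graduated

    # --- cohort ledger: ages are exact post-aging (cohort laid on day d
    # has age a on day d + a, recorded just before day d + a ends)
    age3, age19 = 3, 19
    for age in (age3, age19):
        laid_on = t - age
        rec = state.ledger.get(laid_on)
        if rec is not None:
            key = "n3" if age == age3 else "n19"
            rec[key] = float(brood[age])
            if age == age19:
                rec["day19"] = t
                rec["doy19"] = (t - 1) % DAYS_PER_YEAR + 1

    # --- egg laying -----------------------------------------------------
    laid = 0.0
    if t < state.lay_pause_until:
        if config.stochastic:
            rng.random()  # keep the uniform stream in lockstep across runs
    else:
        rate = seasonal_laying_rate(doy, config)
        occupancy = float(brood.sum())
        nurses = float(inhive.sum()) + config.forager_nurse_weight * foragers
        capacity = min(
            config.MAX_BROODCELLS - occupancy,
            config.brood_per_nurse * nurses - occupancy,
        )
        target = max(0.0, min(rate, capacity))
        if config.stochastic:
            laid = float(min(_poisson(rng, target), max(0.0, capacity)))
        else:
            laid = target
    brood[0] = laid
    state.ledger[t] = {"n0": laid, "n3": None, "n19": None, "day19": None}

    # --- honey ----------------------------------------------------------
    larvae_now = float(brood[larva_slice].sum())
    adults_now = float(inhive.sum()) + foragers
    consumption = (
        adults_now * config.consumption_adult_kg + larvae_now * config.consumption_larva_kg
    )
    income = 0.0
    if config.forage_season[0] <= doy <= config.forage_season[1]:
        if config.stochastic:
            if rng.random() < config.foraging_day_probability:
                income = foragers * config.honey_income_per_forager_kg
        else:
            income = (
                foragers
                * config.honey_income_per_forager_kg
                * config.foraging_day_probability
            )
    honey = min(state.honey + income - consumption, config.MAX_HONEY_STORE_kg)
    if config.HoneyIdeal:
        honey = config.MAX_HONEY_STORE_kg  # store is topped up daily (fed colony)
    if honey < 0.0:
        state.alive = False
        state.death_day = t
        honey = 0.0

    # --- commit ---------------------------------------------------------
    state.brood = brood
    state.inhive = inhive
    state.foragers = foragers
    state.honey = honey
    after = state.population()
    died = before + laid - after  # no other source or sink exists
    state.day = t + 1
    state.year = (state.day - 1) // DAYS_PER_YEAR + 1
    return {"laid": laid, "emerged": emerged, "graduated": graduated, "died": died}


@dataclass(frozen=True)
class SimResult:
    """Trajectory and bookkeeping of one scenario run."""

    trajectory: pd.DataFrame
    swarm_days: tuple
    death_day: int | None
    ledger: dict
    config: SimConfig

    @property
    def survived(self) -> bool:
        return self.death_day is None

    def year_end_adults(self, year: int = 1) -> float:
        """Adult population on the last simulated day of a year (0 if the
        colony died earlier)."""
        traj = self.trajectory[self.trajectory["year"] == year]
        if traj.empty:
            return 0.0
        last = traj.iloc[-1]
        if self.death_day is not None and self.death_day <= int(last["day"]):
            return 0.0
        return float(last["inhive"] + last["foragers"])


def _maybe_swarm(state: ColonyState, config: SimConfig, doy: int) -> bool:
    """Apply the swarming rule after a day step; returns True on a swarm.

    ``doy`` is the day-of-year just simulated (the state's day counter has
    already advanced to the next day).
    """
    if not config.swarming_allowed or not state.alive:
        return False
    pop = state.population(include_brood=config.swarm_count_brood)
    if not state.swarm_armed:
        # hysteresis: re-arm once the colony has shrunk back below the
        # threshold and a refractory period has passed
        if (
            pop < config.swarm_threshold
            and state.swarm_days
            and state.day - state.swarm_days[-1] >= config.swarm_rearm_days
        ):
            state.swarm_armed = True
        return False
    if doy >= config.swarm_deadline or pop <= config.swarm_threshold:
        return False
    keep = 1.0 - config.swarm_fraction
    if config.stochastic:
        state.inhive = np.floor(state.inhive * keep)
        state.foragers = float(math.floor(state.foragers * keep))
    else:
        state.inhive = state.inhive * keep
        state.foragers *= keep
    state.swarm_days.append(state.day)
    state.swarm_armed = False
    state.lay_pause_until = state.day + config.queen_replacement_days
    return True


def run_scenario(
    config: SimConfig, seed: int | None = None, collect_trajectory: bool = True
) -> SimResult:
    """Run one (possibly multi-year) scenario and return its result.

    Swarming (when allowed) removes ``swarm_fraction`` of the adults on
    the day the population first exceeds the threshold before the
    deadline; the simulation follows the remaining colony.  The colony is
    marked dead when honey runs out (unless the store is topped up) or
    when the year-end adult population is below the death floor.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = init_colony(config)
    last_abs_day = (config.years - 1) * DAYS_PER_YEAR + (config.end_day or DAYS_PER_YEAR)
    rows = []
    dur = config.stage_durations
    larva_slice = slice(dur.egg, dur.egg + dur.larva)
    while state.day <= last_abs_day and state.alive:
        doy_before = state.doy
        step_day(state, config, rng)
        swarmed = _maybe_swarm(state, config, doy_before)
        if doy_before == 1:
            state.swarm_armed = True  # new season
        if doy_before == DAYS_PER_YEAR and state.alive:
            if state.adults() < config.death_floor:
                state.alive = False
                state.death_day = state.day - 1
        if collect_trajectory:
            rows.append(
                {
                    "day": state.day - 1,
                    "doy": doy_before,
                    "year": (state.day - 2) // DAYS_PER_YEAR + 1,
                    "eggs": float(state.brood[: dur.egg].sum()),
                    "larvae": float(state.brood[larva_slice].sum()),
                    "pupae": float(state.brood[dur.egg + dur.larva :].sum()),
                    "inhive": float(state.inhive.sum()),
                    "foragers": state.foragers,
                    "honey_kg": state.honey,
                    "swarm_event": int(swarmed),
                }
            )
    traj = pd.DataFrame(
        rows,
        columns=[
            "day",
            "doy",
            "year",
            "eggs",
            "larvae",
            "pupae",
            "inhive",
            "foragers",
            "honey_kg",
            "swarm_event",
        ],
    )
    return SimResult(
        trajectory=traj,
        swarm_days=tuple(state.swarm_days),
        death_day=state.death_day,
        ledger=state.ledger,
        config=config,
    )


def brood_survival_metric(
    result: SimResult, n_cohorts: int = 10, window: tuple | None = None
) -> float:
    """Mean brood survival over the last eligible laying-day cohorts.

    Survival of a cohort is its size at 19 days of age divided by its size
    at 3 days (just after hatching); cohorts with zero size at 3 days are
    skipped.  When a metric window is set (day-of-year span), only cohorts
    reaching 19 days inside the window are eligible; the mean is taken
    over the last ``n_cohorts`` of them.  Returns NaN when no cohort is
    eligible.
    """
    window = result.config.metric_window if window is None else window
    ratios = []
    for laid_on in sorted(result.ledger):
        rec = result.ledger[laid_on]
        n3, n19 = rec.get("n3"), rec.get("n19")
        if n3 is None or n19 is None or n3 <= 0:
            continue
        if window is not None and not (window[0] <= rec["doy19"] <= window[1]):
            continue
        ratios.append(n19 / n3)
    if not ratios:
        return float("nan")
    return float(np.mean(ratios[-n_cohorts:]))


def default_grid(include_zero: bool = False) -> np.ndarray:
    """The calibration grid: modifiers 0.6 to 1.0 in steps of 0.01,
    optionally extended with 0 (total protein deprivation)."""
    grid = np.round(np.arange(0.60, 1.0 + 1e-9, 0.01), 2)
    if include_zero:
        grid = np.concatenate([[0.0], grid])
    return grid


def grid_sweep(
    config: SimConfig,
    grid: Sequence[float],
    replicates: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean and SD of the brood-survival metric at each grid modifier.

    The same replicate seeds are reused at every grid value (common random
    numbers), so differences along the grid reflect the modifier rather
    than Monte-Carlo noise.
    """
    base_seed = config.seed if seed is None else seed
    rep_seeds = np.random.SeedSequence(base_seed).generate_state(replicates) % (2**31)
    rows = []
    for g in grid:
        cfg = replace(config, ProteinNursesModifier_Exposed=float(g))
        metrics = []
        for s in rep_seeds:
            res = run_scenario(cfg, seed=int(s), collect_trajectory=False)
            m = brood_survival_metric(res)
            if not math.isnan(m):
                metrics.append(m)
        metrics = np.asarray(metrics, dtype=float)
        rows.append(
            {
                "modifier": float(g),
                "mean": float(metrics.mean()) if metrics.size else float("nan"),
                "sd": float(metrics.std(ddof=1)) if metrics.size > 1 else 0.0,
                "n": int(metrics.size),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the grid-search calibration of the exposure modifier."""

    target_survival: float
    best_modifier: float
    modeled_survival_mean: float
    modeled_survival_sd: float
    grid: pd.DataFrame


def calibrate_modifier(
    target_survival: float,
    config: SimConfig | None = None,
    grid: Sequence[float] | None = None,
    include_zero: bool = False,
    replicates: int = 30,
    seed: int | None = None,
) -> CalibrationResult:
    """Grid-search the exposure modifier against a target brood survival.

    Runs ``replicates`` seeded nucleus simulations per grid value and
    returns the modifier whose mean brood-survival metric is closest to
    the target (ties resolved toward the larger modifier).
    """
    if not 0.0 <= target_survival <= 1.0:
        raise ValueError("target survival must lie in [0, 1]")
    config = nucleus_2014() if config is None else config
    grid = default_grid(include_zero) if grid is None else np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("calibration grid is empty")
    sweep = grid_sweep(config, grid, replicates=replicates, seed=seed)
    dist = (sweep["mean"] - target_survival).abs()
    # ties -> larger modifier: scan in ascending modifier order with >=
    best_idx = 0
    order = sweep.sort_values("modifier").index
    for idx in order:
        if dist[idx] <= dist[best_idx]:
            best_idx = idx
    best = sweep.loc[best_idx]
    return CalibrationResult(
        target_survival=float(target_survival),
        best_modifier=float(best["modifier"]),
        modeled_survival_mean=float(best["mean"]),
        modeled_survival_sd=float(best["sd"]),
        grid=sweep,
    )
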