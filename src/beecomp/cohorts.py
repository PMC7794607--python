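"""Cohort survival analysis of individually tracked brood cells.

A *fate table* holds one row per tracked brood cell per weekly inspection:
which hive it is in, its treatment group, the week it was first marked as a
young larva (day 4-5 after egg laying), and the stage observed each week.
A cell *survives* when it is capped within the expected time and the cell
is empty (the adult has emerged) within the expected window afterwards; it
*dies* when it is emptied or found dead before capping, or a capped cell
never opens in time; it is *censored* when observation ends first.

From the per-cell fates the module derives weekly survivor counts ``S_t``
(the input of the weekly mortality estimator in :mod:`beecomp.demography`)
and phase survival summaries (mean and SD of per-hive survival fractions),
matching the way field studies report brood survival per phase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "FATE_COLUMNS",
    "FateRecord",
    "CellFate",
    "SurvivalSummary",
    "read_fate_table",
    "write_fate_table",
    "validate_fate_table",
    "records_to_frame",
    "cell_outcome",
    "weekly_survivors",
    "phase_survival_summary",
    "resolve_phase",
]

logger = logging.getLogger(__name__)

#: Recognised observation stages, lower-case.
STAGES = ("egg", "larva", "capped", "empty", "dead", "missing")

FATE_COLUMNS = ["hive_id", "treatment", "cohort_week", "cell_id", "week", "stage"]

#: Experiment-week spans of the two tracking phases.
PHASES = {"A": (1, 4), "B": (4, 7)}

#: Default development windows, in weeks after marking as a day-4-5 larva:
#: capping is expected by +2 weeks (workers cap around day 9 post-laying)
#: and emergence (empty cell) by +3 weeks (around day 21 post-laying).
EXPECTED_CAPPED_WEEKS = 2
EXPECTED_EMPTY_WEEKS = 3


@dataclass(frozen=True)
class FateRecord:
    hive_id: str
    treatment: str
    cohort_week: int
    cell_id: str
    week: int
    stage: str

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.week < self.cohort_week:
            raise ValueError("observation week precedes cohort week")


def records_to_frame(records: Iterable[FateRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=FATE_COLUMNS)


def validate_fate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a fate table and return it with normalised dtypes."""
    missing = [c for c in FATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fate table missing columns {missing}")
    df = df[FATE_COLUMNS].copy()
    if df.empty:
        logger.warning("fate table is empty")
        return df
    df["hive_id"] = df["hive_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    df["cell_id"] = df["cell_id"].astype(str)
    df["cohort_week"] = df["cohort_week"].astype(int)
    df["week"] = df["week"].astype(int)
    df["stage"] = df["stage"].astype(str).str.strip().str.lower()
    bad = ~df["stage"].isin(STAGES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown stage {df['stage'].iloc[row]!r} at data row {row + 1}"
        )
    if (df["week"] < df["cohort_week"]).any():
        raise ValueError("observation week precedes cohort week in fate table")
    dup = df.duplicated(subset=["cell_id", "week"])
    if dup.any():
        pair = df.loc[dup, ["cell_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicate observation for cell {pair['cell_id']!r} in week {pair['week']}"
        )
    return df


def read_fate_table(path) -> pd.DataFrame:
    """Read and validate a fate-table CSV (UTF-8, documented dialect)."""
    df = pd.read_csv(path, dtype={"hive_id": str, "treatment": str, "cell_id": str})
    return validate_fate_table(df)


def write_fate_table(df: pd.DataFrame, path) -> None:
    validate_fate_table(df).to_csv(path, index=False)


@dataclass(frozen=True)
class CellFate:
    """Resolved fate of one tracked cell."""

    outcome: str  # "survived" | "died" | "censored"
    failure_week: int | None = None
    capped_week: int | None = None
    emptied_week: int | None = None


def cell_outcome(
    records,
    expected_capped_weeks: int = EXPECTED_CAPPED_WEEKS,
    expected_empty_weeks: int = EXPECTED_EMPTY_WEEKS,
) -> CellFate:
    """Classify one cell's observation series as survived, died or censored.

    ``records`` is the cell's rows (a DataFrame slice or FateRecord
    sequence) sorted by week; the first observation is the marking week.
    """
    if isinstance(records, pd.DataFrame):
        rows = list(zip(records["week"].astype(int), records["stage"]))
    else:
        rows = [(int(r.week), r.stage) for r in records]
    rows.sort(key=lambda t: t[0])
    if not rows:
        return CellFate("censored")
    mark_week = rows[0][0]
    capped_deadline = mark_week + expected_capped_weeks
    empty_deadline = mark_week + expected_empty_weeks
    capped_week = None
    for week, stage in rows:
        if stage == "missing":
            continue
        if capped_week is None:
            if stage in ("larva", "egg"):
                if week > capped_deadline:  # still open past the capping window
                    return CellFate("died", failure_week=week)
            elif stage == "capped":
                if week > capped_deadline:
                    return CellFate("died", failure_week=week)
                capped_week = week
            else:  # empty or dead before capping: brood removed / died
                return CellFate("died", failure_week=week)
        else:
            if stage == "empty":
                if week <= empty_deadline:
                    return CellFate(
                        "survived", capped_week=capped_week, emptied_week=week
                    )
                return CellFate("died", failure_week=week, capped_week=capped_week)
            if stage == "dead":
                return CellFate("died", failure_week=week, capped_week=capped_week)
            if week > empty_deadline:  # capped cell never opened in time
                return CellFate("died", failure_week=week, capped_week=capped_week)
    return CellFate("censored", capped_week=capped_week)


def resolve_phase(phase) -> tuple:
    """Resolve a phase spec ("A", "B" or "start:end"/(start, end)) to weeks."""
    if isinstance(phase, str):
        key = phase.strip().upper()
        if key in PHASES:
            return PHASES[key]
        if ":" in phase:
            start, end = phase.split(":")
            return int(start), int(end)
        raise ValueError(f"unknown phase {phase!r}")
    start, end = phase
    return int(start), int(end)


def _phase_cells(
    fate: pd.DataFrame,
    group: str,
    phase,
    expected_capped_weeks: int,
    expected_empty_weeks: int,
) -> pd.DataFrame:
    """Per-cell fates for the cohort marked at the phase start week.

    Returns one row per cell with hive, outcome and failure week.
    """
    start, end = resolve_phase(phase)
    sub = fate[(fate["treatment"].astype(str) == str(group))]
    if sub.empty:
        raise KeyError(f"group {group!r} not present in fate table")
    sub = sub[sub["cohort_week"] == start]
    out = []
    for (hive, cell), grp in sub.groupby(["hive_id", "cell_id"], sort=True):
        fateobj = cell_outcome(
            grp.sort_values("week"), expected_capped_weeks, expected_empty_weeks
        )
        out.append(
            {
                "hive_id": hive,
                "cell_id": cell,
                "outcome": fateobj.outcome,
                "failure_week": fateobj.failure_week,
            }
        )
    return pd.DataFrame(out, columns=["hive_id", "cell_id", "outcome", "failure_week"])


def weekly_survivors(
    fate: pd.DataFrame,
    group: str,
    phase,
    censored_policy: str = "exclude",
    expected_capped_weeks: int = EXPECTED_CAPPED_WEEKS,
    expected_empty_weeks: int = EXPECTED_EMPTY_WEEKS,
) -> pd.DataFrame:
    """Weekly survivor counts ``S_t`` per hive for one group and phase.

    ``S_t`` counts the phase-start cohort cells still on a surviving
    trajectory at week ``t`` (a cell that fails at week ``w`` counts in
    weeks ``< w``).  Censored cells are excluded by default or treated as
    dying at the week after their last observation (``censored_policy=
    "died"``).  The result is a hive x week DataFrame, monotone
    non-increasing along each row.
    """
    if censored_policy not in ("exclude", "died"):
        raise ValueError("censored_policy must be 'exclude' or 'died'")
    start, end = resolve_phase(phase)
    cells = _phase_cells(fate, group, phase, expected_capped_weeks, expected_empty_weeks)
    if censored_policy == "exclude":
        cells = cells[cells["outcome"] != "censored"]
    else:
        cens = cells["outcome"] == "censored"
        last_obs = (
            fate[fate["treatment"].astype(str) == str(group)]
            .groupby("cell_id")["week"]
            .max()
        )
        cells = cells.copy()
        cells.loc[cens, "failure_week"] = (
            cells.loc[cens, "cell_id"].map(last_obs) + 1
        )
        cells.loc[cens, "outcome"] = "died"
    weeks = list(range(start, end + 1))
    hives = sorted(cells["hive_id"].unique())
    data = np.zeros((len(hives), len(weeks)), dtype=int)
    for i, hive in enumerate(hives):
        sub = cells[cells["hive_id"] == hive]
        fw = sub["failure_week"].to_numpy(dtype=float)
        fw = np.where(np.isnan(fw), np.inf, fw)
        for j, t in enumerate(weeks):
            data[i, j] = int((fw > t).sum())
    return pd.DataFrame(data, index=pd.Index(hives, name="hive_id"), columns=weeks)


@dataclass(frozen=True)
class SurvivalSummary:
    """Phase survival of a treatment group, summarised across hives."""

    group: str
    phase: tuple
    per_hive_survival: dict
    mean: float
    sd: float
    n_larvae: int
    n_hives: int
    pooled: float = float("nan")  # cell-pooled alternative to the hive mean
    meta: dict = field(default_factory=dict, compare=False)


def phase_survival_summary(
    fate: pd.DataFrame,
    group: str,
    phase,
    censored_policy: str = "exclude",
    expected_capped_weeks: int = EXPECTED_CAPPED_WEEKS,
    expected_empty_weeks: int = EXPECTED_EMPTY_WEEKS,
) -> SurvivalSummary:
    """Phase survival per hive, with the across-hive mean and SD.

    Survival per hive is the fraction of the phase-start cohort still on a
    surviving trajectory at the phase end week.  Dispersion is the sample
    SD across hive-level fractions (the reporting convention of brood
    studies with a handful of hives), not a binomial SE across cells; the
    cell-pooled fraction is also provided.  Hives with zero initial cells
    are excluded with a warning.
    """
    start, end = resolve_phase(phase)
    S = weekly_survivors(
        fate, group, phase, censored_policy, expected_capped_weeks, expected_empty_weeks
    )
    initial = S[start]
    empty_hives = initial[initial == 0].index.tolist()
    if empty_hives:
        warnings.warn(
            f"excluding hives with no initial cells in phase {phase!r}: {empty_hives}",
            stacklevel=2,
        )
        S = S.drop(index=empty_hives)
        initial = S[start]
    per_hive = (S[end] / initial).to_dict()
    fractions = np.array(list(per_hive.values()), dtype=float)
    mean = float(fractions.mean()) if len(fractions) else float("nan")
    sd = float(fractions.std(ddof=1)) if len(fractions) > 1 else 0.0
    pooled = float(S[end].sum() / S[start].sum()) if S[start].sum() else float("nan")
    return SurvivalSummary(
        group=str(group),
        phase=(start, end),
        per_hive_survival=per_hive,
        mean=mean,
        sd=sd,
        n_larvae=int(initial.sum()),
        n_hives=int(len(per_hive)),
        pooled=pooled,
        meta={"censored_policy": censored_policy},
    )
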