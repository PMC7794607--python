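"""Whole-colony brood census analysis: stage ratios and seasonal trends.

A census table records, per hive and week, the number of cells holding
eggs, larvae and capped brood ("capped" and "pupae" are used synonymously
in brood studies; the data model keeps a single ``capped`` column).

The stage-ratio analysis divides one stage's count by another stage's
count one week earlier (the eggs of week ``t-1`` are the larvae of week
``t``), yielding per-hive ratio series whose medians index how much brood
a colony initiates per cell of the preceding stage.  Weeks with a zero
denominator (late-season brood collapse) yield missing ratios, never
infinities, and documented outlier observations can be excluded from the
ratio computation without touching the raw counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CENSUS_COLUMNS",
    "CensusRecord",
    "RatioSeries",
    "TrendFit",
    "read_census",
    "write_census",
    "validate_census",
    "apply_outlier_exclusions",
    "stage_ratio",
    "quadratic_trend",
]

logger = logging.getLogger(__name__)

CENSUS_COLUMNS = ["hive_id", "treatment", "week", "eggs", "larvae", "capped"]
STAGE_COLUMNS = ("eggs", "larvae", "capped")


@dataclass(frozen=True)
class CensusRecord:
    hive_id: str
    treatment: str
    week: int
    eggs: int
    larvae: int
    capped: int

    def __post_init__(self):
        if min(self.eggs, self.larvae, self.capped) < 0:
            raise ValueError("census counts must be non-negative")


def validate_census(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census table missing columns {missing}")
    df = df[CENSUS_COLUMNS].copy()
    df["hive_id"] = df["hive_id"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    df["week"] = df["week"].astype(int)
    for col in STAGE_COLUMNS:
        df[col] = df[col].astype(int)
        neg = df[col] < 0
        if neg.any():
            row = int(np.flatnonzero(neg.to_numpy())[0])
            raise ValueError(f"negative {col} count at data row {row + 1}")
    dup = df.duplicated(subset=["hive_id", "week"])
    if dup.any():
        pair = df.loc[dup, ["hive_id", "week"]].iloc[0]
        raise ValueError(
            f"duplicate census record for hive {pair['hive_id']!r} week {pair['week']}"
        )
    # hives missing a week are accepted; log the gaps for the record
    for hive, grp in df.groupby("hive_id"):
        weeks = sorted(grp["week"])
        gaps = sorted(set(range(weeks[0], weeks[-1] + 1)) - set(weeks))
        if gaps:
            logger.info("hive %s has census gaps in weeks %s", hive, gaps)
    return df


def read_census(path) -> pd.DataFrame:
    """Read and validate a census CSV (UTF-8, documented dialect)."""
    df = pd.read_csv(path, dtype={"hive_id": str, "treatment": str})
    return validate_census(df)


def write_census(df: pd.DataFrame, path) -> None:
    validate_census(df).to_csv(path, index=False)


def apply_outlier_exclusions(
    census: pd.DataFrame, exclusions: Iterable[tuple]
) -> pd.DataFrame:
    """Drop excluded ``(hive_id, week)`` observations from a census copy.

    Intended for ratio computations only - the caller keeps the unfiltered
    table for raw-count reporting.  Exclusions that match no record produce
    a warning, not an error.
    """
    out = census.copy()
    for hive, week in exclusions:
        mask = (out["hive_id"].astype(str) == str(hive)) & (out["week"] == int(week))
        if not mask.any():
            warnings.warn(
                f"exclusion ({hive!r}, week {week}) matches no census record",
                stacklevel=2,
            )
            continue
        out = out[~mask]
    return out


@dataclass(frozen=True)
class RatioSeries:
    """Per-hive stage-ratio series with group-level summaries."""

    group: str
    numerator_stage: str
    denominator_stage: str
    shift_weeks: int
    values: pd.DataFrame  # hive x week, NaN where undefined/excluded
    group_median: dict  # week -> median over hives
    group_mean: dict  # week -> mean over hives
    overall_median: float
    overall_mean: float
    exclusions: tuple = ()
    meta: dict = field(default_factory=dict, compare=False)


def stage_ratio(
    census: pd.DataFrame,
    numerator: str,
    denominator: str,
    shift_weeks: int = 1,
    exclusions: Sequence[tuple] = (),
    group: str | None = None,
) -> RatioSeries:
    """Per-hive ratio ``numerator(t) / denominator(t - shift)``.

    A one-week shift aligns each stage with the cohort it developed from
    (this week's larvae were last week's eggs).  Weeks where the shifted
    denominator is zero or unobserved yield NaN.  Group medians are taken
    over hives per week, then the overall median over the weekly medians;
    means are reported alongside because published summaries of these
    ratios mix the two statistics.
    """
    if numerator == denominator and shift_weeks != 0:
        pass  # legitimate (self-ratio with lag); only identical stage+shift=0 is trivial
    if numerator not in STAGE_COLUMNS or denominator not in STAGE_COLUMNS:
        raise ValueError(f"stages must be one of {STAGE_COLUMNS}")
    if shift_weeks < 0:
        raise ValueError("shift_weeks must be non-negative")
    sub = census if group is None else census[census["treatment"].astype(str) == str(group)]
    if sub.empty:
        raise KeyError(f"group {group!r} not present in census")
    sub = apply_outlier_exclusions(sub, exclusions)
    num = sub.pivot(index="hive_id", columns="week", values=numerator)
    den = sub.pivot(index="hive_id", columns="week", values=denominator)
    weeks = sorted(num.columns)
    ratios = pd.DataFrame(index=num.index, columns=weeks, dtype=float)
    for t in weeks:
        t0 = t - shift_weeks
        if t0 not in den.columns:
            continue
        d = den[t0].astype(float).where(den[t0] > 0)  # zero denominator -> NaN
        ratios[t] = num[t].astype(float) / d
    ratios = ratios.dropna(axis=1, how="all")
    med = ratios.median(axis=0, skipna=True)
    mean = ratios.mean(axis=0, skipna=True)
    return RatioSeries(
        group="all" if group is None else str(group),
        numerator_stage=numerator,
        denominator_stage=denominator,
        shift_weeks=int(shift_weeks),
        values=ratios,
        group_median={int(w): float(v) for w, v in med.items() if not np.isnan(v)},
        group_mean={int(w): float(v) for w, v in mean.items() if not np.isnan(v)},
        overall_median=float(med.median(skipna=True)),
        overall_mean=float(mean.mean(skipna=True)),
        exclusions=tuple((str(h), int(w)) for h, w in exclusions),
    )


@dataclass(frozen=True)
class TrendFit:
    """Descriptive least-squares parabola of mean counts over weeks."""

    group: str
    stage: str
    intercept: float
    slope: float
    curvature: float
    r_squared: float


def quadratic_trend(census: pd.DataFrame, group: str, stage: str) -> TrendFit:
    """OLS fit of mean weekly counts to ``a + b*week + c*week**2``.

    This is the descriptive seasonal trend (brood nests wax and wane over
    a season, so a parabola is the natural low-order summary); it carries
    no mixed-effects inference.
    """
    import statsmodels.api as sm

    if stage not in STAGE_COLUMNS:
        raise ValueError(f"stage must be one of {STAGE_COLUMNS}")
    sub = census[census["treatment"].astype(str) == str(group)]
    if sub.empty:
        raise KeyError(f"group {group!r} not present in census")
    means = sub.groupby("week")[stage].mean()
    if means.index.nunique() < 3:
        raise ValueError(
            f"quadratic trend needs >=3 distinct weeks, got {means.index.nunique()}"
        )
    t = means.index.to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([t, t**2]))
    fit = sm.OLS(means.to_numpy(dtype=float), X).fit()
    b = fit.params
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)  # undefined (non-finite) for constant counts
    return TrendFit(
        group=str(group),
        stage=stage,
        intercept=float(b[0]),
        slope=float(b[1]),
        curvature=float(b[2]),
        r_squared=r2 if np.isfinite(r2) else float("nan"),
    )
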