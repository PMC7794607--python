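"""Stage-structured demography of honeybee worker brood.

The larval population of a colony is modelled with a Lefkovitch (stage-
classified) projection matrix: seven weekly larval age classes plus a queen
class.  The queen contributes ``h`` newly hatched larvae per week (the
fecundity element of the matrix) and each larval class ``x`` survives to the
next with probability ``1 - m_x``, where ``m_x`` is the per-capita weekly
mortality of that class.  Larvae surviving week 7 pupate and leave the
larval population.

Given an observed weekly mortality schedule, the stable-population condition
``A n = n`` is solved in closed form for the weekly hatch rate ``h`` that
holds the total larval population ``L = sum_x l_x`` constant.  Comparing the
``h`` required under an elevated mortality schedule with the control value
quantifies *demographic compensation*: the extra brood-initiation effort a
colony must mount to keep its brood nest stable under stress.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_N_CLASSES",
    "MortalitySchedule",
    "LarvalStateVector",
    "ProjectionMatrix",
    "CompensationRow",
    "build_projection_matrix",
    "project",
    "stable_hatch_rate",
    "pupation_flux",
    "compensation_fold",
    "estimate_weekly_mortality",
    "expand_phase_survival",
    "compensation_table",
    "compensation_table_from_hatch_rates",
]

#: Number of weekly larval age classes before pupation.
DEFAULT_N_CLASSES = 7


class InvalidScheduleError(ValueError):
    """Raised when a mortality schedule is structurally invalid."""


@dataclass(frozen=True)
class MortalitySchedule:
    """Weekly per-capita larval mortality probabilities ``m_1 .. m_W``.

    Entries may be NaN to flag weeks where the mortality is undefined
    (e.g. a zero-count denominator in the survivor-series estimator);
    operations that need a complete schedule reject NaN entries.
    """

    m: tuple
    labels: tuple | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        m = tuple(float(v) for v in self.m)
        if len(m) == 0:
            raise InvalidScheduleError("mortality schedule must have at least one week")
        for i, v in enumerate(m, start=1):
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"mortality m_{i}={v!r} outside [0, 1]")
        if self.labels is not None and len(self.labels) != len(m):
            raise InvalidScheduleError("labels length must match schedule length")
        object.__setattr__(self, "m", m)

    def __len__(self) -> int:
        return len(self.m)

    @property
    def n_classes(self) -> int:
        return len(self.m)

    @property
    def survival(self) -> np.ndarray:
        """Weekly survival probabilities ``1 - m_x`` as an array."""
        return 1.0 - np.asarray(self.m, dtype=float)

    @property
    def undefined_weeks(self) -> tuple:
        """1-based indices of weeks whose mortality is undefined (NaN)."""
        return tuple(i for i, v in enumerate(self.m, start=1) if math.isnan(v))

    def require_complete(self) -> None:
        if self.undefined_weeks:
            raise ValueError(
                f"schedule has undefined mortalities in weeks {self.undefined_weeks}"
            )

    @classmethod
    def from_weekly_survival(cls, survival: Sequence[float], **kw) -> "MortalitySchedule":
        return cls(tuple(1.0 - float(s) for s in survival), **kw)


@dataclass(frozen=True)
class LarvalStateVector:
    """Larval age-class abundances ``l_1 .. l_W`` plus the queen count ``Q``.

    ``Q`` is 1 in all models: the queen class only exists to seed class 1
    with ``h`` hatching larvae per week.
    """

    l: tuple
    Q: float = 1.0

    def __post_init__(self):
        l = tuple(float(v) for v in self.l)
        if any(v < 0 for v in l):
            raise ValueError("larval abundances must be non-negative")
        if self.Q < 0:
            raise ValueError("queen count must be non-negative")
        object.__setattr__(self, "l", l)

    @property
    def total(self) -> float:
        """Total larval population ``L = sum_x l_x`` (queen excluded)."""
        return float(sum(self.l))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.l + (self.Q,), dtype=float)

    @classmethod
    def zeros(cls, n_classes: int = DEFAULT_N_CLASSES, Q: float = 1.0) -> "LarvalStateVector":
        return cls((0.0,) * n_classes, Q=Q)


@dataclass(frozen=True)
class ProjectionMatrix:
    """The ``(W+1) x (W+1)`` weekly projection matrix.

    Layout: top-right element is the fecundity ``h`` (queen -> class 1);
    the subdiagonal carries the survival probabilities ``1 - m_x`` for the
    transitions ``x -> x+1`` (``x = 1 .. W-1``); the bottom-right queen
    self-loop is 1.  Survivors of class ``W`` pupate and leave the larval
    population, so the exit class has no destination row (see
    :func:`pupation_flux`).
    """

    entries: np.ndarray
    h: float
    schedule: MortalitySchedule

    @property
    def n_classes(self) -> int:
        return self.entries.shape[0] - 1


def build_projection_matrix(schedule: MortalitySchedule, h: float) -> ProjectionMatrix:
    """Assemble the weekly Lefkovitch matrix for a mortality schedule.

    Parameters
    ----------
    schedule:
        Weekly per-capita mortality probabilities ``m_1 .. m_W``.
    h:
        Weekly hatch rate: eggs hatching into larval class 1 per week.
    """
    if not isinstance(schedule, MortalitySchedule):
        schedule = MortalitySchedule(tuple(schedule))
    schedule.require_complete()
    if h < 0:
        raise ValueError(f"hatch rate h={h!r} must be non-negative")
    W = schedule.n_classes
    A = np.zeros((W + 1, W + 1), dtype=float)
    A[0, W] = h
    surv = schedule.survival
    for x in range(W - 1):  # class x+1 -> x+2 ; class W survivors pupate
        A[x + 1, x] = surv[x]
    A[W, W] = 1.0
    return ProjectionMatrix(entries=A, h=float(h), schedule=schedule)


def project(state: LarvalStateVector, matrix: ProjectionMatrix) -> LarvalStateVector:
    """Advance the larval state vector one week: ``n_{t+1} = A n_t``."""
    vec = state.to_array()
    if vec.shape[0] != matrix.entries.shape[1]:
        raise ValueError(
            f"state has {vec.shape[0] - 1} larval classes but matrix expects "
            f"{matrix.n_classes}"
        )
    out = matrix.entries @ vec
    return LarvalStateVector(tuple(out[:-1]), Q=float(out[-1]))


def pupation_flux(state: LarvalStateVector, schedule: MortalitySchedule) -> float:
    """Weekly number of larvae pupating: survivors of the final class."""
    schedule.require_complete()
    return state.l[-1] * (1.0 - schedule.m[-1])


def _survivorship_denominator(schedule: MortalitySchedule) -> float:
    """``sum_{x=1..W} prod_{j<x} (1 - m_j)`` - the stable-population
    larva-weeks generated per unit hatch rate."""
    surv = schedule.survival
    cum = np.concatenate([[1.0], np.cumprod(surv[:-1])])
    return float(cum.sum())


def stable_hatch_rate(schedule: MortalitySchedule, L_target: float) -> float:
    """Weekly hatch rate ``h`` holding the larval population at ``L_target``.

    At the fixed point of the projection, class ``x`` holds
    ``h * prod_{j<x}(1 - m_j)`` larvae, so
    ``h = L_target / sum_x prod_{j<x}(1 - m_j)``.
    """
    if not isinstance(schedule, MortalitySchedule):
        schedule = MortalitySchedule(tuple(schedule))
    schedule.require_complete()
    if L_target < 0:
        raise ValueError(f"L_target={L_target!r} must be non-negative")
    return L_target / _survivorship_denominator(schedule)


def compensation_fold(h_dosed: float, h_control: float) -> float:
    """Ratio of a dosed group's required hatch rate to the control's."""
    if h_control <= 0:
        raise ValueError(f"control hatch rate must be positive, got {h_control!r}")
    return h_dosed / h_control


def estimate_weekly_mortality(
    survivors: Sequence[float], *, clamp: bool = False
) -> MortalitySchedule:
    """Per-capita weekly mortality from a cohort survivor series.

    ``m_t = 1 - S_{t+1} / S_t`` for each consecutive pair of counts.  Weeks
    with a zero-count denominator yield NaN and are flagged via
    ``MortalitySchedule.undefined_weeks``.  An increasing pair (more
    survivors than the week before) is a data error and raises, unless
    ``clamp=True``, which sets that week's mortality to 0 with a warning.
    """
    s = [float(v) for v in survivors]
    if len(s) < 2:
        raise ValueError("survivor series needs at least two weekly counts")
    if any(v < 0 for v in s):
        raise ValueError("survivor counts must be non-negative")
    m = []
    for t in range(len(s) - 1):
        if s[t] == 0:
            m.append(float("nan"))
            continue
        ratio = s[t + 1] / s[t]
        if ratio > 1.0:
            if not clamp:
                raise ValueError(
                    f"survivor series increases at week {t + 1}: "
                    f"{s[t]} -> {s[t + 1]}; pass clamp=True to floor mortality at 0"
                )
            warnings.warn(
                f"survivor series increases at week {t + 1}; clamping mortality to 0",
                stacklevel=2,
            )
            ratio = 1.0
        m.append(1.0 - ratio)
    return MortalitySchedule(tuple(m), meta={"estimator": "survivor-series"})


def expand_phase_survival(
    phase_survivals: Sequence[tuple],
    n_classes: int = DEFAULT_N_CLASSES,
    fill_mortality: float = 0.0,
) -> MortalitySchedule:
    """Expand phase-aggregate survivals into a weekly mortality schedule.

    Each phase is given as ``(n_transitions, overall_survival)`` and is
    decomposed under a geometric (equal-weekly) assumption: weekly survival
    ``s = S ** (1 / n)``.  Weeks not covered by any phase are filled with
    ``fill_mortality``.  The geometric assumption is recorded in the
    schedule's ``meta``.
    """
    m: list = []
    for n_trans, S in phase_survivals:
        n_trans = int(n_trans)
        if n_trans < 1:
            raise ValueError("each phase needs at least one weekly transition")
        if not 0.0 <= S <= 1.0:
            raise ValueError(f"phase survival {S!r} outside [0, 1]")
        weekly = 1.0 - S ** (1.0 / n_trans)
        m.extend([weekly] * n_trans)
    if len(m) > n_classes:
        raise InvalidScheduleError(
            f"phases cover {len(m)} transitions but the schedule has {n_classes} weeks"
        )
    m.extend([float(fill_mortality)] * (n_classes - len(m)))
    return MortalitySchedule(
        tuple(m),
        meta={"decomposition": "geometric", "n_filled": n_classes - len(m) or 0},
    )


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompensationRow:
    """One group's row of the compensation table."""

    group_label: str
    L_target: float
    h: float
    h_rounded: int
    fold_vs_control: float

    @property
    def fold_rounded(self) -> float:
        return float(
            Decimal(repr(self.fold_vs_control)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )


def compensation_table(
    schedules: Mapping[str, MortalitySchedule],
    L_target: float = 300.0,
    control_label: str = "control",
) -> list:
    """Stable hatch rates and fold-increases for a set of group schedules.

    Each group's ``h`` is the solution of the stable-population condition at
    the common ``L_target``; folds are taken against the control group's
    ``h`` (control fold = 1).
    """
    if control_label not in schedules:
        raise KeyError(f"control group {control_label!r} missing from schedules")
    h_by_group = {g: stable_hatch_rate(s, L_target) for g, s in schedules.items()}
    return compensation_table_from_hatch_rates(h_by_group, L_target, control_label)


def compensation_table_from_hatch_rates(
    h_by_group: Mapping[str, float],
    L_target: float = 300.0,
    control_label: str = "control",
) -> list:
    """Compensation rows from pre-computed per-group hatch rates."""
    if control_label not in h_by_group:
        raise KeyError(f"control group {control_label!r} missing")
    h_control = h_by_group[control_label]
    rows = []
    for group, h in h_by_group.items():
        rows.append(
            CompensationRow(
                group_label=group,
                L_target=float(L_target),
                h=float(h),
                h_rounded=_round_half_up(h),
                fold_vs_control=compensation_fold(h, h_control),
            )
        )
    return rows


def compensation_frame(rows: Sequence[CompensationRow]):
    """Compensation rows as a DataFrame in the shape of the printed table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "group": [r.group_label for r in rows],
            "L_target": [r.L_target for r in rows],
            "h": [r.h for r in rows],
            "h_rounded": [r.h_rounded for r in rows],
            "fold": [r.fold_rounded for r in rows],
        }
    )
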