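"""Projection-matrix model, stable hatch rate and mortality estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from beecomp import demography as d

W = d.DEFAULT_N_CLASSES


def iterated_total(schedule: d.MortalitySchedule, h: float, n_steps: int = 2 * W) -> float:
    """Independent oracle: total larvae after power-iterating the matrix."""
    A = d.build_projection_matrix(schedule, h)
    state = d.LarvalStateVector.zeros(schedule.n_classes)
    for _ in range(n_steps):
        state = d.project(state, A)
    return state.total


def oracle_hatch_rate(schedule: d.MortalitySchedule, L_target: float) -> float:
    """Root-find the h whose iterated population total equals L_target."""
    if L_target == 0:
        return 0.0
    return brentq(
        lambda h: iterated_total(schedule, h) - L_target,
        0.0,
        max(10.0 * L_target, 1.0),
        xtol=1e-12,
        rtol=1e-14,
    )


class TestProjectionMatrix:
    def test_zero_mortality_layout(self):
        A = d.build_projection_matrix(d.MortalitySchedule((0.0,) * W), 100.0).entries
        assert A.shape == (W + 1, W + 1)
        assert A[0, W] == 100.0
        assert A[W, W] == 1.0
        sub = np.array([A[x + 1, x] for x in range(W - 1)])
        assert np.all(sub == 1.0)
        # the only nonzero entries are fecundity, subdiagonal and queen loop
        assert np.count_nonzero(A) == (W - 1) + 2

    def test_constant_survival_subdiagonal(self):
        A = d.build_projection_matrix(d.MortalitySchedule((0.1,) * W), 50.0).entries
        sub = np.array([A[x + 1, x] for x in range(W - 1)])
        assert np.allclose(sub, 0.9)

    def test_absorbing_first_week(self):
        sched = d.MortalitySchedule((1.0, 0, 0, 0, 0, 0, 0))
        A = d.build_projection_matrix(sched, 10.0).entries
        assert A[1, 0] == 0.0  # no larva survives week 1

    @pytest.mark.parametrize(
        "bad, err",
        [
            ((), d.InvalidScheduleError),
            ((1.2,) * W, ValueError),
            ((-0.1,) * W, ValueError),
        ],
    )
    def test_invalid_schedules_rejected(self, bad, err):
        with pytest.raises(err):
            d.MortalitySchedule(bad)

    def test_negative_hatch_rate_rejected(self):
        with pytest.raises(ValueError):
            d.build_projection_matrix(d.MortalitySchedule((0.1,) * W), -1.0)


class TestProject:
    def test_queen_seeds_first_class(self):
        A = d.build_projection_matrix(d.MortalitySchedule((0.0,) * W), 100.0)
        out = d.project(d.LarvalStateVector.zeros(), A)
        assert out.l == (100.0,) + (0.0,) * (W - 1)
        assert out.Q == 1.0

    def test_geometric_cascade_after_seven_steps(self):
        # h=50, constant weekly mortality 0.1: class x holds 50 * 0.9**(x-1)
        A = d.build_projection_matrix(d.MortalitySchedule((0.1,) * W), 50.0)
        state = d.LarvalStateVector.zeros()
        for _ in range(7):
            state = d.project(state, A)
        expected = (50.0, 45.0, 40.5, 36.45, 32.805, 29.5245, 26.57205)
        assert state.l == pytest.approx(expected, rel=1e-12)

    def test_fixed_point_reached_after_w_steps(self):
        # larval block is nilpotent: any start converges in W applications
        rng = np.random.default_rng(42)
        sched = d.MortalitySchedule(tuple(rng.uniform(0, 1, W)))
        A = d.build_projection_matrix(sched, 80.0)
        state = d.LarvalStateVector(tuple(rng.uniform(0, 50, W)))
        for _ in range(W):
            state = d.project(state, A)
        again = d.project(state, A)
        assert again.l == pytest.approx(state.l, rel=1e-12)
        assert again.Q == 1.0

    def test_conservation_no_creation_beyond_class_one(self):
        rng = np.random.default_rng(7)
        sched = d.MortalitySchedule(tuple(rng.uniform(0, 1, W)))
        A = d.build_projection_matrix(sched, 33.0)
        state = d.LarvalStateVector(tuple(rng.uniform(0, 100, W)))
        out = d.project(state, A)
        assert out.l[0] == A.h * state.Q
        assert sum(out.l[1:]) <= sum(state.l[:-1]) + 1e-9

    def test_dimension_mismatch_raises(self):
        A = d.build_projection_matrix(d.MortalitySchedule((0.1,) * W), 10.0)
        with pytest.raises(ValueError):
            d.project(d.LarvalStateVector.zeros(3), A)


class TestStableHatchRate:
    def test_zero_mortality_uniform_distribution(self):
        assert d.stable_hatch_rate(d.MortalitySchedule((0.0,) * W), 700.0) == 100.0

    def test_constant_survival_geometric_series(self):
        h = d.stable_hatch_rate(d.MortalitySchedule((0.1,) * W), 300.0)
        assert h == pytest.approx(300.0 / 5.217031, abs=1e-3)
        assert h == pytest.approx(57.504, abs=1e-3)

    def test_total_first_week_mortality_only_class_one(self):
        sched = d.MortalitySchedule((1.0, 0.3, 0.3, 0.3, 0.3, 0.3, 0.3))
        assert d.stable_hatch_rate(sched, 300.0) == pytest.approx(300.0)

    def test_agrees_with_root_finding_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            sched = d.MortalitySchedule(tuple(rng.uniform(0, 1, W)))
            L = rng.uniform(1, 1000)
            closed = d.stable_hatch_rate(sched, L)
            assert closed == pytest.approx(oracle_hatch_rate(sched, L), rel=1e-9)

    def test_iterating_at_h_star_reaches_target(self):
        rng = np.random.default_rng(5)
        sched = d.MortalitySchedule(tuple(rng.uniform(0, 0.9, W)))
        h = d.stable_hatch_rate(sched, 300.0)
        assert iterated_total(sched, h) == pytest.approx(300.0, rel=1e-9)

    @given(
        st.lists(st.floats(0, 1), min_size=W, max_size=W),
        st.floats(0, 1e4),
        st.floats(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_scale_equivariance(self, m, L, c):
        sched = d.MortalitySchedule(tuple(m))
        assert d.stable_hatch_rate(sched, c * L) == pytest.approx(
            c * d.stable_hatch_rate(sched, L), rel=1e-9, abs=1e-9
        )

    @given(
        st.lists(st.floats(0, 0.99), min_size=W, max_size=W),
        st.integers(0, W - 1),
        st.floats(0.001, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_each_weekly_mortality(self, m, i, bump):
        base = d.MortalitySchedule(tuple(m))
        bumped = list(m)
        bumped[i] = min(1.0, bumped[i] + bump)
        h0 = d.stable_hatch_rate(base, 300.0)
        h1 = d.stable_hatch_rate(d.MortalitySchedule(tuple(bumped)), 300.0)
        assert h1 >= h0 - 1e-12
        # strictly increasing whenever survivorship through week i is positive
        if i < W - 1 and all(v < 1.0 for v in m[: i + 1]):
            assert h1 > h0

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            d.stable_hatch_rate(d.MortalitySchedule((0.1,) * W), -5.0)


class TestCompensationFold:
    @pytest.mark.parametrize(
        "h_dosed, expected", [(88.0, 1.57), (98.0, 1.75), (107.0, 1.91)]
    )
    def test_published_fold_values(self, h_dosed, expected):
        fold = d.compensation_fold(h_dosed, 56.0)
        assert round(fold, 2) == expected

    def test_identity_fold(self):
        assert d.compensation_fold(64.2, 64.2) == pytest.approx(1.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            d.compensation_fold(88.0, 0.0)


class TestWeeklyMortalityEstimator:
    def test_direct_arithmetic(self):
        assert d.estimate_weekly_mortality([200, 150]).m == (0.25,)

    def test_constant_series_gives_zero_mortality(self):
        assert d.estimate_weekly_mortality([50, 50, 50]).m == (0.0, 0.0)

    def test_geometric_phase_decomposition_roundtrip(self):
        weekly = 1.0 - 0.78 ** (1.0 / 3.0)
        series = [1000 * (1 - weekly) ** k for k in range(4)]
        est = d.estimate_weekly_mortality(series)
        assert est.m == pytest.approx((weekly,) * 3, rel=1e-12)
        assert np.prod(1.0 - np.array(est.m)) == pytest.approx(0.78, rel=1e-12)

    def test_zero_denominator_flags_undefined_week(self):
        est = d.estimate_weekly_mortality([10, 0, 0])
        assert est.undefined_weeks == (2,)
        assert math.isnan(est.m[1])
        with pytest.raises(ValueError):
            est.require_complete()

    def test_increasing_series_errors_unless_clamped(self):
        with pytest.raises(ValueError):
            d.estimate_weekly_mortality([10, 12])
        with pytest.warns(UserWarning):
            est = d.estimate_weekly_mortality([10, 12], clamp=True)
        assert est.m == (0.0,)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            d.estimate_weekly_mortality([10, -1])


class TestExpandPhaseSurvival:
    def test_cube_root_decomposition(self):
        sched = d.expand_phase_survival([(3, 0.78)])
        weekly_survival = 1.0 - sched.m[0]
        assert weekly_survival == pytest.approx(0.9205, abs=5e-5)
        assert weekly_survival**3 == pytest.approx(0.78, rel=1e-12)

    def test_lossless_phase_gives_zero_mortality(self):
        assert d.expand_phase_survival([(3, 1.0)]).m[:3] == (0.0, 0.0, 0.0)

    def test_two_phase_schedule(self):
        sched = d.expand_phase_survival([(3, 0.78), (3, 0.829)])
        surv = 1.0 - np.array(sched.m)
        assert surv[:3] == pytest.approx([0.9205] * 3, abs=5e-5)
        assert surv[3:6] == pytest.approx([0.9394] * 3, abs=5e-5)
        assert sched.m[6] == 0.0  # filled week
        assert sched.meta["decomposition"] == "geometric"

    def test_overfull_phases_rejected(self):
        with pytest.raises(d.InvalidScheduleError):
            d.expand_phase_survival([(4, 0.9), (4, 0.9)])

    def test_out_of_range_survival_rejected(self):
        with pytest.raises(ValueError):
            d.expand_phase_survival([(3, 1.2)])


class TestCompensationTable:
    def test_zero_mortality_all_equal(self):
        scheds = {g: d.MortalitySchedule((0.0,) * W) for g in ("control", "a", "b")}
        rows = d.compensation_table(scheds, L_target=700.0)
        assert all(r.h == 100.0 and r.fold_rounded == 1.0 for r in rows)

    def test_higher_mortality_gives_fold_above_one(self):
        scheds = {
            "control": d.MortalitySchedule((0.05,) * W),
            "dosed": d.MortalitySchedule((0.25,) * W),
        }
        rows = {r.group_label: r for r in d.compensation_table(scheds)}
        assert rows["dosed"].fold_vs_control > 1.0

    def test_published_hatch_rates_reproduce_folds(self):
        rows = d.compensation_table_from_hatch_rates(
            {"control": 56.0, "1": 88.0, "10": 98.0, "100": 107.0}
        )
        assert [r.fold_rounded for r in rows] == [1.0, 1.57, 1.75, 1.91]
        assert [r.h_rounded for r in rows] == [56, 88, 98, 107]

    def test_missing_control_is_configuration_error(self):
        with pytest.raises(KeyError):
            d.compensation_table({"a": d.MortalitySchedule((0.1,) * W)})

    def test_half_up_rounding_of_h(self):
        rows = d.compensation_table_from_hatch_rates({"control": 56.5})
        assert rows[0].h_rounded == 57
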