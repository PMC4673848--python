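"""Volume growth, start-size rule, division geometry and inheritance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budsim.cell_cycle import (
    DIVISION,
    S_ENTRY,
    START_REACHED,
    CellCycleParams,
    Normal,
    divide,
    grow,
    inherit_params,
    new_cycle,
    position_at_age,
    t1_duration,
    time_to_division,
    volume_at,
    volume_at_start,
)


class TestStartSizeRule:
    @pytest.mark.parametrize(
        "r1,k,b,expected",
        [
            (0.7, 0.0, 30.0, 30.0),   # slope-free: Vs is just the intercept
            (1.0, 10.0, 20.0, 30.0),
            (0.6, 25.0, 12.0, 27.0),
        ],
    )
    def test_linear_rule(self, r1, k, b, expected):
        assert volume_at_start(r1, k, b) == pytest.approx(expected)

    def test_negative_start_volume_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            volume_at_start(1.0, 0.0, -5.0)


class TestT1Duration:
    def test_threshold_already_met_lower_bound_binds(self):
        assert t1_duration(V0=30.0, Vs=30.0, r1=0.5, T1min=10.0) == 10.0

    def test_size_threshold_time(self):
        assert t1_duration(V0=20.0, Vs=30.0, r1=0.5, T1min=0.0) == pytest.approx(20.0)

    def test_combiner_branches(self):
        # lower-bound semantics (default) vs the literal min form
        assert t1_duration(20.0, 30.0, 1.0, 30.0, combiner="max") == 30.0
        assert t1_duration(20.0, 30.0, 1.0, 30.0, combiner="min") == 10.0

    def test_stalled_growth_rejected(self):
        with pytest.raises(ValueError, match="never reached"):
            t1_duration(V0=20.0, Vs=30.0, r1=0.0, T1min=10.0)


class TestGrow:
    def test_zero_dt_is_identity(self, base_params):
        pos = new_cycle(25.0, base_params)
        V, new_pos, events = grow(pos, base_params, 0.0)
        assert new_pos == pos
        assert events == []
        assert V == pytest.approx(volume_at(pos, base_params))

    def test_linear_growth_within_t1(self, base_params):
        # V0=25 < Vs=30 so T1 = (30-25)/0.25 = 20 min
        pos = new_cycle(25.0, base_params)
        assert pos.T1 == pytest.approx(30.0)  # lower bound T1min binds
        V, new_pos, events = grow(pos, base_params, 10.0)
        assert V == pytest.approx(25.0 + 0.25 * 10.0)
        assert new_pos.block == "T1"
        assert events == []

    def test_boundary_events_with_exact_times(self, base_params):
        pos = new_cycle(35.0, base_params)  # above Vs: T1 = T1min = 30
        V, new_pos, events = grow(pos, base_params, 30.0 + 15.0 + 75.0)
        kinds = [e.kind for e in events]
        assert kinds == [START_REACHED, S_ENTRY, DIVISION]
        assert [e.time for e in events] == pytest.approx([30.0, 45.0, 120.0])
        assert new_pos.block == "T3"

    def test_division_near_boundary(self, base_params):
        pos = new_cycle(35.0, base_params)
        _, pos, _ = grow(pos, base_params, 30.0 + 15.0 + 75.0 - 1e-6)
        _, pos, events = grow(pos, base_params, 1.0)
        assert [e.kind for e in events] == [DIVISION]

    def test_volume_continuous_and_nondecreasing(self, base_params):
        pos = new_cycle(25.0, base_params)
        last_v = volume_at(pos, base_params)
        t = 0.0
        while True:
            V, pos, events = grow(pos, base_params, 7.0)
            assert V >= last_v - 1e-12
            last_v = V
            if any(e.kind == DIVISION for e in events):
                break
            t += 7.0
            assert t < 1000.0


class TestDivide:
    def test_bud_volume(self, base_params):
        p = CellCycleParams(
            Vi=30, r1=0.25, r2=0.4, r2m=0.15, T1min=30, T2=15, T3=80,
            k=40, b=20, c_inherit=0.25,
        )
        v_m, v_d = divide(60.0, p)
        assert v_d == pytest.approx((0.4 - 0.15) * 80)  # 20
        assert v_m == pytest.approx(40.0)

    def test_zero_size_daughter_rejected(self, base_params):
        p = CellCycleParams(
            Vi=30, r1=0.25, r2=0.3, r2m=0.3, T1min=30, T2=15, T3=75,
            k=40, b=20, c_inherit=0.25,
        )
        with pytest.raises(ValueError, match="not positive"):
            divide(60.0, p)

    def test_daughter_must_be_smaller_than_total(self, base_params):
        with pytest.raises(ValueError, match="total volume"):
            divide(10.0, base_params)  # bud (22.5 fL) exceeds the total

    @settings(deadline=None, max_examples=100)
    @given(
        v_total=st.floats(30.0, 500.0),
        bud_growth=st.floats(0.05, 0.35),
        t3=st.floats(40.0, 110.0),
    )
    def test_volume_conserved_exactly(self, v_total, bud_growth, t3):
        p = CellCycleParams(
            Vi=30, r1=0.25, r2=0.2 + bud_growth, r2m=0.2, T1min=30, T2=15,
            T3=t3, k=40, b=20, c_inherit=0.25,
        )
        if bud_growth * t3 >= v_total:
            return
        v_m, v_d = divide(v_total, p)
        # conserved by construction, up to one rounding ulp of the sum
        assert v_m + v_d == pytest.approx(v_total, rel=4e-16, abs=0.0)
        assert v_m > 0 and v_d > 0


class TestInheritance:
    def test_full_inheritance_copies_parent(self, popn, base_params, rng):
        parent = CellCycleParams(
            **{**vars(base_params), "c_inherit": 1.0}
        )
        daughter = inherit_params(parent, popn, rng)
        for name in ("Vi", "r1", "r2", "r2m", "T1min", "T2", "T3"):
            assert getattr(daughter, name) == pytest.approx(getattr(parent, name))

    def test_zero_inheritance_matches_population_mean(self, popn, base_params, rng):
        parent = CellCycleParams(**{**vars(base_params), "c_inherit": 0.0})
        draws = np.array(
            [inherit_params(parent, popn, rng).T3 for _ in range(10_000)]
        )
        se = popn.T3.sd / np.sqrt(len(draws))
        assert abs(draws.mean() - popn.T3.mean) < 3 * se

    def test_quarter_inheritance_shifts_mean(self, popn, rng):
        # parent one sd above the mean -> daughter mean = mu + 0.25*sd
        mu, sd = popn.T3.mean, popn.T3.sd
        parent = CellCycleParams(
            Vi=30, r1=0.25, r2=0.45, r2m=0.15, T1min=30, T2=15, T3=mu + sd,
            k=40, b=20, c_inherit=0.25,
        )
        draws = np.array(
            [inherit_params(parent, popn, rng).T3 for _ in range(10_000)]
        )
        se = 0.75 * sd / np.sqrt(len(draws))
        assert abs(draws.mean() - (mu + 0.25 * sd)) < 3 * se

    def test_fresh_draws_nonnegative(self, popn, rng):
        tight = Normal(mean=0.5, sd=2.0)  # heavy truncation
        draws = [tight.sample(rng) for _ in range(2000)]
        assert min(draws) >= 0.0


class TestCycleCalibration:
    def test_mother_cycle_mean_is_doubling_time(self, popn, rng):
        """Mothers re-enter G1 above the start size: cycle = T1min+T2+T3."""
        lengths = []
        for _ in range(3000):
            p = popn.sample(rng)
            pos = new_cycle(2.0 * (p.k * p.r1 + p.b), p)  # well past start size
            lengths.append(pos.T1 + p.T2 + p.T3)
        lengths = np.array(lengths)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - popn.mean_cycle_length) < 3 * se

    def test_daughter_cycle_slightly_longer_than_nominal(self, popn, rng):
        """Daughters are born at the start-size margin, so the max() in the
        T1 rule inflates their mean cycle above the nominal doubling time
        (Jensen), but by well under 10%."""
        lengths = []
        for _ in range(3000):
            p = popn.sample(rng)
            v0 = (p.r2 - p.r2m) * p.T3
            pos = new_cycle(v0, p)
            lengths.append(pos.T1 + p.T2 + p.T3)
        mean = float(np.mean(lengths))
        nominal = popn.mean_cycle_length
        assert nominal - 1.0 < mean < 1.10 * nominal

    def test_position_at_age_wraps_cycle(self, base_params):
        pos_fresh = position_at_age(0.0, base_params)
        cycle = pos_fresh.T1 + base_params.T2 + base_params.T3
        pos_wrapped = position_at_age(cycle + 10.0, base_params)
        pos_direct = position_at_age(10.0, base_params)
        assert pos_wrapped.block == pos_direct.block
        assert pos_wrapped.clock == pytest.approx(pos_direct.clock)

    def test_time_to_division_consistent_with_grow(self, base_params):
        pos = position_at_age(40.0, base_params)
        ttd = time_to_division(pos, base_params)
        _, _, events = grow(pos, base_params, ttd + 1e-9)
        assert any(e.kind == DIVISION for e in events)
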