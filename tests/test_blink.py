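"""Blink-cycle water/salt balance, mixing, and the timestep scheduler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tearsim.blink import (
    STANDARD_POLICIES,
    CompartmentState,
    PhysiologyParams,
    TimestepPolicy,
    advance_interblink,
    apply_blink_mixing,
    count_timesteps,
    mix_osmolarity,
    redistribute_volumes,
    simulate_blink_cycles,
)
from tearsim.geometry import REGIONS
from tearsim.simulate import make_drainage_model
from tearsim.drainage import DrainageParams


@pytest.fixture(scope="module")
def physiology():
    return PhysiologyParams()


def drainage_model(geometry, schedule, feedback=True):
    return make_drainage_model(DrainageParams(), geometry, schedule, feedback)


class TestScheduler:
    def test_blink_cycle_duration_is_phase_sum(self, schedule):
        assert schedule.t_blinkcycle == pytest.approx(5.72, abs=1e-12)

    def test_uniform_millisecond_policy_step_count(self, schedule):
        assert count_timesteps(STANDARD_POLICIES["A"], 10, schedule) == 57200

    def test_single_cycle_step(self, schedule):
        pol = TimestepPolicy.uniform(schedule.t_blinkcycle)
        assert count_timesteps(pol, 1, schedule) == 1

    @pytest.mark.parametrize("label", sorted(STANDARD_POLICIES))
    def test_counts_match_explicit_window_walk(self, label, schedule):
        # oracle: walk each window step by step, accumulating accepted steps
        pol = STANDARD_POLICIES[label]
        walked = 0
        for t0, t1, dt in pol.windows:
            tau = t0
            while tau < t1 - 1e-9:
                tau = min(tau + dt, t1)
                walked += 1
        assert count_timesteps(pol, 10, schedule) == walked * 10

    def test_policy_must_tile_contiguously(self):
        with pytest.raises(ValueError, match="contiguous"):
            TimestepPolicy(((0.0, 1.0, 0.1), (2.0, 5.72, 0.1)))

    def test_policy_rejects_nonpositive_dt(self):
        with pytest.raises(ValueError, match="dt"):
            TimestepPolicy(((0.0, 5.72, -0.1),))


def make_state(volumes, osmolarities):
    return CompartmentState(
        volumes=np.asarray(volumes, float),
        osmolarities=np.asarray(osmolarities, float),
    )


class TestInterblinkBalance:
    def test_balanced_fluxes_leave_state_unchanged(self, physiology):
        state = make_state([2.0, 2.0, 1.5, 6.9, 4.1], [302.0] * 5)
        new = advance_interblink(state, 1.0, physiology, physiology.Q_lacrimal, 0.0)
        assert np.allclose(new.volumes, state.volumes, atol=1e-12)
        assert np.allclose(new.osmolarities, state.osmolarities, atol=1e-12)

    def test_evaporation_only_concentrates_tear_film(self, physiology):
        phys = PhysiologyParams(Q_lacrimal=0.0)
        state = make_state([2.0, 2.0, 1.5, 6.9, 4.1], [302.0] * 5)
        osmoles0 = state.total_osmoles
        new = advance_interblink(state, 60.0, phys, 0.0, 0.2)
        tf = REGIONS.index("tear_film")
        assert new.volumes[tf] == pytest.approx(4.1 - 0.2, rel=1e-12)
        assert new.osmolarities[tf] > 302.0
        assert new.total_osmoles == pytest.approx(osmoles0, rel=1e-12)

    def test_interblink_decreases_tear_film_volume(self, geometry, schedule, physiology):
        # default rates over one 5.5 s open-eye phase
        state = CompartmentState.basal(geometry)
        v0 = state.volume("tear_film")
        for _ in range(55):
            state = advance_interblink(state, 0.1, physiology, 0.8, 0.2)
        assert state.volume("tear_film") < v0

    def test_outflow_clamped_at_empty_region(self, physiology):
        state = make_state([2.0, 2.0, 0.001, 6.9, 4.1], [302.0] * 5)
        phys = PhysiologyParams(Q_lacrimal=0.0)
        new = advance_interblink(state, 60.0, phys, (10.0, 0.0), 0.0)
        assert new.volumes.min() >= 0.0
        # accounting matches what was actually removed
        assert new.drained_uL == pytest.approx(0.001, rel=1e-9)

    def test_rejects_bad_steps(self, physiology):
        state = make_state([1.0] * 5, [302.0] * 5)
        with pytest.raises(ValueError):
            advance_interblink(state, -1.0, physiology, 0.0, 0.0)
        with pytest.raises(ValueError):
            advance_interblink(state, 1.0, physiology, -1.0, 0.0)


class TestBlinkMixing:
    def test_volume_weighted_osmolarity_mean(self):
        state = make_state([1.0, 1.0, 0.0, 0.0, 0.0], [280.0, 320.0, 0, 0, 0])
        mixed = mix_osmolarity(state)
        assert np.allclose(mixed.osmolarities, 300.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        volumes=st.lists(st.floats(0.01, 50.0), min_size=5, max_size=5),
        osms=st.lists(st.floats(100.0, 500.0), min_size=5, max_size=5),
    )
    def test_mixing_conserves_osmoles_exactly(self, volumes, osms, geometry):
        state = make_state(volumes, osms)
        osmoles0 = state.total_osmoles
        mixed = apply_blink_mixing(state, geometry)
        assert mixed.total_osmoles == pytest.approx(osmoles0, rel=1e-12)
        assert mixed.total_volume == pytest.approx(state.total_volume, rel=1e-12)

    def test_redistribution_matches_basal_ratios(self, geometry):
        state = make_state([5.0, 1.0, 2.0, 3.0, 6.0], [310.0] * 5)
        new = redistribute_volumes(state, geometry)
        ratios = np.array([geometry.basal_volume_ratios[r] for r in REGIONS])
        assert np.allclose(new.volumes / new.total_volume, ratios, atol=1e-12)


class TestSimulateCycles:
    def test_closed_system_volumes_constant(self, geometry, schedule):
        phys = PhysiologyParams(Q_lacrimal=0.0)
        res = simulate_blink_cycles(
            20,
            STANDARD_POLICIES["E"],
            schedule=schedule,
            geometry=geometry,
            physiology=phys,
            drainage_model=(0.0, 0.0),
            evaporation_rate=0.0,
            record_every=10**9,
        )
        bv = res.cycle_boundary_volumes().sum(axis=1)
        assert np.allclose(bv, bv[0], rtol=1e-12)

    def test_water_and_osmole_balance_close(self, geometry, schedule):
        res = simulate_blink_cycles(
            10,
            STANDARD_POLICIES["E"],
            schedule=schedule,
            geometry=geometry,
            drainage_model=drainage_model(geometry, schedule),
            record_every=10**9,
        )
        s = res.final_state
        water = (
            geometry.total_basal_volume
            + s.secreted_uL
            - s.drained_uL
            - s.evaporated_uL
            - s.spilled_uL
        )
        assert s.total_volume == pytest.approx(water, rel=1e-9)
        osmoles = (
            geometry.total_basal_volume * 302.0
            + s.secreted_osmoles
            - s.drained_osmoles
            - s.spilled_osmoles
        )
        assert s.total_osmoles == pytest.approx(osmoles, rel=1e-9)

    def test_limit_cycle_contraction(self, geometry, schedule):
        """Per-cycle state change shrinks toward a limit cycle.

        Oracle: run 100 cycles and verify the cycle-boundary volume
        increments form a Cauchy (geometrically contracting) sequence.
        """
        res = simulate_blink_cycles(
            100,
            STANDARD_POLICIES["E"],
            schedule=schedule,
            geometry=geometry,
            drainage_model=drainage_model(geometry, schedule, feedback=True),
            record_every=10**9,
        )
        bv = res.cycle_boundary_volumes().sum(axis=1)
        d = np.abs(np.diff(bv))
        # tail increments keep shrinking and are far below the head
        assert d[-1] < d[0]
        assert np.all(d[60:] <= d[40:80][: len(d[60:])] + 1e-12)
        assert d[-1] < 0.5 * d[9]

    @pytest.mark.parametrize("label", ["B", "D", "E", "G"])
    def test_policy_equivalence_with_uniform_baseline(
        self, label, geometry, schedule
    ):
        """Periodic timestep schedules preserve the cycle-boundary states."""
        kw = dict(
            schedule=schedule,
            geometry=geometry,
            drainage_model=drainage_model(geometry, schedule),
            record_every=10**9,
        )
        ref = simulate_blink_cycles(10, STANDARD_POLICIES["A"], **kw)
        alt = simulate_blink_cycles(10, STANDARD_POLICIES[label], **kw)
        rv, av = ref.cycle_boundary_volumes(), alt.cycle_boundary_volumes()
        ro, ao = (
            ref.cycle_boundary_osmolarities(),
            alt.cycle_boundary_osmolarities(),
        )
        assert np.max(np.abs(av - rv) / np.abs(rv)) < 0.01
        assert np.max(np.abs(ao - ro) / np.abs(ro)) < 0.01

    def test_scheduler_refinement_converges(self, geometry, schedule):
        kw = dict(
            schedule=schedule,
            geometry=geometry,
            drainage_model=drainage_model(geometry, schedule),
            record_every=10**9,
        )
        coarse = simulate_blink_cycles(
            3, TimestepPolicy.uniform(0.02), **kw
        ).cycle_boundary_volumes()
        fine = simulate_blink_cycles(
            3, TimestepPolicy.uniform(0.01), **kw
        ).cycle_boundary_volumes()
        assert np.max(np.abs(fine - coarse) / np.abs(fine)) < 1e-3
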