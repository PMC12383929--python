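"""Blink-cycle tear dynamics: volumes and osmolarities of five regions.

One blink cycle has three phases: the eyes stay open (interblink, 5.5 s),
the upper lid falls (closure, 0.04 s), and the lid rises again (deposition,
0.18 s) — 5.72 s in total.  During the interblink, lacrimal secretion enters
the fornical sacs, flows to the lid margins into the menisci, nasolacrimal
drainage withdraws fluid from the menisci through the canaliculi, and
evaporation removes water (not osmoles) from the exposed tear film, raising
its osmolarity.  Lid closure mixes all five regions to a single well-mixed
osmolarity, and the rising lid redistributes the total volume across regions
in proportion to their basal volume ratios, shrinking the menisci.

Integration uses explicit fixed steps tiled by a piecewise-constant
``TimestepPolicy`` keyed to blink-cycle phase windows: fine steps around the
rapid blink events, coarse steps over the slow interblink.  All policies in
``STANDARD_POLICIES`` reproduce the same cycle-boundary states to within 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import REGIONS, TearFilmGeometry

__all__ = [
    "BlinkSchedule",
    "TimestepPolicy",
    "STANDARD_POLICIES",
    "CompartmentState",
    "PhysiologyParams",
    "advance_interblink",
    "apply_blink_mixing",
    "simulate_blink_cycles",
    "count_timesteps",
    "BlinkSimResult",
]

log = logging.getLogger(__name__)

_MENISCI = (REGIONS.index("upper_meniscus"), REGIONS.index("lower_meniscus"))
_SACS = (REGIONS.index("upper_fornical_sac"), REGIONS.index("lower_fornical_sac"))
_TF = REGIONS.index("tear_film")


@dataclass(frozen=True)
class BlinkSchedule:
    """Durations of the three blink-cycle phases [s]."""

    t_interblink_phase: float = 5.5
    t_closure: float = 0.04
    t_deposition: float = 0.18

    def __post_init__(self) -> None:
        for name in ("t_interblink_phase", "t_closure", "t_deposition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def t_blinkcycle(self) -> float:
        return self.t_interblink_phase + self.t_closure + self.t_deposition

    def phase_boundaries(self) -> tuple[float, float, float, float]:
        """Cycle-local times (0, end interblink, end closure, end cycle)."""
        t1 = self.t_interblink_phase
        t2 = t1 + self.t_closure
        return (0.0, t1, t2, self.t_blinkcycle)

    def phase_at(self, tau: float) -> str:
        """Phase name at cycle-local time tau ∈ [0, t_blinkcycle)."""
        _, t1, t2, _ = self.phase_boundaries()
        if tau < t1:
            return "interblink"
        if tau < t2:
            return "closure"
        return "deposition"

    def segments_between(
        self, t0: float, t1: float
    ) -> list[tuple[float, float, str]]:
        """Split cycle-local [t0, t1] at phase boundaries into (a, b, phase)."""
        cuts = [b for b in self.phase_boundaries() if t0 < b < t1 - 1e-12]
        pts = [t0, *cuts, t1]
        return [
            (a, b, self.phase_at(0.5 * (a + b)))
            for a, b in zip(pts[:-1], pts[1:])
            if b - a > 1e-12
        ]


@dataclass(frozen=True)
class TimestepPolicy:
    """Piecewise-constant integration-step schedule over one blink cycle.

    ``windows`` are (t_start, t_end, dt) tiles covering [0, t_blinkcycle]
    without gaps or overlap; the tiling repeats every cycle.
    """

    windows: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("policy needs at least one window")
        prev_end = 0.0
        for t0, t1, dt in self.windows:
            if dt <= 0:
                raise ValueError(f"window ({t0}, {t1}) has non-positive dt")
            if t1 <= t0:
                raise ValueError(f"window ({t0}, {t1}) is empty")
            if abs(t0 - prev_end) > 1e-9:
                raise ValueError(
                    f"windows must tile contiguously from 0; gap at {t0}"
                )
            prev_end = t1

    @classmethod
    def uniform(cls, dt: float, t_blinkcycle: float = 5.72) -> "TimestepPolicy":
        return cls(windows=((0.0, t_blinkcycle, dt),))

    @property
    def t_end(self) -> float:
        return self.windows[-1][1]

    def dt_at(self, tau: float) -> float:
        for t0, t1, dt in self.windows:
            if t0 - 1e-12 <= tau < t1 - 1e-12:
                return dt
        return self.windows[-1][2]

    def step_grid(
        self, schedule: BlinkSchedule | None = None
    ) -> list[tuple[float, int]]:
        """One cycle's accepted steps as (step size, step count) tiles.

        Each window is walked with ceil(span/dt) uniform steps; a step that
        straddles a phase boundary is still one accepted step (the physics
        advance splits it internally).
        """
        if schedule is not None and abs(self.t_end - schedule.t_blinkcycle) > 1e-9:
            raise ValueError(
                f"policy covers [0, {self.t_end}] but the blink cycle "
                f"lasts {schedule.t_blinkcycle} s"
            )
        grid = []
        for t0, t1, dt in self.windows:
            span = t1 - t0
            n = max(1, int(np.ceil(span / dt - 1e-9)))
            grid.append((span / n, n))
        return grid


#: The seven benchmark timestep policies (uniform baseline plus six
#: periodically refined schedules with fine steps around the blink events).
STANDARD_POLICIES: dict[str, TimestepPolicy] = {
    "A": TimestepPolicy.uniform(0.001),
    "B": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 5.40, 0.005), (5.40, 5.72, 0.001))),
    "C": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 5.40, 0.010), (5.40, 5.72, 0.001))),
    "D": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 5.40, 0.050), (5.40, 5.72, 0.001))),
    "E": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 5.30, 0.100), (5.30, 5.72, 0.001))),
    "F": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 4.50, 0.500), (4.50, 5.72, 0.001))),
    "G": TimestepPolicy(((0.0, 0.01, 0.001), (0.01, 4.01, 1.000), (4.01, 5.72, 0.001))),
}


@dataclass(frozen=True)
class PhysiologyParams:
    """Lacrimal secretion and ocular holding capacity.

    Q_lacrimal [µL/min] basal lacrimal secretion at isotonic osmolarity
    C_iso [mOsM]; V_max [µL] is the maximal volume the ocular surface can
    hold (excess is lost to spillover).
    """

    Q_lacrimal: float = 1.0
    C_iso: float = 302.0
    V_max: float = 25.0

    def __post_init__(self) -> None:
        if self.Q_lacrimal < 0:
            raise ValueError("Q_lacrimal must be >= 0")
        if self.V_max <= 0:
            raise ValueError("V_max must be positive")


@dataclass
class CompartmentState:
    """Per-region tear volume [µL] and osmolarity [mOsM] plus sink ledgers.

    Arrays follow :data:`tearsim.geometry.REGIONS` ordering.  Cumulative
    ledgers (secreted/drained/evaporated/spilled volume, secreted/drained/
    spilled osmoles) close the water and osmole balances exactly.
    """

    volumes: np.ndarray
    osmolarities: np.ndarray
    secreted_uL: float = 0.0
    drained_uL: float = 0.0
    evaporated_uL: float = 0.0
    spilled_uL: float = 0.0
    secreted_osmoles: float = 0.0  # [µL·mOsM]
    drained_osmoles: float = 0.0
    spilled_osmoles: float = 0.0

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.osmolarities = np.asarray(self.osmolarities, dtype=float)
        if self.volumes.shape != (len(REGIONS),):
            raise ValueError(f"volumes must have shape ({len(REGIONS)},)")
        if np.any(self.volumes < 0) or np.any(self.osmolarities < 0):
            raise ValueError("volumes and osmolarities must be non-negative")

    @classmethod
    def basal(
        cls, geometry: TearFilmGeometry, osmolarity: float = 302.0
    ) -> "CompartmentState":
        vols = np.array([geometry.region_volumes[r] for r in REGIONS])
        return cls(volumes=vols, osmolarities=np.full(len(REGIONS), osmolarity))

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def total_osmoles(self) -> float:
        return float((self.volumes * self.osmolarities).sum())

    def volume(self, region: str) -> float:
        return float(self.volumes[REGIONS.index(region)])

    def osmolarity(self, region: str) -> float:
        return float(self.osmolarities[REGIONS.index(region)])

    def copy(self) -> "CompartmentState":
        return replace(
            self, volumes=self.volumes.copy(), osmolarities=self.osmolarities.copy()
        )


def _as_pair(rate) -> tuple[float, float]:
    if np.isscalar(rate):
        return float(rate) / 2.0, float(rate) / 2.0
    up, lo = rate
    return float(up), float(lo)


def advance_interblink(
    state: CompartmentState,
    dt: float,
    physiology: PhysiologyParams,
    drainage_rate,
    evaporation_rate: float,
) -> CompartmentState:
    """Advance the open-eye water/salt balance by one explicit step.

    Routing: secretion (at ``C_iso``) splits equally between the two
    fornical sacs and passes through to the matching menisci at the sac
    osmolarity; drainage withdraws from the menisci at their local
    osmolarity (``drainage_rate`` is the summed rate [µL/min], or an
    (upper, lower) pair); evaporation removes water only from the exposed
    tear film.  Fluxes that would drive a region negative are clamped with
    a logged mass-balance note.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    q_up, q_lo = _as_pair(drainage_rate)
    if q_up < 0 or q_lo < 0 or evaporation_rate < 0:
        raise ValueError("rates must be non-negative")
    new = state.copy()
    V, C = new.volumes, new.osmolarities
    dts = dt  # [s]; rates arrive in µL/min
    s_half = physiology.Q_lacrimal / 60.0 / 2.0  # µL/s per sac

    # clamp outflows that would empty their source region within this step
    def clamp(rate_uLs: float, idx: int, what: str) -> float:
        avail = V[idx] / dts
        if rate_uLs > avail:
            log.info(
                "mass-balance note: %s flux clamped from %.4g to %.4g uL/s "
                "to keep %s non-negative",
                what, rate_uLs, avail, REGIONS[idx],
            )
            return avail
        return rate_uLs

    q_up_s = clamp(q_up / 60.0, _MENISCI[0], "upper drainage")
    q_lo_s = clamp(q_lo / 60.0, _MENISCI[1], "lower drainage")
    e_s = clamp(evaporation_rate / 60.0, _TF, "evaporation")

    N = V * C  # osmoles [µL·mOsM]
    for sac, men, q_s in zip(_SACS, _MENISCI, (q_up_s, q_lo_s)):
        C_sac = C[sac]
        C_men = C[men]
        # sac: secretion in at C_iso, pass-through out at C_sac (dV = 0)
        N[sac] += dts * s_half * (physiology.C_iso - C_sac)
        # meniscus: pass-through in, drainage out
        V[men] += dts * (s_half - q_s)
        N[men] += dts * (s_half * C_sac - q_s * C_men)
        new.drained_uL += dts * q_s
        new.drained_osmoles += dts * q_s * C_men
    V[_TF] -= dts * e_s  # water only: N[_TF] unchanged
    new.evaporated_uL += dts * e_s
    new.secreted_uL += dts * 2 * s_half
    new.secreted_osmoles += dts * 2 * s_half * physiology.C_iso

    V[V < 0] = np.where(V[V < 0] > -1e-12, 0.0, V[V < 0])  # scrub roundoff
    new.osmolarities = np.where(V > 0, N / np.maximum(V, 1e-300), C)
    new.volumes = V
    return new


def _advance_closed(
    state: CompartmentState, dt: float, physiology: PhysiologyParams
) -> CompartmentState:
    """Lids-covered advancement: secretion only (no drainage, no evaporation)."""
    return advance_interblink(state, dt, physiology, 0.0, 0.0)


def mix_osmolarity(state: CompartmentState) -> CompartmentState:
    """Pool all five regions to one well-mixed osmolarity (closure)."""
    new = state.copy()
    total_v = new.total_volume
    if total_v > 0:
        c_mix = new.total_osmoles / total_v
        new.osmolarities = np.full(len(REGIONS), c_mix)
    return new


def redistribute_volumes(
    state: CompartmentState, geometry: TearFilmGeometry
) -> CompartmentState:
    """Repartition total volume across regions by basal ratios (deposition)."""
    new = state.copy()
    N = new.volumes * new.osmolarities
    ratios = np.array([geometry.basal_volume_ratios[r] for r in REGIONS])
    total_v = new.total_volume
    total_n = N.sum()
    new.volumes = total_v * ratios
    # redistribution accompanies complete mixing: uniform osmolarity
    if total_v > 0:
        new.osmolarities = np.full(len(REGIONS), total_n / total_v)
    return new


def apply_blink_mixing(
    state: CompartmentState, geometry: TearFilmGeometry
) -> CompartmentState:
    """Closure pooling followed by deposition redistribution."""
    return redistribute_volumes(mix_osmolarity(state), geometry)


def count_timesteps(
    policy: TimestepPolicy,
    n_cycles: int,
    schedule: BlinkSchedule | None = None,
) -> int:
    """Exact number of integration steps the scheduler takes."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    schedule = schedule if schedule is not None else BlinkSchedule()
    per_cycle = sum(n for _, n in policy.step_grid(schedule))
    return per_cycle * n_cycles


@dataclass
class BlinkSimResult:
    """Sampled blink-cycle simulation output."""

    times: np.ndarray
    volumes: np.ndarray  # (n_samples, n_regions) [µL]
    osmolarities: np.ndarray  # (n_samples, n_regions) [mOsM]
    cycle_boundary_states: list[CompartmentState]
    final_state: CompartmentState
    n_steps: int = 0

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.times}
        for j, r in enumerate(REGIONS):
            cols[f"V_{r}_uL"] = self.volumes[:, j]
        for j, r in enumerate(REGIONS):
            cols[f"C_{r}_mOsM"] = self.osmolarities[:, j]
        return pd.DataFrame(cols)

    def cycle_boundary_volumes(self) -> np.ndarray:
        return np.array([s.volumes for s in self.cycle_boundary_states])

    def cycle_boundary_osmolarities(self) -> np.ndarray:
        return np.array([s.osmolarities for s in self.cycle_boundary_states])


def simulate_blink_cycles(
    n_cycles: int,
    policy: TimestepPolicy | None = None,
    *,
    schedule: BlinkSchedule | None = None,
    geometry: TearFilmGeometry | None = None,
    physiology: PhysiologyParams | None = None,
    drainage_model=None,
    evaporation_rate: float = 0.2,
    initial_state: CompartmentState | None = None,
    record_every: int = 1,
    step_callback=None,
) -> BlinkSimResult:
    """Advance the five-region tear balance through repeated blink cycles.

    ``drainage_model`` is either a summed rate [µL/min], an (upper, lower)
    pair, or a callable ``state -> (q_upper, q_lower)`` evaluated at each
    cycle start (cycle-averaged Eq.-1 rates).  Because the canaliculi refill
    during the open-eye phase, the cycle-average withdrawal is applied over
    the interblink window, scaled by t_blinkcycle/t_interblink so each
    cycle's drained volume matches the model.  Evaporation acts only during
    the interblink; secretion runs in every phase.

    Osmolarity pooling happens when the lids meet (closure start) and the
    volume repartition to basal ratios when the lid rises (deposition
    start); after a burn-in the per-cycle state change contracts toward a
    limit cycle.

    ``step_callback(state, dt, phase)`` lets a species-transport layer
    advance in lockstep.  Returns the state sampled every accepted step (or
    every ``record_every``-th).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    from .geometry import derive_geometry

    schedule = schedule if schedule is not None else BlinkSchedule()
    policy = policy if policy is not None else STANDARD_POLICIES["E"]
    geometry = geometry if geometry is not None else derive_geometry()
    physiology = physiology if physiology is not None else PhysiologyParams()
    state = (
        initial_state.copy()
        if initial_state is not None
        else CompartmentState.basal(geometry)
    )
    if drainage_model is None:
        drainage_model = (0.4, 0.4)

    grid = policy.step_grid(schedule)
    scale = schedule.t_blinkcycle / schedule.t_interblink_phase
    times = [0.0]
    vols = [state.volumes.copy()]
    osms = [state.osmolarities.copy()]
    boundaries = [state.copy()]
    t = 0.0
    n_steps = 0
    k = 0
    for _ in range(n_cycles):
        rates = drainage_model(state) if callable(drainage_model) else drainage_model
        q_up, q_lo = _as_pair(rates)
        tau = 0.0
        prev_phase = "interblink"
        for dt, n in grid:
            for _ in range(n):
                for a, b, phase in schedule.segments_between(tau, tau + dt):
                    if phase != prev_phase:
                        if phase == "closure":
                            state = mix_osmolarity(state)
                        elif phase == "deposition":
                            state = redistribute_volumes(state, geometry)
                        prev_phase = phase
                    if phase == "interblink":
                        state = advance_interblink(
                            state,
                            b - a,
                            physiology,
                            (q_up * scale, q_lo * scale),
                            evaporation_rate,
                        )
                    else:
                        state = _advance_closed(state, b - a, physiology)
                    if step_callback is not None:
                        step_callback(state, b - a, phase)
                if not np.all(np.isfinite(state.volumes)) or not np.all(
                    np.isfinite(state.osmolarities)
                ):
                    raise RuntimeError(
                        f"non-finite state at t={t + tau + dt:.4f}s; last "
                        f"balanced step volumes={vols[-1]!r}"
                    )
                tau += dt
                n_steps += 1
                k += 1
                if k % record_every == 0:
                    times.append(t + tau)
                    vols.append(state.volumes.copy())
                    osms.append(state.osmolarities.copy())
        t += schedule.t_blinkcycle
        boundaries.append(state.copy())
    return BlinkSimResult(
        times=np.array(times),
        volumes=np.array(vols),
        osmolarities=np.array(osms),
        cycle_boundary_states=boundaries,
        final_state=state,
        n_steps=n_steps,
    )
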