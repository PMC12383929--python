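"""Suspension-drop species transport through the Q3D tear-film network.

A topically instilled suspension (default: 0.1% dexamethasone, Maxidex®)
carries dissolved drug at the solubility limit plus undissolved particles.
Instillation mixes the drop with the resident tears (the added volume
triggers a reflex blink); volume beyond the ocular holding capacity is lost
to spillover together with its proportional drug mass.  Particles then
dissolve by diffusion-limited shrinking-sphere (Noyes–Whitney, Sherwood
number 2) kinetics, never driving the local concentration above the
solubility limit, while the dissolved phase is advected and diffused along
the Q3D segment network and washed out by nasolacrimal drainage.

Drug amounts are tracked as per-segment *masses* [µg] so that dilution by
secretion and concentration by evaporation fall out of the water balance
automatically; concentrations [µg/mL] are derived from the current segment
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import REGIONS, Q3DMesh

__all__ = [
    "DrugProperties",
    "SpeciesField",
    "DoseEvent",
    "NetworkFlows",
    "build_flows",
    "segment_volumes",
    "instill_dose",
    "dissolution_step",
    "q3d_transport_step",
    "blink_mix_species",
    "region_average_concentration",
]

_BOLTZMANN = 1.380649e-23


def stokes_einstein_diffusivity(
    MW: float, T: float = 308.15, viscosity: float = 7.2e-4
) -> float:
    """Estimate aqueous diffusivity [m²/s] from molecular weight.

    Hydrodynamic radius from the molar volume of a sphere at density
    ~1.3 g/cm³; T defaults to ocular surface temperature (35 °C) with the
    corresponding water viscosity.
    """
    v_m3 = MW * 1e-3 / (1300.0 * 6.02214076e23)  # molecular volume
    r_h = (3.0 * v_m3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return _BOLTZMANN * T / (6.0 * np.pi * viscosity * r_h)


@dataclass(frozen=True)
class DrugProperties:
    """Formulation and drug inputs (defaults: Maxidex® 0.1% dexamethasone).

    C_formulation [mg/mL] total drug concentration of the suspension;
    Cs [µg/mL] solubility limit in tears (excipient-enhanced); M_drug [mg]
    instilled drug mass; rho [kg/m³] solid drug density; K_D distribution
    coefficient at the tear–epithelium interface; r_particle [µm] mean
    suspension particle radius; diffusivity [m²/s] of dissolved drug in
    tears (Stokes–Einstein estimate from MW if not given).
    """

    C_formulation: float = 1.0
    Cs: float = 100.0
    logP: float = 1.83
    M_drug: float = 0.035
    MW: float = 392.5
    rho: float = 1300.0
    K_D: float = 2.5
    r_particle: float = 1.5
    diffusivity: float | None = None

    def __post_init__(self) -> None:
        for name in ("C_formulation", "Cs", "M_drug", "MW", "rho", "K_D",
                     "r_particle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.Cs >= self.C_formulation * 1000.0:
            raise ValueError(
                "not a suspension: solubility Cs must be below the "
                "formulation concentration"
            )
        if self.diffusivity is None:
            object.__setattr__(
                self, "diffusivity", stokes_einstein_diffusivity(self.MW)
            )

    @property
    def dose_volume_uL(self) -> float:
        """Drop volume implied by M_drug / C_formulation [µL]."""
        return self.M_drug / self.C_formulation * 1000.0

    @property
    def dose_mass_ug(self) -> float:
        return self.M_drug * 1000.0


@dataclass
class SpeciesField:
    """Dissolved and particulate drug over the Q3D segments, plus sinks.

    ``dissolved_ug``/``particle_ug`` are per-segment masses [µg];
    ``particle_radius_um`` the (monodisperse) particle radius per segment.
    ``sinks`` accumulate drained, spilled and absorbed mass [µg];
    ``instilled_ug`` closes the global balance.
    """

    dissolved_ug: np.ndarray
    particle_ug: np.ndarray
    particle_radius_um: np.ndarray
    sinks: dict[str, float] = field(
        default_factory=lambda: {"drained": 0.0, "spilled": 0.0, "absorbed": 0.0}
    )
    instilled_ug: float = 0.0

    @classmethod
    def zeros(cls, mesh: Q3DMesh) -> "SpeciesField":
        n = mesh.n_segments
        return cls(
            dissolved_ug=np.zeros(n),
            particle_ug=np.zeros(n),
            particle_radius_um=np.zeros(n),
        )

    def copy(self) -> "SpeciesField":
        return replace(
            self,
            dissolved_ug=self.dissolved_ug.copy(),
            particle_ug=self.particle_ug.copy(),
            particle_radius_um=self.particle_radius_um.copy(),
            sinks=dict(self.sinks),
        )

    def concentrations(self, volumes_uL: np.ndarray) -> np.ndarray:
        """Per-segment dissolved concentration [µg/mL]."""
        v = np.asarray(volumes_uL, dtype=float)
        return np.where(v > 0, self.dissolved_ug / (v * 1e-3), 0.0)

    @property
    def total_mass_ug(self) -> float:
        """Surface-resident + sink drug mass [µg]."""
        return float(
            self.dissolved_ug.sum()
            + self.particle_ug.sum()
            + sum(self.sinks.values())
        )


@dataclass(frozen=True)
class DoseEvent:
    """A topical instillation event.

    ``allocation`` selects where the drop volume lands before mixing:
    ``"basal_ratios"`` spreads it over tear film and menisci per their basal
    volume ratios (default); ``"lower_fornical_sac"`` models a drop placed
    in the lower cul-de-sac.
    """

    time_s: float
    volume_uL: float
    drug_mass_ug: float
    osmolarity: float = 302.0
    allocation: str = "basal_ratios"

    def __post_init__(self) -> None:
        if self.volume_uL < 0 or self.drug_mass_ug < 0:
            raise ValueError("dose volume and mass must be non-negative")

    @classmethod
    def from_formulation(
        cls, drug: DrugProperties, time_s: float = 0.0, **kw
    ) -> "DoseEvent":
        ev = cls(
            time_s=time_s,
            volume_uL=drug.dose_volume_uL,
            drug_mass_ug=drug.dose_mass_ug,
            **kw,
        )
        c_mg_mL = ev.drug_mass_ug / 1000.0 / (ev.volume_uL / 1000.0)
        if abs(c_mg_mL - drug.C_formulation) > 1e-9 * drug.C_formulation:
            raise ValueError("dose volume/mass inconsistent with formulation")
        return ev


def segment_volumes(mesh: Q3DMesh, region_volumes_uL: np.ndarray) -> np.ndarray:
    """Current segment volumes [µL]: basal partition scaled per region."""
    out = np.empty(mesh.n_segments)
    for r_idx, region in enumerate(REGIONS):
        idx = mesh.region_indices(region)
        basal = np.array([mesh.segments[i].volume for i in idx])
        out[idx] = basal / basal.sum() * region_volumes_uL[r_idx]
    return out


def instill_dose(state, f: SpeciesField, dose: DoseEvent, V_max: float,
                 mesh: Q3DMesh, drug: DrugProperties):
    """Apply an instillation with reflex-blink mixing and spillover.

    The drop's solution phase is saturated at ``Cs``; the remainder is
    particulate.  Drop and resident tears pool (uniform dissolved
    concentration, particles spread in proportion to volume); volume above
    ``V_max`` is removed at the post-mixing uniform composition and its drug
    mass credited to the spillover sink; the retained volume is then
    repartitioned across regions by basal ratios.

    Returns the updated ``(state, field)`` pair.
    """
    if dose.volume_uL == 0.0:
        return state, f
    f = f.copy()
    state = state.copy()
    dissolved_in_dose = min(drug.Cs * dose.volume_uL * 1e-3, dose.drug_mass_ug)
    particles_in_dose = dose.drug_mass_ug - dissolved_in_dose
    f.instilled_ug += dose.drug_mass_ug

    V_before = state.total_volume
    V_tot = V_before + dose.volume_uL
    osmoles = state.total_osmoles + dose.volume_uL * dose.osmolarity
    dissolved = f.dissolved_ug.sum() + dissolved_in_dose
    particles = f.particle_ug.sum() + particles_in_dose
    # mass-weighted particle radius of the pooled population
    if particles > 0:
        r_mix = (
            (f.particle_radius_um * f.particle_ug).sum()
            + drug.r_particle * particles_in_dose
        ) / particles
    else:
        r_mix = 0.0

    excess = max(0.0, V_tot - V_max)
    keep = 1.0 - excess / V_tot
    state.spilled_uL += excess
    state.spilled_osmoles += (1.0 - keep) * osmoles
    f.sinks["spilled"] += (1.0 - keep) * (dissolved + particles)

    V_keep = V_tot * keep
    ratios = np.array(
        [mesh.geometry.basal_volume_ratios[r] for r in REGIONS]
    )
    state.volumes = V_keep * ratios
    state.osmolarities = np.full(len(REGIONS), osmoles * keep / V_keep)

    seg_v = segment_volumes(mesh, state.volumes)
    f.dissolved_ug = dissolved * keep * seg_v / seg_v.sum()
    f.particle_ug = particles * keep * seg_v / seg_v.sum()
    f.particle_radius_um = np.where(f.particle_ug > 0, r_mix, 0.0)
    return state, f


def dissolution_step(
    f: SpeciesField,
    dt: float,
    drug: DrugProperties,
    volumes_uL: np.ndarray,
) -> SpeciesField:
    """Diffusion-limited shrinking-sphere dissolution over one step.

    Per segment, N monodisperse particles of radius r dissolve at
    dM/dt = N·4πrD·(Cs − C); with N = M/(4/3 πρr³) this is
    dM/dt = 3 M D (Cs − C)/(ρ r²).  The transfer is capped so the dissolved
    concentration never exceeds Cs and the particulate mass never goes
    negative; the radius then shrinks as r ∝ M^(1/3) at fixed N.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = f.copy()
    v_mL = np.asarray(volumes_uL, dtype=float) * 1e-3
    C = f.concentrations(volumes_uL)
    m = f.particle_ug
    r_m = f.particle_radius_um * 1e-6
    active = (m > 0) & (r_m > 0) & (C < drug.Cs) & (v_mL > 0)
    if not np.any(active):
        return f
    # 1e-3 folds µg/mL -> µg/m³ (×1e6) against m³->mL bookkeeping (×1e-9·…)
    rate = np.zeros_like(m)
    rate[active] = (
        3.0 * m[active] * drug.diffusivity * (drug.Cs - C[active]) * 1e-3
        / (drug.rho * r_m[active] ** 2)
    )
    transfer = np.minimum(rate * dt, m)
    transfer = np.minimum(transfer, np.maximum(drug.Cs - C, 0.0) * v_mL)
    m_new = m - transfer
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(m > 0, (m_new / np.maximum(m, 1e-300)) ** (1.0 / 3.0), 0.0)
    f.particle_radius_um = f.particle_radius_um * shrink
    f.particle_ug = m_new
    f.dissolved_ug = f.dissolved_ug + transfer
    return f


@dataclass(frozen=True)
class NetworkFlows:
    """Volumetric flows on the Q3D network [µL/s].

    ``edges`` maps (upstream index, downstream index) to a non-negative
    flow; ``drain`` maps canaliculus label to the withdrawal flow from the
    meniscus cell carrying that entry node.
    """

    edges: dict[tuple[int, int], float]
    drain: dict[str, float]


def build_flows(
    mesh: Q3DMesh,
    Q_lacrimal_uL_min: float,
    drainage_uL_min: tuple[float, float],
) -> NetworkFlows:
    """Steady interblink routing: secretion → sacs → menisci → canaliculi.

    Secretion splits equally between the sac chains and passes through to
    the menisci; drainage withdraws from the meniscus cells.  Tear-film
    cells carry no net advective flow (their volume changes only by
    evaporation, which is water-only).
    """
    s_half = Q_lacrimal_uL_min / 60.0 / 2.0
    q = {"upper": drainage_uL_min[0] / 60.0, "lower": drainage_uL_min[1] / 60.0}
    edges: dict[tuple[int, int], float] = {}
    for region, can in (
        ("upper_fornical_sac", "upper"),
        ("lower_fornical_sac", "lower"),
    ):
        chain = mesh.region_indices(region)
        men = mesh.region_indices(f"{can}_meniscus")[0]
        for a, b in zip(chain[:-1], chain[1:]):
            edges[(a, b)] = s_half
        edges[(chain[-1], men)] = s_half
    return NetworkFlows(edges=edges, drain=q)


def _meniscus_cell(mesh: Q3DMesh, canaliculus: str) -> int:
    for s in mesh.segments:
        if s.canaliculus == canaliculus:
            return s.index
    raise ValueError(f"mesh has no {canaliculus} canaliculus entry cell")


def q3d_transport_step(
    f: SpeciesField,
    mesh: Q3DMesh,
    flows: NetworkFlows,
    diffusivity: float,
    dt: float,
    volumes_uL: np.ndarray,
    particles_drain: bool = True,
) -> SpeciesField:
    """One finite-volume convective–diffusive update of the species field.

    Upwind advection along the segment connectivity plus Fickian exchange
    between neighbours (transverse directions are well-mixed by the Q3D
    reduction).  Drained flow carries dissolved drug — and, by default,
    particles — to the drainage sink.  Explicit update with CFL
    substepping; a negative mass after the update aborts (scheme guard).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    f = f.copy()
    v = np.asarray(volumes_uL, dtype=float)
    v_mL = v * 1e-3
    D_mm2 = diffusivity * 1e6  # m²/s -> mm²/s
    # diffusive conductances [µL/s] between neighbours
    diff_edges = []
    for s in mesh.segments:
        for j in s.downstream:
            nb = mesh.segments[j]
            A = 0.5 * (s.area + nb.area)
            L = 0.5 * (s.length + nb.length)
            diff_edges.append((s.index, j, D_mm2 * A / L))

    outflow = np.zeros(mesh.n_segments)
    for (i, _j), Q in flows.edges.items():
        outflow[i] += Q
    for can, Q in flows.drain.items():
        outflow[_meniscus_cell(mesh, can)] += Q
    for i, j, G in diff_edges:  # diffusive exchange also bounds the step
        outflow[i] += G
        outflow[j] += G
    with np.errstate(divide="ignore"):
        cfl = np.where(outflow > 0, v / np.maximum(outflow, 1e-300), np.inf)
    n_sub = max(1, int(np.ceil(dt / max(0.5 * float(cfl.min()), 1e-9))))
    h = dt / n_sub

    for _ in range(n_sub):
        c = np.where(v_mL > 0, f.dissolved_ug / np.maximum(v_mL, 1e-300), 0.0)
        cp = np.where(v_mL > 0, f.particle_ug / np.maximum(v_mL, 1e-300), 0.0)
        dM = np.zeros_like(c)
        dP = np.zeros_like(c)
        for (i, j), Q in flows.edges.items():
            adv_d = Q * 1e-3 * c[i]  # µL/s × mL/µL × µg/mL -> µg/s
            adv_p = Q * 1e-3 * cp[i]
            dM[i] -= adv_d
            dM[j] += adv_d
            dP[i] -= adv_p
            dP[j] += adv_p
        for i, j, G in diff_edges:
            flux = G * 1e-3 * (c[i] - c[j])
            dM[i] -= flux
            dM[j] += flux
        for can, Q in flows.drain.items():
            i = _meniscus_cell(mesh, can)
            out_d = Q * 1e-3 * c[i]
            dM[i] -= out_d
            f.sinks["drained"] += h * out_d
            if particles_drain:
                out_p = Q * 1e-3 * cp[i]
                dP[i] -= out_p
                f.sinks["drained"] += h * out_p
        f.dissolved_ug = f.dissolved_ug + h * dM
        f.particle_ug = f.particle_ug + h * dP
        if np.any(f.dissolved_ug < -1e-9) or np.any(f.particle_ug < -1e-9):
            raise RuntimeError(
                "negative species mass after transport update — CFL guard "
                f"failed (min dissolved {f.dissolved_ug.min():.3e} µg)"
            )
        np.clip(f.dissolved_ug, 0.0, None, out=f.dissolved_ug)
        np.clip(f.particle_ug, 0.0, None, out=f.particle_ug)
    return f


def blink_mix_species(f: SpeciesField, volumes_uL: np.ndarray) -> SpeciesField:
    """Complete blink mixing: spread both phases in proportion to volume."""
    f = f.copy()
    v = np.asarray(volumes_uL, dtype=float)
    vtot = v.sum()
    if vtot <= 0:
        return f
    w = v / vtot
    m_p = f.particle_ug.sum()
    if m_p > 0:
        r_mix = (f.particle_radius_um * f.particle_ug).sum() / m_p
    else:
        r_mix = 0.0
    f.dissolved_ug = f.dissolved_ug.sum() * w
    f.particle_ug = m_p * w
    f.particle_radius_um = np.where(f.particle_ug > 0, r_mix, 0.0)
    return f


def region_average_concentration(
    f: SpeciesField,
    mesh: Q3DMesh,
    region: str,
    volumes_uL: np.ndarray | None = None,
) -> float:
    """Volume-weighted mean dissolved concentration [µg/mL] over a region.

    ``region`` is one of :data:`tearsim.geometry.REGIONS` or ``"tear_all"``
    for the average over every tear region (the validation profile).
    """
    if region == "tear_all":
        idx = list(range(mesh.n_segments))
    else:
        idx = mesh.region_indices(region)
    if not idx:
        raise ValueError(f"region {region!r} has no segments")
    v = (
        np.asarray(volumes_uL, dtype=float)
        if volumes_uL is not None
        else mesh.volumes()
    )
    v_sel = v[idx]
    if v_sel.sum() <= 0:
        raise ValueError(f"region {region!r} has zero volume")
    return float(f.dissolved_ug[idx].sum() / (v_sel.sum() * 1e-3))
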