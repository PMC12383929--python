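"""Instillation/spillover, dissolution kinetics, and Q3D species transport."""

import numpy as np
import pytest

from tearsim.blink import CompartmentState
from tearsim.geometry import REGIONS
from tearsim.transport import (
    DoseEvent,
    DrugProperties,
    NetworkFlows,
    SpeciesField,
    blink_mix_species,
    build_flows,
    dissolution_step,
    instill_dose,
    q3d_transport_step,
    region_average_concentration,
    segment_volumes,
)


def basal_state(geometry, total=None):
    state = CompartmentState.basal(geometry)
    if total is not None:
        state.volumes = state.volumes / state.total_volume * total
    return state


class TestDose:
    def test_formulation_drop_volume_and_mass(self, drug):
        ev = DoseEvent.from_formulation(drug)
        assert ev.volume_uL == pytest.approx(35.0)
        assert ev.drug_mass_ug == pytest.approx(35.0)

    def test_spillover_uniform_mixing_balance(self, geometry, mesh, drug):
        # 35 µL drop onto a 7.16 µL resident film, 25 µL capacity:
        # retained mass fraction is V_max / (V_basal + V_dose)
        state = basal_state(geometry, total=7.16)
        field = SpeciesField.zeros(mesh)
        ev = DoseEvent.from_formulation(drug)
        state, field = instill_dose(state, field, ev, 25.0, mesh, drug)
        assert state.total_volume == pytest.approx(25.0, rel=1e-12)
        retained = field.dissolved_ug.sum() + field.particle_ug.sum()
        assert retained == pytest.approx(35.0 * 25.0 / 42.16, rel=1e-9)
        assert field.sinks["spilled"] == pytest.approx(
            35.0 * (1 - 25.0 / 42.16), rel=1e-9
        )
        assert field.total_mass_ug == pytest.approx(field.instilled_ug, rel=1e-12)

    def test_small_dose_fully_retained(self, geometry, mesh, drug):
        state = basal_state(geometry)  # 17.37 µL basal
        field = SpeciesField.zeros(mesh)
        ev = DoseEvent(time_s=0.0, volume_uL=5.0, drug_mass_ug=5.0)
        state, field = instill_dose(state, field, ev, 25.0, mesh, drug)
        assert field.sinks["spilled"] == 0.0
        total = field.dissolved_ug.sum() + field.particle_ug.sum()
        assert total == pytest.approx(5.0, rel=1e-12)

    def test_zero_volume_dose_is_noop(self, geometry, mesh, drug):
        state = basal_state(geometry)
        field = SpeciesField.zeros(mesh)
        ev = DoseEvent(time_s=0.0, volume_uL=0.0, drug_mass_ug=0.0)
        s2, f2 = instill_dose(state, field, ev, 25.0, mesh, drug)
        assert np.array_equal(s2.volumes, state.volumes)
        assert f2.total_mass_ug == 0.0

    def test_suspension_condition_enforced(self):
        with pytest.raises(ValueError, match="suspension"):
            DrugProperties(Cs=2000.0)


class TestDissolution:
    def test_no_flux_at_saturation(self, mesh, drug):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.particle_ug[:] = 1.0
        field.particle_radius_um[:] = drug.r_particle
        field.dissolved_ug = drug.Cs * v * 1e-3  # C = Cs everywhere
        out = dissolution_step(field, 1.0, drug, v)
        assert np.allclose(out.particle_ug, field.particle_ug)
        assert np.allclose(out.dissolved_ug, field.dissolved_ug)

    def test_infinite_sink_r_squared_decays_linearly(self, mesh, drug):
        """Closed form for Sherwood-2 kinetics: r² = r0² − 2·D·Cs·t/ρ."""
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.particle_ug[0] = 1.0
        field.particle_radius_um[0] = drug.r_particle
        dt, t_end = 0.01, 8.0
        steps = int(t_end / dt)
        for _ in range(steps):
            field = dissolution_step(field, dt, drug, v)
            field.dissolved_ug[:] = 0.0  # pin C at zero (infinite sink)
        r0 = drug.r_particle * 1e-6
        r2_exact = r0**2 - 2.0 * drug.diffusivity * drug.Cs * 1e-3 * t_end / drug.rho
        assert (field.particle_radius_um[0] * 1e-6) ** 2 == pytest.approx(
            r2_exact, rel=0.01
        )

    def test_concentration_capped_at_solubility(self, mesh, drug):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.particle_ug[:] = 100.0  # far more than the fluid can dissolve
        field.particle_radius_um[:] = drug.r_particle
        for _ in range(200):
            field = dissolution_step(field, 1.0, drug, v)
        conc = field.concentrations(v)
        assert np.all(conc <= drug.Cs + 1e-9)
        assert conc.max() == pytest.approx(drug.Cs, rel=1e-6)

    def test_mass_moves_between_phases_only(self, mesh, drug):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.particle_ug[:] = 5.0
        field.particle_radius_um[:] = drug.r_particle
        total0 = field.total_mass_ug
        for _ in range(50):
            field = dissolution_step(field, 0.5, drug, v)
        assert field.total_mass_ug == pytest.approx(total0, rel=1e-12)


class TestQ3DTransport:
    def test_zero_flow_zero_diffusion_is_noop(self, mesh):
        field = SpeciesField.zeros(mesh)
        field.dissolved_ug[:] = np.arange(mesh.n_segments, dtype=float)
        flows = NetworkFlows(edges={}, drain={"upper": 0.0, "lower": 0.0})
        out = q3d_transport_step(field, mesh, flows, 0.0, 1.0, mesh.volumes())
        assert np.allclose(out.dissolved_ug, field.dissolved_ug)

    def test_closed_network_conserves_mass(self, mesh):
        field = SpeciesField.zeros(mesh)
        field.dissolved_ug[:] = np.linspace(0.1, 2.0, mesh.n_segments)
        field.particle_ug[:] = 0.5
        field.particle_radius_um[:] = 1.5
        flows = build_flows(mesh, Q_lacrimal_uL_min=1.0, drainage_uL_min=(0, 0))
        flows = NetworkFlows(edges=flows.edges, drain={"upper": 0.0, "lower": 0.0})
        total0 = field.total_mass_ug
        out = field
        for _ in range(50):
            out = q3d_transport_step(out, mesh, flows, 5e-10, 1.0, mesh.volumes())
        assert out.total_mass_ug == pytest.approx(total0, rel=1e-9)

    def test_drained_flow_carries_drug_to_sink(self, mesh):
        field = SpeciesField.zeros(mesh)
        field.dissolved_ug[:] = 1.0
        flows = build_flows(mesh, Q_lacrimal_uL_min=0.0, drainage_uL_min=(0.5, 0.5))
        total0 = field.total_mass_ug
        out = field
        for _ in range(60):
            out = q3d_transport_step(out, mesh, flows, 0.0, 1.0, mesh.volumes())
        assert out.sinks["drained"] > 0.0
        assert out.total_mass_ug == pytest.approx(total0, rel=1e-9)

    def test_well_mixed_limit_matches_one_compartment_oracle(self, mesh):
        """Huge diffusivity collapses the network onto a single stirred tank.

        Oracle: dM/dt = −Q_drain·M/V_total, i.e. exponential washout.
        """
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        M0 = 10.0
        field.dissolved_ug[:] = M0 * v / v.sum()
        q = 0.5  # µL/min per canaliculus
        flows = build_flows(mesh, Q_lacrimal_uL_min=1.0, drainage_uL_min=(q, q))
        t_end, dt = 120.0, 1.0
        out = field
        for _ in range(int(t_end / dt)):
            out = q3d_transport_step(out, mesh, flows, 1e-5, dt, v)
        M_exact = M0 * np.exp(-2 * q / 60.0 * t_end / v.sum())
        M_num = out.dissolved_ug.sum()
        assert M_num == pytest.approx(M_exact, rel=5e-3)
        # near-uniform up to the drain/diffusion conductance ratio
        conc = out.concentrations(v)
        assert conc.std() / conc.mean() < 0.05


class TestRegionAverage:
    def test_uniform_field_returns_itself(self, mesh):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.dissolved_ug = 42.0 * v * 1e-3
        for region in REGIONS:
            assert region_average_concentration(
                field, mesh, region, v
            ) == pytest.approx(42.0)

    def test_equal_volume_mean(self, mesh):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes().copy()
        idx = mesh.region_indices("upper_fornical_sac")
        v[idx] = 1.0
        field.dissolved_ug[idx[0]] = 0.0
        field.dissolved_ug[idx[1]] = 100.0 * 1.0 * 1e-3
        assert region_average_concentration(
            field, mesh, "upper_fornical_sac", v
        ) == pytest.approx(50.0)

    def test_volume_weighted_mean(self, mesh):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes().copy()
        idx = mesh.region_indices("upper_fornical_sac")
        v[idx] = [1.0, 3.0]
        field.dissolved_ug[idx[0]] = 40.0 * 1.0 * 1e-3
        field.dissolved_ug[idx[1]] = 80.0 * 3.0 * 1e-3
        assert region_average_concentration(
            field, mesh, "upper_fornical_sac", v
        ) == pytest.approx(70.0)

    def test_unknown_region_errors(self, mesh):
        field = SpeciesField.zeros(mesh)
        with pytest.raises(ValueError):
            region_average_concentration(field, mesh, "nowhere")

    def test_blink_mixing_commutes_with_averaging(self, mesh):
        field = SpeciesField.zeros(mesh)
        v = mesh.volumes()
        field.dissolved_ug[:] = np.linspace(0.0, 1.0, mesh.n_segments)
        global_avg = region_average_concentration(field, mesh, "tear_all", v)
        mixed = blink_mix_species(field, v)
        for region in REGIONS:
            assert region_average_concentration(
                mixed, mesh, region, v
            ) == pytest.approx(global_avg, rel=1e-12)


def test_segment_volumes_scale_with_region_state(mesh, geometry):
    vols = np.array([geometry.region_volumes[r] for r in REGIONS]) * 2.0
    seg_v = segment_volumes(mesh, vols)
    assert seg_v.sum() == pytest.approx(2.0 * geometry.total_basal_volume)
    tf = mesh.region_indices("tear_film")
    assert seg_v[tf].sum() == pytest.approx(2.0 * geometry.V_TF0)
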