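"""Transport engine: grid construction, implicit stepping, boundary
attachment, dissolution bookkeeping, conservation and the Mason–Weaver
analytic equilibrium."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dgdose as dg
from conftest import small_scenario


class TestGrid:
    def test_case_study_grid_has_600_compartments(self):
        grid = dg.build_grid(0.3, 0.0005)
        assert grid.n == 600
        assert grid.total_height == pytest.approx(0.3, rel=1e-12)

    def test_single_compartment(self):
        assert dg.build_grid(0.3, 0.3).n == 1

    def test_non_divisible_heights_rejected(self):
        with pytest.raises(dg.ScenarioError, match="not an integer multiple"):
            dg.build_grid(0.3, 0.0007)

    def test_graded_grid_sums_to_column(self):
        grid = dg.graded_grid(0.3, 40, ratio=1.1)
        assert grid.total_height == pytest.approx(0.3, rel=1e-12)
        assert grid.heights[0] < grid.heights[-1]  # finer near the cells
        assert np.all(grid.heights > 0)


class TestInitialize:
    def test_uniform_start(self):
        scn = small_scenario(c0=0.01)
        state = dg.initialize(scn)
        assert np.allclose(state.C, 0.01)
        assert state.adsorbed.sum() == 0.0
        assert state.dissolved_fraction == 0.0

    def test_initial_dissolved_fraction_splits_mass(self):
        scn = small_scenario(c0=0.01, dissolution=dg.DissolutionSpec(0.1, "none"))
        state = dg.initialize(scn)
        assert np.allclose(state.C, 0.009)
        assert state.dissolved_fraction == 0.1

    def test_volume_fractions_partition_bins(self):
        scn = small_scenario(c0=0.01, diameters_nm=(10.0, 50.0), fractions=(0.25, 0.75))
        state = dg.initialize(scn)
        assert np.allclose(state.C[0], 0.0025)
        assert np.allclose(state.C[1], 0.0075)

    def test_number_weighted_input_converted_to_mass_fractions(self):
        scn = small_scenario(c0=0.01, diameters_nm=(10.0, 20.0), fractions=(8 / 9, 1 / 9))
        # rebuild with number weighting: equal mass in the two bins
        particle = dg.ParticleSpec(
            "user_defined", 4.0, 2.0,
            dg.SizeDistribution((10.0, 20.0), (8 / 9, 1 / 9), "number"))
        scn = dg.validate_scenario(particle, scn.solvent, scn.simulation,
                                   scn.advanced, scn.output)
        state = dg.initialize(scn)
        assert np.allclose(state.C[0], 0.005)
        assert np.allclose(state.C[1], 0.005)


class TestStep:
    def test_no_transport_leaves_state_unchanged(self):
        scn = small_scenario()
        grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
        state = dg.initialize(scn, grid)
        frozen = dg.CoefficientTable(np.array([0.0]), np.array([0.0]))
        before = state.C.copy()
        for _ in range(10):
            dg.step(state, grid, frozen, 10.0)
        assert np.array_equal(state.C, before)

    def test_flat_profile_is_diffusion_equilibrium(self):
        scn = small_scenario(effective_density=1.0)  # neutral buoyancy: S = 0
        grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
        coeffs = dg.build_coefficients(scn)
        assert coeffs.sedimentation[0] == 0.0
        state = dg.initialize(scn, grid)
        for _ in range(50):
            dg.step(state, grid, coeffs, 100.0)
        assert np.allclose(state.C, 0.01, rtol=1e-12)

    def test_settling_moves_mass_downward(self):
        scn = small_scenario(diameters_nm=(500.0,), effective_density=3.0)
        grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
        coeffs = dg.build_coefficients(scn)
        state = dg.initialize(scn, grid)
        dg.step(state, grid, coeffs, 100.0)
        assert state.C[0, 0] > 0.01 > state.C[0, -1]

    def test_mason_weaver_equilibrium_profile(self):
        # 200 nm agglomerate, betaH ~ 1.9: late-time profile vs closed form.
        # Upwind error bound N*(beta*h)^2/2 ~ 0.9% at this resolution.
        scn = small_scenario(diameters_nm=(200.0,), effective_density=1.2,
                             viscosity=0.00081,
                             n=200, dt=60.0, total_h=24.0, interval_min=24 * 60.0)
        res = dg.simulate(scn)
        c = res.snapshots[-1].layer_concentrations[0]
        S = dg.settling_velocity(200e-7, 1.2, 1.0, scn.solvent.viscosity)
        D = dg.diffusion_coefficient(200e-7, scn.temperature_k, scn.solvent.viscosity)
        exact = dg.mason_weaver_layer_means(res.grid.edges, S, D, 0.1, 0.01)
        assert np.max(np.abs(c / exact - 1.0)) < 0.015


class TestAttachment:
    def test_disabled_stickiness_reflects_everything(self):
        scn = small_scenario(diameters_nm=(500.0,), effective_density=3.0, total_h=1.0)
        res = dg.simulate(scn)
        assert res.snapshots[-1].adsorbed.sum() == 0.0
        assert res.snapshots[-1].mass_balance_drift == pytest.approx(0.0, abs=1e-9)

    def _attach_setup(self, K_D):
        scn = small_scenario(diameters_nm=(500.0,), effective_density=3.0,
                             stickiness=True, K_D=K_D)
        grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
        coeffs = dg.build_coefficients(scn)
        state = dg.initialize(scn, grid)
        return scn, grid, coeffs, state

    def test_empty_surface_adsorbs_full_settling_flux(self):
        # [P] << K_D so theta ~ 0: everything arriving at the floor sticks
        scn, grid, coeffs, state = self._attach_setup(K_D=1.0)
        dt = 10.0
        expected = float(coeffs.sedimentation[0]) * 0.01 * dt
        boundary = dg.attach_at_bottom(state, grid, coeffs, scn.advanced, 3.0,
                                       scn.diameters_cm, dt)
        assert boundary.coverage == pytest.approx(0.0, abs=1e-9)
        assert state.adsorbed[0] == pytest.approx(expected, rel=1e-9)

    def test_half_saturation_adsorbs_half_the_flux(self):
        scn, grid, coeffs, state = self._attach_setup(K_D=1.0)
        P = dg.molar_particle_concentration(0.01, 3.0, 250e-7)
        scn2, grid2, coeffs2, state2 = self._attach_setup(K_D=P)
        dt = 10.0
        dg.attach_at_bottom(state, grid, coeffs, scn.advanced, 3.0, scn.diameters_cm, dt)
        b2 = dg.attach_at_bottom(state2, grid2, coeffs2, scn2.advanced, 3.0,
                                 scn2.diameters_cm, dt)
        assert b2.coverage == pytest.approx(0.5, rel=1e-9)
        assert state2.adsorbed[0] == pytest.approx(0.5 * state.adsorbed[0], rel=1e-6)

    def test_adsorbed_pool_is_irreversible_and_monotone(self):
        scn = small_scenario(diameters_nm=(500.0,), effective_density=3.0,
                             stickiness=True, K_D=1e-12, total_h=1.0)
        res = dg.simulate(scn)
        ads = [s.adsorbed.sum() for s in res.snapshots]
        assert all(b >= a for a, b in zip(ads, ads[1:]))
        assert ads[-1] > 0


class TestDissolution:
    def test_none_is_noop(self):
        scn = small_scenario()
        state = dg.initialize(scn)
        before = state.C.copy()
        dg.apply_dissolution(state, dg.DissolutionSpec(), 10.0)
        assert np.array_equal(state.C, before)

    def test_constant_rate_accumulates_linearly(self):
        # 0.01 of the original mass per hour over 24 h -> 0.24 dissolved
        scn = small_scenario(
            total_h=24.0, dt=60.0, interval_min=60.0,
            dissolution=dg.DissolutionSpec(0.0, "constant_per_hour", rate=0.01))
        res = dg.simulate(scn)
        assert res.snapshots[-1].dissolved_fraction == pytest.approx(0.24, rel=1e-9)

    def test_initial_fraction_adds_to_rate(self):
        scn = small_scenario(
            total_h=24.0, dt=60.0, interval_min=60.0,
            dissolution=dg.DissolutionSpec(0.1, "constant_per_hour", rate=0.01))
        res = dg.simulate(scn)
        assert res.snapshots[-1].dissolved_fraction == pytest.approx(0.34, rel=1e-9)

    def test_tabulated_linear_interpolation(self):
        scn = small_scenario(
            total_h=24.0, dt=60.0, interval_min=60.0,
            dissolution=dg.DissolutionSpec(
                0.0, "tabulated", table=((0.0, 0.0), (24.0, 0.5))))
        res = dg.simulate(scn)
        at_12h = [s for s in res.snapshots if s.time_s == pytest.approx(12 * 3600.0)][0]
        assert at_12h.dissolved_fraction == pytest.approx(0.25, rel=1e-9)

    def test_cumulative_fraction_capped_at_one(self):
        scn = small_scenario(
            total_h=24.0, dt=60.0, interval_min=60.0,
            dissolution=dg.DissolutionSpec(0.0, "constant_per_hour", rate=0.1))
        res = dg.simulate(scn)
        assert res.snapshots[-1].dissolved_fraction == pytest.approx(1.0, abs=1e-12)
        assert res.snapshots[-1].layer_concentrations.sum() == pytest.approx(0.0, abs=1e-15)


class TestSimulate:
    def test_snapshot_schedule(self):
        scn = dg.case_study_scenario("GSH-AgNP", 0.005)
        grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
        assert grid.n == 600
        # 24 hourly snapshots expected for the case-study settings
        assert round(scn.total_time_s / scn.output_interval_s) == 24

    def test_zero_concentration_stays_zero(self):
        res = dg.simulate(small_scenario(c0=0.0))
        for snap in res.snapshots:
            assert np.all(snap.layer_concentrations == 0.0)

    def test_linearity_in_initial_concentration(self):
        kw = dict(diameters_nm=(100.0, 300.0), fractions=(0.4, 0.6),
                  effective_density=2.5, total_h=2.0, interval_min=30.0)
        res1 = dg.simulate(small_scenario(c0=0.005, **kw))
        res2 = dg.simulate(small_scenario(c0=0.010, **kw))
        for s1, s2 in zip(res1.snapshots, res2.snapshots):
            assert np.allclose(2.0 * s1.layer_concentrations,
                               s2.layer_concentrations, rtol=1e-12)

    def test_determinism(self):
        scn = small_scenario(diameters_nm=(100.0,), total_h=1.0)
        a = dg.simulate(scn)
        b = dg.simulate(scn)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.layer_concentrations, sb.layer_concentrations)

    def test_non_negative_concentrations_everywhere(self):
        res = dg.simulate(small_scenario(diameters_nm=(500.0,), effective_density=3.0,
                                         total_h=2.0))
        for snap in res.snapshots:
            assert np.all(snap.layer_concentrations >= 0.0)
            assert snap.clamped_mass <= 1e-12 * 0.01 * 0.1


@given(
    c0=st.floats(min_value=1e-4, max_value=0.5),
    d_nm=st.floats(min_value=5.0, max_value=800.0),
    rho_ev=st.floats(min_value=0.8, max_value=10.0),
    k_s=st.floats(min_value=0.0, max_value=0.1),
    k_d=st.floats(min_value=0.0, max_value=0.1),
    f0=st.floats(min_value=0.0, max_value=0.3),
    rate=st.floats(min_value=0.0, max_value=0.05),
    sticky=st.booleans(),
)
@settings(derandomize=True, max_examples=25, deadline=None)
def test_mass_conservation_under_all_mechanisms(c0, d_nm, rho_ev, k_s, k_d, f0,
                                                rate, sticky):
    """Particulate + adsorbed + dissolved mass per area equals the initial
    value within 1e-9 relative at every snapshot, whatever the mechanism mix."""
    scn = small_scenario(
        c0=c0, diameters_nm=(d_nm,), effective_density=rho_ev, k_s=k_s, k_d=k_d,
        dissolution=dg.DissolutionSpec(f0, "constant_per_hour", rate=rate),
        stickiness=sticky, K_D=1e-11 if sticky else None,
    )
    grid = dg.build_grid(scn.column_height_cm, scn.compartment_height_cm)
    res = dg.simulate(scn, grid)
    m0 = c0 * grid.total_height
    for snap in res.snapshots:
        total = (
            float(snap.layer_concentrations.sum(axis=0) @ np.full(grid.n, grid.heights[0]))
            + float(snap.adsorbed.sum())
            + snap.dissolved_fraction * m0
        )
        assert total == pytest.approx(m0, rel=1e-9)
        assert abs(snap.mass_balance_drift) < 1e-9
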