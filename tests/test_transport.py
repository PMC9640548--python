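import numpy as np
import pytest

import pollensim as ps
from pollensim.transport import (BoundaryCondition, ConcentrationState,
                                 TransportConfig, advect_horizontal,
                                 advect_vertical, diffuse_horizontal,
                                 diffuse_vertical_drydep, run_simulation,
                                 step, wet_scavenge)


def column_mass(c, h, area=1.0):
    return float((c * np.asarray(h)[:, None, None]).sum()) * area


class TestHorizontalAdvection:
    def _tophat(self, nx=20):
        c = np.zeros((1, 1, nx))
        c[0, 0, 5:9] = 1.0
        return c

    def test_exact_translation_at_unit_courant(self):
        c = self._tophat()
        dx, u = 100.0, 2.0
        dt = dx / u  # Courant number exactly 1
        out, _, _ = advect_horizontal(c, np.full_like(c, u), np.zeros_like(c),
                                      dx, dx, dt, h=[1.0])
        assert np.allclose(out[0, 0], np.roll(c[0, 0], 1))

    def test_no_new_extrema_below_unit_courant(self):
        c = self._tophat()
        dx, u = 100.0, 2.0
        out, _, _ = advect_horizontal(c, np.full_like(c, u), np.zeros_like(c),
                                      dx, dx, 0.5 * dx / u, h=[1.0])
        assert out.min() >= c.min() - 1e-15
        assert out.max() <= c.max() + 1e-15

    def test_uniform_field_with_zero_gradient_unchanged(self):
        """Uniform concentration matching the BC value is a steady state."""
        c = np.full((2, 4, 5), 3.0)
        u = np.full_like(c, 1.5)
        out, fin, fout = advect_horizontal(c, u, -u, 500.0, 500.0, 100.0,
                                           h=[10.0, 20.0], bc_value=3.0)
        assert np.allclose(out, 3.0)

    def test_zero_winds_identity(self):
        c = np.random.default_rng(0).random((2, 3, 4))
        out, fin, fout = advect_horizontal(c, np.zeros_like(c), np.zeros_like(c),
                                           100.0, 100.0, 50.0, h=[1.0, 2.0])
        assert np.array_equal(out, c)
        assert fin == fout == 0.0

    def test_mass_change_equals_net_boundary_flux(self):
        rng = np.random.default_rng(1)
        c = rng.random((3, 6, 7))
        u = rng.normal(0, 2, size=c.shape)
        v = rng.normal(0, 2, size=c.shape)
        h = [60.0, 90.0, 250.0]
        dx = dy = 1000.0
        out, fin, fout = advect_horizontal(c, u, v, dx, dy, 200.0, h,
                                           bc_value=0.5)
        m0 = column_mass(c, h, dx * dy)
        m1 = column_mass(out, h, dx * dy)
        assert m1 - m0 == pytest.approx(fin - fout, rel=1e-12, abs=1e-9)

    def test_positivity_with_automatic_substepping(self):
        rng = np.random.default_rng(2)
        c = rng.random((1, 5, 5))
        u = np.full_like(c, 30.0)  # Courant >> 1 at dt = 3600
        out, _, _ = advect_horizontal(c, u, u, 1000.0, 1000.0, 3600.0, [1.0])
        assert out.min() >= 0.0

    def test_non_finite_winds_rejected(self):
        c = np.ones((1, 2, 2))
        u = np.full_like(c, np.nan)
        with pytest.raises(ValueError):
            advect_horizontal(c, u, u, 100.0, 100.0, 10.0, [1.0])


class TestVerticalAdvection:
    def test_settling_conserves_column_plus_deposit(self):
        h = [50.0, 70.0, 180.0]
        c = np.zeros((3, 1, 1))
        c[2] = 10.0  # mass starts in layer 3
        out, dep = advect_vertical(c, np.zeros_like(c), 0.02, h, 3600.0)
        before = column_mass(c, h)
        after = column_mass(out, h) + float(dep.sum())
        assert after == pytest.approx(before, rel=1e-12)

    def test_updraft_cancels_settling(self):
        h = [50.0, 70.0, 180.0]
        c = np.random.default_rng(3).random((3, 1, 1))
        w = np.full_like(c, 0.02)
        out, dep = advect_vertical(c, w, 0.02, h, 3600.0)
        assert np.allclose(out, c)
        assert np.all(dep == 0.0)

    def test_long_time_settling_drains_the_column(self):
        h = [50.0, 70.0, 180.0]
        c = np.ones((3, 1, 1))
        dep_total = np.zeros((1, 1))
        for _ in range(200):  # 200 h of 2 cm/s settling through 300 m
            c, dep = advect_vertical(c, np.zeros_like(c), 0.02, h, 3600.0)
            dep_total += dep
        assert column_mass(c, h) < 1e-6 * float(dep_total.sum())

    def test_settling_only_column_matches_closed_form(self):
        """Single well-mixed layer, fine sub-steps: deposited fraction
        approaches 1 - exp(-v_s t / h)."""
        h = [60.0]
        v_s = 0.0236
        c = np.ones((1, 1, 1))
        n, dt = 3600, 1.0  # one hour in 1 s steps
        for _ in range(n):
            c, _ = advect_vertical(c, np.zeros_like(c), v_s, h, dt)
        expected = np.exp(-v_s * n * dt / h[0])
        assert c[0, 0, 0] == pytest.approx(expected, abs=1e-3)


class TestHorizontalDiffusion:
    def test_uniform_unchanged(self):
        c = np.full((1, 4, 4), 2.5)
        out = diffuse_horizontal(c, 50.0, 100.0, 100.0, 3600.0)
        assert np.allclose(out, 2.5)

    def test_point_mass_conserved_on_closed_domain(self):
        c = np.zeros((1, 9, 9))
        c[0, 4, 4] = 100.0
        out = diffuse_horizontal(c, 200.0, 500.0, 500.0, 3600.0)
        assert out.sum() == pytest.approx(100.0, rel=1e-12)
        assert out.min() >= 0.0
        assert out.var() <= c.var()

    def test_two_box_geometric_decay(self):
        k, dx, dt = 10.0, 100.0, 50.0  # stable without sub-stepping
        c = np.array([[[1.0, 0.0]]])
        out = diffuse_horizontal(c, k, dx, dx, dt)
        factor = 1 - 2 * k * dt / dx**2
        diff0 = c[0, 0, 0] - c[0, 0, 1]
        assert out[0, 0, 0] - out[0, 0, 1] == pytest.approx(diff0 * factor, rel=1e-12)

    def test_negative_diffusivity_rejected(self):
        with pytest.raises(ValueError):
            diffuse_horizontal(np.ones((1, 2, 2)), -1.0, 100.0, 100.0, 10.0)


class TestVerticalDiffusionDryDep:
    def test_identity_with_everything_off(self):
        c = np.random.default_rng(4).random((3, 2, 2))
        out, dep = diffuse_vertical_drydep(c, 0.0, 0.0, [60.0, 90.0, 250.0], 3600.0)
        assert np.allclose(out, c)
        assert np.all(dep == 0.0)

    def test_single_box_implicit_decay(self):
        h, v_d, dt = 60.0, 0.02, 3600.0
        c = np.full((1, 1, 1), 10.0)
        out, dep = diffuse_vertical_drydep(c, 0.0, v_d, [h], dt)
        assert out[0, 0, 0] == pytest.approx(10.0 / (1 + v_d * dt / h), rel=1e-12)
        assert dep[0, 0] == pytest.approx(v_d * out[0, 0, 0] * dt, rel=1e-12)

    def test_column_mass_plus_deposit_conserved(self):
        rng = np.random.default_rng(5)
        h = [60.0, 90.0, 250.0, 600.0]
        c = rng.random((4, 3, 3)) * 100
        out, dep = diffuse_vertical_drydep(c, 15.0, 0.0236, h, 3600.0)
        before = column_mass(c, h)
        after = column_mass(out, h) + float(dep.sum())
        assert after == pytest.approx(before, rel=1e-10)
        assert out.min() >= 0.0

    def test_mixing_moves_toward_uniform(self):
        h = [50.0, 50.0]
        c = np.array([[[10.0]], [[0.0]]])
        out, _ = diffuse_vertical_drydep(c, 100.0, 0.0, h, 36000.0)
        assert abs(out[0, 0, 0] - out[1, 0, 0]) < 1.0


class TestWetScavenging:
    def test_no_rain_identity(self):
        c = np.random.default_rng(6).random((2, 3, 3))
        out, wet = wet_scavenge(c, np.zeros((3, 3)), 3600.0, [60.0, 90.0])
        assert np.array_equal(out, c)
        assert np.all(wet == 0.0)

    def test_half_life(self):
        c = np.full((1, 1, 1), 8.0)
        # pick P so that Lambda*dt = ln 2
        a, b, dt = 8.4e-5, 0.79, 3600.0
        p = (np.log(2) / (a * dt)) ** (1 / b)
        out, _ = wet_scavenge(c, np.full((1, 1), p), dt, [60.0], a=a, b=b)
        assert out[0, 0, 0] == pytest.approx(4.0, rel=1e-12)

    def test_survival_fraction_at_ten_mm_per_hour(self):
        c = np.ones((1, 1, 1))
        out, _ = wet_scavenge(c, np.full((1, 1), 10.0), 3600.0, [60.0])
        assert out[0, 0, 0] == pytest.approx(0.155, abs=1e-3)

    def test_scavenged_mass_goes_to_wet_deposit(self):
        h = [60.0, 90.0]
        c = np.random.default_rng(7).random((2, 2, 2))
        out, wet = wet_scavenge(c, np.full((2, 2), 5.0), 3600.0, h)
        lost = column_mass(c, h) - column_mass(out, h)
        assert float(wet.sum()) == pytest.approx(lost, rel=1e-12)


class TestStepAndRun:
    def test_single_process_step_attribution(self, demo_grid, demo_met):
        cfg = TransportConfig(enabled=("EMIS",))
        state = ConcentrationState.zeros(demo_grid)
        tendency = np.full(demo_grid.shape2d, 7.0)
        new, deltas, emitted = step(demo_grid, state, demo_met, tendency,
                                    v_s=0.02, cfg=cfg)
        assert np.allclose(new.c - state.c, deltas["EMIS"])
        assert np.allclose(deltas["EMIS"][0], 7.0)
        assert all(np.all(deltas[p] == 0) for p in deltas if p != "EMIS")

    def test_budget_closure_each_step(self, demo_run):
        err = demo_run.budget.closure_error(demo_run.history)
        assert err < 1e-8

    def test_global_mass_budget(self, demo_run):
        assert demo_run.mass_budget_error() < 1e-8

    def test_zero_emission_zero_bc_stays_zero(self, demo_grid, demo_met):
        res = run_simulation(demo_grid, demo_met,
                             np.zeros((demo_grid.n_hours,) + demo_grid.shape2d),
                             v_s=0.02, keep_budget=False)
        assert np.all(res.history == 0.0)

    def test_linearity_in_emissions(self, demo_grid, demo_met, demo_emission):
        tendency, _, _ = demo_emission
        sub = 120  # hours — enough to see every process act
        g = ps.build_grid(demo_grid.nx, demo_grid.ny, demo_grid.nz,
                          dx=demo_grid.dx, dy=demo_grid.dy,
                          layer_tops=demo_grid.layer_tops, t0=demo_grid.t0,
                          n_hours=sub)
        met = ps.MeteoFields(t2m=demo_met.t2m[:sub], u10=demo_met.u10[:sub],
                             v10=demo_met.v10[:sub], rh=demo_met.rh[:sub],
                             precip=demo_met.precip[:sub], kh=demo_met.kh,
                             kv=demo_met.kv)
        r1 = run_simulation(g, met, tendency[:sub], 0.0236, keep_budget=False)
        r2 = run_simulation(g, met, 2 * tendency[:sub], 0.0236, keep_budget=False)
        assert np.allclose(r2.history, 2 * r1.history, rtol=1e-10, atol=1e-12)
        assert np.allclose(r2.state.dry_dep, 2 * r1.state.dry_dep, rtol=1e-10)
        assert r2.state.outflow == pytest.approx(2 * r1.state.outflow, rel=1e-10)

    def test_closed_domain_budget(self):
        """No winds, no rain: everything emitted is airborne or dry-deposited."""
        g = ps.build_grid(5, 5, 2, dx=1000.0, dy=1000.0,
                          layer_tops=[60.0, 200.0], n_hours=48)
        n = g.n_hours
        met = ps.MeteoFields(t2m=np.full((n, 5, 5), 288.0),
                             u10=np.zeros((n, 5, 5)), v10=np.zeros((n, 5, 5)),
                             rh=np.full((n, 5, 5), 60.0),
                             precip=np.zeros((n, 5, 5)), kh=0.0, kv=5.0)
        tendency = np.full((n, 5, 5), 100.0)
        res = run_simulation(g, met, tendency, 0.0236)
        vol = g.layer_thickness[:, None, None] * g.cell_area
        airborne = float((res.history[-1] * vol).sum())
        dry = float(res.state.dry_dep.sum()) * g.cell_area
        assert res.state.inflow == res.state.outflow == 0.0
        assert res.state.wet_dep.sum() == 0.0
        assert abs(res.emitted - airborne - dry) / res.emitted < 1e-8

    def test_half_step_convergence_monitored(self, demo_grid):
        """Two dt/2 steps vs one dt step, constant drivers: results agree
        within the first-order splitting error (monitored, not exact)."""
        n, ny, nx = demo_grid.n_hours, demo_grid.ny, demo_grid.nx
        met = ps.MeteoFields(t2m=np.full((n, ny, nx), 288.0),
                             u10=np.full((n, ny, nx), 3.0),
                             v10=np.full((n, ny, nx), 1.0),
                             rh=np.full((n, ny, nx), 60.0),
                             precip=np.full((n, ny, nx), 1.0),
                             kh=500.0, kv=10.0).validate(demo_grid)
        state = ConcentrationState.zeros(demo_grid)
        rng = np.random.default_rng(8)
        state.c[:] = rng.random(demo_grid.shape3d) * 50
        tendency = np.full(demo_grid.shape2d, 10.0)
        full, _, _ = step(demo_grid, state, met, tendency, v_s=0.0236,
                          dt=3600.0)
        half1, _, _ = step(demo_grid, state, met, tendency, v_s=0.0236,
                           dt=1800.0)
        half1.hour = 0  # same constant drivers either way
        half2, _, _ = step(demo_grid, half1, met, tendency, v_s=0.0236,
                           dt=1800.0)
        scale = max(np.abs(full.c).max(), 1e-30)
        rel = np.abs(full.c - half2.c).max() / scale
        assert rel < 0.1


class TestBoundaryConditions:
    def test_invalid_bc_rejected(self):
        with pytest.raises(ValueError):
            BoundaryCondition("constant", -1.0)
        with pytest.raises(ValueError):
            BoundaryCondition("nonsense", 0.0)

    def test_zero_vs_zero_no_difference(self, demo_grid, demo_met, demo_emission):
        tendency, _, _ = demo_emission
        sub = 48
        g = ps.build_grid(demo_grid.nx, demo_grid.ny, demo_grid.nz,
                          dx=demo_grid.dx, dy=demo_grid.dy,
                          layer_tops=demo_grid.layer_tops, t0=demo_grid.t0,
                          n_hours=sub)
        met = ps.MeteoFields(t2m=demo_met.t2m[:sub], u10=demo_met.u10[:sub],
                             v10=demo_met.v10[:sub], rh=demo_met.rh[:sub],
                             precip=demo_met.precip[:sub], kh=demo_met.kh,
                             kv=demo_met.kv)
        out = ps.bc_sensitivity_experiment(g, met, tendency[:sub], 0.0236, 0.0)
        assert out["max_abs_difference"] == 0.0

    def test_strong_inflow_approaches_boundary_value(self):
        """Steady inward wind, no sinks: boundary-adjacent cells fill to the BC."""
        g = ps.build_grid(6, 3, 1, dx=1000.0, dy=1000.0, layer_tops=[60.0],
                          n_hours=48)
        n = g.n_hours
        met = ps.MeteoFields(t2m=np.full((n, 3, 6), 288.0),
                             u10=np.full((n, 3, 6), 2.0),
                             v10=np.zeros((n, 3, 6)),
                             rh=np.full((n, 3, 6), 60.0),
                             precip=np.zeros((n, 3, 6)), kh=0.0, kv=0.0)
        res = run_simulation(g, met, np.zeros((n, 3, 6)), v_s=0.0,
                             bc=BoundaryCondition("constant", 10.0),
                             keep_budget=False)
        assert res.history[-1][0, :, 0] == pytest.approx(10.0, rel=1e-6)
        assert res.history.max() <= 10.0 + 1e-9
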