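"""Solver validation against closed-form solutions and conservation laws."""

import numpy as np
import pytest
from scipy.special import erfc

import oxcycle as ox
from oxcycle.solver import _Discretization

D_GEL = 1.87e-5
W = 0.05
PERIOD = 60.0
OMEGA = 2 * np.pi / PERIOD


def run_sinusoid(stack, grid, dt, mean=76.0, amp=38.0, n_periods=10):
    """Drive the bottom with a sinusoid and return the last-cycle gain per node."""
    times = np.arange(0.0, n_periods * PERIOD + 1e-9, dt)
    f = ox.simulate_custom(
        stack, grid, times, ox.SolverSettings(theta=0.5),
        bottom_pressure=lambda t: mean + amp * np.sin(OMEGA * t),
        initial_pressure=mean,
    )
    last = f.values[times >= (n_periods - 1) * PERIOD - 1e-9]
    return (last.max(axis=0) - last.min(axis=0)) / (2 * amp)


class TestSteadyStates:
    def test_uniform_dirichlet_both_ends(self, single_gel_stack):
        grid = ox.build_grid(single_gel_stack, W / 25)
        times = np.arange(0.0, 2000.0, 2.0)
        f = ox.simulate_custom(
            single_gel_stack, grid, times, ox.SolverSettings(),
            bottom_pressure=lambda t: 152.0, top="dirichlet", top_pressure=152.0,
            initial_pressure=152.0,
        )
        np.testing.assert_allclose(f.values, 152.0, rtol=1e-12)

    def test_linear_profile_between_dirichlet_ends(self, single_gel_stack):
        grid = ox.build_grid(single_gel_stack, W / 25)
        times = np.arange(0.0, 4000.0, 2.0)
        f = ox.simulate_custom(
            single_gel_stack, grid, times, ox.SolverSettings(),
            bottom_pressure=lambda t: 152.0, top="dirichlet", top_pressure=0.0,
            initial_pressure=76.0,
        )
        exact = 152.0 * (1.0 - grid.z / W)
        np.testing.assert_allclose(f.values[-1], exact, rtol=1e-6, atol=1e-6)


class TestClosedFormOracles:
    def test_early_time_step_matches_half_space_erfc(self):
        # 2000 um slab behaves as a half-space for t <= 20 s
        W2 = 0.2
        stack = ox.Stack(layers=(ox.Layer("gel", W2, ox.Medium("gel", D_GEL)),))
        grid = ox.build_grid(stack, W2 / 200)
        times = np.arange(0.0, 20.0001, 0.02)
        f = ox.simulate_custom(
            stack, grid, times, ox.SolverSettings(theta=0.5),
            bottom_pressure=lambda t: 152.0 if t > 0 else 0.0,
            initial_pressure=0.0,
        )
        for t_chk in (5.0, 10.0, 20.0):
            k = int(np.argmin(np.abs(times - t_chk)))
            u = f.values[k] / 152.0
            exact = erfc(grid.z / (2 * np.sqrt(D_GEL * times[k])))
            assert np.abs(u - exact).max() < 0.01

    def test_sinusoid_gain_matches_cosh_oracle(self, single_gel_stack):
        grid = ox.build_grid(single_gel_stack, W / 100)
        gains = run_sinusoid(single_gel_stack, grid, dt=PERIOD / 200)
        oracle = np.array(
            [ox.sinusoid_gain(z, OMEGA, D_GEL, W)[0] for z in grid.z]
        )
        assert np.abs(gains - oracle).max() < 0.01

    def test_second_order_spatial_convergence(self, single_gel_stack):
        errs = []
        for n in (25, 50):
            grid = ox.build_grid(single_gel_stack, W / n, min_nodes_per_layer=2)
            gains = run_sinusoid(single_gel_stack, grid, dt=PERIOD / 1600)
            oracle = np.array(
                [ox.sinusoid_gain(z, OMEGA, D_GEL, W)[0] for z in grid.z]
            )
            errs.append(np.abs(gains - oracle).max())
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0  # halving dz cuts the error ~4x


class TestConservationAndBounds:
    def test_mass_conserved_when_sealed(self, single_gel_stack):
        grid = ox.build_grid(single_gel_stack, W / 50)
        times = np.arange(0.0, 10 * PERIOD + 1e-9, 0.1)
        f = ox.simulate_custom(
            single_gel_stack, grid, times, ox.SolverSettings(),
            bottom="no_flux",
            initial_pressure=np.linspace(10.0, 150.0, grid.n_nodes),
        )
        mass = f.values @ _Discretization(grid).cap
        assert np.abs(mass - mass[0]).max() / mass[0] < 1e-8

    def test_maximum_principle_acellular(self, single_gel_stack, osa_schedule):
        f = ox.simulate(single_gel_stack, osa_schedule, duration=120.0)
        assert f.values.min() >= -1e-9
        assert f.values.max() <= 0.2 * 760.0 + 1e-9

    def test_consumption_never_raises_oxygen(self, osa_schedule):
        gel = ox.Medium("gel", D_GEL)
        cell = ox.Stack(layers=(
            ox.Layer("c", W, gel, rho_cell=5e6, sOCR=1.22e-16, K_m=4.1e-6),
        ))
        acell = ox.Stack(layers=(ox.Layer("a", W, gel),))
        fc = ox.simulate(cell, osa_schedule, duration=120.0)
        fa = ox.simulate(acell, osa_schedule, grid=fc.grid, duration=120.0)
        assert np.all(fc.values <= fa.values + 1e-9)

    def test_two_layer_split_equals_single_layer(self, osa_schedule):
        gel = ox.Medium("gel", D_GEL)
        one = ox.Stack(layers=(ox.Layer("g", W, gel),))
        two = ox.Stack(layers=(
            ox.Layer("a", 0.02, gel), ox.Layer("b", 0.03, gel),
        ))
        g1 = ox.build_grid(one, 1e-3, min_nodes_per_layer=2)
        g2 = ox.build_grid(two, 1e-3, min_nodes_per_layer=2)
        f1 = ox.simulate(one, osa_schedule, grid=g1, duration=120.0)
        f2 = ox.simulate(two, osa_schedule, grid=g2, duration=120.0)
        assert np.abs(f1.values - f2.values).max() / 152.0 < 1e-8


class TestMichaelisMentenLimits:
    @pytest.mark.parametrize("km,regime", [(1e-12, "zero"), (1e-3, "first")])
    def test_asymptotic_consumption_profiles(self, km, regime):
        rho, socr = 5e6, 1.22e-16
        gel = ox.Medium("gel", D_GEL)
        stack = ox.Stack(layers=(
            ox.Layer("c", W, gel, rho_cell=rho, sOCR=socr, K_m=km),
        ))
        const = ox.IHSchedule(0.2, 0.2, PERIOD, total_duration=PERIOD)
        f = ox.run_to_periodic_steady_state(
            stack, const, settings=ox.SolverSettings(psss_tol=1e-6)
        )
        u, z, ub = f.values[-1], f.grid.z, 152.0
        a = gel.alpha / 760.0
        if regime == "zero":
            # saturated sink: parabolic depletion profile
            exact = ub - rho * socr / (D_GEL * a) * (W * z - z * z / 2)
        else:
            # dilute regime: first-order cosh profile
            k = np.sqrt(rho * socr / (D_GEL * km))
            exact = ub * np.cosh(k * (W - z)) / np.cosh(k * W)
        assert np.abs(u - exact).max() / ub < 0.02


class TestPeriodicSteadyState:
    def test_constant_schedule_converges_flat(self, single_gel_stack):
        const = ox.IHSchedule(0.2, 0.2, PERIOD, total_duration=PERIOD)
        f = ox.run_to_periodic_steady_state(single_gel_stack, const)
        assert f.cycles <= 3
        pct = f.percent
        np.testing.assert_allclose(pct.max(axis=0), pct.min(axis=0), atol=1e-9)

    def test_amplitude_attenuates_with_depth(self, pss_gel_500, osa_schedule):
        envs = ox.envelope_profile(pss_gel_500, [0.01, 0.04],
                                   period=osa_schedule.period)
        assert envs[1].amplitude > 0
        assert envs[1].amplitude < envs[0].amplitude

    def test_tighter_tolerance_never_fewer_cycles(self, gel_500_stack, osa_schedule):
        cycles = []
        for tol in (1e-3, 2e-3):
            f = ox.run_to_periodic_steady_state(
                gel_500_stack, osa_schedule,
                settings=ox.SolverSettings(psss_tol=tol),
            )
            cycles.append(f.cycles)
        assert cycles[1] <= cycles[0]

    def test_cycle_limit_raises(self, gel_500_stack, osa_schedule):
        with pytest.raises(ox.SolverError):
            ox.run_to_periodic_steady_state(
                gel_500_stack, osa_schedule,
                settings=ox.SolverSettings(psss_max_cycles=2, psss_tol=1e-9),
            )


class TestSampling:
    def test_node_and_time_grid_values_exact(self, pss_gel_500):
        g = pss_gel_500.grid
        j, k = 10, 5
        val = ox.sample_field(pss_gel_500, float(g.z[j]),
                             pss_gel_500.times[k:k + 1])
        assert val[0] == pytest.approx(pss_gel_500.values[k, j], rel=1e-12)

    def test_midpoint_is_arithmetic_mean(self, pss_gel_500):
        g = pss_gel_500.grid
        zmid = 0.5 * (g.z[10] + g.z[11])
        tr = ox.sample_field(pss_gel_500, float(zmid))
        expect = 0.5 * (pss_gel_500.values[:, 10] + pss_gel_500.values[:, 11])
        np.testing.assert_allclose(tr, expect, rtol=1e-12)

    def test_interpolation_bounded_by_neighbours(self, pss_gel_500):
        g = pss_gel_500.grid
        z = 0.3 * g.z[10] + 0.7 * g.z[11]
        tr = ox.sample_field(pss_gel_500, float(z))
        lo = np.minimum(pss_gel_500.values[:, 10], pss_gel_500.values[:, 11])
        hi = np.maximum(pss_gel_500.values[:, 10], pss_gel_500.values[:, 11])
        assert np.all(tr >= lo - 1e-12) and np.all(tr <= hi + 1e-12)

    def test_outside_stack_rejected(self, pss_gel_500):
        with pytest.raises(ValueError):
            ox.sample_field(pss_gel_500, 1.0)
        with pytest.raises(ValueError):
            ox.sample_field(pss_gel_500, -0.1)
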