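"""Flux estimates, envelope statistics, oracles, and design verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxcycle as ox

# collagen-embedded hepatocyte reference set (high-consuming tissue surrogate)
HEPATOCYTE = dict(
    rho_cell=5e5, sOCR=1.22e-16, K_m=4.1e-6,
    W=0.05, D=1.2e-5, alpha=1.1e-6,
)


def hepatocyte_spec(mean_fraction=0.10, delta_P_mmHg=152.0, **over):
    kw = {**HEPATOCYTE, **over}
    return ox.FluxRatioSpec.from_pressures(
        delta_P_mmHg=delta_P_mmHg, mean_fraction=mean_fraction, **kw
    )


class TestFluxes:
    def test_consumption_flux_reference_value(self):
        # rho*sOCR*C*W/(Km+C) at C = alpha*0.1 atm
        assert ox.consumption_flux(hepatocyte_spec()) == pytest.approx(
            7.97e-14, rel=1e-3
        )

    def test_consumption_zero_without_cells(self):
        assert ox.consumption_flux(hepatocyte_spec(rho_cell=0.0)) == 0.0

    def test_consumption_saturates_at_high_concentration(self):
        spec = hepatocyte_spec()
        sat = ox.FluxRatioSpec(**{**HEPATOCYTE, "C_mean": 1.0, "delta_P": 0.2})
        limit = HEPATOCYTE["rho_cell"] * HEPATOCYTE["sOCR"] * HEPATOCYTE["W"]
        assert ox.consumption_flux(sat) == pytest.approx(limit, rel=1e-5)
        assert ox.consumption_flux(spec) < limit

    def test_diffusion_flux_reference_value(self):
        # D*alpha*dP/W with dP = 0.2 atm
        assert ox.diffusion_flux(hepatocyte_spec()) == pytest.approx(
            5.28e-11, rel=1e-6
        )

    def test_diffusion_flux_zero_gradient(self):
        assert ox.diffusion_flux(hepatocyte_spec(delta_P_mmHg=0.0)) == 0.0

    def test_diffusion_flux_inverse_in_thickness(self):
        assert ox.diffusion_flux(hepatocyte_spec(W=0.10)) == pytest.approx(
            0.5 * ox.diffusion_flux(hepatocyte_spec()), rel=1e-12
        )

    def test_flux_ratio_negligible_for_hepatocyte_set(self):
        r = ox.flux_ratio(hepatocyte_spec())
        assert r == pytest.approx(1.51e-3, rel=1e-2)
        assert r <= 0.015  # consumption negligible against diffusion

    def test_flux_ratio_zero_without_cells(self):
        assert ox.flux_ratio(hepatocyte_spec(rho_cell=0.0)) == 0.0

    def test_flux_ratio_quadratic_in_thickness(self):
        assert ox.flux_ratio(hepatocyte_spec(W=0.10)) == pytest.approx(
            4.0 * ox.flux_ratio(hepatocyte_spec()), rel=1e-12
        )

    def test_flux_ratio_undefined_without_gradient(self):
        with pytest.raises(ZeroDivisionError):
            ox.flux_ratio(hepatocyte_spec(delta_P_mmHg=0.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        rho=st.floats(0.0, 1e8),
        socr=st.floats(1e-18, 1e-15),
        km=st.floats(1e-8, 1e-4),
        cmean=st.floats(0.0, 1e-5),
        w=st.floats(0.01, 0.2),
        d=st.floats(1e-6, 1e-4),
        dp=st.floats(0.01, 1.0),
    )
    def test_ratio_equals_flux_quotient(self, rho, socr, km, cmean, w, d, dp):
        spec = ox.FluxRatioSpec(rho_cell=rho, sOCR=socr, K_m=km, C_mean=cmean,
                                W=w, D=d, alpha=1.1e-6, delta_P=dp)
        assert ox.flux_ratio(spec) == pytest.approx(
            ox.consumption_flux(spec) / ox.diffusion_flux(spec), rel=1e-12
        )


class TestEnvelopes:
    def test_constant_field_collapses(self, single_gel_stack):
        const = ox.IHSchedule(0.2, 0.2, 60.0, total_duration=60.0)
        f = ox.run_to_periodic_steady_state(single_gel_stack, const)
        envs = ox.envelope_profile(f, [0.01, 0.03], period=60.0)
        for e in envs:
            assert e.o2_max == pytest.approx(e.o2_min, abs=1e-9)
            assert e.cycle_mean == pytest.approx(e.o2_max, abs=1e-9)

    def test_pure_sinusoid_amplitude_and_mean(self, single_gel_stack):
        grid = ox.build_grid(single_gel_stack, 0.05 / 25)
        times = np.linspace(0.0, 60.0, 601)
        vals = 76.0 + 38.0 * np.sin(2 * np.pi * times / 60.0)
        f = ox.Field(grid=grid, times=times,
                     values=np.tile(vals[:, None], (1, grid.n_nodes)))
        e = ox.envelope_profile(f, [0.01], period=60.0)[0]
        assert e.amplitude == pytest.approx(2 * 38.0 * 100 / 760, rel=1e-3)
        assert e.cycle_mean == pytest.approx(10.0, rel=1e-3)

    def test_amplitude_strictly_decreasing_in_depth(self, pss_gel_500):
        depths = np.array([0.005, 0.015, 0.025, 0.035, 0.045])
        envs = ox.envelope_profile(pss_gel_500, depths, period=60.0)
        amps = [e.amplitude for e in envs]
        assert np.all(np.diff(amps) < 0)

    def test_short_field_rejected(self, single_gel_stack, osa_schedule):
        f = ox.simulate(single_gel_stack, osa_schedule, duration=30.0)
        with pytest.raises(ValueError):
            ox.envelope_profile(f, [0.01], period=60.0)


class TestHomogeneity:
    def test_identical_envelopes_have_zero_spread(self):
        e = ox.Envelope(z=0.01, o2_max=19.0, o2_min=1.0, cycle_mean=10.0)
        e2 = ox.Envelope(z=0.02, o2_max=19.0, o2_min=1.0, cycle_mean=10.0)
        assert ox.homogeneity_metrics([e, e2]) == (0.0, 0.0, True)

    def test_spread_is_range_of_maxima(self):
        envs = [
            ox.Envelope(z=0.01, o2_max=19.0, o2_min=1.0, cycle_mean=10.0),
            ox.Envelope(z=0.02, o2_max=18.0, o2_min=1.8, cycle_mean=10.0),
        ]
        s_max, s_min, ok = ox.homogeneity_metrics(envs, threshold=2.0)
        assert s_max == pytest.approx(1.0)
        assert s_min == pytest.approx(0.8)
        assert ok

    def test_threshold_comparison(self):
        envs = [
            ox.Envelope(z=0.01, o2_max=19.0, o2_min=1.0, cycle_mean=10.0),
            ox.Envelope(z=0.02, o2_max=16.0, o2_min=4.0, cycle_mean=10.0),
        ]
        assert not ox.homogeneity_metrics(envs, threshold=2.0)[2]
        assert ox.homogeneity_metrics(envs, threshold=4.0)[2]

    def test_single_depth_rejected(self):
        e = ox.Envelope(z=0.01, o2_max=19.0, o2_min=1.0, cycle_mean=10.0)
        with pytest.raises(ValueError):
            ox.homogeneity_metrics([e])


class TestSinusoidGain:
    def test_unity_at_driven_boundary(self):
        gain, phase = ox.sinusoid_gain(0.0, 0.1, 1.87e-5, 0.05)
        assert gain == pytest.approx(1.0)
        assert phase == pytest.approx(0.0)

    def test_quasi_static_limit(self):
        for z in (0.01, 0.05):
            assert ox.sinusoid_gain(z, 0.0, 1.87e-5, 0.05)[0] == 1.0
            assert ox.sinusoid_gain(z, 1e-7, 1.87e-5, 0.05)[0] == pytest.approx(
                1.0, abs=1e-3
            )

    def test_monotone_decreasing_in_depth_and_frequency(self):
        # strict decrease holds at interior depths (at z = 0 the Dirichlet
        # drive pins the gain to 1 for every frequency)
        W, D = 0.05, 1.87e-5
        omegas = 2 * np.pi / np.array([600.0, 60.0, 20.0, 6.0])
        zs = np.linspace(0.005, W, 10)
        table = np.array(
            [[ox.sinusoid_gain(z, om, D, W)[0] for z in zs] for om in omegas]
        )
        assert np.all(np.diff(table, axis=1) < 0)   # deeper -> smaller
        assert np.all(np.diff(table, axis=0) < 0)   # faster -> smaller
        assert np.all(table < 1.0)

    def test_solver_envelope_matches_square_wave_synthesis(
        self, single_gel_stack, osa_schedule
    ):
        grid = ox.build_grid(single_gel_stack, 0.05 / 100)
        f = ox.run_to_periodic_steady_state(
            single_gel_stack, osa_schedule, grid=grid,
            settings=ox.SolverSettings(psss_tol=1e-4),
        )
        for z in (0.01, 0.03, 0.05):
            e = ox.envelope_profile(f, [z], period=60.0)[0]
            o = ox.square_wave_envelope(z, 0.05, 1.87e-5, 60.0, 20.0, 0.0)
            assert e.amplitude == pytest.approx(o.amplitude, rel=0.02)


class TestDesignReport:
    def test_thicker_scaffold_attenuates_more(self, gel_500_stack, gel_800_stack,
                                              osa_schedule):
        # with the physical transmission of this stack, a threshold of 0.05
        # separates the two canonical thicknesses
        r500 = ox.design_report(gel_500_stack, osa_schedule,
                                fidelity_threshold=0.05,
                                homogeneity_threshold=None)
        r800 = ox.design_report(gel_800_stack, osa_schedule,
                                fidelity_threshold=0.05,
                                homogeneity_threshold=None)
        assert r500.suitable
        assert not r800.suitable
        assert r800.fidelity < r500.fidelity
        # verdict is monotone: thicker never flips unsuitable -> suitable
        assert not (not r500.suitable and r800.suitable)

    def test_zero_threshold_always_suitable(self, gel_800_stack, osa_schedule):
        rep = ox.design_report(gel_800_stack, osa_schedule,
                               fidelity_threshold=0.0,
                               homogeneity_threshold=None)
        assert rep.suitable

    def test_report_table_well_formed(self, gel_500_stack, osa_schedule):
        rep = ox.design_report(gel_500_stack, osa_schedule,
                               fidelity_threshold=0.05,
                               homogeneity_threshold=2.0)
        assert list(rep.table.columns) == [
            "z_um", "o2_max_percent", "o2_min_percent",
            "amplitude_percent", "cycle_mean_percent",
        ]
        assert len(rep.table) == 11
        assert rep.cycles_to_steady > 0
        assert 0.0 < rep.fidelity < 1.0
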