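"""Closed-form transport estimates, envelope statistics, and design reports.

Two families of results live here:

* desk-scale estimates for whether cellular O₂ consumption matters relative
  to diffusive supply through a membrane-like scaffold of thickness W —
  the consumed flux V'_con, the diffused flux V'_dif and their ratio, whose
  quadratic growth in W is what ultimately limits scaffold thickness;
* periodic (envelope) analysis of solved fields — per-depth cycle max/min —
  together with the exact linear-slab frequency response used both as a
  solver oracle and for fast design estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import Field, SolverSettings, run_to_periodic_steady_state, sample_field
from .stack import Grid, IHSchedule, Stack
from .units import MMHG_PER_ATM

__all__ = [
    "FluxRatioSpec",
    "Envelope",
    "consumption_flux",
    "diffusion_flux",
    "flux_ratio",
    "envelope_profile",
    "envelopes_to_frame",
    "homogeneity_metrics",
    "sinusoid_gain",
    "square_wave_envelope",
    "DesignReport",
    "design_report",
]


@dataclass(frozen=True)
class FluxRatioSpec:
    """Inputs for the consumed-vs-diffused flux comparison.

    C_mean is the average dissolved O₂ concentration across the construct
    (mol/cm³); delta_P the partial-pressure difference across it (atm).
    The reference parameter set for a high-consuming tissue surrogate is
    collagen-embedded hepatocytes: rho_cell = 5e5 cells/cm³,
    sOCR = 1.22e-16 mol/(cell·s), K_m = 4.1e-6 mol/cm³, D = 1.2e-5 cm²/s.
    """

    rho_cell: float      # cells/cm³
    sOCR: float          # mol/(cell·s)
    K_m: float           # mol/cm³
    C_mean: float        # mol/cm³
    W: float             # cm
    D: float             # cm²/s
    alpha: float         # mol/(cm³·atm)
    delta_P: float       # atm

    def __post_init__(self) -> None:
        if self.rho_cell < 0 or self.C_mean < 0:
            raise ValueError("rho_cell and C_mean must be >= 0")
        for name in ("sOCR", "K_m", "W", "D", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_P < 0:
            raise ValueError("delta_P must be >= 0")

    @classmethod
    def from_pressures(cls, *, rho_cell, sOCR, K_m, W, D, alpha,
                       delta_P_mmHg, mean_fraction) -> "FluxRatioSpec":
        """Convenience constructor in gas-side units.

        ``delta_P_mmHg`` is the pressure difference in mmHg; ``mean_fraction``
        the O₂ fraction whose Henry-law concentration defines C_mean (the
        default convention is the arithmetic mean of the driving fractions,
        e.g. 10% for a 20/0 schedule).
        """
        return cls(
            rho_cell=rho_cell, sOCR=sOCR, K_m=K_m,
            C_mean=alpha * mean_fraction,
            W=W, D=D, alpha=alpha,
            delta_P=delta_P_mmHg / MMHG_PER_ATM,
        )


def consumption_flux(spec: FluxRatioSpec) -> float:
    """Cellular O₂ consumption per unit area, V'_con = ρ·sOCR·C̄·W/(K_m+C̄)."""
    return spec.rho_cell * spec.sOCR * spec.C_mean * spec.W / (spec.K_m + spec.C_mean)


def diffusion_flux(spec: FluxRatioSpec) -> float:
    """Diffusive O₂ supply per unit area, V'_dif = D·α·ΔP/W."""
    return spec.D * spec.alpha * spec.delta_P / spec.W


def flux_ratio(spec: FluxRatioSpec) -> float:
    """V'_con / V'_dif = ρ·sOCR·C̄·W² / (D·α·ΔP·(K_m+C̄)).

    Grows quadratically in W; values ≪ 1 mean consumption is negligible
    against diffusive resupply.  For the hepatocyte reference set at
    W = 500 μm and a 20→0% pressure difference this is ≈1.5e-3.
    """
    if spec.delta_P == 0:
        raise ZeroDivisionError("flux ratio undefined for delta_P = 0")
    return consumption_flux(spec) / diffusion_flux(spec)


@dataclass(frozen=True)
class Envelope:
    """Per-depth periodic-steady-state summary, in %O₂."""

    z: float           # cm
    o2_max: float
    o2_min: float
    cycle_mean: float

    @property
    def amplitude(self) -> float:
        """Peak-to-peak swing, max − min."""
        return self.o2_max - self.o2_min


def envelope_profile(
    field: Field, depths, period: float | None = None
) -> list[Envelope]:
    """Cycle max/min/mean per depth over the final full period of ``field``.

    ``period`` defaults to the field's whole stored span (appropriate when
    the field is one converged cycle from the periodic-steady-state runner).
    """
    span = field.times[-1] - field.times[0]
    if period is None:
        period = span
    if span < period - 1e-9:
        raise ValueError(
            f"field spans {span:g} s, shorter than one period ({period:g} s)"
        )
    t0 = field.times[-1] - period
    mask = field.times >= t0 - 1e-9
    out = []
    for z in np.atleast_1d(depths):
        trace = sample_field(field, float(z))[mask] * (100.0 / MMHG_PER_ATM)
        out.append(Envelope(z=float(z), o2_max=float(trace.max()),
                            o2_min=float(trace.min()),
                            cycle_mean=float(trace.mean())))
    return out


def envelopes_to_frame(envelopes: list[Envelope]) -> pd.DataFrame:
    """Tidy table: z_um, o2_max, o2_min, amplitude, cycle_mean (%O₂)."""
    return pd.DataFrame(
        {
            "z_um": [e.z * 1e4 for e in envelopes],
            "o2_max_percent": [e.o2_max for e in envelopes],
            "o2_min_percent": [e.o2_min for e in envelopes],
            "amplitude_percent": [e.amplitude for e in envelopes],
            "cycle_mean_percent": [e.cycle_mean for e in envelopes],
        }
    )


def homogeneity_metrics(
    envelopes: list[Envelope], threshold: float = 2.0
) -> tuple[float, float, bool]:
    """Across-depth spread (range, %O₂) of the maxima and of the minima.

    The uniformity criterion used for judging whether all depths see "the
    same" hypoxia exposure is that both spreads stay below ``threshold``
    (default 2 %O₂).  Returns (spread_of_maxima, spread_of_minima, pass).
    """
    if len(envelopes) < 2:
        raise ValueError("need >= 2 depths for homogeneity metrics")
    maxima = np.array([e.o2_max for e in envelopes])
    minima = np.array([e.o2_min for e in envelopes])
    s_max = float(maxima.max() - maxima.min())
    s_min = float(minima.max() - minima.min())
    return s_max, s_min, bool(s_max <= threshold and s_min <= threshold)


def sinusoid_gain(z: float, omega: float, D: float, W: float) -> tuple[float, float]:
    """Exact frequency response of an acellular slab, sealed at the top.

    For a sinusoidal Dirichlet drive at z = 0 and no-flux at z = W, the
    periodic solution is  u(z,t) ∝ Re[cosh(γ(W−z))/cosh(γW)·e^{iωt}]  with
    γ = sqrt(iω/D).  Returns (gain, phase_rad); gain is 1 at z = 0 and
    decreases monotonically in both z and ω.
    """
    if not 0.0 <= z <= W + 1e-15:
        raise ValueError("require 0 <= z <= W")
    if omega == 0.0:
        return 1.0, 0.0
    gamma = np.sqrt(1j * omega / D)
    H = np.cosh(gamma * (W - z)) / np.cosh(gamma * W)
    return float(np.abs(H)), float(np.angle(H))


def square_wave_envelope(
    z: float,
    W: float,
    D: float,
    period: float,
    high_percent: float,
    low_percent: float,
    duty: float = 0.5,
    n_harmonics: int = 51,
    n_time: int = 4000,
) -> Envelope:
    """Fourier-synthesized periodic response to a square-wave drive.

    Independent closed-form oracle for the solver: the driving square wave
    (between ``high_percent`` and ``low_percent`` %O₂) is expanded in
    ``n_harmonics`` odd harmonics, each filtered by :func:`sinusoid_gain`,
    and the cycle max/min at depth z are read off the synthesized waveform.
    """
    omega = 2.0 * np.pi / period
    mean = duty * high_percent + (1.0 - duty) * low_percent
    t = np.linspace(0.0, period, n_time, endpoint=False)
    sig = np.full_like(t, mean)
    amp = high_percent - low_percent
    for m in range(n_harmonics):
        k = 2 * m + 1  # duty-0.5 square wave has odd harmonics only
        gain, phase = sinusoid_gain(z, k * omega, D, W)
        coeff = 2.0 * amp / (np.pi * k)
        sig += coeff * gain * np.sin(k * omega * t + phase)
    return Envelope(z=z, o2_max=float(sig.max()), o2_min=float(sig.min()),
                    cycle_mean=float(sig.mean()))


@dataclass
class DesignReport:
    """Outcome of a scaffold/schedule suitability check."""

    table: pd.DataFrame          # envelope profile over z
    spread_max: float            # %O₂
    spread_min: float            # %O₂
    homogeneity_pass: bool | None
    driving_amplitude: float     # %O₂ (peak-to-peak of the gas schedule)
    top_amplitude: float         # %O₂ at the scaffold top
    fidelity: float              # top_amplitude / driving_amplitude
    fidelity_threshold: float
    cycles_to_steady: int
    suitable: bool


def design_report(
    stack: Stack,
    schedule: IHSchedule,
    fidelity_threshold: float = 0.5,
    homogeneity_threshold: float | None = 2.0,
    depths: np.ndarray | None = None,
    grid: Grid | None = None,
    settings: SolverSettings | None = None,
) -> DesignReport:
    """Run to periodic steady state and judge the exposure design.

    The design is "suitable" iff the cycle amplitude at the top of the
    scaffold is at least ``fidelity_threshold`` × the driving amplitude and
    (unless ``homogeneity_threshold`` is None) the across-depth spreads of
    the envelope maxima and minima are within the homogeneity threshold.
    Because attenuation deepens monotonically with thickness, thickening the
    scaffold at fixed settings can only lower the fidelity.
    """
    field = run_to_periodic_steady_state(stack, schedule, grid=grid,
                                         settings=settings)
    z_top = stack.scaffold_top
    if depths is None:
        depths = np.linspace(0.0, z_top, 11)
    envs = envelope_profile(field, depths, period=schedule.period)
    s_max, s_min, homog = homogeneity_metrics(
        envs, homogeneity_threshold if homogeneity_threshold is not None else np.inf
    )
    top_env = envelope_profile(field, [z_top], period=schedule.period)[0]
    driving = schedule.amplitude_percent
    fidelity = top_env.amplitude / driving if driving > 0 else 1.0
    amp_ok = top_env.amplitude >= fidelity_threshold * driving
    homog_ok = None if homogeneity_threshold is None else homog
    suitable = bool(amp_ok and (homog_ok is not False))
    return DesignReport(
        table=envelopes_to_frame(envs),
        spread_max=s_max,
        spread_min=s_min,
        homogeneity_pass=homog_ok,
        driving_amplitude=driving,
        top_amplitude=top_env.amplitude,
        fidelity=fidelity,
        fidelity_threshold=fidelity_threshold,
        cycles_to_steady=field.cycles or 0,
        suitable=suitable,
    )
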