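"""Inverse problem: recover effective diffusivity from depth-tagged traces.

Given microsensor traces at one or more depths, the fit adjusts the scaffold
layer's unknown parameters (its diffusivity D, optionally a lumped volumetric
consumption capacity ρ_cell·sOCR with K_m held fixed) so that lag-applied
forward-model traces match the observations in a least-squares sense.

The three Michaelis–Menten parameters are jointly unidentifiable from
concentration traces when dissolved O₂ sits well below K_m (the sink is then
effectively first order), which is why consumption enters only as the lumped
product.  The sensor time constant is treated as known from the probe
specification: a single quoted number, and weakly identifiable jointly with D
at minute-scale periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .sensor import SensorSpec, SensorTrace, apply_sensor_lag
from .solver import SolverSettings, sample_field, simulate
from .stack import IHSchedule, Layer, Stack
from .units import MMHG_PER_ATM

__all__ = [
    "FitProblem",
    "FitResult",
    "IdentifiabilityError",
    "FitError",
    "fit_parameters",
    "residual_diagnostics",
]


class IdentifiabilityError(ValueError):
    """The data carry no information about the requested parameters."""


class FitError(RuntimeError):
    """No optimizer start converged."""


#: Recognized unknown-parameter names.
KNOWN_UNKNOWNS = ("D", "vmax")


@dataclass(frozen=True)
class FitProblem:
    """A bounded least-squares matching problem.

    ``unknowns`` maps parameter names to (lower, upper) bounds:

    * ``"D"`` — scaffold diffusivity, cm²/s;
    * ``"vmax"`` — lumped ρ_cell·sOCR, mol/(cm³·s), with the template's K_m
      held fixed.

    ``stack_template`` supplies every other physical parameter; the scaffold
    layer is the first layer of kind "scaffold".  The sensor lag (``sensor``)
    is applied to the forward model before comparison; its noise setting is
    ignored here.  Traces must span at least two full cycles.
    """

    traces: tuple[SensorTrace, ...]
    stack_template: Stack
    schedule: IHSchedule
    unknowns: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"D": (1.87e-6, 1.87e-4)}
    )
    sensor: SensorSpec = SensorSpec(noise_sd=0.0)
    settings: SolverSettings | None = None
    initial_fraction: float | None = None  # default: schedule high fraction
    n_starts: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", tuple(self.traces))
        if len(self.traces) == 0:
            raise ValueError("need at least one trace")
        if len(self.unknowns) == 0:
            raise ValueError("need at least one unknown parameter")
        for name, (lo, hi) in self.unknowns.items():
            if name not in KNOWN_UNKNOWNS:
                raise ValueError(
                    f"unknown parameter {name!r}; expected one of {KNOWN_UNKNOWNS}"
                )
            if not (0 < lo < hi and math.isfinite(hi)):
                raise ValueError(f"bounds for {name!r} must be finite and positive")
        span = min(t.times[-1] - t.times[0] for t in self.traces)
        if span < 2.0 * self.schedule.period - 1e-9:
            raise ValueError("traces must span at least two full cycles")
        if self.scaffold_index is None:
            raise ValueError("stack_template has no scaffold layer")

    @property
    def scaffold_index(self) -> int | None:
        for i, la in enumerate(self.stack_template.layers):
            if la.kind == "scaffold":
                return i
        return None


@dataclass
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    estimates: dict[str, float]
    stderr: dict[str, float]
    residual_norm: float          # RMS residual, %O₂
    converged: bool
    n_residuals: int
    starts: list[dict]            # per-start trajectory summaries


def _stack_with(problem: FitProblem, params: dict[str, float]) -> Stack:
    idx = problem.scaffold_index
    layers = list(problem.stack_template.layers)
    la = layers[idx]
    medium = la.medium
    if "D" in params:
        medium = replace(medium, D=params["D"])
    kwargs = {}
    if "vmax" in params:
        km = la.K_m if la.K_m > 0 else 4.1e-6
        kwargs = dict(rho_cell=1.0, sOCR=params["vmax"], K_m=km)
    layers[idx] = replace(la, medium=medium, **kwargs)
    return replace(problem.stack_template, layers=tuple(layers))


def _forward_traces(problem: FitProblem, params: dict[str, float]) -> list[np.ndarray]:
    """Lag-applied model prediction (%O₂) at each trace's depth and clock."""
    stack = _stack_with(problem, params)
    t_end = max(t.times[-1] for t in problem.traces)
    fld = simulate(
        stack, problem.schedule, settings=problem.settings,
        initial=problem.initial_fraction, duration=t_end,
    )
    out = []
    for tr in problem.traces:
        ideal = sample_field(fld, tr.z) * (100.0 / MMHG_PER_ATM)
        lagged = apply_sensor_lag(fld.times, ideal, problem.sensor.tau)
        out.append(np.interp(tr.times, fld.times, lagged))
    return out


def _residuals(problem: FitProblem, params: dict[str, float]) -> np.ndarray:
    model = _forward_traces(problem, params)
    return np.concatenate(
        [tr.values - m for tr, m in zip(problem.traces, model)]
    )


def fit_parameters(problem: FitProblem) -> FitResult:
    """Bounded least squares in log-parameter space with 3 multi-starts.

    Starts are log-spaced across the bounds; the best converged start wins.
    Raises :class:`IdentifiabilityError` for a constant driving waveform or
    flat traces, :class:`FitError` if no start converges.
    """
    if problem.schedule.amplitude_fraction == 0.0:
        raise IdentifiabilityError(
            "constant schedule (high == low): no dynamics constrain the fit"
        )
    if all(np.ptp(tr.values) < 1e-12 for tr in problem.traces):
        raise IdentifiabilityError("all traces are constant")

    names = list(problem.unknowns)
    lo = np.log10([problem.unknowns[n][0] for n in names])
    hi = np.log10([problem.unknowns[n][1] for n in names])

    def resid_x(x: np.ndarray) -> np.ndarray:
        params = {n: 10.0 ** xi for n, xi in zip(names, x)}
        return _residuals(problem, params)

    fractions = np.linspace(0.2, 0.8, problem.n_starts)
    starts: list[dict] = []
    best = None
    for f in fractions:
        x0 = lo + f * (hi - lo)
        try:
            res = least_squares(resid_x, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:  # solver blow-up inside an eval
            starts.append({"x0": list(x0), "error": str(exc), "success": False})
            continue
        starts.append({"x0": list(x0), "x": list(res.x),
                       "cost": float(res.cost), "success": bool(res.success)})
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        raise FitError("no optimizer start converged")

    estimates = {n: float(10.0 ** xi) for n, xi in zip(names, best.x)}
    n_res = best.fun.size
    dof = max(n_res - len(names), 1)
    s2 = 2.0 * best.cost / dof
    # curvature-based SEs in log10 space, propagated to natural scale
    JTJ = best.jac.T @ best.jac
    stderr = {}
    try:
        cov = s2 * np.linalg.inv(JTJ)
        for i, n in enumerate(names):
            se_log = math.sqrt(max(cov[i, i], 0.0))
            stderr[n] = estimates[n] * math.log(10.0) * se_log
    except np.linalg.LinAlgError:
        stderr = {n: float("nan") for n in names}
    return FitResult(
        estimates=estimates,
        stderr=stderr,
        residual_norm=float(np.sqrt(2.0 * best.cost / n_res)),
        converged=True,
        n_residuals=n_res,
        starts=starts,
    )


def residual_diagnostics(problem: FitProblem, result: FitResult) -> pd.DataFrame:
    """Per-depth RMS residual (%O₂), flagging depths with RMS > 3× median.

    A flagged depth indicates model mismatch there — e.g. traces generated
    with consumption but fitted with an acellular template show systematic
    residuals deep in the scaffold.
    """
    if not result.converged:
        raise ValueError("diagnostics require a converged fit")
    model = _forward_traces(problem, result.estimates)
    rows = []
    for tr, m in zip(problem.traces, model):
        r = tr.values - m
        rows.append({"z_um": tr.z * 1e4,
                     "rms_percent": float(np.sqrt(np.mean(r * r))),
                     "n": r.size})
    df = pd.DataFrame(rows)
    med = df["rms_percent"].median()
    df["flagged"] = df["rms_percent"] > 3.0 * med
    return df
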