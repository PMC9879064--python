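"""Transient reaction–diffusion solver for oxygen in the layer stack.

Solves, per layer,

    ∂C/∂t = D ∂²C/∂z² − ρ_cell · sOCR · C / (K_m + C),

with C = α·p/760 the dissolved concentration, in a vertex-centred
finite-volume discretization whose state variable is the partial pressure p
(mmHg).  Pressure is continuous across material interfaces (Henry's law);
nodes sit exactly on interfaces so each inter-node segment has a single
permeability D·α and interfacial flux is conserved exactly.

Time stepping is θ-weighted implicit (backward Euler by default — robust for
the square-wave boundary; trapezoidal available for smooth boundaries where
its lack of numerical damping matters).  The Michaelis–Menten sink is solved
by Newton iteration at every implicit step, which keeps the sink below its
saturation bound and the solution non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.linalg import solve_banded

from .stack import Grid, IHSchedule, Stack, build_grid
from .units import MMHG_PER_ATM

__all__ = [
    "SolverSettings",
    "Field",
    "SolverError",
    "simulate",
    "simulate_custom",
    "run_to_periodic_steady_state",
    "sample_field",
    "schedule_time_grid",
]

PCT_PER_MMHG = 100.0 / MMHG_PER_ATM


class SolverError(RuntimeError):
    """Raised on Newton non-convergence, negative pressures, or no cycling limit."""


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls.

    ``dt`` is the target time step (defaults to period/600, i.e. 0.1 s at
    60 events/h); phase-change times of the driving square wave are inserted
    into the time grid exactly, so the waveform is never smeared across a
    step.  ``theta`` = 1 is backward Euler, 0.5 trapezoidal.  ``psss_*``
    control the periodic-steady-state cycle iteration (tolerance in %O₂ on
    every node's cycle max and min).
    """

    dt: float | None = None
    theta: float = 1.0
    newton_tol: float = 1e-10
    newton_max_iter: int = 25
    psss_tol: float = 1e-3
    psss_max_cycles: int = 200
    target_dz: float = 1e-3  # cm, default grid resolution (10 μm)

    def __post_init__(self) -> None:
        if not 0.5 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0.5, 1]")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.newton_tol <= 0 or self.psss_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Field:
    """Space–time oxygen state: partial pressure (mmHg) per (time, node)."""

    grid: Grid
    times: np.ndarray            # s, strictly increasing
    values: np.ndarray           # mmHg, shape (n_times, n_nodes)
    cycles: int | None = None    # cycles used to reach periodic steady state

    @property
    def percent(self) -> np.ndarray:
        """Values as %O₂."""
        return self.values * PCT_PER_MMHG

    def concentration(self) -> np.ndarray:
        """Dissolved concentration (mol/cm³) per (time, node).

        Interface nodes take the mean of the two adjacent layers' α.
        """
        alpha_node = _node_alpha(self.grid)
        return self.values * (alpha_node / MMHG_PER_ATM)

    def sample(self, z: float, times: np.ndarray | None = None) -> np.ndarray:
        return sample_field(self, z, times)


def _node_alpha(grid: Grid) -> np.ndarray:
    alphas = np.array([la.medium.alpha for la in grid.stack.layers])
    seg_alpha = alphas[grid.segment_layer]
    node = np.empty(grid.n_nodes)
    node[0] = seg_alpha[0]
    node[-1] = seg_alpha[-1]
    node[1:-1] = 0.5 * (seg_alpha[:-1] + seg_alpha[1:])
    return node


def schedule_time_grid(
    schedule: IHSchedule, duration: float, dt: float, t0: float = 0.0
) -> np.ndarray:
    """Time grid over [t0, t0+duration] with phase changes as exact grid points."""
    t_end = t0 + duration
    breaks = [t0]
    half = schedule.duty * schedule.period
    k = math.floor(t0 / schedule.period)
    while k * schedule.period < t_end + 1e-12:
        for b in (k * schedule.period, k * schedule.period + half):
            if t0 + 1e-12 < b < t_end - 1e-12:
                breaks.append(b)
        k += 1
    breaks.append(t_end)
    breaks = sorted(set(breaks))
    parts = [np.array([t0])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(int(math.ceil((b - a) / dt - 1e-9)), 1)
        parts.append(a + (b - a) * np.arange(1, n + 1) / n)
    return np.concatenate(parts)


class _Discretization:
    """Precomputed finite-volume arrays for one stack+grid."""

    def __init__(self, grid: Grid):
        stack = grid.stack
        dz = grid.dz
        D = np.array([la.medium.D for la in stack.layers])[grid.segment_layer]
        alpha = np.array([la.medium.alpha for la in stack.layers])[grid.segment_layer]
        a = alpha / MMHG_PER_ATM          # mol/(cm³·mmHg)
        self.g = D * a / dz               # segment conductance
        self.cap = np.zeros(grid.n_nodes)  # per-node capacity, mol/(cm²·mmHg)
        np.add.at(self.cap, np.arange(dz.size), a * dz / 2)
        np.add.at(self.cap, np.arange(1, dz.size + 1), a * dz / 2)

        vm = np.array([la.rho_cell * la.sOCR for la in stack.layers])[grid.segment_layer]
        km = np.array([max(la.K_m, 1.0) if la.rho_cell == 0 else la.K_m
                       for la in stack.layers])[grid.segment_layer]
        self.seg_vm = vm * dz / 2         # half-segment Vmax per area, mol/(cm²·s)
        self.seg_km = km
        self.seg_a = a
        self.has_sink = bool(np.any(self.seg_vm > 0))
        self.n = grid.n_nodes

    def stiffness_mul(self, u: np.ndarray) -> np.ndarray:
        """A·u where A is the (positive semidefinite) diffusion stiffness."""
        return _negate_divergence(self.g * np.diff(u), u.size)

    def sink(self, u: np.ndarray) -> np.ndarray:
        """Nodal Michaelis–Menten sink, mol/(cm²·s) (≥ 0)."""
        if not self.has_sink:
            return np.zeros_like(u)
        c_lo = self.seg_a * u[:-1]
        c_hi = self.seg_a * u[1:]
        s_lo = self.seg_vm * c_lo / (self.seg_km + c_lo)
        s_hi = self.seg_vm * c_hi / (self.seg_km + c_hi)
        out = np.zeros_like(u)
        np.add.at(out, np.arange(u.size - 1), s_lo)
        np.add.at(out, np.arange(1, u.size), s_hi)
        return out

    def sink_deriv(self, u: np.ndarray) -> np.ndarray:
        """d(sink)/du, diagonal, per node."""
        if not self.has_sink:
            return np.zeros_like(u)
        d_lo = self.seg_vm * self.seg_a * self.seg_km / (self.seg_km + self.seg_a * u[:-1]) ** 2
        d_hi = self.seg_vm * self.seg_a * self.seg_km / (self.seg_km + self.seg_a * u[1:]) ** 2
        out = np.zeros_like(u)
        np.add.at(out, np.arange(u.size - 1), d_lo)
        np.add.at(out, np.arange(1, u.size), d_hi)
        return out


def _negate_divergence(flux: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[:-1] += flux
    out[1:] -= flux
    return -out


BoundaryKind = Literal["dirichlet", "no_flux"]


def simulate_custom(
    stack: Stack,
    grid: Grid,
    times: np.ndarray,
    settings: SolverSettings,
    *,
    bottom: BoundaryKind = "dirichlet",
    bottom_pressure: Callable[[float], float] | None = None,
    top: BoundaryKind = "no_flux",
    top_pressure: float | None = None,
    initial_pressure: np.ndarray | float = 0.0,
) -> Field:
    """Low-level transient solve with arbitrary boundary drivers.

    ``bottom_pressure`` is a callable t → mmHg (required for a Dirichlet
    bottom); ``top_pressure`` a constant mmHg for a Dirichlet top.  This is
    the entry point used by the analytic-oracle validation tests (sinusoidal
    and step boundaries) and by :func:`simulate`.
    """
    disc = _Discretization(grid)
    n = disc.n
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    if bottom == "dirichlet" and bottom_pressure is None:
        raise ValueError("dirichlet bottom requires bottom_pressure")
    if top == "dirichlet" and top_pressure is None:
        raise ValueError("dirichlet top requires top_pressure")

    u = np.empty(n)
    u[:] = initial_pressure
    if bottom == "dirichlet":
        u[0] = bottom_pressure(times[0])
    if top == "dirichlet":
        u[-1] = top_pressure
    if np.any(u < 0) or np.any(u > MMHG_PER_ATM + 1e-9):
        raise ValueError("initial pressure outside [0, 760] mmHg")

    theta = settings.theta
    values = np.empty((times.size, n))
    values[0] = u

    ab = np.zeros((3, n))  # banded Jacobian workspace
    lin_cache: dict[float, np.ndarray] = {}

    def linear_matrix(dt: float) -> np.ndarray:
        key = round(dt, 12)
        if key not in lin_cache:
            diag = disc.cap / dt
            diag[:-1] += theta * disc.g
            diag[1:] += theta * disc.g
            upper = np.zeros(n)
            lower = np.zeros(n)
            upper[1:] = -theta * disc.g
            lower[:-1] = -theta * disc.g
            if bottom == "dirichlet":
                diag[0] = 1.0
                upper[1] = 0.0
            if top == "dirichlet":
                diag[-1] = 1.0
                lower[-2] = 0.0
            lin_cache[key] = np.vstack([upper, diag, lower])
        return lin_cache[key]

    for k in range(1, times.size):
        dt = times[k] - times[k - 1]
        u_old = u
        pb = bottom_pressure(times[k]) if bottom == "dirichlet" else None

        if not disc.has_sink:
            # linear problem: single banded solve per step
            rhs = disc.cap / dt * u_old
            if theta < 1.0:
                rhs -= (1.0 - theta) * disc.stiffness_mul(u_old)
            if bottom == "dirichlet":
                rhs[0] = pb
            if top == "dirichlet":
                rhs[-1] = top_pressure
            u_new = solve_banded((1, 1), linear_matrix(dt), rhs)
            neg = u_new < 0
            if np.any(u_new < -1e-9):
                raise SolverError(
                    f"negative partial pressure beyond roundoff at t = {times[k]:.6g} s"
                )
            if np.any(neg):
                u_new = np.where(neg, 0.0, u_new)
            u = u_new
            values[k] = u
            continue

        expl = disc.stiffness_mul(u_old) + disc.sink(u_old) if theta < 1.0 else None
        u_new = u_old.copy()
        if bottom == "dirichlet":
            u_new[0] = pb
        for it in range(settings.newton_max_iter):
            F = disc.cap * (u_new - u_old) / dt \
                + theta * (disc.stiffness_mul(u_new) + disc.sink(u_new))
            if theta < 1.0:
                F += (1.0 - theta) * expl
            # banded Jacobian: rows upper, diag, lower
            diag = disc.cap / dt + theta * (disc.sink_deriv(u_new))
            diag[:-1] += theta * disc.g
            diag[1:] += theta * disc.g
            upper = np.zeros(n)
            lower = np.zeros(n)
            upper[1:] = -theta * disc.g
            lower[:-1] = -theta * disc.g
            if bottom == "dirichlet":
                F[0] = u_new[0] - pb
                diag[0] = 1.0
                upper[1] = 0.0
            if top == "dirichlet":
                F[-1] = u_new[-1] - top_pressure
                diag[-1] = 1.0
                lower[-2] = 0.0
            ab[0] = upper
            ab[1] = diag
            ab[2] = lower
            delta = solve_banded((1, 1), ab, -F)
            u_new = u_new + delta
            if np.max(np.abs(delta)) <= settings.newton_tol * (np.max(np.abs(u_new)) + 1.0):
                break
        else:
            raise SolverError(
                f"Newton failed to converge at t = {times[k]:.6g} s "
                f"({settings.newton_max_iter} iterations)"
            )

        neg = u_new < 0
        if np.any(u_new < -1e-9):
            raise SolverError(
                f"negative partial pressure beyond roundoff at t = {times[k]:.6g} s"
            )
        if np.any(neg):
            u_new = np.where(neg, 0.0, u_new)
        u = u_new
        values[k] = u

    if not np.all(np.isfinite(values)):
        raise SolverError("non-finite values in solution")
    return Field(grid=grid, times=times, values=values)


def _resolve(stack, schedule, grid, settings):
    if settings is None:
        settings = SolverSettings()
    if grid is None:
        grid = build_grid(stack, settings.target_dz)
    dt = settings.dt if settings.dt is not None else schedule.period / 600.0
    return grid, settings, dt


def simulate(
    stack: Stack,
    schedule: IHSchedule,
    grid: Grid | None = None,
    settings: SolverSettings | None = None,
    initial: float | Field | None = None,
    duration: float | None = None,
    t0: float = 0.0,
) -> Field:
    """Run the stack under the intermittent-hypoxia schedule.

    ``initial`` is a uniform O₂ fraction (default: the schedule's high
    fraction — samples equilibrate in normoxia before cycling) or a previous
    :class:`Field` whose final state is continued.
    """
    grid, settings, dt = _resolve(stack, schedule, grid, settings)
    if duration is None:
        duration = schedule.total_duration or schedule.period
    times = schedule_time_grid(schedule, duration, dt, t0=t0)

    if initial is None:
        u0: np.ndarray | float = schedule.high_fraction * MMHG_PER_ATM
    elif isinstance(initial, Field):
        u0 = initial.values[-1]
    else:
        if not 0.0 <= initial <= 1.0:
            raise ValueError("initial fraction must be in [0, 1]")
        u0 = initial * MMHG_PER_ATM
    top_kind: BoundaryKind = "no_flux"
    top_p = None
    if stack.top.kind == "fixed_fraction":
        top_kind = "dirichlet"
        top_p = stack.top.fraction * MMHG_PER_ATM
    return simulate_custom(
        stack, grid, times, settings,
        bottom="dirichlet", bottom_pressure=lambda t: schedule.pressure(t),
        top=top_kind, top_pressure=top_p, initial_pressure=u0,
    )


def run_to_periodic_steady_state(
    stack: Stack,
    schedule: IHSchedule,
    grid: Grid | None = None,
    settings: SolverSettings | None = None,
) -> Field:
    """Iterate whole cycles until the per-node cycle envelope stops changing.

    Convergence requires every node's cycle max and min (in %O₂) to move less
    than ``settings.psss_tol`` between consecutive cycles.  Returns the
    converged cycle (times relative to cycle start) with ``cycles`` set.
    """
    grid, settings, dt = _resolve(stack, schedule, grid, settings)
    field: Field | None = None
    prev_max = prev_min = None
    resid = math.inf
    for cycle in range(1, settings.psss_max_cycles + 1):
        init = field if field is not None else None
        field = simulate(stack, schedule, grid, settings,
                         initial=init, duration=schedule.period)
        pct = field.percent
        cmax, cmin = pct.max(axis=0), pct.min(axis=0)
        if prev_max is not None:
            resid = max(np.max(np.abs(cmax - prev_max)),
                        np.max(np.abs(cmin - prev_min)))
            if resid < settings.psss_tol:
                field.cycles = cycle
                return field
        prev_max, prev_min = cmax, cmin
    raise SolverError(
        f"no periodic steady state within {settings.psss_max_cycles} cycles "
        f"(last envelope residual {resid:.3g} %O2)"
    )


def sample_field(field: Field, z: float, times: np.ndarray | None = None) -> np.ndarray:
    """Ideal (lag- and noise-free) depth trace: bilinear interpolation in z, t.

    Returns partial pressure in mmHg at the requested times (default: the
    field's stored times).
    """
    zg = field.grid.z
    if not zg[0] - 1e-12 <= z <= zg[-1] + 1e-12:
        raise ValueError(
            f"z = {z:g} cm outside the stack [{zg[0]:g}, {zg[-1]:g}] cm"
        )
    z = min(max(z, zg[0]), zg[-1])
    j = np.searchsorted(zg, z, side="right") - 1
    j = min(j, zg.size - 2)
    w = (z - zg[j]) / (zg[j + 1] - zg[j])
    trace = (1.0 - w) * field.values[:, j] + w * field.values[:, j + 1]
    if times is None:
        return trace
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < field.times[0] - 1e-9) or np.any(times > field.times[-1] + 1e-9):
        raise ValueError("requested times outside the stored field")
    return np.interp(times, field.times, trace)
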