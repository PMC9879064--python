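"""Physical description of the exposure system: gas schedule, layer stack, grid.

The system is a vertical 1D column.  Gas with a square-wave O₂ fraction is
circulated beneath a gas-permeable membrane; a scaffold (hydrogel or tissue
slice, possibly cell-laden) sits on top of the membrane, optionally covered by
a media column.  The coordinate z is measured from the membrane–scaffold
interface, positive into the sample, so the membrane occupies negative z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .units import ALPHA_WATER, MMHG_PER_ATM

__all__ = [
    "Medium",
    "Layer",
    "IHSchedule",
    "TopBoundary",
    "Stack",
    "Grid",
    "schedule_from_events_per_hour",
    "evaluate_schedule",
    "build_grid",
    "WATER_PDMS_ALPHA_NOTE",
]

WATER_PDMS_ALPHA_NOTE = (
    "PDMS solubility defaulted to the water value; partial pressure is "
    "continuous across the interface so only the product D*alpha matters "
    "for flux through the membrane."
)


@dataclass(frozen=True)
class Medium:
    """A diffusing phase: diffusivity D (cm²/s) and solubility α (mol/(cm³·atm))."""

    name: str
    D: float
    alpha: float = ALPHA_WATER.alpha

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"medium {self.name!r}: D must be positive")
        if self.alpha <= 0:
            raise ValueError(f"medium {self.name!r}: alpha must be positive")


@dataclass(frozen=True)
class Layer:
    """One slab of the stack.

    ``kind`` marks the layer's role: "membrane" layers sit below z = 0,
    "scaffold" is the sample that hosts cells, "media" an optional liquid
    column on top.  Cellular O₂ consumption is Michaelis–Menten with density
    ``rho_cell`` (cells/cm³), per-cell maximal rate ``sOCR`` (mol/(cell·s))
    and half-saturation concentration ``K_m`` (mol/cm³).
    """

    name: str
    thickness: float  # cm
    medium: Medium
    kind: Literal["membrane", "scaffold", "media"] = "scaffold"
    rho_cell: float = 0.0
    sOCR: float = 0.0
    K_m: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be positive")
        if self.rho_cell < 0:
            raise ValueError(f"layer {self.name!r}: rho_cell must be >= 0")
        if self.rho_cell > 0 and (self.sOCR <= 0 or self.K_m <= 0):
            raise ValueError(
                f"layer {self.name!r}: cellular layers need sOCR > 0 and K_m > 0"
            )


@dataclass(frozen=True)
class IHSchedule:
    """Square-wave intermittent-hypoxia driving waveform.

    Each cycle starts with the high (normoxic) phase; phase intervals are
    half-open ``[start, end)``.  ``gas_chamber_lag_tau`` > 0 applies a
    first-order relaxation of the chamber gas toward the current plateau,
    modelling finite chamber washout; 0 is an ideal square wave.
    """

    high_fraction: float
    low_fraction: float
    period: float  # s
    duty: float = 0.5
    total_duration: float | None = None
    gas_chamber_lag_tau: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_fraction <= self.high_fraction <= 1.0:
            raise ValueError("require 0 <= low_fraction <= high_fraction <= 1")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty must be in (0, 1)")
        if self.total_duration is not None and self.total_duration < self.period:
            raise ValueError("total_duration must cover at least one period")
        if self.gas_chamber_lag_tau < 0:
            raise ValueError("gas_chamber_lag_tau must be >= 0")

    @property
    def amplitude_fraction(self) -> float:
        """high − low, as a fraction."""
        return self.high_fraction - self.low_fraction

    @property
    def amplitude_percent(self) -> float:
        """Peak-to-peak driving amplitude in %O₂."""
        return 100.0 * self.amplitude_fraction

    @property
    def events_per_hour(self) -> float:
        return 3600.0 / self.period

    def __call__(self, t):
        return evaluate_schedule(self, t)

    def pressure(self, t):
        """Bottom-boundary partial pressure (mmHg) at time(s) t."""
        return MMHG_PER_ATM * evaluate_schedule(self, t)


def schedule_from_events_per_hour(
    rate: float,
    high: float,
    low: float,
    duration: float | None = None,
    *,
    gas_chamber_lag_tau: float = 0.0,
) -> IHSchedule:
    """Build a schedule from an events/h rate (severe OSA ≈ 60 events/h).

    60 events/h gives a 60 s period: 30 s at the high fraction then 30 s at
    the low fraction (duty 0.5).
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    period = 3600.0 / rate
    if duration is None:
        duration = period
    return IHSchedule(
        high_fraction=high,
        low_fraction=low,
        period=period,
        duty=0.5,
        total_duration=duration,
        gas_chamber_lag_tau=gas_chamber_lag_tau,
    )


def _ideal_square(s: IHSchedule, t: np.ndarray) -> np.ndarray:
    phase = np.mod(t, s.period)
    return np.where(phase < s.duty * s.period, s.high_fraction, s.low_fraction)


def evaluate_schedule(s: IHSchedule, t):
    """O₂ fraction of the chamber gas at time(s) ``t`` (t ≥ 0).

    With lag τ > 0 the gas relaxes exponentially toward the current plateau,
    starting from the high plateau at t = 0 (samples are equilibrated in
    normoxia before cycling starts).  The value reaches 90% of a step
    τ·ln(10) after the phase change.
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("schedule evaluated at negative time")
    if s.gas_chamber_lag_tau == 0.0:
        out = _ideal_square(s, t_arr)
        return float(out[0]) if scalar else out

    tau = s.gas_chamber_lag_tau
    t_high = s.duty * s.period
    t_low = s.period - t_high
    # Phase-start values converge geometrically; iterate cycles analytically.
    n_cycles = int(np.max(t_arr) // s.period) + 1
    start_high = np.empty(n_cycles)  # value at beginning of each high phase
    start_low = np.empty(n_cycles)   # value at beginning of each low phase
    v = s.high_fraction
    for k in range(n_cycles):
        start_high[k] = v
        v = s.high_fraction + (v - s.high_fraction) * math.exp(-t_high / tau)
        start_low[k] = v
        v = s.low_fraction + (v - s.low_fraction) * math.exp(-t_low / tau)

    cyc = np.minimum((t_arr // s.period).astype(int), n_cycles - 1)
    phase = t_arr - cyc * s.period
    in_high = phase < t_high
    out = np.empty_like(t_arr)
    out[in_high] = s.high_fraction + (
        start_high[cyc[in_high]] - s.high_fraction
    ) * np.exp(-phase[in_high] / tau)
    out[~in_high] = s.low_fraction + (
        start_low[cyc[~in_high]] - s.low_fraction
    ) * np.exp(-(phase[~in_high] - t_high) / tau)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class TopBoundary:
    """Top-of-stack condition: sealed (no_flux) or held at a fixed gas fraction.

    The physical top condition (media column, bath) is under-characterized in
    typical experiments; "no_flux" is the default because exchange of the
    overlying liquid with ambient air is slow relative to one hypoxia cycle.
    A media column can instead be modelled explicitly as a "media" layer.
    """

    kind: Literal["no_flux", "fixed_fraction"] = "no_flux"
    fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed_fraction":
            if self.fraction is None or not 0.0 <= self.fraction <= 1.0:
                raise ValueError("fixed_fraction boundary needs fraction in [0, 1]")
        elif self.kind != "no_flux":
            raise ValueError(f"unknown top boundary kind {self.kind!r}")


@dataclass(frozen=True)
class Stack:
    """Ordered layers, bottom → top (membrane first when present).

    The bottom boundary is Dirichlet in partial pressure, driven by the gas
    schedule; the top boundary is a :class:`TopBoundary`.
    """

    layers: tuple[Layer, ...]
    top: TopBoundary = TopBoundary()

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("stack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        kinds = [la.kind for la in self.layers]
        if "membrane" in kinds[1:]:
            raise ValueError("a membrane layer must be the bottom layer")

    @property
    def membrane(self) -> Layer | None:
        return self.layers[0] if self.layers[0].kind == "membrane" else None

    @property
    def z_origin_offset(self) -> float:
        """Distance from the stack bottom to z = 0 (membrane top)."""
        return self.layers[0].thickness if self.membrane is not None else 0.0

    @property
    def total_thickness(self) -> float:
        return sum(la.thickness for la in self.layers)

    @property
    def z_bottom(self) -> float:
        return -self.z_origin_offset

    @property
    def z_top(self) -> float:
        return self.total_thickness - self.z_origin_offset

    @property
    def scaffold_top(self) -> float:
        """z of the top of the highest non-media layer (the sample surface)."""
        z = self.z_bottom
        top = self.z_top
        for la in self.layers:
            z += la.thickness
            if la.kind != "media":
                top = z
        return top


@dataclass(frozen=True)
class Grid:
    """Vertex-centred spatial grid.

    Nodes are placed exactly on material interfaces so each inter-node segment
    lies in a single material; partial pressure is single-valued at interfaces
    (Henry-law pressure continuity), concentration jumps via the per-layer α.
    """

    z: np.ndarray                 # node positions, cm, strictly increasing
    segment_layer: np.ndarray     # layer index per inter-node segment
    stack: Stack

    @property
    def n_nodes(self) -> int:
        return self.z.size

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z)


def build_grid(stack: Stack, target_dz: float, min_nodes_per_layer: int = 21) -> Grid:
    """Discretize the stack with per-layer uniform spacing ≤ ``target_dz``.

    Every layer gets at least ``min_nodes_per_layer`` nodes (21 nodes = 20
    segments); interface nodes are shared between layers.
    """
    if target_dz <= 0:
        raise ValueError("target_dz must be positive")
    thinnest = min(la.thickness for la in stack.layers)
    if target_dz >= thinnest:
        raise ValueError(
            f"target_dz ({target_dz:g} cm) must be smaller than the thinnest "
            f"layer ({thinnest:g} cm)"
        )
    z_parts: list[np.ndarray] = []
    seg_layer: list[np.ndarray] = []
    z0 = stack.z_bottom
    for idx, la in enumerate(stack.layers):
        n_seg = max(int(math.ceil(la.thickness / target_dz)),
                    min_nodes_per_layer - 1)
        edges = z0 + la.thickness * np.arange(n_seg + 1) / n_seg
        if idx == 0:
            z_parts.append(edges)
        else:
            z_parts.append(edges[1:])
        seg_layer.append(np.full(n_seg, idx, dtype=int))
        z0 += la.thickness
    z = np.concatenate(z_parts)
    # pin exact endpoints against accumulated roundoff
    z[0] = stack.z_bottom
    z[-1] = stack.z_top
    return Grid(z=z, segment_layer=np.concatenate(seg_layer), stack=stack)
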