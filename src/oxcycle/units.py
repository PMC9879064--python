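"""Unit system, physical constants, and closed-form transport-time estimates.

The package works in one canonical unit system throughout:

* length — cm
* time — s
* concentration — mol/cm³
* pressure — mmHg (atmospheric reference 760 mmHg)
* gas composition — O₂ volume fraction in [0, 1]

User-facing %O₂ values are converted at the boundary (``fraction = percent/100``).
At 760 mmHg, a 20% O₂ gas phase corresponds to a partial pressure of 152 mmHg,
and with the Henry-law solubility of water (α = 1.1e-6 mol/(cm³·atm)) to a
dissolved concentration of 2.2e-7 mol/cm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GasConstants",
    "Solubility",
    "AtmosphericReference",
    "O2",
    "CO2",
    "ALPHA_WATER",
    "STANDARD_ATMOSPHERE",
    "MMHG_PER_ATM",
    "fraction_to_partial_pressure",
    "partial_pressure_to_fraction",
    "partial_pressure_to_concentration",
    "concentration_to_partial_pressure",
    "diffusion_time",
]

#: mmHg per standard atmosphere.
MMHG_PER_ATM = 760.0

#: Effective O₂ diffusivity used for ECM-type hydrogels, cm²/s.  Literature on
#: comparable gels (alginate, agarose, collagen, dense fibrin, rBM) puts the
#: hydrogel diffusivity near 75% of the value in water; the stored constant is
#: the rounded figure conventionally quoted for this class of gel.
D_HYDROGEL_O2 = 1.87e-5

#: Henry-law solubility of O₂ in water, mol/(cm³·atm).
_ALPHA_WATER_VALUE = 1.1e-6


@dataclass(frozen=True)
class GasConstants:
    """Diffusivities of one gas species in the materials of the layer stack.

    Parameters
    ----------
    species:
        Identifier of the gas ("O2" or "CO2").
    D_pdms:
        Diffusivity in the PDMS membrane, cm²/s.
    D_water:
        Diffusivity in water, cm²/s.
    hydrogel_fraction_of_water:
        Ratio D_hydrogel / D_water used by :meth:`D_hydrogel` when no printed
        hydrogel value is available.  ECM-type hydrogels sit around 0.75.
    D_hydrogel_printed:
        Conventional rounded hydrogel diffusivity, cm²/s; takes precedence
        over the 75%-of-water rule so that worked examples reproduce exactly.
    """

    species: str
    D_pdms: float
    D_water: float
    hydrogel_fraction_of_water: float = 0.75
    D_hydrogel_printed: float | None = None

    def __post_init__(self) -> None:
        if self.D_pdms <= 0 or self.D_water <= 0:
            raise ValueError("diffusivities must be positive")
        if not 0 < self.hydrogel_fraction_of_water <= 1:
            raise ValueError("hydrogel_fraction_of_water must be in (0, 1]")

    @property
    def D_hydrogel(self) -> float:
        """Hydrogel diffusivity, cm²/s (printed value if set, else the rule)."""
        if self.D_hydrogel_printed is not None:
            return self.D_hydrogel_printed
        return self.hydrogel_fraction_of_water * self.D_water


@dataclass(frozen=True)
class Solubility:
    """Henry-law solubility α, mol/(cm³·atm)."""

    alpha: float = _ALPHA_WATER_VALUE

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class AtmosphericReference:
    """Total ambient pressure, mmHg."""

    pressure: float = MMHG_PER_ATM

    def __post_init__(self) -> None:
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")


#: O₂ constants: PDMS is slightly more permeable than water.
O2 = GasConstants("O2", D_pdms=3.5e-5, D_water=2.5e-5,
                  D_hydrogel_printed=D_HYDROGEL_O2)

#: CO₂ constants (for intermittent-hypercapnia estimates).
CO2 = GasConstants("CO2", D_pdms=2.2e-5, D_water=2.1e-5)

#: Default solubility (water value).
ALPHA_WATER = Solubility()

STANDARD_ATMOSPHERE = AtmosphericReference()


def fraction_to_partial_pressure(
    fraction: float, atm: AtmosphericReference = STANDARD_ATMOSPHERE
) -> float:
    """Convert an O₂ volume fraction to a partial pressure in mmHg.

    ``fraction_to_partial_pressure(0.20)`` → 152 mmHg at 760 mmHg ambient.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    return fraction * atm.pressure


def partial_pressure_to_fraction(
    p: float, atm: AtmosphericReference = STANDARD_ATMOSPHERE
) -> float:
    """Inverse of :func:`fraction_to_partial_pressure`."""
    if p < 0:
        raise ValueError(f"partial pressure must be non-negative, got {p}")
    return p / atm.pressure


def partial_pressure_to_concentration(p: float, sol: Solubility = ALPHA_WATER) -> float:
    """Dissolved concentration C = α·(p/760), mol/cm³, for p in mmHg."""
    if p < 0:
        raise ValueError(f"partial pressure must be non-negative, got {p}")
    return sol.alpha * p / MMHG_PER_ATM


def concentration_to_partial_pressure(c: float, sol: Solubility = ALPHA_WATER) -> float:
    """Inverse of :func:`partial_pressure_to_concentration` (mmHg)."""
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c * MMHG_PER_ATM / sol.alpha


def diffusion_time(L: float, D: float) -> float:
    """Characteristic diffusion time Δt = L²/(6D), seconds.

    The L²/6D form (the point-source mean-square-displacement time in three
    dimensions) is the conventional quick estimate in this field and is applied
    to both membranes and slabs; it is a factor-of-3 optimistic relative to the
    planar relaxation time L²/2D, so treat it as an order-of-magnitude figure.
    A 500 μm hydrogel at D = 1.87e-5 cm²/s gives 22 s; 800 μm gives 57 s.
    """
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got {D}")
    if L < 0:
        raise ValueError(f"thickness must be non-negative, got {L}")
    return L * L / (6.0 * D)
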