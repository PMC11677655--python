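"""Equilibrium headspace prediction from liquid composition.

The gas phase above an essential oil is approximated as an ideal
(Raoult) solution in equilibrium with the liquid: each component's
partial pressure is its liquid mole fraction times its pure-component
vapor pressure, optionally scaled by an activity coefficient. Partial
pressures convert to mass concentrations through the ideal-gas law,

    C_i = x_i * gamma_i * P_vap,i * M_i / (R * T),

reported in mg/m^3 (the unit odor thresholds are tabulated in).
Measured headspace series are ingested through the same container type,
with a 1 ug/mL = 1000 mg/m^3 conversion at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import DegenerateInputError, MissingPropertyError, NotFoundError
from .quantify import CompositionTable
from .registry import Compound, CompoundRegistry

logger = logging.getLogger(__name__)

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = 8.314

#: Default experiment temperature (25 degC).
DEFAULT_TEMPERATURE_K = 298.15


def ug_per_ml_to_mg_m3(value: float) -> float:
    """Convert a gas concentration from ug/mL to the canonical mg/m^3."""
    return value * 1000.0


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """One gas-phase concentration, canonical unit mg/m^3."""

    compound: str
    concentration: float  # mg/m^3
    time: float = 0.0  # min
    port_distance: float | None = None  # mm from the liquid-vapor interface
    source: str = "measured"  # "measured" | "predicted"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.time < 0:
            raise ValueError("time must be >= 0")


def mole_fractions_from_areas(
    table: CompositionTable, registry: CompoundRegistry
) -> list[tuple[str, float]]:
    """Liquid mole fractions from GC area percentages.

    Treats area % as proportional to mass, so moles scale as
    area_i / M_i. Every compound in the table must resolve in the
    registry. Fractions sum to 1 within 1e-9.
    """
    moles: list[tuple[str, float]] = []
    for row in table.rows:
        compound = registry.get(row.compound)  # raises NotFoundError when absent
        moles.append((row.compound, row.area_percent / compound.molar_mass))
    total = sum(m for _, m in moles)
    if total <= 0:
        raise DegenerateInputError("all areas are zero; mole fractions undefined")
    return [(name, m / total) for name, m in moles]


def ideal_headspace_concentration(
    x: float,
    compound: Compound,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    activity_coefficient: float = 1.0,
) -> float:
    """Ideal-solution headspace concentration of one component, mg/m^3.

    Partial pressure p = gamma * x * P_vap; ideal-gas conversion
    C = p * M / (R * T) in g/m^3, returned as mg/m^3.
    """
    if not 0 <= x <= 1:
        raise ValueError("mole fraction must lie in [0, 1]")
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0 K")
    if compound.vapor_pressure is None:
        raise MissingPropertyError(f"{compound.name}: vapor pressure unavailable")
    partial_pressure = activity_coefficient * x * compound.vapor_pressure  # Pa
    grams_per_m3 = partial_pressure * compound.molar_mass / (GAS_CONSTANT * temperature_k)
    return grams_per_m3 * 1000.0


def headspace_profile(
    table: CompositionTable,
    registry: CompoundRegistry,
    temperature_k: float = DEFAULT_TEMPERATURE_K,
    activity_coefficients: dict[str, float] | None = None,
    strict: bool = True,
) -> list[ConcentrationMeasurement]:
    """Predict the full equilibrium headspace for a composition.

    Compounds lacking a vapor pressure are omitted with a logged
    warning. With ``strict=False``, compounds absent from the registry
    are likewise omitted (logged) instead of raising, which is how the
    radar chain restricts a full GC table to its property subset.
    """
    usable = table
    if not strict:
        missing = [r.compound for r in table.rows if r.compound not in registry]
        if missing:
            logger.warning("omitting %d compound(s) without registry entries: %s",
                           len(missing), ", ".join(missing))
        usable = table.subset(n for n in table.compounds if n in registry)
        if len(usable) == 0:
            raise DegenerateInputError("no table compound is present in the registry")

    fractions = mole_fractions_from_areas(usable, registry)
    gammas = activity_coefficients or {}
    out: list[ConcentrationMeasurement] = []
    for name, x in fractions:
        compound = registry.get(name)
        if compound.vapor_pressure is None:
            logger.warning("omitting %s: vapor pressure unavailable", name)
            continue
        conc = ideal_headspace_concentration(
            x, compound, temperature_k, gammas.get(name, 1.0)
        )
        out.append(
            ConcentrationMeasurement(
                compound=name, concentration=conc, source="predicted"
            )
        )
    if not out:
        raise DegenerateInputError("no compound has a usable vapor pressure")
    return out


def read_headspace_csv(path) -> list[ConcentrationMeasurement]:
    """Read measured headspace series: ``compound,time_min,port_mm,concentration_ug_per_ml``."""
    import pandas as pd

    frame = pd.read_csv(path)
    out = []
    for r in frame.itertuples():
        out.append(
            ConcentrationMeasurement(
                compound=str(r.compound),
                concentration=ug_per_ml_to_mg_m3(float(r.concentration_ug_per_ml)),
                time=float(getattr(r, "time_min", 0.0) or 0.0),
                port_distance=None if pd.isna(getattr(r, "port_mm", None)) else float(r.port_mm),
            )
        )
    return out
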