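"""Conversion of reported fluxes to canonical units (g gas m⁻² yr⁻¹).

Three steps, applied in order where relevant:

1. ``to_gas_mass`` — rewrite the reported rate on a gas-mass basis
   (element-basis and molar rates are scaled by molar-mass ratios);
2. ``annualize`` — multiply a daily rate by the ice-free season length
   (sites with seasonal ice/snow cover) or by 365 otherwise;
3. ``night_correct_co2`` — optionally scale daytime-only CO₂ rates by a
   night-time correction factor (default 1.27).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .data_model import GAS_CONSTANTS, GASES, GasConstants

logger = logging.getLogger("ditchflux")


@dataclass(frozen=True)
class RawFlux:
    value: float
    unit: str
    gas: str


# unit -> (scale to grams, basis, time basis). "element" basis means the rate
# is reported as mass of C or N; "mol" as moles of gas.
UNIT_DEFS: dict[str, tuple[float, str, str]] = {
    "g_gas_m2_d": (1.0, "gas", "d"),
    "mg_gas_m2_d": (1e-3, "gas", "d"),
    "g_gas_m2_yr": (1.0, "gas", "yr"),
    "mg_gas_m2_yr": (1e-3, "gas", "yr"),
    "mol_gas_m2_d": (1.0, "mol", "d"),
    "mmol_gas_m2_d": (1e-3, "mol", "d"),
    "umol_gas_m2_d": (1e-6, "mol", "d"),
    "g_element_m2_d": (1.0, "element", "d"),
    "mg_element_m2_d": (1e-3, "element", "d"),
    "g_element_m2_yr": (1.0, "element", "yr"),
}


def to_gas_mass(
    value: float, unit: str, gas: str, constants: GasConstants = GAS_CONSTANTS
) -> float:
    """Convert a reported rate to g gas m⁻² per the unit's own time basis.

    Element-basis rates are multiplied by molar_mass(gas)/element_mass
    (e.g. C→CO₂ by 44.01/12.01), molar rates by the molar mass. The time
    basis (per day / per year) is left untouched.
    """
    if gas not in GASES:
        raise ValueError(f"unknown gas: {gas!r}")
    try:
        scale, basis, _ = UNIT_DEFS[unit]
    except KeyError:
        raise ValueError(f"unknown flux unit: {unit!r}") from None
    grams = value * scale
    if basis == "gas":
        return grams
    if basis == "mol":
        return grams * constants.molar_mass[gas]
    # element basis
    return grams * constants.molar_mass[gas] / constants.element_mass[gas]


def unit_time_basis(unit: str) -> str:
    """'d' or 'yr' for a recognized unit."""
    try:
        return UNIT_DEFS[unit][2]
    except KeyError:
        raise ValueError(f"unknown flux unit: {unit!r}") from None


def annualize(daily_flux: float, season_length_days: int | None = None) -> float:
    """Daily → annual flux.

    Sites with seasonal ice/snow cover contribute only over the ice-free
    season, so their daily rate is multiplied by the season length;
    everywhere else by 365. Sign is preserved.
    """
    if season_length_days is None:
        return daily_flux * 365.0
    if not 1 <= season_length_days <= 365:
        raise ValueError(
            f"season_length_days must be in 1..365, got {season_length_days}"
        )
    return daily_flux * float(season_length_days)


def night_correct_co2(
    annual_co2: float, daytime_only: bool, factor: float = 1.27
) -> float:
    """Scale a daytime-only CO₂ flux for higher night-time emissions.

    Applies only when the measurement covered daytime only; the default
    factor 1.27 reflects 27% higher night-time CO₂ emissions. CO₂ only —
    no analogous correction is defined for CH₄ or N₂O.
    """
    if factor <= 0:
        raise ValueError(f"night correction factor must be positive, got {factor}")
    return annual_co2 * factor if daytime_only else annual_co2


def element_basis(
    flux_gas: float, gas: str, constants: GasConstants = GAS_CONSTANTS
) -> float:
    """g gas m⁻² yr⁻¹ → g element m⁻² yr⁻¹ (CO₂→C, N₂O→N, CH₄→C)."""
    if gas not in GASES:
        raise ValueError(f"unknown gas: {gas!r}")
    return flux_gas * constants.element_fraction(gas)


def harmonize_record_flux(
    value: float,
    unit: str,
    gas: str,
    season_length_days: int | None = None,
    daytime_only: bool = False,
    night_correction: bool = False,
    night_factor: float = 1.27,
    constants: GasConstants = GAS_CONSTANTS,
) -> float:
    """Full raw → canonical pipeline for one reported rate.

    Converts to gas mass, annualizes if the unit is a daily rate, and (for
    CO₂, when enabled) applies the night-time correction. Night correction
    is off by default: it belongs to the refined emission-factor variant,
    not to the site-level summary statistics.
    """
    grams = to_gas_mass(value, unit, gas, constants)
    annual = (
        annualize(grams, season_length_days)
        if unit_time_basis(unit) == "d"
        else grams
    )
    if gas == "CO2" and night_correction:
        annual = night_correct_co2(annual, daytime_only, night_factor)
    logger.debug("harmonized %s %s %s -> %.6g g %s m-2 yr-1", value, unit, gas, annual, gas)
    return annual
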