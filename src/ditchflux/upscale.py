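"""Global upscaling: areal flux means → global element-basis emissions.

The estimate is deliberately simple, mirroring Tier-1-style inventory
arithmetic: global emission = mean areal flux × global ditch surface area,
converted to an element basis (CO₂ → C, N₂O → N). Uncertainty propagates
the t-based 95% CI of the flux mean at fixed central area; an optional
Monte Carlo mode additionally samples the area over its published range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import GAS_CONSTANTS, GLOBAL_DEFAULT, GasConstants, GlobalConstants

M2_PER_HA = 1e4
TG_PER_G = 1e-12


def mean_ci(
    fluxes: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Sample mean with a two-sided t-interval: mean ± t·sd/√n."""
    arr = np.asarray(fluxes, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if not np.all(np.isfinite(arr)):
        raise ValueError("fluxes must be finite")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    t = float(stats.t.ppf((1 + confidence) / 2, arr.size - 1))
    half = t * sem
    return mean, mean - half, mean + half


@dataclass
class UpscaleResult:
    gas: str
    element: str
    mean_flux: float  # g gas m-2 yr-1
    flux_ci: tuple[float, float]
    area_ha: float
    emission_tg: float  # Tg element yr-1
    emission_ci: tuple[float, float]
    budget_shares: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "gas": self.gas,
            "element": self.element,
            "mean_flux_g_gas_m2_yr": self.mean_flux,
            "flux_ci": list(self.flux_ci),
            "area_ha": self.area_ha,
            "emission_Tg_element_yr": self.emission_tg,
            "emission_ci": list(self.emission_ci),
            "budget_shares_percent": self.budget_shares,
        }


def _flux_to_tg(flux: float, area_ha: float, gas: str, constants: GasConstants) -> float:
    return flux * area_ha * M2_PER_HA * constants.element_fraction(gas) * TG_PER_G


def upscale_global(
    mean_flux: float,
    ci: tuple[float, float],
    area_ha: float,
    gas: str,
    constants: GasConstants = GAS_CONSTANTS,
) -> UpscaleResult:
    """Mean areal flux (with CI) → global emission in Tg element yr⁻¹.

    emission = flux × (area_ha × 10⁴ m² ha⁻¹) × element_fraction × 10⁻¹² Tg/g,
    applied identically to the mean and both CI bounds.
    """
    if area_ha <= 0:
        raise ValueError(f"area must be positive, got {area_ha}")
    emission = _flux_to_tg(mean_flux, area_ha, gas, constants)
    eci = tuple(_flux_to_tg(b, area_ha, gas, constants) for b in ci)
    return UpscaleResult(
        gas=gas,
        element=constants.element[gas],
        mean_flux=mean_flux,
        flux_ci=tuple(ci),
        area_ha=area_ha,
        emission_tg=emission,
        emission_ci=eci,
    )


def percent_of_budget(emission_tg: float, budget_tg: float) -> float:
    """Emission as a percentage of a global budget denominator."""
    if budget_tg <= 0:
        raise ValueError(f"budget must be positive, got {budget_tg}")
    return 100.0 * emission_tg / budget_tg


def add_budget_shares(
    result: UpscaleResult, budgets: Mapping[str, float]
) -> UpscaleResult:
    """Attach central/low/high percent-of-budget shares for each budget."""
    for name, denom in budgets.items():
        result.budget_shares[name] = {
            "central": percent_of_budget(result.emission_tg, denom),
            "low": percent_of_budget(result.emission_ci[0], denom),
            "high": percent_of_budget(result.emission_ci[1], denom),
        }
    return result


def emission_factor(
    fluxes: Sequence[float],
    gas: str,
    confidence: float = 0.95,
    constants: GasConstants = GAS_CONSTANTS,
) -> tuple[float, float, float]:
    """Tier-1-style emission factor in t element ha⁻¹ yr⁻¹ with 95% CI.

    g gas m⁻² yr⁻¹ × element_fraction × 10⁻² = t element ha⁻¹ yr⁻¹
    (10⁴ m² ha⁻¹ / 10⁶ g t⁻¹).
    """
    mean, low, high = mean_ci(fluxes, confidence)
    scale = constants.element_fraction(gas) * 1e-2
    return mean * scale, low * scale, high * scale


def flux_to_emission_factor(
    flux: float, gas: str, constants: GasConstants = GAS_CONSTANTS
) -> float:
    """Single-value g gas m⁻² yr⁻¹ → t element ha⁻¹ yr⁻¹ conversion."""
    return flux * constants.element_fraction(gas) * 1e-2


def ditch_area(drained_area_ha: float, frac_ditch: float) -> float:
    """Ditch water-surface area from drained land area × Frac_ditch."""
    if not 0 < frac_ditch <= 1:
        raise ValueError(f"frac_ditch must be in (0, 1], got {frac_ditch}")
    return drained_area_ha * frac_ditch


def monte_carlo_emission(
    fluxes: Sequence[float],
    gas: str,
    constants: GasConstants = GAS_CONSTANTS,
    global_constants: GlobalConstants = GLOBAL_DEFAULT,
    n_draws: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Optional Monte Carlo interval sampling area over its published range.

    Draws the flux mean from its t-distribution and the ditch area uniformly
    over the published range, reporting the 2.5/50/97.5 percentiles of the
    implied global emission (Tg element yr⁻¹). Wider than the fixed-area CI
    by construction; reported separately, never in its place.
    """
    arr = np.asarray(fluxes, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    sem = arr.std(ddof=1) / np.sqrt(arr.size)
    mean_draws = arr.mean() + sem * rng.standard_t(arr.size - 1, size=n_draws)
    area_draws = rng.uniform(*global_constants.ditch_area_range_ha, size=n_draws)
    tg = (
        mean_draws * area_draws * M2_PER_HA * constants.element_fraction(gas) * TG_PER_G
    )
    lo, med, hi = np.percentile(tg, [2.5, 50, 97.5])
    return {"low": float(lo), "median": float(med), "high": float(hi)}


def upscale_report_json(results: Sequence[UpscaleResult]) -> str:
    return json.dumps([r.to_dict() for r in results], indent=2)
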