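"""CO₂-equivalent accounting and per-gas contribution shares.

Two metrics are supported:

* ``gwp100`` — the pulse-emission Global Warming Potential over 100 years
  (CH₄ 27, N₂O 273), applied regardless of flux sign;
* ``sustained`` — sustained-flux factors: persistent emissions use the
  SGWP₁₀₀ (CH₄ 45, N₂O 270) while persistent uptake uses the SGCP₁₀₀
  (CH₄ 203, N₂O 349). CO₂ has factor 1 in both directions.

Shares are percentages of the summed absolute contributions, so they always
total 100% and remain meaningful when a gas is a net sink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data_model import GWP_DEFAULT, GwpCoefficients

METRICS = ("gwp100", "sustained")


@dataclass
class Ch4Total:
    value: float
    ebullition_missing: bool


def ch4_total(
    diffusive: float | None, ebullitive: float | None
) -> Ch4Total | None:
    """Total CH₄ flux = diffusive + ebullitive.

    When ebullition was not measured it contributes 0 and the result is
    flagged, since total CH₄ is then likely an underestimate. Both absent →
    no result.
    """
    if diffusive is None and ebullitive is None:
        return None
    missing = ebullitive is None
    return Ch4Total((diffusive or 0.0) + (ebullitive or 0.0), missing)


@dataclass
class Co2eqBreakdown:
    """Per-gas CO₂-equivalent fluxes (g CO₂-eq m⁻² yr⁻¹) and percent shares."""

    contributions: dict[str, float]
    shares: dict[str, float]
    total: float
    metric: str
    ebullition_missing: bool = False


def co2eq(
    co2: float | None,
    ch4: float | None,
    n2o: float | None,
    metric: str = "gwp100",
    coefficients: GwpCoefficients = GWP_DEFAULT,
) -> Co2eqBreakdown:
    """CO₂-equivalent breakdown of one record's multi-gas fluxes.

    ``ch4`` is the total (diffusive + ebullitive) CH₄ flux. Under the
    sustained metric the SGWP applies to positive and the SGCP to negative
    fluxes, per gas. Absent gases contribute 0 and receive a 0 share.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric: {metric!r}")
    if co2 is None and ch4 is None and n2o is None:
        raise ValueError("at least one gas flux must be present")
    fluxes = {"CO2": co2, "CH4": ch4, "N2O": n2o}
    contributions: dict[str, float] = {}
    for gas, fx in fluxes.items():
        if fx is None:
            contributions[gas] = 0.0
        elif metric == "gwp100":
            contributions[gas] = fx * coefficients.gwp100[gas]
        else:
            table = coefficients.sgwp100 if fx >= 0 else coefficients.sgcp100
            contributions[gas] = fx * table[gas]
    denom = sum(abs(c) for c in contributions.values())
    shares = {
        gas: (100.0 * abs(c) / denom if denom > 0 else 0.0)
        for gas, c in contributions.items()
    }
    return Co2eqBreakdown(
        contributions, shares, total=sum(contributions.values()), metric=metric
    )


def record_co2eq(
    record, metric: str = "gwp100", coefficients: GwpCoefficients = GWP_DEFAULT
) -> Co2eqBreakdown:
    """``co2eq`` applied to a FluxObservation, totalling CH₄ first."""
    ch4 = ch4_total(record.ch4_diffusive, record.ch4_ebullitive)
    breakdown = co2eq(
        record.co2_flux,
        None if ch4 is None else ch4.value,
        record.n2o_flux,
        metric=metric,
        coefficients=coefficients,
    )
    breakdown.ebullition_missing = bool(ch4 is not None and ch4.ebullition_missing)
    return breakdown


def mean_contribution_shares(
    records: Sequence,
    metric: str = "gwp100",
    coefficients: GwpCoefficients = GWP_DEFAULT,
    aggregation: str = "mean_of_shares",
) -> dict[str, float]:
    """Aggregate per-gas shares over an all-three-gas subset of records.

    ``mean_of_shares`` (default) averages each record's percent shares and
    renormalizes to 100; ``pooled`` sums the absolute CO₂-eq contributions
    across records first and takes shares of the pooled totals. Records
    missing any of the three gases are rejected.
    """
    if aggregation not in ("mean_of_shares", "pooled"):
        raise ValueError(f"unknown aggregation: {aggregation!r}")
    if len(records) == 0:
        raise ValueError("empty record subset")
    for rec in records:
        if rec.co2_flux is None or rec.n2o_flux is None or (
            rec.ch4_diffusive is None and rec.ch4_ebullitive is None
        ):
            raise ValueError(f"site {rec.site_id}: subset requires all three gases")
    breakdowns = [record_co2eq(r, metric, coefficients) for r in records]
    gases = ("CO2", "CH4", "N2O")
    if aggregation == "mean_of_shares":
        raw = {g: float(np.mean([b.shares[g] for b in breakdowns])) for g in gases}
    else:
        pooled = {g: sum(abs(b.contributions[g]) for b in breakdowns) for g in gases}
        denom = sum(pooled.values())
        raw = {g: 100.0 * pooled[g] / denom for g in gases}
    total = sum(raw.values())
    return {g: 100.0 * raw[g] / total for g in gases}
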