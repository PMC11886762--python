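"""Categorical site classification: climate, land use, trophic state, hydrology.

All classifiers are pure and total: anything outside the recognized
vocabulary maps to ``"unknown"`` with a logged warning rather than raising,
so a partially documented literature site never aborts the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("ditchflux")


# Köppen main group (first letter) -> climate class. Polar (E) sites are not
# represented in the compiled database and are flagged unknown.
_KOPPEN_MAIN = {
    "A": "tropical",
    "B": "arid",
    "C": "temperate",
    "D": "continental",
}

# Corine Land Cover labels (level 1 and common level-2/3 labels), lowercased.
_CORINE = {
    # artificial surfaces -> urban
    "artificial surfaces": "urban",
    "continuous urban fabric": "urban",
    "discontinuous urban fabric": "urban",
    "industrial or commercial units": "urban",
    "green urban areas": "urban",
    # agricultural areas
    "agricultural areas": "agriculture",
    "arable land": "agriculture",
    "non-irrigated arable land": "agriculture",
    "permanently irrigated land": "agriculture",
    "pastures": "agriculture",
    "rice fields": "agriculture",
    "heterogeneous agricultural areas": "agriculture",
    "permanent crops": "agriculture",
    # forest and semi-natural areas
    "forest and semi-natural areas": "natural_forest",
    "forests": "natural_forest",
    "broad-leaved forest": "natural_forest",
    "coniferous forest": "natural_forest",
    "mixed forest": "natural_forest",
    "natural grasslands": "natural_forest",
    "moors and heathland": "natural_forest",
    "transitional woodland-shrub": "natural_forest",
    # wetlands
    "wetlands": "wetland",
    "inland marshes": "wetland",
    "peat bogs": "wetland",
    "salt marshes": "wetland",
}


def classify_climate(koppen_code: str) -> str:
    """Köppen–Geiger code → one of four main climate classes.

    Only the first letter matters: A→tropical, B→arid, C→temperate,
    D→continental. Polar codes (E) and unparseable strings → unknown.
    """
    code = (koppen_code or "").strip()
    if not code:
        logger.warning("empty Köppen code; climate set to unknown")
        return "unknown"
    main = code[0].upper()
    if main == "E":
        logger.warning("polar Köppen code %r; climate set to unknown", koppen_code)
        return "unknown"
    cls = _KOPPEN_MAIN.get(main)
    if cls is None:
        logger.warning("unparseable Köppen code %r; climate set to unknown", koppen_code)
        return "unknown"
    return cls


def classify_land_use(corine_label: str) -> str:
    """Corine Land Cover label → {agriculture, natural_forest, urban, wetland}."""
    label = (corine_label or "").strip().lower()
    cls = _CORINE.get(label)
    if cls is None:
        logger.warning("unmapped Corine label %r; land use set to unknown", corine_label)
        return "unknown"
    return cls


@dataclass(frozen=True)
class TrophicThresholds:
    """Ascending cut points separating oligo/meso/eu/hypereutrophic.

    Defaults follow the freshwater nutrient scheme of Smith et al.:
    TP (µg L⁻¹) 10/30/100, TN (µg L⁻¹) 350/650/1200, chl-a (µg L⁻¹)
    3.5/9/25. Overridable via config.
    """

    tp: tuple[float, float, float] = (10.0, 30.0, 100.0)
    tn: tuple[float, float, float] = (350.0, 650.0, 1200.0)
    chl_a: tuple[float, float, float] = (3.5, 9.0, 25.0)

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "chl_a"):
            cuts = getattr(self, name)
            if not (cuts[0] < cuts[1] < cuts[2]):
                raise ValueError(f"{name} cut points must be strictly increasing")


_CLASSES = ("oligotrophic", "mesotrophic", "eutrophic", "hypereutrophic")

DEFAULT_THRESHOLDS = TrophicThresholds()


def _vote(value: float, cuts: tuple[float, float, float]) -> int:
    return sum(value > c for c in cuts)


def classify_trophic(
    tp: float | None = None,
    tn: float | None = None,
    chl_a: float | None = None,
    thresholds: TrophicThresholds = DEFAULT_THRESHOLDS,
    rule: str = "max",
) -> str:
    """Trophic state from TP, TN and/or chlorophyll-a concentrations.

    Each available variable votes through its own cut points; with
    ``rule="max"`` (default) the final class is the most eutrophic vote — a
    precautionary maximum. ``rule="tp_priority"`` uses TP alone when present
    and falls back to the max rule otherwise. All-absent → unknown.
    """
    if rule not in ("max", "tp_priority"):
        raise ValueError(f"unknown tie rule: {rule!r}")
    for name, value in (("tp", tp), ("tn", tn), ("chl_a", chl_a)):
        if value is not None and value < 0:
            raise ValueError(f"negative concentration {name}={value}")
    if rule == "tp_priority" and tp is not None:
        return _CLASSES[_vote(tp, thresholds.tp)]
    votes = [
        _vote(value, getattr(thresholds, name))
        for name, value in (("tp", tp), ("tn", tn), ("chl_a", chl_a))
        if value is not None
    ]
    if not votes:
        return "unknown"
    return _CLASSES[max(votes)]


def classify_hydrology(ever_dry: bool, currently_dry: bool) -> str:
    """Hydrological regime from drying history and state at sampling."""
    if not ever_dry:
        return "perennial"
    return "nonperennial_dry" if currently_dry else "nonperennial_wet"
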