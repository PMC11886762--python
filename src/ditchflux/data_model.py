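"""Observation schema, categorical vocabularies, constants and CSV I/O.

The unit conventions used throughout the package:

* fluxes are areal annual rates in g gas m⁻² yr⁻¹, signed with the
  atmosphere-positive convention (emission > 0, uptake < 0);
* global emissions are expressed on an element basis (Tg C or Tg N yr⁻¹);
* concentrations follow the column comments below (mg L⁻¹ or µg L⁻¹).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("ditchflux")

# ---------------------------------------------------------------------------
# categorical vocabularies

CLIMATES = ("continental", "temperate", "arid", "tropical", "unknown")
LAND_USES = ("agriculture", "natural_forest", "urban", "wetland", "unknown")
TROPHIC_STATES = (
    "oligotrophic",
    "mesotrophic",
    "eutrophic",
    "hypereutrophic",
    "unknown",
)
SOIL_TYPES = ("mineral", "organic", "unknown")
HYDRO_REGIMES = ("perennial", "nonperennial_wet", "nonperennial_dry", "unknown")
VEGETATION = ("present", "absent", "unknown")
METHODS = ("floating_chamber", "dissolved_concentration", "unknown")

GASES = ("CO2", "N2O", "CH4")

_ENUM_FIELDS: dict[str, tuple[str, ...]] = {
    "climate": CLIMATES,
    "land_use": LAND_USES,
    "trophic_state": TROPHIC_STATES,
    "soil_type": SOIL_TYPES,
    "hydro_regime": HYDRO_REGIMES,
    "vegetation": VEGETATION,
    "method": METHODS,
}

# quantitative covariates: attribute -> unit (documentation only)
COVARIATES: dict[str, str] = {
    "do": "mg L-1",
    "ph": "unitless",
    "ec": "uS cm-1",
    "doc": "mg L-1",
    "tp": "ug L-1",
    "tn": "ug L-1",
    "chl_a": "ug L-1",
    "no3_n": "mg L-1",
    "cn_ratio": "unitless",
    "width": "m",
    "depth": "m",
    "velocity": "m s-1",
    "discharge": "m3 s-1",
    "mat": "degC",
    "map_mm": "mm yr-1",
}


@dataclass
class FluxObservation:
    """One ditch site-condition record.

    Fluxes are annualized rates in g gas m⁻² yr⁻¹ (signed). ``daily_flux_*``
    carry the pre-harmonization reported rate, when known, so the
    harmonization step can be exercised/re-run.
    """

    site_id: str
    latitude: float | None = None
    longitude: float | None = None
    elevation: float | None = None
    climate: str = "unknown"
    land_use: str = "unknown"
    trophic_state: str = "unknown"
    soil_type: str = "unknown"
    hydro_regime: str = "unknown"
    vegetation: str = "unknown"
    method: str = "unknown"
    co2_flux: float | None = None
    n2o_flux: float | None = None
    ch4_diffusive: float | None = None
    ch4_ebullitive: float | None = None
    do: float | None = None
    ph: float | None = None
    ec: float | None = None
    doc: float | None = None
    tp: float | None = None
    tn: float | None = None
    chl_a: float | None = None
    no3_n: float | None = None
    cn_ratio: float | None = None
    width: float | None = None
    depth: float | None = None
    velocity: float | None = None
    discharge: float | None = None
    mat: float | None = None
    map_mm: float | None = None
    daily_flux_value: float | None = None
    daily_flux_unit: str | None = None
    daily_flux_gas: str | None = None
    season_length_days: int | None = None
    daytime_only: bool = False


FLUX_FIELDS = ("co2_flux", "n2o_flux", "ch4_diffusive", "ch4_ebullitive")

#: canonical CSV column order
COLUMNS: tuple[str, ...] = tuple(f.name for f in dataclasses.fields(FluxObservation))

_FLOAT_FIELDS = {
    "latitude",
    "longitude",
    "elevation",
    *FLUX_FIELDS,
    *COVARIATES,
    "daily_flux_value",
}


# ---------------------------------------------------------------------------
# physical and accounting constants


@dataclass(frozen=True)
class GasConstants:
    """Molar masses and element-basis ratios (g mol⁻¹).

    ``element_mass`` is the mass of the reported element per mole of gas:
    one C (12.01) in CO₂ and CH₄, two N (28.01) in N₂O.
    """

    molar_mass: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 44.01, "N2O": 44.01, "CH4": 16.04}
    )
    element: Mapping[str, str] = field(
        default_factory=lambda: {"CO2": "C", "N2O": "N", "CH4": "C"}
    )
    element_mass: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 12.01, "N2O": 28.01, "CH4": 12.01}
    )

    def element_fraction(self, gas: str) -> float:
        return self.element_mass[gas] / self.molar_mass[gas]


@dataclass(frozen=True)
class GwpCoefficients:
    """100-year CO₂-equivalence factors.

    ``gwp100`` is the pulse-emission metric; ``sgwp100``/``sgcp100`` are the
    sustained-flux factors applied to persistent emission and persistent
    uptake respectively.
    """

    gwp100: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 1.0, "CH4": 27.0, "N2O": 273.0}
    )
    sgwp100: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 1.0, "CH4": 45.0, "N2O": 270.0}
    )
    sgcp100: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 1.0, "CH4": 203.0, "N2O": 349.0}
    )


@dataclass(frozen=True)
class GlobalConstants:
    """Global ditch surface area and the budget denominators.

    Budgets are in Tg element yr⁻¹ (1 Pg = 1000 Tg).
    """

    ditch_area_ha: float = 5_353_000.0
    ditch_area_range_ha: tuple[float, float] = (1_420_000.0, 10_700_000.0)
    frac_ditch: float = 0.03
    frac_ditch_range: tuple[float, float] = (0.01, 0.05)
    budgets: Mapping[str, float] = field(
        default_factory=lambda: {
            "anthropogenic_co2": 11_100.0,  # Tg C yr-1 (11.1 Pg C)
            "inland_water_co2": 3_900.0,  # Tg C yr-1 (3.9 Pg C)
            "anthropogenic_n2o": 6.5,  # Tg N yr-1
            "inland_water_n2o": 0.5,  # Tg N yr-1
        }
    )
    night_correction_factor: float = 1.27


GAS_CONSTANTS = GasConstants()
GWP_DEFAULT = GwpCoefficients()
GLOBAL_DEFAULT = GlobalConstants()


def load_constants(path: str | Path) -> tuple[GlobalConstants, GwpCoefficients]:
    """Load constant overrides from a YAML or JSON config file.

    Top-level keys ``global`` and ``gwp`` each hold field overrides; absent
    keys fall back to the package defaults, so a config needs to list only
    what it changes.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    gconf = dict(data.get("global", {}))
    for key in ("ditch_area_range_ha", "frac_ditch_range"):
        if key in gconf:
            gconf[key] = tuple(gconf[key])
    glob = dataclasses.replace(GlobalConstants(), **gconf)
    gwp = dataclasses.replace(GwpCoefficients(), **data.get("gwp", {}))
    _check_constants(glob, gwp)
    return glob, gwp


def dump_default_config(path: str | Path) -> None:
    data = {
        "global": dataclasses.asdict(GlobalConstants()),
        "gwp": dataclasses.asdict(GwpCoefficients()),
    }
    data["global"]["ditch_area_range_ha"] = list(
        data["global"]["ditch_area_range_ha"]
    )
    data["global"]["frac_ditch_range"] = list(data["global"]["frac_ditch_range"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _check_constants(glob: GlobalConstants, gwp: GwpCoefficients) -> None:
    lo, hi = glob.ditch_area_range_ha
    if not (0 < lo <= glob.ditch_area_ha <= hi):
        raise ValueError("ditch area range must bracket the central value")
    if any(v <= 0 for v in glob.budgets.values()):
        raise ValueError("budget denominators must be positive")
    for table in (gwp.gwp100, gwp.sgwp100, gwp.sgcp100):
        if any(v <= 0 for v in table.values()):
            raise ValueError("GWP coefficients must be positive")


# ---------------------------------------------------------------------------
# CSV read / write / validate


def _parse_float(raw: object, column: str, site: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        logger.warning("site %s: cannot parse %s=%r; treated as missing", site, column, raw)
        return None


def read_observations(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[FluxObservation]:
    """Read per-site observations from a CSV file.

    ``column_map`` maps *file* column names onto canonical schema names so
    third-party tables can be ingested without editing. Unknown categorical
    strings fall back to ``"unknown"`` and numeric parse failures to missing,
    each with a logged warning; the row count is always preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[1] == 0 or (frame.shape[0] == 0 and frame.shape[1] == 0):
        raise ValueError(f"{path}: empty file")
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    if "site_id" not in frame.columns:
        raise ValueError(f"{path}: mandatory column 'site_id' is missing")

    records: list[FluxObservation] = []
    known = set(COLUMNS)
    for _, row in frame.iterrows():
        site = str(row["site_id"])
        kwargs: dict[str, object] = {"site_id": site}
        for col in frame.columns:
            if col not in known or col == "site_id":
                continue
            raw = row[col]
            text = str(raw).strip() if raw is not None else ""
            if col in _FLOAT_FIELDS:
                kwargs[col] = _parse_float(raw, col, site)
            elif col in _ENUM_FIELDS:
                if not text:
                    kwargs[col] = "unknown"
                elif text in _ENUM_FIELDS[col]:
                    kwargs[col] = text
                else:
                    logger.warning(
                        "site %s: %s=%r not in vocabulary; mapped to 'unknown'",
                        site, col, text,
                    )
                    kwargs[col] = "unknown"
            elif col == "season_length_days":
                val = _parse_float(raw, col, site)
                kwargs[col] = int(val) if val is not None else None
            elif col == "daytime_only":
                kwargs[col] = text.lower() in ("true", "1", "yes")
            elif col in ("daily_flux_unit", "daily_flux_gas"):
                kwargs[col] = text or None
        records.append(FluxObservation(**kwargs))
    return records


def write_observations(records: Iterable[FluxObservation], path: str | Path) -> None:
    """Write records as CSV with deterministic column order.

    Missing values serialize as empty fields; floats keep full repr precision
    so read∘write round-trips exactly.
    """
    rows = []
    for rec in records:
        row = {}
        for col in COLUMNS:
            val = getattr(rec, col)
            if val is None:
                row[col] = ""
            elif isinstance(val, bool):
                row[col] = "true" if val else "false"
            elif isinstance(val, float):
                row[col] = repr(val)
            else:
                row[col] = val
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(path, index=False)


@dataclass
class ValidationReport:
    n_records: int
    violations: dict[str, int] = field(default_factory=dict)

    @property
    def n_violations(self) -> int:
        return sum(self.violations.values())

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def validate(records: Sequence[FluxObservation]) -> ValidationReport:
    """Check record invariants; returns per-invariant violation counts.

    Pure reporting: the input is never mutated and repeated calls yield
    identical reports.
    """
    report = ValidationReport(n_records=len(records))

    def hit(key: str) -> None:
        report.violations[key] = report.violations.get(key, 0) + 1

    for rec in records:
        for fieldname in FLUX_FIELDS:
            val = getattr(rec, fieldname)
            if val is not None and not math.isfinite(val):
                hit(f"{fieldname}_not_finite")
        if rec.ch4_ebullitive is not None and rec.ch4_ebullitive < 0:
            hit("ch4_ebullitive_negative")
        if rec.latitude is not None and not -90 <= rec.latitude <= 90:
            hit("latitude_out_of_bounds")
        if rec.longitude is not None and not -180 <= rec.longitude <= 180:
            hit("longitude_out_of_bounds")
        for fieldname, vocab in _ENUM_FIELDS.items():
            if getattr(rec, fieldname) not in vocab:
                hit(f"{fieldname}_invalid")
        if rec.season_length_days is not None and not 1 <= rec.season_length_days <= 365:
            hit("season_length_out_of_range")
    return report


def to_frame(records: Sequence[FluxObservation]) -> pd.DataFrame:
    """Records as a DataFrame (one row per observation, canonical columns)."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=list(COLUMNS))


def summary_json(report: ValidationReport) -> str:
    return json.dumps(
        {"n_records": report.n_records, "violations": report.violations}, indent=2
    )
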