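"""Nonparametric group comparisons and rank correlations.

The compiled flux data are strongly right-skewed with occasional net sinks,
so all comparisons are rank-based: Kruskal–Wallis for factors with more
than two levels, Mann–Whitney (Wilcoxon rank-sum) for two-level factors,
pairwise Wilcoxon with a multiplicity correction as the post hoc, and
Spearman rank correlations for quantitative covariates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("ditchflux")

ALPHA = 0.05

_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "BH": "fdr_bh"}

#: categorical factors tested per gas
FACTORS = (
    "method",
    "land_use",
    "climate",
    "trophic_state",
    "soil_type",
    "hydro_regime",
    "vegetation",
)

#: quantitative covariates screened per gas
COVARIATE_BATTERY = (
    "latitude",
    "elevation",
    "mat",
    "map_mm",
    "width",
    "depth",
    "velocity",
    "discharge",
    "do",
    "ph",
    "ec",
    "doc",
    "tp",
    "tn",
    "chl_a",
    "no3_n",
    "cn_ratio",
)


@dataclass
class GroupComparisonResult:
    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    df: int | None = None
    posthoc: pd.DataFrame | None = None


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    rho: float | None
    p: float | None
    n: int


def _clean_groups(
    values: Sequence[float], groups: Sequence[object]
) -> dict[object, np.ndarray]:
    """Group finite values by label, dropping missing values and 'unknown'."""
    out: dict[object, list[float]] = {}
    for v, g in zip(values, groups, strict=True):
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            continue
        if g == "unknown" or g is None:
            continue
        out.setdefault(g, []).append(float(v))
    return {g: np.asarray(vals) for g, vals in sorted(out.items(), key=lambda kv: str(kv[0]))}


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[object]
) -> GroupComparisonResult:
    """Kruskal–Wallis rank-sum test with tie correction.

    H is referred to a chi-square with k−1 degrees of freedom. The fully
    degenerate case (every value identical) is reported as H = 0, p = 1.
    """
    by = _clean_groups(values, groups)
    if len(by) < 2:
        raise ValueError(f"need >=2 non-empty groups, got {len(by)}")
    samples = list(by.values())
    ns = tuple(len(s) for s in samples)
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return GroupComparisonResult("kruskal-wallis", 0.0, 1.0, ns, df=len(by) - 1)
    h, p = stats.kruskal(*samples)
    return GroupComparisonResult("kruskal-wallis", float(h), float(p), ns, df=len(by) - 1)


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> GroupComparisonResult:
    """Two-sided Mann–Whitney U test.

    The p-value is exact (full enumeration of rank assignments) when both
    samples have n ≤ 8 and there are no ties; otherwise a tie-corrected
    normal approximation with continuity correction is used. ``exact``
    forces the choice.
    """
    x = np.asarray([v for v in x if v is not None and np.isfinite(v)], dtype=float)
    y = np.asarray([v for v in y if v is not None and np.isfinite(v)], dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if exact is None:
        exact = len(x) <= 8 and len(y) <= 8 and not ties
    if exact and ties:
        logger.warning("ties present; falling back to normal approximation")
        exact = False
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparisonResult(
        f"mann-whitney-{method}", float(res.statistic), float(res.pvalue), (len(x), len(y))
    )


def pairwise_wilcoxon(
    values: Sequence[float],
    groups: Sequence[object],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Post hoc pairwise Wilcoxon rank-sum tests over all group pairs.

    Raw two-sided p-values are adjusted jointly across the pairs by
    ``adjust`` ∈ {holm, bonferroni, BH}; adjusted p ≥ raw p always.
    Returns a tidy frame (group1, group2, n1, n2, statistic, p_raw, p_adj).
    """
    if adjust not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method: {adjust!r}")
    by = _clean_groups(values, groups)
    if len(by) < 2:
        raise ValueError(f"need >=2 non-empty groups, got {len(by)}")
    rows = []
    for (g1, x), (g2, y) in itertools.combinations(by.items(), 2):
        res = mann_whitney(x, y)
        rows.append(
            {"group1": str(g1), "group2": str(g2), "n1": len(x), "n2": len(y),
             "statistic": res.statistic, "p_raw": res.p}
        )
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(
        frame["p_raw"].to_numpy(), method=_ADJUST_METHODS[adjust]
    )[1]
    return frame


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation on pairwise-complete observations.

    rho is the Pearson correlation of mid-ranks; p uses the t
    approximation. With fewer than 3 complete pairs, or zero rank variance
    in either variable, rho is reported as absent with a warning.
    """
    xa = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    ya = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    mask = np.isfinite(xa) & np.isfinite(ya)
    n = int(mask.sum())
    if n < 3:
        logger.warning("fewer than 3 complete pairs (n=%d); rho not reported", n)
        return CorrelationResult(("x", "y"), None, None, n)
    xs, ys = xa[mask], ya[mask]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        logger.warning("zero rank variance; rho undefined")
        return CorrelationResult(("x", "y"), None, None, n)
    rho, p = stats.spearmanr(xs, ys)
    return CorrelationResult(("x", "y"), float(rho), float(p), n)


@dataclass
class BatteryReport:
    """Tidy battery output: one row per factor test / correlation."""

    tests: pd.DataFrame
    posthoc: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.tests.to_csv(path, index=False)


_GAS_FIELD = {"CO2": "co2_flux", "N2O": "n2o_flux"}


def run_comparison_battery(
    records: Sequence,
    gases: Sequence[str] = ("CO2", "N2O"),
    adjust: str = "holm",
    alpha: float = ALPHA,
    min_level_n: int = 2,
) -> BatteryReport:
    """The full per-gas comparison battery over harmonized records.

    For each gas, every categorical factor (sampling method, land use,
    climate, trophic state, soil type, hydrological regime, vegetation) is
    tested — Mann–Whitney when two levels are populated, Kruskal–Wallis plus
    a pairwise post hoc when more — and every quantitative covariate is
    screened with Spearman rank correlation, pairwise-complete. Records with
    the flux or the category missing are dropped per test; levels with fewer
    than ``min_level_n`` observations are excluded; factors left with fewer
    than two populated levels are skipped with a warning.
    """
    rows = []
    posthoc: dict[tuple[str, str], pd.DataFrame] = {}
    for gas in gases:
        fluxfield = _GAS_FIELD[gas]
        flux = [getattr(r, fluxfield) for r in records]
        for factor in FACTORS:
            labels = [getattr(r, factor) for r in records]
            by = _clean_groups(flux, labels)
            by = {g: v for g, v in by.items() if len(v) >= min_level_n}
            if len(by) < 2:
                logger.warning("%s ~ %s: <2 populated levels; skipped", gas, factor)
                continue
            vals = np.concatenate(list(by.values()))
            labs = np.concatenate([[g] * len(v) for g, v in by.items()])
            if len(by) == 2:
                res = mann_whitney(by[list(by)[0]], by[list(by)[1]])
            else:
                res = kruskal_wallis(vals, labs)
                posthoc[(gas, factor)] = pairwise_wilcoxon(vals, labs, adjust=adjust)
            rows.append(
                {"gas": gas, "kind": "factor", "name": factor, "test": res.test,
                 "statistic": res.statistic, "p": res.p, "n": int(sum(res.n)),
                 "significant": res.p < alpha}
            )
        covariates = list(COVARIATE_BATTERY)
        covariates.append("n2o_flux" if gas == "CO2" else "ch4_diffusive")
        for cov in covariates:
            cres = spearman(flux, [getattr(r, cov) for r in records])
            if cres.rho is None:
                continue
            rows.append(
                {"gas": gas, "kind": "correlation", "name": cov, "test": "spearman",
                 "statistic": cres.rho, "p": cres.p, "n": cres.n,
                 "significant": cres.p < alpha}
            )
    return BatteryReport(pd.DataFrame(rows), posthoc)
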