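"""Case cleaning, habitat rules, and combination of risk layers.

Combines incidence-based district flags with the deterministic habitat
rule (rural population below 1,200 m in Moist/Wet/Pluvial biotic units)
into per-census-unit high-risk classifications and a populated-high-risk
raster mask (2 km buffers around high-risk centroids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .raster import RasterGrid, require_aligned
from .synthetic_world import BIOTIC_UNITS, CensusUnit

__all__ = [
    "HabitatRule",
    "RiskClassification",
    "DEDUP_KEYS",
    "deduplicate_cases",
    "impute_mean",
    "classify_habitat",
    "habitat_suitability_raster",
    "populated_area_mask",
    "high_risk_districts",
    "combine_risk",
    "population_risk_summary",
]

DEDUP_KEYS = ["age", "sex", "month", "district_id"]

KNOWN_BIOTIC_UNITS = set(BIOTIC_UNITS.values())


@dataclass
class HabitatRule:
    max_elevation_m: float = 1200.0
    suitable_biotic_units: frozenset = frozenset({"Moist", "Wet", "Pluvial"})

    def __post_init__(self) -> None:
        if self.max_elevation_m <= 0:
            raise ValueError("max_elevation_m must be > 0")
        if not self.suitable_biotic_units:
            raise ValueError("suitable_biotic_units must be non-empty")


@dataclass
class RiskClassification:
    """Per-unit flags with reasons, plus the populated-high-risk mask."""

    units: pd.DataFrame  # unit_id, district_id, population, urban, high_risk, reason
    mask: RasterGrid  # boolean raster, 2 km buffer around high-risk units

    def __post_init__(self) -> None:
        bad = self.units[(~self.units["high_risk"]) & (self.units["reason"] != "")]
        if len(bad):
            raise ValueError("reason set on units not flagged high-risk")


def deduplicate_cases(records: pd.DataFrame):
    """Remove exact duplicates on (age, sex, month, district of residence).

    Keeps the first record of each duplicate group in stable input order.
    Records missing any key field are routed to a rejected-records frame
    rather than silently dropped.

    Returns (cleaned, n_removed, rejected).
    """
    missing_cols = [k for k in DEDUP_KEYS if k not in records.columns]
    if missing_cols:
        raise ValueError(f"records lack key columns: {missing_cols}")
    bad = records[DEDUP_KEYS].isna().any(axis=1)
    rejected = records[bad].copy()
    usable = records[~bad]
    cleaned = usable.drop_duplicates(subset=DEDUP_KEYS, keep="first")
    return cleaned.copy(), len(usable) - len(cleaned), rejected


def impute_mean(values, missing_mask=None) -> np.ndarray:
    """Fill missing entries with the arithmetic mean of the observed ones."""
    values = np.asarray(values, dtype=float)
    mask = np.isnan(values) if missing_mask is None else np.asarray(missing_mask, bool)
    if mask.all():
        raise ValueError("all values missing; mean imputation undefined")
    out = values.copy()
    out[mask] = values[~mask].mean()
    return out


def classify_habitat(elevation_m, biotic_unit, rule: HabitatRule | None = None):
    """True iff strictly below the elevation bound AND in a suitable unit."""
    rule = rule or HabitatRule()
    scalar = np.isscalar(biotic_unit) or isinstance(biotic_unit, str)
    units = np.atleast_1d(np.asarray(biotic_unit, dtype=object))
    unknown = sorted({u for u in units if u not in KNOWN_BIOTIC_UNITS})
    if unknown:
        raise ValueError(f"unknown biotic unit(s): {unknown}")
    elev = np.atleast_1d(np.asarray(elevation_m, dtype=float))
    ok = (elev < rule.max_elevation_m) & np.isin(
        units, sorted(rule.suitable_biotic_units)
    )
    return bool(ok[0]) if scalar and ok.size == 1 else ok


def habitat_suitability_raster(
    elevation: RasterGrid, biotic: RasterGrid, rule: HabitatRule | None = None
) -> RasterGrid:
    """Boolean suitability raster from elevation and biotic-unit layers."""
    require_aligned(elevation, biotic)
    codes = biotic.values.astype(int)
    names = np.array([BIOTIC_UNITS[k] for k in sorted(BIOTIC_UNITS)], dtype=object)
    suitable = classify_habitat(
        elevation.values.ravel(), names[codes.ravel()], rule
    ).reshape(elevation.shape)
    return elevation.like(suitable.astype(int), nodata=-1)


def populated_area_mask(
    census_units, grid: RasterGrid, radius: float = 2000.0
) -> RasterGrid:
    """Cells whose centers lie within ``radius`` of any unit centroid."""
    mask = np.zeros(grid.shape, dtype=bool)
    pts = [(cu.x, cu.y) for cu in census_units]
    if pts:
        xs, ys = grid.cell_centers()
        tree = cKDTree(np.column_stack([xs.ravel(), ys.ravel()]))
        hit = tree.query_ball_point(pts, r=radius)
        for idx in hit:
            mask.ravel()[idx] = True  # view write-through: mask is C-contiguous
    return grid.like(mask.astype(int), nodata=-1)


def high_risk_districts(exceedance_probs, cutoff: float = 0.10) -> np.ndarray:
    """Flag districts whose exceedance probability is >= cutoff."""
    probs = np.asarray(exceedance_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("exceedance probabilities must lie in [0, 1]")
    return probs >= cutoff


def combine_risk(
    census_units,
    habitat: RasterGrid,
    flagged_district_ids,
    buffer_radius: float = 2000.0,
) -> RiskClassification:
    """Unit is high-risk iff its district is flagged, or it is rural and
    sits on suitable habitat. The mask buffers high-risk units by 2 km."""
    flagged = set(flagged_district_ids)
    rows = []
    for cu in census_units:
        if not habitat.contains(cu.x, cu.y):
            raise ValueError(f"census unit {cu.unit_id} lies outside the raster")
        r, c = habitat.index_of(cu.x, cu.y)
        suitable = bool(habitat.values[int(r), int(c)])
        by_district = cu.district_id in flagged
        by_habitat = (not cu.urban) and suitable
        if by_district and by_habitat:
            reason = "both"
        elif by_district:
            reason = "district-incidence"
        elif by_habitat:
            reason = "habitat"
        else:
            reason = ""
        rows.append(
            {"unit_id": cu.unit_id, "district_id": cu.district_id,
             "x": cu.x, "y": cu.y, "population": cu.population,
             "urban": cu.urban, "high_risk": bool(reason), "reason": reason}
        )
    units = pd.DataFrame(rows)
    risky = [cu for cu in census_units
             if units.loc[units["unit_id"] == cu.unit_id, "high_risk"].iloc[0]]
    mask = populated_area_mask(risky, habitat, radius=buffer_radius)
    return RiskClassification(units=units, mask=mask)


def population_risk_summary(classification: RiskClassification) -> dict:
    """Population fractions by risk reason (exhaustive partition).

    ``district`` counts units in flagged districts (with or without
    habitat risk), ``habitat_only`` the additional rural-habitat units,
    ``either`` their sum, ``neither`` the rest; district + habitat_only +
    neither = 1.
    """
    units = classification.units
    total = units["population"].sum()
    if total <= 0:
        raise ValueError("total population is zero")
    in_district = units["reason"].isin(["district-incidence", "both"])
    habitat_only = units["reason"] == "habitat"
    frac_district = units.loc[in_district, "population"].sum() / total
    frac_habitat = units.loc[habitat_only, "population"].sum() / total
    return {
        "district": float(frac_district),
        "habitat_only": float(frac_habitat),
        "either": float(frac_district + frac_habitat),
        "neither": float(1.0 - frac_district - frac_habitat),
    }
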