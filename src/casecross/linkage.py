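"""Link daily exposures to matched stratum-days by grid cell and date.

Every stratum-day receives the daily maximum and mean temperature of its
grid cell, a three-level precipitation category, and a holiday indicator.
Exposure values are copied bit-exactly from the weather table; a stratum
with any missing weather day is dropped whole (a partial stratum cannot
contribute to the conditional likelihood) and counted in a warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .holidays import HolidayCalendar, is_holiday

__all__ = ["nearest_cell", "haversine_km", "precip_category", "link"]

logger = logging.getLogger(__name__)

DEFAULT_PRECIP_MEAN_MM = 2.68  # study-period mean daily rainfall used as the wet/wetter cut

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def nearest_cell(lon: float, lat: float, cells: pd.DataFrame):
    """Grid cell whose center is closest (great-circle); ties -> smallest cell_id.

    ``cells`` needs columns ``cell_id, lon, lat``.
    """
    if len(cells) == 0:
        raise ValueError("empty cell set")
    d = haversine_km(lon, lat, cells["lon"].to_numpy(), cells["lat"].to_numpy())
    dmin = d.min()
    candidates = cells.loc[d <= dmin + 1e-12, "cell_id"]
    return candidates.min()


def precip_category(precip_mm, mean_mm: float = DEFAULT_PRECIP_MEAN_MM):
    """Rainfall category: 0 = dry, 1 = below the mean, 2 = at or above the mean.

    The boundary value precip_mm == mean_mm is assigned to category 2 so that
    category 1 is strictly interior (0 < precip < mean).
    """
    if mean_mm <= 0:
        raise ValueError("mean_mm must be positive")
    p = np.asarray(precip_mm, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative precipitation")
    out = np.where(p == 0, 0, np.where(p < mean_mm, 1, 2))
    return int(out) if out.ndim == 0 else out


def link(
    strata: pd.DataFrame,
    weather: pd.DataFrame,
    calendar: HolidayCalendar,
    mean_mm: float = DEFAULT_PRECIP_MEAN_MM,
) -> pd.DataFrame:
    """Attach exposures to every stratum-day.

    Parameters
    ----------
    strata
        Long-format matched strata (``stratum_id, role, date, cell_id`` and
        optionally ``tract_id``).
    weather
        One row per cell-day: ``cell_id, date, tmax_c, tmean_c, precip_mm``.
    calendar
        Holiday table covering every study year (raises otherwise).
    mean_mm
        Rainfall cut for the precipitation categories.

    Returns the linked frame (one row per retained stratum-day) with columns
    ``stratum_id, date, role, cell_id[, tract_id], dtmax_c, dtmean_c,
    precip_cat, holiday``.  Strata with any day missing from ``weather`` are
    dropped entirely, with a logged warning giving the count.
    """
    s = strata.copy()
    s["date"] = pd.to_datetime(s["date"])
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    merged = s.merge(
        w.rename(columns={"tmax_c": "dtmax_c", "tmean_c": "dtmean_c"}),
        on=["cell_id", "date"],
        how="left",
        validate="many_to_one",
    )
    incomplete = merged.loc[merged["dtmax_c"].isna(), "stratum_id"].unique()
    if len(incomplete):
        logger.warning(
            "dropping %d strata with missing weather on at least one day", len(incomplete)
        )
        merged = merged[~merged["stratum_id"].isin(incomplete)].copy()
    merged["precip_cat"] = precip_category(merged["precip_mm"].to_numpy(), mean_mm)
    merged["holiday"] = np.fromiter(
        (is_holiday(d, calendar) for d in merged["date"].dt.date), dtype=bool, count=len(merged)
    )
    keep = ["stratum_id", "date", "role", "cell_id"]
    if "tract_id" in merged.columns:
        keep.append("tract_id")
    keep += ["dtmax_c", "dtmean_c", "precip_cat", "holiday"]
    return merged[keep]
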