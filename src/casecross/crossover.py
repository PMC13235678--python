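"""Time-stratified case-crossover matched strata.

Each fatal-encounter case day is compared with its own control days: every
other date in the same calendar month and year that falls on the same day of
the week, at the same location (grid cell).  This referent scheme yields 3 or
4 control days per case, avoids overlap bias, and conditions out any
confounder that is constant within a location-month (including all individual
characteristics of the person involved).
"""

from __future__ import annotations

import calendar as _calendar
import datetime as dt

import pandas as pd

__all__ = ["control_days", "build_strata"]

STRATA_COLUMNS = ["stratum_id", "role", "date", "cell_id", "tract_id"]


def control_days(case_date: dt.date) -> list[dt.date]:
    """All other same-weekday dates in the case day's month and year, ascending.

    The case day itself is never included.  A Gregorian month has 4 or 5
    occurrences of each weekday, so the result has 3 or 4 dates.
    """
    if isinstance(case_date, dt.datetime):
        case_date = case_date.date()
    n_days = _calendar.monthrange(case_date.year, case_date.month)[1]
    first = dt.date(case_date.year, case_date.month, 1)
    offset = (case_date.weekday() - first.weekday()) % 7
    return [
        dt.date(case_date.year, case_date.month, day)
        for day in range(1 + offset, n_days + 1, 7)
        if day != case_date.day
    ]


def build_strata(events: pd.DataFrame) -> pd.DataFrame:
    """Build one matched stratum per event (no case is ever excluded).

    Parameters
    ----------
    events
        Frame with columns ``event_id``, ``date``, ``cell_id`` and optionally
        ``tract_id``.  ``cell_id`` must be resolved for every event.

    Returns
    -------
    Long-format frame, one row per stratum-day, columns
    ``stratum_id, role, date, cell_id, tract_id`` with ``role`` in
    {"case", "control"}.  Two events on the same cell-day produce two
    distinct strata with identical day sets: each case conditions its own
    stratum.
    """
    required = {"event_id", "date", "cell_id"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events frame missing columns: {sorted(missing)}")
    bad = events.loc[events["cell_id"].isna(), "event_id"].tolist()
    if bad:
        raise ValueError(f"events with unresolved location (cell_id): {bad}")

    has_tract = "tract_id" in events.columns
    rows = []
    for ev in events.itertuples(index=False):
        case_date = pd.Timestamp(ev.date).date()
        tract = getattr(ev, "tract_id", None) if has_tract else None
        rows.append((ev.event_id, "case", case_date, ev.cell_id, tract))
        for d in control_days(case_date):
            rows.append((ev.event_id, "control", d, ev.cell_id, tract))
    out = pd.DataFrame(rows, columns=STRATA_COLUMNS)
    out["date"] = pd.to_datetime(out["date"])
    return out
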