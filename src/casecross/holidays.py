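"""US federal holiday calendar with observed-date shifting.

Holiday adjustment in the temperature model requires a day-level indicator
for "US major holidays".  The canonical choice is the federal holiday list:
eleven holidays, with fixed-date holidays falling on a Saturday observed the
preceding Friday and those falling on a Sunday observed the following Monday.
Juneteenth enters the list in 2021.  A custom list can be supplied instead
via :func:`load_holidays`.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["HolidayCalendar", "us_federal_holidays", "load_holidays", "is_holiday"]


@dataclass(frozen=True)
class HolidayCalendar:
    """A set of holiday dates together with the years it declares coverage for."""

    years: frozenset
    dates: frozenset

    def covers(self, date: dt.date) -> bool:
        return date.year in self.years


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th occurrence (1-based) of ``weekday`` (Mon=0) in a month; n=-1 for last."""
    if n > 0:
        first = dt.date(year, month, 1)
        offset = (weekday - first.weekday()) % 7
        return first + dt.timedelta(days=offset + 7 * (n - 1))
    # last occurrence: walk back from the final day of the month
    last = (dt.date(year, month, 28) + dt.timedelta(days=4)).replace(day=1) - dt.timedelta(days=1)
    return last - dt.timedelta(days=(last.weekday() - weekday) % 7)


def _observed(date: dt.date) -> dt.date:
    """Shift fixed-date holidays: Saturday -> preceding Friday, Sunday -> following Monday."""
    if date.weekday() == 5:
        return date - dt.timedelta(days=1)
    if date.weekday() == 6:
        return date + dt.timedelta(days=1)
    return date


def us_federal_holidays(years: Iterable[int]) -> HolidayCalendar:
    """Build the federal-holiday calendar for the given years.

    Both the actual and the observed date of each fixed-date holiday are
    included, since either day may carry the behavioural shift the adjustment
    is meant to absorb.
    """
    years = sorted(set(int(y) for y in years))
    dates: set[dt.date] = set()
    for y in years:
        fixed = [dt.date(y, 1, 1), dt.date(y, 7, 4), dt.date(y, 11, 11), dt.date(y, 12, 25)]
        if y >= 2021:
            fixed.append(dt.date(y, 6, 19))  # Juneteenth, federal since 2021
        for d in fixed:
            dates.add(d)
            dates.add(_observed(d))
        dates.add(_nth_weekday(y, 1, 0, 3))    # Martin Luther King Jr. Day
        dates.add(_nth_weekday(y, 2, 0, 3))    # Washington's Birthday
        dates.add(_nth_weekday(y, 5, 0, -1))   # Memorial Day
        dates.add(_nth_weekday(y, 9, 0, 1))    # Labor Day
        dates.add(_nth_weekday(y, 10, 0, 2))   # Columbus Day
        dates.add(_nth_weekday(y, 11, 3, 4))   # Thanksgiving
    return HolidayCalendar(years=frozenset(years), dates=frozenset(dates))


def load_holidays(path: str | Path, years: Iterable[int] | None = None) -> HolidayCalendar:
    """Read a holiday list (one ISO date per line; blank lines and # comments ignored).

    ``years`` declares coverage explicitly; by default the span of years
    present in the file is used (an empty file requires explicit ``years``).
    """
    dates = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        dates.add(dt.date.fromisoformat(line))
    if years is None:
        if not dates:
            raise ValueError("empty holiday file: coverage years must be given explicitly")
        ys = {d.year for d in dates}
        years = range(min(ys), max(ys) + 1)
    return HolidayCalendar(years=frozenset(int(y) for y in years), dates=frozenset(dates))


def is_holiday(date: dt.date, calendar: HolidayCalendar) -> bool:
    """True iff ``date`` is in the calendar; raises if the year is outside coverage."""
    if isinstance(date, dt.datetime):
        date = date.date()
    if not calendar.covers(date):
        raise ValueError(f"date {date} outside holiday-table coverage years")
    return date in calendar.dates
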