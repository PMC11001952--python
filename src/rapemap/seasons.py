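"""Season calendars for winter and spring rapeseed.

Winter rapeseed is sown in autumn and flowers the following spring (typically
March); spring rapeseed is sown in April and flowers in July.  All date
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import datetime

WINTER = "winter"
SPRING = "spring"
SEASONS = (WINTER, SPRING)

#: Morphological hole-filling threshold in hectares, by season.  Winter fields
#: in the south are small and scattered (1 ha); spring fields in the north are
#: large and regular (5 ha).
HOLE_THRESHOLD_HA = {WINTER: 1.0, SPRING: 5.0}

#: Plausible peak-flowering day-of-year range, by season (winter: Jan-May,
#: spring: Jun-Aug).  Predictions outside the range are flagged, not clipped.
DOY_RANGE = {WINTER: (1, 151), SPRING: (152, 243)}


def _check(season: str) -> None:
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")


def image_window(season: str, year: int) -> tuple[datetime.date, datetime.date]:
    """Image-acquisition window ``[start, end)`` for a mapping ``year``.

    Winter: November 1 of the preceding year to June 1; spring: April 1 to
    September 1 of the same year.
    """
    _check(season)
    if season == WINTER:
        return datetime.date(year - 1, 11, 1), datetime.date(year, 6, 1)
    return datetime.date(year, 4, 1), datetime.date(year, 9, 1)


def env_window(season: str, year: int) -> tuple[datetime.date, datetime.date]:
    """Environmental-driver window ``[start, end)`` for a mapping ``year``.

    Winter: November 1 of the preceding year to February 1; spring: April 1
    to July 1.
    """
    _check(season)
    if season == WINTER:
        return datetime.date(year - 1, 11, 1), datetime.date(year, 2, 1)
    return datetime.date(year, 4, 1), datetime.date(year, 7, 1)


def window_dates(window: tuple[datetime.date, datetime.date]) -> list[datetime.date]:
    """All calendar days inside a half-open window."""
    start, end = window
    n = (end - start).days
    return [start + datetime.timedelta(days=i) for i in range(n)]


def doy_to_date(doy: int | float, year: int) -> datetime.date:
    """Convert a day-of-year (1-based) of ``year`` to a calendar date."""
    return datetime.date(year, 1, 1) + datetime.timedelta(days=int(round(doy)) - 1)


def date_to_doy(date: datetime.date) -> int:
    return date.timetuple().tm_yday
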