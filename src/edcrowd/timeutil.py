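"""Small time helpers: minute-resolution parsing and HH:MM rendering.

All timestamps in the package are naive local wall-clock times at minute
resolution; daylight-saving duplicated hours are taken at face value because
source ED systems log wall-clock time.
"""

from __future__ import annotations

from datetime import datetime, timedelta

TS_FORMAT = "%Y-%m-%d %H:%M"
DATE_FORMAT = "%Y-%m-%d"

HOUR = timedelta(hours=1)
MINUTE = timedelta(minutes=1)


def parse_ts(text: str) -> datetime:
    """Parse an ISO-8601 ``YYYY-MM-DD HH:MM`` timestamp."""
    return datetime.strptime(text, TS_FORMAT)


def format_ts(ts: datetime) -> str:
    return ts.strftime(TS_FORMAT)


def parse_date(text: str):
    return datetime.strptime(text, DATE_FORMAT).date()


def format_date(d) -> str:
    return d.strftime(DATE_FORMAT)


def floor_minute(ts: datetime) -> datetime:
    """Drop seconds and microseconds (sub-minute times are floored)."""
    return ts.replace(second=0, microsecond=0)


def floor_hour(ts: datetime) -> datetime:
    return ts.replace(minute=0, second=0, microsecond=0)


def is_on_hour(ts: datetime) -> bool:
    return ts.minute == 0 and ts.second == 0 and ts.microsecond == 0


def hours_between(start: datetime, end: datetime) -> float:
    return (end - start).total_seconds() / 3600.0


def format_hhmm(hours: float) -> str:
    """Render a duration in hours as zero-padded ``HH:MM``.

    The duration is rounded to the nearest whole minute; hours may exceed 24
    (durations, not clock times).
    """
    if hours < 0:
        raise ValueError("duration must be non-negative")
    minutes = int(round(hours * 60))
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def parse_hhmm(text: str) -> float:
    """Inverse of :func:`format_hhmm`; returns hours as a float."""
    hh, mm = text.split(":")
    return int(hh) + int(mm) / 60.0
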