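import datetime as _dt

import pytest

from flarediary import (
    DailyEntry,
    ParticipantSeries,
    derive_flare_states,
)

D0 = _dt.date(2020, 1, 1)


def series_from_pattern(pattern: str, pid: str = "P1", threshold: int = 3):
    """Build a participant series (and its flare states) from a day-status
    string: '1' flare-on entry, '0' flare-off entry, 'x' entry without a
    flare score, '.' no entry."""
    entries = []
    for t, c in enumerate(pattern):
        date = D0 + _dt.timedelta(days=t)
        if c == "1":
            entries.append(DailyEntry(pid, date, {"flare": threshold, "pain": 2}))
        elif c == "0":
            entries.append(DailyEntry(pid, date, {"flare": threshold + 1, "pain": 4}))
        elif c == "x":
            entries.append(DailyEntry(pid, date, {"pain": 3}))
        elif c != ".":
            raise ValueError(f"bad pattern char {c!r}")
    series = ParticipantSeries(pid, entries)
    return series, derive_flare_states(series, threshold)


@pytest.fixture
def make_series():
    return series_from_pattern
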