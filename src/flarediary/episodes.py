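"""Flare-episode reconstruction from daily flare states.

An episode is a maximal run of flare-on days, where a single calendar day
with *no diary entry at all* sandwiched between two flare-on days is bridged
into the episode (the one-missing-day rule). A recorded flare-off day — or
any entered day whose flare petal is unscored — always terminates an
episode, and gaps of two or more consecutive missing days are never bridged.
Episode duration is counted in calendar days (end − start + 1), so a bridged
day contributes to duration but not to the recorded flare-day count.
"""
from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .data import FlareState, ParticipantSeries


@dataclass(frozen=True)
class FlareEpisode:
    participant_id: str
    start_date: _dt.date
    end_date: _dt.date
    n_recorded_flare_days: int
    bridged_gap_count: int
    touches_boundary: bool = False

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("episode end precedes start")
        if self.n_recorded_flare_days < 1:
            raise ValueError("episode must contain a recorded flare day")
        if self.duration_days != self.n_recorded_flare_days + self.bridged_gap_count:
            raise ValueError("duration must equal recorded days plus bridged days")


def segment_episodes(
    series: ParticipantSeries, flare_states: Sequence[FlareState]
) -> list[FlareEpisode]:
    """Segment one participant's diary into flare episodes.

    ``flare_states`` must align one-to-one with ``series.entries``. Returns
    episodes sorted by start date. Episodes touching the first or last entry
    day are kept (never truncated) and flagged via ``touches_boundary``.
    """
    if len(flare_states) != len(series.entries):
        raise ValueError("flare_states must align with series entries")
    if not series.entries:
        return []
    entry_dates = {e.date.toordinal() for e in series.entries}
    first = series.entries[0].date.toordinal()
    last = series.entries[-1].date.toordinal()

    episodes: list[FlareEpisode] = []
    start = end = None  # ordinals of the open episode
    n_on = bridged = 0

    def close() -> None:
        nonlocal start, end, n_on, bridged
        if start is not None:
            episodes.append(
                FlareEpisode(
                    series.participant_id,
                    _dt.date.fromordinal(start),
                    _dt.date.fromordinal(end),
                    n_on,
                    bridged,
                    touches_boundary=(start == first or end == last),
                )
            )
        start = end = None
        n_on = bridged = 0

    for entry, state in zip(series.entries, flare_states):
        day = entry.date.toordinal()
        if state.is_flare_on:
            if start is None:
                start = end = day
                n_on = 1
            elif day == end + 1:
                end = day
                n_on += 1
            elif day == end + 2 and (end + 1) not in entry_dates:
                # exactly one intervening calendar day with no diary entry
                end = day
                n_on += 1
                bridged += 1
            else:
                close()
                start = end = day
                n_on = 1
        else:
            # flare-off, or entered day with the flare petal unscored:
            # either way the day carries data and terminates the episode
            close()
    close()
    return episodes


def flare_frequency_interval(
    series: ParticipantSeries,
    episodes: Sequence[FlareEpisode],
    method: Literal["span", "onset"] = "span",
) -> float | None:
    """Mean number of days per flare episode for one participant.

    ``span`` (default): observation span in calendar days — last entry date
    minus first entry date plus one — divided by the episode count.
    ``onset``: mean onset-to-onset gap between consecutive episodes
    (requires at least two episodes).

    Returns None for participants with no episodes (or fewer than two under
    ``onset``); such participants are excluded from frequency summaries.
    """
    if not episodes:
        return None
    if method == "span":
        span = (series.last_date - series.first_date).days + 1
        return span / len(episodes)
    if method == "onset":
        if len(episodes) < 2:
            return None
        starts = sorted(e.start_date.toordinal() for e in episodes)
        return float(np.mean(np.diff(starts)))
    raise ValueError(f"unknown frequency method {method!r}")


@dataclass(frozen=True)
class EpisodeSummary:
    """Pooled episode-duration statistics and per-participant frequency
    statistics (over participants with at least one episode)."""

    n_flares_total: int
    n_participants_with_flare: int
    duration_mean: float | None
    duration_sd: float | None
    duration_min: int | None
    duration_max: int | None
    frequency_interval_mean: float | None
    frequency_interval_sd: float | None
    frequency_interval_min: float | None
    frequency_interval_max: float | None


def _moments(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd


def summarize_episodes(
    episodes_by_participant: dict[str, Sequence[FlareEpisode]],
    series_by_participant: dict[str, ParticipantSeries],
    frequency_method: Literal["span", "onset"] = "span",
) -> EpisodeSummary:
    """Summarize durations over all episodes and frequency intervals over
    participants with >= 1 episode. S.d. uses the n−1 denominator and is
    reported missing when only one observation exists."""
    durations = [
        e.duration_days for eps in episodes_by_participant.values() for e in eps
    ]
    intervals = []
    for pid, eps in episodes_by_participant.items():
        interval = flare_frequency_interval(
            series_by_participant[pid], eps, method=frequency_method
        )
        if interval is not None:
            intervals.append(interval)
    d_mean, d_sd = _moments(durations)
    f_mean, f_sd = _moments(intervals)
    return EpisodeSummary(
        n_flares_total=len(durations),
        n_participants_with_flare=sum(
            1 for eps in episodes_by_participant.values() if eps
        ),
        duration_mean=d_mean,
        duration_sd=d_sd,
        duration_min=min(durations) if durations else None,
        duration_max=max(durations) if durations else None,
        frequency_interval_mean=f_mean,
        frequency_interval_sd=f_sd,
        frequency_interval_min=min(intervals) if intervals else None,
        frequency_interval_max=max(intervals) if intervals else None,
    )
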