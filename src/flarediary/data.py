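"""Core diary data model: daily entries, per-participant series, flare state
derivation and baseline covariate records."""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .catalogue import DEFAULT_CATALOGUE, PetalCatalogue


class DiaryValidationError(ValueError):
    """Raised when diary or baseline input violates the data contract."""


LIKERT_RANGE = (1, 5)

#: Continuous baseline covariates (clinical indices and derived scores).
CONTINUOUS_COVARIATES: tuple[str, ...] = (
    "basmi",
    "basdai",
    "basfi",
    "eq5d",
    "pain_discomfort",
    "anxiety_depression",
    "patient_global",
    "asqol",
    "work_productivity_impairment",
    "activity_impairment",
)

#: Binary (0/1) baseline covariates.
BINARY_COVARIATES: tuple[str, ...] = (
    "employed",
    "female",
    "male",
    "hla_b27_positive",
    "current_smoker",
    "ex_smoker",
    "never_smoker",
    "bdmard_ever",
    "chronic_widespread_pain",
)

SMOKER_COVARIATES = ("current_smoker", "ex_smoker", "never_smoker")


@dataclass
class DailyEntry:
    """A single participant-day of diary scores.

    ``scores`` maps variable name -> integer Likert score in 1..5; variables
    the participant did not score that day are simply absent.
    """

    participant_id: str
    date: _dt.date
    scores: dict[str, int] = field(default_factory=dict)

    def validate(self, catalogue: PetalCatalogue = DEFAULT_CATALOGUE) -> None:
        for name, score in self.scores.items():
            if name not in catalogue:
                raise DiaryValidationError(
                    f"unknown variable {name!r} for participant "
                    f"{self.participant_id} on {self.date}"
                )
            if not isinstance(score, (int,)) or isinstance(score, bool):
                raise DiaryValidationError(
                    f"non-integer score {score!r} for {name!r} on {self.date}"
                )
            if not LIKERT_RANGE[0] <= score <= LIKERT_RANGE[1]:
                raise DiaryValidationError(
                    f"score {score} out of range 1..5 for {name!r} "
                    f"(participant {self.participant_id}, {self.date})"
                )


@dataclass
class ParticipantSeries:
    """Date-ordered daily entries for one participant."""

    participant_id: str
    entries: list[DailyEntry] = field(default_factory=list)
    chosen_optional: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e.date)
        dates = [e.date for e in self.entries]
        if len(set(dates)) != len(dates):
            dup = next(d for i, d in enumerate(dates) if d in dates[:i])
            raise DiaryValidationError(
                f"duplicate date {dup} for participant {self.participant_id}"
            )
        for e in self.entries:
            if e.participant_id != self.participant_id:
                raise DiaryValidationError(
                    f"entry participant id {e.participant_id!r} does not match "
                    f"series id {self.participant_id!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_entry_days(self) -> int:
        return len(self.entries)

    @property
    def first_date(self) -> _dt.date | None:
        return self.entries[0].date if self.entries else None

    @property
    def last_date(self) -> _dt.date | None:
        return self.entries[-1].date if self.entries else None


@dataclass(frozen=True)
class FlareState:
    """Binary flare status of one entry, or undefined when the flare petal
    was not scored that day."""

    is_flare_on: bool | None

    @property
    def defined(self) -> bool:
        return self.is_flare_on is not None


def derive_flare_state(entry: DailyEntry, threshold: int = 3) -> FlareState:
    """Binarize the flare petal: flare-on iff its score <= ``threshold``.

    Scores run 1 (least healthy) to 5; low flare scores mean the participant
    reports being in flare. A missing flare score yields an undefined state,
    which excludes the entry from all flare-conditioned aggregation.
    """
    if not 1 <= threshold <= 5:
        raise ValueError("flare threshold must be in 1..5")
    score = entry.scores.get("flare")
    if score is None:
        return FlareState(None)
    return FlareState(score <= threshold)


def derive_flare_states(
    series: ParticipantSeries, threshold: int = 3
) -> list[FlareState]:
    return [derive_flare_state(e, threshold) for e in series.entries]


@dataclass
class BaselineRecord:
    """Baseline clinical covariates for one participant.

    Continuous covariates are real scores or None (missing); binary
    covariates are 0/1 or None. Missing cells are never coerced to zero.
    """

    participant_id: str
    continuous: dict[str, float | None] = field(default_factory=dict)
    binary: dict[str, int | None] = field(default_factory=dict)

    def validate(self) -> None:
        for name in self.continuous:
            if name not in CONTINUOUS_COVARIATES:
                raise DiaryValidationError(f"unknown continuous covariate {name!r}")
        for name, value in self.binary.items():
            if name not in BINARY_COVARIATES:
                raise DiaryValidationError(f"unknown binary covariate {name!r}")
            if value is not None and value not in (0, 1):
                raise DiaryValidationError(
                    f"binary covariate {name!r} must be 0/1, got {value!r}"
                )
        smoker = [self.binary.get(k) for k in SMOKER_COVARIATES]
        present = [v for v in smoker if v is not None]
        if present and len(present) == len(SMOKER_COVARIATES):
            if sum(present) != 1:
                raise DiaryValidationError(
                    f"smoker categories must be mutually exclusive for "
                    f"participant {self.participant_id}: {smoker}"
                )
        female, male = self.binary.get("female"), self.binary.get("male")
        if female is not None and male is not None and female + male != 1:
            raise DiaryValidationError(
                f"female/male indicators must be complementary for "
                f"participant {self.participant_id}"
            )
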