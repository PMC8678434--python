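"""Catalogue of the diary variables ("petals") tracked by participants.

Every participant scores 8 fixed variables daily plus 2 optional variables
chosen at enrolment, each on a 5-point Likert scale where 1 is the least
healthy/desirable outcome and 5 the most healthy.
"""
from __future__ import annotations

from dataclasses import dataclass, field


FIXED_VARIABLES: tuple[str, ...] = (
    "pain",
    "mood",
    "fatigue",
    "sleep quality",
    "stress",
    "flare",
    "recommended exercise",
    "anti-inflammatory use",
)

OPTIONAL_VARIABLES: tuple[str, ...] = (
    "caffeine intake",
    "hot flushes",
    "adherence to medication",
    "screen time",
    "confidence in self-management",
    "eyesight",
    "hydration",
    "chest pain",
    "flare of psoriasis",
    "impact of menstrual cycle",
    "red painful eyes",
    "smoking habits",
    "blood in stool",
)

#: The seven fixed symptom/behaviour petals used for clustering; the flare
#: petal itself is the conditioning variable and is never a feature.
CLUSTERING_VARIABLES: tuple[str, ...] = (
    "pain",
    "fatigue",
    "sleep quality",
    "recommended exercise",
    "mood",
    "anti-inflammatory use",
    "stress",
)

#: Row order of the per-variable paired-test report (fixed symptom petals
#: first, then the optional petals).
REPORT_VARIABLE_ORDER: tuple[str, ...] = CLUSTERING_VARIABLES + OPTIONAL_VARIABLES


@dataclass(frozen=True)
class PetalCatalogue:
    """The set of known diary variables.

    Parameters
    ----------
    fixed_variables : tuple of str
        Exactly 8 names tracked by every participant; must include "flare".
    optional_variables : tuple of str
        Exactly 13 names from which each participant chooses 2.
    """

    fixed_variables: tuple[str, ...] = FIXED_VARIABLES
    optional_variables: tuple[str, ...] = OPTIONAL_VARIABLES

    def __post_init__(self) -> None:
        if len(self.fixed_variables) != 8:
            raise ValueError("catalogue requires exactly 8 fixed variables")
        if len(self.optional_variables) != 13:
            raise ValueError("catalogue requires exactly 13 optional variables")
        names = self.fixed_variables + self.optional_variables
        if len(set(names)) != len(names):
            raise ValueError("catalogue variable names must be unique")
        if "flare" not in self.fixed_variables:
            raise ValueError('"flare" must be a fixed variable')

    @property
    def all_variables(self) -> tuple[str, ...]:
        return self.fixed_variables + self.optional_variables

    def __contains__(self, name: str) -> bool:
        return name in self.fixed_variables or name in self.optional_variables


DEFAULT_CATALOGUE = PetalCatalogue()
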