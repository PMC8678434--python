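"""Per-participant flare-conditioned features and the normalized matrix fed
to clustering.

For each variable the participant's entries are split by flare state
(derived from the flare petal); the mean score during flare (``mean_on``)
and outside flare (``mean_off``) give the difference feature
``diff = mean_on − mean_off``, capturing the effect of a flare on that
variable for that participant. Entries whose flare state is undefined are
excluded entirely. Difference features over the clustering variable set are
min-max rescaled column-wise to [−1, 1] before clustering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogue import CLUSTERING_VARIABLES, DEFAULT_CATALOGUE, PetalCatalogue
from .data import FlareState, ParticipantSeries


@dataclass
class FeatureRow:
    """Flare-on/off means, counts and differences for one participant."""

    participant_id: str
    mean_on: dict[str, float] = field(default_factory=dict)
    mean_off: dict[str, float] = field(default_factory=dict)
    n_on: dict[str, int] = field(default_factory=dict)
    n_off: dict[str, int] = field(default_factory=dict)
    n_entry_days: int = 0

    def diff(self, variable: str) -> float | None:
        """mean_on − mean_off, or None unless both sides were observed."""
        if variable in self.mean_on and variable in self.mean_off:
            return self.mean_on[variable] - self.mean_off[variable]
        return None


def aggregate_flare_features(
    series: ParticipantSeries,
    flare_states: Sequence[FlareState],
    catalogue: PetalCatalogue = DEFAULT_CATALOGUE,
) -> FeatureRow:
    """Aggregate one participant's diary to flare-on/off mean scores.

    For each variable, entries where the variable is scored *and* the flare
    state is defined contribute to the mean for their flare state; all other
    entries are ignored for that variable. Missing on/off combinations yield
    missing features, never zeros.
    """
    if len(flare_states) != len(series.entries):
        raise ValueError("flare_states must align with series entries")
    sums: dict[tuple[str, bool], float] = {}
    counts: dict[tuple[str, bool], int] = {}
    for entry, state in zip(series.entries, flare_states):
        if not state.defined:
            continue
        on = bool(state.is_flare_on)
        for variable, score in entry.scores.items():
            key = (variable, on)
            sums[key] = sums.get(key, 0.0) + score
            counts[key] = counts.get(key, 0) + 1
    row = FeatureRow(series.participant_id, n_entry_days=len(series.entries))
    for (variable, on), n in counts.items():
        mean = sums[(variable, on)] / n
        if on:
            row.mean_on[variable] = mean
            row.n_on[variable] = n
        else:
            row.mean_off[variable] = mean
            row.n_off[variable] = n
    return row


def eligibility_filter(
    rows: Sequence[FeatureRow],
    min_days: int = 10,
    require_diff_variables: Sequence[str] | None = None,
) -> list[FeatureRow]:
    """Retain participants with at least ``min_days`` distinct entry dates.

    When ``require_diff_variables`` is given (the clustering case), a
    participant must additionally have a defined difference feature — at
    least one flare-on and one flare-off observation — for every listed
    variable; participants with no flares ever recorded therefore drop out
    of clustering here.
    """
    if min_days < 1:
        raise ValueError("min_days must be >= 1")
    kept = [r for r in rows if r.n_entry_days >= min_days]
    if require_diff_variables is not None:
        kept = [
            r
            for r in kept
            if all(r.diff(v) is not None for v in require_diff_variables)
        ]
    return kept


def feature_frame(
    rows: Sequence[FeatureRow], variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tabulate rows as a DataFrame with ``<var>_flare_on``, ``<var>_flare_off``
    and ``<var>_diff`` columns, indexed by participant_id."""
    if variables is None:
        variables = list(CLUSTERING_VARIABLES)
    data: dict[str, list[float]] = {}
    for v in variables:
        data[f"{v}_flare_on"] = [r.mean_on.get(v, np.nan) for r in rows]
        data[f"{v}_flare_off"] = [r.mean_off.get(v, np.nan) for r in rows]
        data[f"{v}_diff"] = [
            d if (d := r.diff(v)) is not None else np.nan for r in rows
        ]
    return pd.DataFrame(data, index=pd.Index([r.participant_id for r in rows], name="participant_id"))


@dataclass
class NormalizedFeatureMatrix:
    """Column-rescaled difference-feature matrix, values in [−1, 1].

    ``column_min``/``column_max`` record the pre-scaling extremes so the map
    is invertible; degenerate (constant) columns are set to all zeros and
    flagged.
    """

    participant_ids: list[str]
    variables: list[str]
    values: np.ndarray
    column_min: np.ndarray
    column_max: np.ndarray
    degenerate: np.ndarray  # boolean per column
    scheme: str = "minmax"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.participant_ids, name="participant_id"),
            columns=[f"{v}_diff_norm" for v in self.variables],
        )


def normalize_features(
    diff_matrix: pd.DataFrame, scheme: str = "minmax"
) -> NormalizedFeatureMatrix:
    """Rescale each difference column into [−1, 1].

    ``minmax`` (default): x ↦ 2·(x − min)/(max − min) − 1, so every
    non-degenerate column attains both −1 and +1. ``maxabs``: x ↦ x/max|x|,
    preserving the sign and zero of the raw differences. Constant columns
    map to all zeros and are flagged degenerate under either scheme.
    """
    if diff_matrix.isna().any().any():
        raise ValueError(
            "normalize_features requires a complete-case matrix; apply "
            "eligibility_filter with require_diff_variables first"
        )
    X = diff_matrix.to_numpy(dtype=float)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    degenerate = hi == lo
    out = np.zeros_like(X)
    if scheme == "minmax":
        span = np.where(degenerate, 1.0, hi - lo)
        out = 2.0 * (X - lo) / span - 1.0
    elif scheme == "maxabs":
        scale = np.maximum(np.abs(lo), np.abs(hi))
        degenerate = scale == 0
        out = X / np.where(degenerate, 1.0, scale)
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    out[:, degenerate] = 0.0
    variables = [c.removesuffix("_diff") for c in diff_matrix.columns]
    return NormalizedFeatureMatrix(
        participant_ids=[str(i) for i in diff_matrix.index],
        variables=variables,
        values=out,
        column_min=lo,
        column_max=hi,
        degenerate=degenerate,
        scheme=scheme,
    )
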